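import numpy as np
import pytest

from radbed import DVHShapeSpec, example_cases, gen_oar_dvh, gen_target_dvh


@pytest.fixture(scope="session")
def cases():
    return example_cases(seed=0)


@pytest.fixture
def prostate_plan(cases):
    return cases["prostate"].plan


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_oar_curve(rng, name="OAR"):
    """A randomized synthetic OAR cumulative curve (percent volumes)."""
    spec = DVHShapeSpec(
        "oar",
        characteristic_dose=float(rng.uniform(5, 40)),
        sigma=float(rng.uniform(1, 3)),
        hot_spot_fraction=float(rng.uniform(0, 0.3)),
        grid_step=float(rng.uniform(0.2, 1.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return gen_oar_dvh(spec, structure_name=name)


def random_target_curve(rng, name="PTV"):
    spec = DVHShapeSpec(
        "target",
        characteristic_dose=float(rng.uniform(40, 80)),
        sigma=float(rng.uniform(0.5, 2)),
        hot_spot_fraction=float(rng.uniform(0, 0.1)),
        grid_step=float(rng.uniform(0.2, 0.8)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return gen_target_dvh(spec, structure_name=name)
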