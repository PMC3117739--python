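"""Synthetic DVH / plan generators and the three worked clinical cases.

Real treatment-planning DVHs are patient data and are not shipped;
everything here is generated.  Target structures get a steep sigmoid
cumulative DVH around the prescription dose (emulating the usual
planning goal of covering >= 95 % of the volume with the prescribed
dose, with small controlled hot/cold spots); organs at risk get a long
low-dose tail (a stretched-exponential decay, optionally with a
higher-dose shoulder mimicking partial overlap with the target).

Generation is pure: the same :class:`DVHShapeSpec` (including its seed)
always produces bit-identical arrays.

:func:`example_cases` builds three simultaneous-integrated-boost
prescriptions commonly used as benchmarks — a prostate + pelvic-nodes
case (80 Gy / 40 fx reference), a three-level head & neck case
(69.96 Gy at 2.12 Gy/fx, 33 fx reference) and a hypofractionated lung
case (50 Gy / 5 fx boost reference) — each with a matched synthetic
plan, so every pipeline is exercisable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io import DVHCurve, Plan, write_dvh
from .lqm import Schedule, SIBPrescription, TargetPrescription

__all__ = [
    "DVHShapeSpec",
    "gen_target_dvh",
    "gen_oar_dvh",
    "gen_plan",
    "ExampleCase",
    "example_cases",
    "write_fixture_tree",
]


@dataclass(frozen=True)
class DVHShapeSpec:
    """Shape parameters for one synthetic structure.

    characteristic_dose : prescription dose (targets) or the decay
        scale of the low-dose tail (OARs), in Gy.
    sigma : sigmoid steepness (targets) / shoulder width (OARs), Gy.
    hot_spot_fraction / cold_spot_fraction : small volume fractions
        pushed above / below the prescription plateau (targets) or into
        the high-dose shoulder (OARs).
    grid_step : dose grid spacing, Gy.
    seed : RNG seed; generation is deterministic given the spec.
    """

    kind: str  # 'target' | 'oar'
    characteristic_dose: float
    sigma: float = 1.0
    hot_spot_fraction: float = 0.02
    cold_spot_fraction: float = 0.0
    grid_step: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("target", "oar"):
            raise ParameterError(f"kind must be 'target' or 'oar', got {self.kind!r}")
        if not self.characteristic_dose > 0:
            raise ParameterError("characteristic_dose must be > 0")
        if not self.sigma > 0:
            raise ParameterError("sigma must be > 0")
        if not self.grid_step > 0:
            raise ParameterError("grid_step must be > 0")
        for name in ("hot_spot_fraction", "cold_spot_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ParameterError(f"{name} must lie in [0, 0.5), got {v}")


def gen_target_dvh(
    spec: DVHShapeSpec, structure_name: str = "PTV", total_volume_cc: float | None = None
) -> DVHCurve:
    """Cumulative sigmoid target DVH with V(prescription) >= 95 %."""
    if spec.kind != "target":
        raise ParameterError("gen_target_dvh needs a 'target' spec")
    rng = np.random.default_rng(spec.seed)
    presc = spec.characteristic_dose
    sigma = spec.sigma * float(rng.uniform(0.85, 1.15))
    # place the sigmoid midpoint so that V(presc) sits at 95% plus margin
    margin = float(rng.uniform(0.3, 0.8)) * sigma
    mid = presc + sigma * np.log(19.0) + margin
    top = mid + 8.0 * sigma * (1.0 + spec.hot_spot_fraction * 10.0)
    dose = np.arange(0.0, top + spec.grid_step, spec.grid_step)
    vol = 1.0 / (1.0 + np.exp((dose - mid) / sigma))
    if spec.hot_spot_fraction > 0:
        # a small hot tail: shallow sigmoid carrying the hot-spot volume
        hot_mid = mid + 4.0 * sigma
        vol = (1.0 - spec.hot_spot_fraction) * vol + spec.hot_spot_fraction / (
            1.0 + np.exp((dose - hot_mid) / (2.0 * sigma))
        )
    if spec.cold_spot_fraction > 0:
        cold_mid = presc * float(rng.uniform(0.5, 0.8))
        vol = (1.0 - spec.cold_spot_fraction) * vol + spec.cold_spot_fraction / (
            1.0 + np.exp((dose - cold_mid) / sigma)
        )
    vol = 100.0 * vol / vol[0]
    vol[vol < 1e-10] = 0.0
    return DVHCurve(
        structure_name=structure_name,
        kind="cumulative",
        dose_gy=dose,
        volume=vol,
        volume_unit="percent",
        total_volume_cc=total_volume_cc,
    )


def gen_oar_dvh(
    spec: DVHShapeSpec, structure_name: str = "OAR", total_volume_cc: float | None = None
) -> DVHCurve:
    """Cumulative OAR DVH: long low-dose tail, optional high-dose shoulder."""
    if spec.kind != "oar":
        raise ParameterError("gen_oar_dvh needs an 'oar' spec")
    rng = np.random.default_rng(spec.seed)
    scale = spec.characteristic_dose * float(rng.uniform(0.85, 1.15))
    p = float(rng.uniform(1.2, 2.0))  # stretched-exponential shape
    shoulder = spec.hot_spot_fraction
    sh_mid = scale * 2.5
    top = sh_mid + 8.0 * spec.sigma if shoulder > 0 else scale * 3.2
    dose = np.arange(0.0, top + spec.grid_step, spec.grid_step)
    vol = (1.0 - shoulder) * np.exp(-((dose / scale) ** p))
    if shoulder > 0:
        # partial-overlap shoulder mimicking OAR abutting the target
        vol = vol + shoulder / (1.0 + np.exp((dose - sh_mid) / spec.sigma))
    # soft terminal cutoff: no volume lingers near the grid top
    vol = vol / (1.0 + np.exp((dose - 0.9 * top) / (0.03 * top)))
    vol = 100.0 * vol / vol[0]
    vol[vol < 1e-10] = 0.0
    return DVHCurve(
        structure_name=structure_name,
        kind="cumulative",
        dose_gy=dose,
        volume=vol,
        volume_unit="percent",
        total_volume_cc=total_volume_cc,
    )


def gen_plan(
    plan_label: str,
    patient_id: str,
    schedule: Schedule,
    targets: dict[str, DVHShapeSpec],
    oars: dict[str, DVHShapeSpec],
    source_dialect: str = "canonical",
) -> Plan:
    """Assemble a synthetic plan from per-structure shape specs."""
    curves: dict[str, DVHCurve] = {}
    for name, spec in targets.items():
        curves[name] = gen_target_dvh(spec, structure_name=name)
    for name, spec in oars.items():
        curves[name] = gen_oar_dvh(spec, structure_name=name)
    return Plan(
        plan_label=plan_label,
        patient_id=patient_id,
        schedule=schedule,
        curves=curves,
        source_dialect=source_dialect,
    )


@dataclass(frozen=True)
class ExampleCase:
    """A worked SIB case: prescription plus a matched synthetic plan."""

    label: str
    prescription: SIBPrescription
    plan: Plan


def example_cases(seed: int = 0) -> dict[str, ExampleCase]:
    """The three benchmark SIB cases with matched synthetic plans.

    prostate : reference prostate 80 Gy / 40 fx at 2 Gy/fx; pelvic
        nodes originally 50 Gy at 2 Gy/fx; alpha/beta 1.5 Gy for both.
    head_neck : reference PGTV 69.96 Gy / 33 fx at 2.12 Gy/fx; PCTV
        59.36 Gy and PETV 53 Gy, both at 2.12 Gy/fx (sequential
        schedule: 25 + 3 + 5 fractions); tumor alpha/beta 10 Gy.
    lung : hypofractionated; reference boost 50 Gy / 5 fx at 10 Gy/fx;
        PTV originally 40 Gy at 10 Gy/fx; alpha/beta 10 Gy.

    The matched plans put each target's synthetic DVH at its prescribed
    dose under the reference schedule, with case-typical OARs.
    """
    s = int(seed)

    prostate_rx = SIBPrescription(
        targets=(
            TargetPrescription("prostate", Schedule(80.0, 2.0, 40), 1.5),
            TargetPrescription("pelvic nodes", Schedule(50.0, 2.0, 25), 1.5),
        ),
        reference_index=0,
    )
    prostate_plan = gen_plan(
        "prostate SIB", "case-prostate", prostate_rx.reference.schedule,
        targets={
            "prostate": DVHShapeSpec("target", 80.0, sigma=0.8, seed=s + 1),
            "pelvic nodes": DVHShapeSpec("target", 58.88, sigma=1.0, seed=s + 2),
        },
        oars={
            "rectum": DVHShapeSpec("oar", 25.0, sigma=2.0, hot_spot_fraction=0.15, seed=s + 3),
            "bladder": DVHShapeSpec("oar", 22.0, sigma=2.0, hot_spot_fraction=0.10, seed=s + 4),
            "femoral head": DVHShapeSpec("oar", 12.0, seed=s + 5),
            "intestine": DVHShapeSpec("oar", 10.0, seed=s + 6),
        },
    )

    hn_rx = SIBPrescription(
        targets=(
            TargetPrescription("PGTV", Schedule.from_fractions(2.12, 33), 10.0),
            TargetPrescription("PCTV", Schedule.from_fractions(2.12, 28), 10.0),
            TargetPrescription("PETV", Schedule.from_fractions(2.12, 25), 10.0),
        ),
        reference_index=0,
    )
    hn_plan = gen_plan(
        "head-neck SIB", "case-hn", hn_rx.reference.schedule,
        targets={
            "PGTV": DVHShapeSpec("target", 69.96, sigma=0.8, seed=s + 11),
            "PCTV": DVHShapeSpec("target", 60.76, sigma=0.9, seed=s + 12),
            "PETV": DVHShapeSpec("target", 55.05, sigma=1.0, seed=s + 13),
        },
        oars={
            "spinal cord": DVHShapeSpec("oar", 12.0, sigma=2.0, seed=s + 14),
            "brain stem": DVHShapeSpec("oar", 10.0, seed=s + 15),
            "parotid": DVHShapeSpec("oar", 14.0, sigma=2.5, hot_spot_fraction=0.12, seed=s + 16),
            "larynx": DVHShapeSpec("oar", 16.0, seed=s + 17),
        },
    )

    lung_rx = SIBPrescription(
        targets=(
            TargetPrescription("boost", Schedule(50.0, 10.0, 5), 10.0),
            TargetPrescription("PTV", Schedule(40.0, 10.0, 4), 10.0),
        ),
        reference_index=0,
    )
    lung_plan = gen_plan(
        "lung SIB", "case-lung", lung_rx.reference.schedule,
        targets={
            "boost": DVHShapeSpec("target", 50.0, sigma=0.6, seed=s + 21),
            "PTV": DVHShapeSpec("target", 43.01, sigma=0.7, seed=s + 22),
        },
        oars={
            "lung": DVHShapeSpec("oar", 6.0, sigma=1.5, hot_spot_fraction=0.05, seed=s + 23),
            "spinal cord": DVHShapeSpec("oar", 5.0, seed=s + 24),
            "esophagus": DVHShapeSpec("oar", 7.0, seed=s + 25),
            "heart": DVHShapeSpec("oar", 6.0, seed=s + 26),
        },
    )

    return {
        "prostate": ExampleCase("prostate", prostate_rx, prostate_plan),
        "head_neck": ExampleCase("head_neck", hn_rx, hn_plan),
        "lung": ExampleCase("lung", lung_rx, lung_plan),
    }


def write_fixture_tree(root_dir, seed: int = 0) -> list[str]:
    """Write every example-case plan in every dialect under ``root_dir``.

    Layout: ``root_dir/<case>/<case>_<dialect>.dvh`` — an importable
    patient-directory tree.  Returns the written paths.
    """
    from pathlib import Path

    from .io import DIALECTS

    root = Path(root_dir)
    written: list[str] = []
    for name, case in example_cases(seed).items():
        folder = root / name
        folder.mkdir(parents=True, exist_ok=True)
        for dialect in DIALECTS():
            path = folder / f"{name}_{dialect}.dvh"
            write_dvh(case.plan, path, dialect)
            written.append(str(path))
    return written
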