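"""Poisson TCP, LKB NTCP with effective-volume reduction, and P+."""

import dataclasses
import math

import numpy as np
import pytest

import radbed as rb
from radbed.analysis import to_differential
from radbed.errors import ParameterError, RadbedError

from _naive import naive_ntcp, naive_p_plus, naive_tcp
from conftest import random_oar_curve, random_target_curve

TUMOR = rb.TumorLQParams(alpha_beta=10.0, alpha=0.3, clonogen_number=1e7)


def uniform_diff_curve(dose, name="u"):
    """Differential curve with all volume in one bin at `dose`."""
    eps = max(1.0, dose * 0.01)
    return rb.DVHCurve(
        name, "differential", np.array([max(0.0, dose - eps), dose]),
        np.array([0.0, 100.0]),
    )


class TestTcpPoisson:
    def test_zero_dose_gives_exp_minus_nstar(self):
        c = rb.DVHCurve(
            "z", "differential", np.array([0.0, 1.0]), np.array([100.0, 0.0])
        )
        params = rb.TumorLQParams(10.0, alpha=0.3, clonogen_number=5.0)
        assert rb.tcp_poisson(c, params) == pytest.approx(math.exp(-5.0), rel=1e-12)

    def test_uniform_60gy_at_2gy_per_fx(self):
        # hand chain: ln sf = -0.3*60*1.2 = -21.6; TCP = exp(-1e7 * e^-21.6)
        c = uniform_diff_curve(60.0)
        expected = math.exp(-1e7 * math.exp(-21.6))
        assert rb.tcp_poisson(c, TUMOR) == pytest.approx(expected, rel=1e-12)
        assert rb.tcp_poisson(c, TUMOR) == pytest.approx(0.99585, abs=5e-6)

    def test_monotone_in_dose_scale(self, rng):
        c = to_differential(random_target_curve(rng))
        up = dataclasses.replace(c, dose_gy=c.dose_gy * 1.01)
        assert rb.tcp_poisson(up, TUMOR) > rb.tcp_poisson(c, TUMOR)

    def test_requires_differential_and_tcp_params(self, rng):
        cum = random_target_curve(rng)
        with pytest.raises(RadbedError, match="differential"):
            rb.tcp_poisson(cum, TUMOR)
        with pytest.raises(ParameterError, match="required"):
            rb.tcp_poisson(to_differential(cum), rb.TumorLQParams(10.0))


class TestEffectiveVolume:
    def test_uniform_whole_organ_is_one(self):
        assert rb.effective_volume(uniform_diff_curve(50.0), 0.5) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_half_volume_at_half_dose_n1(self):
        c = rb.DVHCurve(
            "h", "differential", np.array([30.0, 60.0]), np.array([50.0, 50.0])
        )
        assert rb.effective_volume(c, 1.0) == pytest.approx(0.75, rel=1e-12)

    def test_half_volume_at_half_dose_n025(self):
        c = rb.DVHCurve(
            "h", "differential", np.array([30.0, 60.0]), np.array([50.0, 50.0])
        )
        # 0.5 + 0.5 * (1/2)^(1/0.25) = 0.53125
        assert rb.effective_volume(c, 0.25) == pytest.approx(0.53125, rel=1e-12)

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ParameterError, match="volume_exponent"):
            rb.effective_volume(uniform_diff_curve(50.0), 0.0)

    def test_scale_invariance_of_volumes(self, rng):
        """Multiplying all volumes by a constant changes nothing."""
        c = to_differential(random_oar_curve(rng))
        scaled = dataclasses.replace(c, volume=c.volume * 3.7, volume_unit="cc")
        for n in (0.1, 0.5, 1.0):
            assert rb.effective_volume(scaled, n) == pytest.approx(
                rb.effective_volume(c, n), rel=1e-12
            )


class TestTd50AndProbit:
    def test_whole_organ_identity(self):
        assert rb.td50_at_veff(80.0, 1.0, 0.5) == 80.0

    def test_power_law_value(self):
        assert rb.td50_at_veff(80.0, 0.25, 0.5) == pytest.approx(160.0, rel=1e-12)

    def test_monotone_decreasing_in_veff(self):
        vals = [rb.td50_at_veff(80.0, v, 0.3) for v in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_ntcp_half_at_td50(self):
        for m in (0.05, 0.15, 0.5):
            for td50 in (20.0, 80.0):
                assert rb.ntcp_lkb(td50, td50, m) == 0.5

    def test_ntcp_one_sigma(self):
        # s = 1: Phi(1) = 0.841345
        assert rb.ntcp_lkb(88.0, 80.0, 0.1) == pytest.approx(0.8413447, abs=1e-6)

    def test_ntcp_vanishes_at_zero_dose(self):
        assert rb.ntcp_lkb(0.0, 80.0, 0.1) < 1e-12

    def test_bad_inputs(self):
        with pytest.raises(ParameterError):
            rb.ntcp_lkb(50.0, 80.0, 0.0)
        with pytest.raises(ParameterError):
            rb.td50_at_veff(80.0, 0.0, 0.5)


class TestNtcpFromDvh:
    def test_uniform_at_td50_gives_half(self):
        params = rb.OARLKBParams(3.0, 80.0, 0.15, 0.5)
        # uniform whole-organ NTD2 dose equal to TD50(1):
        # deliver exactly 2 Gy/fx so NTD2 == physical dose
        c = uniform_diff_curve(80.0)
        assert rb.ntcp_from_dvh(c, 40, params) == pytest.approx(0.5, abs=1e-12)

    def test_equals_manual_chain(self, rng):
        params = rb.OARLKBParams(3.0, 80.0, 0.15, 0.12)
        c = random_oar_curve(rng)
        diff = to_differential(c)
        ntd2 = rb.ntd2_transform(diff, 30, params.alpha_beta)
        veff = rb.effective_volume(ntd2, params.volume_exponent)
        td50 = rb.td50_at_veff(params.td50_whole, veff, params.volume_exponent)
        nz = ntd2.volume > 0
        expected = rb.ntcp_lkb(float(ntd2.dose_gy[nz][-1]), td50, params.slope_m)
        assert rb.ntcp_from_dvh(c, 30, params) == pytest.approx(expected, abs=1e-15)

    def test_serialish_monotone_in_spared_volume(self, rng):
        """Shrinking all volume except the hottest bin lowers veff and NTCP."""
        params = rb.OARLKBParams(3.0, 60.0, 0.15, 0.3)
        d = np.array([10.0, 30.0, 58.0])
        v1 = np.array([30.0, 40.0, 30.0])
        v2 = np.array([60.0, 10.0, 30.0])  # same hottest bin, colder elsewhere
        c1 = rb.DVHCurve("a", "differential", d, v1)
        c2 = rb.DVHCurve("b", "differential", d, v2)
        n1, n2 = rb.ntcp_from_dvh(c1, 20, params), rb.ntcp_from_dvh(c2, 20, params)
        assert n2 < n1


class TestTherapeuticGain:
    def test_no_oars(self):
        assert rb.therapeutic_gain(0.7, []) == 0.7

    def test_certain_complication_zeroes_gain(self):
        assert rb.therapeutic_gain(0.9, [0.3, 1.0]) == 0.0

    def test_product_value(self):
        assert rb.therapeutic_gain(0.8, [0.1, 0.2]) == pytest.approx(0.576, rel=1e-12)

    def test_difference_form(self):
        assert rb.therapeutic_gain(0.8, [0.1, 0.2], method="difference") == (
            pytest.approx(0.5, rel=1e-12)
        )
        assert rb.therapeutic_gain(0.2, [0.3, 0.2], method="difference") == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            rb.therapeutic_gain(1.2, [])
        with pytest.raises(ParameterError):
            rb.therapeutic_gain(0.5, [-0.1])


class TestPipelineAgainstNaiveOracle:
    def test_whole_pipeline_matches_straight_line_evaluation(self, rng):
        """Composed operations equal an independent naive implementation.

        This mirrors validating the tool against a hand-built
        spreadsheet: 200 random synthetic DVHs, agreement to 1e-9.
        """
        params = rb.OARLKBParams(3.0, 70.0, 0.15, 0.25)
        worst = 0.0
        for i in range(100):
            t = random_target_curve(rng)
            o = random_oar_curve(rng)
            n = int(rng.integers(5, 45))
            tcp = rb.tcp_poisson(
                rb.ntd2_transform(to_differential(t), n, TUMOR.alpha_beta), TUMOR
            )
            ntcp = rb.ntcp_from_dvh(o, n, params)
            pp = rb.therapeutic_gain(tcp, [ntcp])
            tcp_n = naive_tcp(list(t.dose_gy), list(t.volume), n, TUMOR.alpha,
                              TUMOR.alpha_beta, TUMOR.clonogen_number)
            ntcp_n = naive_ntcp(list(o.dose_gy), list(o.volume), n,
                                params.alpha_beta, params.td50_whole,
                                params.slope_m, params.volume_exponent)
            pp_n = naive_p_plus(tcp_n, [ntcp_n])
            worst = max(worst, abs(tcp - tcp_n), abs(ntcp - ntcp_n), abs(pp - pp_n))
        assert worst < 1e-9


class TestDoseResponse:
    @pytest.fixture
    def setup(self, prostate_plan):
        tumor = rb.TumorLQParams(1.5, alpha=0.15, clonogen_number=1e6)
        oars = {
            "rectum": rb.OARLKBParams(3.0, 80.0, 0.15, 0.12),
            "bladder": rb.OARLKBParams(3.0, 80.0, 0.11, 0.5),
        }
        return prostate_plan, tumor, oars

    def test_identity_scale_reproduces_point_estimates(self, setup):
        plan, tumor, oars = setup
        res = rb.dose_response_curves(plan, "prostate", tumor, oars, [1.0])
        pt = res.points[0]
        assert pt.prescribed_dose == pytest.approx(plan.schedule.total_dose)
        direct_tcp = rb.tcp_poisson(
            rb.ntd2_transform(
                to_differential(plan.curves["prostate"]), 40, tumor.alpha_beta
            ),
            tumor,
        )
        assert pt.tcp == pytest.approx(direct_tcp, rel=1e-12)
        for name, p in oars.items():
            direct = rb.ntcp_from_dvh(plan.curves[name], 40, p)
            assert pt.ntcp_per_oar[name] == pytest.approx(direct, rel=1e-12)

    def test_monotone_columns(self, setup):
        plan, tumor, oars = setup
        grid = np.linspace(0.3, 1.6, 14)
        res = rb.dose_response_curves(plan, "prostate", tumor, oars, grid)
        df = res.to_frame()
        assert (df["tcp"].diff().dropna() >= -1e-12).all()
        for name in oars:
            assert (df[f"ntcp_{name}"].diff().dropna() >= -1e-12).all()

    def test_interior_p_plus_maximum_stable_under_refinement(self, setup):
        plan, tumor, oars = setup
        coarse = np.linspace(0.4, 2.0, 33)
        fine = np.linspace(0.4, 2.0, 321)
        r_coarse = rb.dose_response_curves(plan, "prostate", tumor, oars, coarse)
        r_fine = rb.dose_response_curves(plan, "prostate", tumor, oars, fine)
        step = (2.0 - 0.4) / 32 * plan.schedule.total_dose
        assert r_coarse.best.p_plus > r_coarse.points[0].p_plus
        assert r_coarse.best.p_plus > r_coarse.points[-1].p_plus
        assert abs(r_coarse.optimal_dose - r_fine.optimal_dose) <= step

    def test_empty_grid_errors(self, setup):
        plan, tumor, oars = setup
        with pytest.raises(RadbedError, match="empty"):
            rb.dose_response_curves(plan, "prostate", tumor, oars, [])

    def test_missing_reference_errors(self, setup):
        plan, tumor, oars = setup
        with pytest.raises(RadbedError, match="reference target"):
            rb.dose_response_curves(plan, "nope", tumor, oars, [1.0])

    def test_tsv_round_numbers(self, setup):
        plan, tumor, oars = setup
        res = rb.dose_response_curves(plan, "prostate", tumor, oars, [0.8, 1.0, 1.2])
        text = res.to_tsv()
        lines = text.strip().splitlines()
        assert lines[0].startswith("prescribed_dose_gy\ttcp\tntcp_")
        assert len(lines) == 4
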