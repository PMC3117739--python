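"""Linear-quadratic core: BED, isoeffect solve, NTD2, SIB synthesis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

import radbed as rb
from radbed.errors import LQValidityWarning, ParameterError


def bisection_dpf(bed_target, n, alpha_beta):
    """Independent root of n*d*(1+d/ab) - BED by bisection."""
    return bisect(lambda d: n * d * (1 + d / alpha_beta) - bed_target, 0.0, 100.0,
                  xtol=1e-12)


class TestBed:
    @pytest.mark.parametrize(
        "D,d,ab,expected",
        [
            (0.0, 2.0, 10.0, 0.0),
            (50.0, 2.0, 1.5, 50 * (1 + 2 / 1.5)),  # 116.667
            (40.0, 10.0, 10.0, 80.0),
        ],
    )
    def test_values(self, D, d, ab, expected):
        assert rb.bed(D, d, ab) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_alpha_beta(self):
        with pytest.raises(ParameterError):
            rb.bed(50, 2, 0.0)
        with pytest.raises(ParameterError):
            rb.bed(50, 2, -3)

    def test_log_sf_equals_minus_alpha_bed(self, rng):
        for _ in range(100):
            D = rng.uniform(1, 100)
            d = rng.uniform(0.5, 12)
            a = rng.uniform(0.05, 0.6)
            ab = rng.uniform(0.5, 20)
            assert rb.log_surviving_fraction(D, d, a, ab) == pytest.approx(
                -a * rb.bed(D, d, ab), rel=1e-12
            )

    def test_log_sf_zero_dose(self):
        assert rb.log_surviving_fraction(0.0, 2.0, 0.3, 10.0) == 0.0

    def test_log_sf_hand_value(self):
        # -0.3 * 60 * (1 + 2/10)
        assert rb.log_surviving_fraction(60, 2, 0.3, 10) == pytest.approx(-21.6)


class TestIsobedDosePerFraction:
    def test_round_trip_same_schedule(self):
        b = rb.bed(60, 2, 10)
        assert rb.isobed_dose_per_fraction(b, 30, 10) == pytest.approx(2.0, rel=1e-9)

    @pytest.mark.parametrize(
        "bed_target,n,ab,d_expect,total_expect",
        [
            # frozen from the bisection oracle (prostate-nodes-like inputs)
            (50 * (1 + 2 / 1.5), 40, 1.5, 1.4720486043, 58.8819441732),
            # frozen from the bisection oracle (lung-like inputs)
            (80.0, 5, 10.0, 8.6014705087, 43.0073525437),
        ],
    )
    def test_worked_examples(self, bed_target, n, ab, d_expect, total_expect):
        d = rb.isobed_dose_per_fraction(bed_target, n, ab)
        assert d == pytest.approx(d_expect, abs=1e-7)
        assert n * d == pytest.approx(total_expect, abs=1e-6)
        assert d == pytest.approx(bisection_dpf(bed_target, n, ab), abs=1e-9)

    def test_bed_reproduced(self, rng):
        for _ in range(200):
            b = rng.uniform(1, 300)
            n = int(rng.integers(1, 50))
            ab = rng.uniform(0.5, 20)
            d = rb.isobed_dose_per_fraction(b, n, ab)
            if d * n == 0:
                continue
            assert rb.bed(n * d, d, ab) == pytest.approx(b, rel=1e-9)

    def test_degenerate_zero_bed(self):
        assert rb.isobed_dose_per_fraction(0.0, 10, 3.0) == 0.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ParameterError):
            rb.isobed_dose_per_fraction(-1, 10, 3)
        with pytest.raises(ParameterError):
            rb.isobed_dose_per_fraction(100, 0, 3)
        with pytest.raises(ParameterError):
            rb.isobed_dose_per_fraction(100, 10, -1)

    def test_extreme_hypofractionation_warns_not_raises(self):
        with pytest.warns(LQValidityWarning):
            d = rb.isobed_dose_per_fraction(400.0, 1, 10.0)
        assert d > 18

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        D=st.floats(1, 100),
        d=st.floats(0.5, 12),
        n=st.integers(1, 50),
        ab=st.floats(0.5, 20),
    )
    def test_round_trip_property(self, D, d, n, ab):
        """isobed(bed(D1,d1), n1) recovers d1 when n1 = D1/d1."""
        b = rb.bed(d * n, d, ab)
        assert rb.isobed_dose_per_fraction(b, n, ab) == pytest.approx(d, rel=1e-9)

    def test_monotone_in_n(self):
        b = rb.bed(70, 2, 3)
        ds = [rb.isobed_dose_per_fraction(b, n, 3.0) for n in range(1, 80)]
        totals = [n * d for n, d in zip(range(1, 80), ds)]
        assert all(a > b_ for a, b_ in zip(ds, ds[1:]))  # d strictly decreasing
        assert all(a < b_ for a, b_ in zip(totals, totals[1:]))  # total increasing


class TestNtd2Point:
    def test_identity_at_2gy(self, rng):
        for _ in range(20):
            D = rng.uniform(0, 100)
            ab = rng.uniform(0.5, 20)
            assert rb.ntd2_point(D, 2.0, ab) == pytest.approx(D, rel=1e-12)

    def test_hand_value(self):
        assert rb.ntd2_point(50, 10, 10) == pytest.approx(50 * 20 / 12, rel=1e-12)

    def test_zero_dose(self):
        assert rb.ntd2_point(0.0, 5.0, 3.0) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(D=st.floats(0.1, 120), d=st.floats(0.2, 15), ab=st.floats(0.5, 20))
    def test_preserves_bed(self, D, d, ab):
        """NTD2 at 2 Gy/fx carries the same BED as the original pair."""
        ntd2 = rb.ntd2_point(D, d, ab)
        assert rb.bed(ntd2, 2.0, ab) == pytest.approx(rb.bed(D, d, ab), rel=1e-9)


class TestSchedule:
    def test_inconsistent_rejected(self):
        with pytest.raises(ParameterError):
            rb.Schedule(60.0, 2.0, 25)

    def test_from_fractions(self):
        s = rb.Schedule.from_fractions(2.12, 33)
        assert s.total_dose == pytest.approx(69.96)
        assert s.n_fractions == 33

    def test_nonpositive_fields_rejected(self):
        with pytest.raises(ParameterError):
            rb.Schedule(-2.0, 2.0, 1)
        with pytest.raises(ParameterError):
            rb.Schedule(0.0, 0.0, 1)


class TestSIBPrescription:
    def test_single_target_unchanged(self):
        rx = rb.SIBPrescription(
            targets=(rb.TargetPrescription("t", rb.Schedule(60, 2, 30), 10.0),)
        )
        out = rb.sib_prescription(rx)
        assert out == [("t", rb.Schedule(60, 2, 30))]

    def test_prostate_case(self):
        rx = rb.SIBPrescription(
            targets=(
                rb.TargetPrescription("prostate", rb.Schedule(80, 2, 40), 1.5),
                rb.TargetPrescription("nodes", rb.Schedule(50, 2, 25), 1.5),
            ),
            reference_index=0,
        )
        out = dict(rb.sib_prescription(rx))
        assert out["prostate"] == rb.Schedule(80, 2, 40)
        nodes = out["nodes"]
        assert nodes.n_fractions == 40
        assert nodes.dose_per_fraction == pytest.approx(1.4720486043, abs=1e-7)
        assert nodes.total_dose == pytest.approx(58.8819, abs=1e-3)

    def test_head_neck_case(self, cases):
        out = dict(rb.sib_prescription(cases["head_neck"].prescription))
        petv = out["PETV"]
        assert petv.n_fractions == 33
        assert petv.dose_per_fraction == pytest.approx(1.6682422381, abs=1e-7)
        assert petv.total_dose == pytest.approx(55.052, abs=1e-3)

    def test_bed_preserved_for_every_target(self, cases, rng):
        for case in cases.values():
            rx = case.prescription
            out = rb.sib_prescription(rx)
            for (label, sched), t in zip(out, rx.targets):
                assert rb.schedule_bed(sched, t.alpha_beta) == pytest.approx(
                    rb.schedule_bed(t.schedule, t.alpha_beta), rel=1e-9
                )

    def test_reference_index_out_of_range(self):
        with pytest.raises(ParameterError):
            rb.SIBPrescription(
                targets=(rb.TargetPrescription("t", rb.Schedule(60, 2, 30), 10.0),),
                reference_index=2,
            )

    def test_more_than_three_targets_warns(self):
        ts = tuple(
            rb.TargetPrescription(f"t{i}", rb.Schedule(60, 2, 30), 10.0)
            for i in range(4)
        )
        with pytest.warns(UserWarning, match="at most 3"):
            rx = rb.SIBPrescription(targets=ts)
        assert len(rb.sib_prescription(rx)) == 4
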