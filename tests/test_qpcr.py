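"""Standard-curve fitting, acceptance criteria, melt peaks, knockdown math."""

import math

import numpy as np
import pytest

from isoprimer import fixtures
from isoprimer.fixtures import FixtureSpec
from isoprimer.qpcr import (
    DilutionSeries,
    QpcrInputError,
    fit_dilution,
    knockdown,
    melt_peak_count,
    qc_verdict,
)

from helpers import ols_slope_oracle, peak_count_oracle


def _series(cqs, factor=4.0, ntc=None):
    return DilutionSeries(cq=[[c] for c in cqs], dilution_factor=factor, ntc_cq=ntc)


def _ideal_cqs(efficiency, n=5, factor=4.0, anchor=10.0):
    return [anchor + i * math.log10(factor) / math.log10(1 + efficiency)
            for i in range(n)]


class TestDilutionFit:
    def test_perfect_doubling_series_is_analytic(self):
        fit = fit_dilution(_series([10, 12, 14, 16, 18], ntc=35.0))
        assert fit.slope == pytest.approx(-2.0 / math.log10(4.0))
        assert fit.efficiency_pct == pytest.approx(100.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.spacing == pytest.approx(2.0)
        assert fit.max_cq == 18.0
        assert fit.ntc_distance == pytest.approx(17.0)

    def test_constant_shift_leaves_slope_efficiency_r2_unchanged(self):
        a = fit_dilution(_series([10, 12, 14, 16, 18]))
        b = fit_dilution(_series([15, 17, 19, 21, 23]))
        assert a.slope == pytest.approx(b.slope)
        assert a.efficiency_pct == pytest.approx(b.efficiency_pct)
        assert a.r_squared == pytest.approx(b.r_squared)

    def test_noisy_series_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        cqs = [c + rng.normal(0, 0.1) for c in _ideal_cqs(1.0)]
        series = _series(cqs)
        fit = fit_dilution(series)
        slope, intercept = ols_slope_oracle(series.log_input.tolist(), cqs)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_zero_variance_raises_typed_error(self):
        with pytest.raises(QpcrInputError):
            fit_dilution(_series([12, 12, 12, 12, 12]))

    def test_replicates_are_averaged(self):
        s = DilutionSeries(cq=[[10, 10.2], [12, 12.2], [14, 14.2]])
        assert fit_dilution(s).spacing == pytest.approx(2.0)


class TestQcVerdict:
    def test_perfect_series_passes_all_criteria(self):
        fit = fit_dilution(_series([10, 12, 14, 16, 18], ntc=35.0))
        v = qc_verdict(fit, melt_peak_count=1)
        assert v.passed and all(v.flags.values())

    def test_low_efficiency_fails_the_efficiency_flag(self):
        fit = fit_dilution(_series(_ideal_cqs(0.85), ntc=40.0))
        assert fit.efficiency_pct == pytest.approx(85.0)
        v = qc_verdict(fit)
        assert not v.passed and not v.flags["efficiency"]

    def test_r_squared_below_printed_bound_fails(self):
        cqs = [10.0, 12.6, 13.4, 16.4, 17.6]  # wobbly but monotone
        fit = fit_dilution(_series(cqs))
        assert fit.r_squared < 0.995
        v = qc_verdict(fit)
        assert not v.flags["r_squared"]

    def test_late_crossing_fails_max_cq(self):
        fit = fit_dilution(_series([24, 26, 28, 30, 32]))
        assert not qc_verdict(fit).flags["max_cq"]

    def test_close_ntc_fails(self):
        fit = fit_dilution(_series([10, 12, 14, 16, 18], ntc=21.0))
        assert not qc_verdict(fit).flags["ntc"]
        fit_no_ntc = fit_dilution(_series([10, 12, 14, 16, 18]))
        assert qc_verdict(fit_no_ntc).flags["ntc"]  # undetected NTC passes


class TestMeltCurve:
    def test_single_transition_gives_one_peak(self):
        temps, f = fixtures.simulate_melt(FixtureSpec(seed=1), peak_tms=(82.0,))
        assert melt_peak_count(temps, f) == 1

    def test_two_separated_transitions_give_two_peaks(self):
        temps, f = fixtures.simulate_melt(FixtureSpec(seed=1), peak_tms=(72.0, 88.0))
        assert melt_peak_count(temps, f) == 2

    def test_matches_brute_force_local_maximum_oracle(self):
        temps, f = fixtures.simulate_melt(FixtureSpec(seed=9), peak_tms=(75.0, 86.0),
                                          noise_sd=0.004)
        d = -np.gradient(f, temps)
        smoothed = np.convolve(d, np.ones(3) / 3.0, mode="same")
        expected = peak_count_oracle(smoothed.tolist(), 0.2 * smoothed.max())
        assert melt_peak_count(temps, f) == expected

    def test_too_few_points_raises(self):
        with pytest.raises(QpcrInputError):
            melt_peak_count([55, 56, 57], [1, 2, 1])


class TestKnockdown:
    REFS = {"ref1": 18.0, "ref2": 18.0, "ref3": 18.0}

    def test_identical_cqs_give_no_knockdown(self):
        res = knockdown(20.0, 20.0, self.REFS, self.REFS)
        assert res.rel_expr == pytest.approx(1.0)
        assert res.knockdown_pct == pytest.approx(0.0)

    def test_one_cycle_shift_means_half_expression(self):
        res = knockdown(21.0, 20.0, self.REFS, self.REFS)
        assert res.rel_expr == pytest.approx(0.5)
        assert res.knockdown_pct == pytest.approx(50.0)

    def test_benchmark_sixty_percent_knockdown(self):
        res = knockdown(21.3219, 20.0, self.REFS, self.REFS)
        assert round(res.knockdown_pct) == 60
        assert res.n_refs == 3

    def test_swapping_conditions_gives_reciprocal_expression(self):
        a = knockdown(21.3219, 20.0, self.REFS, self.REFS)
        b = knockdown(20.0, 21.3219, self.REFS, self.REFS)
        assert a.rel_expr * b.rel_expr == pytest.approx(1.0)

    def test_mismatched_reference_sets_raise(self):
        with pytest.raises(QpcrInputError):
            knockdown(21.0, 20.0, {"ref1": 18.0}, {"ref2": 18.0})

    def test_reference_shift_cancels(self):
        shifted = {g: c + 1.5 for g, c in self.REFS.items()}
        res = knockdown(22.5, 20.0, shifted, self.REFS)
        assert res.rel_expr == pytest.approx(0.5)


class TestSimulationRecovery:
    def test_efficiency_and_fold_recovered_from_noisy_simulation(self):
        spec = FixtureSpec(seed=7, cq_noise_sd=0.1, true_efficiency=1.0,
                           true_fold_changes={"q1": 0.4})
        dil = fixtures.simulate_dilution(spec, ["g1"])
        pts = dil[dil["dilution_index"] >= 0]
        cq = [grp["cq"].tolist() for _, grp in pts.groupby("dilution_index")]
        fit = fit_dilution(DilutionSeries(cq=cq))
        assert abs(fit.efficiency_pct - 100.0) <= 2.0

        kd = fixtures.simulate_knockdown(spec)

        def cqs(cond, gene):
            sel = kd[(kd["condition"] == cond) & (kd["target"] == gene)]
            return sel["cq"].tolist()

        res = knockdown(
            cqs("treated", "q1"), cqs("control", "q1"),
            {g: cqs("treated", g) for g in ("ref1", "ref2", "ref3")},
            {g: cqs("control", g) for g in ("ref1", "ref2", "ref3")},
        )
        # recovery within 5 percentage points of expression (the strict
        # relative reading would be a ~0.75-sigma band for this estimator,
        # i.e. a coin flip for any seed; see docs/methods.md)
        assert abs(res.rel_expr - 0.4) <= 0.05

    def test_noise_free_simulation_is_exact(self):
        spec = FixtureSpec(seed=1, cq_noise_sd=0.0, true_efficiency=1.0)
        dil = fixtures.simulate_dilution(spec, ["g1"])
        pts = dil[dil["dilution_index"] >= 0]
        cq = [grp["cq"].tolist() for _, grp in pts.groupby("dilution_index")]
        fit = fit_dilution(DilutionSeries(cq=cq))
        assert fit.efficiency_pct == pytest.approx(100.0)
        assert fit.r_squared == pytest.approx(1.0)
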