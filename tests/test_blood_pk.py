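"""Blood-side pharmacokinetics: partitioning, metabolites, tail fit, clearance."""

import math

import numpy as np
import pytest

from mirdkit.blood_pk import (
    ParentFractionCurve,
    PlasmaSampleSeries,
    clearance,
    fit_monoexp_tail,
    fit_parent_fraction,
    metabolite_correct,
    plasma_to_blood_ratio,
    protein_bound_fraction,
)
from mirdkit.kinetics import TimeActivityCurve

SCHEDULE = np.array([2, 3, 5, 6, 7, 10, 15, 20, 30, 60, 90, 180, 240], float)


def conc_curve(times, values):
    return TimeActivityCurve("plasma", times, values, units="kBq/mL", decay_corrected=True)


class TestPlasmaToBloodRatio:
    def test_equal_series_gives_unit_ratio(self):
        s = PlasmaSampleSeries(SCHEDULE, np.full(13, 5.0), np.full(13, 5.0))
        out = plasma_to_blood_ratio(s)
        assert out.mean == pytest.approx(1.0)
        assert out.sd == pytest.approx(0.0)

    def test_single_point_arithmetic(self):
        s = PlasmaSampleSeries([1, 2, 3], [100, 100, 100], [170, 170, 170])
        assert plasma_to_blood_ratio(s).mean == pytest.approx(1.7)

    def test_constant_partition_recovered_from_generator(self, noise_free_subject):
        out = plasma_to_blood_ratio(noise_free_subject.plasma)
        assert out.mean == pytest.approx(1.70, abs=0.005)
        assert out.sd < 0.01

    def test_zero_blood_excluded_with_warning(self):
        s = PlasmaSampleSeries([1, 2, 3], [0.0, 100, 100], [50, 170, 170])
        with pytest.warns(UserWarning, match="excluded"):
            out = plasma_to_blood_ratio(s)
        assert np.isnan(out.ratios[0])
        assert out.mean == pytest.approx(1.7)

    def test_all_excluded_raises(self):
        s = PlasmaSampleSeries([1, 2, 3], [0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            plasma_to_blood_ratio(s)


class TestProteinBinding:
    def series(self, plasma, sup):
        n = len(plasma)
        return PlasmaSampleSeries(
            np.arange(1, n + 1, dtype=float), np.ones(n), np.asarray(plasma, float),
            protein_free_supernatant=np.asarray(sup, float),
        )

    def test_extremes(self):
        assert protein_bound_fraction(self.series([10.0], [10.0]))[0] == pytest.approx(0.0)
        assert protein_bound_fraction(self.series([10.0], [0.0]))[0] == pytest.approx(100.0)

    def test_cohort_mean_arithmetic(self):
        out = protein_bound_fraction(self.series([100.0], [74.1]))
        assert out[0] == pytest.approx(25.9, abs=1e-9)

    def test_supernatant_excess_raises(self):
        with pytest.raises(ValueError, match="tolerance"):
            protein_bound_fraction(self.series([100.0], [110.0]))


class TestParentFractionFit:
    def test_constant_input(self):
        pf = fit_parent_fraction(SCHEDULE[:5], np.ones(5))
        assert pf(0.0) == 1.0 and pf(1000.0) == 1.0

    def test_exponential_plus_plateau_recovered(self):
        t = np.array([0.5, 1, 2, 3, 5, 8, 12, 20, 40], float)
        y = 0.85 * np.exp(-0.3 * t) + 0.02
        pf = fit_parent_fraction(t, y)
        assert pf.amplitude == pytest.approx(0.85, rel=1e-6)
        assert pf.rate == pytest.approx(0.3, rel=1e-6)
        assert pf.plateau == pytest.approx(0.02, abs=1e-7)

    def test_two_point_cohort_anchors_exactly_determined(self):
        """With the plateau fixed at 0, the fit passes through 79.2% @ 1 min
        and 4.3% @ 10 min (exactly determined two-parameter case)."""
        pf = fit_parent_fraction([1.0, 10.0], [0.792, 0.043], fix_plateau=0.0)
        assert pf(1.0) == pytest.approx(0.792, abs=1e-6)
        assert pf(10.0) == pytest.approx(0.043, abs=1e-6)

    def test_curve_monotone_and_bounded(self):
        pf = ParentFractionCurve(1.1, 0.4, 0.02)
        t = np.linspace(0.0, 300.0, 400)
        vals = pf(t)
        assert np.all((vals >= 0.0) & (vals <= 1.0))
        assert np.all(np.diff(vals) <= 1e-15)

    def test_nonmonotone_input_flagged(self):
        with pytest.warns(UserWarning, match="non-monotone"):
            pf = fit_parent_fraction([1.0, 5.0, 10.0, 20.0], [0.8, 0.2, 0.5, 0.1])
        assert pf.nonmonotone_input


class TestMetaboliteCorrection:
    def test_identity_and_annihilation(self):
        c = conc_curve(SCHEDULE, np.linspace(10, 1, 13))
        unity = ParentFractionCurve(0.0, 0.0, 1.0)
        zero = ParentFractionCurve(0.0, 0.0, 0.0)
        np.testing.assert_allclose(metabolite_correct(c, unity).values, c.values)
        assert np.all(metabolite_correct(c, zero).values == 0.0)

    def test_pointwise_product(self):
        c = conc_curve(np.array([5.0]), np.array([100.0]))
        pf = ParentFractionCurve(0.0, 0.0, 0.25)
        assert metabolite_correct(c, pf).values[0] == pytest.approx(25.0)

    def test_never_increases_concentration(self, noise_free_subject):
        plasma = noise_free_subject.plasma
        pf = fit_parent_fraction(plasma.times, plasma.parent_fraction)
        parent = metabolite_correct(plasma.plasma_curve(), pf)
        assert np.all(parent.values <= plasma.plasma + 1e-12)


class TestMonoexpTail:
    def test_exact_on_noise_free_exponential(self):
        lam = math.log(2) / 106.9
        c = conc_curve(SCHEDULE, 10.0 * np.exp(-lam * SCHEDULE))
        pk = fit_monoexp_tail(c, tail_start=60.0)
        assert pk.lambda_tail == pytest.approx(lam, rel=1e-10)
        assert pk.half_life == pytest.approx(106.9, rel=1e-3)

    def test_flat_tail_flagged(self):
        c = conc_curve(SCHEDULE, np.ones(13))
        pk = fit_monoexp_tail(c, 60.0)
        assert pk.lambda_tail == pytest.approx(0.0, abs=1e-15)
        assert math.isinf(pk.half_life)
        assert "no elimination detected" in pk.flags

    def test_too_few_tail_samples(self):
        c = conc_curve(SCHEDULE, 10.0 * np.exp(-0.01 * SCHEDULE))
        with pytest.raises(ValueError, match=">= 3"):
            fit_monoexp_tail(c, tail_start=200.0)

    def test_noisy_median_within_two_percent(self):
        lam = 0.006484
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = 10.0 * np.exp(-lam * SCHEDULE) * np.exp(0.01 * rng.standard_normal(13) - 5e-5)
            pk = fit_monoexp_tail(conc_curve(SCHEDULE, y), 60.0)
            errs.append(abs(pk.lambda_tail - lam) / lam)
        assert np.median(errs) < 0.02


class TestClearance:
    def test_dense_monoexponential_closed_form(self):
        lam, c0, dose = 0.01, 5.0, 150.0
        t = np.linspace(0.5, 600.0, 1200)
        pk = clearance(conc_curve(t, c0 * np.exp(-lam * t)), dose, lam)
        assert pk.clearance == pytest.approx(dose * 1000.0 * lam / c0, rel=0.01)

    def test_tail_extrapolation_increases_auc(self):
        lam = 0.006
        y = 10.0 * np.exp(-lam * SCHEDULE)
        with_tail = clearance(conc_curve(SCHEDULE, y), 150.0, lam, back_extrapolate=False)
        trapz_only = float(np.trapezoid(y, SCHEDULE))
        assert with_tail.auc_0_inf > trapz_only

    def test_linear_trapezoid_converges_at_second_order(self):
        lam, c0 = 0.01, 5.0
        truth = c0 / lam
        errs = []
        for n in (50, 100, 200):
            t = np.linspace(0.0, 1200.0, n + 1)
            pk = clearance(conc_curve(t, c0 * np.exp(-lam * t)), 150.0, lam, method="linear")
            errs.append(abs(pk.auc_0_inf - truth))
        assert errs[0] / errs[1] > 3.5 and errs[1] / errs[2] > 3.5

    def test_parent_clearance_exceeds_total(self, noise_free_subject):
        plasma = noise_free_subject.plasma
        total = plasma.plasma_curve()
        pf = fit_parent_fraction(plasma.times, plasma.parent_fraction)
        parent = metabolite_correct(total, pf)
        lam_tot = fit_monoexp_tail(total, 60.0).lambda_tail
        lam_par = fit_monoexp_tail(parent, 60.0).lambda_tail
        cl_tot = clearance(total, 162.0, lam_tot).clearance
        cl_par = clearance(parent, 162.0, lam_par, analyte="parent").clearance
        assert cl_par > cl_tot

    def test_zero_injected_activity_rejected(self):
        c = conc_curve(SCHEDULE, 10.0 * np.exp(-0.01 * SCHEDULE))
        with pytest.raises(ValueError):
            clearance(c, 0.0, 0.01)

    def test_heavy_extrapolation_flagged(self):
        t = np.array([1.0, 2.0, 3.0, 4.0], float)
        y = 10.0 * np.exp(-0.001 * t)  # nearly flat: almost all AUC is tail
        pk = clearance(conc_curve(t, y), 150.0, 0.001)
        assert pk.extrapolated_fraction > 0.5
        assert any("unreliable" in f for f in pk.flags)
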