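"""Median-effect fitting, Combination Index, isobolograms and grading."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

import bronchosynergy as bs
from bronchosynergy.errors import (
    ConfigurationError,
    DegenerateCurveError,
    DomainError,
    InsufficientDataError,
)
from bronchosynergy.unified import STANDARD_EFFECT_LEVELS, default_fa_grid


def me_fa(dose, m, dm):
    r = (np.asarray(dose, float) / dm) ** m
    return r / (1 + r)


def me_fit(m, dm, n=6, label=None, lo=-1.2, hi=1.2):
    dose = dm * np.logspace(lo, hi, n)
    return bs.fit_median_effect(dose, me_fa(dose, m, dm), label=label)


class TestMedianEffectFit:
    def test_exact_linearization(self):
        fit = me_fit(1.0, 10.0)
        assert fit.m == pytest.approx(1.0, abs=1e-9)
        assert fit.dm == pytest.approx(10.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_median_definition(self):
        fit = me_fit(1.7, 42.0)
        assert fit.fa_at_dose(fit.dm) == pytest.approx(0.5, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        """Slope/intercept agree with the closed-form OLS normal equations."""
        dose = np.array([2.0, 5.0, 20.0, 80.0])
        fa = np.array([0.15, 0.35, 0.62, 0.88])
        fit = bs.fit_median_effect(dose, fa)
        x, y = np.log10(dose), np.log10(fa / (1 - fa))
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x**2).sum() - x.sum() ** 2)
        intercept = (y.sum() - slope * x.sum()) / n
        assert fit.m == pytest.approx(slope, rel=1e-12)
        assert fit.dm == pytest.approx(10 ** (-intercept / slope), rel=1e-12)

    def test_out_of_bounds_points_excluded_and_counted(self):
        dose = np.array([1e-4, 0.1, 1.0, 10.0, 100.0, 1e6])
        fa = me_fa(dose, 1.0, 10.0)          # extremes fall outside (1e-3, 1-1e-3)
        fit = bs.fit_median_effect(dose, fa)
        assert fit.n_points_used == 4 and fit.n_points_excluded == 2
        assert fit.dm == pytest.approx(10.0, rel=1e-6)

    def test_insufficient_and_degenerate(self):
        with pytest.raises(InsufficientDataError):
            bs.fit_median_effect(np.array([1.0, 10.0]), np.array([0.3, 0.7]))
        with pytest.raises(DegenerateCurveError):
            bs.fit_median_effect(
                np.array([1.0, 10.0, 100.0]), np.array([1e-6, 1e-5, 1e-4])
            )

    def test_accepts_crc(self):
        from conftest import make_curve

        dose = 10 * np.logspace(-1.2, 1.2, 6)
        curve = make_curve(dose, 100 * me_fa(dose, 1.0, 10.0))
        fit = bs.fit_median_effect(curve)
        assert fit.dm == pytest.approx(10.0, rel=1e-9)


class TestDoseForFa:
    def test_median_and_closed_form(self):
        fit = me_fit(1.0, 10.0)
        assert bs.dose_for_fa(fit, 0.5) == pytest.approx(10.0, rel=1e-9)
        assert bs.dose_for_fa(fit, 0.75) == pytest.approx(30.0, rel=1e-9)

    def test_monotone_and_matches_root_finding_oracle(self):
        fit = me_fit(1.8, 25.0)
        fas = np.linspace(0.05, 0.95, 19)
        doses = [bs.dose_for_fa(fit, f) for f in fas]
        assert np.all(np.diff(doses) > 0)
        for f, d in zip(fas[::3], doses[::3]):
            root = optimize.brentq(
                lambda dd: fit.fa_at_dose(dd) - f, 1e-6, 1e9, xtol=1e-12, rtol=1e-14
            )
            assert d == pytest.approx(root, rel=1e-8)

    @pytest.mark.parametrize("fa", [0.0, 1.0, -0.2, 1.3])
    def test_domain(self, fa):
        with pytest.raises(DomainError):
            bs.dose_for_fa(me_fit(1.0, 10.0), fa)


class TestCombinationIndex:
    @given(
        m=st.floats(0.3, 4.0),
        log_dm=st.floats(-2.0, 3.0),
        ratio=st.floats(0.01, 100.0),
        fa=st.floats(0.05, 0.95),
    )
    def test_sham_self_combination_is_additive(self, m, log_dm, ratio, fa):
        """A drug combined with itself at any ratio gives CI = 1 at every fa."""
        fit = bs.MedianEffectFit(m=m, dm=10.0**log_dm, r_squared=1.0, n_points_used=6)
        ci = bs.combination_index(fa, fit, fit, fit, mass_ratio=(ratio, 1.0))
        assert ci == pytest.approx(1.0, rel=1e-9)

    def test_inactive_component_limit(self):
        """With component b fully inactive, CI reduces to D1/Dx1."""
        fit_a = me_fit(1.0, 10.0)
        combo = me_fit(1.0, 10.0 * 106 / 100)   # mixture dilutes a by 100:106
        ci = bs.combination_index(
            0.5, combo, fit_a, None, mass_ratio=(100, 6), drop_inactive="b"
        )
        d1 = bs.dose_for_fa(combo, 0.5) * 100 / 106
        assert ci == pytest.approx(d1 / bs.dose_for_fa(fit_a, 0.5), rel=1e-12)
        assert ci == pytest.approx(1.0, rel=1e-9)

    def test_missing_fit_without_flag_is_configuration_error(self):
        fit = me_fit(1.0, 10.0)
        with pytest.raises(ConfigurationError):
            bs.combination_index(0.5, fit, fit, None)

    def test_loewe_additive_mixture_gives_ci_one(self):
        """Dose-additive equal-shape mixture: CI = 1 within 1e-3 across fa,
        cross-checked against a brute-force isobole-construction oracle."""
        m, dm_a, dm_b = 1.4, 5.0, 80.0
        ra, rb = 100.0, 6.0
        wa, wb = ra / (ra + rb), rb / (ra + rb)

        def combo_fa(total):
            u = total * (wa / dm_a + wb / dm_b)    # potency-normalized sum
            return u**m / (1 + u**m)

        totals = np.logspace(-1.5, 1.5, 9) / (wa / dm_a + wb / dm_b)
        fit_combo = bs.fit_median_effect(totals, combo_fa(totals))
        fit_a, fit_b = me_fit(m, dm_a), me_fit(m, dm_b)
        for fa in np.arange(0.1, 0.91, 0.1):
            ci = bs.combination_index(fa, fit_combo, fit_a, fit_b, (ra, rb))
            assert ci == pytest.approx(1.0, abs=1e-3)
            # oracle: invert the additive surface numerically for the same fa
            total = optimize.brentq(lambda t: combo_fa(t) - fa, 1e-9, 1e9)
            dx_a = dm_a * (fa / (1 - fa)) ** (1 / m)
            dx_b = dm_b * (fa / (1 - fa)) ** (1 / m)
            oracle_ci = total * wa / dx_a + total * wb / dx_b
            assert ci == pytest.approx(oracle_ci, abs=1e-3)

    def test_unit_invariance(self):
        """Rescaling every dose by a constant leaves CI unchanged."""
        dose = 10 * np.logspace(-1.2, 1.2, 7)
        fa_mix = me_fa(dose, 1.2, 6.0)
        for scale in (1.0, 1000.0):
            fc = bs.fit_median_effect(dose * scale, fa_mix)
            fa_ = bs.fit_median_effect(dose * scale, me_fa(dose, 1.0, 10.0))
            fb_ = bs.fit_median_effect(dose * scale, me_fa(dose, 1.5, 30.0))
            ci = bs.combination_index(0.5, fc, fa_, fb_)
            if scale == 1.0:
                base = ci
        assert ci == pytest.approx(base, rel=1e-9)

    def test_nonexclusive_adds_cross_term(self):
        fit = me_fit(1.0, 10.0)
        excl = bs.combination_index(0.5, fit, fit, fit, (1, 1))
        nonexcl = bs.combination_index(0.5, fit, fit, fit, (1, 1), nonexclusive=True)
        assert nonexcl == pytest.approx(excl + 0.25, rel=1e-9)


class TestProfileAndIsobologram:
    def _sham(self):
        fit = me_fit(1.2, 15.0)
        return bs.ci_profile(fit, fit, fit, mass_ratio=(3, 1))

    def test_sham_log_ci_is_zero_on_grid(self):
        prof = self._sham()
        assert np.allclose(prof.table["log10_ci"], 0.0, atol=1e-9)

    def test_grid_contains_standard_levels(self):
        prof = self._sham()
        for level in (0.15, 0.25, 0.50, 0.75, 0.90):
            assert np.isclose(prof.table["fa"], level).any()
        assert set(np.round(default_fa_grid(), 2)) >= set(STANDARD_EFFECT_LEVELS)

    def test_profile_equals_pointwise_calls(self):
        fit_c, fit_a, fit_b = me_fit(1.3, 8.0), me_fit(1.0, 10.0), me_fit(1.6, 40.0)
        prof = bs.ci_profile(fit_c, fit_a, fit_b)
        for _, row in prof.table.iterrows():
            assert row["ci"] == pytest.approx(
                bs.combination_index(row["fa"], fit_c, fit_a, fit_b), rel=1e-12
            )

    def test_sham_isobologram_point_on_additivity_line(self):
        prof = self._sham()
        iso = prof.isobologram_points
        row = iso[np.isclose(iso["fa"], 0.5)].iloc[0]
        assert row["x"] + row["y"] == pytest.approx(1.0, rel=1e-9)

    def test_isobologram_coordinates_sum_to_ci(self):
        fit_c, fit_a, fit_b = me_fit(1.3, 8.0), me_fit(1.0, 10.0), me_fit(1.6, 40.0)
        iso = bs.isobologram(fit_c, fit_a, fit_b)
        for _, row in iso.iterrows():
            ci = bs.combination_index(row["fa"], fit_c, fit_a, fit_b)
            assert row["x"] + row["y"] == pytest.approx(ci, rel=1e-12)

    def test_synergistic_mixture_below_line(self):
        """CI < 1 puts the isobologram point strictly below x + y = 1."""
        fit_a, fit_b = me_fit(1.0, 10.0), me_fit(1.0, 40.0)
        fit_c = me_fit(1.0, 2.0)      # far more potent than additivity allows
        iso = bs.isobologram(fit_c, fit_a, fit_b)
        ci = np.array([bs.combination_index(f, fit_c, fit_a, fit_b) for f in iso["fa"]])
        assert (ci < 1).all()
        assert ((iso["x"] + iso["y"]) < 1).all()
        assert (np.log10(ci) < 0).all()


class TestGrading:
    # every printed (CI, symbol) pair of the study's magnitude table:
    # rows = effect levels 15/25/50/75/90% Emax, columns = condition
    TABLE3 = [
        # medium bronchi, non-sensitized
        (0.47, "+++"), (0.34, "+++"), (0.22, "++++"), (0.15, "++++"), (0.10, "++++"),
        # medium bronchi, passively sensitized
        (0.51, "+++"), (0.38, "+++"), (0.26, "++++"), (0.20, "++++"), (0.14, "++++"),
        # small airways, non-sensitized
        (0.47, "+++"), (0.29, "++++"), (0.12, "++++"), (0.05, "+++++"), (0.02, "+++++"),
        # small airways, passively sensitized
        (0.06, "+++++"), (0.08, "+++++"), (0.15, "++++"), (0.28, "++++"), (0.52, "+++"),
    ]

    @pytest.mark.parametrize("ci,symbol", TABLE3)
    def test_reproduces_all_printed_grades(self, ci, symbol):
        assert bs.grade_ci(ci).symbol == symbol

    @pytest.mark.parametrize(
        "ci,grade",
        [
            (0.75, bs.SynergyGrade.MODERATE_SYNERGISM),
            (0.87, bs.SynergyGrade.SLIGHT_SYNERGISM),
            (1.0, bs.SynergyGrade.NEARLY_ADDITIVE),
            (1.1, bs.SynergyGrade.NEARLY_ADDITIVE),
            (1.15, bs.SynergyGrade.SLIGHT_ANTAGONISM),
            (1.3, bs.SynergyGrade.MODERATE_ANTAGONISM),
            (2.0, bs.SynergyGrade.ANTAGONISM),
            (5.0, bs.SynergyGrade.STRONG_ANTAGONISM),
            (20.0, bs.SynergyGrade.VERY_STRONG_ANTAGONISM),
        ],
    )
    def test_additive_and_antagonism_bands(self, ci, grade):
        assert bs.grade_ci(ci) is grade

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.inf, np.nan])
    def test_domain(self, bad):
        with pytest.raises(DomainError):
            bs.grade_ci(bad)


class TestOverallCI:
    def test_mean_of_values(self):
        assert bs.overall_ci([0.47, 0.34, 0.51, 0.38]) == pytest.approx(0.425)

    def test_mean_over_profile_levels(self):
        fit = me_fit(1.2, 15.0)
        prof = bs.ci_profile(fit, fit, fit, mass_ratio=(3, 1))
        assert bs.overall_ci(prof, fa_levels=(0.25, 0.5)) == pytest.approx(1.0, rel=1e-9)
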