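"""Bliss Independence additivity analysis.

The expected combined effect of two independently acting agents with
fractional effects Ex, Ey is E(x, y) = Ex + Ey - Ex*Ey.  The analysis
compares the observed fixed-ratio combination response against this expected
additive response at every tested combination total: a positive delta
(observed - expected) with p < alpha is synergistic, a negative one
antagonistic, otherwise additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConcentrationResponseCurve, DEFAULT_MASS_RATIO
from .errors import DomainError, InsufficientReplicationError
from .hillfit import HillFit, fit_hill

#: fractional effects are clipped just below 1 so that fa/fu stays finite
FRACTION_CLIP_HI = 1.0 - 1e-6


def clip_fraction(value, warn: bool = True):
    """Clip fractional effect(s) to [0, 1 - 1e-6]; values above 1 warn."""
    arr = np.asarray(value, dtype=float)
    if warn and np.any(arr > 1.0):
        warnings.warn(
            "fractional effect > 1 clipped to 1 - 1e-6 (normalized response "
            "exceeded the papaverine maximum)",
            stacklevel=2,
        )
    return np.clip(arr, 0.0, FRACTION_CLIP_HI)


def bliss_expected(ex, ey):
    """Expected additive fractional effect under Bliss Independence.

    Raises :class:`DomainError` on negative inputs; inputs above 1 are
    clipped with a warning (normalized responses can exceed 100%).
    """
    ex_a, ey_a = np.asarray(ex, dtype=float), np.asarray(ey, dtype=float)
    if np.any(ex_a < 0) or np.any(ey_a < 0):
        raise DomainError("fractional effects must be non-negative")
    ex_a, ey_a = clip_fraction(ex_a), clip_fraction(ey_a)
    out = ex_a + ey_a - ex_a * ey_a
    return float(out) if out.ndim == 0 else out


def propagate_expected_sem(ex, ey, sem_x, sem_y):
    """Delta-method SEM of the Bliss expected effect.

    d/dEx = 1 - Ey and d/dEy = 1 - Ex, so
    SEM = sqrt((1-Ey)^2 sem_x^2 + (1-Ex)^2 sem_y^2).
    """
    ex, ey = np.asarray(ex, float), np.asarray(ey, float)
    sem_x, sem_y = np.asarray(sem_x, float), np.asarray(sem_y, float)
    if np.any(sem_x < 0) or np.any(sem_y < 0):
        raise DomainError("SEMs must be non-negative")
    out = np.sqrt((1.0 - ey) ** 2 * sem_x**2 + (1.0 - ex) ** 2 * sem_y**2)
    return float(out) if out.ndim == 0 else out


@dataclass
class BlissComparison:
    """Per-concentration observed-vs-expected table plus curve-level ANOVA."""

    table: pd.DataFrame          # one row per combination total
    p_curve: float               # two-way ANOVA p for observed-vs-expected
    anova_table: pd.DataFrame
    alpha: float = 0.05
    mass_ratio: tuple[float, float] = DEFAULT_MASS_RATIO
    notes: list[str] = field(default_factory=list)

    @property
    def classifications(self) -> pd.Series:
        return self.table["classification"]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "mass_ratio": list(self.mass_ratio),
            "p_curve": self.p_curve,
            "per_point": self.table.to_dict(orient="records"),
            "anova": self.anova_table.reset_index().to_dict(orient="records"),
            "notes": self.notes,
        }


def _component_concentrations(totals: np.ndarray, mass_ratio):
    a, b = mass_ratio
    tot = a + b
    return totals * (a / tot), totals * (b / tot)


def _mono_effects(
    curves: list[ConcentrationResponseCurve],
    conc: np.ndarray,
    fits: list[HillFit] | None,
    use_fits: bool,
) -> np.ndarray:
    """Per-tissue fractional effects at the requested concentrations.

    Returns an (n_tissues, n_conc) array.  With ``use_fits`` the per-tissue
    fitted Hill curve is evaluated (the default: smooth expected curves);
    otherwise the raw responses are log-linearly interpolated.
    """
    def interp(c):
        return np.interp(np.log10(conc), np.log10(c.concentrations), c.responses) / 100.0

    rows = []
    if use_fits:
        fits = fits or [fit_hill(c) for c in curves]
        for f, c in zip(fits, curves):
            # a sub-20%-Emax ("NC") fit sits on the Top bound and is not a
            # reliable smooth reference; use the raw responses instead
            rows.append(interp(c) if f.potency_not_calculable else f.predict(conc) / 100.0)
    else:
        rows = [interp(c) for c in curves]
    return np.vstack(rows)


def bliss_delta_analysis(
    observed_combo: list[ConcentrationResponseCurve],
    mono_a: list[ConcentrationResponseCurve],
    mono_b: list[ConcentrationResponseCurve],
    mass_ratio: tuple[float, float] = DEFAULT_MASS_RATIO,
    *,
    grid: np.ndarray | None = None,
    alpha: float = 0.05,
    use_fits: bool = True,
    fits_a: list[HillFit] | None = None,
    fits_b: list[HillFit] | None = None,
) -> BlissComparison:
    """Observed-vs-Bliss-expected comparison for a fixed-ratio combination.

    ``mass_ratio`` = (a, b) splits each combination total C into component
    concentrations C*a/(a+b) for agent a and C*b/(a+b) for agent b (100:6
    BDP:FF by default).  Monotherapy effects are read off the per-tissue
    fitted Hill curves at those component concentrations; tissue i of arm a
    is paired with tissue i of arm b (sorted by id) to form per-replicate
    expected values for the per-point Welch t-tests.  The curve-level test is
    an ordinary two-way ANOVA (response type x concentration) on the
    observed/expected replicate values; its response-type main effect is
    reported as ``p_curve``.

    Observed responses enter the tests un-clipped; only the fractional
    inputs of the Bliss formula are clipped to [0, 1).
    """
    if min(len(observed_combo), len(mono_a), len(mono_b)) < 2:
        raise InsufficientReplicationError(
            "Bliss analysis needs >= 2 tissues in the combination and both "
            "monotherapy arms"
        )
    observed_combo = sorted(observed_combo, key=lambda c: c.tissue.tissue_id)
    mono_a = sorted(mono_a, key=lambda c: c.tissue.tissue_id)
    mono_b = sorted(mono_b, key=lambda c: c.tissue.tissue_id)

    if grid is None:
        grid = observed_combo[0].concentrations
    grid = np.asarray(grid, dtype=float)
    conc_a, conc_b = _component_concentrations(grid, mass_ratio)

    n_pair = min(len(mono_a), len(mono_b))
    ex = clip_fraction(
        _mono_effects(mono_a, conc_a, fits_a, use_fits)[:n_pair], warn=False
    )
    ey = clip_fraction(
        _mono_effects(mono_b, conc_b, fits_b, use_fits)[:n_pair], warn=False
    )
    expected = 100.0 * (ex + ey - ex * ey)           # (n_pair, n_conc) percent

    obs_rows = []
    for c in observed_combo:
        resp = np.interp(np.log10(grid), np.log10(c.concentrations), c.responses)
        obs_rows.append(resp)
    observed = np.vstack(obs_rows)                    # percent, un-clipped

    mean_obs, mean_exp = observed.mean(axis=0), expected.mean(axis=0)
    sem_obs = observed.std(axis=0, ddof=1) / np.sqrt(observed.shape[0])
    sem_x = ex.std(axis=0, ddof=1) / np.sqrt(n_pair)
    sem_y = ey.std(axis=0, ddof=1) / np.sqrt(n_pair)
    sem_exp = 100.0 * propagate_expected_sem(
        ex.mean(axis=0), ey.mean(axis=0), sem_x, sem_y
    )
    delta = mean_obs - mean_exp

    p_point = np.empty(len(grid))
    for j in range(len(grid)):
        se = np.sqrt(
            observed[:, j].var(ddof=1) / observed.shape[0]
            + expected[:, j].var(ddof=1) / n_pair
        )
        if se < 1e-9:   # degenerate: numerically identical replicates
            p_point[j] = 1.0 if abs(delta[j]) <= 1e-9 else 0.0
        else:
            p_point[j] = stats.ttest_ind(
                observed[:, j], expected[:, j], equal_var=False
            ).pvalue
    classification = np.where(
        p_point < alpha,
        np.where(delta > 0, "synergistic", "antagonistic"),
        "additive",
    )

    p_curve, anova_tab = _two_way_anova(observed, expected, grid)

    table = pd.DataFrame(
        {
            "concentration_total": grid,
            "concentration_a": conc_a,
            "concentration_b": conc_b,
            "ex": ex.mean(axis=0),
            "ey": ey.mean(axis=0),
            "e_expected": mean_exp / 100.0,
            "e_observed": mean_obs / 100.0,
            "expected_percent": mean_exp,
            "observed_percent": mean_obs,
            "sem_expected": sem_exp,
            "sem_observed": sem_obs,
            "delta": delta,
            "p_per_point": p_point,
            "classification": classification,
        }
    )
    return BlissComparison(
        table=table,
        p_curve=p_curve,
        anova_table=anova_tab,
        alpha=alpha,
        mass_ratio=mass_ratio,
    )


def _two_way_anova(observed: np.ndarray, expected: np.ndarray, grid: np.ndarray):
    """Ordinary two-way ANOVA: response type (observed/expected) x concentration."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    frames = []
    for kind, arr in (("observed", observed), ("expected", expected)):
        n, m = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "value": arr.ravel(),
                    "kind": kind,
                    "conc": np.tile(np.arange(m), n).astype(str),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    model = ols("value ~ C(kind) * C(conc)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    kind_ss = float(tab.loc["C(kind)", "sum_sq"])
    resid_ss = float(tab.loc["Residual", "sum_sq"])
    if resid_ss < 1e-10:   # degenerate: numerically identical replicates
        return (1.0 if kind_ss < 1e-10 else 0.0), tab
    return float(tab.loc["C(kind)", "PR(>F)"]), tab
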