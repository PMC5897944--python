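"""Median-effect fits, Combination Index, isobolograms and magnitude grading.

The median-effect equation fa/fu = (D/Dm)^m (fa fraction affected, fu =
1 - fa, Dm the median-effect dose, m the shape) is linear in log-log
coordinates: log(fa/fu) = m log D - m log Dm.  For a fixed-ratio mixture the
Combination Index at effect level fa is

    CI = D1/Dx1 + D2/Dx2

where (D1, D2) are the component doses of the mixture total that reaches fa
and Dx1, Dx2 are the single-agent doses reaching the same fa.  CI < 1 means
synergism, CI = 1 additivity, CI > 1 antagonism; magnitude bands grade how
far from 1 the index lies.  The two-term (mutually exclusive) form is the
default; the mutually nonexclusive third term is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .core import ConcentrationResponseCurve, DEFAULT_MASS_RATIO
from .errors import (
    ConfigurationError,
    DegenerateCurveError,
    DomainError,
    InsufficientDataError,
)

#: fa clipping bounds for the log-linearization; points outside are excluded
FA_BOUNDS = (1e-3, 1.0 - 1e-3)

#: effect levels (% Emax) at which CI magnitudes are conventionally tabulated
STANDARD_EFFECT_LEVELS = (0.15, 0.25, 0.50, 0.75, 0.90)


@dataclass
class MedianEffectFit:
    """Linearized median-effect parameters for one agent or fixed-ratio mixture."""

    m: float                 # shape (median-effect slope)
    dm: float                # dose giving fa = 0.5, canonical units
    r_squared: float
    n_points_used: int
    n_points_excluded: int = 0
    label: str | None = None
    low_emax_caveat: bool = False   # fitted on a sub-20%-Emax response range

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.dm > 0):
            raise DomainError(
                f"median-effect fit requires m > 0 and Dm > 0, got m={self.m!r}, "
                f"dm={self.dm!r}"
            )

    def fa_at_dose(self, dose) -> np.ndarray | float:
        """Forward model: fa = (D/Dm)^m / (1 + (D/Dm)^m)."""
        r = (np.asarray(dose, float) / self.dm) ** self.m
        out = r / (1.0 + r)
        return float(out) if out.ndim == 0 else out


def fit_median_effect(
    dose,
    fa=None,
    *,
    label: str | None = None,
    low_emax_caveat: bool = False,
) -> MedianEffectFit:
    """Ordinary least squares of log10(fa/fu) on log10(D).

    Accepts either (dose_array, fa_array) or a single
    :class:`ConcentrationResponseCurve` (normalized percent / 100 as fa).
    Points with fa outside (1e-3, 1 - 1e-3) are excluded and counted.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 usable points.
    DegenerateCurveError
        Every point sits outside the fa bounds.
    """
    if isinstance(dose, ConcentrationResponseCurve):
        curve = dose
        fa = curve.responses / 100.0
        dose = curve.concentrations
        label = label or f"{curve.tissue.tissue_id}:{curve.arm.value}"
    dose = np.asarray(dose, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if dose.shape != fa.shape:
        raise DomainError("dose and fa arrays must have the same shape")

    usable = (fa > FA_BOUNDS[0]) & (fa < FA_BOUNDS[1]) & (dose > 0)
    n_excluded = int((~usable).sum())
    if usable.sum() == 0:
        raise DegenerateCurveError(
            "all fractional effects lie outside the usable (fa, fu) range"
        )
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"median-effect fit needs >= 3 usable points, got {int(usable.sum())}"
        )
    x = np.log10(dose[usable])
    y = np.log10(fa[usable] / (1.0 - fa[usable]))
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise DegenerateCurveError(
            f"median-effect slope must be positive, fitted m={m:.4g}"
        )
    resid = y - (m * x + intercept)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 1.0
    return MedianEffectFit(
        m=float(m),
        dm=float(10.0 ** (-intercept / m)),
        r_squared=float(max(0.0, min(1.0, r2))),
        n_points_used=int(usable.sum()),
        n_points_excluded=n_excluded,
        label=label,
        low_emax_caveat=low_emax_caveat,
    )


def dose_for_fa(fit: MedianEffectFit, fa: float) -> float:
    """Invert the median-effect model: Dx = Dm * (fa / (1 - fa))^(1/m)."""
    if not (0.0 < fa < 1.0):
        raise DomainError(f"fa must be in (0, 1), got {fa!r}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(
    fa: float,
    fit_combo: MedianEffectFit,
    fit_a: MedianEffectFit | None,
    fit_b: MedianEffectFit | None,
    mass_ratio: tuple[float, float] = DEFAULT_MASS_RATIO,
    *,
    nonexclusive: bool = False,
    drop_inactive: str | None = None,
) -> float:
    """Combination Index at effect level ``fa`` for a fixed-ratio mixture.

    ``fit_combo`` is the median-effect fit of the mixture on its *total*
    dose; ``mass_ratio`` = (a, b) splits the total into components.  When a
    component's potency is not calculable (Emax below 20%), either pass its
    sub-range median-effect fit with ``low_emax_caveat`` set (default path),
    or drop its term with ``drop_inactive`` in {"a", "b"} for an upper-bound
    CI in the fully-inactive limit.
    """
    if not (0.0 < fa < 1.0):
        raise DomainError(f"fa must be in (0, 1), got {fa!r}")
    if drop_inactive not in (None, "a", "b"):
        raise ConfigurationError("drop_inactive must be None, 'a' or 'b'")
    if drop_inactive != "a" and fit_a is None:
        raise ConfigurationError(
            "component a has no median-effect fit; pass drop_inactive='a' to "
            "treat it as fully inactive"
        )
    if drop_inactive != "b" and fit_b is None:
        raise ConfigurationError(
            "component b has no median-effect fit; pass drop_inactive='b' to "
            "treat it as fully inactive"
        )
    ra, rb = mass_ratio
    total = dose_for_fa(fit_combo, fa)
    d1, d2 = total * ra / (ra + rb), total * rb / (ra + rb)
    ci = 0.0
    t1 = t2 = None
    if drop_inactive != "a":
        t1 = d1 / dose_for_fa(fit_a, fa)
        ci += t1
    if drop_inactive != "b":
        t2 = d2 / dose_for_fa(fit_b, fa)
        ci += t2
    if nonexclusive and t1 is not None and t2 is not None:
        ci += t1 * t2
    return float(ci)


class SynergyGrade(Enum):
    """Chou magnitude bands for the Combination Index."""

    VERY_STRONG_SYNERGISM = "+++++"
    STRONG_SYNERGISM = "++++"
    SYNERGISM = "+++"
    MODERATE_SYNERGISM = "++"
    SLIGHT_SYNERGISM = "+"
    NEARLY_ADDITIVE = "±"
    SLIGHT_ANTAGONISM = "-"
    MODERATE_ANTAGONISM = "--"
    ANTAGONISM = "---"
    STRONG_ANTAGONISM = "----"
    VERY_STRONG_ANTAGONISM = "-----"

    @property
    def symbol(self) -> str:
        return self.value


# (upper CI bound, grade); bands scanned in order, upper bound inclusive
_GRADE_BANDS = [
    (0.1, SynergyGrade.VERY_STRONG_SYNERGISM),   # CI < 0.1
    (0.3, SynergyGrade.STRONG_SYNERGISM),        # 0.1 <= CI < 0.3
    (0.7, SynergyGrade.SYNERGISM),               # 0.3 <= CI < 0.7
    (0.85, SynergyGrade.MODERATE_SYNERGISM),
    (0.9, SynergyGrade.SLIGHT_SYNERGISM),
    (1.1, SynergyGrade.NEARLY_ADDITIVE),         # includes 1.1
    (1.2, SynergyGrade.SLIGHT_ANTAGONISM),
    (1.45, SynergyGrade.MODERATE_ANTAGONISM),
    (3.3, SynergyGrade.ANTAGONISM),
    (10.0, SynergyGrade.STRONG_ANTAGONISM),
]


def grade_ci(ci: float) -> SynergyGrade:
    """Grade a Combination Index into the conventional magnitude bands.

    Synergism bands use half-open intervals [lo, hi) so that e.g. CI = 0.10
    is strong (not very strong) synergism; the nearly-additive band is
    [0.9, 1.1] inclusive.
    """
    if not (ci > 0) or not np.isfinite(ci):
        raise DomainError(f"CI must be a positive finite number, got {ci!r}")
    for hi, grade in _GRADE_BANDS:
        if ci < hi or (ci == hi and grade is SynergyGrade.NEARLY_ADDITIVE):
            return grade
    return SynergyGrade.VERY_STRONG_ANTAGONISM


def default_fa_grid() -> np.ndarray:
    """0.05 .. 0.95 in steps of 0.05 plus the standard tabulated effect levels."""
    grid = set(np.round(np.arange(0.05, 0.951, 0.05), 2))
    grid |= set(STANDARD_EFFECT_LEVELS)
    return np.array(sorted(grid))


@dataclass
class CombinationIndexProfile:
    """CI over an fa grid with grades and isobologram coordinates."""

    table: pd.DataFrame                    # fa, ci, log10_ci, grade
    isobologram_points: pd.DataFrame       # fa, x (D1/Dx1), y (D2/Dx2)
    mass_ratio: tuple[float, float] = DEFAULT_MASS_RATIO
    notes: list[str] = field(default_factory=list)

    def ci_at(self, fa: float) -> float:
        row = self.table[np.isclose(self.table["fa"], fa)]
        if row.empty:
            raise DomainError(f"fa={fa} is not on the profile grid")
        return float(row["ci"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "mass_ratio": list(self.mass_ratio),
            "fa_ci": self.table.assign(grade=self.table["grade"].map(lambda g: g.symbol))
            .to_dict(orient="records"),
            "isobologram": self.isobologram_points.to_dict(orient="records"),
            "notes": self.notes,
        }


def ci_profile(
    fit_combo: MedianEffectFit,
    fit_a: MedianEffectFit | None,
    fit_b: MedianEffectFit | None,
    mass_ratio: tuple[float, float] = DEFAULT_MASS_RATIO,
    fa_grid: np.ndarray | None = None,
    **ci_kwargs,
) -> CombinationIndexProfile:
    """Evaluate CI, log10 CI, grades and isobologram points over an fa grid."""
    if fa_grid is None:
        fa_grid = default_fa_grid()
    fa_grid = np.asarray(fa_grid, dtype=float)
    ci = np.array(
        [
            combination_index(fa, fit_combo, fit_a, fit_b, mass_ratio, **ci_kwargs)
            for fa in fa_grid
        ]
    )
    table = pd.DataFrame(
        {
            "fa": fa_grid,
            "ci": ci,
            "log10_ci": np.log10(ci),
            "grade": [grade_ci(c) for c in ci],
        }
    )
    iso = isobologram(
        fit_combo, fit_a, fit_b, mass_ratio,
        fa_levels=[f for f in STANDARD_EFFECT_LEVELS],
        **ci_kwargs,
    )
    notes = []
    for f, side in ((fit_a, "a"), (fit_b, "b")):
        if f is not None and f.low_emax_caveat:
            notes.append(
                f"component {side}: median-effect fit restricted to a sub-20% "
                "Emax response range; its CI contribution is indicative only"
            )
    return CombinationIndexProfile(
        table=table, isobologram_points=iso, mass_ratio=mass_ratio, notes=notes
    )


def isobologram(
    fit_combo: MedianEffectFit,
    fit_a: MedianEffectFit | None,
    fit_b: MedianEffectFit | None,
    mass_ratio: tuple[float, float] = DEFAULT_MASS_RATIO,
    fa_levels=STANDARD_EFFECT_LEVELS,
    *,
    nonexclusive: bool = False,
    drop_inactive: str | None = None,
) -> pd.DataFrame:
    """Normalized isobologram coordinates (D1/Dx1, D2/Dx2) at given fa levels.

    Points below the additivity line x + y = 1 indicate synergy; the
    coordinates of a point sum to the (two-term) CI at that level.
    """
    ra, rb = mass_ratio
    rows = []
    for fa in fa_levels:
        if not (0.0 < fa < 1.0):
            raise DomainError(f"fa level must be in (0, 1), got {fa!r}")
        total = dose_for_fa(fit_combo, fa)
        d1, d2 = total * ra / (ra + rb), total * rb / (ra + rb)
        x = d1 / dose_for_fa(fit_a, fa) if (fit_a and drop_inactive != "a") else 0.0
        y = d2 / dose_for_fa(fit_b, fa) if (fit_b and drop_inactive != "b") else 0.0
        rows.append({"fa": fa, "x": x, "y": y, "d1": d1, "d2": d2})
    return pd.DataFrame(rows)


def overall_ci(profile_or_cis, fa_levels=None) -> float:
    """Arithmetic mean CI over a set of tabulated effect levels.

    Accepts a :class:`CombinationIndexProfile` (with ``fa_levels`` selecting
    rows) or a flat iterable of CI values, possibly pooled across several
    conditions.  This is an interpretive summary: the mean of the per-level
    indices within an effect band.
    """
    if isinstance(profile_or_cis, CombinationIndexProfile):
        if fa_levels is None:
            fa_levels = STANDARD_EFFECT_LEVELS
        cis = [profile_or_cis.ci_at(f) for f in fa_levels]
    else:
        cis = list(profile_or_cis)
    if not cis:
        raise DomainError("no CI values to average")
    return float(np.mean(cis))
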