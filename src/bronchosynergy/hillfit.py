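"""Variable-slope logistic (4PL / Hill) fitting of normalized CRCs.

The model is the standard log(agonist)-vs-response, variable slope form

    Y = Bottom + (Top - Bottom) / (1 + 10^((logEC50 - X) * HillSlope))

with X = log10 concentration.  Fits use bounded trust-region least squares
with a small multistart over logEC50 and slope, because organ-bath curves at
n ~ 9 points and 3% noise can trap single-start optimizers.  Non-monotone
(bell-shaped) curves are routed to a rise-fall product-of-logistics model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import (
    ARM_COMPOUND,
    MOLECULAR_WEIGHTS,
    ConcentrationResponseCurve,
    pec50_from_log_ec50,
)
from .errors import DomainError, FitFailureError, InsufficientDataError, NotBellShapedError

# physiologic bounds, with tolerance for >100% papaverine-normalized readings
BOTTOM_BOUNDS = (-5.0, 20.0)
TOP_BOUNDS = (20.0, 115.0)
SLOPE_BOUNDS = (0.1, 6.0)

#: Emax below which potency is reported "not calculable" (NC)
EMAX_NC_THRESHOLD = 20.0

# bell-shape detection: Spearman rho below this AND an interior peak with a
# terminal drop of at least PEAK_DROP_MIN percentage points
MONOTONE_SPEARMAN_MIN = 0.5
PEAK_DROP_MIN = 10.0


def hill_response(x_log: np.ndarray, bottom: float, top: float,
                  log_ec50: float, slope: float) -> np.ndarray:
    """Evaluate the 4PL at log10 concentration(s) ``x_log``."""
    x_log = np.asarray(x_log, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - x_log) * slope))


@dataclass
class HillFit:
    """Fitted 4PL parameters with diagnostics."""

    bottom: float
    top: float
    log_ec50: float          # log10 EC50 on the canonical ng/ml scale
    hill_slope: float
    r_squared: float
    converged: bool
    sse: float
    n_points: int
    se: dict[str, float] = field(default_factory=dict)
    pec50: float | None = None           # -log10 EC50 in molar, if MW known
    potency_not_calculable: bool = False
    max_observed: float | None = None    # largest normalized response seen
    tissue_id: str | None = None
    arm: str | None = None

    @property
    def emax(self) -> float:
        return self.top

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50

    def predict(self, concentration) -> np.ndarray:
        """Fitted response (percent) at concentration(s) in ng/ml."""
        return hill_response(
            np.log10(np.asarray(concentration, dtype=float)),
            self.bottom, self.top, self.log_ec50, self.hill_slope,
        )


def detect_shape(curve: ConcentrationResponseCurve) -> str:
    """Classify a CRC as ``"monotone"`` or ``"bell"``.

    Bell means: rank correlation of response with log concentration below
    ``MONOTONE_SPEARMAN_MIN`` *and* the peak lies strictly inside the tested
    span with a terminal drop of at least ``PEAK_DROP_MIN`` points.
    """
    y = curve.responses
    x = np.log10(curve.concentrations)
    if len(y) < 4:
        return "monotone"
    rho = stats.spearmanr(x, y).statistic
    k = int(np.argmax(y))
    interior_peak = 0 < k < len(y) - 1
    drop = y[k] - y[-1]
    if rho < MONOTONE_SPEARMAN_MIN and interior_peak and drop >= PEAK_DROP_MIN:
        return "bell"
    return "monotone"


def _multistarts(x: np.ndarray, y: np.ndarray):
    b0 = float(np.clip(y.min(), *BOTTOM_BOUNDS))
    t0 = float(np.clip(y.max(), *TOP_BOUNDS))
    for q in (0.25, 0.5, 0.75):
        for s in (0.5, 1.0, 2.0):
            yield (b0, t0, float(np.quantile(x, q)), s)


def fit_hill(curve: ConcentrationResponseCurve) -> HillFit:
    """Fit the 4PL to one curve with multistart bounded least squares.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 points.
    FitFailureError
        No start converges; diagnostics carry the per-start status.
    """
    if len(curve) < 4:
        raise InsufficientDataError(
            f"4PL fit needs >= 4 points, got {len(curve)}"
        )
    x = np.log10(curve.concentrations)
    y = curve.responses
    span = (x.min() - 2.0, x.max() + 2.0)
    lo = [BOTTOM_BOUNDS[0], TOP_BOUNDS[0], span[0], SLOPE_BOUNDS[0]]
    hi = [BOTTOM_BOUNDS[1], TOP_BOUNDS[1], span[1], SLOPE_BOUNDS[1]]

    best = None
    diagnostics = {"starts": []}
    for p0 in _multistarts(x, y):
        p0 = np.clip(p0, lo, hi)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    hill_response, x, y, p0=p0, bounds=(lo, hi),
                    method="trf", maxfev=2000,
                )
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            diagnostics["starts"].append(str(exc))
            continue
        sse = float(np.sum((hill_response(x, *popt) - y) ** 2))
        diagnostics["starts"].append(sse)
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise FitFailureError("4PL fit failed from every start", diagnostics)

    popt, pcov, sse = best
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 1.0
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    bottom, top, log_ec50, slope = map(float, popt)

    compound = ARM_COMPOUND.get(curve.arm)
    mw = MOLECULAR_WEIGHTS.get(compound) if compound else None
    # potency "not calculable": the fitted plateau sits below 20% Emax, or the
    # tissue never responded above 20% over the tested span (the fitted Top is
    # bounded >= 20 and would otherwise mask a sub-threshold curve)
    nc = top < EMAX_NC_THRESHOLD or float(y.max()) < EMAX_NC_THRESHOLD
    return HillFit(
        bottom=bottom,
        top=top,
        log_ec50=log_ec50,
        hill_slope=slope,
        r_squared=max(0.0, min(1.0, r2)),
        converged=True,
        sse=sse,
        n_points=len(curve),
        se=dict(zip(("bottom", "top", "log_ec50", "hill_slope"), map(float, perr))),
        pec50=None if (mw is None or nc) else pec50_from_log_ec50(log_ec50, mw),
        potency_not_calculable=nc,
        max_observed=float(y.max()),
        tissue_id=curve.tissue.tissue_id,
        arm=curve.arm.value,
    )


def invert_effect(fit: HillFit, percent_of_emax: float) -> float:
    """Concentration (ng/ml) at which the fitted curve reaches a given percent
    of its (Top - Bottom) window above Bottom.  Closed-form 4PL inversion:
    ECp = EC50 * (p / (100 - p))^(1/slope).
    """
    p = percent_of_emax
    if not (0.0 < p < 100.0):
        raise DomainError(f"percent of Emax must be in (0, 100), got {p!r}")
    if not fit.converged:
        raise DomainError("cannot invert a non-converged fit")
    return 10.0 ** (fit.log_ec50 + np.log10(p / (100.0 - p)) / fit.hill_slope)


# ---------------------------------------------------------------------------
# bell-shaped (rise-fall) curves


def bell_response(x_log, bottom, top, log_ec50_rise, slope_rise,
                  log_ec50_fall, slope_fall):
    """Product-of-logistics rise-fall model for non-monotone CRCs."""
    x_log = np.asarray(x_log, dtype=float)
    rise = 1.0 / (1.0 + 10.0 ** ((log_ec50_rise - x_log) * slope_rise))
    fall = 1.0 / (1.0 + 10.0 ** ((x_log - log_ec50_fall) * slope_fall))
    return bottom + (top - bottom) * rise * fall


@dataclass
class BellFit:
    """Fitted rise-fall parameters and the implied peak."""

    bottom: float
    top: float
    log_ec50_rise: float
    slope_rise: float
    log_ec50_fall: float
    slope_fall: float
    peak_effect: float
    peak_log_conc: float
    r_squared: float
    sse: float
    converged: bool = True
    tissue_id: str | None = None
    arm: str | None = None

    def predict(self, concentration) -> np.ndarray:
        return bell_response(
            np.log10(np.asarray(concentration, dtype=float)),
            self.bottom, self.top, self.log_ec50_rise, self.slope_rise,
            self.log_ec50_fall, self.slope_fall,
        )


def fit_bell_shaped(curve: ConcentrationResponseCurve) -> BellFit:
    """Fit the rise-fall model to a non-monotone CRC.

    Raises
    ------
    NotBellShapedError
        The curve is monotone; callers should use :func:`fit_hill`.
    """
    if detect_shape(curve) != "bell":
        raise NotBellShapedError(
            "curve is monotone non-decreasing; use the sigmoid fit"
        )
    x = np.log10(curve.concentrations)
    y = curve.responses
    k = int(np.argmax(y))
    lo = [BOTTOM_BOUNDS[0], TOP_BOUNDS[0], x.min() - 2, 0.1, x.min() - 2, 0.1]
    hi = [BOTTOM_BOUNDS[1], 2 * TOP_BOUNDS[1], x.max() + 2, 6.0, x.max() + 2, 6.0]
    best = None
    for s in (0.5, 1.0, 2.0):
        p0 = np.clip(
            [max(y.min(), 0.0), min(y.max() * 1.1, 2 * TOP_BOUNDS[1]),
             x[max(k - 1, 0)], s, x[min(k + 1, len(x) - 1)], s],
            lo, hi,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    bell_response, x, y, p0=p0, bounds=(lo, hi),
                    method="trf", maxfev=4000,
                )
        except RuntimeError:
            continue
        sse = float(np.sum((bell_response(x, *popt) - y) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise FitFailureError("bell-shape fit failed from every start")
    popt, sse = best
    # locate the peak on a dense grid then refine
    grid = np.linspace(x.min() - 1, x.max() + 1, 2001)
    yy = bell_response(grid, *popt)
    k0 = int(np.argmax(yy))
    res = optimize.minimize_scalar(
        lambda t: -bell_response(t, *popt),
        bounds=(grid[max(k0 - 1, 0)], grid[min(k0 + 1, len(grid) - 1)]),
        method="bounded",
    )
    peak_x = float(res.x)
    tss = float(np.sum((y - y.mean()) ** 2))
    return BellFit(
        *map(float, popt),
        peak_effect=float(bell_response(peak_x, *popt)),
        peak_log_conc=peak_x,
        r_squared=max(0.0, 1.0 - sse / tss) if tss > 0 else 1.0,
        sse=sse,
        tissue_id=curve.tissue.tissue_id,
        arm=curve.arm.value,
    )


def fit_crc(curve: ConcentrationResponseCurve) -> HillFit | BellFit:
    """Dispatch a CRC to the sigmoid or the bell-shaped fitter."""
    if detect_shape(curve) == "bell":
        return fit_bell_shaped(curve)
    return fit_hill(curve)
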