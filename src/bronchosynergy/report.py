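"""End-to-end analysis pipeline and report assembly.

Runs QC filtering, per-curve Hill fits, the Bliss Independence comparison
and the median-effect / Combination Index analysis for every
(compartment, sensitization) cell of a dataset, and assembles a JSON-able
report with full provenance (config hash, seed, versions).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bliss import BlissComparison, bliss_delta_analysis
from .core import (
    Arm,
    Compartment,
    ConcentrationResponseCurve,
    Sensitization,
    StudyDataset,
)
from .errors import DegenerateCurveError, InsufficientDataError, StudyDataError
from .hillfit import BellFit, EMAX_NC_THRESHOLD, HillFit, fit_crc
from .qc import ExclusionReport, qc_vitality_filter
from .unified import (
    CombinationIndexProfile,
    MedianEffectFit,
    ci_profile,
    default_fa_grid,
    fit_median_effect,
)


@dataclass
class AnalysisConfig:
    """Pipeline options; defaults follow the study conventions (alpha 0.05,
    smooth fitted monotherapy curves as the Bliss reference, exclusive-case
    two-term CI)."""

    alpha: float = 0.05
    mass_ratio: tuple[float, float] = (100.0, 6.0)   # (BDP, FF) weight/weight
    use_hill_fits: bool = True
    nonexclusive_ci: bool = False
    drop_inactive: str | None = None
    fa_grid: list[float] | None = None
    min_tissues: int = 2

    def hash(self) -> str:
        doc = asdict(self)
        doc["mass_ratio"] = list(doc["mass_ratio"])
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class CellResult:
    """All results for one (compartment, sensitization) cell."""

    compartment: str
    sensitization: str
    fits: list[HillFit | BellFit]
    group_summary: pd.DataFrame
    bliss: BlissComparison | None
    ci_profile: CombinationIndexProfile | None
    median_effect_fits: dict[str, MedianEffectFit]
    notes: list[str] = field(default_factory=list)


@dataclass
class AnalysisReport:
    """Assembled pipeline output with provenance."""

    cells: list[CellResult]
    qc: ExclusionReport
    time_controls: dict
    provenance: dict

    def to_dict(self) -> dict:
        out = {
            "provenance": self.provenance,
            "qc_exclusions": self.qc.excluded,
            "time_controls": self.time_controls,
            "cells": [],
        }
        for cell in self.cells:
            doc = {
                "compartment": cell.compartment,
                "sensitization": cell.sensitization,
                "curve_fits": [_fit_to_dict(f) for f in cell.fits],
                "group_summary": cell.group_summary.to_dict(orient="records"),
                "median_effect": {
                    k: {a: getattr(f, a) for a in
                        ("m", "dm", "r_squared", "n_points_used", "low_emax_caveat")}
                    for k, f in cell.median_effect_fits.items()
                },
                "bliss": cell.bliss.to_dict() if cell.bliss else None,
                "combination_index": cell.ci_profile.to_dict() if cell.ci_profile else None,
                "notes": cell.notes,
            }
            out["cells"].append(doc)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _fit_to_dict(f) -> dict:
    doc = asdict(f)
    doc["model"] = "bell" if isinstance(f, BellFit) else "hill"
    return doc


def group_mean_curve(curves: list[ConcentrationResponseCurve]):
    """Mean normalized response across tissues at each shared concentration."""
    frames = [
        pd.DataFrame({"conc": c.concentrations.round(9), "resp": c.responses})
        for c in curves
    ]
    df = pd.concat(frames).groupby("conc", sort=True)["resp"].mean()
    return df.index.to_numpy(), df.to_numpy()


def summarize_time_controls(ds: StudyDataset) -> dict:
    """Mean per-step drift of the vehicle time controls (no correction applied)."""
    drifts = []
    for c in ds.select(arm=Arm.VEHICLE):
        y = c.responses
        if len(y) > 1:
            drifts.append(float((y[-1] - y[0]) / (len(y) - 1)))
    return {
        "n_time_controls": len(drifts),
        "mean_drift_per_step": float(np.mean(drifts)) if drifts else None,
    }


def _group_summary(fits: list[HillFit | BellFit]) -> pd.DataFrame:
    rows = []
    by_arm: dict[str, list] = {}
    for f in fits:
        by_arm.setdefault(f.arm, []).append(f)
    for arm, arm_fits in by_arm.items():
        hill = [f for f in arm_fits if isinstance(f, HillFit)]
        # for sub-threshold (NC) curves the bounded fit extrapolates Top above
        # the tested range; summarize their observed maximum instead
        tops = np.array([
            f.max_observed if (f.potency_not_calculable and f.max_observed is not None)
            else f.top
            for f in hill
        ])
        pec = np.array([f.pec50 for f in hill if f.pec50 is not None])
        # group potency is NC when most curves are individually NC
        nc = bool(hill) and sum(f.potency_not_calculable for f in hill) > len(hill) / 2
        n = len(hill)
        rows.append(
            {
                "arm": arm,
                "n": n,
                "emax_mean": float(tops.mean()) if n else None,
                "emax_sem": float(tops.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
                "pec50_mean": None if (nc or not len(pec)) else float(pec.mean()),
                "pec50_sem": (
                    None if (nc or len(pec) < 2)
                    else float(pec.std(ddof=1) / np.sqrt(len(pec)))
                ),
                "potency": "NC" if nc else "calculable",
                "n_bell_shaped": len(arm_fits) - n,
            }
        )
    return pd.DataFrame(rows)


def analyze_cell(
    ds: StudyDataset,
    compartment: Compartment,
    sensitization: Sensitization,
    config: AnalysisConfig,
) -> CellResult:
    notes: list[str] = []
    sel = lambda arm: ds.select(compartment, sensitization, arm)
    treated = [
        c for c in ds.select(compartment, sensitization) if c.arm is not Arm.VEHICLE
    ]
    fits = [fit_crc(c) for c in treated]
    summary = _group_summary(fits)

    combo, ff, bdp = sel(Arm.BDP_FF_COMBO), sel(Arm.FF_MONO), sel(Arm.BDP_MONO)
    bliss = None
    profile = None
    me_fits: dict[str, MedianEffectFit] = {}

    if min(len(combo), len(ff), len(bdp)) >= config.min_tissues:
        hill_by_tissue = {f.tissue_id: f for f in fits if isinstance(f, HillFit)}
        bliss = bliss_delta_analysis(
            combo, bdp, ff,                      # mass_ratio (BDP, FF) order
            mass_ratio=config.mass_ratio,
            alpha=config.alpha,
            use_fits=config.use_hill_fits,
            fits_a=[hill_by_tissue[c.tissue.tissue_id] for c in sorted(
                bdp, key=lambda c: c.tissue.tissue_id)],
            fits_b=[hill_by_tissue[c.tissue.tissue_id] for c in sorted(
                ff, key=lambda c: c.tissue.tissue_id)],
        )
        try:
            me_fits = _median_effect_fits(combo, ff, bdp, notes)
            drop = config.drop_inactive
            if "BDP" not in me_fits and drop is None:
                drop = "a"  # BDP term has no usable fit: upper-bound CI
            profile = ci_profile(
                me_fits["combo"],
                me_fits.get("BDP"),
                me_fits.get("FF"),
                mass_ratio=config.mass_ratio,
                fa_grid=config.fa_grid or default_fa_grid(),
                nonexclusive=config.nonexclusive_ci,
                drop_inactive=drop,
            )
        except (InsufficientDataError, DegenerateCurveError) as exc:
            notes.append(f"Combination Index analysis skipped: {exc}")
    else:
        notes.append(
            "Bliss / Combination Index analysis skipped: needs the combination "
            "and both monotherapy arms with >= "
            f"{config.min_tissues} tissues each"
        )

    return CellResult(
        compartment=compartment.value,
        sensitization=sensitization.value,
        fits=fits,
        group_summary=summary,
        bliss=bliss,
        ci_profile=profile,
        median_effect_fits=me_fits,
        notes=notes,
    )


def _median_effect_fits(combo, ff, bdp, notes) -> dict[str, MedianEffectFit]:
    """Median-effect fits on the group-mean curves (one fit per condition)."""
    out: dict[str, MedianEffectFit] = {}
    conc, resp = group_mean_curve(combo)
    out["combo"] = fit_median_effect(conc, resp / 100.0, label="BDP_FF")
    conc, resp = group_mean_curve(ff)
    out["FF"] = fit_median_effect(conc, resp / 100.0, label="FF")
    conc, resp = group_mean_curve(bdp)
    caveat = float(np.max(resp)) < EMAX_NC_THRESHOLD
    try:
        out["BDP"] = fit_median_effect(
            conc, resp / 100.0, label="BDP", low_emax_caveat=caveat
        )
    except StudyDataError as exc:
        notes.append(f"BDP median-effect fit unavailable ({exc}); term dropped")
    return out


def run_analysis(
    ds: StudyDataset,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full pipeline: QC -> fits -> Bliss -> Combination Index."""
    config = config or AnalysisConfig()
    filtered, qc_report = qc_vitality_filter(ds)
    time_controls = summarize_time_controls(filtered)
    cells = [
        analyze_cell(filtered, comp, sens, config)
        for comp, sens in filtered.cells()
    ]
    provenance = {
        "package_version": __version__,
        "config_hash": config.hash(),
        "config": {**asdict(config), "mass_ratio": list(config.mass_ratio)},
        "seed": ds.metadata.get("generator_seed"),
        "n_curves_input": len(ds),
        "n_curves_analyzed": len(filtered),
    }
    return AnalysisReport(
        cells=cells, qc=qc_report, time_controls=time_controls, provenance=provenance
    )


def render_report(report: AnalysisReport | dict) -> str:
    """Human-readable summary of an analysis report."""
    doc = report.to_dict() if isinstance(report, AnalysisReport) else report
    lines = [
        f"bronchosynergy analysis report (config {doc['provenance']['config_hash']})",
        f"curves analyzed: {doc['provenance']['n_curves_analyzed']}"
        f" / {doc['provenance']['n_curves_input']}"
        f" (QC excluded tissues: {len(doc['qc_exclusions'])})",
    ]
    tc = doc["time_controls"]
    if tc.get("n_time_controls"):
        lines.append(
            f"time controls: n={tc['n_time_controls']}, mean drift "
            f"{tc['mean_drift_per_step']:+.2f}%/step (summary only, no correction)"
        )
    for cell in doc["cells"]:
        lines.append(f"\n== {cell['compartment']} airways, {cell['sensitization']} ==")
        for row in cell["group_summary"]:
            pec_mean = row.get("pec50_mean")
            have_pec = pec_mean is not None and np.isfinite(pec_mean)
            pec_sem = row.get("pec50_sem")
            pot = (
                f"pEC50 {pec_mean:.2f}"
                + (f" ± {pec_sem:.2f}" if pec_sem is not None and np.isfinite(pec_sem) else "")
                if row["potency"] != "NC" and have_pec
                else "pEC50 NC"
            )
            lines.append(
                f"  {row['arm']:>7}: n={row['n']}, Emax {row['emax_mean']:.2f}%"
                + (f" ± {row['emax_sem']:.2f}" if row.get("emax_sem") else "")
                + f", {pot}"
            )
        if cell["bliss"]:
            n_syn = sum(
                1 for r in cell["bliss"]["per_point"]
                if r["classification"] == "synergistic"
            )
            lines.append(
                f"  Bliss: {n_syn}/{len(cell['bliss']['per_point'])} points "
                f"synergistic; curve-level ANOVA p = {cell['bliss']['p_curve']:.2g}"
            )
        if cell["combination_index"]:
            lines.append("  Combination Index (fa: CI grade):")
            for row in cell["combination_index"]["fa_ci"]:
                if round(row["fa"] * 100) in (15, 25, 50, 75, 90):
                    lines.append(
                        f"    {row['fa']:.2f}: {row['ci']:.2f} {row['grade']}"
                    )
        elif cell["bliss"] is None:
            lines.append("  no combination arms in this cell")
    return "\n".join(lines)
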