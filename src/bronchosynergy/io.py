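"""CSV reading/writing of study datasets and tabular exports.

The long-format schema has one row per cumulative-addition step; all columns
are addressed by name, never by position.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ARM_COMPOUND,
    MOLECULAR_WEIGHTS,
    Arm,
    Compartment,
    ConcentrationResponseCurve,
    ConcentrationResponsePoint,
    Sensitization,
    StudyDataset,
    ng_ml_to_molar,
    normalize_relaxation,
)
from .errors import DuplicateRowError, RowValidationError, SchemaError

REQUIRED_COLUMNS = [
    "tissue_id",
    "subject_id",
    "compartment",
    "sensitization",
    "arm",
    "concentration_ng_ml",
    "raw_response",
    "response_units",
    "histamine_plateau",
    "papaverine_response",
    "qc_efs",
    "qc_ach_area_reduction",
]


def read_study(path: str | Path) -> StudyDataset:
    """Read a long-format CRC table into a validated :class:`StudyDataset`.

    Rows are grouped into curves keyed by (tissue_id, arm) and sorted by
    ascending concentration; normalized relaxation is recomputed from the raw
    response and the tissue's plateau/papaverine references.

    Raises
    ------
    SchemaError
        Missing required columns or an empty file.
    RowValidationError
        Non-positive concentration or inconsistent per-tissue metadata.
    DuplicateRowError
        Repeated (tissue, arm, concentration) triple.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    bad = df.index[~(df["concentration_ng_ml"] > 0)]
    if len(bad):
        raise RowValidationError(
            f"{path}: non-positive concentration in row(s) {list(bad[:5])}"
        )
    dup = df.duplicated(subset=["tissue_id", "arm", "concentration_ng_ml"])
    if dup.any():
        raise DuplicateRowError(
            f"{path}: duplicate (tissue, arm, concentration) in row(s) "
            f"{list(df.index[dup][:5])}"
        )

    curves: list[ConcentrationResponseCurve] = []
    for (tissue_id, arm_name), grp in df.groupby(["tissue_id", "arm"], sort=True):
        grp = grp.sort_values("concentration_ng_ml")
        first = grp.iloc[0]
        for col in ("subject_id", "compartment", "sensitization", "histamine_plateau",
                    "papaverine_response", "response_units"):
            if grp[col].nunique(dropna=False) > 1:
                raise RowValidationError(
                    f"{path}: tissue {tissue_id} arm {arm_name}: column {col!r} "
                    "is not constant within the curve"
                )
        tissue = _tissue_from_row(first)
        arm = Arm(arm_name)
        mw = MOLECULAR_WEIGHTS.get(ARM_COMPOUND[arm] or "", None)
        points = []
        for _, row in grp.iterrows():
            conc = float(row["concentration_ng_ml"])
            points.append(
                ConcentrationResponsePoint(
                    concentration=conc,
                    raw_response=float(row["raw_response"]),
                    normalized_relaxation=normalize_relaxation(
                        tissue.histamine_plateau,
                        tissue.papaverine_response,
                        float(row["raw_response"]),
                    ),
                    concentration_molar=ng_ml_to_molar(conc, mw) if mw else None,
                )
            )
        curves.append(ConcentrationResponseCurve(tissue=tissue, arm=arm, points=points))
    return StudyDataset(curves=curves, metadata={"source": str(path)})


def _tissue_from_row(row: pd.Series):
    from .core import TissueRecord

    qc_efs = row["qc_efs"]
    qc_ach = row["qc_ach_area_reduction"]
    return TissueRecord(
        tissue_id=str(row["tissue_id"]),
        subject_id=str(row["subject_id"]),
        compartment=Compartment(row["compartment"]),
        sensitization=Sensitization(row["sensitization"]),
        histamine_plateau=float(row["histamine_plateau"]),
        papaverine_response=float(row["papaverine_response"]),
        response_units=str(row["response_units"]),
        qc_efs_responsive=None if pd.isna(qc_efs) else bool(int(qc_efs)),
        qc_ach_area_reduction=None if pd.isna(qc_ach) else float(qc_ach),
    )


def study_to_frame(ds: StudyDataset) -> pd.DataFrame:
    """Flatten a dataset back to the long-format schema."""
    rows = []
    for curve in ds.curves:
        t = curve.tissue
        for p in curve.points:
            rows.append(
                {
                    "tissue_id": t.tissue_id,
                    "subject_id": t.subject_id,
                    "compartment": t.compartment.value,
                    "sensitization": t.sensitization.value,
                    "arm": curve.arm.value,
                    "concentration_ng_ml": p.concentration,
                    "raw_response": p.raw_response,
                    "response_units": t.response_units,
                    "histamine_plateau": t.histamine_plateau,
                    "papaverine_response": t.papaverine_response,
                    "qc_efs": (
                        np.nan if t.qc_efs_responsive is None else int(t.qc_efs_responsive)
                    ),
                    "qc_ach_area_reduction": (
                        np.nan if t.qc_ach_area_reduction is None else t.qc_ach_area_reduction
                    ),
                }
            )
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)


def write_study(ds: StudyDataset, path: str | Path) -> None:
    """Write a dataset to CSV; ``read_study`` of the result round-trips."""
    study_to_frame(ds).to_csv(Path(path), index=False)
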