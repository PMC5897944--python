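"""Tissue-vitality quality control.

Organ-bath rings must respond to electrical field stimulation (25 Hz); PCLS
must show at least a 25% luminal-area reduction to acetylcholine.  Tissues
failing the rule for their compartment are excluded before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Compartment, StudyDataset
from .errors import QCFieldMissingError

#: minimum acetylcholine-induced area reduction for a vital PCLS
ACH_AREA_REDUCTION_MIN = 0.25


@dataclass
class ExclusionReport:
    """Tissues removed by QC and the reason each one failed."""

    excluded: dict[str, str] = field(default_factory=dict)  # tissue_id -> reason

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def qc_vitality_filter(ds: StudyDataset) -> tuple[StudyDataset, ExclusionReport]:
    """Drop non-vital tissues; return the filtered dataset and an exclusion report.

    Raises
    ------
    QCFieldMissingError
        If the QC field matching a tissue's compartment is absent.
    """
    report = ExclusionReport()
    keep = []
    for curve in ds.curves:
        t = curve.tissue
        if t.tissue_id in report.excluded:
            continue
        if t.compartment is Compartment.MEDIUM_BRONCHUS:
            if t.qc_efs_responsive is None:
                raise QCFieldMissingError(
                    f"tissue {t.tissue_id}: organ-bath ring lacks the EFS vitality flag"
                )
            if not t.qc_efs_responsive:
                report.excluded[t.tissue_id] = "no response to EFS (25 Hz)"
                continue
        else:
            if t.qc_ach_area_reduction is None:
                raise QCFieldMissingError(
                    f"tissue {t.tissue_id}: PCLS lacks the ACh area-reduction QC field"
                )
            if t.qc_ach_area_reduction < ACH_AREA_REDUCTION_MIN:
                report.excluded[t.tissue_id] = (
                    f"ACh area reduction {t.qc_ach_area_reduction:.2f} < "
                    f"{ACH_AREA_REDUCTION_MIN:.2f}"
                )
                continue
        keep.append(curve)
    filtered = StudyDataset(
        curves=[c for c in keep if c.tissue.tissue_id not in report.excluded],
        metadata=dict(ds.metadata),
    )
    return filtered, report
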