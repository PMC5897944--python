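"""Core data model for ex vivo concentration-response studies.

An experiment measures bronchorelaxation in isolated human airways: medium
bronchi mounted in an organ bath (isometric tension, grams) or small airways
as precision-cut lung slices (luminal area, mm^2).  Each tissue is
sub-maximally pre-contracted with histamine, then relaxed by cumulative
additions of drug; papaverine at the end of the experiment defines the
maximal achievable relaxation (100%).  Responses are therefore expressed as
percent of the papaverine maximum.

Canonical concentration unit is ng/ml: the fixed-dose combination arms are
defined by a 100:6 BDP:FF *mass* ratio, so mass concentration is primary and
molar values are derived through a molecular-weight table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

from .errors import DegenerateTissueError, RowValidationError


class Compartment(str, Enum):
    """Airway compartment; determines the measurement modality and QC rule."""

    MEDIUM_BRONCHUS = "medium"   # organ-bath ring, isometric tension (g)
    SMALL_AIRWAY = "small"       # PCLS, luminal area (mm^2)


class Sensitization(str, Enum):
    NS = "NS"  # incubated with non-atopic control serum
    PS = "PS"  # passively sensitized with atopic asthmatic serum


class Arm(str, Enum):
    FF_MONO = "FF"
    BDP_MONO = "BDP"
    BDP_FF_COMBO = "BDP_FF"
    VEHICLE = "vehicle"


#: molecular weights (g/mol) used for the molar annotation of mass
#: concentrations; FF is the fumarate dihydrate (the form FDC doses refer to)
MOLECULAR_WEIGHTS: dict[str, float] = {"FF": 840.91, "BDP": 521.04}

#: compound whose molecular weight applies to a monotherapy arm
ARM_COMPOUND: dict[Arm, str | None] = {
    Arm.FF_MONO: "FF",
    Arm.BDP_MONO: "BDP",
    Arm.BDP_FF_COMBO: None,   # mixture: no single molar scale
    Arm.VEHICLE: None,
}

#: default BDP:FF weight/weight ratio of the fixed-dose combination
DEFAULT_MASS_RATIO: tuple[float, float] = (100.0, 6.0)


def ng_ml_to_molar(conc_ng_ml: float, mw: float) -> float:
    """Convert a mass concentration (ng/ml) to molar using weight ``mw`` (g/mol)."""
    return conc_ng_ml / (mw * 1e6)


def molar_to_ng_ml(conc_molar: float, mw: float) -> float:
    return conc_molar * mw * 1e6


def pec50_from_log_ec50(log_ec50_ng_ml: float, mw: float) -> float:
    """pEC50 = -log10(EC50 in molar) from a log10 EC50 on the ng/ml scale."""
    return math.log10(mw) + 6.0 - log_ec50_ng_ml


def log_ec50_from_pec50(pec50: float, mw: float) -> float:
    return math.log10(mw) + 6.0 - pec50


def normalize_relaxation(plateau: float, papaverine: float, observed: float) -> float:
    """Express an observed raw response as percent of the papaverine maximum.

    ``plateau`` is the histamine pre-contraction reading, ``papaverine`` the
    reading after the maximal relaxant; both in raw units (tension in g, where
    relaxation lowers the reading, or luminal area in mm^2, where relaxation
    raises it).  The affine map sends plateau -> 0% and papaverine -> 100% and
    is sign-convention free: it works unchanged for both modalities.

    Raises
    ------
    DegenerateTissueError
        If the tissue has no dynamic range (plateau == papaverine).
    """
    span = plateau - papaverine
    if span == 0 or not math.isfinite(span):
        raise DegenerateTissueError(
            f"zero dynamic range: plateau {plateau!r} equals papaverine {papaverine!r}"
        )
    return 100.0 * (plateau - observed) / span


@dataclass
class TissueRecord:
    """One isolated airway preparation and its reference readings."""

    tissue_id: str
    subject_id: str
    compartment: Compartment
    sensitization: Sensitization
    histamine_plateau: float
    papaverine_response: float
    response_units: str = "g"                       # "g" or "mm2"
    qc_efs_responsive: bool | None = None           # organ-bath rings only
    qc_ach_area_reduction: float | None = None      # PCLS only, fraction

    def __post_init__(self) -> None:
        self.compartment = Compartment(self.compartment)
        self.sensitization = Sensitization(self.sensitization)
        if self.histamine_plateau == self.papaverine_response:
            raise DegenerateTissueError(
                f"tissue {self.tissue_id}: plateau equals papaverine response"
            )

    def normalize(self, observed: float) -> float:
        return normalize_relaxation(
            self.histamine_plateau, self.papaverine_response, observed
        )


@dataclass
class ConcentrationResponsePoint:
    """One cumulative-addition step: concentration plus raw and normalized response."""

    concentration: float          # ng/ml, canonical
    raw_response: float           # tension g or luminal area mm^2
    normalized_relaxation: float  # percent of papaverine maximum
    concentration_molar: float | None = None

    def __post_init__(self) -> None:
        if not (self.concentration > 0):
            raise RowValidationError(
                f"concentration must be positive, got {self.concentration!r}"
            )


@dataclass
class ConcentrationResponseCurve:
    """Ordered CRC of one tissue under one treatment arm."""

    tissue: TissueRecord
    arm: Arm
    points: list[ConcentrationResponsePoint]
    ratio_bdp_ff: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.arm = Arm(self.arm)
        conc = [p.concentration for p in self.points]
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise RowValidationError(
                f"tissue {self.tissue.tissue_id} arm {self.arm.value}: cumulative "
                "concentrations must be strictly increasing"
            )
        if self.arm is Arm.BDP_FF_COMBO and self.ratio_bdp_ff is None:
            self.ratio_bdp_ff = DEFAULT_MASS_RATIO

    @property
    def concentrations(self):
        import numpy as np

        return np.array([p.concentration for p in self.points])

    @property
    def responses(self):
        import numpy as np

        return np.array([p.normalized_relaxation for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class StudyDataset:
    """Collection of CRCs, typically several tissues x several arms."""

    curves: list[ConcentrationResponseCurve]
    metadata: dict = field(default_factory=dict)

    def select(
        self,
        compartment: Compartment | str | None = None,
        sensitization: Sensitization | str | None = None,
        arm: Arm | str | None = None,
    ) -> list[ConcentrationResponseCurve]:
        out: Iterable[ConcentrationResponseCurve] = self.curves
        if compartment is not None:
            compartment = Compartment(compartment)
            out = [c for c in out if c.tissue.compartment is compartment]
        if sensitization is not None:
            sensitization = Sensitization(sensitization)
            out = [c for c in out if c.tissue.sensitization is sensitization]
        if arm is not None:
            arm = Arm(arm)
            out = [c for c in out if c.arm is arm]
        return list(out)

    def n_tissues(self, compartment=None, sensitization=None, arm=None) -> int:
        return len({c.tissue.tissue_id for c in self.select(compartment, sensitization, arm)})

    def cells(self) -> list[tuple[Compartment, Sensitization]]:
        """Distinct (compartment, sensitization) cells present in the dataset."""
        seen: list[tuple[Compartment, Sensitization]] = []
        for c in self.curves:
            key = (c.tissue.compartment, c.tissue.sensitization)
            if key not in seen:
                seen.append(key)
        return seen

    def __iter__(self) -> Iterator[ConcentrationResponseCurve]:
        return iter(self.curves)

    def __len__(self) -> int:
        return len(self.curves)
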