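import numpy as np
import pytest
from hypothesis import settings

from bronchosynergy import (
    Arm,
    Compartment,
    ConcentrationResponseCurve,
    ConcentrationResponsePoint,
    GeneratorConfig,
    Sensitization,
    TissueRecord,
    generate_study,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_tissue(
    tissue_id="T1",
    compartment=Compartment.MEDIUM_BRONCHUS,
    sensitization=Sensitization.NS,
    plateau=2.0,
    papaverine=0.5,
    **kw,
):
    defaults = dict(qc_efs_responsive=True)
    if Compartment(compartment) is Compartment.SMALL_AIRWAY:
        defaults = dict(qc_ach_area_reduction=0.4)
        kw.setdefault("response_units", "mm2")
    defaults.update(kw)
    return TissueRecord(
        tissue_id=tissue_id,
        subject_id=f"S-{tissue_id}",
        compartment=compartment,
        sensitization=sensitization,
        histamine_plateau=plateau,
        papaverine_response=papaverine,
        **defaults,
    )


def make_curve(conc, resp, arm=Arm.FF_MONO, tissue=None, **tissue_kw):
    """Build a CRC from concentration / normalized-response arrays; raw
    responses are back-computed from the tissue references."""
    tissue = tissue or make_tissue(**tissue_kw)
    span = tissue.histamine_plateau - tissue.papaverine_response
    points = [
        ConcentrationResponsePoint(
            concentration=float(c),
            raw_response=float(tissue.histamine_plateau - r / 100.0 * span),
            normalized_relaxation=float(r),
        )
        for c, r in zip(conc, resp)
    ]
    return ConcentrationResponseCurve(tissue=tissue, arm=arm, points=points)


@pytest.fixture(scope="session")
def ns_medium_study():
    """One default simulated study (NS medium bronchi, Bliss-null, seed 42)."""
    return generate_study(GeneratorConfig(), seed=42)


@pytest.fixture()
def study_csv(tmp_path, ns_medium_study):
    from bronchosynergy import write_study

    ds, _ = ns_medium_study
    path = tmp_path / "study.csv"
    write_study(ds, path)
    return path
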