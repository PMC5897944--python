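"""Synthetic organ-bath / PCLS study generator.

Emulates the statistical structure of an ex vivo fixed-ratio combination
study: per-tissue Hill-curve truths drawn around group-level monotherapy
parameters, a combination surface built from a configurable interaction
model, additive Gaussian measurement noise on the normalized response, raw
tension/area readings consistent with drawn plateau and papaverine
references, vehicle time controls at the 1-in-7 organ-bath rate, and
optional QC failures.

Interaction models:

``bliss_null``
    The combination response is the probabilistic-independence composite of
    the component fractional effects (the Bliss surface); the Bliss delta is
    0 in expectation, so this is the type-I-error null.
``loewe_null``
    Dose-additive combination of two median-effect agents with a shared
    shape; the Combination Index is exactly 1 at every effect level, so this
    is the CI null.
``potency_shift``
    The Bliss surface evaluated at component doses multiplied by a synergy
    factor psi >= 1; psi = 1 recovers ``bliss_null``, psi > 1 yields
    positive Bliss deltas and CI < 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bliss import clip_fraction
from .core import (
    Arm,
    Compartment,
    ConcentrationResponseCurve,
    ConcentrationResponsePoint,
    MOLECULAR_WEIGHTS,
    Sensitization,
    StudyDataset,
    TissueRecord,
    log_ec50_from_pec50,
    pec50_from_log_ec50,
)
from .errors import ConfigurationError, PairingError
from .hillfit import fit_hill, hill_response

SQRT5 = math.sqrt(5.0)


@dataclass
class ArmTruth:
    """Group-level Hill truth for one monotherapy arm plus between-tissue SDs."""

    top: float                  # Emax, percent of papaverine maximum
    pec50: float                # -log10 EC50 (molar)
    slope: float = 1.0
    bottom: float = 0.0
    mw: float = MOLECULAR_WEIGHTS["FF"]
    sd_log_ec50: float = 0.0    # between-tissue SD of log10 EC50
    sd_top: float = 0.0         # between-tissue SD of Emax
    potency_not_calculable: bool = False

    @property
    def log_ec50(self) -> float:
        """log10 EC50 on the canonical ng/ml scale."""
        return log_ec50_from_pec50(self.pec50, self.mw)


def table2_presets() -> dict[tuple[Compartment, Sensitization], dict[str, ArmTruth]]:
    """Monotherapy truths per (compartment, sensitization) cell.

    FF Emax and pEC50 are the study's printed group values, with
    between-tissue SDs back-calculated as SEM * sqrt(5); the PS small-airway
    Emax has no printed SEM, so the mean of the other three (2.78%) is used.
    BDP arms are shallow sub-20%-Emax curves (potency not calculable); their
    parameters are nominal, chosen mid-grid so the NC pathway is exercised.
    """
    ff_mw, bdp_mw = MOLECULAR_WEIGHTS["FF"], MOLECULAR_WEIGHTS["BDP"]

    def ff(top, sem_top, pec50, sem_pec50):
        return ArmTruth(
            top=top, pec50=pec50, slope=1.0, mw=ff_mw,
            sd_log_ec50=sem_pec50 * SQRT5, sd_top=sem_top * SQRT5,
        )

    def bdp(pec50):
        return ArmTruth(
            top=12.0, pec50=pec50, slope=0.8, mw=bdp_mw,
            sd_log_ec50=0.2, sd_top=3.0, potency_not_calculable=True,
        )

    M, S = Compartment.MEDIUM_BRONCHUS, Compartment.SMALL_AIRWAY
    NS, PS = Sensitization.NS, Sensitization.PS
    return {
        (M, NS): {"FF": ff(97.00, 2.77, 8.26, 0.07), "BDP": bdp(7.24)},
        (M, PS): {"FF": ff(94.96, 1.22, 8.89, 0.04), "BDP": bdp(7.24)},
        (S, NS): {"FF": ff(72.03, 4.34, 7.13, 0.11), "BDP": bdp(6.72)},
        (S, PS): {"FF": ff(105.30, 2.78, 7.52, 0.09), "BDP": bdp(6.72)},
    }


def default_grids() -> dict[str, dict[Compartment, np.ndarray]]:
    """Dosing grids (ng/ml): combination totals 1.06-106 in medium bronchi and
    1.06-1060 in small airways, with monotherapy grids spanning each agent's
    active range."""
    M, S = Compartment.MEDIUM_BRONCHUS, Compartment.SMALL_AIRWAY
    return {
        "combo": {
            M: np.round(1.06 * np.logspace(0, 2, 9), 6),
            S: np.round(1.06 * np.logspace(0, 3, 9), 6),
        },
        "FF": {M: np.logspace(-2, 2, 9), S: np.logspace(-1, 3, 9)},
        "BDP": {M: np.logspace(0, 2, 7), S: np.logspace(0, 3, 7)},
    }


@dataclass
class GeneratorConfig:
    """Everything needed to simulate a study; defaults mirror the ex vivo design
    (n = 5 tissues per arm, 3% response noise, 100:6 BDP:FF mass ratio)."""

    cells: list[tuple[Compartment, Sensitization]] = field(
        default_factory=lambda: [(Compartment.MEDIUM_BRONCHUS, Sensitization.NS)]
    )
    truths: dict = field(default_factory=table2_presets)
    grids: dict = field(default_factory=default_grids)
    n_tissues: int = 5
    noise_sd: float = 3.0                      # percent of papaverine maximum
    mass_ratio: tuple[float, float] = (100.0, 6.0)
    interaction_model: str = "bliss_null"      # bliss_null | loewe_null | potency_shift
    psi: float = 1.0                           # synergy factor, >= 1
    include_arms: tuple[str, ...] = ("FF", "BDP", "BDP_FF")
    time_control_drift: float = 0.5            # percent drift per addition step
    qc_fail_prob: float = 0.0

    def validate(self) -> None:
        if self.psi < 1.0:
            raise ConfigurationError(f"psi must be >= 1, got {self.psi}")
        if self.n_tissues < 2:
            raise ConfigurationError("n_tissues must be >= 2")
        if self.interaction_model not in ("bliss_null", "loewe_null", "potency_shift"):
            raise ConfigurationError(
                f"unknown interaction model {self.interaction_model!r}"
            )
        for grids in self.grids.values():
            for g in grids.values():
                g = np.asarray(g)
                if np.any(np.diff(g) <= 0):
                    raise ConfigurationError("dosing grids must be strictly increasing")
        for cell in self.cells:
            if tuple(cell) not in {tuple(k) for k in self.truths}:
                raise ConfigurationError(f"no truth configured for cell {cell}")


def loewe_null_config(sd_log_ec50: float = 0.1, noise_sd: float = 3.0) -> GeneratorConfig:
    """Canonical dose-additive null scenario for Combination Index calibration.

    Two fully active agents (Emax 100%) with a shared unit shape and a ~0.8
    log potency gap, combined at the 100:6 mass ratio.  Dosing grids bracket
    each condition's median-effect dose by +/- 1.5 log units, the standard
    design for median-effect analysis (points spanning fa ~ 0.05-0.95).
    Under this truth the Combination Index is exactly 1 at every effect
    level, so the pipeline's CI estimates can be checked against 1.
    """
    M, NS = Compartment.MEDIUM_BRONCHUS, Sensitization.NS
    ff = ArmTruth(top=100.0, pec50=8.26, slope=1.0,
                  mw=MOLECULAR_WEIGHTS["FF"], sd_log_ec50=sd_log_ec50)
    bdp = ArmTruth(top=100.0, pec50=7.24, slope=1.0,
                   mw=MOLECULAR_WEIGHTS["BDP"], sd_log_ec50=sd_log_ec50)
    ec_ff, ec_bdp = 10.0**ff.log_ec50, 10.0**bdp.log_ec50
    w_bdp, w_ff = 100.0 / 106.0, 6.0 / 106.0
    dm_combo = 1.0 / (w_bdp / ec_bdp + w_ff / ec_ff)
    span = np.logspace(-1.5, 1.5, 9)
    return GeneratorConfig(
        cells=[(M, NS)],
        truths={(M, NS): {"FF": ff, "BDP": bdp}},
        grids={
            "FF": {M: ec_ff * span},
            "BDP": {M: ec_bdp * span},
            "combo": {M: dm_combo * span},
        },
        interaction_model="loewe_null",
        noise_sd=noise_sd,
    )


@dataclass
class GroundTruth:
    """Latent parameters behind a simulated dataset, for recovery checks."""

    seed: int
    interaction_model: str
    psi: float
    mass_ratio: tuple[float, float]
    noise_sd: float
    arm_truths: dict        # "<comp>|<sens>|<arm>" -> ArmTruth fields
    tissue_params: dict     # tissue_id -> latent parameter dict

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["mass_ratio"] = list(doc["mass_ratio"])
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        doc["mass_ratio"] = tuple(doc["mass_ratio"])
        return cls(**doc)


def _draw_tissue_params(rng, truth: ArmTruth) -> dict:
    top = rng.normal(truth.top, truth.sd_top)
    # sub-threshold ("NC") arms stay below 20% Emax; active arms within the
    # physiologic window with >100% clip tolerance
    top = float(
        np.clip(top, 5.0, 18.0) if truth.potency_not_calculable
        else np.clip(top, 20.0, 115.0)
    )
    return {
        "bottom": truth.bottom,
        "top": top,
        "log_ec50": float(rng.normal(truth.log_ec50, truth.sd_log_ec50)),
        "slope": truth.slope,
        "pec50_offset": truth.pec50 + truth.log_ec50,  # mw offset, for reporting
    }


def _hill_frac(params: dict, conc: np.ndarray) -> np.ndarray:
    """Fractional effect of one latent Hill curve at ng/ml concentrations."""
    resp = hill_response(
        np.log10(conc), params["bottom"], params["top"],
        params["log_ec50"], params["slope"],
    )
    return clip_fraction(resp / 100.0, warn=False)


def _combo_response(
    model: str, psi: float, p_ff: dict, p_bdp: dict,
    c_ff: np.ndarray, c_bdp: np.ndarray,
) -> np.ndarray:
    if model in ("bliss_null", "potency_shift"):
        ex = _hill_frac(p_ff, psi * c_ff)
        ey = _hill_frac(p_bdp, psi * c_bdp)
        return 100.0 * (ex + ey - ex * ey)
    # loewe_null: dose-additive median-effect agents with shared shape
    if not np.isclose(p_ff["slope"], p_bdp["slope"]):
        raise ConfigurationError(
            "loewe_null requires equal Hill slopes for both components"
        )
    m = p_ff["slope"]
    u = c_ff / 10.0 ** p_ff["log_ec50"] + c_bdp / 10.0 ** p_bdp["log_ec50"]
    return 100.0 * u**m / (1.0 + u**m)


def generate_study(config: GeneratorConfig, seed: int) -> tuple[StudyDataset, GroundTruth]:
    """Simulate one study; identical (config, seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(seed)
    ra, rb = config.mass_ratio
    curves: list[ConcentrationResponseCurve] = []
    tissue_params: dict[str, dict] = {}
    arm_truths: dict[str, dict] = {}

    for comp, sens in (tuple(c) for c in config.cells):
        comp, sens = Compartment(comp), Sensitization(sens)
        cell_truth = config.truths[(comp, sens)]
        for drug, truth in cell_truth.items():
            arm_truths[f"{comp.value}|{sens.value}|{drug}"] = asdict(truth)

        n_treated_rings = 0
        for arm_name in config.include_arms:
            arm = Arm(arm_name)
            grid = np.asarray(
                config.grids["combo" if arm is Arm.BDP_FF_COMBO else arm_name][comp],
                dtype=float,
            )
            for i in range(config.n_tissues):
                tid = f"{comp.value}-{sens.value}-{arm.value}-{i + 1:02d}"
                if arm is Arm.BDP_FF_COMBO:
                    p_ff = _draw_tissue_params(rng, cell_truth["FF"])
                    p_bdp = _draw_tissue_params(rng, cell_truth["BDP"])
                    c_bdp, c_ff = grid * ra / (ra + rb), grid * rb / (ra + rb)
                    mean_resp = _combo_response(
                        config.interaction_model, config.psi, p_ff, p_bdp, c_ff, c_bdp
                    )
                    latent = {"FF": p_ff, "BDP": p_bdp}
                else:
                    params = _draw_tissue_params(rng, cell_truth[arm.value])
                    mean_resp = 100.0 * _hill_frac(params, grid)
                    latent = params
                noise = rng.normal(0.0, config.noise_sd, size=grid.shape)
                resp = np.clip(mean_resp + noise, -5.0, 115.0)
                curves.append(
                    _make_curve(rng, comp, sens, arm, tid, grid, resp, config)
                )
                tissue_params[tid] = {
                    "arm": arm.value,
                    "compartment": comp.value,
                    "sensitization": sens.value,
                    "latent": latent,
                }
                if comp is Compartment.MEDIUM_BRONCHUS:
                    n_treated_rings += 1

        # vehicle time controls: one ring per seven mounted in the organ bath
        if comp is Compartment.MEDIUM_BRONCHUS and Arm.VEHICLE.value not in config.include_arms:
            n_vehicle = max(1, round(n_treated_rings / 6))
            grid = np.asarray(config.grids["combo"][comp], dtype=float)
            for i in range(n_vehicle):
                tid = f"{comp.value}-{sens.value}-vehicle-{i + 1:02d}"
                drift = config.time_control_drift * np.arange(len(grid))
                resp = np.clip(
                    drift + rng.normal(0.0, config.noise_sd, size=grid.shape),
                    -5.0, 115.0,
                )
                curves.append(
                    _make_curve(rng, comp, sens, Arm.VEHICLE, tid, grid, resp, config)
                )
                tissue_params[tid] = {
                    "arm": Arm.VEHICLE.value,
                    "compartment": comp.value,
                    "sensitization": sens.value,
                    "latent": {"drift_per_step": config.time_control_drift},
                }

    dataset = StudyDataset(
        curves=curves,
        metadata={"generator_seed": int(seed), "interaction_model": config.interaction_model},
    )
    truth = GroundTruth(
        seed=int(seed),
        interaction_model=config.interaction_model,
        psi=config.psi,
        mass_ratio=config.mass_ratio,
        noise_sd=config.noise_sd,
        arm_truths=arm_truths,
        tissue_params=tissue_params,
    )
    return dataset, truth


def _make_curve(rng, comp, sens, arm, tid, grid, resp, config) -> ConcentrationResponseCurve:
    qc_fail = rng.random() < config.qc_fail_prob
    if comp is Compartment.MEDIUM_BRONCHUS:
        plateau = float(rng.uniform(1.5, 2.5))                 # g tension
        papaverine = float(rng.uniform(0.2, 0.5))
        units = "g"
        qc_efs, qc_ach = not qc_fail, None
    else:
        papaverine = float(rng.uniform(0.4, 0.8))              # relaxed area mm^2
        plateau = papaverine * float(rng.uniform(0.3, 0.6))    # contracted area
        units = "mm2"
        qc_efs = None
        qc_ach = float(rng.uniform(0.10, 0.24) if qc_fail else rng.uniform(0.30, 0.60))
    tissue = TissueRecord(
        tissue_id=tid,
        subject_id=f"S-{tid}",
        compartment=comp,
        sensitization=sens,
        histamine_plateau=plateau,
        papaverine_response=papaverine,
        response_units=units,
        qc_efs_responsive=qc_efs,
        qc_ach_area_reduction=qc_ach,
    )
    points = [
        ConcentrationResponsePoint(
            concentration=float(c),
            raw_response=float(plateau - r / 100.0 * (plateau - papaverine)),
            normalized_relaxation=float(r),
        )
        for c, r in zip(grid, resp)
    ]
    return ConcentrationResponseCurve(
        tissue=tissue, arm=arm, points=points,
        ratio_bdp_ff=config.mass_ratio if arm is Arm.BDP_FF_COMBO else None,
    )


def ground_truth_recovery_report(ds: StudyDataset, truth: GroundTruth) -> dict:
    """Bias and RMSE of fitted pEC50 and Emax against the latent truths.

    Covers the monotherapy FF arms (the arms with calculable potency).

    Raises
    ------
    PairingError
        Dataset and truth do not describe the same tissues.
    """
    ds_ids = {c.tissue.tissue_id for c in ds.curves}
    if not ds_ids <= set(truth.tissue_params):
        raise PairingError("dataset contains tissues absent from the ground truth")

    err_pec50, err_top = [], []
    for curve in ds.select(arm=Arm.FF_MONO):
        latent = truth.tissue_params[curve.tissue.tissue_id]["latent"]
        fit = fit_hill(curve)
        mw_offset = latent["pec50_offset"]
        true_pec50 = mw_offset - latent["log_ec50"]
        fitted_pec50 = mw_offset - fit.log_ec50
        err_pec50.append(fitted_pec50 - true_pec50)
        err_top.append(fit.top - latent["top"])
    if not err_pec50:
        raise PairingError("no monotherapy FF curves to evaluate")
    e_p, e_t = np.asarray(err_pec50), np.asarray(err_top)
    return {
        "n_curves": len(e_p),
        "pec50_bias": float(e_p.mean()),
        "pec50_rmse": float(np.sqrt(np.mean(e_p**2))),
        "pec50_mad": float(np.median(np.abs(e_p))),
        "emax_bias": float(e_t.mean()),
        "emax_rmse": float(np.sqrt(np.mean(e_t**2))),
    }
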