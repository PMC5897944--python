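"""Synthetic study generator: determinism, construction identities, presets,
potency ordering and ground-truth recovery."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

import bronchosynergy as bs
from bronchosynergy.core import Arm, Compartment, Sensitization
from bronchosynergy.errors import ConfigurationError, PairingError
from bronchosynergy.hillfit import hill_response
from bronchosynergy.io import study_to_frame
from bronchosynergy.simulate import default_grids, loewe_null_config

M, S = Compartment.MEDIUM_BRONCHUS, Compartment.SMALL_AIRWAY
NS, PS = Sensitization.NS, Sensitization.PS


class TestPresets:
    def test_ff_parameters_match_study_values(self):
        presets = bs.table2_presets()
        assert presets[(M, NS)]["FF"].top == 97.00
        assert presets[(M, NS)]["FF"].pec50 == 8.26
        assert presets[(M, PS)]["FF"].pec50 == 8.89
        assert presets[(S, NS)]["FF"].top == 72.03
        assert presets[(S, PS)]["FF"].top == 105.30
        assert presets[(S, PS)]["FF"].pec50 == 7.52

    def test_between_tissue_sd_backcalculated_from_sem(self):
        p = bs.table2_presets()[(M, NS)]["FF"]
        assert p.sd_log_ec50 == pytest.approx(0.07 * np.sqrt(5))
        assert p.sd_top == pytest.approx(2.77 * np.sqrt(5))

    def test_bdp_arms_are_sub_threshold(self):
        for cell in bs.table2_presets().values():
            assert cell["BDP"].top < 20 and cell["BDP"].potency_not_calculable


class TestGenerateStudy:
    def test_determinism_under_fixed_seed(self):
        cfg = bs.GeneratorConfig()
        ds1, t1 = bs.generate_study(cfg, seed=99)
        ds2, t2 = bs.generate_study(cfg, seed=99)
        pdt.assert_frame_equal(study_to_frame(ds1), study_to_frame(ds2))
        assert t1 == t2

    def test_different_seeds_differ(self):
        cfg = bs.GeneratorConfig()
        ds1, _ = bs.generate_study(cfg, seed=1)
        ds2, _ = bs.generate_study(cfg, seed=2)
        assert not study_to_frame(ds1)["raw_response"].equals(
            study_to_frame(ds2)["raw_response"]
        )

    def test_row_count_contract(self, ns_medium_study):
        """Rows = tissues x grid points per arm, plus the vehicle controls."""
        ds, _ = ns_medium_study
        g = default_grids()
        expected = 5 * (len(g["FF"][M]) + len(g["BDP"][M]) + len(g["combo"][M]))
        expected += 2 * len(g["combo"][M])  # round(15 treated rings / 6) controls
        assert len(study_to_frame(ds)) == expected

    def test_vehicle_time_controls_one_in_seven(self, ns_medium_study):
        ds, _ = ns_medium_study
        n_treated = len(ds.select(arm=Arm.FF_MONO)) + len(
            ds.select(arm=Arm.BDP_MONO)) + len(ds.select(arm=Arm.BDP_FF_COMBO))
        n_vehicle = len(ds.select(arm=Arm.VEHICLE))
        assert n_vehicle == max(1, round(n_treated / 6))

    def test_zero_noise_bliss_null_construction_identity(self):
        """Without noise or heterogeneity, the combination response equals the
        Bliss composite of the monotherapy truths at every grid point."""
        tr = {
            "FF": bs.ArmTruth(top=97.0, pec50=8.26, slope=1.0),
            "BDP": bs.ArmTruth(
                top=12.0, pec50=7.24, slope=0.8,
                mw=bs.MOLECULAR_WEIGHTS["BDP"], potency_not_calculable=True,
            ),
        }
        cfg = bs.GeneratorConfig(truths={(M, NS): tr}, noise_sd=0.0)
        ds, _ = bs.generate_study(cfg, seed=5)
        combo = ds.select(arm=Arm.BDP_FF_COMBO)[0]
        tot = combo.concentrations
        ex = hill_response(np.log10(tot * 6 / 106), 0, 97.0, tr["FF"].log_ec50, 1.0) / 100
        ey = hill_response(np.log10(tot * 100 / 106), 0, 12.0, tr["BDP"].log_ec50, 0.8) / 100
        assert np.allclose(combo.responses / 100, ex + ey - ex * ey, atol=1e-9)

    def test_sensitization_and_compartment_potency_ordering(self):
        """Fitted PS arms are more potent than NS; medium more than small."""
        pec = {}
        for cell in [(M, NS), (M, PS), (S, NS), (S, PS)]:
            cfg = bs.GeneratorConfig(cells=[cell], include_arms=("FF",))
            ds, _ = bs.generate_study(cfg, seed=31)
            fits = [bs.fit_hill(c) for c in ds.select(arm=Arm.FF_MONO)]
            pec[cell] = np.mean([f.pec50 for f in fits])
        ps_shift = (pec[(M, PS)] + pec[(S, PS)]) / 2 - (pec[(M, NS)] + pec[(S, NS)]) / 2
        gap = (pec[(M, NS)] + pec[(M, PS)]) / 2 - (pec[(S, NS)] + pec[(S, PS)]) / 2
        assert 0.2 < ps_shift < 0.8      # ~0.5-log sensitization shift
        assert 0.9 < gap < 1.6           # ~1.25-log compartment gap

    def test_potency_shift_produces_synergy_signal(self):
        cfg = bs.GeneratorConfig(interaction_model="potency_shift", psi=5.0)
        ds, _ = bs.generate_study(cfg, seed=3)
        out = bs.bliss_delta_analysis(
            ds.select(arm=Arm.BDP_FF_COMBO),
            ds.select(arm=Arm.BDP_MONO),
            ds.select(arm=Arm.FF_MONO),
        )
        assert out.table["delta"].mean() > 0
        assert (out.table["classification"] == "synergistic").any()

    @pytest.mark.parametrize(
        "bad",
        [
            {"psi": 0.5},
            {"n_tissues": 1},
            {"interaction_model": "zip"},
        ],
    )
    def test_config_validation(self, bad):
        with pytest.raises(ConfigurationError):
            bs.generate_study(bs.GeneratorConfig(**bad), seed=0)

    def test_truth_sidecar_roundtrip(self, tmp_path, ns_medium_study):
        _, truth = ns_medium_study
        path = tmp_path / "truth.json"
        truth.to_json(path)
        assert bs.GroundTruth.from_json(path) == truth


class TestRecovery:
    def test_zero_noise_zero_bias(self):
        tr = {(M, NS): {"FF": bs.ArmTruth(top=97.0, pec50=8.26, slope=1.0),
                        "BDP": bs.table2_presets()[(M, NS)]["BDP"]}}
        cfg = bs.GeneratorConfig(truths=tr, noise_sd=0.0, include_arms=("FF",))
        ds, truth = bs.generate_study(cfg, seed=8)
        rep = bs.ground_truth_recovery_report(ds, truth)
        assert abs(rep["pec50_bias"]) < 1e-4 and rep["pec50_rmse"] < 1e-4
        assert rep["emax_rmse"] < 1e-3

    def test_recovery_improves_as_noise_shrinks(self):
        rmses = []
        for sd in (6.0, 3.0, 1.0, 0.0):
            cfg = bs.GeneratorConfig(noise_sd=sd, include_arms=("FF",))
            errs = []
            for s in range(8):
                ds, truth = bs.generate_study(cfg, seed=40_000 + s)
                errs.append(bs.ground_truth_recovery_report(ds, truth)["pec50_rmse"])
            rmses.append(np.mean(errs))
        assert rmses[0] > rmses[1] > rmses[2] > rmses[3]

    def test_rmse_matches_direct_monte_carlo_oracle(self):
        """Generator-path RMSE(pEC50) at 3% noise agrees within 10% with a
        direct Monte-Carlo simulation using an independent unbounded fitter."""
        tr = {(M, NS): {"FF": bs.ArmTruth(top=97.0, pec50=8.26, slope=1.0),
                        "BDP": bs.table2_presets()[(M, NS)]["BDP"]}}
        cfg = bs.GeneratorConfig(truths=tr, include_arms=("FF",))
        errs = []
        for s in range(40):     # 200 curves through the package path
            ds, truth = bs.generate_study(cfg, seed=60_000 + s)
            rep = bs.ground_truth_recovery_report(ds, truth)
            errs.append(rep["pec50_rmse"] ** 2 * rep["n_curves"])
        pipeline_rmse = np.sqrt(np.sum(errs) / (40 * 5))

        from scipy.optimize import curve_fit

        rng = np.random.default_rng(123)
        x = np.log10(default_grids()["FF"][M])
        log_ec50 = np.log10(bs.MOLECULAR_WEIGHTS["FF"] * 1e6) - 8.26
        sq = 0.0
        n_mc = 500
        for _ in range(n_mc):
            y = hill_response(x, 0, 97.0, log_ec50, 1.0) + rng.normal(0, 3.0, x.size)
            popt, _ = curve_fit(
                hill_response, x, np.clip(y, -5, 115),
                p0=[0.0, 97.0, log_ec50, 1.0], maxfev=5000,
            )
            sq += (popt[2] - log_ec50) ** 2
        mc_rmse = np.sqrt(sq / n_mc)
        assert pipeline_rmse == pytest.approx(mc_rmse, rel=0.10)

    def test_pairing_error_on_mismatched_truth(self):
        ds, _ = bs.generate_study(bs.GeneratorConfig(), seed=1)
        _, other = bs.generate_study(
            bs.GeneratorConfig(cells=[(S, PS)]), seed=2
        )
        with pytest.raises(PairingError):
            bs.ground_truth_recovery_report(ds, other)


class TestLoeweNullScenario:
    def test_equal_slopes_required(self):
        cfg = loewe_null_config()
        cfg.truths[(M, NS)]["BDP"].slope = 2.0
        with pytest.raises(ConfigurationError):
            bs.generate_study(cfg, seed=0)

    def test_noiseless_pipeline_ci_is_one(self):
        from bronchosynergy.report import group_mean_curve

        cfg = loewe_null_config(sd_log_ec50=0.0, noise_sd=0.0)
        ds, _ = bs.generate_study(cfg, seed=0)
        me = {}
        for name, arm in (("combo", Arm.BDP_FF_COMBO), ("FF", Arm.FF_MONO),
                          ("BDP", Arm.BDP_MONO)):
            conc, resp = group_mean_curve(ds.select(arm=arm))
            me[name] = bs.fit_median_effect(conc, resp / 100.0)
        for fa in (0.2, 0.5, 0.8):
            ci = bs.combination_index(fa, me["combo"], me["BDP"], me["FF"])
            assert ci == pytest.approx(1.0, abs=1e-6)
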