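"""Tests for the synthetic multi-herd generator: determinism, distribution
fidelity, truncation bounds, and metric-recovery behaviour."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mpyeval import metrics as mm
from mpyeval import pipeline, simulate
from mpyeval.metrics import PairedSeries
from mpyeval.model import MPYEvaluation
from mpyeval.simulate import GeneratorConfig, Scenario, generate_cows, generate_herd_set
from mpyeval.types import InvalidInputError


def frames(herd_set):
    return pipeline.herd_set_to_frames(herd_set)


class TestCowGeneration:
    def test_degenerate_sd_gives_constant_bw(self):
        config = dataclasses.replace(GeneratorConfig(), bw_sd=0.0, bw_herd_sd=0.0,
                                     n_herds=3, n_cows=30)
        cows = generate_cows(config, seed=1)
        assert all(c.bw == 672.0 for c in cows)

    def test_seeded_determinism(self, small_config):
        a = generate_cows(small_config, seed=5)
        b = generate_cows(small_config, seed=5)
        assert a == b

    def test_herd_structure(self, small_config):
        cows = generate_cows(small_config, seed=2)
        sizes = pd.Series([c.herd_id for c in cows]).value_counts()
        assert len(cows) == small_config.n_cows
        assert len(sizes) == small_config.n_herds
        assert (sizes >= small_config.min_herd_size).all()

    def test_trait_means_recovered_at_large_n(self):
        """Law of large numbers: configured Table-style means recovered
        well within 2 SE at n = 541."""
        config = GeneratorConfig()
        cows = generate_cows(config, seed=13)
        bw = np.array([c.bw for c in cows])
        dim = np.array([c.dim for c in cows])
        n = len(cows)
        assert bw.mean() == pytest.approx(672.0, abs=2 * 57.7 / np.sqrt(n) + 672 * 0.01)
        assert dim.mean() == pytest.approx(202.0, abs=2 * 116 / np.sqrt(n))

    def test_truncation_bounds_respected(self, small_herd_set):
        cows, sup = frames(small_herd_set)
        cfg = small_herd_set.config
        assert cows["bw"].between(*cfg.bw_bounds).all()
        assert cows["dim"].between(*cfg.dim_bounds).all()
        assert cows["mpy_obs"].between(*cfg.mpy_bounds).all()
        assert cows["parity"].between(*cfg.parity_bounds).all()
        assert cows["rha"].dropna().between(*cfg.rha_bounds).all()
        assert (sup.drop(columns=["cow_id", "scenario"]) >= 0).all().all()

    def test_some_rha_missing_at_default_rate(self):
        cows = generate_cows(GeneratorConfig(), seed=3)
        n_missing = sum(c.rha is None for c in cows)
        assert 0 < n_missing < 60   # 13/541 rate, wide Binomial envelope

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(InvalidInputError):
            GeneratorConfig(bw_bounds=(900.0, 800.0))
        with pytest.raises(InvalidInputError):
            GeneratorConfig(truth_model="nope")


class TestSupplies:
    def test_noise_free_calibration_hits_table_means(self):
        """With all noise off and DMI at its scenario mean, the generated
        supplies land on the calibration targets."""
        config = GeneratorConfig()
        sc = config.scenarios[Scenario.DMI_Ao]
        quiet = dataclasses.replace(
            sc, dmi_sd=0.0, mp_noise_cv=0.0, de_noise_cv=0.0, denp_frac_sd=0.0,
            dndf_noise_cv=0.0, aa_noise_cv=0.0, oaa_noise_cv=0.0)
        config = dataclasses.replace(
            config, scenarios={Scenario.DMI_Ao: quiet}, tpuri_noise_cv=0.0,
            tpfecal_noise_cv=0.0, tpscurf_noise_cv=0.0)
        cow = simulate.CowRecord("c", "h", parity=2, bw=672.0, dim=202.0,
                                 mpy_obs=894.0, rha=304.0)
        rng = np.random.default_rng(0)
        sup, exp = simulate.generate_supplies(cow, Scenario.DMI_Ao, config, rng,
                                              intake_z=0.0)
        assert sup.dmi == pytest.approx(23.4)
        assert sup.mp_supply == pytest.approx(2059.0, abs=0.5)
        assert sup.de_intake == pytest.approx(71.5, abs=0.05)
        assert sup.dndf_kg == pytest.approx(5.7, abs=0.01)
        assert exp.tpuri == pytest.approx(223.0, abs=0.5)
        assert exp.tpfecal_mp == pytest.approx(421.0, abs=0.5)

    def test_fecal_coefficient_calibrated_on_animal_only_scenario(self):
        """The 18 g/kg DMI metabolic-fecal coefficient, applied to the
        animal+ration DMI mean, lands near (not on) that column's printed
        mean — a documented single-coefficient choice."""
        assert 18.0 * 20.9 == pytest.approx(376.2)
        assert abs(18.0 * 20.9 - 365.0) / 365.0 < 0.05

    def test_eaa_sq_is_exact_sum_of_squares(self, small_herd_set):
        for sup in small_herd_set.supplies.values():
            expected = sup.his**2 + sup.ile**2 + sup.leu**2 + sup.lys**2 + sup.met**2
            assert sup.eaa_sq == expected

    def test_supply_means_and_sds_match_config_at_5000(self):
        """At n = 5000, generated DMI/MP/DE/AA means sit within 1% of the
        configured targets and SDs within 10%."""
        config = dataclasses.replace(GeneratorConfig(), n_cows=5000, n_herds=23)
        herd_set = generate_herd_set(config, seed=99)
        _, sup = frames(herd_set)
        for scenario, sc in config.scenarios.items():
            sub = sup[sup["scenario"] == scenario.value]
            targets = {
                "dmi": (sc.dmi_mean, sc.dmi_sd),
                "mp_supply": (sc.dmi_mean * sc.mp_per_kg_dmi, None),
                "de_intake": (sc.dmi_mean * sc.de_per_kg_dmi, None),
            }
            for aa, frac in sc.aa_frac.items():
                targets[aa] = (frac * sc.dmi_mean * sc.mp_per_kg_dmi, None)
            for col, (mean, sd) in targets.items():
                assert sub[col].mean() == pytest.approx(mean, rel=0.01), col
            # dispersion: DMI spread times residual noise
            assert sub["dmi"].std() == pytest.approx(sc.dmi_sd, rel=0.10)
            mp_cv_target = np.hypot(sc.dmi_sd / sc.dmi_mean, sc.mp_noise_cv)
            got_cv = sub["mp_supply"].std() / sub["mp_supply"].mean()
            assert got_cv == pytest.approx(mp_cv_target, rel=0.10)

    def test_growth_positive_for_first_parity_only(self, small_herd_set):
        for cow in small_herd_set.cows:
            exp = small_herd_set.expenditures[(cow.cow_id, Scenario.DMI_Ao)]
            if cow.parity == 1:
                assert exp.tpgrowth_mp > 0
            else:
                assert exp.tpgrowth_mp == 0.0


class TestObservedMpyTruthModels:
    def quiet_config(self, truth_model="eff_model"):
        return dataclasses.replace(GeneratorConfig(), n_herds=5, n_cows=100,
                                   herd_effect_sd=0.0, noise_sd=0.0,
                                   truth_model=truth_model)

    def test_noise_free_eff_truth_is_self_consistent(self):
        """obs generated from the efficiency predictor is recovered
        exactly by it: RMSE 0, CCC 1."""
        herd_set = generate_herd_set(self.quiet_config(), seed=21)
        results = MPYEvaluation.from_herd_set(herd_set).fit(
            scenarios=[Scenario.DMI_Ao], predictors=["eff"])
        rep = results.reports[(Scenario.DMI_Ao, "eff")]
        assert rep.rmse == pytest.approx(0.0, abs=1e-9)
        assert rep.ccc == pytest.approx(1.0, rel=1e-9)

    def test_noise_free_multi_truth_symmetry(self):
        """With the multivariate predictor as truth, its residuals vanish
        while the efficiency predictor's do not."""
        herd_set = generate_herd_set(self.quiet_config("multi_model"), seed=22)
        preds = MPYEvaluation.from_herd_set(herd_set).predict(Scenario.DMI_Ao)
        assert np.allclose(preds["resid_multi"], 0.0, atol=1e-9)
        assert np.abs(preds["resid_eff"]).max() > 1.0

    def test_truth_favours_its_own_model_under_noise(self):
        config = dataclasses.replace(GeneratorConfig(), noise_sd=0.10)
        herd_set = generate_herd_set(config, seed=23)
        results = MPYEvaluation.from_herd_set(herd_set).fit(
            scenarios=[Scenario.DMI_Ao])
        assert (results.reports[(Scenario.DMI_Ao, "eff")].ccc
                > results.reports[(Scenario.DMI_Ao, "multi")].ccc)

    @pytest.mark.parametrize("sigma, slope_tol, cb_min", [
        (0.0, 1e-9, 1 - 1e-9), (0.05, 0.03, 0.98), (0.15, 0.08, 0.90)])
    def test_recovery_tightens_as_noise_shrinks(self, sigma, slope_tol, cb_min):
        """obs-on-pred slope → 1 and Cb → 1 as the observation noise → 0."""
        config = dataclasses.replace(GeneratorConfig(), n_herds=10, n_cows=300,
                                     herd_effect_sd=0.0, noise_sd=sigma)
        herd_set = generate_herd_set(config, seed=31)
        rep = MPYEvaluation.from_herd_set(herd_set).fit(
            scenarios=[Scenario.DMI_Ao], predictors=["eff"]
        ).reports[(Scenario.DMI_Ao, "eff")]
        assert rep.slope_obs_on_pred == pytest.approx(1.0, abs=slope_tol)
        assert rep.cb > cb_min

    def test_injected_dim_bias_detected_with_correct_sign(self):
        """Adding b·(DIM − 202) to predictions leaves residuals that
        correlate with DIM at sign −sign(b)."""
        config = dataclasses.replace(GeneratorConfig(), n_herds=10, n_cows=300,
                                     herd_effect_sd=0.0, noise_sd=0.05)
        herd_set = generate_herd_set(config, seed=41)
        preds = MPYEvaluation.from_herd_set(herd_set).predict(Scenario.DMI_Ao)
        dim = preds["dim"].to_numpy()
        for b in (0.8, -0.8):
            biased = preds["mpy_eff"].to_numpy() + b * (dim - 202.0)
            r, p = mm.residual_correlation(preds["mpy_obs"].to_numpy() - biased, dim)
            assert np.sign(r) == -np.sign(b)
            assert p < 0.01


def test_full_set_bit_identical_for_same_seed(small_config):
    a_cows, a_sup = frames(generate_herd_set(small_config, seed=77))
    b_cows, b_sup = frames(generate_herd_set(small_config, seed=77))
    pd.testing.assert_frame_equal(a_cows, b_cows)
    pd.testing.assert_frame_equal(a_sup, b_sup)
    c_cows, _ = frames(generate_herd_set(small_config, seed=78))
    assert not a_cows["bw"].equals(c_cows["bw"])
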