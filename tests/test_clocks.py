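"""Null and PC Cox models, the hazard-to-Gompertz-age conversion, stability
selection, linear collapse and bundle serialization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clinclock as cc
from clinclock.clocks import ClockError, _breslow_loglik


class TestHazardToDeltaAge:
    @pytest.mark.parametrize("ratio,mrdt,expected", [
        (1.0, 8.0, 0.0), (2.0, 8.0, 8.0), (0.5, 8.0, -8.0),
        (4.0, 5.0, 10.0), (0.25, 5.0, -10.0),
    ])
    def test_closed_form(self, ratio, mrdt, expected):
        assert cc.hazard_to_delta_age(np.log(ratio), mrdt) == \
            pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(log_r=st.floats(-5, 5), mrdt=st.floats(2, 30))
    def test_antisymmetric_in_log_hazard(self, log_r, mrdt):
        d1 = cc.hazard_to_delta_age(log_r, mrdt)
        d2 = cc.hazard_to_delta_age(-log_r, mrdt)
        assert d1 == pytest.approx(-d2, abs=1e-9)

    def test_invalid_inputs_error(self):
        with pytest.raises(ClockError):
            cc.hazard_to_delta_age(np.nan, 8.0)
        with pytest.raises(ClockError):
            cc.hazard_to_delta_age(0.0, -1.0)


class TestBreslowLoglik:
    def test_matches_direct_enumeration(self):
        """Brute-force partial likelihood on a 5-subject example."""
        eta = np.array([0.5, -0.2, 0.0, 1.0, -1.0])
        time = np.array([2.0, 5.0, 3.0, 1.0, 4.0])
        event = np.array([1, 0, 1, 1, 0])
        expected = 0.0
        for i in np.flatnonzero(event == 1):
            risk = time >= time[i]
            expected += eta[i] - np.log(np.exp(eta[risk]).sum())
        assert _breslow_loglik(eta, time, event) == pytest.approx(expected)

    def test_tied_times_share_risk_set(self):
        eta = np.array([0.3, -0.3, 0.1, 0.0])
        time = np.array([2.0, 2.0, 3.0, 1.0])
        event = np.array([1, 1, 0, 0])
        denom = np.log(np.exp(eta[np.array([0, 1, 2])]).sum())
        expected = eta[0] + eta[1] - 2 * denom
        assert _breslow_loglik(eta, time, event) == pytest.approx(expected)


class TestNullModel:
    def test_mrdt_recovered_from_gompertz_truth(self):
        cfg = cc.SyntheticConfig(n_subjects=10_000, n_latent=1,
                                 latent_effects=(0.0,), seed=31)
        cohort, _ = cc.generate_cohort(cfg)
        null = cc.fit_null_model(cohort)
        for sex in ("male", "female"):
            assert 7.4 <= null.mrdt[sex] <= 8.6

    def test_steeper_slope_recovered_within_ten_percent(self):
        cfg = cc.SyntheticConfig(n_subjects=10_000, n_latent=1,
                                 latent_effects=(0.0,),
                                 gompertz_slope=0.1386, gompertz_intercept=-12.5,
                                 seed=32)
        cohort, _ = cc.generate_cohort(cfg)
        null = cc.fit_null_model(cohort)
        for sex in ("male", "female"):
            assert abs(null.mrdt[sex] - 5.0) / 5.0 < 0.10

    def test_time_rescaling_leaves_slope_unchanged(self, signal_cohort):
        """Cox partial likelihood depends only on the ranking of event times."""
        cohort, _ = signal_cohort
        doubled = cohort.copy()
        doubled.meta = doubled.meta.copy()
        doubled.meta["followup_time"] = doubled.meta["followup_time"] * 2
        b1 = cc.fit_null_model(cohort).b
        b2 = cc.fit_null_model(doubled).b
        for sex in b1:
            assert b1[sex] == pytest.approx(b2[sex], rel=1e-6)

    def test_no_events_errors(self, toy_cohort):
        dead = toy_cohort.copy()
        dead.meta = dead.meta.copy()
        dead.meta["event"] = 0
        with pytest.raises(ClockError):
            cc.fit_null_model(dead)


class TestPCCox:
    def test_single_informative_pc_coefficient_recovered(self):
        cfg = cc.SyntheticConfig(n_subjects=10_000, n_features=8, n_latent=1,
                                 latent_effects=(0.5,), noise_sd=0.1, seed=33)
        cohort, truth = cc.generate_cohort(cfg)
        pm = cc.fit_svd(cohort, cc.fit_normalization(cohort))
        cc.select_components(pm, 0.99)
        clock = cc.fit_pc_cox(cohort, pm, cc.fit_null_model(cohort))
        scores = cc.project(pm, cohort)
        # effect per unit of latent is 0.5; rescale to per-unit-PC1-score
        slope = np.polyfit(scores["PC1"], truth.latents["latent_0"], 1)[0]
        for sex, params in clock.coefs.items():
            assert params["PC1"] * (1 / slope) == pytest.approx(0.5, abs=0.1)

    def test_centering_invariance_of_biological_age(self, signal_cohort,
                                                    trained_clock):
        """Shifting every subject along the first singular vector changes the
        mean linear predictor but not any biological age."""
        cohort, _ = signal_cohort
        pm = trained_clock.pc_model
        shift = pd.Series(pm.V[:, 0] * pm.normalization.scales["pooled"].values,
                          index=pm.feature_names)
        shifted = cohort.copy()
        shifted.X = shifted.X + 3.0 * shift
        norm2 = cc.fit_normalization(shifted)
        # refit everything on the shifted cohort: survival unchanged, features
        # rigidly translated -> identical biological ages
        pm2 = cc.fit_svd(shifted, norm2)
        cc.select_components(pm2, 0.99)
        clock2 = cc.fit_pc_cox(shifted, pm2, cc.fit_null_model(shifted))
        ba1 = cc.predict_biological_age(trained_clock, cohort)
        ba2 = cc.predict_biological_age(clock2, shifted)
        np.testing.assert_allclose(ba1["bio_age"], ba2["bio_age"], atol=1e-6)


class TestPredictBiologicalAge:
    def test_training_mean_delta_age_is_zero_per_sex(self, signal_cohort,
                                                     trained_clock):
        cohort, _ = signal_cohort
        ba = cc.predict_biological_age(trained_clock, cohort)
        means = ba.join(cohort.meta["sex"]).groupby("sex")["delta_age"].mean()
        np.testing.assert_allclose(means, 0.0, atol=1e-8)

    def test_subject_at_training_means_has_zero_delta(self, signal_cohort,
                                                      trained_clock):
        cohort, _ = signal_cohort
        probe = cohort.copy()
        for sex in ("male", "female"):
            mask = (cohort.meta["sex"] == sex).to_numpy()
            # projection is linear, so the mean feature vector maps to the
            # per-sex mean PC scores
            probe.X.loc[mask] = cohort.X.loc[mask].mean().values
            probe.meta.loc[mask, "chron_age"] = trained_clock.mean_ca[sex]
        ba = cc.predict_biological_age(trained_clock, probe)
        np.testing.assert_allclose(ba["delta_age"], 0.0, atol=1e-8)

    def test_delta_age_tracks_generative_truth(self, signal_cohort,
                                               trained_clock):
        cohort, truth = signal_cohort
        ba = cc.predict_biological_age(trained_clock, cohort)
        r = np.corrcoef(ba["delta_age"], truth.true_delta_age)[0, 1]
        assert r >= 0.8

    def test_unknown_sex_errors(self, trained_clock, signal_cohort):
        cohort, _ = signal_cohort
        males = cohort.subset(cohort.meta.index[cohort.meta.sex == "male"])
        # clock trained on both sexes happily predicts a male-only cohort
        cc.predict_biological_age(trained_clock, males)


class TestStabilitySelection:
    def test_signal_pc_selected_noise_excluded(self):
        cfg = cc.SyntheticConfig(n_subjects=2000, n_features=10, n_latent=1,
                                 latent_effects=(0.5,), seed=41)
        cohort, _ = cc.generate_cohort(cfg)
        pm = cc.fit_svd(cohort, cc.fit_normalization(cohort))
        rep = cc.select_pcs_regularized(cohort, pm, n_iterations=10,
                                        min_count=1, seed=42)
        assert "PC1" in rep.selected
        for alpha, counts in rep.counts.items():
            assert counts["PC1"] == 10

    def test_fixed_seed_reproducible(self):
        cfg = cc.SyntheticConfig(n_subjects=600, n_features=6, n_latent=1,
                                 latent_effects=(0.5,), seed=43)
        cohort, _ = cc.generate_cohort(cfg)
        pm = cc.fit_svd(cohort, cc.fit_normalization(cohort))
        r1 = cc.select_pcs_regularized(cohort, pm, n_iterations=4, seed=7,
                                       min_count=1)
        r2 = cc.select_pcs_regularized(cohort, pm, n_iterations=4, seed=7,
                                       min_count=1)
        assert r1.selected == r2.selected
        for a in r1.counts:
            pd.testing.assert_series_equal(r1.counts[a], r2.counts[a])

    def test_too_few_subjects_errors(self, toy_cohort):
        pm = cc.fit_svd(toy_cohort, cc.fit_normalization(toy_cohort))
        with pytest.raises(ClockError):
            cc.select_pcs_regularized(toy_cohort, pm, folds=10)


class TestCollapse:
    def test_linear_form_reproduces_pc_path_exactly(self, signal_cohort,
                                                    trained_clock):
        cohort, _ = signal_cohort
        linear = cc.collapse_to_linear(trained_clock, verify_cohort=cohort)
        ba_pc = cc.predict_biological_age(trained_clock, cohort)
        ba_lin = linear.predict(cohort)
        assert float((ba_pc["bio_age"] - ba_lin["bio_age"]).abs().max()) < 1e-8

    def test_full_rank_collapse_exact(self, signal_cohort):
        cohort, _ = signal_cohort
        pm = cc.fit_svd(cohort, cc.fit_normalization(cohort))
        pm.m = pm.V.shape[1]  # all components
        clock = cc.fit_pc_cox(cohort, pm, cc.fit_null_model(cohort))
        cc.collapse_to_linear(clock, verify_cohort=cohort)

    def test_zero_weight_feature_shifts_ba_by_its_term(self, signal_cohort,
                                                       trained_clock):
        cohort, _ = signal_cohort
        linear = cc.collapse_to_linear(trained_clock)
        base = linear.predict(cohort)
        flagged = cohort.copy()
        flagged.zero_weight_features.add("feat_005")
        dropped = linear.predict(flagged)
        norm = trained_clock.pc_model.normalization
        z = norm.transform(cohort.X, cohort.meta["sex"])["feat_005"]
        for sex, w in linear.weights.items():
            mask = (cohort.meta["sex"] == sex).to_numpy()
            expected = -w["feat_005"] * z[mask]
            got = (dropped["bio_age"] - base["bio_age"])[mask]
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_zero_z_substitution_for_missing_cell_is_exactly_linear(
            self, signal_cohort, trained_clock):
        """A sporadically missing cell under zero-z substitution changes BA
        by exactly that feature's weight times its (removed) z-score."""
        cohort, _ = signal_cohort
        linear = cc.collapse_to_linear(trained_clock)
        base = linear.predict(cohort)
        subj = cohort.meta.index[0]
        sex = cohort.meta.loc[subj, "sex"]
        holey = cohort.copy()
        holey.X.loc[subj, "feat_002"] = np.nan
        with pytest.raises(ClockError):
            linear.predict(holey)  # without the substitution flag: error
        sub = linear.predict(holey, zero_z_missing=True)
        norm = trained_clock.pc_model.normalization
        z = norm.transform(cohort.X, cohort.meta["sex"]).loc[subj, "feat_002"]
        expected = -linear.weights[sex]["feat_002"] * z
        got = sub.loc[subj, "bio_age"] - base.loc[subj, "bio_age"]
        assert got == pytest.approx(expected, abs=1e-10)
        # all other subjects untouched
        others = cohort.meta.index[1:]
        np.testing.assert_allclose(sub.loc[others, "bio_age"],
                                   base.loc[others, "bio_age"], atol=1e-12)

    def test_gauge_freedom_rotation_invariance(self, signal_cohort):
        """Jointly rotating the singular vectors and the PC weights leaves
        every biological age unchanged."""
        cohort, _ = signal_cohort
        pm = cc.fit_svd(cohort, cc.fit_normalization(cohort))
        cc.select_components(pm, 0.99)
        null = cc.fit_null_model(cohort)
        clock = cc.fit_pc_cox(cohort, pm, null)
        ba1 = cc.predict_biological_age(clock, cohort)

        rng = np.random.default_rng(5)
        m = pm.m
        Q, _ = np.linalg.qr(rng.normal(size=(m, m)))
        import copy
        pm_rot = copy.deepcopy(pm)
        pm_rot.V = pm.V.copy()
        pm_rot.V[:, :m] = pm.V[:, :m] @ Q
        clock_rot = copy.deepcopy(clock)
        clock_rot.pc_model = pm_rot
        for sex in clock.coefs:
            beta = clock.coefs[sex][[f"PC{i+1}" for i in range(m)]] \
                .to_numpy(float)
            rotated = Q.T @ beta
            for i in range(m):
                clock_rot.coefs[sex][f"PC{i+1}"] = rotated[i]
        ba2 = cc.predict_biological_age(clock_rot, cohort)
        np.testing.assert_allclose(ba1["bio_age"], ba2["bio_age"], atol=1e-8)

    def test_selection_mismatch_errors(self, signal_cohort, trained_clock):
        cohort, _ = signal_cohort
        fake = cc.SelectionReport(counts={}, n_iterations=1, min_count=1,
                                  selected=["PC1"], seed=0)
        with pytest.raises(ClockError, match="selection"):
            cc.collapse_to_linear(trained_clock, selection=fake)


class TestDeltaAgeRecoveryScaling:
    def test_rmse_decreases_with_cohort_size(self):
        rmses = []
        for n in (500, 2000, 8000):
            cfg = cc.SyntheticConfig(n_subjects=n, n_features=8, n_latent=1,
                                     latent_effects=(0.5,), seed=51)
            cohort, truth = cc.generate_cohort(cfg)
            pm = cc.fit_svd(cohort, cc.fit_normalization(cohort))
            cc.select_components(pm, 0.99)
            clock = cc.fit_pc_cox(cohort, pm, cc.fit_null_model(cohort))
            ba = cc.predict_biological_age(clock, cohort)
            err = ba["delta_age"] - truth.true_delta_age
            rmses.append(float(np.sqrt((err**2).mean())))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_ba_concordance_beats_ca_when_signal_present(self, signal_cohort,
                                                         trained_clock):
        cohort, _ = signal_cohort
        ba = cc.predict_biological_age(trained_clock, cohort)
        assert cc.concordance(cohort, ba["bio_age"]) > \
            cc.concordance(cohort, ba["chron_age"])


class TestBundle:
    def test_round_trip_reproduces_predictions(self, signal_cohort,
                                               trained_clock, tmp_path):
        cohort, _ = signal_cohort
        linear = cc.collapse_to_linear(trained_clock, verify_cohort=cohort)
        path = tmp_path / "bundle.json"
        cc.save_clock_bundle(path, trained_clock, linear)
        clock2, linear2 = cc.load_clock_bundle(path)
        ba1 = cc.predict_biological_age(trained_clock, cohort)
        ba2 = cc.predict_biological_age(clock2, cohort)
        pd.testing.assert_frame_equal(ba1, ba2)
        pd.testing.assert_frame_equal(linear.predict(cohort),
                                      linear2.predict(cohort))

    def test_newer_major_version_refused(self, signal_cohort, trained_clock,
                                         tmp_path):
        import json
        path = tmp_path / "bundle.json"
        cc.save_clock_bundle(path, trained_clock)
        payload = json.loads(path.read_text())
        payload["bundle_version"] = "99.0"
        path.write_text(json.dumps(payload))
        with pytest.raises(ClockError, match="newer"):
            cc.load_clock_bundle(path)
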