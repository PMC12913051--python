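"""Endocrine statistics: residualisation, LMM/LRT, phases, PCA, power."""

import numpy as np
import pandas as pd
import pytest

from cyclovasc import stats
from cyclovasc.synthetic import CohortTruth, gen_cohort


def panel_df(e2, p4, participants=None, phases=None):
    n = len(e2)
    return pd.DataFrame({
        "participant": participants or [f"P{i}" for i in range(n)],
        "phase": phases or ["EFP"] * n,
        "oestradiol": e2,
        "progesterone": p4,
    })


class TestResidualize:
    def test_exactly_linear_p4_gives_zero_residuals(self):
        e2 = np.array([100.0, 200.0, 300.0, 400.0])
        out = stats.residualize_progesterone(panel_df(e2, 2.0 + 0.01 * e2))
        np.testing.assert_allclose(out["res_progesterone"], 0.0, atol=1e-10)

    def test_orthogonal_hormones_give_centred_p4(self):
        e2 = np.array([1.0, 2.0, 3.0, 4.0])
        p4 = np.array([3.0, 7.0, 7.0, 3.0])      # zero covariance with e2
        assert np.cov(e2, p4)[0, 1] == pytest.approx(0.0)
        out = stats.residualize_progesterone(panel_df(e2, p4))
        np.testing.assert_allclose(out["res_progesterone"], p4 - p4.mean(),
                                   atol=1e-12)

    def test_residuals_uncorrelated_with_oestradiol(self):
        rng = np.random.default_rng(0)
        e2 = rng.normal(300, 150, 60)
        p4 = 1.0 + 0.02 * e2 + rng.normal(0, 5, 60)   # r ~ 0.5
        out = stats.residualize_progesterone(panel_df(e2, p4))
        cov = np.cov(out["oestradiol"], out["res_progesterone"])[0, 1]
        assert abs(cov) < 1e-9 * np.std(e2) * np.std(p4)

    def test_constant_oestradiol_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            out = stats.residualize_progesterone(
                panel_df(np.full(4, 200.0), np.array([1.0, 2.0, 3.0, 4.0])))
        np.testing.assert_allclose(out["res_progesterone"],
                                   [-1.5, -0.5, 0.5, 1.5])


class TestHormoneLmm:
    def test_noise_free_outcome_recovers_slope_exactly(self, cohort_tables):
        panel, _, _ = cohort_tables
        b = 0.01
        df = panel.copy()
        df["metric"] = "toy"
        df["value"] = 3.0 + b * df["oestradiol"]
        res = stats.fit_hormone_lmm(df, "toy")
        assert res["oestradiol"].slope == pytest.approx(b, rel=1e-4)
        # the likelihood ratio diverges in the deterministic limit
        assert res["oestradiol"].chi2 > 1e3
        assert res["oestradiol"].p < 1e-200

    def test_generating_slopes_recovered_within_ci(self, cohort_tables):
        _, _, merged = cohort_tables
        res = stats.fit_hormone_lmm(merged, "perfusion_global")
        truth = CohortTruth()
        r_e2 = res["oestradiol"]
        r_rp = res["res_progesterone"]
        assert r_e2.ci_low <= truth.slope_oestradiol <= r_e2.ci_high
        assert r_rp.ci_low <= truth.slope_resprog <= r_rp.ci_high
        assert r_e2.p < 1e-6 and r_rp.p < 1e-3

    def test_lrt_invariant_to_outcome_rescaling(self, cohort_tables):
        _, _, merged = cohort_tables
        res1 = stats.fit_hormone_lmm(merged, "perfusion_global")
        scaled = merged.copy()
        scaled["value"] = scaled["value"] * 12.5 + 3.0
        res2 = stats.fit_hormone_lmm(scaled, "perfusion_global")
        for h in stats.HORMONES:
            assert res2[h].chi2 == pytest.approx(res1[h].chi2, rel=1e-4)
            assert res2[h].slope == pytest.approx(12.5 * res1[h].slope,
                                                  rel=1e-4)

    def test_duplicated_keys_rejected(self, cohort_tables):
        _, _, merged = cohort_tables
        dup = pd.concat([merged, merged.iloc[:1]])
        with pytest.raises(ValueError, match="duplicated"):
            stats.fit_hormone_lmm(dup, "perfusion_global")


class TestOutlierExclusion:
    def test_clean_data_unchanged(self, cohort_tables):
        _, _, merged = cohort_tables
        filtered, res = stats.exclude_outlier_residuals(
            merged, "perfusion_global", k=50.0)
        assert len(filtered) == len(merged)
        assert res["oestradiol"].excluded_outliers == 0

    def test_planted_gross_outlier_removed(self, cohort_tables):
        _, _, merged = cohort_tables
        spiked = merged.copy().reset_index(drop=True)
        spiked.loc[10, "value"] += 60.0          # ~10 residual SDs
        filtered, res = stats.exclude_outlier_residuals(
            spiked, "perfusion_global", k=2.5)
        assert res["oestradiol"].excluded_outliers == 1
        assert 10 not in filtered.index


class TestInteraction:
    @pytest.fixture(scope="class")
    def roi_tables(self):
        truth = CohortTruth(seed=7, residual_sd=1.0)
        slopes = {"global": truth.slope_oestradiol,
                  "frontal": truth.slope_oestradiol,
                  "occipital": 2.0 * truth.slope_oestradiol}
        panel, outcomes = gen_cohort(truth, roi_slopes=slopes)
        return outcomes.merge(panel, on=["participant", "phase"])

    def test_gate_refuses_nonsignificant_main_effect(self, roi_tables):
        with pytest.raises(ValueError, match="gated"):
            stats.test_interaction(roi_tables, "perfusion_global",
                                   "oestradiol", main_effect_p=0.5)

    def test_single_roi_metric_rejected(self, cohort_tables):
        _, _, merged = cohort_tables
        with pytest.raises(ValueError, match="multiple ROIs"):
            stats.test_interaction(merged, "perfusion_global", "oestradiol")

    def test_deviant_roi_flagged_against_global_reference(self, roi_tables):
        res = stats.test_interaction(roi_tables, "perfusion_global",
                                     "oestradiol")
        assert res["p"] < 0.05
        con = res["roi_contrasts"]
        assert set(con) == {"frontal", "occipital"}
        # the doubled-slope ROI is the extreme contrast
        assert abs(con["occipital"]["t"]) > abs(con["frontal"]["t"])
        assert con["occipital"]["p"] < 0.05

    def test_equal_slopes_rarely_significant(self):
        # null interaction: rejection at the nominal rate, spot-checked
        hits = 0
        for seed in range(20):
            truth = CohortTruth(seed=100 + seed)
            slopes = {r: truth.slope_oestradiol
                      for r in ("global", "a", "b")}
            panel, outcomes = gen_cohort(truth, roi_slopes=slopes)
            merged = outcomes.merge(panel, on=["participant", "phase"])
            res = stats.test_interaction(merged, "perfusion_global",
                                         "oestradiol")
            hits += res["p"] < 0.05
        assert hits <= 4


class TestExtremePhases:
    def make_panel(self, values, phases=("EFP", "LFP", "MLP")):
        return pd.DataFrame({
            "participant": ["P0"] * len(values),
            "phase": list(phases)[:len(values)],
            "oestradiol": values,
        })

    def test_simple_min_max(self):
        out = stats.select_extreme_phases(
            self.make_panel([100.0, 600.0, 300.0]), "oestradiol")
        assert out.loc[0, "low_phase"] == "EFP"
        assert out.loc[0, "high_phase"] == "LFP"

    def test_tied_low_takes_earlier_tied_high_takes_later(self):
        out = stats.select_extreme_phases(
            self.make_panel([100.0, 100.0, 300.0]), "oestradiol")
        assert out.loc[0, "low_phase"] == "EFP"
        assert out.loc[0, "high_phase"] == "MLP"

    def test_all_equal_spans_cycle(self):
        out = stats.select_extreme_phases(
            self.make_panel([200.0, 200.0, 200.0]), "oestradiol")
        assert out.loc[0, "low_phase"] == "EFP"
        assert out.loc[0, "high_phase"] == "MLP"

    def test_single_phase_participant_excluded(self):
        out = stats.select_extreme_phases(
            self.make_panel([200.0], phases=("LFP",)), "oestradiol")
        assert out.empty

    def test_low_never_equals_high(self, cohort_tables):
        panel, _, _ = cohort_tables
        out = stats.select_extreme_phases(panel, "oestradiol")
        assert (out["low_phase"] != out["high_phase"]).all()


class TestStatePca:
    def test_perfectly_correlated_variables_single_component(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 40)
        data = pd.DataFrame({f"v{i}": 2.0 * i + base for i in range(5)})
        pca = stats.state_pca(data)
        assert pca.explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_independent_variables_flat_spectrum_large_n(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(0, 1, (5000, 12)),
                            columns=[f"v{i}" for i in range(12)])
        pca = stats.state_pca(data)
        np.testing.assert_allclose(pca.explained, 1.0 / 12.0, atol=0.02)

    def test_obs_cos2_sums_to_one(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(0, 1, (30, 6)),
                            columns=list("abcdef"))
        pca = stats.state_pca(data)
        np.testing.assert_allclose(pca.obs_cos2.sum(axis=1), 1.0, atol=1e-10)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(0, 1, (25, 8)))
        data.columns = [f"v{i}" for i in range(8)]
        pca = stats.state_pca(data)
        assert pca.explained.sum() == pytest.approx(1.0)

    def test_all_missing_variable_dropped(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(0, 1, (20, 3)), columns=list("abc"))
        data["d"] = np.nan
        with pytest.warns(UserWarning, match="all-missing"):
            pca = stats.state_pca(data)
        assert pca.variables == list("abc")


class TestProjection:
    @pytest.fixture(scope="class")
    def low_data(self):
        rng = np.random.default_rng(5)
        factor = rng.normal(0, 1, (30, 1))
        noise = rng.normal(0, 0.5, (30, 6))
        return pd.DataFrame(factor @ np.ones((1, 6)) + noise,
                            columns=[f"v{i}" for i in range(6)])

    def test_identity_projection_reproduces_scores(self, low_data):
        pca = stats.state_pca(low_data)
        out = stats.project_condition(low_data, pca)
        np.testing.assert_allclose(out["scores"], pca.scores, atol=1e-10)

    def test_identical_conditions_zero_change(self, low_data):
        pca = stats.state_pca(low_data)
        out = stats.project_condition(low_data, pca)
        for comp, pct in out["alignment_change_pct"].items():
            assert pct == pytest.approx(0.0, abs=1e-9)

    def test_variable_mismatch_listed(self, low_data):
        pca = stats.state_pca(low_data)
        other = low_data.rename(columns={"v0": "w0"})
        with pytest.raises(ValueError, match="w0"):
            stats.project_condition(other, pca)

    def test_isotropic_noise_reduces_leading_alignment(self, low_data):
        pca = stats.state_pca(low_data)
        rng = np.random.default_rng(6)
        noisy = low_data + rng.normal(0, 1.0, low_data.shape)
        out = stats.project_condition(noisy, pca)
        assert out["alignment_change_pct"][1] < 0


class TestPower:
    def test_monotone_in_effect_size(self):
        sizes = [stats.required_sample_size(dz) for dz in (0.5, 0.8, 1.1)]
        assert sizes == sorted(sizes, reverse=True)

    def test_threshold_behaviour_around_answer(self):
        n = stats.required_sample_size(0.98, 0.90, 0.05)
        assert stats.power_one_sample_t(n, 0.98) >= 0.90
        assert stats.power_one_sample_t(n - 1, 0.98) < 0.90

    def test_monte_carlo_agrees_with_exact(self):
        n = stats.required_sample_size(0.98, 0.90, 0.05)
        exact = stats.power_one_sample_t(n, 0.98)
        mc = stats.monte_carlo_power(n, 0.98, n_sims=40_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.required_sample_size(-1.0)
        with pytest.raises(ValueError):
            stats.required_sample_size(0.5, power=1.5)

    def test_across_cycle_change_is_slope_times_range(self):
        assert stats.across_cycle_change(0.17, 20.433) == pytest.approx(
            3.47, abs=0.005)
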