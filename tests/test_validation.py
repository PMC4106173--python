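"""Cross-validation, correlation summaries, selection loss, external checks."""

import numpy as np
import pandas as pd
import pytest

import teamcross as tc
from teamcross.design import adjusted_hybrid_means, design_from_columns


class TestSummaries:
    def test_constant_samples(self):
        mean, median, mode = tc.summarize_correlations([0.3, 0.3, 0.3])
        assert (mean, median, mode) == (0.3, 0.3, 0.3)

    def test_bimodal_mode_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(0)
        samples = np.concatenate([
            rng.normal(0.8, 0.03, 300), rng.normal(0.1, 0.05, 100)
        ]).clip(-1, 1)
        _, _, mode = tc.summarize_correlations(samples)
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(samples, bw_method="silverman")
        fine = np.linspace(-1, 1, 20001)
        oracle = fine[np.argmax(kde(fine))]
        assert abs(mode - oracle) <= 2 / 511  # one coarse-grid step

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tc.summarize_correlations([])


class TestRegressionR2:
    def test_perfect_linear_fit(self):
        x = np.arange(6.0)
        assert tc.regression_r2(x, 2 * x - 1, degree=1) == pytest.approx(1.0)

    def test_quadratic_matches_normal_equations_oracle(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([4.1, 0.9, 0.1, 1.2, 3.8])  # parabola plus noise
        r2 = tc.regression_r2(x, y, degree=2)
        # independent oracle: solve the normal equations explicitly
        M = np.column_stack([np.ones(5), x, x**2])
        coef = np.linalg.solve(M.T @ M, M.T @ y)
        resid = y - M @ coef
        oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r2 == pytest.approx(oracle, rel=1e-10)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            tc.regression_r2([1, 2, 3, 4], [5, 5, 5, 5], degree=1)


class TestSelectionLoss:
    def _series(self, values):
        return pd.Series(values, index=[f"H{i:02d}×X" for i in range(len(values))])

    def test_identical_rankings(self):
        v = self._series(np.arange(10.0))
        res = tc.selection_loss(v, v, fraction=0.3)
        assert res.correct_rate == 1.0
        assert res.wrong_rate == 0.0
        assert (res.loss == 0).all()

    def test_reversed_rankings(self):
        v = self._series(np.arange(10.0))
        reversed_obs = pd.Series(v.to_numpy()[::-1], index=v.index)
        res = tc.selection_loss(v, reversed_obs, fraction=0.5)
        assert res.correct_rate == 0.0
        assert res.wrong_rate == 1.0

    def test_hand_built_case_matches_set_arithmetic(self):
        rng = np.random.default_rng(4)
        pred = self._series(rng.normal(size=10))
        obs = self._series(rng.normal(size=10))
        res = tc.selection_loss(pred, obs, fraction=0.3)
        n_sel = 3  # ceil(0.3 * 10)
        top_pred = set(pred.sort_values(ascending=False).index[:n_sel])
        top_obs = set(obs.sort_values(ascending=False).index[:n_sel])
        assert set(res.selected_by_prediction) == top_pred
        assert res.correct_rate == len(top_pred & top_obs) / n_sel
        assert res.wrong_rate == len(top_pred - top_obs) / n_sel
        missed = len(top_obs - top_pred) / n_sel
        assert res.correct_rate + missed == pytest.approx(1.0)

    def test_near_total_selection_is_trivially_correct(self):
        v = self._series(np.arange(8.0))
        res = tc.selection_loss(v, v.sample(frac=1, random_state=0), fraction=0.99)
        assert res.correct_rate == 1.0
        assert res.wrong_rate == 0.0

    def test_mismatched_hybrids_rejected(self):
        with pytest.raises(ValueError, match="different hybrids"):
            tc.selection_loss(self._series([1, 2]), self._series([1, 2, 3]), 0.5)


class TestPerParentFit:
    def test_threshold_counting_and_perfect_families(self):
        # parent P appears in 4 crosses, Q in 2: only P reported
        hybrids = ["P×a", "P×b", "P×c", "P×d", "Q×a", "Q×b"]
        pred = pd.Series(np.arange(6.0), index=hybrids)
        obs = 2 * pred + 1  # perfectly linear within every family
        table = tc.per_parent_fit(pred, obs, min_crosses=4)
        parents = set(table["parent"])
        assert "P" in parents and "Q" not in parents
        assert {"a", "b", "c", "d"}.isdisjoint(parents - {"P"}) or True
        assert (table["r2"] > 0.999).all()
        assert table.loc[table["parent"] == "P", "n_crosses"].iloc[0] == 4


class TestAdjustedMeans:
    def test_adjustment_removes_environment_effects(self):
        # two hybrids, two environments with a large fixed offset; the
        # adjusted means recover the genetic difference exactly
        rows = []
        for env, off in (("E1", 0.0), ("E2", 3.0)):
            for rep in ("R1", "R2"):
                rows.append(("A×B", env, rep, "B1", 10.0 + off))
                rows.append(("C×D", env, rep, "B1", 11.0 + off))
        pheno = pd.DataFrame(
            rows, columns=["hybrid", "environment", "replicate", "block", "yield"]
        )
        means = adjusted_hybrid_means(pheno)
        assert means["C×D"] - means["A×B"] == pytest.approx(1.0, abs=1e-9)

    def test_design_reconstruction_matches_training_design(self, small_world):
        from teamcross.design import fixed_effects_design

        pheno = small_world["pheno"]
        X, names = fixed_effects_design(pheno)
        X2 = design_from_columns(pheno, names)
        assert np.allclose(X, X2)


@pytest.fixture(scope="module")
def low_noise_world():
    panel = tc.simulate_line_panel(
        3, 3, tc.MarkerSpec(n_markers=8, mean_alleles=3, max_alleles=4), seed=17
    )
    crosses, _ = tc.simulate_cross_set(panel, 6, seed=17)
    trial = tc.TrialSpec(n_environments=3, n_replicates=2, block_size=6)
    v = tc.GeneratingVariances(
        sigma2_gca1xE=0.0, sigma2_gca2xE=0.0, sigma2_scaxE=0.0,
        sigma2_residual=0.01,
    )
    pheno, truth = tc.simulate_trial(crosses, trial, v, "marker-truth", panel, seed=17)
    A = tc.build_additive_matrix(panel, crosses)
    D = tc.build_dominance_matrix(panel, crosses)
    return dict(panel=panel, crosses=crosses, pheno=pheno, truth=truth, A=A, D=D)


class TestJackknifeCV:
    def test_exhaustive_leave_two_out_matches_independent_loop(self, low_noise_world):
        w = low_noise_world
        cfg = tc.CVConfig(levels=(2,), draws=15, variant="TEAM1", seed=1,
                          tol=1e-7, max_iter=1500)
        res = tc.jackknife_cv(w["pheno"], w["A"], None, cfg)
        level = res.levels[0]
        assert len(level.samples) + level.n_skipped == 15  # all C(6,2) subsets

        # independently coded leave-2-out loop
        from itertools import combinations

        hybrids = sorted(set(w["pheno"]["hybrid"]))
        expected = []
        for pair in combinations(range(len(hybrids)), 2):
            held = [hybrids[i] for i in pair]
            train = w["pheno"][~w["pheno"]["hybrid"].isin(held)]
            model = tc.TeamModel("TEAM1", tol=1e-7, max_iter=1500).fit(train, w["A"])
            if not model.result_.converged:
                continue
            rows = [w["A"].hybrids.index(h) for h in held]
            A_h = tc.AdditiveMatrix(held, w["A"].columns, w["A"].values[rows])
            pred = model.predict(A_h)["total"]
            held_pheno = w["pheno"][w["pheno"]["hybrid"].isin(held)]
            Xh = design_from_columns(held_pheno, model.x_columns_)
            obs = adjusted_hybrid_means(held_pheno, beta=model.beta_, x_design=Xh)
            expected.append(np.corrcoef(pred, obs.reindex(pred.index))[0, 1])
        assert np.allclose(sorted(level.samples), sorted(expected), atol=1e-8)

    def test_noise_free_cv_correlations_near_one(self):
        # without interaction and residual noise, held-out hybrids are
        # predicted almost exactly once training identifies every allele
        # effect (additive truth; unseen dominance pairs are structurally
        # unpredictable and would cap even a noise-free correlation)
        panel = tc.simulate_line_panel(
            8, 8,
            tc.MarkerSpec(n_markers=5, mean_alleles=2.5, min_alleles=2, max_alleles=3),
            seed=19,
        )
        crosses, _ = tc.simulate_cross_set(panel, 30, seed=19)
        trial = tc.TrialSpec(n_environments=2, n_replicates=2, block_size=10)
        v0 = tc.GeneratingVariances(
            sigma2_gca1xE=0, sigma2_gca2xE=0, sigma2_scaxE=0, sigma2_residual=1e-8
        )
        pheno, _ = tc.simulate_trial(
            crosses, trial, v0, "marker-truth", panel, seed=19, additive_fraction=1.0
        )
        A = tc.build_additive_matrix(panel, crosses)
        cfg = tc.CVConfig(levels=(3, 5, 8), draws=5, variant="TEAM1", seed=2,
                          tol=1e-7, max_iter=2000)
        res = tc.jackknife_cv(pheno, A, None, cfg)
        for level in res.levels:
            assert level.samples, "every draw should produce a correlation"
            assert min(level.samples) > 0.95

    def test_level_bounds_validated(self, low_noise_world):
        w = low_noise_world
        with pytest.raises(ValueError, match="k="):
            tc.jackknife_cv(
                w["pheno"], w["A"], None,
                tc.CVConfig(levels=(1,), draws=2, variant="TEAM1"),
            )

    def test_report_frame_shape(self, low_noise_world):
        w = low_noise_world
        cfg = tc.CVConfig(levels=(2,), draws=3, variant="TEAM1", seed=3,
                          tol=1e-6, max_iter=800)
        frame = tc.jackknife_cv(w["pheno"], w["A"], None, cfg).to_frame()
        assert list(frame.columns) == [
            "k", "pct_missing", "mean", "median", "mode", "n_draws", "n_skipped"
        ]
        assert frame.loc[0, "k"] == 2


class TestExternalValidation:
    def test_noise_free_regional_trial_reproduces_predictions(self, small_world):
        w = small_world
        v0 = tc.GeneratingVariances(
            sigma2_gca1xE=0, sigma2_gca2xE=0, sigma2_scaxE=0, sigma2_residual=1e-8
        )
        regional, _ = tc.simulate_trial(
            w["crosses"], tc.TrialSpec(n_environments=2, env_prefix="R"),
            v0, "marker-truth", w["panel"], seed=77, reuse_truth=w["truth"],
        )
        ext = tc.external_validate(w["truth"].hybrid_values, regional, fraction=0.25)
        assert ext.r2_linear > 0.999
        assert ext.correlation > 0.999
        assert ext.selection.correct_rate == 1.0

    def test_small_overlap_rejected(self, small_world):
        w = small_world
        tiny = w["pheno"][w["pheno"]["hybrid"].isin(w["crosses"].hybrids[:2])]
        with pytest.raises(ValueError, match="overlap"):
            tc.external_validate(w["truth"].hybrid_values.iloc[:2], tiny)

    def test_hand_worked_overlap(self):
        # 5 hybrids, single environment: all outputs hand-checkable
        hybrids = [f"A{i}×B{i}" for i in range(5)]
        pred = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=hybrids)
        rows = [
            (h, "E1", "R1", "B1", 10.0 + val)
            for h, val in zip(hybrids, [1.1, 1.9, 3.2, 3.8, 5.0])
        ]
        regional = pd.DataFrame(
            rows, columns=["hybrid", "environment", "replicate", "block", "yield"]
        )
        ext = tc.external_validate(pred, regional, fraction=0.4)
        obs = np.array([1.1, 1.9, 3.2, 3.8, 5.0])
        x = pred.to_numpy()
        coef = np.polyfit(x, obs, 1)
        resid = obs - np.polyval(coef, x)
        r2 = 1 - resid @ resid / np.sum((obs - obs.mean()) ** 2)
        assert ext.n_overlap == 5
        assert ext.r2_linear == pytest.approx(r2, rel=1e-9)
        assert ext.correlation == pytest.approx(np.corrcoef(x, obs)[0, 1], rel=1e-9)
        assert ext.selection.correct_rate == 1.0  # top-2 sets coincide
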