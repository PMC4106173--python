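"""Diallel and TEAM model fits, marker-variance recovery, prediction."""

import logging

import numpy as np
import pandas as pd
import pytest

import teamcross as tc
from teamcross.diallel import build_diallel_spec
from teamcross.team import recover_marker_variances


class TestDiallel:
    def test_components_recovered_from_informative_simulation(self):
        # strong genetic signal, mild noise: estimates land near the truth
        panel = tc.simulate_line_panel(12, 12, tc.MarkerSpec(n_markers=2), seed=21)
        crosses, _ = tc.simulate_cross_set(panel, 60, seed=21)
        trial = tc.TrialSpec(n_environments=8, n_replicates=2)
        v = tc.GeneratingVariances(0.3, 0.4, 0.2, 0.02, 0.02, 0.02, 0.05)
        est = {"gca1": [], "gca2": [], "sca": []}
        for seed in (1, 2, 3, 4):
            pheno, _ = tc.simulate_trial(crosses, trial, v, "diallel-truth", panel, seed=seed)
            s = tc.fit_diallel(pheno, crosses, panel, max_iter=3000)
            for key in est:
                est[key].append(s.components.by_term[key])
        assert np.mean(est["gca1"]) == pytest.approx(0.3, rel=0.5)
        assert np.mean(est["gca2"]) == pytest.approx(0.4, rel=0.5)
        assert np.mean(est["sca"]) == pytest.approx(0.2, rel=0.5)

    def test_hybrid_blups_track_true_genetic_values(self, small_world):
        w = small_world
        pheno, truth = tc.simulate_trial(
            w["crosses"], tc.TrialSpec(n_environments=4),
            tc.GeneratingVariances(0.2, 0.2, 0.1, 0.02, 0.02, 0.02, 0.05),
            "diallel-truth", w["panel"], seed=31,
        )
        s = tc.fit_diallel(pheno, w["crosses"], w["panel"], max_iter=3000)
        r = np.corrcoef(s.hybrid_blups, truth.hybrid_values.reindex(s.hybrid_blups.index))[0, 1]
        assert r > 0.8
        # the summary's total is the sum of its parts by construction
        c = s.components.by_term
        assert s.sigma2_g == pytest.approx(c["gca1"] + c["gca2"] + c["sca"])

    def test_single_environment_drops_interactions(self, small_world, caplog):
        w = small_world
        pheno = w["pheno"][w["pheno"]["environment"] == "E1"]
        with caplog.at_level(logging.WARNING):
            spec = build_diallel_spec(pheno, w["crosses"], w["panel"])
        assert spec.term_labels == ["gca1", "gca2", "sca"]
        assert any("single-environment" in m for m in caplog.messages)

    def test_within_group_cross_rejected(self):
        panel = tc.simulate_line_panel(3, 3, tc.MarkerSpec(n_markers=2), seed=0)
        bad = tc.CrossSet([("L01", "L02")])  # both group 1
        with pytest.raises(ValueError, match="group1×group2"):
            bad.parents_by_group(panel)


class TestHeritability:
    def _comp(self, g1, g2, sca, gxe, resid):
        return tc.VarianceComponents(
            {"gca1": g1, "gca2": g2, "sca": sca,
             "gca1xE": gxe / 3, "gca2xE": gxe / 3, "scaxE": gxe / 3},
            resid,
        )

    def test_limits(self):
        from teamcross.diallel import heritability

        assert heritability(self._comp(0.1, 0.1, 0.1, 0.0, 1e-12), 5, 2) == pytest.approx(1.0)
        assert heritability(self._comp(0, 0, 0, 0.5, 0.3), 5, 2) == 0.0

    def test_study_preset_lands_in_reported_range(self):
        from teamcross.diallel import heritability

        v = tc.replication_preset()
        comp = self._comp(
            v.sigma2_gca1 + v.sigma2_gca2, 0.0, v.sigma2_sca,
            v.total_gxe, v.sigma2_residual,
        )
        h2 = heritability(comp, 7, 2)
        assert 0.6 < h2 < 0.7


class TestTeamModel:
    def test_zero_dominance_design_reduces_to_team1(self, small_world):
        w = small_world
        D0 = tc.DominanceMatrix(
            w["D"].hybrids, w["D"].columns, np.zeros_like(w["D"].values)
        )
        m1 = tc.TeamModel("TEAM1", max_iter=400).fit(w["pheno"], w["A"])
        m2 = tc.TeamModel("TEAM2", max_iter=400).fit(w["pheno"], w["A"], D0)
        assert np.allclose(
            m1.additive_effects_.to_numpy(), m2.additive_effects_.to_numpy(), atol=1e-8
        )
        assert np.allclose(m1.beta_, m2.beta_, atol=1e-8)
        assert np.allclose(m2.dominance_effects_.to_numpy(), 0.0)

    def test_effect_recovery_improves_with_heritability(self, small_world):
        w = small_world
        rs = {}
        for label, (gxe, resid) in {
            "high": (0.0, 1e-6), "low": (0.3, 0.4),
        }.items():
            v = tc.GeneratingVariances(
                sigma2_gca1xE=gxe, sigma2_gca2xE=gxe, sigma2_scaxE=gxe,
                sigma2_residual=resid,
            )
            pheno, truth = tc.simulate_trial(
                w["crosses"], w["trial"], v, "marker-truth", w["panel"], seed=13
            )
            model = tc.TeamModel("TEAM2", max_iter=2000).fit(pheno, w["A"], w["D"])
            pred = model.predict(w["A"], w["D"])["total"]
            rs[label] = np.corrcoef(pred, truth.hybrid_values.reindex(pred.index))[0, 1]
        assert rs["high"] > 0.99
        assert rs["high"] > rs["low"]

    def test_marker_variance_formula_matches_dense_oracle(self, small_world, team_fit):
        # recompute s2_a, s2_d from a dense inverse of the full coefficient
        # matrix, independently of the solver's block bookkeeping
        w = small_world
        fit = team_fit.result_
        from teamcross.design import fixed_effects_design, hybrid_incidence

        X, _ = fixed_effects_design(w["pheno"])
        H, _ = hybrid_incidence(w["pheno"], w["A"].hybrids)
        Za = (H @ w["A"].values.astype(float))
        Zd = (H @ w["D"].values.astype(float))
        Z = np.hstack([Za, Zd])
        s2 = fit.components.residual
        lam = np.concatenate([
            np.full(Za.shape[1], s2 / fit.components.by_term["additive"]),
            np.full(Zd.shape[1], s2 / fit.components.by_term["dominance"]),
        ])
        C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + np.diag(lam)]])
        Cinv = np.linalg.inv(C)
        p, n, k = X.shape[1], Za.shape[1], Zd.shape[1]
        a = fit.effects["additive"]
        d = fit.effects["dominance"]
        wn = Cinv[p : p + n, p : p + n]
        wk = Cinv[p + n :, p + n :]
        s2_a = (a @ a + np.trace(wn) * s2) / n
        s2_d = (d @ d + np.trace(wk) * s2) / k
        mv = recover_marker_variances(fit, n=n, k=k)
        assert mv.sigma2_a == pytest.approx(s2_a, rel=1e-6)
        assert mv.sigma2_d == pytest.approx(s2_d, rel=1e-6)
        assert mv.sigma2_g == pytest.approx(n * s2_a + k * s2_d, rel=1e-6)

    def test_misaligned_hybrids_rejected(self, small_world):
        w = small_world
        rogue = w["pheno"].copy()
        rogue.loc[rogue.index[0], "hybrid"] = "Z1×Z2"
        with pytest.raises(ValueError, match="unknown hybrids"):
            tc.TeamModel("TEAM1", max_iter=50).fit(rogue, w["A"])


class TestPrediction:
    def test_predictions_are_inner_products(self, small_world, team_fit):
        w = small_world
        pred = tc.predict_hybrids(team_fit, w["A"], w["D"])
        a = team_fit.additive_effects_.to_numpy()
        d = team_fit.dominance_effects_.to_numpy()
        assert np.allclose(pred["alpha"], w["A"].values @ a)
        assert np.allclose(pred["delta"], w["D"].values @ d)
        assert np.allclose(pred["total"], pred["alpha"] + pred["delta"])

    def test_shared_allele_counts_double(self, team_fit, small_world):
        # lambda = 2 coding: a hybrid whose parents share an allele gets
        # twice that allele's effect in alpha
        w = small_world
        key = w["A"].columns[0]
        row = np.zeros((1, len(w["A"].columns)))
        row[0, 0] = 2
        single = tc.AdditiveMatrix(["synthetic×pair"], w["A"].columns, row)
        pred = team_fit.predict(
            single,
            tc.DominanceMatrix(
                ["synthetic×pair"], w["D"].columns, np.zeros((1, len(w["D"].columns)))
            ),
        )
        assert pred["alpha"].iloc[0] == pytest.approx(
            2 * team_fit.additive_effects_[key]
        )

    def test_prediction_is_linear_in_design_rows(self, small_world, team_fit):
        w = small_world
        two = w["A"].values[:2].astype(float)
        summed = tc.AdditiveMatrix(["s×um"], w["A"].columns, two.sum(0, keepdims=True))
        parts = tc.AdditiveMatrix(["a×1", "a×2"], w["A"].columns, two)
        d0_cols = w["D"].columns
        d_sum = tc.DominanceMatrix(["s×um"], d0_cols, w["D"].values[:2].sum(0, keepdims=True))
        d_parts = tc.DominanceMatrix(["a×1", "a×2"], d0_cols, w["D"].values[:2])
        total_sum = team_fit.predict(summed, d_sum)["total"].iloc[0]
        total_parts = team_fit.predict(parts, d_parts)["total"].sum()
        assert total_sum == pytest.approx(total_parts)

    def test_rank_invariant_to_phenotype_shift(self, small_world):
        w = small_world
        m1 = tc.TeamModel("TEAM2", max_iter=300).fit(w["pheno"], w["A"], w["D"])
        shifted = w["pheno"].assign(**{"yield": w["pheno"]["yield"] + 5.0})
        m2 = tc.TeamModel("TEAM2", max_iter=300).fit(shifted, w["A"], w["D"])
        r1 = tc.predict_all_crosses(w["panel"], m1)
        r2 = tc.predict_all_crosses(w["panel"], m2)
        assert list(r1.index) == list(r2.index)
        assert np.allclose(r1["total"], r2["total"], atol=1e-6)

    def test_all_crosses_enumeration_and_training_flags(self, small_world, team_fit):
        w = small_world
        ranked = tc.predict_all_crosses(w["panel"], team_fit)
        assert len(ranked) == 8 * 8  # all group1 x group2 pairs
        assert ranked["trained"].sum() == len(w["crosses"])
        assert (ranked["total"].to_numpy()[:-1] >= ranked["total"].to_numpy()[1:]).all()
        trained = set(w["crosses"].hybrids)
        assert set(ranked.index[ranked["trained"]]) == trained

    def test_two_line_panel_single_prediction(self, team_fit, small_world):
        w = small_world
        lines = [w["panel"].group_lines(1)[0], w["panel"].group_lines(2)[0]]
        small = tc.LinePanel(
            w["panel"].genotypes.loc[lines], w["panel"].groups.loc[lines]
        )
        ranked = tc.predict_all_crosses(small, team_fit)
        assert len(ranked) == 1
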