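"""Consensus signatures, pathway projection, similarity and ROC statistics."""

import numpy as np
import pandas as pd
import pytest

from combiseq.signatures import (
    RankDeficientDesignError,
    consensus_signatures,
    drug_pathway_assoc,
    make_design,
    pathway_activity,
    roc_matched_drugs,
    signature_similarity,
)


def _design_two_group(n_treated=6, n_control=6):
    obs = pd.DataFrame(
        {
            "drug_rt": ["X"] * n_treated + ["DMSO"] * n_control,
            "drug_pcr": ["DMSO"] * (n_treated + n_control),
        },
        index=[f"s{i}" for i in range(n_treated + n_control)],
    )
    return obs, make_design(obs)


class TestDesign:
    def test_indicator_structure(self):
        obs = pd.DataFrame(
            {
                "drug_rt": ["A", "A", "DMSO"],
                "drug_pcr": ["B", "DMSO", "DMSO"],
            },
            index=["s0", "s1", "s2"],
        )
        D = make_design(obs)
        assert list(D.columns) == ["intercept", "A", "B"]
        assert D.loc["s0"].tolist() == [1.0, 1.0, 1.0]
        assert D.loc["s1"].tolist() == [1.0, 1.0, 0.0]
        assert D.loc["s2"].tolist() == [1.0, 0.0, 0.0]

    def test_combination_rows_have_two_indicators(self):
        obs = pd.DataFrame(
            {"drug_rt": ["A", "B"], "drug_pcr": ["B", "A"]}, index=["s0", "s1"]
        )
        D = make_design(obs)
        assert (D[["A", "B"]].sum(axis=1) == 2).all()


class TestConsensusSignatures:
    def test_two_group_closed_form(self, rng):
        obs, D = _design_two_group()
        X = pd.DataFrame(
            rng.normal(size=(12, 5)),
            index=obs.index,
            columns=[f"g{i}" for i in range(5)],
        )
        sig = consensus_signatures(X, D)
        treated = X.iloc[:6].mean()
        control = X.iloc[6:].mean()
        np.testing.assert_allclose(
            sig.coefficients["X"], treated - control, atol=1e-10
        )
        np.testing.assert_allclose(sig.intercept, control, atol=1e-10)

    def test_planted_effect_recovery(self, rng):
        drugs = [f"d{i}" for i in range(8)]
        obs = pd.DataFrame(
            {
                "drug_rt": rng.choice(drugs + ["DMSO"], 120),
                "drug_pcr": rng.choice(drugs + ["DMSO"], 120),
            }
        )
        D = make_design(obs)
        truth = rng.normal(0, 1, size=(len(D.columns) - 1, 100))
        X = pd.DataFrame(
            D.to_numpy()[:, 1:] @ truth + rng.normal(0, 0.5, (120, 100)),
            columns=[f"g{i}" for i in range(100)],
        )
        sig = consensus_signatures(X, D)
        for i, d in enumerate(c for c in D.columns if c != "intercept"):
            assert np.corrcoef(sig.coefficients[d], truth[i])[0, 1] > 0.95

    def test_all_zero_response_gives_zero_coefficients(self):
        obs, D = _design_two_group(4, 4)
        X = pd.DataFrame(np.zeros((8, 3)), index=obs.index, columns=list("abc"))
        sig = consensus_signatures(X, D)
        assert (sig.coefficients.to_numpy() == 0).all()

    def test_rank_deficiency_lists_collinear_columns(self, rng):
        obs = pd.DataFrame(
            {"drug_rt": ["A", "A", "DMSO", "DMSO", "A"],
             "drug_pcr": ["B", "B", "DMSO", "DMSO", "B"]},
        )
        D = make_design(obs)  # A and B always co-occur: collinear
        X = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(RankDeficientDesignError) as err:
            consensus_signatures(X, D)
        assert {"A", "B"} <= set(err.value.collinear)

    def test_residuals_orthogonal_to_design(self, rng):
        obs, D = _design_two_group()
        X = pd.DataFrame(rng.normal(size=(12, 4)), index=obs.index)
        sig = consensus_signatures(X, D)
        fitted = (
            D.to_numpy()[:, 1:] @ sig.coefficients.to_numpy().T
            + sig.intercept.to_numpy()
        )
        resid = X.to_numpy() - fitted
        np.testing.assert_allclose(D.to_numpy().T @ resid, 0, atol=1e-9)

    def test_matches_statsmodels_single_gene(self, rng):
        import statsmodels.api as sm

        obs, D = _design_two_group(5, 7)
        X = pd.DataFrame(rng.normal(size=(12, 1)), index=obs.index, columns=["g"])
        sig = consensus_signatures(X, D)
        fit = sm.OLS(X["g"].to_numpy(), D.to_numpy()).fit()
        assert sig.coefficients.loc["g", "X"] == pytest.approx(fit.params[1])
        assert sig.standard_errors.loc["g", "X"] == pytest.approx(fit.bse[1])


class TestPathwayActivity:
    def test_identity_weights_give_zscored_expression(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        W = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["p1", "p2"])
        act, cov = pathway_activity(X, W)
        expected = (X[["a", "b"]] - X[["a", "b"]].mean()) / X[["a", "b"]].std(ddof=0)
        np.testing.assert_allclose(act.to_numpy(), expected.to_numpy(), atol=1e-10)
        assert (cov == 1.0).all()

    def test_weight_scaling_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        W = pd.DataFrame(rng.normal(size=(6, 3)), index=X.columns)
        act1, _ = pathway_activity(X, W)
        act2, _ = pathway_activity(X, 2.0 * W)
        np.testing.assert_allclose(act1.to_numpy(), act2.to_numpy(), atol=1e-10)

    def test_planted_factor_recovered(self, rng):
        from scipy.stats import spearmanr

        W = pd.DataFrame(
            rng.normal(size=(50, 1)), index=[f"g{i}" for i in range(50)],
            columns=["path"],
        )
        factor = rng.normal(size=30)
        X = pd.DataFrame(
            np.outer(factor, W["path"]) + rng.normal(0, 0.5, (30, 50)),
            columns=W.index,
        )
        act, _ = pathway_activity(X, W)
        rho = spearmanr(act["path"], factor).statistic
        assert rho > 0.9

    def test_unmatched_pathway_dropped(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        W = pd.DataFrame(
            {"p1": [1.0, 0.0, 0.0], "p2": [0.0, 0.0, 1.0]},
            index=["a", "b", "zzz"],
        )
        with pytest.warns(UserWarning, match="no matched genes"):
            act, _ = pathway_activity(X, W)
        assert list(act.columns) == ["p1"]

    def test_no_shared_genes_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        W = pd.DataFrame({"p1": [1.0]}, index=["zzz"])
        with pytest.raises(ValueError):
            pathway_activity(X, W)


class TestDrugPathwayAssoc:
    def test_single_drug_closed_form(self, rng):
        obs, D = _design_two_group(5, 5)
        act = pd.DataFrame(rng.normal(size=(10, 3)), index=obs.index,
                           columns=["p1", "p2", "p3"])
        assoc = drug_pathway_assoc(act, D)
        diff = act.iloc[:5].mean() - act.iloc[5:].mean()
        np.testing.assert_allclose(assoc.loc["X"], diff, atol=1e-10)

    def test_planted_effects_recovered(self, rng):
        drugs = ["A", "B", "C"]
        obs = pd.DataFrame(
            {
                "drug_rt": rng.choice(drugs + ["DMSO"], 60),
                "drug_pcr": rng.choice(drugs + ["DMSO"], 60),
            }
        )
        D = make_design(obs)
        truth = rng.normal(size=(3, 4))
        act = pd.DataFrame(D.to_numpy()[:, 1:] @ truth + rng.normal(0, 0.1, (60, 4)))
        assoc = drug_pathway_assoc(act, D)
        np.testing.assert_allclose(assoc.to_numpy(), truth, atol=0.15)

    def test_permuted_activities_center_at_zero(self, rng):
        obs, D = _design_two_group(10, 10)
        coefs = []
        base = rng.normal(size=20)
        for _ in range(200):
            act = pd.DataFrame({"p": rng.permutation(base)}, index=obs.index)
            coefs.append(drug_pathway_assoc(act, D).loc["X", "p"])
        assert abs(np.mean(coefs)) < 3 * np.std(coefs) / np.sqrt(len(coefs))


class TestSimilarityROC:
    def _sigs(self, rng, n_genes=60, n_drugs=5, prefix="d"):
        return pd.DataFrame(
            rng.normal(size=(n_genes, n_drugs)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"{prefix}{i}" for i in range(n_drugs)],
        )

    def test_self_similarity_diagonal_is_one(self, rng):
        A = self._sigs(rng)
        sim = signature_similarity(A, A)
        np.testing.assert_allclose(np.diag(sim), 1.0, atol=1e-12)

    def test_monotone_transform_invariance(self, rng):
        A = self._sigs(rng, n_drugs=3)
        B = A.copy()
        B["d0"] = np.exp(B["d0"] * 0.5)  # strictly increasing transform
        sim_ab = signature_similarity(A, B)
        sim_aa = signature_similarity(A, A)
        np.testing.assert_allclose(sim_ab.to_numpy(), sim_aa.to_numpy(), atol=1e-12)

    def test_independent_signatures_near_zero(self, rng):
        A = self._sigs(rng, n_genes=300)
        B = self._sigs(rng, n_genes=300, prefix="e")
        sim = signature_similarity(A, B)
        assert np.abs(sim.to_numpy()).mean() < 0.1

    def test_min_shared_genes_enforced(self, rng):
        A = self._sigs(rng, n_genes=5)
        with pytest.raises(ValueError, match="shared genes"):
            signature_similarity(A, A, min_shared_genes=10)

    def test_perfect_ranking_gives_auc_one(self, rng):
        drugs = [f"d{i}" for i in range(5)]
        sim = pd.DataFrame(
            rng.uniform(0.0, 0.5, size=(5, 5)), index=drugs, columns=drugs
        )
        np.fill_diagonal(sim.to_numpy(), 0.9)
        sim.iloc[:, :] = np.where(np.eye(5, dtype=bool), 0.9, sim.to_numpy())
        roc = roc_matched_drugs(sim, n_perm=99, seed=0)
        assert roc.auc == 1.0

    def test_auc_equals_brute_force_pair_counting(self, rng):
        """AUC must equal concordant-pair counting with ties worth 1/2."""
        drugs = [f"d{i}" for i in range(6)]
        sim = pd.DataFrame(
            np.round(rng.normal(size=(6, 6)), 1), index=drugs, columns=drugs
        )
        roc = roc_matched_drugs(sim, n_perm=99, seed=0)
        truth = np.eye(6, dtype=bool).ravel()
        scores = sim.to_numpy().ravel()
        pos, neg = scores[truth], scores[~truth]
        num = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert roc.auc == pytest.approx(num / (len(pos) * len(neg)))

    def test_label_independent_scores_auc_half(self, rng):
        drugs = [f"d{i}" for i in range(8)]
        aucs = []
        for _ in range(50):
            sim = pd.DataFrame(
                rng.normal(size=(8, 8)), index=drugs, columns=drugs
            )
            aucs.append(roc_matched_drugs(sim, n_perm=99, seed=1).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.07)

    def test_degenerate_label_sets_rejected(self, rng):
        sim = pd.DataFrame(rng.normal(size=(1, 1)), index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            roc_matched_drugs(sim, n_perm=99)
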