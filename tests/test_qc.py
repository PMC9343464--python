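"""Filtering, normalization, silhouette permutation QC and spike-in stats."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from combiseq.qc import (
    EmptyFilterError,
    QCThresholds,
    filter_counts,
    normalize,
    remove_batch,
    select_top_expressed,
    silhouette_samples_from_distance,
    silhouette_test,
    spikein_accuracy,
    spikein_sensitivity,
    tpm,
)


def _adata(X, genes=None, obs=None):
    X = np.asarray(X)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    adata = ad.AnnData(
        X=X,
        obs=obs if obs is not None else pd.DataFrame(index=[f"s{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=genes),
    )
    return adata


class TestFiltering:
    def test_mito_fraction_threshold(self):
        # mito fractions 5%, 14%, 20% at a 15% ceiling: two samples survive
        X = np.array(
            [[5, 95, 30], [14, 86, 30], [20, 80, 30]], dtype=float
        )
        adata = _adata(X, genes=["MT-1", "g1", "g2"])
        out, report = filter_counts(
            adata, QCThresholds(min_genes_per_sample=1), mito_genes=["MT-1"]
        )
        assert out.n_obs == 2
        assert report["n_samples_removed_mito"] == 1

    def test_all_pass_is_identity(self):
        X = np.ones((4, 5))
        adata = _adata(X)
        out, report = filter_counts(adata, QCThresholds(min_genes_per_sample=1))
        assert out.shape == adata.shape
        assert report["n_samples_out"] == 4 and report["n_genes_out"] == 5

    def test_low_detection_gene_removed(self):
        X = np.ones((20, 3))
        X[1:, 0] = 0  # gene 0 detected in 1/20 = 5% < 10%
        adata = _adata(X)
        out, report = filter_counts(adata, QCThresholds(min_genes_per_sample=1))
        assert "g0" not in out.var_names
        assert report["n_genes_removed_dropout"] == 1

    def test_report_reconciles_with_dimensions(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(5, size=(30, 40)).astype(float)
        X[:3] = 0.0  # empty samples removed by gene-count floor
        adata = _adata(X, genes=["MT-0"] + [f"g{i}" for i in range(39)])
        out, rep = filter_counts(
            adata, QCThresholds(min_genes_per_sample=10), mito_genes=["MT-0"]
        )
        assert rep["n_samples_in"] - rep["n_samples_removed_low_genes"] - rep[
            "n_samples_removed_mito"
        ] == rep["n_samples_out"]
        assert rep["n_genes_in"] - rep["n_genes_removed_dropout"] == rep["n_genes_out"]
        assert out.shape == (rep["n_samples_out"], rep["n_genes_out"])

    def test_empty_result_signalled(self):
        adata = _adata(np.ones((2, 3)))
        with pytest.raises(EmptyFilterError):
            filter_counts(adata, QCThresholds(min_genes_per_sample=10))

    def test_unknown_mito_gene_rejected(self):
        adata = _adata(np.ones((2, 3)))
        with pytest.raises(ValueError, match="absent"):
            filter_counts(adata, mito_genes=["MT-X"])


class TestNormalize:
    def test_depth_invariance_before_zscore(self):
        X = np.array([[10.0, 30.0, 60.0], [20.0, 60.0, 120.0]])
        out = normalize(_adata(X), zscore=False)
        np.testing.assert_allclose(out.X[0], out.X[1], rtol=1e-12)

    def test_zscore_columns_standardized(self, rng):
        X = rng.poisson(20, size=(15, 8)).astype(float) + 1
        out = normalize(_adata(X))
        np.testing.assert_allclose(np.asarray(out.X).mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(np.asarray(out.X).std(axis=0), 1, atol=1e-8)

    def test_constant_gene_dropped_with_warning(self, rng):
        X = rng.poisson(20, size=(6, 4)).astype(float) + 1
        X[:, 2] = 0.0  # zero counts in every sample: constant after log
        with pytest.warns(UserWarning, match="zero-variance"):
            out = normalize(_adata(X))
        assert "g2" not in out.var_names

    def test_zero_depth_sample_rejected(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="zero-depth"):
            normalize(_adata(X))


class TestBatchRemoval:
    def _planted(self, rng, delta=3.0):
        X = rng.normal(0, 1, size=(20, 6))
        batch = np.array(["a"] * 10 + ["b"] * 10)
        X[batch == "b"] += delta
        obs = pd.DataFrame(
            {"replicate": batch}, index=[f"s{i}" for i in range(20)]
        )
        return _adata(X, obs=obs)

    def test_planted_offset_removed(self, rng):
        adata = self._planted(rng)
        out = remove_batch(adata, "replicate")
        X = np.asarray(out.X)
        b = adata.obs["replicate"] == "b"
        diff = X[b.to_numpy()].mean(axis=0) - X[(~b).to_numpy()].mean(axis=0)
        np.testing.assert_allclose(diff, 0, atol=1e-10)

    def test_single_batch_identity(self, rng):
        X = rng.normal(size=(6, 4))
        obs = pd.DataFrame({"replicate": ["a"] * 6}, index=[f"s{i}" for i in range(6)])
        adata = _adata(X, obs=obs)
        out = remove_batch(adata, "replicate")
        np.testing.assert_allclose(np.asarray(out.X), X, atol=1e-12)

    def test_balanced_contrasts_preserved(self, rng):
        # balanced two-batch design: condition effect identical in each batch
        effect = np.array([1.0, -1.0, 0.5, 0.0])
        X = rng.normal(0, 0.1, size=(8, 4))
        cond = np.array([0, 0, 1, 1] * 2)
        X[cond == 1] += effect
        batch = np.array(["a"] * 4 + ["b"] * 4)
        X[batch == "b"] += 2.5
        obs = pd.DataFrame({"replicate": batch}, index=[f"s{i}" for i in range(8)])
        out = remove_batch(_adata(X.copy(), obs=obs), "replicate")
        Xc = np.asarray(out.X)
        # closed form: per-batch centering cannot change a balanced contrast
        contrast_before = X[cond == 1].mean(axis=0) - X[cond == 0].mean(axis=0) - 2.5 * 0
        got = Xc[cond == 1].mean(axis=0) - Xc[cond == 0].mean(axis=0)
        want = (X[cond == 1].mean(axis=0) - X[cond == 0].mean(axis=0))
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_singleton_batch_warns(self, rng):
        X = rng.normal(size=(5, 3))
        obs = pd.DataFrame(
            {"replicate": ["a", "a", "a", "a", "b"]},
            index=[f"s{i}" for i in range(5)],
        )
        with pytest.warns(UserWarning, match="singleton"):
            remove_batch(_adata(X, obs=obs), "replicate")


class TestTopExpressed:
    def test_all_genes_is_identity_set(self, rng):
        adata = _adata(rng.poisson(5, size=(4, 6)).astype(float))
        top = select_top_expressed(adata, n=6)
        assert set(top) == set(adata.var_names)

    def test_known_max_gene(self):
        X = np.array([[1.0, 9.0, 2.0], [2.0, 8.0, 1.0]])
        assert select_top_expressed(_adata(X), n=1) == ["g1"]

    def test_lexical_tie_break(self):
        X = np.ones((3, 3))
        adata = _adata(X, genes=["zeta", "alpha", "mid"])
        assert select_top_expressed(adata, n=2) == ["alpha", "mid"]


class TestSilhouette:
    def test_worked_example_matches_brute_force(self):
        """Two tight 1-D clusters {0, 0.1} and {10, 10.1}."""
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        labels = np.array([0, 0, 1, 1])
        D = np.abs(pts[:, None] - pts[None, :])
        a, b, s = silhouette_samples_from_distance(D, labels)
        # brute force for sample 0: a = 0.1, b = mean(10, 10.1) = 10.05
        assert a[0] == pytest.approx(0.1)
        assert b[0] == pytest.approx(10.05)
        assert s[0] == pytest.approx((10.05 - 0.1) / 10.05)
        assert s.mean() == pytest.approx(0.99, abs=1e-3)

    def test_matches_sklearn(self, rng):
        from scipy.spatial.distance import pdist, squareform
        from sklearn.metrics import silhouette_samples

        X = rng.normal(size=(25, 4))
        labels = rng.integers(0, 3, size=25)
        D = squareform(pdist(X))
        _, _, s = silhouette_samples_from_distance(D, labels)
        np.testing.assert_allclose(s, silhouette_samples(X, labels), atol=1e-10)

    def test_separated_clusters_significant(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        labels = np.repeat([0, 1], 10)
        res = silhouette_test(X, labels, n_perm=199, seed=0)
        assert res.mean_score > 0.9
        # a permuted labelling can reproduce the same two-set partition
        # (label swap), so the smallest attainable p may be slightly above
        # the add-one floor of 1/200
        assert res.p_value <= 2 / 200

    def test_p_matches_exact_enumeration_at_n4(self, rng):
        """Sampled permutation p agrees with exhaustive label-permutation p."""
        pts = rng.normal(size=(4, 2))
        labels = np.array([0, 0, 1, 1])
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        obs = silhouette_samples_from_distance(D, labels)[2].mean()
        null = [
            silhouette_samples_from_distance(D, np.array(perm))[2].mean()
            for perm in itertools.permutations(labels)
        ]
        exact_frac = np.mean([v >= obs for v in null])
        res = silhouette_test(D, labels, n_perm=999, seed=3, precomputed=True)
        mc_sd = np.sqrt(exact_frac * (1 - exact_frac) / 999) + 1e-3
        assert abs(res.p_value - exact_frac) < 4 * mc_sd + 1 / 1000

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_test(rng.normal(size=(6, 2)), np.zeros(6), n_perm=99)

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            silhouette_test(rng.normal(size=(6, 2)), np.repeat([0, 1], 3), n_perm=10)


class TestSpikeIns:
    def test_tpm_sums_to_million(self, rng):
        counts = rng.poisson(10, size=(5, 92)) + 1
        t = tpm(counts)
        np.testing.assert_allclose(t.sum(axis=1), 1e6, rtol=1e-12)

    def test_proportional_tpm_gives_r_one(self):
        conc = np.logspace(-1, 3, 20)
        table = pd.DataFrame(
            {"known_conc_attomol_ul": conc, "tpm": conc * 50.0}
        )
        assert spikein_accuracy(table, pseudocount=0.0)["r"] == pytest.approx(1.0)

    def test_poisson_ladder_recovers_high_correlation(self):
        from combiseq.simulate import simulate_spikeins

        tab = simulate_spikeins(seed=5)
        r = spikein_accuracy(tab)["r"]
        assert r > 0.9

    def test_shuffled_concentrations_near_zero(self, rng):
        from combiseq.simulate import simulate_spikeins

        tab = simulate_spikeins(seed=6, n_replicates=1)
        rs = []
        for i in range(20):
            shuffled = tab.copy()
            shuffled["known_conc_attomol_ul"] = rng.permutation(
                shuffled["known_conc_attomol_ul"].to_numpy()
            )
            rs.append(spikein_accuracy(shuffled)["r"])
        assert abs(np.mean(rs)) < 0.1

    def test_degenerate_variance_rejected(self):
        table = pd.DataFrame(
            {"known_conc_attomol_ul": [1.0, 1.0, 1.0], "tpm": [5.0, 5.0, 5.0]}
        )
        with pytest.raises(ValueError):
            spikein_accuracy(table)

    def test_lod50_recovered_within_ci(self, rng):
        # detection drawn from a known logistic in log10 concentration
        b0, b1 = -3.0, 2.0  # true LOD50 at 1.5
        conc = np.repeat(np.logspace(-1, 4, 50), 10)
        p = 1 / (1 + np.exp(-(b0 + b1 * np.log10(conc))))
        det = rng.random(len(conc)) < p
        table = pd.DataFrame({"known_conc_attomol_ul": conc, "detected": det.astype(int)})
        res = spikein_sensitivity(table)
        assert not res.separated
        assert res.lod50_ci[0] <= -b0 / b1 <= res.lod50_ci[1]

    def test_step_detection_flagged_as_separated(self):
        conc = np.logspace(0, 3, 16)
        det = (conc >= 30).astype(int)
        table = pd.DataFrame({"known_conc_attomol_ul": conc, "detected": det})
        res = spikein_sensitivity(table)
        assert res.separated
        below = np.log10(conc[det == 0].max())
        above = np.log10(conc[det == 1].min())
        assert below <= res.lod50_log10 <= above

    def test_constant_detection_rejected(self):
        table = pd.DataFrame(
            {"known_conc_attomol_ul": [1, 10, 100], "detected": [1, 1, 1]}
        )
        with pytest.raises(ValueError):
            spikein_sensitivity(table)

    def test_zero_slope_rejected(self):
        # detection symmetric in concentration: MLE slope is exactly 0
        table = pd.DataFrame(
            {
                "known_conc_attomol_ul": [1.0, 1.0, 100.0, 100.0] * 5,
                "detected": [0, 1, 0, 1] * 5,
            }
        )
        with pytest.raises(ValueError, match="slope"):
            spikein_sensitivity(table)
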