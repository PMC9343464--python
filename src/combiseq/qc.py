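"""Count-matrix quality control, normalization, and clustering QC.

Follows the shallow-sequencing QC used for pooled-droplet screens: samples
(= treatment conditions) with few detected genes or a mitochondrial read
fraction above 15% are removed, genes with high dropout are removed, counts
are depth-normalized, log-transformed and z-scored per gene, and replicate
batch structure is removed by per-batch mean-centering.

Clustering structure is quantified by mean silhouette scores per labelling
factor, tested against a label-permutation null; spike-in ladders yield an
accuracy correlation and a logistic limit of detection (LOD50).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist


class EmptyFilterError(RuntimeError):
    """All samples or all genes were removed by filtering."""


@dataclass(frozen=True)
class QCThresholds:
    """Sample/gene filters.

    The mitochondrial ceiling of 0.15 is the assay's stated cutoff; the
    gene-count floor and detection fraction are configurable defaults (an
    order of magnitude below the ~3200 genes/sample seen in deeply sequenced
    validation screens, and a 10% detection requirement respectively).
    """

    min_genes_per_sample: int = 200
    max_mito_fraction: float = 0.15
    min_detection_fraction: float = 0.10

    def __post_init__(self):
        for f in (self.max_mito_fraction, self.min_detection_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def filter_counts(
    adata: ad.AnnData,
    thresholds: QCThresholds | None = None,
    mito_genes: list[str] | None = None,
) -> tuple[ad.AnnData, dict]:
    """Remove low-quality samples and high-dropout genes.

    Samples go first (detected-gene floor, mitochondrial fraction ceiling),
    then genes detected in fewer than ``min_detection_fraction`` of the
    retained samples.  Returns the filtered copy plus a removal report that
    reconciles exactly with the dimension changes.
    """
    thresholds = thresholds or QCThresholds()
    mito_genes = list(mito_genes or [])
    missing = set(mito_genes) - set(adata.var_names)
    if missing:
        raise ValueError(f"mito genes absent from matrix: {sorted(missing)}")

    X = np.asarray(adata.X)
    genes_per_sample = (X > 0).sum(axis=1)
    depth = X.sum(axis=1)
    if mito_genes:
        mito_idx = adata.var_names.get_indexer(mito_genes)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(depth > 0, X[:, mito_idx].sum(axis=1) / depth, 0.0)
    else:
        mito_frac = np.zeros(adata.n_obs)

    keep_samples = (genes_per_sample >= thresholds.min_genes_per_sample) & (
        mito_frac <= thresholds.max_mito_fraction
    )
    if not keep_samples.any():
        raise EmptyFilterError("no samples survive filtering")
    sub = adata[keep_samples].copy()

    detection = (np.asarray(sub.X) > 0).mean(axis=0)
    keep_genes = detection >= thresholds.min_detection_fraction
    if not keep_genes.any():
        raise EmptyFilterError("no genes survive filtering")
    out = sub[:, keep_genes].copy()

    report = {
        "n_samples_in": int(adata.n_obs),
        "n_samples_removed_low_genes": int(
            (genes_per_sample < thresholds.min_genes_per_sample).sum()
        ),
        "n_samples_removed_mito": int(
            (
                (mito_frac > thresholds.max_mito_fraction)
                & (genes_per_sample >= thresholds.min_genes_per_sample)
            ).sum()
        ),
        "n_samples_out": int(out.n_obs),
        "n_genes_in": int(adata.n_vars),
        "n_genes_removed_dropout": int((~keep_genes).sum()),
        "n_genes_out": int(out.n_vars),
    }
    return out, report


def normalize(adata: ad.AnnData, zscore: bool = True) -> ad.AnnData:
    """Depth-normalize to the median depth, log1p, and z-score per gene.

    Genes with zero variance after log transform cannot be z-scored and are
    dropped with a warning.  Provenance flags are recorded in ``uns``.
    """
    X = np.asarray(adata.X, dtype=float)
    depth = X.sum(axis=1)
    if (depth <= 0).any():
        raise ValueError("zero-depth samples present; filter first")
    target = float(np.median(depth))
    Xn = np.log1p(X * (target / depth)[:, None])

    dropped: list[str] = []
    if zscore:
        mu = Xn.mean(axis=0)
        sd = Xn.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = list(np.asarray(adata.var_names)[~keep])
            warnings.warn(
                f"dropping {len(dropped)} zero-variance gene(s) during z-scoring"
            )
        Xn = (Xn[:, keep] - mu[keep]) / sd[keep]
        out = adata[:, keep].copy()
    else:
        out = adata.copy()
    out.X = Xn
    out.uns["normalization"] = {
        "depth_target": target,
        "log1p": True,
        "zscore": bool(zscore),
        "dropped_zero_variance": dropped,
        "batch_centered": False,
    }
    return out


def remove_batch(adata: ad.AnnData, batch_key: str = "replicate") -> ad.AnnData:
    """Equalize per-gene batch means (per-batch centering, global mean restored).

    A deterministic, closed-form correction adequate for additive replicate
    offsets.  Singleton batches are centered by the global mean with a
    warning; a single batch is an identity operation.
    """
    out = adata.copy()
    X = np.asarray(out.X, dtype=float)
    batches = out.obs[batch_key].to_numpy()
    uniq = pd.unique(batches)
    global_mean = X.mean(axis=0)
    if len(uniq) >= 2:
        for b in uniq:
            m = batches == b
            if m.sum() < 2:
                warnings.warn(f"singleton batch {b!r}: centered by global mean only")
                continue
            X[m] = X[m] - X[m].mean(axis=0) + global_mean
    out.X = X
    norm = dict(out.uns.get("normalization", {}))
    norm["batch_centered"] = True
    out.uns["normalization"] = norm
    return out


def select_top_expressed(adata: ad.AnnData, n: int = 100) -> list[str]:
    """The ``n`` genes with highest mean expression; ties broken by gene label."""
    if n > adata.n_vars:
        raise ValueError("n exceeds number of genes")
    means = np.asarray(adata.X).mean(axis=0)
    order = sorted(zip(-means, adata.var_names))  # descending mean, lexical ties
    return [g for _, g in order[:n]]


# ------------------------------------------------------------- silhouettes


@dataclass
class SilhouetteResult:
    """Per-sample silhouette components and a permutation test of the mean."""

    a: np.ndarray  # mean intra-cluster distance
    b: np.ndarray  # mean nearest-other-cluster distance
    s: np.ndarray  # (b - a) / max(a, b)
    mean_score: float
    null_scores: np.ndarray
    p_value: float
    n_perm: int


def silhouette_samples_from_distance(
    D: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample silhouette a/b/s from a full distance matrix.

    s = (b - a) / max(a, b); singleton-cluster samples get s = 0 (and a = 0),
    matching the scikit-learn convention.
    """
    labels = np.asarray(labels)
    n = len(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    onehot = np.zeros((n, len(uniq)))
    onehot[np.arange(n), inv] = 1.0
    counts = onehot.sum(axis=0)
    sums = D @ onehot  # (n, k) summed distance to each cluster
    own = counts[inv]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(own > 1, sums[np.arange(n), inv] / np.maximum(own - 1, 1), 0.0)
        mean_other = sums / counts[None, :]
        mean_other[np.arange(n), inv] = np.inf
        b = mean_other.min(axis=1)
        s = np.where(own > 1, (b - a) / np.maximum(a, b), 0.0)
    return a, b, s


def silhouette_test(
    data: np.ndarray,
    labels,
    n_perm: int = 199,
    seed: int = 0,
    precomputed: bool = False,
    n_components: int = 50,
) -> SilhouetteResult:
    """Mean silhouette of a labelling, tested against a label-permutation null.

    ``data`` is either a samples x features matrix (reduced to its top
    ``n_components`` principal components before computing Euclidean
    distances, mirroring dimension-reduced clustering QC) or, with
    ``precomputed=True``, a full distance matrix.  The empirical p-value uses
    the add-one estimator ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("all samples share one cluster label")
    if precomputed:
        D = np.asarray(data, dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        k = min(n_components, X.shape[0], X.shape[1])
        if X.shape[1] > k:
            from sklearn.decomposition import PCA

            X = PCA(n_components=k, random_state=seed).fit_transform(X)
        D = squareform(pdist(X))

    a, b, s = silhouette_samples_from_distance(D, labels)
    observed = float(s.mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        null[i] = silhouette_samples_from_distance(D, perm)[2].mean()
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return SilhouetteResult(
        a=a, b=b, s=s, mean_score=observed, null_scores=null, p_value=float(p),
        n_perm=n_perm,
    )


# --------------------------------------------------------------- spike-ins


def tpm(counts: np.ndarray) -> np.ndarray:
    """Transcripts per million along the last axis (sums to 1e6 per sample)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=-1, keepdims=True)
    if (total <= 0).any():
        raise ValueError("zero-total sample in TPM normalization")
    return counts / total * 1e6


def spikein_accuracy(
    table: pd.DataFrame,
    conc_col: str = "known_conc_attomol_ul",
    tpm_col: str = "tpm",
    pseudocount: float = 1.0,
) -> dict:
    """Pearson correlation of log10 input concentration vs log10 measured TPM.

    Zero TPM entries receive ``pseudocount`` before the log; the pseudocount
    is reported alongside r.
    """
    conc = table[conc_col].to_numpy(dtype=float)
    meas = table[tpm_col].to_numpy(dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    if (meas > 0).sum() < 3:
        raise ValueError("need >= 3 species with nonzero TPM")
    x = np.log10(conc)
    y = np.log10(meas + pseudocount)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance in accuracy inputs")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(table), "pseudocount": pseudocount}


@dataclass
class LODResult:
    """Logistic detection fit: LOD50 on the log10 concentration scale."""

    lod50_log10: float
    intercept: float
    slope: float
    lod50_ci: tuple[float, float]
    separated: bool


def spikein_sensitivity(
    table: pd.DataFrame,
    conc_col: str = "known_conc_attomol_ul",
    detected_col: str = "detected",
) -> LODResult:
    """Fit detection probability ~ log10(concentration) and locate LOD50.

    LOD50 = -intercept/slope is where the fitted probability crosses 0.5.
    Complete separation is reported as the midpoint between the highest
    undetected and lowest detected concentration, flagged rather than fitted.
    The CI comes from the delta method on (intercept, slope).
    """
    import statsmodels.api as sm

    conc = np.log10(table[conc_col].to_numpy(dtype=float))
    det = table[detected_col].to_numpy(dtype=float)
    if det.min() == det.max():
        raise ValueError("detection flags do not vary")

    hi_undet = conc[det == 0].max()
    lo_det = conc[det == 1].min()
    if hi_undet < lo_det:  # perfect step: logistic MLE diverges
        boundary = 0.5 * (hi_undet + lo_det)
        return LODResult(
            lod50_log10=float(boundary),
            intercept=np.nan,
            slope=np.inf,
            lod50_ci=(float(hi_undet), float(lo_det)),
            separated=True,
        )

    X = sm.add_constant(conc)
    fit = sm.GLM(det, X, family=sm.families.Binomial()).fit()
    b0, b1 = fit.params
    if abs(b1) < 1e-12:
        raise ValueError("zero detection slope: no LOD defined")
    lod = -b0 / b1
    # Delta method: grad of -b0/b1 wrt (b0, b1)
    grad = np.array([-1.0 / b1, b0 / b1**2])
    var = float(grad @ fit.cov_params() @ grad)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return LODResult(
        lod50_log10=float(lod),
        intercept=float(b0),
        slope=float(b1),
        lod50_ci=(float(lod - half), float(lod + half)),
        separated=False,
    )
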