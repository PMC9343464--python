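"""Consensus drug signatures, pathway projection, and similarity ROC.

A screen condition contains up to two drugs (one per injection role), so the
expression of each gene is modelled across all conditions as
``expression ~ drug_1 + drug_2 + ... + drug_n`` on presence indicators.  The
per-drug coefficient vectors are consensus signatures usable for
cross-dataset comparison.  Pathway activities are weighted gene sums
(footprint-style projection with externally supplied weights); associations
between drugs and pathway activities reuse the same linear model.  Signature
similarity across datasets is Spearman rank correlation, summarized by a ROC
AUC over matched vs unmatched drug pairs with a label-permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class RankDeficientDesignError(ValueError):
    def __init__(self, collinear: list[str]):
        super().__init__(f"design matrix is rank deficient; collinear columns: {collinear}")
        self.collinear = collinear


def make_design(
    obs: pd.DataFrame,
    drug_cols: tuple[str, str] = ("drug_rt", "drug_pcr"),
    control_label: str = "DMSO",
) -> pd.DataFrame:
    """Drug-presence indicator matrix (with intercept) from condition metadata.

    A condition row gets a 1 for each non-control drug it contains;
    control-only conditions are all-zero apart from the intercept.  A drug
    delivered twice in one condition (same drug in both roles) still yields
    an indicator of 1: the model codes presence, not dose.
    """
    drugs = sorted(
        {
            d
            for col in drug_cols
            for d in obs[col].unique()
            if d != control_label
        }
    )
    D = pd.DataFrame(0.0, index=obs.index, columns=["intercept"] + drugs)
    D["intercept"] = 1.0
    for col in drug_cols:
        for d in drugs:
            D.loc[obs[col] == d, d] = 1.0
    return D


def _ols(D: np.ndarray, Y: np.ndarray, names: list[str]):
    """Vectorized OLS of every response column on the design; closed form."""
    n, p = D.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    rank = np.linalg.matrix_rank(D)
    if rank < p:
        # Identify columns whose removal restores full rank.
        collinear = []
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            if np.linalg.matrix_rank(D[:, keep]) == rank:
                collinear.append(names[j])
        raise RankDeficientDesignError(collinear)
    coef, _, _, _ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    XtX_inv = np.linalg.inv(D.T @ D)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    return coef, se, resid


@dataclass
class SignatureMatrix:
    """Per-drug coefficient vectors (genes x drugs) with standard errors."""

    coefficients: pd.DataFrame  # genes x drugs
    standard_errors: pd.DataFrame
    intercept: pd.Series
    n_samples: int

    @property
    def drugs(self) -> list[str]:
        return list(self.coefficients.columns)

    @property
    def genes(self) -> pd.Index:
        return self.coefficients.index

    def to_tsv(self, path) -> None:
        self.coefficients.to_csv(path, sep="\t")


def consensus_signatures(X: pd.DataFrame, design: pd.DataFrame) -> SignatureMatrix:
    """Fit ``expression ~ drugs`` per gene; coefficients are drug signatures.

    ``X`` is samples x genes (normalized expression); ``design`` is the
    indicator matrix from :func:`make_design` (intercept column included).
    Replicates enter as extra rows of the single pooled model.
    """
    D = design.to_numpy(dtype=float)
    Y = X.to_numpy(dtype=float)
    coef, se, _ = _ols(D, Y, list(design.columns))
    cols = list(design.columns)
    drug_cols = [c for c in cols if c != "intercept"]
    idx = [cols.index(c) for c in drug_cols]
    i0 = cols.index("intercept") if "intercept" in cols else None
    return SignatureMatrix(
        coefficients=pd.DataFrame(coef[idx].T, index=X.columns, columns=drug_cols),
        standard_errors=pd.DataFrame(se[idx].T, index=X.columns, columns=drug_cols),
        intercept=pd.Series(coef[i0] if i0 is not None else np.zeros(Y.shape[1]), index=X.columns),
        n_samples=len(X),
    )


def pathway_activity(
    X: pd.DataFrame, weights: pd.DataFrame, zscore: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Project expression onto pathway weight vectors.

    ``weights`` is genes x pathways.  Activity per sample is the weighted
    sum over the genes shared with ``X``, z-scored across samples (so a
    global rescaling of the weights is irrelevant).  Pathways with zero
    matched genes are dropped with a warning.  Returns the samples x
    pathways activity frame and per-pathway gene coverage fractions.
    """
    shared = X.columns.intersection(weights.index)
    if len(shared) == 0:
        raise ValueError("no weighted genes present in the expression matrix")
    W = weights.loc[shared]
    coverage = (W != 0).sum(axis=0) / (weights != 0).sum(axis=0).replace(0, 1)
    nonzero = (W != 0).any(axis=0)
    if not nonzero.all():
        dropped = list(W.columns[~nonzero])
        warnings.warn(f"dropping pathways with no matched genes: {dropped}")
        W = W.loc[:, nonzero]
    act = X[shared].to_numpy() @ W.to_numpy()
    act = pd.DataFrame(act, index=X.index, columns=W.columns)
    if zscore:
        sd = act.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise ValueError("constant pathway activity cannot be z-scored")
        act = (act - act.mean(axis=0)) / sd
    return act, coverage.loc[W.columns]


def drug_pathway_assoc(activities: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway linear-model coefficients for each drug (drugs x pathways)."""
    D = design.to_numpy(dtype=float)
    Y = activities.to_numpy(dtype=float)
    coef, _, _ = _ols(D, Y, list(design.columns))
    cols = list(design.columns)
    drug_cols = [c for c in cols if c != "intercept"]
    idx = [cols.index(c) for c in drug_cols]
    return pd.DataFrame(coef[idx], index=drug_cols, columns=activities.columns)


def signature_similarity(
    sigs_a: SignatureMatrix | pd.DataFrame,
    sigs_b: SignatureMatrix | pd.DataFrame,
    min_shared_genes: int = 10,
) -> pd.DataFrame:
    """Spearman rank correlation between every drug pair across two signature sets.

    Computed on the shared-gene intersection; ties receive average ranks.
    """
    A = sigs_a.coefficients if isinstance(sigs_a, SignatureMatrix) else sigs_a
    B = sigs_b.coefficients if isinstance(sigs_b, SignatureMatrix) else sigs_b
    shared = A.index.intersection(B.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between signature sets")
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared genes (< {min_shared_genes} required)"
        )
    rho, _ = stats.spearmanr(A.loc[shared].to_numpy(), B.loc[shared].to_numpy())
    rho = np.atleast_2d(rho)
    na, nb = A.shape[1], B.shape[1]
    block = np.asarray(rho)[:na, na : na + nb]
    return pd.DataFrame(block, index=A.columns, columns=B.columns)


@dataclass
class SimilarityROC:
    auc: float
    null_aucs: np.ndarray
    p_value: float
    n_true: int
    n_false: int


def roc_matched_drugs(
    similarity: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    true_matches: pd.DataFrame | None = None,
) -> SimilarityROC:
    """ROC AUC of similarity scores for matched vs unmatched drug pairs.

    By default a pair is a true match when the row and column drug labels
    are equal; ``true_matches`` may supply an explicit boolean frame.  The
    null distribution permutes the column drug labels; the empirical p-value
    uses the add-one estimator.
    """
    from sklearn.metrics import roc_auc_score

    scores = similarity.to_numpy(dtype=float)
    if true_matches is None:
        truth = np.equal.outer(
            similarity.index.to_numpy(), similarity.columns.to_numpy()
        )
    else:
        truth = true_matches.loc[similarity.index, similarity.columns].to_numpy(bool)
    n_true = int(truth.sum())
    n_false = int((~truth).sum())
    if n_true < 2 or n_false < 2:
        raise ValueError("need >= 2 matched and >= 2 unmatched pairs")
    auc = float(roc_auc_score(truth.ravel(), scores.ravel()))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(truth.shape[1])
        null[i] = roc_auc_score(truth[:, perm].ravel(), scores.ravel())
    p = (1.0 + np.sum(null >= auc)) / (n_perm + 1.0)
    return SimilarityROC(
        auc=auc, null_aucs=null, p_value=float(p), n_true=n_true, n_false=n_false
    )
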