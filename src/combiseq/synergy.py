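"""Viability prediction from expression, GR dose-response, and Bliss synergy.

Combination effects are referenced to the Bliss independence null: two
non-interacting drugs with monotherapy viabilities vA and vB are expected to
leave vA x vB of cells viable.  Positive synergy scores mean the measured
(or predicted) combination viability falls below that expectation.

Monotherapy anchor doses use the growth-rate inhibition scale: GR(c) is the
normalized growth rate relative to an untreated control, insensitive to the
number of divisions during the assay; GR35 is the concentration producing
35% GR inhibition (GR = 0.65).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


# ----------------------------------------------------------- viability model


@dataclass
class ViabilityModel:
    """Ridge-regularized linear map from expression to relative viability.

    Prediction on a new matrix aligns by gene name; genes absent from the
    input are imputed as 0 (on the z-scored scale this is the training mean)
    and the resulting coverage is reported.
    """

    genes: list[str]
    weights: np.ndarray
    intercept: float
    alpha: float
    cv_correlation: float | None = None
    min_coverage: float = 0.5

    def predict(self, X: pd.DataFrame) -> pd.Series:
        coverage = len(X.columns.intersection(self.genes)) / len(self.genes)
        if coverage < self.min_coverage:
            raise ValueError(
                f"gene coverage {coverage:.2f} below floor {self.min_coverage:.2f}"
            )
        M = X.reindex(columns=self.genes, fill_value=0.0).to_numpy(dtype=float)
        pred = pd.Series(M @ self.weights + self.intercept, index=X.index)
        pred.attrs["coverage"] = coverage
        return pred


def fit_viability_model(
    X: pd.DataFrame,
    viability,
    alpha: float = 1.0,
    cv_folds: int = 5,
    seed: int = 0,
    min_coverage: float = 0.5,
) -> ViabilityModel:
    """Fit viability ~ expression with ridge regularization strength ``alpha``.

    ``alpha = 0`` gives the ordinary least-squares limit.  Cross-validated
    Pearson correlation between held-out predictions and labels is recorded
    as a performance summary.
    """
    from sklearn.linear_model import LinearRegression, Ridge
    from sklearn.model_selection import KFold

    y = np.asarray(viability, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 training samples")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate viability labels")
    if y.min() <= 0 or y.max() > 1.5:
        warnings.warn("viability labels outside the expected (0, 1.5] range")

    def _make():
        return LinearRegression() if alpha == 0 else Ridge(alpha=alpha)

    M = X.to_numpy(dtype=float)
    cv_corr = None
    if cv_folds and cv_folds >= 2 and len(X) >= 2 * cv_folds:
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        preds = np.empty_like(y)
        for tr, te in kf.split(M):
            est = _make().fit(M[tr], y[tr])
            preds[te] = est.predict(M[te])
        if np.std(preds) > 0:
            cv_corr = float(np.corrcoef(preds, y)[0, 1])
    est = _make().fit(M, y)
    return ViabilityModel(
        genes=list(X.columns),
        weights=np.asarray(est.coef_, dtype=float),
        intercept=float(est.intercept_),
        alpha=alpha,
        cv_correlation=cv_corr,
        min_coverage=min_coverage,
    )


def predict_viability(model: ViabilityModel, X: pd.DataFrame) -> pd.Series:
    """Per-sample viability predictions (see :meth:`ViabilityModel.predict`)."""
    return model.predict(X)


def crossfit_viability_predictions(
    X: pd.DataFrame,
    viability,
    groups,
    alpha: float = 1.0,
    n_splits: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Out-of-fold viability predictions with condition-grouped folds.

    Samples sharing a group label (e.g. replicates of one treatment
    condition) are always held out together, so every prediction comes from
    a model that never saw that condition -- the appropriate stand-in for a
    viability model trained on independent data.
    """
    from sklearn.model_selection import GroupKFold

    y = np.asarray(viability, dtype=float)
    groups = np.asarray(groups)
    M = X.to_numpy(dtype=float)
    preds = np.empty(len(X))
    gkf = GroupKFold(n_splits=n_splits)
    for tr, te in gkf.split(M, y, groups):
        model = fit_viability_model(
            X.iloc[tr], y[tr], alpha=alpha, cv_folds=0, seed=seed
        )
        preds[te] = model.predict(X.iloc[te]).to_numpy()
    return pd.Series(preds, index=X.index)


def screen_expression_synergy(
    X: pd.DataFrame,
    viability,
    obs: pd.DataFrame,
    control_label: str = "DMSO",
    alpha: float = 10.0,
    n_splits: int = 5,
    seed: int = 0,
    rule: str = "bliss",
) -> pd.DataFrame:
    """Expression-predicted synergy scores for every drug pair in a screen.

    ``X`` is normalized expression (samples x genes), ``viability`` the
    training labels, and ``obs`` per-sample metadata with ``drug_rt`` and
    ``drug_pcr`` columns where ``control_label`` marks the vehicle.
    Predictions are cross-fitted with condition-grouped folds, averaged over
    replicates per condition, and combined into one score per
    (valve drug, autosampler drug) pair via :func:`expression_synergy`.
    """
    groups = obs["drug_rt"].astype(str) + "|" + obs["drug_pcr"].astype(str)
    preds = crossfit_viability_predictions(
        X, viability, groups, alpha=alpha, n_splits=n_splits, seed=seed
    )
    # Ridge shrinkage compresses held-out predictions toward the training
    # mean, which would bias the multiplicative Bliss comparison; a single
    # global affine recalibration against the labels undoes it without using
    # any per-condition information.
    y = np.asarray(viability, dtype=float)
    slope = np.cov(preds, y)[0, 1] / np.var(preds.to_numpy())
    preds = (preds - preds.mean()) * slope + y.mean()
    mean_pred = (
        pd.DataFrame(
            {"drug_rt": obs["drug_rt"], "drug_pcr": obs["drug_pcr"], "pred": preds}
        )
        .groupby(["drug_rt", "drug_pcr"])["pred"]
        .mean()
    )
    entries = []
    for (d_rt, d_pcr), v_combo in mean_pred.items():
        if d_rt == control_label or d_pcr == control_label:
            continue
        key_a = (d_rt, control_label)
        key_b = (control_label, d_pcr)
        if key_a not in mean_pred.index or key_b not in mean_pred.index:
            continue
        entries.append(
            expression_synergy(
                v_combo, mean_pred[key_a], mean_pred[key_b],
                drug_a=d_rt, drug_b=d_pcr, rule=rule,
            )
        )
    return synergy_table(entries)


# ------------------------------------------------------------ dose response


def gr_value(x: float | np.ndarray, x_ctrl: float, x0: float) -> np.ndarray:
    """Growth-rate inhibition value GR(c) from endpoint cell counts.

    GR = 2^( log2(x/x0) / log2(x_ctrl/x0) ) - 1, where x is the treated
    count, x_ctrl the untreated endpoint and x0 the initial count.  GR = 1
    means no effect, 0 full cytostasis, negative values net cell loss.
    """
    x = np.asarray(x, dtype=float)
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    if x_ctrl <= x0:
        raise ValueError("non-growing control (x_ctrl <= x0)")
    if (x <= 0).any():
        raise ValueError("treated counts must be positive")
    return 2.0 ** (np.log2(x / x0) / np.log2(x_ctrl / x0)) - 1.0


def _four_pl(logc: np.ndarray, lower: float, upper: float, log_ec50: float, hill: float):
    return lower + (upper - lower) / (1.0 + 10.0 ** (hill * (logc - log_ec50)))


@dataclass
class GRCurveFit:
    lower: float
    upper: float
    log10_ec50: float
    hill: float
    residual_norm: float

    def __call__(self, conc) -> np.ndarray:
        return _four_pl(np.log10(np.asarray(conc, dtype=float)), self.lower,
                        self.upper, self.log10_ec50, self.hill)


def fit_gr_curve(conc: np.ndarray, gr: np.ndarray) -> GRCurveFit:
    """4-parameter logistic fit of GR against log10 concentration.

    Nonlinear least squares from three fixed starting points (shallow,
    centered, steep); the best residual wins, making the fit deterministic.
    """
    conc = np.asarray(conc, dtype=float)
    gr = np.asarray(gr, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    order = np.argsort(conc)
    conc, gr = conc[order], gr[order]
    logc = np.log10(conc)

    def resid(p):
        return _four_pl(logc, *p) - gr

    mid = float(np.median(logc))
    starts = [
        (gr.min(), gr.max(), mid, 0.5),
        (gr.min(), gr.max(), mid, 1.0),
        (gr.min(), gr.max(), mid, 2.0),
    ]
    best = None
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("dose-response fit failed from all starts")
    lower, upper, log_ec50, hill = best.x
    return GRCurveFit(float(lower), float(upper), float(log_ec50), float(hill),
                      float(np.sqrt(2 * best.cost)))


def gr35_concentration(
    conc: np.ndarray, gr: np.ndarray, target_gr: float = 0.65
) -> float:
    """Concentration where the fitted GR curve crosses 0.65 (35% inhibition).

    Raises ``ValueError`` with the curve's boundary values if the fitted
    curve never reaches the target within the tested concentration range.
    """
    fit = fit_gr_curve(conc, gr)
    lo, hi = float(np.min(conc)), float(np.max(conc))
    f_lo, f_hi = fit([lo]).item(), fit([hi]).item()
    if (f_lo - target_gr) * (f_hi - target_gr) > 0:
        raise ValueError(
            f"fitted GR curve does not cross {target_gr} within "
            f"[{lo:g}, {hi:g}] (boundary GR {f_lo:.3f}, {f_hi:.3f})"
        )
    # Invert the 4PL analytically on the log10 scale.
    lower, upper, log_ec50, hill = fit.lower, fit.upper, fit.log10_ec50, fit.hill
    frac = (upper - lower) / (target_gr - lower) - 1.0
    if frac <= 0:
        raise ValueError("target outside the fitted asymptotes")
    logc = log_ec50 + np.log10(frac) / hill
    return float(10.0 ** logc)


# ------------------------------------------------------------------- Bliss


def bliss_expected(v_a, v_b):
    """Expected combination viability under Bliss independence: vA x vB.

    Viabilities are fractions of control; negatives are clipped to 0 before
    the product, values above 1 (stimulation) are allowed.
    """
    v_a = np.clip(np.asarray(v_a, dtype=float), 0.0, None)
    v_b = np.clip(np.asarray(v_b, dtype=float), 0.0, None)
    out = v_a * v_b
    return float(out) if out.ndim == 0 else out


@dataclass
class SynergyEntry:
    drug_a: str
    drug_b: str
    expected_viability: float
    observed_viability: float
    score: float  # positive = synergistic
    source: str  # "plate" or "expression"
    n_cells_used: int | None = None
    flags: list[str] = field(default_factory=list)


def plate_synergy(
    grid: pd.DataFrame,
    mono_a: pd.Series,
    mono_b: pd.Series,
    drug_a: str = "A",
    drug_b: str = "B",
) -> SynergyEntry:
    """Bliss synergy score for a checkerboard viability matrix.

    ``grid`` is concA x concB measured combination viabilities (fractions of
    control); ``mono_a``/``mono_b`` map each tested concentration to its
    monotherapy viability.  The score is the mean over the grid of
    (Bliss-expected - measured); missing cells are skipped and flagged.
    """
    diffs = []
    flags: list[str] = []
    exp_sum = obs_sum = 0.0
    for ca in grid.index:
        for cb in grid.columns:
            measured = grid.loc[ca, cb]
            if pd.isna(measured):
                continue
            expected = bliss_expected(mono_a[ca], mono_b[cb])
            diffs.append(expected - float(measured))
            exp_sum += expected
            obs_sum += float(measured)
    if not diffs:
        raise ValueError("no measured cells in the dose grid")
    n_total = grid.size
    if len(diffs) < n_total:
        flags.append(f"missing_cells:{n_total - len(diffs)}")
    n = len(diffs)
    return SynergyEntry(
        drug_a=drug_a,
        drug_b=drug_b,
        expected_viability=exp_sum / n,
        observed_viability=obs_sum / n,
        score=float(np.mean(diffs)),
        source="plate",
        n_cells_used=n,
        flags=flags,
    )


def expression_synergy(
    v_combo: float,
    v_a: float,
    v_b: float,
    drug_a: str = "A",
    drug_b: str = "B",
    rule: str = "bliss",
) -> SynergyEntry:
    """Synergy score from expression-predicted viabilities.

    Default rule compares the combination prediction with the Bliss
    expectation from the two monotherapy predictions:
    score = vA*vB - v_combo.  The alternative highest-single-agent rule
    (``rule='hsa'``) uses min(vA, vB) - v_combo.
    """
    for name, v in (("v_combo", v_combo), ("v_a", v_a), ("v_b", v_b)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing prediction for {name}")
    flags = []
    if max(v_a, v_b, v_combo) > 1.0:
        flags.append("viability_above_1")
    if rule == "bliss":
        expected = bliss_expected(v_a, v_b)
    elif rule == "hsa":
        expected = min(max(v_a, 0.0), max(v_b, 0.0))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return SynergyEntry(
        drug_a=drug_a,
        drug_b=drug_b,
        expected_viability=float(expected),
        observed_viability=float(v_combo),
        score=float(expected - v_combo),
        source="expression",
        flags=flags,
    )


def synergy_table(entries: list[SynergyEntry]) -> pd.DataFrame:
    """Long-form table of synergy entries."""
    return pd.DataFrame(
        {
            "drug_a": [e.drug_a for e in entries],
            "drug_b": [e.drug_b for e in entries],
            "expected_viability": [e.expected_viability for e in entries],
            "observed_viability": [e.observed_viability for e in entries],
            "synergy_score": [e.score for e in entries],
            "source": [e.source for e in entries],
            "flags": [";".join(e.flags) for e in entries],
        }
    )


def synergy_matrix(entries: list[SynergyEntry]) -> pd.DataFrame:
    """Pivot entries into a drugs x drugs score matrix (rows = drug_a)."""
    df = synergy_table(entries)
    return df.pivot(index="drug_a", columns="drug_b", values="synergy_score")
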