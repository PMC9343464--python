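"""End-to-end benchmark scenarios on synthetic data with known truth.

Each function builds its own inputs with the generators in
:mod:`combiseq.simulate`, runs the relevant pipeline stage, and returns the
measured quantities together with the problem size, so the same scenarios
can back both the test suite and reproducibility scripts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import qc, signatures, synergy
from .barcodes import BarcodeSpec, build_codebook, generate_barcodes
from .demux import demux_read_pairs, match_barcode
from .simulate import (
    default_screen_scenario,
    make_transcripts,
    plate_from_long,
    simulate_expression,
    simulate_plate,
    simulate_reads,
    simulate_spikeins,
    simulate_trace,
)


def corruption_oracle_ok(barcodes: list[str]) -> bool:
    """Exhaustively corrupt every barcode at every position by every base.

    True when each single-substitution corruption decodes uniquely back to
    its source barcode at tolerance 1.
    """
    for bc in barcodes:
        for pos in range(len(bc)):
            for base in "ACGT":
                if base == bc[pos]:
                    continue
                hit, reason, _ = match_barcode(
                    bc[:pos] + base + bc[pos + 1 :], barcodes, max_mismatch=1
                )
                if hit != bc or reason != "ok":
                    return False
    return True


def demux_fidelity(
    n_reads: int = 100_000,
    substitution_rate: float = 0.005,
    seed: int = 0,
    n_rt: int = 20,
    n_pcr: int = 21,
) -> dict:
    """Simulate a full screen's read pairs and score condition assignment.

    Reads whose barcode segments each carry at most one substitution (and
    whose linker passes) are the population the distance-3 design protects;
    the benchmark reports their correct-assignment fraction and the number
    of wrong assignments among them, plus the exhaustive corruption oracle
    over the codebook's barcode set.
    """
    spec = BarcodeSpec(seed=seed)
    book = build_codebook(
        [f"valve{i:02d}" for i in range(n_rt)],
        [f"well{i:02d}" for i in range(n_pcr)],
        spec,
    )
    transcripts = make_transcripts(n_genes=50, length=120, seed=seed)
    per_cond = int(round(n_reads / len(book.conditions)))
    reads, truth = simulate_reads(
        book, transcripts, per_cond, substitution_rate=substitution_rate,
        seed=seed + 1,
    )
    result = demux_read_pairs(reads, book)

    tt = truth.table
    protected = (
        (tt["n_sub_bc_pcr"] <= 1)
        & (tt["n_sub_bc_rt"] <= 1)
        & (tt["n_sub_linker"] <= 1)
    ).to_numpy()
    assigned = result.records["condition_id"].to_numpy()
    correct = assigned == tt["condition_id"].to_numpy()
    wrong = np.array([a is not None for a in assigned]) & ~correct
    return {
        "n_reads": len(reads),
        "ok_fraction": result.ok_fraction,
        "protected_fraction_correct": float(correct[protected].mean()),
        "wrong_assignments_protected": int(wrong[protected].sum()),
        "wrong_assignments_total": int(wrong.sum()),
        "corruption_oracle_ok": corruption_oracle_ok(
            book.rt_barcodes + book.pcr_barcodes
        ),
    }


def synergy_recovery(seed: int = 0) -> dict:
    """10 x 10 screen with 5 planted synergistic and 5 antagonistic pairs.

    Runs count simulation, QC normalization, batch centering, cross-fitted
    viability prediction and Bliss scoring, then compares the scores of the
    interacting pairs with the planted excesses.
    """
    from scipy.stats import spearmanr

    scenario = default_screen_scenario(seed=seed)
    adata, truth = simulate_expression(scenario)
    mito = [g for g in adata.var_names if g.startswith("MT-")]
    filtered, _ = qc.filter_counts(adata, qc.QCThresholds(), mito)
    norm = qc.remove_batch(qc.normalize(filtered), "replicate")
    X = pd.DataFrame(
        np.asarray(norm.X), index=norm.obs_names, columns=norm.var_names
    )
    table = synergy.screen_expression_synergy(
        X, norm.obs["true_viability"].to_numpy(), norm.obs, seed=seed
    ).set_index(["drug_a", "drug_b"])
    planted = np.array(list(truth.interactions.values()))
    scores = np.array(
        [table.loc[pair, "synergy_score"] for pair in truth.interactions]
    )
    return {
        "n_pairs": len(planted),
        "sign_matches": int((np.sign(planted) == np.sign(scores)).sum()),
        "spearman": float(spearmanr(planted, scores).statistic),
        "cells_per_condition": scenario.cells_per_condition,
    }


def silhouette_calibration(
    n_replicates: int = 500,
    n_samples: int = 40,
    n_features: int = 10,
    n_clusters: int = 4,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the silhouette permutation test under a null.

    Data are i.i.d. Gaussian and labels are independent of the data, so the
    fraction of replicates with p < alpha estimates the test's size.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    labels = np.repeat(np.arange(n_clusters), n_samples // n_clusters)
    for i in range(n_replicates):
        X = rng.normal(size=(n_samples, n_features))
        res = qc.silhouette_test(
            X, rng.permutation(labels), n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        rejections += res.p_value < alpha
    return {
        "n_replicates": n_replicates,
        "rejection_rate": rejections / n_replicates,
        "nominal_alpha": alpha,
    }


def plate_panel(
    n_drugs_a: int = 4, n_drugs_b: int = 3, grid_size: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Simulate and score every plate of an A x B validation panel."""
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_drugs_a):
        for j in range(n_drugs_b):
            excess = float(rng.uniform(-0.15, 0.15))
            df, _ = simulate_plate(
                f"drugA{i}", f"drugB{j}",
                ec50_a=float(rng.uniform(0.5, 2.0)),
                ec50_b=float(rng.uniform(0.5, 2.0)),
                bliss_excess=excess, grid_size=grid_size,
                noise_sd=0.02, seed=int(rng.integers(2**31)),
            )
            grid, mono_a, mono_b = plate_from_long(df)
            entry = synergy.plate_synergy(grid, mono_a, mono_b,
                                          f"drugA{i}", f"drugB{j}")
            entries.append(
                {"drug_a": entry.drug_a, "drug_b": entry.drug_b,
                 "score": entry.score, "planted_excess": excess}
            )
    return pd.DataFrame(entries)


def signature_recovery(
    n_samples: int = 120, noise_sd: float = 0.5, n_drugs: int = 8,
    n_genes: int = 100, seed: int = 0,
) -> dict:
    """Additive per-drug expression model: OLS signatures vs planted effects."""
    rng = np.random.default_rng(seed)
    drugs = [f"d{i}" for i in range(n_drugs)]
    obs = pd.DataFrame(
        {
            "drug_rt": rng.choice(drugs + ["DMSO"], n_samples),
            "drug_pcr": rng.choice(drugs + ["DMSO"], n_samples),
        }
    )
    design = signatures.make_design(obs)
    planted = rng.normal(size=(len(design.columns) - 1, n_genes))
    X = pd.DataFrame(
        design.to_numpy()[:, 1:] @ planted
        + rng.normal(0, noise_sd, (n_samples, n_genes)),
        columns=[f"g{i}" for i in range(n_genes)],
    )
    sig = signatures.consensus_signatures(X, design)
    corrs = [
        float(np.corrcoef(sig.coefficients[d], planted[i])[0, 1])
        for i, d in enumerate(c for c in design.columns if c != "intercept")
    ]
    return {"n_samples": n_samples, "min_correlation": min(corrs),
            "mean_correlation": float(np.mean(corrs))}


def viability_weight_recovery(
    n_samples: int = 200, n_genes: int = 40, seed: int = 0
) -> dict:
    """Noiseless linear viability data: OLS-limit fit vs planted weights."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n_samples, n_genes)),
        columns=[f"g{i}" for i in range(n_genes)],
    )
    w = rng.normal(size=n_genes) * 0.02
    b = 0.8
    y = X.to_numpy() @ w + b
    model = synergy.fit_viability_model(X, y, alpha=0.0, cv_folds=0)
    rel = float(
        np.linalg.norm(model.weights - w) / np.linalg.norm(w)
    )
    return {"n_samples": n_samples, "relative_error": rel}


def lod_recovery(seed: int = 0) -> dict:
    """Logistic detection with known parameters: is the true LOD in the CI?"""
    rng = np.random.default_rng(seed)
    b0, b1 = -3.0, 2.0
    true_lod = -b0 / b1
    conc = np.repeat(np.logspace(-1, 4, 60), 8)
    p = 1.0 / (1.0 + np.exp(-(b0 + b1 * np.log10(conc))))
    det = (rng.random(len(conc)) < p).astype(int)
    table = pd.DataFrame({"known_conc_attomol_ul": conc, "detected": det})
    res = qc.spikein_sensitivity(table)
    return {
        "n_observations": len(conc),
        "true_lod50_log10": true_lod,
        "fitted_lod50_log10": res.lod50_log10,
        "within_ci": bool(res.lod50_ci[0] <= true_lod <= res.lod50_ci[1]),
    }


def carryover_recovery(kappa: float = 0.015, n_plugs: int = 100, seed: int = 0) -> dict:
    """Planted plug carryover vs the detector's mean negative/positive ratio."""
    from .fluidics import assign_polarity, contamination_ratio, detect_peaks

    trace, _ = simulate_trace(
        n_plugs=n_plugs, carryover=kappa, noise_sd=0.0005, seed=seed
    )
    series = detect_peaks(
        trace["time_s"].to_numpy(), trace["uv"].to_numpy(),
        threshold=kappa * 0.3, min_width_s=0.2, channel="uv",
    )
    series = assign_polarity(series, first="positive")
    _, summary = contamination_ratio(series)
    return {
        "n_plugs": n_plugs,
        "planted_carryover": kappa,
        "recovered_carryover": summary["mean_ratio"],
        "relative_error": abs(summary["mean_ratio"] - kappa) / kappa,
    }


def spikein_benchmark(cells_per_sample: int = 250, seed: int = 0) -> dict:
    """Accuracy r and LOD50 on a simulated 92-species spike-in ladder."""
    table = simulate_spikeins(cells_per_sample=cells_per_sample, seed=seed)
    acc = qc.spikein_accuracy(table)
    lod = qc.spikein_sensitivity(table)
    return {
        "n_species": table["species"].nunique(),
        "accuracy_r": acc["r"],
        "lod50_log10_attomol_ul": lod.lod50_log10,
    }
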