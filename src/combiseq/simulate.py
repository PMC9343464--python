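"""Synthetic data generators with machine-readable ground truth.

Every input the pipeline consumes can be generated here: codebooks come
from :mod:`combiseq.barcodes`; this module adds synthetic transcripts,
barcoded read pairs, condition x gene count matrices with planted per-drug
and interaction effects, spike-in dilution ladders, checkerboard viability
plates, droplet intensity sets, and two-channel plug fluorescence traces.

The expression generator plants a linear viability structure by
construction: a sparse gene weight vector ``w`` maps log-scale expression
shifts to viability, each drug's effect vector is built so that its
monotherapy viability is exactly ``1 - kill_fraction``, and pairwise
interaction terms shift expression along ``w`` so that the combination
viability equals the Bliss product minus the planted excess.  Downstream
estimators can therefore be scored against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .barcodes import CodeBook, LINKER
from .demux import ReadLayout

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ScreenScenario:
    """Study conditions for a simulated combinatorial screen.

    Defaults mirror the droplet screen setup: 250 single-cell droplets per
    condition at an encapsulation density of 0.1 cells per droplet, three
    replicate runs, a 0.5% per-base substitution error rate, and
    negative-binomial counts (dispersion 0.3) over 500 synthetic genes of
    which 10% are flagged mitochondrial.
    """

    n_rt_drugs: int = 10
    n_pcr_drugs: int = 10
    cells_per_condition: int = 250
    reads_per_cell: int = 130
    substitution_rate: float = 0.005
    n_genes: int = 500
    n_replicates: int = 3
    nb_dispersion: float = 0.3
    mito_fraction_genes: float = 0.10
    mito_expression_share: float = 0.08
    drug_effect_sd: float = 0.2
    affected_gene_fraction: float = 0.10
    n_viability_genes: int = 250
    kill_fraction_range: tuple[float, float] = (0.05, 0.30)
    batch_sd: float = 0.10
    droplet_occupancy: float = 0.1
    include_dmso: bool = True
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for r in (self.substitution_rate, self.mito_fraction_genes,
                  self.affected_gene_fraction, self.droplet_occupancy):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("invalid dispersion")

    @property
    def rt_drugs(self) -> list[str]:
        names = [f"RTdrug{i:02d}" for i in range(1, self.n_rt_drugs + (0 if self.include_dmso else 1))]
        return (["DMSO"] + names) if self.include_dmso else names

    @property
    def pcr_drugs(self) -> list[str]:
        names = [f"PCRdrug{i:02d}" for i in range(1, self.n_pcr_drugs + (0 if self.include_dmso else 1))]
        return (["DMSO"] + names) if self.include_dmso else names


def default_screen_scenario(
    n_rt_drugs: int = 10,
    n_pcr_drugs: int = 10,
    n_synergistic: int = 5,
    n_antagonistic: int = 5,
    strength_range: tuple[float, float] = (0.10, 0.30),
    seed: int = 0,
    **kwargs,
) -> ScreenScenario:
    """Scenario with planted synergistic/antagonistic drug pairs.

    Interaction strengths are evenly spaced magnitudes in ``strength_range``
    assigned to distinct (valve drug, autosampler drug) pairs; positive
    values are synergistic (extra kill beyond Bliss), negative antagonistic.
    """
    sc = ScreenScenario(n_rt_drugs=n_rt_drugs, n_pcr_drugs=n_pcr_drugs, seed=seed, **kwargs)
    rng = np.random.default_rng(seed + 101)
    rt = [d for d in sc.rt_drugs if d != "DMSO"]
    pcr = [d for d in sc.pcr_drugs if d != "DMSO"]
    all_pairs = [(a, b) for a in rt for b in pcr]
    n_int = n_synergistic + n_antagonistic
    if n_int > len(all_pairs):
        raise ValueError("more interacting pairs requested than drug pairs exist")
    chosen = [all_pairs[i] for i in rng.choice(len(all_pairs), size=n_int, replace=False)]
    mags = np.linspace(strength_range[0], strength_range[1], max(n_int, 2))[:n_int]
    signs = np.array([1.0] * n_synergistic + [-1.0] * n_antagonistic)
    order = rng.permutation(n_int)
    sc.interactions = {
        pair: float(signs[k] * mags[k]) for pair, k in zip(chosen, order)
    }
    return sc


@dataclass
class ExpressionTruth:
    """Ground truth emitted with a simulated count matrix."""

    conditions: pd.DataFrame  # per sample: drugs, replicate, viability, epsilon...
    drug_effects: pd.DataFrame  # genes x drugs log-scale effect vectors
    viability_weights: pd.Series  # genes; v = 1 + w . delta(log-mean)
    kill_fractions: pd.Series  # per drug
    interactions: dict[tuple[str, str], float]
    baseline_log_mean: pd.Series


def simulate_expression(scenario: ScreenScenario) -> tuple[ad.AnnData, ExpressionTruth]:
    """Simulate a conditions x genes count matrix with known truth.

    Counts are negative binomial with log-mean = baseline + drug effects +
    interaction term + replicate batch offset; a fixed share of reads goes
    to mitochondrial genes and sequencing depth varies mildly per sample.
    Deterministic for a fixed scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    G = scenario.n_genes
    n_mito = int(round(scenario.mito_fraction_genes * G))
    genes = [f"MT-g{i:04d}" for i in range(n_mito)] + [
        f"gene{i:04d}" for i in range(G - n_mito)
    ]
    baseline = rng.normal(1.0, 1.0, size=G)  # log-scale, lognormal abundances
    # Give mitochondrial genes a fixed expression share.
    if n_mito:
        p = np.exp(baseline)
        p /= p.sum()
        scale = scenario.mito_expression_share / p[:n_mito].sum()
        scale_rest = (1 - scenario.mito_expression_share) / p[n_mito:].sum()
        baseline = np.log(np.concatenate([p[:n_mito] * scale, p[n_mito:] * scale_rest]))

    # Viability response direction u (log-scale gene shifts, entries O(1) on
    # the responsive gene set) and its dual weight vector w with w . u = 1,
    # so viability = 1 + w . delta(log-mean) exactly.
    u = np.zeros(G)
    vi_idx = rng.choice(G, size=scenario.n_viability_genes, replace=False)
    u[vi_idx] = rng.normal(0.0, 1.0, size=scenario.n_viability_genes)
    w = u / (u @ u)

    drugs = sorted(set(scenario.rt_drugs) | set(scenario.pcr_drugs))
    kill = {}
    effects = {}
    lo, hi = scenario.kill_fraction_range
    for d in drugs:
        if d == "DMSO":
            kill[d] = 0.0
            effects[d] = np.zeros(G)
            continue
        a = float(rng.uniform(lo, hi))
        kill[d] = a
        n_aff = int(round(scenario.affected_gene_fraction * G))
        delta = np.zeros(G)
        aff = rng.choice(G, size=n_aff, replace=False)
        delta[aff] = rng.normal(0.0, scenario.drug_effect_sd, size=n_aff)
        delta -= (w @ delta) / (w @ w) * w  # keep delta orthogonal to w
        effects[d] = -a * u + delta

    batch_offsets = {
        r: rng.normal(0.0, scenario.batch_sd, size=G)
        for r in range(1, scenario.n_replicates + 1)
    }

    rows = []
    X = []
    depth_base = scenario.cells_per_condition * scenario.reads_per_cell
    r_nb = 1.0 / scenario.nb_dispersion
    for rep in range(1, scenario.n_replicates + 1):
        for d_rt in scenario.rt_drugs:
            for d_pcr in scenario.pcr_drugs:
                eps = scenario.interactions.get((d_rt, d_pcr), 0.0)
                a1, a2 = kill[d_rt], kill[d_pcr]
                t = a1 * a2 - eps  # deviation-from-additivity term
                delta = effects[d_rt] + effects[d_pcr] + t * u
                v_true = float(np.clip(1.0 + w @ delta, 0.05, 1.5))
                log_mean = baseline + delta + batch_offsets[rep]
                p = np.exp(log_mean)
                p /= p.sum()
                depth = depth_base * rng.uniform(0.8, 1.2)
                mean = depth * p
                lam = rng.gamma(shape=r_nb, scale=mean / r_nb)
                counts = rng.poisson(lam)
                X.append(counts)
                rows.append(
                    {
                        "condition_id": f"{d_rt}|{d_pcr}|rep{rep}",
                        "drug_rt": d_rt,
                        "drug_pcr": d_pcr,
                        "replicate": rep,
                        "true_viability": v_true,
                        "bliss_viability": (1 - a1) * (1 - a2),
                        "epsilon": eps,
                        "synergy_class": (
                            "synergistic" if eps > 0
                            else "antagonistic" if eps < 0 else "none"
                        ),
                    }
                )
    obs = pd.DataFrame(rows).set_index("condition_id")
    adata = ad.AnnData(
        X=np.asarray(X, dtype=np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = ExpressionTruth(
        conditions=obs.copy(),
        drug_effects=pd.DataFrame({d: effects[d] for d in drugs}, index=genes),
        viability_weights=pd.Series(w, index=genes),
        kill_fractions=pd.Series(kill),
        interactions=dict(scenario.interactions),
        baseline_log_mean=pd.Series(baseline, index=genes),
    )
    return adata, truth


# ---------------------------------------------------------------- transcripts


def make_transcripts(
    n_genes: int = 500, length: int = 200, seed: int = 0, seed_length: int = 25
) -> dict[str, str]:
    """Random transcript 3' regions with unique terminal ``seed_length``-mers."""
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    seen: set[str] = set()
    i = 0
    while len(out) < n_genes:
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        tail = seq[-seed_length:]
        if tail in seen:
            continue
        seen.add(tail)
        out[f"gene{i:04d}"] = seq
        i += 1
    return out


# --------------------------------------------------------------------- reads


@dataclass
class ReadTruth:
    """Per-read ground truth for scoring the demultiplexer."""

    table: pd.DataFrame  # condition_id, gene, n_sub_bc_pcr, n_sub_linker, n_sub_bc_rt


def simulate_reads(
    codebook: CodeBook,
    transcripts: dict[str, str],
    reads_per_condition: int | dict[str, int],
    expression: pd.DataFrame | None = None,
    substitution_rate: float = 0.005,
    seed: int = 0,
    layout: ReadLayout | None = None,
) -> tuple[list[tuple[str, str, str]], ReadTruth]:
    """Generate paired reads for every condition in a codebook.

    Read 1 is the condition's barcode pair in the standard layout
    (BC-PCR + GCGGC + BC-RT + one dT base); Read 2 is the 3'-terminal
    59 nt of a transcript drawn per gene in proportion to ``expression``
    (uniform if omitted).  I.i.d. substitutions are applied at
    ``substitution_rate`` to both reads; the truth table records the true
    condition, gene, and per-segment substitution counts.
    """
    layout = layout or ReadLayout()
    rng = np.random.default_rng(seed)
    genes = list(transcripts)
    tails = [transcripts[g][-layout.read2_length:] for g in genes]
    if any(len(t) < layout.read2_length for t in tails):
        raise ValueError("transcripts shorter than the Read 2 length")

    conds = list(codebook.conditions.items())
    cond_ids = [c.condition_id for _, c in conds]
    if isinstance(reads_per_condition, int):
        per_cond = {cid: reads_per_condition for cid in cond_ids}
    else:
        per_cond = dict(reads_per_condition)

    # Per-condition gene sampling probabilities.
    probs = {}
    for cid in cond_ids:
        if expression is not None and cid in expression.index:
            v = expression.loc[cid, genes].to_numpy(dtype=float)
            v = np.clip(v, 0, None)
            probs[cid] = v / v.sum() if v.sum() > 0 else np.full(len(genes), 1 / len(genes))
        else:
            probs[cid] = np.full(len(genes), 1.0 / len(genes))

    n_total = sum(per_cond.values())
    L1, L2 = layout.read1_length, layout.read2_length
    r1 = np.empty((n_total, L1), dtype=np.uint8)
    r2 = np.empty((n_total, L2), dtype=np.uint8)
    cond_col = np.empty(n_total, dtype=object)
    gene_col = np.empty(n_total, dtype=object)

    tail_arr = np.frombuffer("".join(tails).encode(), dtype=np.uint8).reshape(
        len(genes), L2
    )
    row = 0
    for (rt_bc, pcr_bc), cond in conds:
        n = per_cond.get(cond.condition_id, 0)
        if n == 0:
            continue
        template = (pcr_bc + layout.linker + rt_bc + "T").encode()
        t1 = np.frombuffer(template, dtype=np.uint8)
        gidx = rng.choice(len(genes), size=n, p=probs[cond.condition_id])
        r1[row : row + n] = t1[None, :]
        r2[row : row + n] = tail_arr[gidx]
        cond_col[row : row + n] = cond.condition_id
        gene_col[row : row + n] = [genes[i] for i in gidx]
        row += n

    def _mutate(arr):
        mask = rng.random(arr.shape) < substitution_rate
        if mask.any():
            # Replace with a uniformly random different base.
            shift = rng.integers(1, 4, size=int(mask.sum()))
            cur = arr[mask]
            cur_idx = np.searchsorted(_BASES, cur)
            arr[mask] = _BASES[(cur_idx + shift) % 4]
        return mask

    m1 = _mutate(r1)
    _mutate(r2)

    b0, b1 = layout.bc_pcr_span
    l0, l1 = layout.linker_span
    q0, q1 = layout.bc_rt_span
    truth = pd.DataFrame(
        {
            "condition_id": cond_col,
            "gene": gene_col,
            "n_sub_bc_pcr": m1[:, b0:b1].sum(axis=1),
            "n_sub_linker": m1[:, l0:l1].sum(axis=1),
            "n_sub_bc_rt": m1[:, q0:q1].sum(axis=1),
        }
    )
    reads = [
        (f"read{i}", r1[i].tobytes().decode(), r2[i].tobytes().decode())
        for i in range(n_total)
    ]
    return reads, ReadTruth(table=truth)


def write_fastq_pair(
    reads: list[tuple[str, str, str]], fastq1: str | Path, fastq2: str | Path
) -> None:
    """Write simulated read pairs as (optionally gzipped) FASTQ files."""
    import gzip

    def _open(path):
        path = Path(path)
        return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")

    with _open(fastq1) as f1, _open(fastq2) as f2:
        for rid, s1, s2 in reads:
            f1.write(f"@{rid}\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{rid}\n{s2}\n+\n{'I' * len(s2)}\n")


# ------------------------------------------------------------------ spike-ins


def simulate_spikeins(
    n_species: int = 92,
    conc_range_log10: tuple[float, float] = (-1.0, 3.0),
    cells_per_sample: int = 250,
    counts_per_cell_per_unit: float = 0.02,
    n_replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson spike-in ladder across a >= 4-decade concentration range.

    Expected counts are proportional to concentration x depth (depth scales
    with the number of cells); a species is detected when its count is >= 1.
    Returns a long table with columns species, known_conc_attomol_ul, count,
    tpm, detected, replicate.
    """
    rng = np.random.default_rng(seed)
    conc = np.logspace(conc_range_log10[0], conc_range_log10[1], n_species)
    rows = []
    for rep in range(1, n_replicates + 1):
        mean = conc * cells_per_sample * counts_per_cell_per_unit
        counts = rng.poisson(mean)
        total = counts.sum()
        if total == 0:
            raise ValueError("no spike-in molecules detected at this depth")
        tpm = counts / total * 1e6
        for i in range(n_species):
            rows.append(
                {
                    "species": f"ERCC-{i:05d}",
                    "known_conc_attomol_ul": conc[i],
                    "count": int(counts[i]),
                    "tpm": float(tpm[i]),
                    "detected": int(counts[i] >= 1),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- plates


def simulate_plate(
    drug_a: str,
    drug_b: str,
    ec50_a: float,
    ec50_b: float,
    bliss_excess: float = 0.0,
    hill: float = 1.5,
    grid_size: int = 4,
    top_conc_a: float | None = None,
    top_conc_b: float | None = None,
    dilution: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Checkerboard viability plate with a planted Bliss excess.

    Monotherapy viabilities follow a Hill curve v(c) = 1/(1+(c/EC50)^hill);
    measured combination viability is vA(cA)*vB(cB) - excess + noise.  The
    grid is a ``grid_size`` x ``grid_size`` checkerboard of ``dilution``-fold
    series from the top concentrations (default: each drug's EC50), plus
    monotherapy rows (the partner at concentration 0).  Returns the long
    table (drugA, drugB, concA, concB, viability) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    top_a = top_conc_a if top_conc_a is not None else ec50_a
    top_b = top_conc_b if top_conc_b is not None else ec50_b
    conc_a = top_a / dilution ** np.arange(grid_size)[::-1]
    conc_b = top_b / dilution ** np.arange(grid_size)[::-1]

    def v(c, ec50):
        return 1.0 / (1.0 + (c / ec50) ** hill)

    rows = []
    for ca in conc_a:  # monotherapy A
        rows.append((drug_a, drug_b, ca, 0.0, v(ca, ec50_a) + rng.normal(0, noise_sd)))
    for cb in conc_b:  # monotherapy B
        rows.append((drug_a, drug_b, 0.0, cb, v(cb, ec50_b) + rng.normal(0, noise_sd)))
    for ca in conc_a:
        for cb in conc_b:
            meas = v(ca, ec50_a) * v(cb, ec50_b) - bliss_excess + rng.normal(0, noise_sd)
            rows.append((drug_a, drug_b, ca, cb, meas))
    df = pd.DataFrame(rows, columns=["drugA", "drugB", "concA", "concB", "viability"])
    truth = {
        "bliss_excess": bliss_excess,
        "ec50_a": ec50_a,
        "ec50_b": ec50_b,
        "hill": hill,
        "grid_size": grid_size,
    }
    return df, truth


def plate_from_long(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Split a long plate table into (combination grid, mono A, mono B)."""
    mono_a = (
        df[(df["concA"] > 0) & (df["concB"] == 0)]
        .set_index("concA")["viability"]
        .groupby(level=0)
        .mean()
    )
    mono_b = (
        df[(df["concB"] > 0) & (df["concA"] == 0)]
        .set_index("concB")["viability"]
        .groupby(level=0)
        .mean()
    )
    combo = df[(df["concA"] > 0) & (df["concB"] > 0)]
    grid = combo.pivot_table(index="concA", columns="concB", values="viability")
    return grid, mono_a, mono_b


# --------------------------------------------------------------------- traces


def simulate_trace(
    n_plugs: int = 40,
    positive_height: float = 1.0,
    carryover: float = 0.015,
    plug_width_s: float = 1.0,
    gap_s: float = 0.5,
    dt_s: float = 0.005,
    noise_sd: float = 0.0,
    height_jitter: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Two-channel plug trace under the alternating-dye loading scheme.

    Odd plugs carry the UV dye, even plugs the green dye, so each channel
    alternates positive/negative; every negative plateau is ``carryover``
    times the previous positive plateau in that channel.  Returns the trace
    (time_s, uv, green) and truth (carryover, plug count, polarity of the
    first plug per channel).
    """
    if not 0.0 <= carryover < 0.5:
        raise ValueError("carryover must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    heights = {"uv": [], "green": []}
    prev_pos = {"uv": positive_height, "green": positive_height}
    for i in range(n_plugs):
        pos_channel = "uv" if i % 2 == 0 else "green"
        neg_channel = "green" if i % 2 == 0 else "uv"
        h = positive_height * (1.0 + rng.normal(0.0, height_jitter))
        heights[pos_channel].append(h)
        heights[neg_channel].append(carryover * prev_pos[neg_channel])
        prev_pos[pos_channel] = h

    n_per_plug = int(round(plug_width_s / dt_s))
    n_gap = int(round(gap_s / dt_s))
    total = n_plugs * (n_per_plug + n_gap) + n_gap
    t = np.arange(total) * dt_s
    uv = np.zeros(total)
    green = np.zeros(total)
    for i in range(n_plugs):
        s = n_gap + i * (n_per_plug + n_gap)
        uv[s : s + n_per_plug] = heights["uv"][i]
        green[s : s + n_per_plug] = heights["green"][i]
    if noise_sd > 0:
        uv += rng.normal(0, noise_sd, size=total)
        green += rng.normal(0, noise_sd, size=total)
    df = pd.DataFrame({"time_s": t, "uv": uv, "green": green})
    truth = {
        "carryover": carryover,
        "n_plugs": n_plugs,
        "first_polarity": {"uv": "positive", "green": "negative"},
    }
    return df, truth


def simulate_droplets(
    n_combinations: int = 180,
    droplets_per_combination: int = 100,
    center: float = 1000.0,
    relative_spread: float = 0.03,
    intra_cv: float = 0.05,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Droplet intensity sets whose per-combination medians have a known CV.

    Per-combination medians are normal with relative spread
    ``relative_spread`` around ``center``; droplets scatter around their
    combination median with CV ``intra_cv``.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_combinations):
        m = center * (1.0 + rng.normal(0.0, relative_spread))
        out[f"combo{i:03d}"] = rng.normal(m, intra_cv * m, size=droplets_per_combination)
    return out
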