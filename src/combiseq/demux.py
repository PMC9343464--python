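"""Demultiplexing of barcode reads into treatment conditions.

Read 1 (26 nt) carries the ligated barcode pair: 10 nt BC-PCR barcode,
the 5 nt GCGGC ligation linker, 10 nt BC-RT barcode, and one base of the
poly-dT tract.  Read 2 (59 nt) carries the cDNA.  Conditions -- not cells --
are the unit of demultiplexing: every read pair is assigned to the treatment
condition its barcode pair encodes, and Read 2 is quantified against a
transcript reference to yield a conditions x genes count matrix.

Counts are read counts; this chemistry has no UMIs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .barcodes import CodeBook, hamming

# Assignment outcomes, in reporting order.
REASONS = ("ok", "bc1_nomatch", "bc2_nomatch", "ambiguous", "linker_fail")


@dataclass(frozen=True)
class ReadLayout:
    """Coordinate layout of Read 1 (0-based, half-open spans).

    ``offset`` shifts the whole layout right if any bases precede the BC-PCR
    barcode (the default assumes the custom sequencing primer anneals flush
    with the barcode).
    """

    barcode_length: int = 10
    linker: str = "GCGGC"
    offset: int = 0
    read1_length: int = 26
    read2_length: int = 59

    @property
    def bc_pcr_span(self) -> tuple[int, int]:
        return (self.offset, self.offset + self.barcode_length)

    @property
    def linker_span(self) -> tuple[int, int]:
        s = self.offset + self.barcode_length
        return (s, s + len(self.linker))

    @property
    def bc_rt_span(self) -> tuple[int, int]:
        s = self.offset + self.barcode_length + len(self.linker)
        return (s, s + self.barcode_length)

    @property
    def min_length(self) -> int:
        return self.bc_rt_span[1]


@dataclass(frozen=True)
class ParsedRead1:
    bc_pcr: str
    linker: str
    bc_rt: str
    tail: str
    linker_mismatches: int
    linker_ok: bool


def parse_read1(
    seq: str, layout: ReadLayout | None = None, max_linker_mismatch: int = 1
) -> ParsedRead1:
    """Split a Read 1 sequence into its four segments.

    Raises ``ValueError`` for reads shorter than the layout requires; a
    divergent linker is reported via ``linker_ok`` rather than an exception.
    """
    layout = layout or ReadLayout()
    if len(seq) < layout.min_length:
        raise ValueError(
            f"read too short: {len(seq)} < {layout.min_length} required by layout"
        )
    seq = seq.upper()
    b0, b1 = layout.bc_pcr_span
    l0, l1 = layout.linker_span
    r0, r1 = layout.bc_rt_span
    linker = seq[l0:l1]
    mm = hamming(linker, layout.linker)
    return ParsedRead1(
        bc_pcr=seq[b0:b1],
        linker=linker,
        bc_rt=seq[r0:r1],
        tail=seq[r1:],
        linker_mismatches=mm,
        linker_ok=mm <= max_linker_mismatch,
    )


def match_barcode(
    observed: str, role_set: Sequence[str], max_mismatch: int = 1
) -> tuple[str | None, str, int]:
    """Match an observed barcode against a role's set within a mismatch budget.

    Returns ``(barcode, reason, mismatches)`` where reason is 'ok',
    'nomatch', or 'ambiguous' (two set members tie at the minimal distance
    within budget).
    """
    if len(set(role_set)) != len(role_set):
        raise ValueError("role_set barcodes must be unique")
    if any(len(b) != len(observed) for b in role_set):
        raise ValueError("observed length does not match role_set barcode length")
    dists = [hamming(observed.upper(), b) for b in role_set]
    dmin = min(dists)
    if dmin > max_mismatch:
        return None, "nomatch", dmin
    hits = [b for b, d in zip(role_set, dists) if d == dmin]
    if len(hits) > 1:
        return None, "ambiguous", dmin
    return hits[0], "ok", dmin


class _VectorMatcher:
    """Vectorized nearest-barcode matcher over a fixed barcode set."""

    def __init__(self, barcodes: Sequence[str]):
        self.barcodes = list(barcodes)
        self._arr = np.frombuffer(
            "".join(barcodes).encode(), dtype=np.uint8
        ).reshape(len(barcodes), -1)

    def match(self, observed: np.ndarray, max_mismatch: int) -> tuple[np.ndarray, np.ndarray]:
        """observed: (n_reads, length) uint8 array.

        Returns (index array with -1 for nomatch / -2 for ambiguous,
        min-mismatch array).
        """
        # (n_reads, n_bc) mismatch counts
        mm = (observed[:, None, :] != self._arr[None, :, :]).sum(axis=2)
        dmin = mm.min(axis=1)
        idx = mm.argmin(axis=1)
        n_at_min = (mm == dmin[:, None]).sum(axis=1)
        out = np.where(dmin <= max_mismatch, idx, -1)
        out = np.where((dmin <= max_mismatch) & (n_at_min > 1), -2, out)
        return out.astype(np.int64), dmin.astype(np.int64)


@dataclass
class DemuxResult:
    """Per-read assignments, per-condition read bins, and a summary table."""

    records: pd.DataFrame  # read_id, condition_id, reason, mm_bc_pcr, mm_bc_rt
    bins: dict[str, list[str]]  # condition_id -> list of Read 2 sequences
    summary: pd.DataFrame  # reason, n_reads, fraction

    @property
    def n_reads(self) -> int:
        return len(self.records)

    @property
    def ok_fraction(self) -> float:
        return float((self.records["reason"] == "ok").mean())


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from a FASTQ file, validating record shape."""
    with _open_maybe_gzip(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(qual) != len(seq):
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            yield header[1:].split()[0], seq
            idx += 1


def demux_read_pairs(
    read_pairs: Iterable[tuple[str, str, str]],
    codebook: CodeBook,
    layout: ReadLayout | None = None,
    max_mismatch: int = 1,
    max_linker_mismatch: int = 1,
) -> DemuxResult:
    """Assign read pairs ``(read_id, read1, read2)`` to conditions.

    Every read is classified exactly once with a single reason; quality
    strings play no role in matching.  Matching is exact-or-one-substitution
    by default (indels are demux failures), which the distance-3 barcode
    design makes unambiguous.
    """
    layout = layout or ReadLayout()
    ids: list[str] = []
    read2s: list[str] = []
    r1_list: list[str] = []
    for rid, r1, r2 in read_pairs:
        if len(r1) < layout.min_length:
            raise ValueError(f"read {rid!r} shorter than layout minimum")
        ids.append(rid)
        r1_list.append(r1.upper()[: layout.min_length])
        read2s.append(r2)

    n = len(ids)
    rt_set = codebook.rt_barcodes
    pcr_set = codebook.pcr_barcodes
    reasons = np.full(n, "ok", dtype=object)
    cond_ids = np.full(n, None, dtype=object)
    mm_pcr = np.zeros(n, dtype=int)
    mm_rt = np.zeros(n, dtype=int)

    if n:
        arr = np.frombuffer("".join(r1_list).encode(), dtype=np.uint8).reshape(
            n, layout.min_length
        )
        b0, b1 = layout.bc_pcr_span
        l0, l1 = layout.linker_span
        r0, r1_ = layout.bc_rt_span
        linker_ref = np.frombuffer(layout.linker.encode(), dtype=np.uint8)
        linker_mm = (arr[:, l0:l1] != linker_ref[None, :]).sum(axis=1)

        pcr_idx, mm_pcr = _VectorMatcher(pcr_set).match(arr[:, b0:b1], max_mismatch)
        rt_idx, mm_rt = _VectorMatcher(rt_set).match(arr[:, r0:r1_], max_mismatch)

        # Classification priority: linker integrity first, then the two
        # barcodes in read order (BC-PCR then BC-RT), then ambiguity.
        reasons[linker_mm > max_linker_mismatch] = "linker_fail"
        m = reasons == "ok"
        reasons[m & (pcr_idx == -1)] = "bc1_nomatch"
        m = reasons == "ok"
        reasons[m & (rt_idx == -1)] = "bc2_nomatch"
        m = reasons == "ok"
        reasons[m & ((pcr_idx == -2) | (rt_idx == -2))] = "ambiguous"
        m = reasons == "ok"
        for i in np.flatnonzero(m):
            cond = codebook.decode(rt_set[rt_idx[i]], pcr_set[pcr_idx[i]])
            cond_ids[i] = cond.condition_id  # cross-product codebook: always present

    records = pd.DataFrame(
        {
            "read_id": ids,
            "condition_id": cond_ids,
            "reason": reasons,
            "mm_bc_pcr": mm_pcr,
            "mm_bc_rt": mm_rt,
        }
    )
    bins: dict[str, list[str]] = {c.condition_id: [] for c in codebook.conditions.values()}
    ok_mask = records["reason"].to_numpy() == "ok"
    for i in np.flatnonzero(ok_mask):
        bins[cond_ids[i]].append(read2s[i])

    counts = records["reason"].value_counts()
    summary = pd.DataFrame(
        {
            "reason": REASONS,
            "n_reads": [int(counts.get(r, 0)) for r in REASONS],
        }
    )
    summary["fraction"] = summary["n_reads"] / max(n, 1)
    return DemuxResult(records=records, bins=bins, summary=summary)


def demux_fastq(
    fastq1: str | Path,
    fastq2: str | Path,
    codebook: CodeBook,
    layout: ReadLayout | None = None,
    **kwargs,
) -> DemuxResult:
    """Demultiplex a paired FASTQ file pair (plain or gzip)."""
    pairs = (
        (id1, s1, s2)
        for (id1, s1), (_, s2) in zip(iter_fastq(fastq1), iter_fastq(fastq2))
    )
    return demux_read_pairs(pairs, codebook, layout=layout, **kwargs)


# --------------------------------------------------------------- gene counts


class TranscriptReference:
    """Toy 3'-end reference: each gene matched by its terminal ``seed_length``-mer.

    Stands in for alignment when reads are generated from synthetic
    transcripts; duplicate seeds are rejected at load since they would make
    assignment ambiguous.
    """

    def __init__(self, transcripts: dict[str, str], seed_length: int = 25):
        self.seed_length = seed_length
        self.transcripts = dict(transcripts)
        self.genes = list(self.transcripts)
        seeds = {}
        for gene, seq in self.transcripts.items():
            seed = seq[-seed_length:].upper()
            if len(seed) < seed_length:
                raise ValueError(f"transcript {gene!r} shorter than seed length")
            if seed in seeds:
                raise ValueError(
                    f"ambiguous reference: genes {seeds[seed]!r} and {gene!r} "
                    "share a 3'-end seed"
                )
            seeds[seed] = gene
        self._seed_to_gene = seeds

    def assign(self, read2: str) -> str | None:
        """Assign a Read 2 by exact match of its 3'-terminal seed."""
        return self._seed_to_gene.get(read2[-self.seed_length :].upper())


def quantify_genes(
    result: DemuxResult,
    reference: TranscriptReference,
    codebook: CodeBook,
    replicate: str | int | None = None,
) -> ad.AnnData:
    """Count gene assignments per condition into a conditions x genes matrix.

    Returns an :class:`anndata.AnnData` with per-condition metadata
    (``drug_rt``, ``drug_pcr``, ``replicate``, ``n_reads_assigned``,
    ``n_reads_unmatched``).  Empty conditions keep all-zero rows.
    """
    cond_meta = {c.condition_id: c for c in codebook.conditions.values()}
    cond_ids = list(result.bins)
    genes = reference.genes
    gene_index = {g: j for j, g in enumerate(genes)}
    X = np.zeros((len(cond_ids), len(genes)), dtype=np.int64)
    unmatched = np.zeros(len(cond_ids), dtype=np.int64)
    for i, cid in enumerate(cond_ids):
        for read2 in result.bins[cid]:
            gene = reference.assign(read2)
            if gene is None:
                unmatched[i] += 1
            else:
                X[i, gene_index[gene]] += 1
    obs = pd.DataFrame(
        {
            "drug_rt": [cond_meta[c].drug_rt for c in cond_ids],
            "drug_pcr": [cond_meta[c].drug_pcr for c in cond_ids],
            "replicate": [replicate] * len(cond_ids),
            "n_reads_assigned": [len(result.bins[c]) for c in cond_ids],
            "n_reads_unmatched": unmatched,
        },
        index=pd.Index(cond_ids, name="condition_id"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["counting"] = {"unit": "reads", "umis": False}
    return adata


def write_count_matrix(adata: ad.AnnData, prefix: str | Path) -> None:
    """Write a count matrix as TSV plus matrix-market triplets with sidecars."""
    import scipy.io
    import scipy.sparse

    prefix = Path(prefix)
    df = pd.DataFrame(adata.X, index=adata.obs_names, columns=adata.var_names)
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t")
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), scipy.sparse.csr_matrix(adata.X))
    pd.Series(adata.obs_names).to_csv(
        prefix.parent / (prefix.name + ".rows.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        prefix.parent / (prefix.name + ".cols.tsv"), sep="\t", index=False, header=False
    )
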