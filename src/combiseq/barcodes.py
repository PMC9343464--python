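"""Deterministic combinatorial barcode design.

Drug pairs are encoded by ligating two barcode fragments inside a droplet:
a barcoded poly-dT primer (BC-RT, delivered with the valve-module drug) and
a barcoded PCR primer with a common amplification handle (BC-PCR, delivered
with the autosampler drug).  The ordered pair of 10-nt barcodes read out in
a single 26-bp sequencing read identifies the treatment condition.

This module designs balanced barcode sets with a guaranteed minimum pairwise
Hamming distance, assembles the full oligonucleotide sequences for both
fragment roles, builds the codebook mapping barcode pairs to conditions, and
exports the valve-controller schedule used to produce plug trains.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgtNVn", "TGCAtgcaNBn")

#: Common PCR handle on the BC-PCR fragment (template-switch primer site).
PCR_COMMON_PRIMER = "AAGCAGTGGTATCAACGCAGAGTAC"
#: Poly-T spacer between the 5' biotin and the common primer.
PCR_SPACER = "TTTTTTT"
#: Single-stranded ligation site joining BC-PCR to BC-RT.
LINKER = "GCGGC"
#: Poly-dT capture tract on the BC-RT fragment, anchored by V (A/C/G) + N.
RT_DT_TRACT = "T" * 20
RT_ANCHOR = "VN"


class BarcodeDesignError(RuntimeError):
    """Raised when barcode constraints cannot be satisfied within budget."""

    def __init__(self, message: str, attempts: int | None = None):
        super().__init__(message)
        self.attempts = attempts


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC V/N handled)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_hamming(barcodes: Sequence[str]) -> int:
    """Smallest pairwise Hamming distance in a set (inf-like for < 2 items)."""
    if len(barcodes) < 2:
        return len(barcodes[0]) if barcodes else 0
    return min(hamming(a, b) for a, b in itertools.combinations(barcodes, 2))


def _max_homopolymer_run(seq: str) -> int:
    return max(len(list(g)) for _, g in itertools.groupby(seq))


@dataclass(frozen=True)
class BarcodeSpec:
    """Constraints for a balanced barcode set.

    ``per_base_count_min/max`` bound how often each nucleotide occurs in a
    single barcode; 2-3 occurrences in a 10-mer is the closest achievable
    approximation to a uniform base composition at that length.
    """

    length: int = 10
    min_pairwise_hamming: int = 3
    per_base_count_min: int = 2
    per_base_count_max: int = 3
    max_homopolymer: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.length < self.min_pairwise_hamming:
            raise ValueError("length must be >= min_pairwise_hamming")
        if not (4 * self.per_base_count_min <= self.length <= 4 * self.per_base_count_max):
            raise ValueError(
                "per-base composition bounds unsatisfiable: need "
                f"4*{self.per_base_count_min} <= {self.length} <= 4*{self.per_base_count_max}"
            )

    def composition_ok(self, barcode: str) -> bool:
        return all(
            self.per_base_count_min <= barcode.count(b) <= self.per_base_count_max
            for b in ALPHABET
        )


def generate_barcodes(
    spec: BarcodeSpec,
    n: int,
    attempt_budget: int = 10**6,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Generate ``n`` barcodes satisfying composition, homopolymer and
    pairwise-distance constraints by seeded rejection sampling.

    Deterministic for a fixed ``spec.seed``.  Raises
    :class:`BarcodeDesignError` (with the attempt count) if the constraints
    cannot be met within ``attempt_budget`` candidate draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    # Candidate draws are shuffles of an admissible base multiset, so the
    # composition constraint holds by construction.
    compositions = [
        c
        for c in itertools.product(
            range(spec.per_base_count_min, spec.per_base_count_max + 1), repeat=4
        )
        if sum(c) == spec.length
    ]
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < n:
        if attempts >= attempt_budget:
            raise BarcodeDesignError(
                f"could not find {n} barcodes after {attempts} attempts "
                f"({len(accepted)} found)",
                attempts=attempts,
            )
        attempts += 1
        comp = compositions[rng.integers(len(compositions))]
        letters = [b for b, k in zip(ALPHABET, comp) for _ in range(k)]
        perm = rng.permutation(len(letters))
        candidate = "".join(letters[i] for i in perm)
        if _max_homopolymer_run(candidate) > spec.max_homopolymer:
            continue
        if any(hamming(candidate, a) < spec.min_pairwise_hamming for a in accepted):
            continue
        accepted.append(candidate)
    return accepted


@dataclass(frozen=True)
class BarcodeFragment:
    """One annealed barcode fragment (top and bottom strands).

    ``top_modification`` carries the 5' chemical modification of the top
    strand ("biotin" for BC-PCR, "phos" for BC-RT); ``bottom_modification``
    likewise for the bottom strand.
    """

    role: str  # "RT" or "PCR"
    barcode: str
    top_oligo: str
    bottom_oligo: str
    top_modification: str
    bottom_modification: str

    @property
    def annotated_top(self) -> str:
        return f"/5{self.top_modification}/{self.top_oligo}"


def assemble_oligos(barcode: str, role: str) -> BarcodeFragment:
    """Build the full top/bottom oligo pair for a barcode in a given role.

    BC-PCR top strand: 5'-biotin - poly-T spacer - common primer - barcode -
    GCGGC linker.  Its bottom strand is the reverse complement of everything
    upstream of the linker (the linker stays single-stranded for ligation)
    and carries a 5' phosphate.

    BC-RT top strand: 5'-phosphate - barcode - dT(20) - VN.  Its bottom
    strand reverse-complements the barcode and appends the GCCGC overhang
    complementary to the BC-PCR linker.
    """
    barcode = barcode.upper()
    if set(barcode) - set(ALPHABET):
        raise ValueError(f"invalid characters in barcode: {barcode!r}")
    role = role.upper()
    if role == "PCR":
        top = PCR_SPACER + PCR_COMMON_PRIMER + barcode + LINKER
        bottom = reverse_complement(PCR_SPACER + PCR_COMMON_PRIMER + barcode)
        return BarcodeFragment(role, barcode, top, bottom, "biotin", "phos")
    if role == "RT":
        top = barcode + RT_DT_TRACT + RT_ANCHOR
        bottom = reverse_complement(barcode) + reverse_complement(LINKER)
        return BarcodeFragment(role, barcode, top, bottom, "phos", "none")
    raise ValueError(f"unknown role {role!r}; expected 'RT' or 'PCR'")


def extract_barcode(top_oligo: str, role: str) -> str:
    """Recover the barcode from an assembled top-strand sequence."""
    role = role.upper()
    seq = top_oligo.upper()
    if role == "PCR":
        prefix = PCR_SPACER + PCR_COMMON_PRIMER
        if not (seq.startswith(prefix) and seq.endswith(LINKER)):
            raise ValueError("sequence does not match the BC-PCR architecture")
        return seq[len(prefix) : -len(LINKER)]
    if role == "RT":
        suffix = RT_DT_TRACT + RT_ANCHOR
        if not seq.endswith(suffix):
            raise ValueError("sequence does not match the BC-RT architecture")
        return seq[: -len(suffix)]
    raise ValueError(f"unknown role {role!r}")


@dataclass(frozen=True)
class Condition:
    """One treatment condition: an ordered (valve drug, autosampler drug) pair."""

    condition_id: str
    drug_rt: str
    drug_pcr: str
    conc_rt: float | None = None
    conc_pcr: float | None = None

    @property
    def unordered_pair(self) -> frozenset:
        return frozenset((self.drug_rt, self.drug_pcr))


@dataclass
class CodeBook:
    """Deterministic mapping from (BC-RT, BC-PCR) barcode pairs to conditions.

    The condition space is the full cross-product of the two drug lists, so
    ``len(conditions) == len(rt_entries) * len(pcr_entries)``.
    """

    rt_entries: list[tuple[str, str, float | None]]  # (barcode, drug, conc)
    pcr_entries: list[tuple[str, str, float | None]]
    conditions: dict[tuple[str, str], Condition] = field(default_factory=dict)

    def __post_init__(self):
        for entries, role in ((self.rt_entries, "RT"), (self.pcr_entries, "PCR")):
            bcs = [b for b, _, _ in entries]
            if len(set(bcs)) != len(bcs):
                raise ValueError(f"duplicate barcodes in {role} role")
        if not self.conditions:
            for rt_bc, rt_drug, rt_conc in self.rt_entries:
                for pcr_bc, pcr_drug, pcr_conc in self.pcr_entries:
                    cid = f"{rt_drug}|{pcr_drug}"
                    self.conditions[(rt_bc, pcr_bc)] = Condition(
                        cid, rt_drug, pcr_drug, rt_conc, pcr_conc
                    )
        ids = [c.condition_id for c in self.conditions.values()]
        if len(set(ids)) != len(ids):
            raise ValueError("condition ids are not unique")

    @property
    def rt_barcodes(self) -> list[str]:
        return [b for b, _, _ in self.rt_entries]

    @property
    def pcr_barcodes(self) -> list[str]:
        return [b for b, _, _ in self.pcr_entries]

    def decode(self, rt_barcode: str, pcr_barcode: str) -> Condition | None:
        return self.conditions.get((rt_barcode, pcr_barcode))

    def pair_counts(self, collapse_self_pairs: bool = True) -> dict[str, int]:
        """Number of ordered conditions and of distinct unordered drug pairs.

        For a 4 x 4 same-drug design this is 16 ordered / 10 unordered
        (C(4,2) + 4 self-pairs when the diagonal is collapsed).
        """
        ordered = len(self.conditions)
        unordered = len({c.unordered_pair for c in self.conditions.values()})
        return {"ordered": ordered, "unordered": unordered}

    def swapped_roles(self) -> "CodeBook":
        """Codebook with RT and PCR roles exchanged (barcode-swap control)."""
        return CodeBook(rt_entries=list(self.pcr_entries), pcr_entries=list(self.rt_entries))

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["role", "barcode", "drug", "concentration", "condition_id"])
            for bc, drug, conc in self.rt_entries:
                w.writerow(["RT", bc, drug, "" if conc is None else conc, ""])
            for bc, drug, conc in self.pcr_entries:
                w.writerow(["PCR", bc, drug, "" if conc is None else conc, ""])
            for (rt_bc, pcr_bc), cond in self.conditions.items():
                w.writerow(["PAIR", f"{rt_bc},{pcr_bc}", "", "", cond.condition_id])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodeBook":
        rt, pcr = [], []
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                conc = float(row["concentration"]) if row["concentration"] else None
                if row["role"] == "RT":
                    rt.append((row["barcode"], row["drug"], conc))
                elif row["role"] == "PCR":
                    pcr.append((row["barcode"], row["drug"], conc))
        return cls(rt_entries=rt, pcr_entries=pcr)

    def oligos_to_fasta(self, path: str | Path) -> None:
        """Write all fragment strands as FASTA; modifications go in headers."""
        with open(path, "w") as fh:
            for entries, role in ((self.rt_entries, "RT"), (self.pcr_entries, "PCR")):
                for bc, drug, _ in entries:
                    frag = assemble_oligos(bc, role)
                    fh.write(
                        f">BC-{role}_{drug}_top mod=5'{frag.top_modification}\n"
                        f"{frag.top_oligo}\n"
                        f">BC-{role}_{drug}_bottom mod=5'{frag.bottom_modification}\n"
                        f"{frag.bottom_oligo}\n"
                    )


def build_codebook(
    rt_drugs: Sequence[str | tuple[str, float]],
    pcr_drugs: Sequence[str | tuple[str, float]],
    spec: BarcodeSpec | None = None,
) -> CodeBook:
    """Design barcodes for both roles and map every barcode pair to a condition.

    Barcodes for the two roles are drawn from a single generation run, so the
    minimum pairwise distance holds across roles as well as within each role.
    """
    spec = spec or BarcodeSpec()

    def _norm(drugs) -> list[tuple[str, float | None]]:
        out = []
        for d in drugs:
            if isinstance(d, tuple):
                out.append((str(d[0]), float(d[1])))
            else:
                out.append((str(d), None))
        return out

    rt = _norm(rt_drugs)
    pcr = _norm(pcr_drugs)
    if not rt or not pcr:
        raise ValueError("drug lists must be non-empty")
    for labels, role in (([d for d, _ in rt], "RT"), ([d for d, _ in pcr], "PCR")):
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate drug labels in {role} role")

    barcodes = generate_barcodes(spec, len(rt) + len(pcr))
    rt_entries = [(bc, d, c) for bc, (d, c) in zip(barcodes[: len(rt)], rt)]
    pcr_entries = [(bc, d, c) for bc, (d, c) in zip(barcodes[len(rt) :], pcr)]
    return CodeBook(rt_entries=rt_entries, pcr_entries=pcr_entries)


def platform_capacity(n_plates: int, wells_per_plate: int, n_valves: int) -> int:
    """Theoretical number of combinations: plates x wells x valve channels."""
    if min(n_plates, wells_per_plate, n_valves) < 1:
        raise ValueError("all counts must be >= 1")
    return n_plates * wells_per_plate * n_valves


@dataclass(frozen=True)
class ScheduleRow:
    valves_to_open: str
    opening_time_s: float
    outcome: str


@dataclass
class ValveSchedule:
    """Valve-controller opening sequence producing plug trains.

    Each cycle opens every compound valve for 7 s (one plug), with a 2 s oil
    spacer after each plug except the last, which is followed by a 120 s
    plug-injection step that pushes the finished train into the drop-maker.
    """

    rows: list[ScheduleRow]
    n_cycles: int
    n_valves: int

    @property
    def n_compound_plugs(self) -> int:
        return sum(1 for r in self.rows if r.outcome == "Compound Plug")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["valves_to_open", "opening_time_s", "outcome"])
            for r in self.rows:
                w.writerow([r.valves_to_open, r.opening_time_s, r.outcome])


def _valve_label(i: int) -> str:
    # A..Z then AA.. for >26 valves
    label = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def emit_valve_schedule(
    n_cycles: int,
    n_valves: int = 20,
    plug_time_s: float = 7.0,
    spacer_time_s: float = 2.0,
    injection_time_s: float = 120.0,
) -> ValveSchedule:
    """Build the opening schedule for ``n_cycles`` plug trains.

    One cycle per autosampler drug; e.g. 21 cycles combine a 20-plug valve
    train with each of 21 wells.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rows: list[ScheduleRow] = []
    for _ in range(n_cycles):
        for v in range(n_valves):
            rows.append(ScheduleRow(_valve_label(v), plug_time_s, "Compound Plug"))
            if v < n_valves - 1:
                rows.append(ScheduleRow("2x oil", spacer_time_s, "Oil Spacer"))
        rows.append(ScheduleRow("2x oil", injection_time_s, "Plug injection"))
    return ValveSchedule(rows=rows, n_cycles=n_cycles, n_valves=n_valves)
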