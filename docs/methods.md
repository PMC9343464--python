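# Methods

This note records the models, conventions and numerical choices behind
`combiseq`, and what the synthetic-data experiments do and do not show.

## Barcode design and the codebook

Treatment conditions are encoded by ordered pairs of 10-nt barcodes, one on
the poly-dT reverse-transcription fragment (BC-RT) and one on the PCR-handle
fragment (BC-PCR). Barcodes are drawn by seeded rejection sampling from the
set of 10-mers in which every base occurs 2–3 times ("balanced" — the
closest approximation to uniform composition at length 10), with
homopolymer runs capped at 3 (to avoid confusion with the dT tract and for
synthesis/sequencing robustness), and accepted only if they keep the
pairwise Hamming distance of the growing set at ≥ 3. Distance 3 is the
smallest distance at which every single-substitution corruption decodes
uniquely at a one-mismatch tolerance; the package verifies this property by
exhaustive corruption rather than assuming it. Both roles are drawn from
one generation run, so the distance guarantee also holds across roles. The
sampler's attempt budget (default 10⁶) turns unsatisfiable requests into an
explicit error carrying the attempt count.

Assembled oligos follow the fragment architecture of the assay: the BC-PCR
top strand is 5′-biotin – TTTTTTT – AAGCAGTGGTATCAACGCAGAGTAC – barcode –
GCGGC, with a 5′-phosphorylated bottom strand reverse-complementing
everything upstream of the linker (the GCGGC overhang stays single-stranded
for ligation); the BC-RT top strand is 5′-phosphate – barcode – dT(20) – VN
with a bottom strand carrying the complementary GCCGC overhang. The
codebook is the full cross-product of the two drug lists; with 20 valve
drugs and 21 autosampler drugs it has 420 conditions, and the theoretical
platform ceiling is plates × wells × valves (3 × 384 × 20 = 23,040).

`CodeBook.pair_counts()` reports ordered and unordered pair counts computed
from first principles: a 4 × 4 same-drug design has 16 ordered conditions
and 10 unordered pairs (C(4,2) + 4 self-pairs). Published descriptions of
such designs sometimes transpose the two numbers; the package keeps the
combinatorially correct labelling.

The valve schedule follows the controller's cycle structure: per cycle, each
of the 20 compound valves opens for 7 s with a 2 s oil spacer after every
plug except the last, which is followed by a 120 s plug-injection step; one
cycle per autosampler drug (21 cycles for the 420-condition screen).

## Read layout and demultiplexing

Read 1 (26 nt) is parsed with 0-based half-open spans as
[BC-PCR 0–10)[GCGGC 10–15)[BC-RT 15–25)[dT 25–26); the 26th base falls in
the dT tract and is ignored for matching. This is the unique arrangement
consistent with the fragment chemistry and the 26-bp read. Whether any
common-primer bases precede BC-PCR depends on the sequencing primer's
annealing position; an `offset` parameter shifts the whole layout if needed
(default 0).

Matching tolerates ≤ 1 mismatch per barcode and ≤ 1 in the linker; indels
are demultiplexing failures by design, since the distance-3 guarantee covers
substitutions only. Each read receives exactly one outcome: `ok`,
`linker_fail`, `bc1_nomatch` (BC-PCR), `bc2_nomatch` (BC-RT), or
`ambiguous` (two barcodes tie at the minimal distance within tolerance —
impossible inside a distance-3 codebook but reachable for user-supplied
sets). Quality strings are read but never used. Counts are read counts;
this chemistry has no UMIs, and the unit of demultiplexing is the treatment
condition, not the cell.

Reads with at most one substitution per segment are *provably* decoded
correctly; reads with ≥ 2 substitutions in one barcode can in principle
land within distance 1 of a wrong codebook entry, which no distance-3 code
can prevent. Fidelity benchmarks therefore score the protected population
(and separately report overall rates).

Gene assignment for synthetic references is an exact 3′-terminal 25-mer
lookup: each transcript contributes its terminal seed, duplicates are
rejected at load, and a read maps to a gene iff its own 3′-terminal 25-mer
equals a seed. This stands in for read alignment, which is out of scope.

## Expression QC and normalization

Samples are filtered on a detected-gene floor (default 200 — roughly an
order of magnitude below the ~3,200 genes/sample of a deeply sequenced
validation screen; the exact production cutoff is not fixed by the assay
and is configurable) and a mitochondrial read fraction ceiling of 15%.
Genes must be detected in ≥ 10% of retained samples (configurable).
Normalization scales each sample to the median depth, applies log1p, and
z-scores each gene; zero-variance genes are dropped with a warning.

Replicate batch structure is removed by per-gene, per-batch mean-centering
with the global mean restored — a deterministic closed form that exactly
removes additive replicate offsets and leaves balanced condition contrasts
untouched. Empirical-Bayes batch correction (ComBat-style) would
additionally moderate variances; for replicate offsets of a pooled screen
the mean shift is the dominant term, and the closed form keeps the
operation reproducible and testable. This is a deliberate simplification.

## Silhouette clustering QC

For a labelling factor, each sample's silhouette is s = (b − a)/max(a, b)
with a the mean intra-cluster and b the mean nearest-other-cluster
distance; singleton clusters score 0 (scikit-learn convention, against
which the implementation is cross-checked). Distances are Euclidean on the
top 50 principal components by default (capped by the data's dimensions;
any precomputed distance matrix can be supplied instead), mirroring
dimension-reduced clustering practice. The test statistic is the mean
silhouette; the null permutes sample labels, and the empirical p-value uses
the add-one estimator (1 + #{null ≥ observed})/(n_perm + 1), which can
never return 0. With 199 permutations the test's exact size at the 0.05
level is 9/200 = 4.5%; calibration benchmarks use 2000 null replicates so
that the Monte-Carlo error of the estimated rejection rate (~0.5
percentage points) is small against the ±2-point acceptance band.

## Spike-in accuracy and sensitivity

Accuracy is the Pearson correlation between log10 input concentration and
log10 measured TPM (pseudocount 1 for zeros, recorded in the output; TPM
columns sum to 10⁶ per sample by construction). Sensitivity fits detection
(count ≥ 1) against log10 concentration with a binomial GLM; LOD50 =
−intercept/slope is the concentration at 50% detection probability, with a
delta-method 95% CI. Complete separation (a perfect detection step) makes
the MLE diverge; the package reports the midpoint of the separating gap
with a `separated` flag instead of a fitted value, and a zero slope is an
error (no LOD exists).

## Signatures, pathways and similarity

Consensus drug signatures come from one pooled per-gene OLS of expression
on drug-presence indicators (intercept + one column per non-control drug;
combination samples carry two 1s, vehicle-only samples none). Replicates
enter as extra rows; batch structure is handled upstream. The fit is the
closed-form least-squares solution computed for all genes at once, with
standard errors from the residual variance; rank-deficient designs raise an
error naming the collinear columns. Pathway activities are weighted sums
over the genes shared with an externally supplied genes × pathways weight
matrix, z-scored across samples (so global weight scaling is irrelevant);
pathway coverage is reported and unmatched pathways are dropped. Whether
activities are z-scored before the drug association model is a flag
(default: yes). Drug–pathway associations reuse the same OLS with pathway
activities as responses.

Cross-dataset similarity is Spearman correlation (average ranks for ties)
on the shared-gene intersection, requiring ≥ 10 shared genes by default.
The matched-drug ROC treats similarities as scores and same-drug pairs as
positives; the AUC equals the Mann–Whitney pair-counting statistic (ties
half-weighted), the null permutes the column drug labels, and the p-value
uses the add-one estimator (default 1000 permutations). An external
reference compendium is emulated by a second synthetic signature set;
aggregation over grouping keys is a plain mean.

## Viability, GR anchors and synergy

The viability model is a ridge regression from normalized expression to
relative viability (α = 0 gives the OLS limit). Predictions align genes by
name, impute absent genes at 0 (the training mean on the z-scored scale),
and refuse to predict below a 50% gene-coverage floor. Screen-level scoring
uses out-of-fold predictions from condition-grouped folds, so a condition's
replicates never inform its own prediction, followed by a single global
affine recalibration of the predictions against the training labels —
ridge shrinkage compresses held-out predictions toward the mean, which
would otherwise bias the multiplicative Bliss comparison.

GR values are GR(c) = 2^(log2(x/x0)/log2(x_ctrl/x0)) − 1 for endpoint count
x, untreated endpoint x_ctrl and initial count x0 (1 = no effect, 0 = full
cytostasis; requires a growing control). Dose–response curves are
4-parameter logistics in log10 concentration fitted by Levenberg–Marquardt
from three fixed starts (Hill slopes 0.5, 1, 2; best residual wins —
deterministic). GR35 is the concentration where the fitted curve equals
0.65, i.e. 35% growth-rate inhibition — the natural anchor by analogy with
GR50 at 0.5; the curve is inverted analytically and a missing crossing
within the tested range is an explicit out-of-range error.

Bliss independence sets the expected combination viability to v_A·v_B
(fractions of control; negatives clipped at 0, values > 1 allowed but
flagged). Plate synergy is the mean of (expected − measured) over the dose
grid — positive = synergistic — with missing wells skipped and counted.
Both 4 × 4 and 5 × 5 checkerboards are supported; descriptions of such
panels vary between the two, and nothing in the scoring depends on the
choice. Expression synergy compares the combination prediction to the
Bliss product of the two monotherapy predictions (score = v̂_A·v̂_B − v̂_AB);
which monotherapy comparison a given study used is often ambiguous, so a
highest-single-agent alternative (min single − combo) sits behind
`rule="hsa"`.

## Fluidics QC

Plug traces are segmented at a threshold; a peak's height is the *median*
of its plateau, robust to the <100 ms flow-equilibration spikes at plug
boundaries (this choice, rather than maximum height or integration, is a
declared convention). Segments much wider than the median width are
flagged as possible merged plugs. Polarity (dye-positive vs dye-negative)
follows the declared alternating loading order — supplied metadata, never
inferred. Carryover per transition is height(negative n)/height(positive
n−1), summarized per channel; the statistic is invariant to global
intensity scaling. Droplet mixing precision is the CV (sd/mean, ddof = 1)
of per-combination median intensities.

## Synthetic data: what it emulates and what it does not

The generators mirror the screen's stated operating points: 250 cells per
condition, ~130 reads per cell (so ~3 × 10⁴ reads/sample, the shallow
regime of a 420-condition screen), per-base substitution rate 0.5%, three
replicates with per-gene Gaussian batch offsets (sd 0.1), droplet occupancy
0.1, negative-binomial counts with dispersion 0.3 over 500 genes (10%
flagged mitochondrial, 8% of reads), and a 92-species spike-in ladder
spanning four decades.

Expression and viability are linked by construction: a dense "viability
response" direction u (nonzero on 250 of 500 genes, entries O(1) log-fold
per unit kill) and its dual weight vector w (w·u = 1) are drawn once per
scenario; each drug's effect vector is −kill·u plus a w-orthogonal
drug-specific component, so monotherapy viability is exactly 1 − kill, and
pairwise interaction terms shift expression along u so that combination
viability equals the Bliss product minus the planted excess. Planted
excesses are ±0.10–0.30; kill fractions are uniform on 0.05–0.30. Making
half the transcriptome viability-responsive reflects the premise of
expression-based viability inference — growth arrest and death reshape
broad programs — and gives the linear model a realistic signal to find;
with a much sparser program the information ceiling (prediction with the
true weights) drops below what reliable interaction calling requires.

What the simulations do *not* model: real transcriptome structure and
gene–gene correlation, PCR amplification bias, droplet-physics artifacts
beyond a phenomenological carryover parameter, drug exchange between
droplets, UMI-free duplicate structure, or the nonlinear
expression–viability relationships of real compendia. Passing the
recovery benchmarks therefore demonstrates that the estimators are correct
and well-calibrated under their own assumptions — not that those
assumptions hold for any particular real screen.

All generators are deterministic given a seed, and every emitted read and
sample is traceable to ground truth.

## Benchmark problem sizes

The packaged benchmarks use: 10⁵ read pairs over the 420-condition codebook
for demultiplexing fidelity; a 10 × 10 screen (DMSO included per role,
three replicates, 300 samples) with 5 + 5 planted interactions for synergy
recovery; 2000 null replicates at 199 permutations for silhouette
calibration; n = 120 samples at noise sd 0.5 for signature recovery; a
noiseless n = 200 fit for the viability OLS limit; 480 Bernoulli draws from
a known logistic for LOD50; and 100 plugs at κ = 0.015 for carryover.
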