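# Methods

This note documents the models, statistics and design choices behind
fusionwire, and what the synthetic-data generators do and do not
emulate.

## Coordinates and gene models

All internal coordinates are 0-based, half-open; GTF input (1-based,
inclusive) is converted on read and BED-style tables are used natively.
Genes are single-transcript: one canonical ordered exon chain, exon 1
first in transcription order (so reverse-strand genes have exon 1 at
the highest genomic coordinates). Multi-isoform quantification is out
of scope.

A translocation breakpoint is intronic by assumption; a breakpoint
inside an exon raises an error unless explicitly overridden, in which
case the containing exon is truncated and counted on the retained side.
For a 5' partner the fusion retains the contiguous exon prefix
transcriptionally upstream of the break; for a 3' partner the suffix
downstream. A breakpoint upstream of exon 1 of the 5' partner yields an
empty retained prefix and a warning (promoterless fusion), not an
error. The packaged toy gene models place exon k of each gene at
[off + 1000k, off + 1000k + 200); only the retained exon *ranges* are
meaningful, not the synthetic coordinates.

## Exonic imbalance and epistate inference

**Model.** A fusion joining an enhancer-driven allele to a silent or
weakly expressed wild-type allele leaves a step in exon-level RNA-seq:
exons retained in the fusion transcript are expressed far above exons
beyond the breakpoint, which are covered only by the wild-type allele.
Balanced biallelic expression shows no step.

**Normalization.** x_ij = log2(count_ij / (L_i/10³) / (N_j/10⁶) + c),
i.e. log RPKM with pseudocount c (default 1). Library sizes default to
column sums. Doubling all counts and the library size together leaves x
unchanged; at c = 0 the downstream statistics are exactly invariant to
per-sample count scaling.

**Z scoring.** The headline per-sample score is computed against the
cohort: each sample's x vector is mean-centered across the gene's exons
(removing library, promoter-strength and lineage-silencing level
shifts, which carry no information about differential exon *usage*),
and each exon's residual is divided by a robust per-exon scale, 1.4826
times the median absolute deviation of that exon's residuals across the
cohort. Z\* = max_i |z_ij|. Two properties motivated this construction:

* *Shift invariance.* A gene uniformly silenced in one sample (e.g. the
  wild-type PAX3 allele in fusion-positive tumors with no fusion-allele
  contribution) scores at baseline — silencing is not imbalance.
* *Exchangeability under the null.* Every sample is scored against the
  same cohort-wide scale, so no group is privileged and the group
  comparison is calibrated; the MAD makes that scale resistant to the
  fusion-positive minority. Mean (not median) centering is used because
  with few exons the within-sample median leaves residuals piled at
  zero, which deflates the cross-sample MAD.

A within-sample alternative (studentizing each sample's exon vector by
its own mean and SD, z then summarized by max |z|) is selectable
(`method="within_sample"`), with the caveat that its denominator
absorbs the imbalance step itself: a pure 7-vs-2 exon step yields
max |z| ≈ 1.76 regardless of step size, indistinguishable from the
max |z| of nine iid noise values, so it has essentially no power as a
cohort statistic. It is retained for vectors where no cohort reference
exists. Degenerate inputs (single exon, zero variance) give an all-zero
z vector rather than NaN.

**Breakpoint contrast.** When the fusion architecture is known,
Δ = (mean x over retained − mean x over lost exons) / pooled SD, with
the pooled SD from the within-side variances. Δ beyond a threshold τ
(default 1.5) calls the epistate: for a 5' partner gene, Δ > τ means
the retained prefix is overexpressed (imbalanced 5'); signs and labels
mirror for 3' partners; |Δ| ≤ τ is balanced. If both sides are
internally constant and unequal, Δ is ±∞ (a pure step).

**Group comparison.** Two-tailed Welch t test (unequal variances,
Welch–Satterthwaite df), applied to log2(1 + Z\*). Z\* is a strictly
positive max-statistic with a heavy right tail — a single sample in
which a silenced exon drops to zero counts can reach Z\* ≈ 30 and
dominate a small group's variance — and the monotone log transform
stabilizes variance without changing group ordering on Z\*. Each
fusion-positive group is compared on its *own* 5' partner gene (PAX3
for PAX3-X fusions, PAX7 for PAX7-FOXO1). No multiple-testing
correction is applied by default (single-gene analyses);
Benjamini–Hochberg is available through `statsmodels` for gene-wide
scans by the caller. Groups with fewer than two samples cannot be
tested and are reported without p values.

## Super-enhancer calling and spike-in normalization

Peaks within a stitch gap (default 12,500 bp) are merged; stitched
signal is the *sum* of constituent signals (rank-by-load convention,
not max). An optional TSS-exclusion table removes promoter-proximal
peaks before stitching. Stitching is idempotent and equals a
transitive-closure merge.

Regions are ranked by signal; on the rank curve with both axes min–max
scaled to [0, 1], the SE cutoff is the point where a line of slope 1 is
tangent to the curve, computed as argmin(y − x). (Thresholding raw
adjacent-point slopes is equivalent for convex curves but is tripped by
a single large gap between the bulk and the tail; the tangent form is
stable.) Regions with signal strictly above the cutoff signal are SEs.
Ranks are dense, 1 = highest signal, ties broken by (chrom, start);
percentile = 100 (N − rank + 1)/N. With all-equal signals there is no
elbow: zero SEs, with a warning. The SE set is invariant under uniform
scaling of all signals.

`rank_percentile` reports, per sample, the percentile of the
highest-percentile stitched region sharing at least one base with the
query interval — the natural reading of "the enhancer percentile at a
gene locus" — and explicit absence (NaN) when nothing overlaps.

ChIP-Rx: RRPM_i = count_i × 10⁶ / (spike-in total reads); delta tracks
are the signed per-bin difference of two RRPM tracks on identical bins.

## Derivative locus and neo-TAD logic

The derivative chromosome is the 5' source segment followed by the 3'
segment on one axis; feature positions are remapped by offset
arithmetic, and on flipped segments both position (mirror: offset +
segment end − position) and CTCF motif orientation are reversed. The
mapping is exactly invertible, and round-trip identity is asserted in
tests. Orientation is encoded relative to the coordinate axis (forward
= motif points toward increasing coordinate); motif scanning from
sequence is out of scope — orientations are inputs.

A site pair (i, j) with position_i < position_j is loop-permissive iff
i is forward and j reverse (convergent/"antiparallel", the
configuration compatible with loop extrusion). The insulated
neighborhood around an anchor (the fusion promoter) is the
smallest-span permissive pair strictly spanning the anchor — the
innermost loop is taken as the operative regulatory unit — with the
outermost spanning pair (the TAD-boundary candidate) reported
alongside. Absence of any spanning pair is an explicit "no
neighborhood" result, which is how boundary loss (deleting the
reverse-oriented member of the only spanning pair) manifests.
Containment is strict: an element exactly at a boundary position is
outside. Element classes combine with the intra/outside flag into
composite labels (`intra_tad_se`, `outside_tad_se`, ...) consumed by
the screen analysis.

## CRISPR tiling-screen dropout

Counts are normalized per timepoint to counts-per-million after adding
a pseudocount (default 0.5; avoids −∞ LFC for guides that drop to
zero). Per-sgRNA LFC = log2(a_t / a_ref) with the earliest timepoint
(day 2) as reference; a plasmid-pool reference column can be supplied
instead. Element scores are per-sgRNA LFC medians (robust to a single
bad guide; mean selectable). Classes are compared with both the shared
Welch t test and a two-sided Mann-Whitney U. LFC is antisymmetric in
(t, reference) by construction.

## Synthetic-data generators

The generators define the study conditions for every test; all
generated effects are recorded in truth tables.

**Cohort.** Group sizes default to FN = 61, PAX3-FOXO1 = 23,
PAX7-FOXO1 = 10, PAX3-NCOA1 = 2, PAX3-INO80D = 1. Expected count for
exon i in sample j is

    mu_ij = (L_i/10³) · s_j · (b · w + r · b · w · 1[i retained, j fusion-positive])

with base rate b (default 200 counts/kb at unit library factor),
library factors s_j log-uniform on [0.5, 2], lineage silencing w of the
5' partner's wild-type allele in fusion-positive samples (default 0.2;
the wild-type PAX3/7 allele is near-silent in FP tumors), and
imbalance ratio r (default 10) defined as fusion-allele over wild-type
allele expression so that the expected retained/lost ratio is r + 1
regardless of w; r = 0 is the null. The fusion allele covers the
retained prefix of the 5' gene and the retained suffix of the 3' gene
at one shared rate (it is one transcript). Counts are
negative-binomial with var = mu + phi·mu², phi = 0.1 (typical bulk
RNA-seq overdispersion). r and w were chosen for clear but unsaturated
separation; the underlying tumor data report no effect sizes, so these
are testability choices, not biological calibration.

**Enhancer landscape.** n non-overlapping intervals; signals are a
log-normal bulk (median 100, sigma 0.8) with a Bernoulli(tail fraction,
default 0.04 — SEs are a few percent of enhancers) tail component whose
median is tail_scale (default 20) times the bulk median, sigma 0.5.
The truth flag records tail membership.

**Screen.** Guides tile six element classes with per-day depletion
rates delta ordered promoter (0.30) > intra-TAD SE (0.15) >
TAD-boundary CTCF (0.06) > typical enhancer = outside-TAD SE = control
(0). Latent abundance of guide g decays as exp(−delta_class·(t − t₀))
from day 2 across days 2, 5, 7, 10, 13, 17, 20, 25; observed counts
are one multinomial draw of depth 10⁶ reads per timepoint over a
log-normal initial guide distribution (sigma 0.25). The closed form
LFC(t) = −delta·(t − t₀)/ln 2 holds for the latent abundance; CPM
renormalization and the count pseudocount bias the measured LFC upward
when depleting guides are a non-trivial fraction of the library or
terminal counts approach 1, so the closed-form recovery check uses a
mostly-neutral, deeply sequenced configuration (promoters ~1% of
guides, depth 10⁷) where both biases are below 0.1 log2 units.

**What the generators do not emulate.** Read-level artifacts
(mappability, GC bias, positional coverage), copy-number variation,
isoform switching, batch effects, sgRNA off-target activity and
cutting-efficiency heterogeneity, and spatial structure of real
enhancer landscapes. Passing tests therefore demonstrate that the
statistics recover the effects they are designed for under their
stated noise model — not that they are robust to every artifact of
real tumor data.

## Problem sizes and numerical conventions

Recovery and calibration suites run at the cohort's own dimensions (97
samples; 100 replicates for separation, 1000 for type-I error, 200
seeds for screen class ordering, 20 seeds at n = 1000 enhancers for SE
recall); expectations in monotonicity checks are averaged over 12 seeds
per condition. All randomness flows through `numpy.random.default_rng`
seeds recorded in specs and manifests; identical spec + seed is
bit-identical, and the pipeline writes TSVs with a fixed float format
("%.6g") so reruns compare byte-for-byte. Sample (n−1) standard
deviations throughout; zero-variance and single-exon degenerate cases
yield zero scores rather than NaN; signal ties in ranking break by
genomic position for determinism.

## Known limitations

Single-transcript gene models; point (midpoint) features for CTCF
sites and screen elements; no attempt to resolve which convergent pair
is functionally dominant when chromatin-contact and perturbation
evidence disagree; the exonic-imbalance score presumes a cohort
containing a reasonable fraction (< ~40%) of reference-like samples
for the MAD scale to hold; and the CLI covers the common paths only —
the library functions are the primary interface.
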