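# Methods

This note documents the models and numerical choices behind
`lcshic`: what each statistic computes, what the synthetic generator
does and does not emulate, and where genuinely open design choices
were resolved.

## Genome model and compartment ranks

A genome is an ordered list of chromosomes tiled by fixed-size bins
(0-based half-open; terminal bins may be short). Chromosomes carry a
long/short territory class; with the human-like default order,
chr1–chr14 and chrX are long and chr15–chr22 short. Compartment
state is a continuous rank in [0, 1] per bin (0 = most B-like,
1 = most A-like) discretised into eight labels (B.2.2 … A.1.1) by
rank octile; rank 1.0 belongs to the top octile. Segmentations are
BED-like tables of non-overlapping segments with a rank and label;
binning assigns each bin the rank of the segment containing its
midpoint, and uncovered bins are missing (NaN) and propagate.

The bundled desk-scale karyotype has 23 chromosomes of 2.65–10 Mb at
50 kb bins (~2,900 bins genome-wide). All algorithms are scale-free
in the number of bins; the reduced size keeps the full pipeline —
simulation through scoring — inside seconds per condition.

## Synthetic Hi-C generator

The expected contact matrix combines four ingredients:

- **distance decay** (d + 1)^α within chromosomes, α = −1 by default
  (the classic fractal-globule-like slope);
- **compartment affinity** exp(−|rank_i − rank_j|/τ)^a with
  τ = 0.25, a = 1 — any kernel monotone in rank similarity produces
  the checkerboard the downstream statistics read; this one makes
  the 8-level gradient explicit;
- **TAD insulation**: contacts crossing a planted boundary are
  divided by `insulation_depth` (default 3) per boundary crossed;
- **chromosome territories**: long–short pair weights are divided by
  `territory_bias` (default 2), with pair weights otherwise
  proportional to the product of chromosome lengths.

Whole-genome doubling is modelled as mixing: with strength
λ ∈ [0, 1] the expected map is (1 − λ)·structured + λ·unstructured,
where the unstructured map keeps distance decay and chromosome
lengths but drops affinity, insulation and territory bias. λ is a
phenomenological dial calibrated only to reproduce the qualitative
loss-of-segregation signatures (territory intermixing, compartment
blurring, boundary weakening); no generative model of post-WGD
chromatin is claimed. Counts are Poisson around the expected map
(the simplest noise consistent with sparse Hi-C counts); single
cells are multinomial draws of a fixed number of contacts.

Two normalisations shape the expected map. Intra-chromosomal blocks
and the genome-wide matrix are symmetrically rescaled toward
constant marginals, so the default output behaves like a *balanced*
map — appropriate because every downstream operation either demands
balanced input (insulation, O/E) or balances internally
(interchromosomal analysis), and because it removes desk-scale edge
artifacts that 2–10 Mb chromosomes would otherwise exaggerate. An
optional per-bin log-normal visibility bias (`bin_bias_sd`) restores
raw-read behaviour for the one analysis that consumes raw coverage:
CNV calling. At `bin_bias_sd = 0.2` the raw-coverage MAD is ~9% of
the median at 250 kb analysis bins, the regime the γ·MAD gap-masking
rule presumes — with near-zero MAD that rule would mask genuine
single-copy losses as "gaps".

Planted truth:

- **CNVs** (chrom, span, copy ratio): the expected matrix is
  Sinkhorn-rescaled to target marginals so each bin's expected
  coverage scales by exactly its copy ratio, as read depth does.
- **CoREs** (rank shifts applied to a second condition's track):
  events are placed only where the full shift stays inside [0, 1]
  (activations need headroom toward A), span ~30% of their
  chromosome (at least 10 bins) with alternating sign, and default
  to |shift| = 0.3. The span fraction makes the event the dominant
  contribution to chromosome-level ΔR variance — the regime in which
  the mean/SD recursion can enter the chromosome at all (an isolated
  shift of 0.2 on fraction p contributes sd √(p(1−p))·0.2 ≤ 0.1 = σ*
  for every p, so detectability at the σ* boundary is intrinsically
  marginal; see "Detection boundary" below).
- **Boundaries** at compartment-segment edges. Segment lengths are
  9 bins (450 kb) minimum, ~600 kb mean — octile-scale compartment
  domains — and the minimum strictly exceeds the 400 kb half-window
  of the local-minimum boundary caller, since two dips inside one
  calling window can yield only one minimum.
- **Replicate noise** on segmentations is segment-wise Gaussian
  (rank calls vary between replicates at the segment level), with
  per-replicate sd 0.054 so the replicate-difference vector ΔR_E has
  sd ≈ 0.077; the repositioning threshold σ* = 0.1 is then ~1.3×
  that spread, reproducing the stated calibration of the detection
  threshold against replicate variability.
- Phased contacts: a control diploid emits per-haplotype cis counts
  C, C and cross-haplotype T; doubling emits 3C, 3C, 4T (each
  haplotype 1 → 2 copies: cis pair classes per haplotype 1 → 3,
  cross classes 1 → 4), with optional multiplicative log-normal
  noise.

Single-cell ground-truth labels live in a sidecar table only; the
contact records carry no label. A configurable fraction of contacts
(default 60%) receives read support ≥ 2 so QC deduplication is
exercised; the rest are singletons.

What the generator does **not** emulate: polymer/loop-extrusion
physics, sequence-level artefacts, mappability structure beyond the
log-normal bias, translocations, and realistic inter-chromosomal
fine structure (inter blocks are uniform within a pair). Passing
tests therefore demonstrate algorithmic correctness and directional
behaviour under the stated contact model, not performance on real
libraries.

## Interchromosomal analysis

Contacts aggregate to a symmetric chromosome-pair matrix whose
diagonal (intra totals) is excluded from all statistics. Iterative
correction is symmetric Sinkhorn scaling of the off-diagonal part to
unit marginals (tol 1e−8, max 200 iterations); chromosomes with zero
interchromosomal counts are masked and exempt. Balancing is
invariant to global scaling of the input. The bin-level variant
zeroes intra blocks and balances bins to unit interchromosomal
marginals (for coarse-resolution visualisation maps and pseudo-bulk
cells). Condition comparisons take log₂ ratios of balanced entries
on unmasked off-diagonal pairs, label each pair LL/LS/SS, and test
category differences with two-sided Mann–Whitney on unique unordered
pairs (chrX included; sidedness was an open choice — two-sided is
the conservative default). Zero-denominator entries are masked, not
clamped.

The phased trans/cis ratio is r = T/(C₁ + C₂) per condition; the
homolog-doubling model predicts r_WGD/r_Control = (4T/6C)/(T/2C) = 4/3.

## Compartment segregation

Intra maps are aggregated to 1 Mb, divided by the mean contact at
each genomic distance (distances with zero coverage are undefined
and propagate), and upscaled to 50 kb by exact 20:1 superpixel
nesting (a short terminal superpixel keeps the mean of the pixels it
covers). Bins excluded at 1 Mb are dropped at 50 kb. Per bin,
contact sums to the 8 levels are divided by the bin total and by the
per-level chromosome-coverage fraction B_comp (computed
chromosome-wise, since the analysis is per-chromosome), then
normalised to fractions summing to 1; the own-level fraction is the
bin's CScore.

Between conditions, loss/gain counts form ratios
σ_comp₁(comp₂) = #loss/#gain; ties (equal fractions) count half to
each side so identical profiles give exactly 1 — the displayed ratio
is silent on ties, and the half-tie rule makes σ continuous around
the no-change point. The symmetric matrix averages the two ordered
ratios and reports −log₂ (positive = gain of contacts). Per-level
scores use CScore counts; zero denominators are reported as +∞ with
an `undefined` flag rather than clamped.

## Insulation

The insulation score at bin b is the mean contact in the w×w window
of pairs crossing the gap between bins b−1 and b (w = 1 Mb each
side); windows that do not fit, or with > 20% missing pixels, are
missing. Valid means are divided by the chromosome geometric mean
and log₂-scaled, so tracks centre at 0 and are invariant to global
scaling. Boundaries are strict local minima within ±400 kb; exact
ties and plateaus yield their leftmost bin, and flat stretches are
not minima. Shared-boundary matching is greedy one-to-one by
distance within ±50 kb (nearest pairs first — whether multi-matches
should deduplicate was unstated; greedy one-to-one assumed). The
top-k selection takes each condition's k-th smallest boundary score,
uses the larger (weaker) as threshold, and keeps shared pairs with
both scores at or below it — the k-th boundary defines the
threshold and is itself a member of the top-k set, hence the
inclusive comparison; the final count need not be exactly k.

## CoRE detection (DiffComp)

ΔR = C_X − C_Y per 50 kb bin, in [−1, 1], positive toward active.
Missing bins split chromosomes into runs; the recursion never spans
a gap (unmappable regions must not bridge events). Each run: if
sd < σ* (= 0.1) or a single bin remains, stop and assign the mean as
repositioning score; otherwise split into maximal runs at/above vs
below the mean (≥ mean counts as "above") and recurse. The segments
partition every non-missing bin exactly once.

The empirical p-value of segment s is the fraction of replicate-null
values |E| (pooled genome-wide from ΔR_E; per-chromosome pooling was
an open choice, pooled gives a larger null) exceeding max|ΔR(s)|;
it is non-increasing in the segment's max deviation and can be
exactly 0. CoREs pass |score| ≥ 0.1, p ≤ 0.01 and length ≥ 300 kb
(inclusive comparisons).

**Detection boundary.** With the null calibrated as above
(sd(ΔR_E) ≈ 0.077), P(|E| > 0.2) ≈ 0.009: an event whose max
deviation is exactly 0.2 sits on the p = 0.01 cutoff, and the
recursion's entry condition is marginal for any isolated 0.2-shift
(previous section). Recovery guarantees are therefore stated and
tested at planted |shift| = 0.3; shifts at the 0.2 boundary are
detected at roughly even odds by construction of the thresholds.

The alternative engine (`method="cbs"`) applies changepoint
segmentation to the same vector with identical scoring and filters.
The engine tests *arcs* — every contiguous segment against its
complement, the circular-test geometry — with the breakpoint
accepted when the observed max t statistic exceeds the 99th
percentile of 1,000 within-segment permutations (α = 0.01). Plain
binary splitting was tried first and rejected: an interior
copy-number bump at realistic noise fails the single-split
permutation test even when visually obvious.

Tracing assigns each CoRE the mean binned rank over its span in the
control and intermediate segmentations; the final rank is
r_control + score. The intermediate class is activating/inactivating
when |r_mid − r_control| ≥ ε (= 0.05), else unchanged; a CoRE is
consistent when intermediate and final classes agree and are not
unchanged. CoREs without intermediate coverage are flagged missing
and excluded from the six-class counts. Overlap analysis merges
same-direction intervals from both lists (book-ended intervals
merge, as the standard interval-merge tools do) and classes each
union region common when CoREs of that direction from both lists
overlap it (≥ 1 bp); with `consistent_only`, at least one
overlapping CoRE must carry the consistent flag.

## CNV calling from coverage

Coverage n_b is the total contact ends (cis + trans) per bin — the
natural reading of Hi-C "coverage". Bins overlapping supplied gaps,
partial terminal bins (structurally reduced span), and bins with
n_b < R̄ − γM (R̄ genome median, M the *unscaled* MAD — the rule is
stated on the raw deviation, so no 1.4826 consistency factor) are
masked and excluded from all statistics. Chromosome-median
normalised coverage of unmasked bins is segmented by the changepoint
engine; a chromosome without accepted breakpoints is one segment
(masked bins do not count toward segment extent). Each segment's
w_s = median(n_b/R̄); segments with |w_s − 1| ≥ t are gains
(w_s > 1) or losses. Presets: bulk 2 Mb/γ = 7/t = 0.4; phased γ = 4;
single-cell 5 Mb/γ = 4/t = 0.4. All normalisations are
median-relative, so calls are invariant to uniform scaling of total
coverage. Consensus merging expands same-type intervals by ±50 kb
and merges transitively with per-sample support counts; significance
testing of individual CNVs (external tools' KS/Wilcoxon) is out of
scope — the caller emits w_s only.

## Single-cell analysis

QC removes cells with singleton fraction > 75% or fewer than 100,000
unfiltered interactions (strict "fewer than": exactly 100,000 is
kept), then drops singleton contacts and collapses duplicates; the
filters are order-independent. The LCS score balances each retained
cell's 23×23 matrix and takes LS/(LL + SS) over balanced
off-diagonal entries ("balanced interactions" could also mean
bin-level balancing at coarse resolution; chromosome-level is
implemented, with the bin-level variant available separately).
Duplicating every record leaves the score unchanged. Pair rankings
rank the 253 unordered chromosome pairs per cell by balanced count
(rank 1 = most interacting, ties share the mean rank) and average
across cells.

Compartment imputation per chromosome: 1 Mb matrix, zero-marginal
bins removed (< 4 usable bins skips the chromosome), O/E against a
log-spaced distance-decay profile (base-2 groups {0}, {1}, {2,3},
{4..7}, …), centred by subtracting 1, bin–bin Pearson correlation,
then the two leading principal components of the correlation matrix
(column-mean-centred SVD; component 1's sign is fixed to correlate
positively with the bulk A indicator). The silhouette between the
bulk-assigned A and B point sets measures per-cell segregation;
k-means (k = 2) clusters relabelled to best match bulk give the
cell's own calls, scored by adjusted Rand index, and chromosomes
with ARI ≤ 0 are excluded from consistency. Consistency per 1 Mb bin
is max(A, B)/(A + B) over contributing cells. At the desk-scale
genome (≤ 10 bins per chromosome at 1 Mb) real simulated cells carry
little imputable compartment signal; the quantitative behaviour of
this stage is validated on constructed correlation structures
(block checkerboards, decay-only matrices), and on simulated cells
only the mechanical contracts are exercised.

Pseudo-bulk sums per-cell interchromosomal counts to I, estimates
E_ij = C_i·C_j/2N (C_i the chromosome's interchromosomal ends, N the
total interactions; ΣC_i = 2N), forms OE = I/E, and computes
ρ_ij = Spearman(OE_i, OE_j) over rows excluding the two self
columns (the self-pair entries would tie the rows trivially);
condition differences are σ_ij = log₂((ρ^b + 1)/(ρ^a + 1)).

## Annotation

Signals are log₂(x + 1)-scaled per source interval, averaged into
50 kb bins, and divided by the chromosome median (all-zero
chromosomes flagged undefined). Genes attach to the bin containing
their TSS (interval start on +, end on −). DE-on-CoRE enrichment
computes log₂ of overlap-percentage ratios for the four
(DE direction × CoRE direction) classes; the null draws random gene
sets of the same size 100,000 times — sampled as hypergeometric
overlap counts, which is the exact distribution of the overlap count
under random subset selection — and p is the fraction of null sets
with overlap percentage ≥ observed. Gene–CoRE overlap means the TSS
bin intersects the CoRE span; a proximity window is exposed
(default 0 for enrichment, ±1 Mb available for labelling-style
reporting, since reported proximity analyses use both conventions).
Signal–CoRE correlation assigns each CoRE its mean per-bin signal
difference, computes Spearman ρ against CoRE scores (invariant to
monotone transforms of the signal), and re-places each CoRE
uniformly on its own chromosome 1,000 times for the null;
p = fraction of |ρ_null| ≥ |ρ_obs|. Boundary-context reporting flags
genes within ±50 kb of a control boundary with insulation score
below −0.1 and classes those boundaries as gaining (score decreases)
or losing insulation.

## Numerical conventions

- Intervals are 0-based half-open BED throughout.
- Sinkhorn balancing is symmetric (D^{-1/2} W D^{-1/2}); tolerances
  1e−8 (matrices) with explicit residual-carrying errors on
  non-convergence.
- Permutation p-values are plain fractions (minimum 0); all
  permutation nulls are seeded and reproducible.
- Degenerate inputs (empty levels, zero denominators, all-missing
  chromosomes) produce flagged NaN/±∞ or warnings, never silent
  clamps.

## Known limitations

- The λ-mixing WGD model is phenomenological; effect sizes on real
  data need not match any particular λ.
- Inter-chromosomal expected structure is uniform within a
  chromosome pair, so bin-level interchromosomal statistics beyond
  marginals are not informative on simulated data.
- The CBS-style engine is an arc-permutation changepoint method,
  not a port of the reference CBS implementation; it reproduces
  breakpoint behaviour on step and bump signals but has no pruning
  ("undo") step.
- Desk-scale chromosomes (2–10 Mb) compress every genomic scale by
  ~25×; window sizes (1 Mb insulation, 400 kb minima) keep their
  real-data values, so per-chromosome object counts are small and
  top-k selections use proportionally smaller k.
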