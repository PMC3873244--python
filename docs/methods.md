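# Methods

This note records the models, conventions, and numerical choices behind
`fivec`, and what the synthetic benchmarks do and do not establish.

## Coordinates and restriction maps

All coordinates are 0-based half-open internally; BED I/O is native, and
published 1-based inclusive spans are converted on read
(`GenomicInterval.from_one_based`). In-silico digestion places every
fragment boundary at the **first base** of a recognition-site occurrence
(`CUT_OFFSET = 0`). The physical EcoRI cut falls inside the site
(G^AATTC), but all downstream logic keys on fragment identity rather than
sub-site coordinates, so any fixed convention is equivalent; this one
makes each internal fragment begin with the site, so ligation-junction
references reconstitute GAATTC by construction. Overlapping site
occurrences (impossible for GAATTC, possible for user-supplied sites) are
resolved left-to-right greedily. With this convention re-digesting any
fragment is a no-op for non-self-overlapping sites.

Fragment eligibility reads the size exclusions strictly: fragments
> 20,000 bp or < 100 bp cannot host primers, so 100 bp and 20,000 bp
fragments are eligible; the boundary behaviour is unit-tested.

## 5C designs

Two layouts are supported. *Anchored*: reverse primers on every eligible
fragment overlapping the anchor (a gene cluster), forward primers on all
other eligible fragments — a genes-vs-region matrix. *Alternating*:
forward/reverse alternate along eligible fragments in genomic order,
starting forward — an all-vs-all style matrix in which the forward and
reverse counts differ by at most one.

Primer cores are the `primer_len` (default 30 nt) bases of the fragment
abutting a cut: forward cores end at the downstream cut, reverse cores
start at the upstream cut. Forward primers carry the universal A-key
prefix, reverse primers the P1-key suffix and a 5′ phosphate. Melting
temperature optimisation and genome-wide uniqueness screening belong to
external primer designers; an exclusion list of fragment indices stands in
for them. Eligible fragments shorter than the primer length are skipped
with a warning, as is a reverse primer on the region's first fragment
(which does not start at a cut, so its junctions could not contain the
site).

## Read mapping and filters

Mapping is a deterministic aligner stand-in: a read maps to the unique
junction reference it matches allowing a start shift of up to 5 nt and up
to 2 substitutions; zero or multiple candidates leave it unmapped. An
exact hash over all shifted reference suffixes handles unmutated reads;
a vectorised byte-level Hamming scan covers the rest. The observable the
filters need — the start offset — is exact.

Filters: quality ≥ 30, |offset| ≤ 2 nt, recognition site present in the
read. The offset is compared by absolute value (direction is not
penalised). Rejected reads are tallied by the first failing rule in the
order quality, offset, site; reads without a mapping are tallied as
`unmapped` (their offset is undefined), after the quality check since
quality is defined regardless. Precedence affects only the tally
breakdown, never the kept set. The read quality is treated as a per-read
mapping quality; when reads arrive as FASTQ, the per-read minimum base
quality stands in for it (documented in `read_fastq`).

## Matrices

Missing cells are NaN everywhere and are never imputed as zero; all
operations propagate missingness. Normalization divides each raw count by
the total reads passing filters in the run (including control-region
contacts) and multiplies by 10³. Binning assigns each fragment pair to
exactly one bin pair by fragment midpoints on a grid shared by both axes
(anchored at the matrix extent), and averages; midpoint assignment keeps
the per-bin mean exact and testable, whereas overlap-weighted assignment
is ambiguous. Smoothing is a uniform boxcar mean over a genomic-distance
window (default 8 kb, ±window/2 inclusive on each axis); no Gaussian
weighting, because the target statistic is "the mean IF per window". The
default pipeline bins (20 kb) and then smooths; the orders are exposed
separately because the composition is not commutative and either is
defensible. Differentials are computed on normalized (optionally
binned/smoothed) matrices only — subtracting raw counts from runs of
different depth is refused. Replicate agreement is the Pearson
correlation of log(IF + ε) over shared non-missing cells with ε = 10⁻³,
one read at the per-1000 scale.

Matrix TSVs mirror published supplementary tables: axis labels
`name|genome|chrom:start-end` with 1-based inclusive coordinates on disk,
values at the ×10³ scale, `NA` for missing; round trips are lossless to
6 significant digits.

## Boundary calling

Published domain boundaries at this scale are often drawn by eye; the
caller here is an explicit, reproducible stand-in, not a re-derivation of
any published coordinates. The insulation score of boundary b is the mean
of the w×w off-diagonal square (w = `window_bins`, default 3; ≈60 kb at
20 kb bins); the matrix is first symmetrized by NaN-aware averaging with
its transpose because a design measures each contact in one orientation
only. Boundaries too close to the matrix edge are undefined. Calls are
local minima with prominence ≥ `min_prominence` × SD(profile) —
SD-relative so that calls are invariant under rescaling the matrix.
Plateau minima report their lowest position. The default prominence of
2.5 SD was calibrated on simulated maps with planted boundaries: at the
benchmark contrast and depth (2× cross-block depletion, ≥12 bins per
block, 10⁵ reads), genuine junctions dip by ≥ 2.8 SD while counting-noise
minima stay under 2 SD, and the caller achieves precision and recall
≥ 0.95 within one bin over 20 simulations.

## Enhancer candidates

The rule is evidence-monotone by construction: branch A seeds on each
RNAP2 peak overlapping ≥1 peak of any other mark, branch B on each p300
peak overlapping an H3K27Ac peak; candidate intervals are the union of
the seed and its supporting peaks (unions preserve the evidenced
footprint and make merging stable); candidates overlapping a promoter
padded by ±1,000 bp are removed (the proximal-promoter distance is not
standardised; 1 kb is the conventional window and is configurable);
surviving overlapping candidates merge with marks unioned and branch A
taking precedence. Overlap means ≥1 bp; peak significance is upstream and
out of scope. The rule is tissue-agnostic over whatever peak sets are
supplied.

## 3C quantification

The IF of a pair is the mean of the nine pairwise template/control ratios
(a literal nine-ratio mean, not a ratio of means), with the standard
error of the nine ratios alongside. Controls must be strictly positive —
the BAC control library is equimolar by construction, so a zero control
is a failed reaction; zero templates legitimately give IF 0. Replicates
are averaged per pair after normalization (SEM of the mean; a single
replicate reports SEM 0 by convention). The cross-library factor is the
mean of reference/profile ratios over ≥3 shared control-region pairs; the
reference regions can be pooled into one factor. Per-pair efficiency bias
cancels exactly at zero noise and to correlation > 0.95 with truth at
CV = 0.1 over 20 pairs.

## The synthetic generator

All generators are pure functions of (parameters, seed); seeds flow
through `numpy.random.SeedSequence` spawning.

*Region*: restriction sites are a seeded point process (Poisson count,
uniform positions, ≥3 site-lengths apart); the random background sequence
is scrubbed of chance GAATTC occurrences before and after planting, so
the digest reproduces the planted map exactly and every junction
reference contains exactly one site. *Contacts*:
`E[i,j] ∝ (d+d0)^−α · β_T^(TAD crossings) · β_S^(sub-TAD crossings) · γ`
on matching tissue-specific contacts, normalized to sum 1 off-diagonal.
*Reads*: multinomial pair draws; contaminant classes are planted with
exact counts (not per-read Bernoulli) so filter tests are exact — clean
reads are verbatim references with quality 30–42, low-quality reads draw
quality 0–29, shifted reads lose 3–5 leading bases, ablated reads carry
one substitution in the junction site (re-drawn if any site survives).
*ChIP*: per-mark peak emission with dropout, promoter RNAP2 peaks, and
single-mark decoys placed away from true features. *3C*: log-normal,
mean-preserving PCR noise (chosen for positivity) around
bias-times-contact expectations.

Default study conditions ("mini-HoxA"): 1 Mb region, site density
0.25/kb (≈4 kb fragments, the assay's typical resolution), α = 1,
d0 = 10 kb, one TAD boundary at 880 kb splitting a 10-promoter cluster
(800–980 kb), sub-TAD boundaries at 240/500/760 kb, β_T = 0.2,
β_S = 0.5, two enhancer clusters (300/340/380 and 560/600/640 kb), six
limb-specific enhancer–promoter contacts at γ = 8, contamination rates
0.012/0.008/0.005 (120/80/50 per 10⁴ reads), 10⁵ reads per run. The
boundary-recovery benchmark uses bin-aligned boundaries at 240/500/760 kb
with 2× contrast so "within ±1 bin" is well defined.

What the generator does **not** emulate: polymer physics, ligation-noise
structure beyond multinomial counting, mappability and GC biases,
cell-population heterogeneity, trans contacts, and real aligner behaviour.
Passing benchmarks therefore demonstrate the correctness and statistical
power of the analysis code under the stated model, not the biological
fidelity of any particular dataset.

## Problem sizes and degenerate inputs

The shipped benchmarks use a 1 Mb region (~260 fragments), 10⁴-read runs
for filter exactness, 10⁵-read runs for boundary recovery (20 seeds), and
10⁶-read runs per tissue for differential recovery — sizes at which each
statistical claim is comfortably identified. Degenerate inputs are
errors, not silent defaults: empty sequences, non-positive run totals,
windows/bins ≤ 0, anchors overlapping no eligible fragment, one-sided
designs, controls ≤ 0, fewer than 3 shared cells/pairs for correlations
and factors, constant matrices for correlation.

## Known limitations

The aligner stand-in models substitutions and start shifts only (no
indels). The insulation caller assumes a roughly uniform bin grid and one
boundary per local minimum; closely spaced boundaries (< window) merge.
Iterative matrix balancing (ICE-style) and 5C primer-efficiency
correction are out of scope — at this assay's scale the equimolar BAC
control (3C) and per-run scaling (5C) are the published corrections.
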