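# Methods

## Detection model

A binned intra-chromosomal contact matrix holds raw counts `raw[i, j]`
(upper triangle, 0-based half-open genomic coordinates). Iterative
correction (ICE) finds per-bin weights `w` so that the balanced matrix
`B[i, j] = raw[i, j] · w_i · w_j` has equal marginals; we iterate
`w_i ← w_i / (marginal_i / mean marginal)` until the coefficient of
variation of the nonzero balanced marginals is below `tol = 1e-4`
(`max_iter = 1000`), scale weights so the mean nonzero balanced marginal is
1, and assign missing (NaN) weights to bins with zero raw marginal. The
expected profile `E(d)` is the plain per-diagonal mean of defined balanced
values (no smoothing; denominators count only pairs with both weights
defined, so chromosome edges are handled exactly).

Enriched pixels are detected HiCCUPS-style. For a tested pixel `(i, j)` and
each kernel `k ∈ {donut, lower-left, horizontal, vertical}` the local
expected rate in raw-count units is

    λ_k = E(j − i) · ( Σ_footprint B[u, v] / Σ_footprint E(|u − v|) ) / (w_i · w_j)

with both footprint sums restricted to defined cells. Kernel geometry (the
paper-trail convention of the HiCCUPS family, half-widths `p < w`):

* **donut** — Chebyshev radius in `(p, w]`, minus the width-1 row and
  column through the center;
* **lower-left** — the quadrant toward the diagonal, `du ∈ [1, w]`,
  `dv ∈ [−w, −1]`, minus its inner `p × p` corner;
* **horizontal / vertical** — bands of half-width 1 and extent `(p, w]`
  along one axis.

Defaults are `(p, w) = (4, 7)` at 5 kb and `(2, 5)` at 10 kb and coarser.
The p-value is the Poisson upper tail `P(X ≥ obs | λ_k)`. Pixels are tested
at bin distance in `[w + 1, max_loci_separation / resolution]`; pixels with
missing weights, undefined expected, or more than `max_nans_tolerated = 4`
missing footprint cells are *untested* (not zero-λ), which avoids spurious
infinite enrichment.

Per kernel, p-values are Benjamini–Hochberg corrected within geometric
lambda chunks with edges at `2^(k/3)` and all `λ < 1` pooled into an
underflow chunk; a pixel is **enriched** iff `q ≤ lambda_bin_fdr = 0.1`
under *all four* kernels.

### Implementation notes

Footprint sums are computed from summed-area tables over `tile_size` row
blocks with `kernel_w` overlap, each kernel decomposed into signed
axis-aligned rectangles; interior pixels of fully-valid tiles take a fast
path in which the expected-sum is a pure function of distance. Results are
therefore independent of the tiling up to floating-point summation order
(verified to ~1e-9 relative; the per-pixel enumeration oracle agrees to
1e-12). Identical inputs and parameters give byte-identical tables.

## Conventional baseline (per-sample)

Each sample's enriched pixels are clustered at `clustering_radius = 20 kb`
(Euclidean distance in bp on the points `(bin1·res, bin2·res)`; connected
components of the radius graph). The centroid is the member with maximal
balanced value in that sample. Centroids must pass the empirical enrichment
ratios — `obs/λ ≥ 1.75` against donut and lower-left, `≥ 1.5` against
horizontal and vertical — and singletons (clusters of one pixel) must
additionally satisfy `qvalue_max ≤ 0.02`. These thresholds mirror the
reference convention and are configurable. Sample specificity in the
conventional workflow is then assigned by exact coordinate matching of the
final calls across samples.

## Union workflow

Enriched-pixel tables of all samples — plus the MEGA map, the element-wise
sum of all samples' raw counts, re-balanced and re-profiled — are pooled
with provenance and clustered once with the same radius algorithm. For each
cluster the representative (centroid) is the distinct member coordinate
maximizing the summed balanced contacts over the cluster's contributing
sources (its samples, plus MEGA if it contributed); ties break to the
smallest `(bin1, bin2)`, and an all-missing cluster falls back to the
maximum observed count (logged). Remaining singletons survive only if (a)
one of their anchors falls inside the same-axis anchor range (`[min, max]`
bin interval, no slack by default) of a non-singleton cluster on the same
chromosome, and (b) when sample-specific, their `qvalue_max ≤ 0.02`;
non-singleton clusters pass unconditionally — in particular, the union
list deliberately does **not** re-apply the centroid enrichment ratios.

Labels are the sets of contributing biological samples; MEGA contributes
pooling, clustering and centroid signal but never labels, and MEGA-only
clusters are emitted to a side table rather than the union list. A cluster
whose members share one coordinate but span two or more samples is not a
singleton — singleton semantics concern single-sample, single-pixel
evidence. For each labeled sample the loop's origin is `hiccups` if any of
that sample's final conventional calls matches a member coordinate exactly
(both call sets derive from the same pixel tables, so coordinates are
commensurable), else `rescued`.

Design choices worth stating: pooled sums use ICE-balanced values as-is,
without per-sample depth rescaling — ICE normalizes marginals onto a
comparable scale; the two singleton filters apply conjunctively; the
anchor-sharing test uses inclusive bin-range overlap with a configurable
slack (default 0).

## Quantification

Loop windows are `2·flank/res + 1`-sided squares of balanced values
centered on the loop pixel (21×21 at 5 kb with the default 50 kb flank);
out-of-chromosome and missing-weight cells are NaN. Pileups are per-cell
means over defined cells. Loop strength is the mean of the central 3×3
block divided by the pooled mean of three 6×6 corner blocks (upper-left,
upper-right, lower-right; rows = upstream anchor increasing downward). The
lower-left corner is excluded because it lies at shorter genomic distance,
inside the loop, where the decay background is inflated; the block size is
a configurable convention. Stackups take each window's middle row and sort
descending by the mean of the middle four columns (`W//2 − 2 … W//2 + 1`).
Pairwise 1-D signal matrices are half the outer sum of the row/column
per-bin signal vectors; z-scoring uses the population (n) standard
deviation over defined cells, so output moments are exactly (0, 1).

## Synthetic cohorts

The generator draws, per sample, independent Poisson counts with mean

    M_s[i, j] = b_i · b_j · E(|i − j|) · L_s(i, j),   E(d) ∝ (1 + d)^(−α)

where `b` is lognormal per-bin coverage bias (σ = 0.2 by default) and
`L_s` multiplies in each planted loop present in sample `s` as a Gaussian
bump of height `f` and spread `σ_bins`, centered on a per-sample jittered
pixel; the mean matrix is rescaled so the expected total equals the
configured depth. Truth (base pixel, per-sample jittered pixels, presence
set, factor) and a peak track (one bin-sized interval per true anchor) are
emitted alongside. All draws derive from child streams of one root seed;
identical seeds give byte-identical cohorts. A negative-binomial
overdispersion knob exists for robustness experiments and is off by
default, matching the Poisson assumption of the detection test so that
calibration is checkable.

Default study conditions: one 25 Mb chromosome at 5 kb (5000 bins), three
samples, 1e7 expected cis contacts per sample (a deeply sequenced
experiment at this genome fraction), α = 1, 200 planted loops at 100–300 kb
anchor separation with factor 6, spread 1 bin and ±1-bin per-sample jitter
(`shared_jitter`). The `weak_rescue` preset plants sharp factor-4.6 loops
at half depth — calibrated so per-sample detections surface mostly as
sub-threshold singletons, the regime the rescue mechanism targets. The
`outlier_sample` preset makes the third sample stronger (×4/3) and more
jittered (±2 bins), the regime that separates max-single-sample from
summed representative selection. Dot calling on these cohorts caps the
search band at 2 Mb with 2.5 Mb tiles (planted loops lie well inside 1 Mb);
the package-wide defaults remain 10 Mb / 5 Mb.

What the simulator does *not* emulate: TADs and compartments (no structured
background beyond distance decay), trans contacts, read-level artifacts,
restriction-fragment effects, and replicate-level biological variability.
Passing tests on these cohorts therefore demonstrates the combinatorial and
statistical correctness of the workflow under its own model assumptions,
not performance on real chromatin.

## Numerical and degenerate-input conventions

Ties in every argmax/representative selection break lexicographically by
`(chrom, bin1, bin2, sample)` for determinism. Inter-chromosomal records
are rejected; lower-triangle input pixels are flipped on ingestion. An
all-zero matrix balances to all-missing weights (not an error); a
zero-background window yields NaN strength (not an exception); a constant
matrix z-scores to zeros with a warning. Truth matching is greedy
nearest-first by Chebyshev bin distance (tolerance 2 bins in the standard
evaluations), verified against optimal assignment on small separated
instances.

## Known limitations

* The enriched-pixel caller controls FDR within each (kernel, lambda-chunk)
  BH family. On a completely loop-free chromosome with ~2M tested pixels
  the probability that *some* extreme Poisson draw is called enriched is
  substantial (≈ 0.65 per map; 0–2 pixels out of ~1.9M tested), even though
  the false-call rate per tested pixel is ~5e-7. This is intrinsic to
  chunked BH — it bounds the expected false fraction per family, not the
  family-wise union — and matches the behavior of the reference procedure.
* ICE weights on bias-free data are flat only away from chromosome edges;
  decay truncation makes marginals position-dependent, so weight CV is
  ~1.5% centrally (Poisson marginal noise) and ~4% overall at default
  depth.
* Background loop strength is exactly 1 only where the distance-decay is
  locally flat across the window; at anchor separations below ~500 kb the
  corner blocks straddle measurably different decay regimes, so calibration
  positions are sampled at 0.5–2 Mb separation.
* A 5 Mb scoring tile at whole-chromosome scale changes results only at
  the 1e-13 level (floating-point summation order), not bit-exactly.
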