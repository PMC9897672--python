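# Methods

`tadbound` implements the quantitative core of a chromatin-topology study of
TAD-boundary establishment in early fly embryos: how strongly boundaries
insulate, which boundaries weaken when an insulator protein is removed, which
combinations of insulator proteins occupy them, which zygotic genes respond
(including enhancer hijacking into the neighboring TAD), how single-allele
3-D FISH distances shift, and how quantitative C&T coverage is normalized by
a cross-species spike-in.  Because the corresponding embryo-derived datasets
are far too large to ship, every analysis stage is driven by a synthetic-data
generator that reproduces the statistical structure the analysis assumes, so
each stage can be validated against planted ground truth.

## Synthetic contact matrices

Counts are Poisson draws around an expected matrix

    lambda(i, j) = A |i - j|^(-alpha) * prod_{b crossed} (1 - s_b),
    lambda(i, i) = A c0,

with one draw per unordered bin pair.  A boundary of strength `s` in [0, 1)
removes a fraction `s` of expected cross-boundary contacts; attenuation
composes multiplicatively across all boundaries a pair straddles, which makes
insulation monotone in `s` by construction.  A matched depletion condition
reduces each strength to `s (1 - w)`, where `w` is the per-boundary
weakening.

Defaults: a 20-Mb chromosome at 10-kb bins (2,000 bins — the working
resolution of the whole package), `alpha = 0.75`, diagonal level `c0 = 2`,
and `A = 2000` expected counts at one-bin distance.  `A` was set from a noise
budget: with the diamond windows below, the per-bin insulation track must
have noise (≈ 4 sigma of the log2 diamond mean) below the topographic
prominence threshold of 0.05 used for boundary calling, which requires
upward of ~150 expected counts per diamond cell; `A = 2000` corresponds to
roughly 1e8 intra-chromosomal read pairs on this chromosome, i.e.
deep merged-replicate Hi-C.  Poisson noise (rather than negative binomial)
is the simplest model exhibiting the needed structure; overdispersion is a
possible extension.  Matrices are assumed pre-normalized; no balancing is
implemented.

What the generator does *not* emulate: compartments, loops, replicate batch
effects, mappability artifacts, and overdispersed counts.  Recovery rates on
these matrices are therefore upper bounds on what identical settings achieve
on real embryo Hi-C.

## Insulation score and boundary calling

The insulation score at bin `i` with window `w` bins is the mean count over
the diamond of pairs straddling the boundary between bins `i - 1` and `i`
(rows `[i - w, i)`, columns `[i, i + w)`), log2-transformed and centred by
the chromosome mean of log2 diamond means (a geometric-mean normalization,
so the valid track averages exactly to zero and the score is invariant to
global count scaling).  Lower score = stronger insulation.  Bins within `w`
of a chromosome edge, or with zero diamond coverage, are masked.  The
separation score averages insulation tracks over several windows (defaults:
50 kb and 100 kb at 10-kb bins).

Boundary calling proceeds in three steps:

1. **Candidates** — local minima of the separation score with topographic
   prominence >= `delta_min` (default 0.05).
2. **Significance** — per candidate, a one-sided Mann-Whitney test that the
   distance-detrended values (observed / expected-by-distance) of the
   cross-boundary diamond are smaller than the pooled off-diagonal values of
   the two flanking within-TAD squares of the same width.  Detrending is
   essential: raw cross-boundary pairs span larger genomic distances than
   flanking within-side pairs and would look depleted under any distance
   decay, boundary or not.
3. **Multiplicity** — Benjamini-Hochberg across all candidates; calls with
   q < `q_threshold` (default 0.1) are kept.

Because candidate minima are *selected* from the same data, testing the
selected diamond on the same matrix is anti-conservative (the selection
itself drags the cross values low).  For integer-count matrices the counts
are therefore split into two independent binomial halves (p = 0.5, fixed
internal seed so calls are a deterministic function of the matrix):
candidates are selected on one half and tested on the other.  Noise-free
expected matrices are real-valued and are used directly — there selection
bias does not arise.

A called boundary's position is the left edge of its bin, i.e. the exact
TAD-partition coordinate; the "boundary region" used for peak assignment is
position ± 5 kb (half-open), a 10-kb window.  Insulation loss between
conditions is score(depletion) − score(WT) at the boundary bin: positive
loss = weakened insulation.

## Kernel-correlation differential boundary score

An idealized boundary template is built from the decay model itself: the
expected matrix for a single boundary of reference strength `s_ref = 0.5` is
detrended by pure decay, log2-transformed, and the (2r+1)-bin window centred
on the boundary (default r = 8, i.e. 17 x 17) is standardized to mean 0,
sd 1.  This self-consistent kernel replaces any published numeric template;
validation is on recovery of planted weakenings, not kernel-value identity.

A boundary's score in a condition is the Pearson correlation between the
kernel and `log2((counts + 1) / (P(s) + 1))` over the same window, where
`P(s)` is that matrix's own mean count per distance and the +1 pseudo-count
handles empty bins.  Its signal-to-noise ratio is

    snr = |mean(within-TAD quadrants) - mean(cross-boundary quadrants)|
          / sd(residuals after removing the two quadrant means).

The residual sd (not the raw window sd) is the denominator deliberately: the
raw sd is dominated by the quadrant contrast itself, which would cap snr
near 2 for any boundary regardless of data quality and make a threshold of 5
unsatisfiable.  With the residual definition, snr measures contrast over
noise and the default exclusion threshold `snr < 5` (evaluated on the WT
window) behaves as intended.

For the differential analysis the deeper matrix is first subsampled to the
shallower one's total count by seeded binomial thinning; the differential
score is score(depletion) − score(WT), so negative values mean loss of the
boundary pattern.  Boundaries are flagged at cutoffs −0.1 (lenient) and −0.2
(stringent).  Since no significance value accompanies the differential
score, results are stratified: the `top_k` most-negative scores versus a
disjoint "stable" set of the `n_stable` smallest |score| (defaults 100 and
200 at genome scale; the bundled scenario scales these to its boundary
count), with ties broken by genomic position.

## Insulator occupancy classes

Genome-wide colocalization clusters summits by single linkage at 200 bp: two
summits join whenever they lie within the radius, and chains merge
transitively (the radius is small relative to peak spacing, so chaining is
rare; the convention is declared rather than inferred).  Cluster labels —
the set of factors present — are the rows of an UpSet table.

A factor occupies a boundary iff at least one summit falls in the 10-kb
boundary region (half-open, centred on the boundary).  The resulting factor
combinations partition the boundaries; classes are compared on their
insulation-score distributions (ordered by median, strongest insulation
first) with pairwise two-sided KS tests, classes below two members being
flagged and excluded from testing.  "Peak intensity" at a boundary is the
maximum summit height of that factor in the window.

## Expression and enhancer hijacking

Differential-expression statistics are *inputs* (the DE model fit is out of
scope); the synthetic generator plants log2 fold-change effects and derives
p-values from the declared z-model `p = 2 (1 - Phi(|log2FC| / sigma))` with
`sigma` the expression noise sd, which makes null p-values uniform.  The
pipeline then applies, in order: the zygotic filter (maternally deposited
genes removed), strict DEG thresholds |log2FC| > 0.7 and FDR < 0.05 (BH
within the zygotic universe when only p-values are supplied), promoter
overlap (TSS ± 500 bp, half-open, against insulator peaks, with a Fisher
test of bound x DEG over the zygotic universe), DEG-to-boundary distance
curves with KS comparison, and hijacking candidates: up-regulated zygotic
DEGs whose TSS lies in one of the two TADs sharing a disrupted boundary.

## FISH quantification

Allele distances are a two-state mixture: with probability `pi` the allele
is in the contact state (folded normal, default mu 120 nm, sigma 90 nm),
otherwise open (zero-truncated normal, default mu 650 nm, sigma 280 nm).
Rendered stacks place one Gaussian blob per spot on an anisotropic voxel
grid (60 x 60 x 200 nm) with Poisson background.  Spot detection thresholds
the image, forms 26-connected 3-D components, drops components under 4
voxels (shot-noise guard), and takes the background-subtracted
intensity-weighted centroid in nm.  Alleles pair spots across channels
within labelled clusters, or by mutual-nearest-neighbour within 1,000 nm
when no labels exist (replacing interactive cluster selection; the radius is
configurable).  Condition summaries are the strict fractions of distances
< 250 nm and > 600 nm and two-sided KS tests between conditions.

## Spike-in normalization

Every C&T sample carries a fixed amount of exogenous-species chromatin, so
the spike-in read-count ratio calibrates per-sample tagmentation/sequencing
depth: each track is multiplied by reference_spike / sample_spike, with the
WT sample of a pair as reference.  Binding loss per reference peak is the
ratio (depletion + 1) / (WT + 1) of scaled mean coverage in summit ± 500 bp.
The generator ties a common per-sample depth factor to both the target-genome
coverage and the spike-in count, so rescaling cancels depth by construction;
peak enrichment defaults to 100x over a flat background of 2 per 100-bp bin,
matching the high on-target enrichment characteristic of the assay.

## Scenario runner and determinism

The bundled scenario (YAML-configurable, versioned schema) runs all stages
in order on one configuration: simulate, insulation tracks, boundary calls,
differential scores, occupancy, expression/hijacking, FISH, spike-in, and a
report aggregating planted-truth recovery.  All randomness derives from the
single config seed via fixed offsets or spawned sub-seeds, and all outputs
are plain text with deterministic formatting, so a rerun with the same
config and seed is byte-identical.  Default scenario conditions: 99
boundaries of strength 0.7 on the 2,000-bin chromosome, every tenth
weakened by w = 0.8; peak classes cycle through the common factor
combinations with 1-kb summit jitter and 50 background peaks per factor;
three genes per TAD with a planted +1.5 log2FC hijack gene beside each
weakened boundary, expression noise sd 0.1, 30% maternal genes; FISH
conditions with contact probabilities 0.12 (WT) and 0.31 (depleted), 400
alleles each; full C&T depletion at 60 reference peaks.

## Numerical choices and known limitations

* Strict inequalities throughout where thresholds are printed as strict
  (DEG |log2FC| > 0.7, FDR < 0.05, q < 0.1, distances < 250 / > 600 nm);
  intervals are half-open, closed on the left.
* Ties in differential stratification break by genomic position, ascending.
* Degenerate inputs are errors, not silent results: all-zero matrices,
  windows off the chromosome edge (masked in scoring, rejected in loss
  computations), empty samples, constant input to correlation.
* Two-sample KS p-values use the asymptotic Kolmogorov distribution at
  effective size n1 n2 / (n1 + n2); sample sizes in this pipeline are
  hundreds, where the asymptotic form is adequate. Two-sided by default.
* Mann-Whitney uses the tie-corrected normal approximation without
  continuity correction; Fisher is two-sided by the probability-mass method.
* The Monte-Carlo checks in the test suite use a 2,000-bin chromosome and
  20-50 seeds per property — sizes at which the planted effects are
  comfortably detectable while the whole suite stays fast.
* Boundary positions are only resolved to the bin (10 kb by default);
  sub-bin localization is out of scope, as are A/B compartments, loop
  calling, TAD interval segmentation beyond boundary positions, motif
  analysis, and read-level simulation.
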