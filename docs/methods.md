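# Methods

This note documents the models, defaults and numerical choices behind
`chromlink`, and what the synthetic-data results do and do not demonstrate
about real data.

## Read-pair processing

A proximity-ligation read may run through the bridge-linker junction between
two genomic fragments.  `trim_linker` searches both linker orientations
(`CGCGATATCTTATCTGACT`, `GTCAGATAAGATATCGCGT`) for the leftmost full copy
(exact match by default; a Hamming-mismatch allowance is configurable but
defaults to 0, since trimming specificity matters more than sensitivity at
these linker lengths) and keeps the 5' flank.  Reads with no linker pass
through unchanged but are flagged, so a caller can choose to drop or keep
them; fragments shorter than `min_fragment` (default 20 bp, a mappability
floor) are marked discarded rather than raising.  A linker at the very start
of a read leaves an empty 5' fragment and is discarded; a linker at the very
end still yields a usable 5' fragment.

Pair classification is purely geometric.  After canonical ordering
((chrom1, pos1) ≤ (chrom2, pos2)): different chromosomes → inter; span at or
above the threshold → intra; below the threshold, inward pairs (upstream
mate on +) are unligated full segments, outward pairs are self-ligations,
and same-strand pairs are kept as intra ligations because producing a short
same-strand pair requires a ligation event.  The span threshold is estimated
by histogramming intra-chromosomal spans in ~30 log-spaced bins and
returning the left edge of the earliest bin from which every later
well-populated bin (≥ 50 pairs) has all four strand-orientation fractions
within 0.05 of 0.25; requiring *persistence* rather than a single balanced
bin guards against one noisy early bin.  With under 1,000 intra pairs the
estimator falls back to 3 kb (the expected scale for a 4-bp cutter) with a
warning.

## Contact matrices

Matrices are genome-wide, symmetric, dense in memory (appropriate below a
few thousand bins) and stored on disk as a bin-table TSV plus an
upper-triangle sparse-triplet TSV.  ICE balancing iterates
`counts / outer(s, s)` on row sums until the maximum relative row-sum
deviation is below `tol` (default 1e-5, capped at 200 iterations with a
warning on non-convergence); weights are rescaled so the corrected matrix
preserves total unmasked mass.  Zero-coverage bins are always masked;
additionally the lowest-coverage `mask_low` fraction (default 2%) can be
masked.  That fractional mask exists for real-data sparsity and mappability
artifacts.  On the synthetic maps every bin is deeply and near-uniformly
covered, and rank-based masking would preferentially remove compartment-
switched bins — whose coverage is genuinely but *informatively* lower —
so the compartment workflows balance with `mask_low=0`.

The observed/expected transform divides each intra-chromosomal diagonal by
its mean corrected value over defined bins; it is exactly scale-invariant
and its per-diagonal mean is 1 by construction.  Replicate reproducibility
is the Pearson correlation of log2(1 + count) over intra-chromosomal
upper-triangle cells after coarsening to 1 Mb, the scale of whole-genome
heatmaps.

Bin self-contact (diagonal) counts are retained in matrices but excluded
from TAD internal sums: they are dominated by short-range ligation
artifacts rather than folding.

## Compartments

Per chromosome: O/E transform, Pearson correlation matrix of bin contact
profiles, then the first principal component of that correlation matrix
(column-centred, leading eigenvector of its covariance) scores each bin.
Undefined O/E cells inside the defined submatrix are set to the neutral
value 1 before correlation.  The eigenvector sign is arbitrary, so each
chromosome's track is flipped to correlate positively with a marker density
— TSS count per bin by default, active-mark peak density as an alternative —
making A (positive) the gene-dense active compartment.  A compartment change
is called only when every condition-1 replicate and every condition-2
replicate agree (A→B or B→A); bins undefined in any replicate are excluded
into their own category, and reported fractions sum to 1 over all bins.

One caveat: permutation equivariance holds for the PCA step but not for the
full track computation, because the O/E expectation is a function of genomic
distance and a bin permutation scrambles distances.

## TAD dynamics

Internal counts sum over bin pairs i < j inside a TAD (midpoint-assigned
bins, diagonal excluded); external counts over intra-chromosomal cells with
exactly one end inside.  Samples are rescaled to the mean intra-chromosomal
mass before testing, keeping values on a count-like magnitude so that the
0.5 pseudocount added before log2 (to absorb zeros) is negligible for
populated TADs.

The differential test is non-parametric: within-condition replicate log2
ratios per TAD, pooled over both conditions (internal and external handled
separately), form an empirical background of technical fold-change noise.
Each index-matched replicate pairing (condition-2 rep k vs condition-1
rep k) yields an observed log2 fold change per TAD, assigned the two-sided
rank p-value (1 + 2·min(#bg ≤ obs, #bg ≥ obs)) / (N + 1), capped at 1 — the
add-one correction keeps p in (0, 1] and conservative.  A TAD is significant
only if the internal p-value is below α (default 0.05) in *every* pairing;
this is the "both replicates" rule.  External p-values are reported
alongside but do not gate significance, since the analysis targets internal
reorganization.

σ-categories standardize the internal log2 fold changes by their mean and
standard deviation and cut at ±0.5, ±1, ±2 σ, giving seven exhaustive
categories (1 = most decreased, 7 = most increased); the edges are exposed
because no canonical values exist.  Boundary stability treats the unique
TAD start/end positions as boundaries and asks, per boundary of set 1,
whether a boundary of set 2 lies within a tolerance (default one bin,
40 kb).

## Differential gene-regulatory interactions

Bins gain the *gene region* role when a promoter-mark peak midpoint lies
within ±2 kb of an expressed gene's TSS (the ±2 kb operationalizes "the
promoter spread"; it is a package choice, configurable), and the
*regulatory region* role when a distal-mark peak midpoint lies outside every
expressed promoter window.  Candidate pairs are ordered (gene bin,
regulatory bin) pairs with distinct indices in the same TAD; replicate
counts are pooled per condition, raw (not balanced — the binomial model
needs integer sampling counts), with library totals n_i the pooled
intra-chromosomal masses.  Pairs with C1 + C2 < 10 are dropped to keep the
normal approximation sane.

The statistic is the MA-plot binomial random-sampling test described in the
README.  Two deliberate conventions: M is the standard log2 ratio (not the
halved variant sometimes printed — the z statistic is invariant to a
consistent rescaling of M and the halved form's variance algebra is
identical), and M is oriented condition 2 − condition 1 so Gain is positive.
Because p̂ is estimated from the observed A, the conditional mean reduces
exactly to log2(n2/n1) and the slope term vanishes at the conditioning
point.

Accuracy of the approximation: the delta-method conditional moments carry
O(1/C) relative error.  At the conditioning point the first-order log-biases
of M and A cancel exactly against the regression slope, so the conditional
*mean* is accurate to O(1/C²); the conditional *variance* retains an O(1/C)
term of roughly 1–2% at counts near 100, immaterial for calling at
|z| > 3.3 but resolvable by a 10⁶-draw Monte-Carlo simulation.  The
Monte-Carlo verification grid therefore uses counts ≥ 400 with matched
library totals, where both moments sit inside 3 Monte-Carlo standard
errors; depth asymmetry is verified exactly through closed-form identities
(a count ratio equal to the depth ratio gives z = 0; swapping conditions
negates z and preserves p).  Null calibration is checked on 50,000
equal-proportion binomial pairs at expected counts uniform on [20, 500]:
type-I error at α = 0.001 and a decile chi-square uniformity test.  A
decile histogram is deliberate: at n = 50,000, finer-grained tests (KS,
20 bins) have the power to resolve the count discreteness near p = 1 that
every discrete test statistic shows, which is not a calibration defect.

Gain/Loss calls apply Benjamini–Hochberg over the tested batch and require
adjusted p < 0.001 plus the matching direction of the count proportions.

## Downstream statistics

Fisher exact tests default to the one-sided "greater" alternative, the
natural direction for enrichment claims.  Mann–Whitney uses the exact null
when min(n1, n2) ≤ 8 without ties and the tie-corrected normal
approximation otherwise.  Region signal fold changes use an ε = 0.5
pseudocount.  The TF-target network is consumed as a user-supplied edge
list (database contents are version-dependent, so none is bundled);
hub degrees are total in+out degree on the induced subnetwork after
duplicate-edge collapse, sorted by degree then id.

## The synthetic system

`TruthConfig` defaults define the study conditions: 2 chromosomes × 20 Mb at
40-kb bins (500 bins each); TADs of 240–800 kb (~400 kb average) tiling each
chromosome; an A/B checkerboard in blocks of 10–25 bins; contact decay
|i−j|^(−1); within-TAD enrichment ×2 for all TADs (needed for any within-TAD
candidate structure); same-compartment affinity ×2; expected depth 2×10⁶
counts per replicate, which matches a deeply sequenced human library
(~150 M contacts) scaled to the toy genome's ~1/75 of a human genome; a constant inter-chromosomal
floor contributing ~10% of reads.  Condition 2 plants: 40 Gain and 40 Loss
promoter–enhancer pairs with a twofold effect, at 2–4 bin (80–160 kb)
separations — enhancer–promoter geometry, matching exemplar loci where
enhancers sit tens of kb from the promoter — with both ends in the same
compartment and unswitched; A→B switches on 1% of bins and B→A on 0.5%
(the asymmetry seen in differentiation data); optionally a ×2 internal
boost in a fraction of TADs (off by default; the TAD-test scenarios switch
it on).  Expression is Gaussian on the log2 scale (4 replicates, sd 0.3)
with planted |log2FC| = 2 for genes at planted pairs, analyzed by t-test
plus BH.  Condition-specific distal/open peaks appear at planted regulatory
bins with probability 0.9, plus a 5% background specificity rate and
per-replicate noise peaks that the replicate-intersection ("convincing
peaks") rule removes.

All randomness flows from one seed through named substreams, so every
output — including gzipped FASTQ bytes (mtime pinned to 0) — is
reproducible bit for bit.

What the generator does *not* emulate: genomic sequence (reads are random
letters around the planted linker), mappability and GC bias, restriction-
fragment structure, overdispersion beyond Poisson, sub-compartments, loops
at TAD corners, and trans-chromosomal structure beyond a constant floor.
Passing recovery tests therefore demonstrate the correctness and internal
calibration of the statistics under their own model assumptions — not
robustness to the systematic biases of real libraries, which is what ICE
masking, the convincing-peak rule and the count filter are there to absorb.

## Evaluation conventions

Planted-recovery metrics: recall is the fraction of planted gene-regulatory
pairs called with the correct direction; precision is measured against
*generator truth* — every matrix cell whose expected counts genuinely
differ between conditions, which includes cells altered by planted
compartment switches.  A call on such a cell is a true detection of a real
(if unplanted) difference, not a false positive.  The planted A→B switch
fraction is compared on the all-bins denominator that the change
classifier reports.

## Problem sizes

The default test suite and the reproduction script run the full toy system
(1,000 bins, four matrices, ~1,100 candidate pairs), 50,000 null pairs for
calibration, 12 × 10⁶ Monte-Carlo draws for the moment check, and 20,000
simulated read pairs — about 15 s for the suite and 5 s for the script on
one CPU.  These sizes were chosen so the statistics have the resolution the
checks need (e.g. Monte-Carlo standard errors small enough to be
meaningful) while remaining interactive.
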