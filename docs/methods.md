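# Methods

## The model

Genes on a chromosome arm are ordered by their annotated transcription start
coordinate.  The arm is partitioned into contiguous *coexpression segments*:
runs of adjacent genes assumed to share a regional, tissue-dependent
expression level.  For gene *i* in segment *S* and tissue *t*,

    x_it = s_St + e_it

where the segment effect s_St is drawn from f, a two-component normal
mixture (phi, mu1, sigma1, mu2, sigma2), and the gene-specific deviation
e_it is drawn from g = N(0, sigma^2).  The mixture captures the bimodal
shape of pooled log-scale expression (a low "off/low" mode and a high
"expressed" mode); the deviation absorbs private regulation and measurement
noise.  Tissues and segments are independent; within a segment and tissue,
genes are exchangeable given the segment effect.

The probability of one segment's data in one tissue integrates the shared
effect out:

    P(x_1..x_n) = ∫ Π_i N(x_i − s; 0, sigma^2) f(s) ds

By normal–normal conjugacy this has a closed form per mixture component.
With sufficient statistics n, Σx, Σx² and component (mu, tau):

    A = n/sigma² + 1/tau²,  B = Σx/sigma² + mu/tau²,  C = Σx²/sigma² + mu²/tau²
    log M = −(n/2)·log(2π sigma²) − ½·log(tau²·A) − ½·(C − B²/A)

and the two components are combined in log space by a max-shifted
exponential sum.  An adaptive-quadrature evaluation of the defining
integral is kept in the package purely as a test oracle; the test suite
verifies closed form vs quadrature to 1e−8 absolute on randomized
instances.

Model selection uses a BIC-style score (lower is better):

    score = −2 ln P(x | θ) + K ln n

K counts one parameter per segment plus the free distribution parameters.
Because f is fitted once to the pooled values and then fixed, only sigma is
free, so K = (#segments) + 1 by default; the count is configurable
(`--k-dist-params`) since any constant offset cancels in every move
comparison at fixed parameters.  n is the number of data points on the arm
(genes × tissues); each arm is analyzed separately, so the per-arm n is the
self-consistent choice.

## Fitting f

f is estimated by a hand-written 1-D EM on the pooled values over all genes
and tissues (two components; responsibilities, weighted moment updates, a
variance floor of (1e−4)²).  Components are initialized at the 25th/75th
percentiles with the pooled variance; five restarts jitter the means and
the best log-likelihood wins; components are reported in increasing-mean
order.  Convergence is a relative log-likelihood change below 1e−8 (default)
with a 500-iteration cap; the observed-data log-likelihood trace is exposed
and tested to be non-decreasing.  The fit agrees with an independent
general-purpose mixture implementation (scikit-learn) in a cross-check
test.  Note that fitting f to *observed* values folds the deviation
variance into the component variances (observed component variance is
sigma_k² + sigma²); this is the intended approximation — f is a description
of the pooled expression distribution, not a deconvolution.

## Searching segmentation space

At fixed f and sigma the score is additive over segments, so the cost
−2·(segment log-marginal summed over tissues) of every candidate segment
[i, j) is precomputed from per-tissue prefix sums — O(G²·T) once per
(arm, sigma) — and shared by all replicates.  Three moves are considered
from a current segmentation: *split* a multigenic segment at any internal
position, *merge* two adjacent segments, and *shift* a boundary to any
position within its two flanking segments (leaving at least one gene in
each).  Every move is evaluated each iteration (O(1) table lookups; an
explicit test confirms incremental deltas equal full rescoring to 1e−9) and
the single best strictly-improving move is applied; ties break by a fixed
enumeration order (splits by segment then position, then merges by
boundary, then shifts by boundary then position).  Descent stops when no
move improves the score by more than 1e−9.

Because descent is strictly downhill, it is restarted from many random
initial segmentations ("replicates", default 1024; segment lengths
geometric with mean 2 — the mean has little effect on the converged
patterns).  Per-replicate RNG streams are spawned from a master seed
(SeedSequence children), making every run bit-reproducible.  The median
replicate score (best/mean selectable) is the objective assigned to the
current sigma.

sigma is trained by 1-D Nelder–Mead on log(sigma) (positivity for free),
with simplex tolerance 1e−3 on log-sigma (~0.1% relative).  Every objective
evaluation reuses the *same* replicate seed streams (common random
numbers), so the objective is a deterministic, nearly smooth function of
sigma.  The reported result is the best-scoring single segmentation found
at the best-scoring sigma.  sigma is floored at 1e−4 (expression units)
everywhere a likelihood is evaluated, preventing divergence.

A dynamic-programming solver computes the exact global optimum in O(G²)
table lookups (valid because the score is additive with one ln n penalty
per segment).  It serves as the oracle for the greedy search — on random
12-gene instances DP equals exhaustive enumeration of all 2¹¹
segmentations, and greedy-with-replicates attains the DP score — and is
exposed as `--exact`, where it replaces the replicate search inside sigma
training.

## The simulator

`simulate_dataset` generates one arm exactly under the model: geometric
segment lengths (mean 2) truncated at the arm end, an f-draw per (segment,
tissue), a g-draw per (gene, tissue).  Defaults are phi = 0.4, components
N(3.5, 1.2²) and N(7.5, 1.8²), sigma = 0.6 — a realistic shape for
normalized log-scale microarray data pooled over tissues.  The
heteroscedastic variant draws an independent sigma for every (segment,
tissue) effect from a log-normal with median sigma and geometric SD 1.5
(positivity with symmetric multiplicative spread).  The simulator
reproduces the model's assumptions and nothing else: no probe-level noise,
batch effects, replicate structure, missing values, or correlated tissues.
Passing recovery tests therefore demonstrates correctness of the estimation
machinery under the model, not robustness to real-data violations of it.

Recovery is scored by internal-boundary precision/recall/F1 (vacuous sides
count as 1), an exact-match flag, and the Rand index of the induced gene
partitions.

## Scale and identifiability

The test suite establishes, via the DP oracle, that greedy descent with
replicates reliably reaches the global BIC optimum.  Whether that optimum
*is* the generating truth depends on data scale: with 27 tissues (the
reference tissue count; suite runs at 300 and 2,000 genes) recovery is
exact and trained sigma lands within sampling error of the truth (relative
SD roughly 1%, so the suite's bound is 4% ≈ 3.6 SDs).  With only 8 tissues,
two adjacent segments occasionally draw similar effects in every tissue,
and the globally optimal model then genuinely merges them — one test runs
this 8-tissue configuration end-to-end and documents the resulting
near-misses (boundary F1 ≈ 0.99, sigma errors up to ~4%).  This is an
information limit of the small-tissue regime, not a search failure.

Problem sizes used by the default suite and acceptance script (5 datasets
of 300 genes with 8 or 27 tissues, 32–64 replicates, 12-gene exhaustive
instances) are the package's chosen desk-scale study conditions; the CLI
defaults (`validate`: 40 datasets, 2000 genes, 27 tissues, 512 replicates)
reproduce the full-scale experiment.

## Downstream statistics

- Segment profiles: a segment's value in a tissue is the mean of its
  genes' values; the across-tissue mean and sample SD place it on the
  housekeeping-like vs tissue-restricted axis.  Segments with ≥ 3 genes are
  classified; the top quartile by SD (ties at the cutoff included) is
  tissue-restricted; "expressed in tissue t" means strictly above the
  dataset-wide median value; exactly one such tissue = single-tissue
  restricted.
- Intergenic regions are start-to-start between adjacent genes (a tied
  start yields a zero-length region, kept so n genes always give n−1
  regions); intersegment regions are the intergenic regions at segment
  boundaries.  Length comparison uses the two-sample KS test.
- Orientation of an adjacent pair (ordered by start): head-to-head =
  divergent (− then +), tail-to-tail = convergent (+ then −); classes are
  compared by a 2×3 chi-squared test without continuity correction.
- Peak enrichment: peaks per kilobase in two region sets (a peak counts
  once per set on ≥ 1 bp overlap; interval queries via an interval tree and
  verified against a quadratic brute-force oracle), ratio of densities, and
  a Fisher exact test on [peak count, non-peak count] rows, where non-peaks
  = (region bases − count × mean peak length)/mean peak length, i.e. the
  remaining bases in peak-sized units.  The literal reading of the
  alternative formula ((bases − count)/mean length) is available behind a
  flag.  Optional masking removes peaks overlapping fixed-width windows
  centered on interaction-domain boundaries.  Batch runs over a peak-set
  family apply Bonferroni correction.  A calibration test confirms the p
  value is super-uniform under uniformly placed peaks.
- Endpoint sharing: each intergenic region is flagged as segment endpoint
  and/or domain endpoint (a domain edge falling in [begin, end) of the
  region); Fisher exact on the 2×2 of the four combinations, plus the
  fraction of domain endpoints that are segment endpoints.
- Shuffled segmentations permute the segment-length list (gene order
  preserved) and resample until no internal boundary coincides with the
  original; uniformity over the valid permutation set is property-tested.
- Term enrichment: per multigenic segment, each term present is tested by
  the hypergeometric upper tail against the full gene list, Bonferroni
  corrected within the segment; significant terms carried by a single gene
  in the segment are discarded; the count of enriched segments is compared
  against pooled shuffled segmentations by Fisher exact.
- All Fisher tests are two-sided (the convention adopted throughout).

## Other conventions and edge cases

- Coordinates are 0-based half-open internally; BED is read as-is, GFF3
  converted on read.  The transcription start taken from BED6/GFF3 is the
  strand-appropriate edge (left edge for +, right edge for −).
- Ties in gene start order break lexicographically by gene id; matrix genes
  without annotation are dropped with a warning, annotation without matrix
  genes is ignored.
- Replicate QC keeps a tissue only if every pair of its biological
  replicates has Pearson r ≥ 0.98 across genes; a zero-variance replicate
  (undefined correlation) drops the tissue with a warning.  Kept replicates
  are averaged per gene and tissue.
- Expression input is assumed already normalized (e.g. RMA); the TSV
  reader/writer round-trips float64 bit-exactly (17 significant digits,
  round-trip parser).
- `DeviationParams` accepts sigma = 0 so the simulator can express its
  zero-noise limit; every likelihood path enforces the 1e−4 floor.

## Known limitations

- f and g are shared across tissues and (for f) across the genome; there is
  no tissue-specific or segment-class-specific parameterization.
- The mixture is fixed at two components.
- Exact DP is quadratic in gene count — practical to a few thousand genes,
  but the greedy search is the intended tool at scale.
- The simulator's independence assumptions (tissues, segments) mean the
  recovery guarantees say nothing about spatially correlated noise or
  shared batch structure in real data.
- Term enrichment uses a flat gene→term map (GO-Slim style); no ontology
  propagation.
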