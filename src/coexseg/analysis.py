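"""Downstream characterization of a segmentation.

Segment expression profiles and their housekeeping-like / tissue-restricted
classification, intergenic-length comparison (Kolmogorov-Smirnov), adjacent
gene-pair orientation tests (2x3 chi-squared), interval-annotation enrichment
for ChIP peaks (peaks per kilobase, Fisher exact, with optional masking of
peaks near interaction-domain boundaries), endpoint sharing between segments
and physical interaction domains, shuffled-segmentation null patterns, and
per-segment term enrichment (hypergeometric).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .data_io import ExpressionMatrix, IntervalSet
from .model import Segmentation

log = logging.getLogger("coexseg")

__all__ = [
    "SegmentProfile",
    "OrientationResult",
    "PeakEnrichment",
    "TermEnrichmentResult",
    "segment_profiles",
    "classify_segments",
    "compare_intergenic_lengths",
    "classify_pair_orientation",
    "orientation_test",
    "endpoint_sharing_test",
    "peak_enrichment",
    "peak_enrichment_batch",
    "shuffle_segmentation",
    "term_enrichment",
]

ORIENTATIONS = ("same", "head-to-head", "tail-to-tail")


# ---------------------------------------------------------------------------
# Segment profiles and classification
# ---------------------------------------------------------------------------

@dataclass
class SegmentProfile:
    """Across-tissue expression summary of one segment.

    The segment's value in a tissue is the mean of its genes' values; the
    across-tissue mean and (sample) SD of those values position the segment
    on the housekeeping-like vs tissue-restricted axis.
    """

    index: int
    n_genes: int
    per_tissue: np.ndarray
    mean: float
    sd: float
    klass: str = "unclassified"
    restricted_tissues: frozenset[str] = frozenset()


def segment_profiles(seg: Segmentation, matrix: ExpressionMatrix) -> list[SegmentProfile]:
    """Per-segment per-tissue means, then across-tissue mean and sample SD."""
    if seg.n_genes != matrix.n_genes:
        raise ValueError("segmentation does not match matrix gene count")
    b = seg.boundaries()
    out = []
    for k, (i, j) in enumerate(zip(b[:-1], b[1:])):
        per_tissue = matrix.values[i:j].mean(axis=0)
        sd = float(np.std(per_tissue, ddof=1)) if matrix.n_tissues > 1 else 0.0
        out.append(SegmentProfile(k, int(j - i), per_tissue, float(per_tissue.mean()), sd))
    return out


def classify_segments(
    profiles: Sequence[SegmentProfile],
    dataset_median: float,
    min_genes: int = 3,
) -> list[SegmentProfile]:
    """Classify eligible segments by across-tissue variability.

    Only segments with >= ``min_genes`` genes are classified.  Those in the
    top quartile of across-tissue SD (ties at the cutoff included) are
    tissue-restricted candidates; the rest are housekeeping-like.
    ``restricted_tissues`` lists the tissues where the segment value strictly
    exceeds the dataset-wide median gene expression; a candidate with exactly
    one such tissue is single-tissue restricted.
    """
    eligible = [p for p in profiles if p.n_genes >= min_genes]
    if len(eligible) < 4:
        raise ValueError(
            f"quartile undefined: only {len(eligible)} segments with >= {min_genes} genes"
        )
    cutoff = float(np.quantile([p.sd for p in eligible], 0.75))
    for p in profiles:
        if p.n_genes < min_genes:
            p.klass = "unclassified"
            p.restricted_tissues = frozenset()
            continue
        p.klass = "tissue-restricted" if p.sd >= cutoff else "housekeeping-like"
        p.restricted_tissues = frozenset(
            str(t) for t in np.nonzero(p.per_tissue > dataset_median)[0]
        )
    return list(profiles)


def single_tissue_restricted(profiles: Sequence[SegmentProfile]) -> list[SegmentProfile]:
    return [p for p in profiles if p.klass == "tissue-restricted" and len(p.restricted_tissues) == 1]


# ---------------------------------------------------------------------------
# Intergenic lengths and gene orientation
# ---------------------------------------------------------------------------

def compare_intergenic_lengths(within, between) -> tuple[float, float]:
    """Two-sample KS test of intra-segment vs intersegment region lengths."""
    within = np.asarray(within, dtype=float)
    between = np.asarray(between, dtype=float)
    if within.size == 0 or between.size == 0:
        raise ValueError("both length samples must be non-empty")
    res = stats.ks_2samp(within, between, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def classify_pair_orientation(strand_upstream: str, strand_downstream: str) -> str | None:
    """Orientation of an adjacent gene pair (ordered by start coordinate).

    Head-to-head: divergent starts (upstream -, downstream +); tail-to-tail:
    convergent (+ then -); otherwise same orientation.  Returns None when a
    strand is undefined.
    """
    if strand_upstream not in "+-" or strand_downstream not in "+-":
        return None
    if strand_upstream == strand_downstream:
        return "same"
    if strand_upstream == "-":
        return "head-to-head"
    return "tail-to-tail"


@dataclass
class OrientationResult:
    counts: dict[str, dict[str, int]]
    chi2: float
    pvalue: float
    dof: int
    n_excluded: int
    compared: tuple[str, str]


def orientation_test(
    pairs: Sequence[tuple[str, str]],
    classes: Sequence[str],
    compare: tuple[str, str],
) -> OrientationResult:
    """3-way orientation counts per pair class and a 2x3 chi-squared test.

    ``pairs`` are (upstream strand, downstream strand) for adjacent gene
    pairs; ``classes`` assigns each pair a category (e.g. within-two-gene
    segment / within-longer-segment / intersegment).  Pairs with undefined
    strand are excluded and counted.  The chi-squared test compares the two
    requested classes (df = 2, no continuity correction).
    """
    if len(pairs) != len(classes):
        raise ValueError("pairs and classes must have equal length")
    counts: dict[str, dict[str, int]] = {}
    n_excluded = 0
    for (up, down), cls in zip(pairs, classes):
        orient = classify_pair_orientation(up, down)
        if orient is None:
            n_excluded += 1
            continue
        row = counts.setdefault(cls, {o: 0 for o in ORIENTATIONS})
        row[orient] += 1
    if n_excluded:
        log.warning("%d gene pairs with undefined strand excluded", n_excluded)
    for cls in compare:
        if cls not in counts:
            raise ValueError(f"no pairs in class {cls!r}")
    table = np.array([[counts[c][o] for o in ORIENTATIONS] for c in compare])
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return OrientationResult(counts, float(chi2), float(p), int(dof), n_excluded, tuple(compare))


# ---------------------------------------------------------------------------
# Endpoint sharing and peak enrichment
# ---------------------------------------------------------------------------

def endpoint_sharing_test(
    seg_endpoint: Sequence[bool], domain_endpoint: Sequence[bool]
) -> tuple[np.ndarray, float, float]:
    """Fisher exact test of segment vs interaction-domain endpoint sharing.

    Each intergenic region is flagged as segment endpoint and/or domain
    endpoint; the 2x2 table counts [both, segment-only; domain-only,
    neither].  Also returns the fraction of domain endpoints that are segment
    endpoints.
    """
    s = np.asarray(seg_endpoint, dtype=bool)
    d = np.asarray(domain_endpoint, dtype=bool)
    if s.shape != d.shape:
        raise ValueError("flag arrays must have equal length")
    table = np.array(
        [
            [int(np.sum(s & d)), int(np.sum(s & ~d))],
            [int(np.sum(~s & d)), int(np.sum(~s & ~d))],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    n_dom = table[0, 0] + table[1, 0]
    shared = table[0, 0] / n_dom if n_dom else float("nan")
    return table, float(p), shared


def _region_trees(regions: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for arm, b, e in regions:
        if e > b:
            trees.setdefault(arm, IntervalTree()).addi(b, e)
    return trees


def _count_overlapping(regions: IntervalSet, peaks: IntervalSet) -> int:
    """Number of peaks overlapping >= 1 bp of the region set (each peak once)."""
    trees = _region_trees(regions)
    n = 0
    for arm, b, e in peaks:
        t = trees.get(arm)
        if t is not None and t.overlaps(b, e):
            n += 1
    return n


def _mask_peaks(peaks: IntervalSet, mask: IntervalSet | None) -> IntervalSet:
    if mask is None:
        return peaks
    trees = _region_trees(mask)
    kept = [
        (arm, b, e)
        for arm, b, e in peaks
        if not (trees.get(arm) is not None and trees[arm].overlaps(b, e))
    ]
    return IntervalSet(kept, label=peaks.label)


@dataclass
class PeakEnrichment:
    """Peaks-per-kilobase comparison of two region sets."""

    count_a: int
    count_b: int
    density_a: float
    density_b: float
    enrichment: float
    table: np.ndarray
    pvalue: float
    n_peaks_used: int


def peak_enrichment(
    regions_a: IntervalSet,
    regions_b: IntervalSet,
    peaks: IntervalSet,
    mask: IntervalSet | None = None,
    literal_nonpeaks: bool = False,
) -> PeakEnrichment:
    """Peak density (peaks/kb) in two region sets and a Fisher exact test.

    Peaks overlapping the optional ``mask`` windows are removed first.  A
    peak counts once per region set if it overlaps any of its regions by at
    least 1 bp.  The Fisher 2x2 rows are [peak count, non-peak count] where
    the non-peak count expresses the remaining bases in peak-sized units:
    (region bases - count x mean peak length) / mean peak length, rounded
    (``literal_nonpeaks`` switches to (bases - count) / mean length).
    """
    used = _mask_peaks(peaks, mask)
    bases_a, bases_b = regions_a.total_bases, regions_b.total_bases
    if bases_a == 0 or bases_b == 0:
        raise ValueError("region sets must have positive total length")
    count_a = _count_overlapping(regions_a, used)
    count_b = _count_overlapping(regions_b, used)
    density_a = count_a / (bases_a / 1000.0)
    density_b = count_b / (bases_b / 1000.0)
    if count_a == 0 and count_b == 0:
        log.warning("no peaks overlap either region set; enrichment undefined")
        enrichment = float("nan")
    else:
        enrichment = density_a / density_b if density_b > 0 else float("inf")
    mean_len = float(np.mean(used.lengths())) if len(used) else float("nan")

    def non_peaks(bases: int, count: int) -> int:
        if not math.isfinite(mean_len) or mean_len <= 0:
            return 0
        if literal_nonpeaks:
            v = (bases - count) / mean_len
        else:
            v = (bases - count * mean_len) / mean_len
        return max(int(round(v)), 0)

    table = np.array(
        [
            [count_a, non_peaks(bases_a, count_a)],
            [count_b, non_peaks(bases_b, count_b)],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return PeakEnrichment(
        count_a, count_b, density_a, density_b, enrichment, table, float(p), len(used)
    )


def peak_enrichment_batch(
    regions_a: IntervalSet,
    regions_b: IntervalSet,
    peak_sets: Mapping[str, IntervalSet],
    mask: IntervalSet | None = None,
    literal_nonpeaks: bool = False,
) -> dict[str, tuple[PeakEnrichment, float]]:
    """Enrichment for a family of peak sets with Bonferroni-corrected p-values."""
    m = len(peak_sets)
    out = {}
    for name, peaks in peak_sets.items():
        res = peak_enrichment(regions_a, regions_b, peaks, mask, literal_nonpeaks)
        out[name] = (res, min(res.pvalue * m, 1.0))
    return out


# ---------------------------------------------------------------------------
# Shuffled segmentations and term enrichment
# ---------------------------------------------------------------------------

def shuffle_segmentation(
    seg: Segmentation, rng: np.random.Generator | int | None = None, max_tries: int = 1000
) -> Segmentation:
    """Random permutation of the segment lengths sharing no internal boundary.

    Gene order is preserved; the multiset of lengths is preserved; candidate
    permutations are resampled until the internal boundary set is disjoint
    from the original.  Raises when no valid shuffle is found in
    ``max_tries`` (e.g. all lengths equal).
    """
    if seg.n_segments < 2:
        raise ValueError("need at least 2 segments to shuffle")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    original = seg.internal_boundaries()
    lengths = np.asarray(seg.lengths)
    for _ in range(max_tries):
        perm = rng.permutation(lengths)
        cand = Segmentation(seg.arm_id, tuple(int(v) for v in perm))
        if not (cand.internal_boundaries() & original):
            return cand
    raise RuntimeError(
        f"no boundary-disjoint permutation of lengths found in {max_tries} tries"
    )


@dataclass
class TermEnrichmentResult:
    """Per-segment enriched terms and the comparison against shuffled nulls."""

    tests: list[dict]
    significant: list[dict]
    n_enriched_segments: int
    n_multigenic_segments: int
    shuffled_enriched: int
    shuffled_total: int
    fisher_p: float


def _segment_term_tests(
    seg: Segmentation,
    genes: Sequence[str],
    gene_terms: Mapping[str, set],
    alpha: float,
) -> tuple[list[dict], list[dict]]:
    n_genes = len(genes)
    term_totals: dict[str, int] = {}
    for g in genes:
        for t in gene_terms.get(g, ()):
            term_totals[t] = term_totals.get(t, 0) + 1
    b = seg.boundaries()
    tests, significant = [], []
    for k, (i, j) in enumerate(zip(b[:-1], b[1:])):
        if j - i < 2:
            continue
        seg_genes = genes[i:j]
        seg_terms: dict[str, int] = {}
        for g in seg_genes:
            for t in gene_terms.get(g, ()):
                seg_terms[t] = seg_terms.get(t, 0) + 1
        n_tests = len(seg_terms)
        for term, k_hits in sorted(seg_terms.items()):
            K = term_totals[term]
            p_raw = float(stats.hypergeom.sf(k_hits - 1, n_genes, K, j - i))
            p_corr = min(p_raw * n_tests, 1.0)
            rec = {
                "segment": k,
                "term": term,
                "n_genes": int(j - i),
                "k": k_hits,
                "K": K,
                "p_raw": p_raw,
                "p_bonferroni": p_corr,
            }
            tests.append(rec)
            # the one-gene-carrier rule: a term carried by a single gene in
            # the segment is never reported as a significant segment term
            if p_corr < alpha and k_hits >= 2:
                significant.append(rec)
    return tests, significant


def term_enrichment(
    seg: Segmentation,
    genes: Sequence[str],
    gene_terms: Mapping[str, set],
    alpha: float = 0.05,
    n_shuffles: int = 10,
    rng: np.random.Generator | int | None = None,
) -> TermEnrichmentResult:
    """Hypergeometric term enrichment per multigenic segment, vs shuffled nulls.

    Each term present in a segment is tested against the genome background
    (all genes supplied), Bonferroni-corrected within the segment.  Segments
    where only one gene carries the term are removed from the significant
    list.  The count of segments with >= 1 enriched term is compared with the
    pooled count over ``n_shuffles`` shuffled segmentations by Fisher exact.
    """
    if not gene_terms:
        raise ValueError("empty gene->term map")
    if len(genes) != seg.n_genes:
        raise ValueError("gene list does not match segmentation")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tests, significant = _segment_term_tests(seg, genes, gene_terms, alpha)
    enriched_segments = {rec["segment"] for rec in significant}
    n_multi = sum(1 for v in seg.lengths if v >= 2)

    shuf_enriched = 0
    shuf_total = 0
    for _ in range(n_shuffles):
        shuf = shuffle_segmentation(seg, rng)
        _, sig = _segment_term_tests(shuf, genes, gene_terms, alpha)
        shuf_enriched += len({rec["segment"] for rec in sig})
        shuf_total += sum(1 for v in shuf.lengths if v >= 2)
    table = [
        [len(enriched_segments), n_multi - len(enriched_segments)],
        [shuf_enriched, shuf_total - shuf_enriched],
    ]
    _, fisher_p = stats.fisher_exact(np.array(table), alternative="two-sided")
    return TermEnrichmentResult(
        tests,
        significant,
        len(enriched_segments),
        n_multi,
        shuf_enriched,
        shuf_total,
        float(fisher_p),
    )
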