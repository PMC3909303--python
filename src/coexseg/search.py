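"""Search for the best-scoring segmentation of a chromosome arm.

The score surface is explored by greedy descent over three move types —
split, merge and shift of a boundary — from many random initial
segmentations ("replicates", 1024 by default), each descent running until no
move improves the BIC score.  The median replicate score serves as the
objective for a 1-D Nelder-Mead (simplex) search over the gene-deviation
parameter sigma; f stays fixed throughout.  An exact dynamic-programming
solver provides the global optimum for small arms.

Because the log-likelihood is additive over segments, the cost of every
candidate segment [i, j) can be precomputed once per (arm, sigma) from prefix
sums; a greedy iteration then evaluates every possible move with O(1) table
lookups, which is numerically identical to rescoring the touched segments
from scratch.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .data_io import ExpressionMatrix
from .model import (
    SIGMA_FLOOR,
    DeviationParams,
    MixtureParams,
    ScoredSegmentation,
    Segmentation,
    _component_log_marginal,
)

log = logging.getLogger("coexseg")

__all__ = [
    "Move",
    "ReplicateResult",
    "SegmentScorer",
    "SigmaFit",
    "random_segmentation",
    "enumerate_moves",
    "apply_move",
    "invert_move",
    "greedy_descent",
    "run_replicates",
    "aggregate_scores",
    "train_sigma",
    "dp_optimal_segmentation",
    "replicate_agreement",
]

#: score-improvement threshold below which descent terminates
IMPROVEMENT_EPS = 1e-9


# ---------------------------------------------------------------------------
# Segment cost table
# ---------------------------------------------------------------------------

class SegmentScorer:
    """Per-arm table of segment costs at fixed f and sigma.

    ``cost[i, j]`` is -2 x (log marginal likelihood of genes [i, j) summed
    over tissues); a segmentation's score is the sum of its segments' costs
    plus ``K ln n``.  Built once per (arm, sigma) and shared by every
    replicate descent and by the DP solver.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        f: MixtureParams,
        g: DeviationParams,
        n_free_dist_params: int = 1,
    ):
        if g.sigma < SIGMA_FLOOR:
            raise ValueError(f"g.sigma = {g.sigma} below likelihood floor {SIGMA_FLOOR}")
        self.matrix = matrix
        self.f = f
        self.g = g
        self.n_free_dist_params = int(n_free_dist_params)
        G, T = matrix.n_genes, matrix.n_tissues
        self.n_genes = G
        self.n_data = G * T
        if self.n_data < 2:
            raise ValueError("arm must contain at least 2 data points")
        self.lnN = math.log(self.n_data)

        X = matrix.values
        p1 = np.vstack([np.zeros((1, T)), np.cumsum(X, axis=0)])
        p2 = np.vstack([np.zeros((1, T)), np.cumsum(X * X, axis=0)])
        idx = np.arange(G + 1)
        m = (idx[None, :] - idx[:, None]).astype(float)  # segment sizes j - i
        acc = np.zeros((G + 1, G + 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            lw1 = np.log(f.phi) if f.phi > 0 else -np.inf
            lw2 = np.log1p(-f.phi) if f.phi < 1 else -np.inf
            for t in range(T):
                s1 = p1[None, :, t] - p1[:, None, t]
                s2 = p2[None, :, t] - p2[:, None, t]
                l1 = _component_log_marginal(m, s1, s2, f.mu1, f.sigma1, g.sigma)
                l2 = _component_log_marginal(m, s1, s2, f.mu2, f.sigma2, g.sigma)
                acc += np.logaddexp(lw1 + l1, lw2 + l2)
        cost = -2.0 * acc
        cost[m <= 0] = np.inf  # only i < j is a segment
        self.cost = cost

    def loglik(self, seg: Segmentation) -> float:
        b = seg.boundaries()
        return -0.5 * float(np.sum(self.cost[b[:-1], b[1:]]))

    def score(self, seg: Segmentation) -> float:
        K = seg.n_segments + self.n_free_dist_params
        return -2.0 * self.loglik(seg) + K * self.lnN

    def scored(self, seg: Segmentation) -> ScoredSegmentation:
        ll = self.loglik(seg)
        K = seg.n_segments + self.n_free_dist_params
        return ScoredSegmentation(seg, ll, K, self.n_data, -2.0 * ll + K * self.lnN)


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Move:
    """A segmentation move.

    split: ``location`` = segment index, ``detail`` = absolute split position.
    merge: ``location`` = boundary index (merges segments k and k+1).
    shift: ``location`` = boundary index, ``detail`` = new absolute position.
    """

    kind: str
    location: int
    detail: int | None = None


def enumerate_moves(seg: Segmentation) -> list[Move]:
    """All distinct moves, in the canonical (deterministic) order.

    Splits by segment index then position; merges by boundary index; shifts
    by boundary index then new position.  A shift may reposition a boundary
    anywhere within its two flanking segments, as long as each keeps a gene.
    """
    b = seg.boundaries()
    S = seg.n_segments
    moves: list[Move] = []
    for k in range(S):
        for p in range(b[k] + 1, b[k + 1]):
            moves.append(Move("split", k, int(p)))
    for k in range(S - 1):
        moves.append(Move("merge", k))
    for k in range(S - 1):
        cur = b[k + 1]
        for p in range(b[k] + 1, b[k + 2]):
            if p != cur:
                moves.append(Move("shift", k, int(p)))
    return moves


def apply_move(seg: Segmentation, move: Move) -> Segmentation:
    b = list(seg.boundaries())
    if move.kind == "split":
        k, p = move.location, move.detail
        if not b[k] < p < b[k + 1]:
            raise ValueError(f"invalid split of segment {k} at {p}")
        b.insert(k + 1, p)
    elif move.kind == "merge":
        k = move.location
        if not 0 <= k < seg.n_segments - 1:
            raise ValueError(f"invalid merge at boundary {k}")
        del b[k + 1]
    elif move.kind == "shift":
        k, p = move.location, move.detail
        if not (0 <= k < seg.n_segments - 1 and b[k] < p < b[k + 2] and p != b[k + 1]):
            raise ValueError(f"invalid shift of boundary {k} to {p}")
        b[k + 1] = p
    else:
        raise ValueError(f"unknown move kind {move.kind!r}")
    lengths = tuple(int(j - i) for i, j in zip(b[:-1], b[1:]))
    return Segmentation(seg.arm_id, lengths)


def invert_move(seg: Segmentation, move: Move) -> Move:
    """The move that undoes ``move`` when applied to ``apply_move(seg, move)``."""
    b = seg.boundaries()
    if move.kind == "split":
        return Move("merge", move.location)
    if move.kind == "merge":
        return Move("split", move.location, int(b[move.location + 1]))
    if move.kind == "shift":
        return Move("shift", move.location, int(b[move.location + 1]))
    raise ValueError(f"unknown move kind {move.kind!r}")


# ---------------------------------------------------------------------------
# Random initial segmentations
# ---------------------------------------------------------------------------

def random_segmentation(
    n_genes: int,
    mean_len: float = 2.0,
    rng: np.random.Generator | int | None = None,
    arm_id: str = "arm",
) -> Segmentation:
    """Segment lengths drawn iid from a geometric law with the given mean.

    Lengths on {1, 2, ...} with success probability 1/mean_len are drawn
    until the arm is covered; the final segment is truncated to fit exactly.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if mean_len < 1:
        raise ValueError("mean_len must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p = 1.0 / mean_len
    lengths: list[int] = []
    remaining = n_genes
    while remaining > 0:
        batch = rng.geometric(p, size=max(8, int(1 + 2 * remaining * p)))
        for v in batch:
            v = int(min(v, remaining))
            lengths.append(v)
            remaining -= v
            if remaining == 0:
                break
    return Segmentation(arm_id, tuple(lengths))


# ---------------------------------------------------------------------------
# Greedy descent
# ---------------------------------------------------------------------------

@dataclass
class ReplicateResult:
    """One greedy descent: its seed, final local optimum and iteration count."""

    seed: int
    final: ScoredSegmentation
    n_iterations: int
    score_trace: list[float] | None = None
    segmentation_trace: list[Segmentation] | None = None


def _move_deltas(B: np.ndarray, cost: np.ndarray, lnN: float, G: int):
    """Score change of every move, concatenated in canonical move order.

    Returns (deltas, n_splits, n_merges, split positions p, containing segment
    of p, shift boundary indices jj, shift positions pp, lexsort order).
    """
    S = len(B) - 1
    isb = np.zeros(G + 1, dtype=bool)
    isb[B] = True
    p = np.nonzero(~isb[1:G])[0] + 1  # internal non-boundary positions
    segi = np.searchsorted(B, p, side="right") - 1
    ls = B[segi]
    rs = B[segi + 1]
    d_split = cost[ls, p] + cost[p, rs] - cost[ls, rs] + lnN
    if S >= 2:
        d_merge = cost[B[:-2], B[2:]] - cost[B[:-2], B[1:-1]] - cost[B[1:-1], B[2:]] - lnN
    else:
        d_merge = np.empty(0)
    mL = segi >= 1  # p as new position of the boundary left of its segment
    jL, pL = segi[mL], p[mL]
    dL = cost[B[jL - 1], pL] + cost[pL, B[jL + 1]] - cost[B[jL - 1], B[jL]] - cost[B[jL], B[jL + 1]]
    mR = segi <= S - 2  # p as new position of the boundary right of its segment
    jR, pR = segi[mR] + 1, p[mR]
    dR = cost[B[jR - 1], pR] + cost[pR, B[jR + 1]] - cost[B[jR - 1], B[jR]] - cost[B[jR], B[jR + 1]]
    jj = np.concatenate([jL, jR])
    pp = np.concatenate([pL, pR])
    dshift = np.concatenate([dL, dR])
    order = np.lexsort((pp, jj))
    deltas = np.concatenate([d_split, d_merge, dshift[order]])
    return deltas, d_split.size, d_merge.size, p, segi, jj, pp, order


def greedy_descent(
    matrix: ExpressionMatrix | None = None,
    init: Segmentation | None = None,
    f: MixtureParams | None = None,
    g: DeviationParams | None = None,
    *,
    scorer: SegmentScorer | None = None,
    eps: float = IMPROVEMENT_EPS,
    seed: int = 0,
    return_trace: bool = False,
) -> ReplicateResult:
    """Strictly-downhill descent to a local optimum of the BIC score.

    Every possible split, merge and shift is evaluated at each iteration and
    the single move with the greatest score improvement is applied; ties are
    broken by the canonical move enumeration order.  Terminates when no move
    improves the score by more than ``eps``.
    """
    if scorer is None:
        scorer = SegmentScorer(matrix, f, g)
    if init is None:
        raise ValueError("an initial segmentation is required")
    if init.n_genes != scorer.n_genes:
        raise ValueError("initial segmentation does not cover the arm")
    cost, lnN, G = scorer.cost, scorer.lnN, scorer.n_genes
    B = init.boundaries().astype(np.intp)
    score = scorer.score(init)
    if not np.isfinite(score):
        raise RuntimeError("non-finite score at initial segmentation")
    traces = ([score], [init]) if return_trace else None
    it = 0
    while True:
        deltas, ns, nm, p, segi, jj, pp, order = _move_deltas(B, cost, lnN, G)
        if deltas.size == 0:
            break
        best = int(np.argmin(deltas))
        d = float(deltas[best])
        if not np.isfinite(d):
            raise RuntimeError("non-finite move delta encountered")
        if d >= -eps:
            break
        if best < ns:
            B = np.insert(B, segi[best] + 1, p[best])
        elif best < ns + nm:
            B = np.delete(B, best - ns + 1)
        else:
            i = order[best - ns - nm]
            B = B.copy()
            B[jj[i]] = pp[i]
        score += d
        it += 1
        if traces is not None:
            traces[0].append(score)
            traces[1].append(Segmentation(init.arm_id, tuple(np.diff(B))))
    final = scorer.scored(Segmentation(init.arm_id, tuple(np.diff(B))))
    res = ReplicateResult(seed, final, it)
    if traces is not None:
        res.score_trace, res.segmentation_trace = traces
    return res


# ---------------------------------------------------------------------------
# Replicates and sigma training
# ---------------------------------------------------------------------------

def aggregate_scores(scores: Sequence[float], aggregator: str = "median") -> float:
    if aggregator == "median":
        return float(np.median(scores))
    if aggregator == "best":
        return float(np.min(scores))
    if aggregator == "mean":
        return float(np.mean(scores))
    raise ValueError(f"unknown aggregator {aggregator!r}")


def run_replicates(
    matrix: ExpressionMatrix | None = None,
    f: MixtureParams | None = None,
    g: DeviationParams | None = None,
    n_replicates: int = 1024,
    master_seed: int = 0,
    aggregator: str = "median",
    mean_len: float = 2.0,
    scorer: SegmentScorer | None = None,
) -> tuple[float, list[ReplicateResult]]:
    """Independent greedy descents from fresh random initial segmentations.

    Per-replicate rng streams are spawned from the master seed (counter-based
    SeedSequence children), so the full set of results is a deterministic
    function of ``master_seed``.  Returns the aggregated score (median by
    default; even counts take the mean of the central pair) and all results.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if scorer is None:
        scorer = SegmentScorer(matrix, f, g)
    children = np.random.SeedSequence(master_seed).spawn(n_replicates)
    results = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        init = random_segmentation(scorer.n_genes, mean_len, rng, scorer.matrix.arm_id)
        results.append(greedy_descent(scorer=scorer, init=init, seed=i))
    return aggregate_scores([r.final.score for r in results], aggregator), results


@dataclass
class SigmaFit:
    """Result of simplex training of sigma."""

    sigma: float
    best: ScoredSegmentation
    objective: float
    n_evals: int
    evals: list[tuple[float, float]] = field(default_factory=list)


def train_sigma(
    matrix: ExpressionMatrix,
    f: MixtureParams,
    sigma_init: float = 0.5,
    n_replicates: int = 1024,
    master_seed: int = 0,
    tol: float = 1e-3,
    mean_len: float = 2.0,
    aggregator: str = "median",
    maxiter: int = 200,
    search: str = "greedy",
    n_free_dist_params: int = 1,
) -> SigmaFit:
    """Nelder-Mead over log(sigma), objective = aggregated replicate score.

    f is fixed; only sigma is trained.  Each objective evaluation reuses the
    same per-replicate seed streams (common random numbers), so the objective
    is a deterministic function of sigma.  Returns the sigma with the best
    objective among all evaluated points and the best-scoring single
    segmentation found at that sigma — with ``search='exact'`` the inner
    optimizer is the DP global solver instead of greedy replicates.
    """
    if sigma_init <= 0:
        raise ValueError("sigma_init must be positive")
    cache: dict[float, float] = {}
    evals: list[tuple[float, float, ScoredSegmentation]] = []

    def objective(z: np.ndarray) -> float:
        ls = float(z[0])
        if ls in cache:
            return cache[ls]
        sigma = max(math.exp(ls), SIGMA_FLOOR)
        scorer = SegmentScorer(matrix, f, DeviationParams(sigma), n_free_dist_params)
        if search == "exact":
            best = dp_optimal_segmentation(scorer=scorer)
            agg = best.score
        elif search == "greedy":
            agg, results = run_replicates(
                n_replicates=n_replicates,
                master_seed=master_seed,
                aggregator=aggregator,
                mean_len=mean_len,
                scorer=scorer,
            )
            best = min(results, key=lambda r: r.final.score).final
        else:
            raise ValueError(f"unknown search mode {search!r}")
        cache[ls] = agg
        evals.append((sigma, agg, best))
        log.debug("sigma eval: sigma=%.6g objective=%.6f", sigma, agg)
        return agg

    res = minimize(
        objective,
        np.array([math.log(sigma_init)]),
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": 1e-2, "maxiter": maxiter},
    )
    if not evals or not any(math.isfinite(a) for _, a, _ in evals):
        raise RuntimeError("sigma objective non-finite at every evaluated point")
    best_sigma, best_agg, best_seg = min(evals, key=lambda e: e[1])
    log.info("trained sigma = %.6g (objective %.4f, %d evaluations)", best_sigma, best_agg, len(evals))
    return SigmaFit(best_sigma, best_seg, best_agg, len(evals), [(s, a) for s, a, _ in evals])


# ---------------------------------------------------------------------------
# Exact DP solver and replicate agreement
# ---------------------------------------------------------------------------

def dp_optimal_segmentation(
    matrix: ExpressionMatrix | None = None,
    f: MixtureParams | None = None,
    g: DeviationParams | None = None,
    *,
    scorer: SegmentScorer | None = None,
    n_free_dist_params: int = 1,
) -> ScoredSegmentation:
    """Exact global BIC minimum by dynamic programming over segment ends.

    Valid because the score is additive over segments (each contributes its
    cost plus one ln n penalty term).  O(G^2) table lookups; intended for
    arms of up to a few hundred genes and as an oracle for the greedy search.
    """
    if scorer is None:
        scorer = SegmentScorer(matrix, f, g, n_free_dist_params)
    G = scorer.n_genes
    cost, lnN = scorer.cost, scorer.lnN
    dp = np.full(G + 1, np.inf)
    dp[0] = 0.0
    back = np.zeros(G + 1, dtype=int)
    for j in range(1, G + 1):
        cand = dp[:j] + cost[:j, j] + lnN
        i = int(np.argmin(cand))
        dp[j] = cand[i]
        back[j] = i
    bounds = [G]
    while bounds[-1] > 0:
        bounds.append(int(back[bounds[-1]]))
    bounds.reverse()
    lengths = tuple(j - i for i, j in zip(bounds[:-1], bounds[1:]))
    return scorer.scored(Segmentation(scorer.matrix.arm_id, lengths))


def replicate_agreement(results: Sequence[ReplicateResult]) -> dict[str, float]:
    """Boundary and segment sharing among replicate local optima.

    ``best_vs_second`` / ``best_vs_worst``: fraction of the best replicate's
    intersegment boundaries present in the second-best / worst replicate
    (vacuously 1 when the best replicate has a single segment).
    ``segments_majority``: fraction of segments found in at least one
    replicate that appear in more than half of the replicates.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 replicates")
    ranked = sorted(results, key=lambda r: (r.final.score, r.seed))

    def bset(r: ReplicateResult) -> frozenset[int]:
        return r.final.segmentation.internal_boundaries()

    def shared(a: frozenset[int], b: frozenset[int]) -> float:
        return 1.0 if not a else len(a & b) / len(a)

    seg_counts: dict[tuple[int, int], int] = {}
    for r in results:
        b = r.final.segmentation.boundaries()
        for i, j in zip(b[:-1], b[1:]):
            seg_counts[(int(i), int(j))] = seg_counts.get((int(i), int(j)), 0) + 1
    half = len(results) / 2.0
    majority = sum(1 for c in seg_counts.values() if c > half) / len(seg_counts)
    return {
        "best_vs_second": shared(bset(ranked[0]), bset(ranked[1])),
        "best_vs_worst": shared(bset(ranked[0]), bset(ranked[-1])),
        "segments_majority": majority,
    }
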