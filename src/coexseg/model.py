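"""The segment probability model: f, g, marginal likelihood and BIC score.

A chromosome arm is partitioned into contiguous coexpression segments.  For a
segment of n genes in one tissue, every gene shares a latent segment effect
s drawn from f (a two-component normal mixture, fitted once to the pooled
expression values and then fixed), and each gene adds a private deviation
drawn from g = N(0, sigma^2).  The probability of the segment's data x_1..x_n
in that tissue is the marginal

    integral  prod_i N(x_i - s; 0, sigma^2) f(s) ds,

which has a closed form per mixture component (normal-normal conjugacy).
Tissues and segments are independent, so a segmentation's log-likelihood is
the sum of these terms, and model selection uses the BIC-style score

    score = -2 ln P(x | theta) + K ln n        (lower is better)

with K the number of estimated parameters (one per segment, plus the free
distribution parameters — by default just sigma, since f is fixed) and n the
number of data points on the arm (genes x tissues).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .data_io import ExpressionMatrix

log = logging.getLogger("coexseg")

__all__ = [
    "SIGMA_FLOOR",
    "MixtureParams",
    "DeviationParams",
    "Segmentation",
    "ScoredSegmentation",
    "EMFit",
    "fit_mixture_em",
    "segment_log_marginal",
    "segment_log_marginal_quadrature",
    "segmentation_loglik",
    "bic_score",
]

#: lower bound on any standard deviation entering a likelihood (expression units)
SIGMA_FLOOR = 1e-4

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MixtureParams:
    """Two-component normal mixture f of segment effects.

    phi is the weight of component 1; (mu1, sigma1) and (mu2, sigma2) the
    component means and standard deviations.
    """

    phi: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("component standard deviations must be positive")
        for name in ("phi", "mu1", "sigma1", "mu2", "sigma2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def mean(self) -> float:
        return self.phi * self.mu1 + (1.0 - self.phi) * self.mu2

    @property
    def var(self) -> float:
        m = self.mean
        return (
            self.phi * (self.sigma1**2 + (self.mu1 - m) ** 2)
            + (1.0 - self.phi) * (self.sigma2**2 + (self.mu2 - m) ** 2)
        )

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return self.phi * stats.norm.pdf(x, self.mu1, self.sigma1) + (
            1.0 - self.phi
        ) * stats.norm.pdf(x, self.mu2, self.sigma2)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return self.phi * stats.norm.cdf(x, self.mu1, self.sigma1) + (
            1.0 - self.phi
        ) * stats.norm.cdf(x, self.mu2, self.sigma2)

    def ordered(self) -> "MixtureParams":
        """Canonical label order: component 1 has the smaller mean."""
        if self.mu1 <= self.mu2:
            return self
        return MixtureParams(1.0 - self.phi, self.mu2, self.sigma2, self.mu1, self.sigma1)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name in ("phi", "mu1", "sigma1", "mu2", "sigma2"):
                fh.write(f"{name} = {getattr(self, name):.17g}\n")

    @classmethod
    def from_file(cls, path) -> "MixtureParams":
        kv = _read_kv(path)
        try:
            return cls(**{k: float(kv[k]) for k in ("phi", "mu1", "sigma1", "mu2", "sigma2")})
        except KeyError as exc:
            raise ValueError(f"{path}: missing mixture parameter {exc}") from exc


@dataclass(frozen=True)
class DeviationParams:
    """Gene-specific deviation distribution g = N(0, sigma^2).

    sigma = 0 is permitted as the simulator's zero-noise limit; likelihood
    evaluation enforces the SIGMA_FLOOR lower bound and rejects smaller values.
    """

    sigma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma}")

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"sigma = {self.sigma:.17g}\n")

    @classmethod
    def from_file(cls, path) -> "DeviationParams":
        kv = _read_kv(path)
        if "sigma" not in kv:
            raise ValueError(f"{path}: missing 'sigma'")
        return cls(float(kv["sigma"]))


def _read_kv(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


@dataclass(frozen=True)
class Segmentation:
    """Ordered segment lengths (genes per segment) covering one arm."""

    arm_id: str
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", tuple(int(v) for v in self.lengths))
        if len(self.lengths) == 0:
            raise ValueError("segmentation must have at least one segment")
        if any(v < 1 for v in self.lengths):
            raise ValueError("all segment lengths must be >= 1")

    @property
    def n_genes(self) -> int:
        return sum(self.lengths)

    @property
    def n_segments(self) -> int:
        return len(self.lengths)

    def boundaries(self) -> np.ndarray:
        """Gene-index boundaries including 0 and n_genes."""
        return np.concatenate([[0], np.cumsum(self.lengths)])

    def internal_boundaries(self) -> frozenset[int]:
        return frozenset(int(b) for b in self.boundaries()[1:-1])

    def segment_of_gene(self) -> np.ndarray:
        """For each gene index, the index of its segment."""
        return np.repeat(np.arange(self.n_segments), self.lengths)


@dataclass(frozen=True)
class ScoredSegmentation:
    """A segmentation with its log-likelihood, parameter count and BIC score."""

    segmentation: Segmentation
    loglik: float
    K: int
    n_data: int
    score: float

    def __post_init__(self) -> None:
        expected = -2.0 * self.loglik + self.K * math.log(self.n_data)
        if not math.isclose(self.score, expected, rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError(
                f"score invariant violated: stored {self.score!r}, "
                f"-2 loglik + K ln n = {expected!r}"
            )


# ---------------------------------------------------------------------------
# EM fit of f
# ---------------------------------------------------------------------------

@dataclass
class EMFit:
    params: MixtureParams
    loglik: float
    loglik_trace: list[float]
    n_iter: int
    converged: bool


def fit_mixture_em(
    values: Sequence[float],
    n_components: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    n_restarts: int = 5,
    full_output: bool = False,
):
    """Maximum-likelihood two-component normal mixture by EM.

    Fits f to the pooled expression values over all genes and tissues; the
    result is fixed during all subsequent segmentation.  Components are seeded
    at the 25th/75th percentiles with the pooled variance; restarts jitter the
    seeds and the best log-likelihood is kept.  Iteration stops when the
    relative change of the observed-data log-likelihood drops below ``tol``.

    Returns a :class:`MixtureParams` (components ordered by mean), or the full
    :class:`EMFit` record when ``full_output`` is set.
    """
    if n_components != 2:
        raise ValueError("only two-component mixtures are supported")
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("expression values must be finite")
    if x.size < 10 * n_components:
        raise ValueError(f"need at least {10 * n_components} values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: all values equal (variance floor violation)")

    rng = np.random.default_rng(seed)
    pooled_sd = max(float(np.std(x)), SIGMA_FLOOR)
    q25, q75 = np.percentile(x, [25, 75])

    best: EMFit | None = None
    for restart in range(max(1, n_restarts)):
        mu = np.array([q25, q75], dtype=float)
        if restart > 0:
            mu = mu + rng.normal(0.0, 0.25 * pooled_sd, size=2)
        sd = np.array([pooled_sd, pooled_sd])
        w = np.array([0.5, 0.5])
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            # E-step: responsibilities and observed-data log-likelihood
            logp = np.log(w)[:, None] + stats.norm.logpdf(x[None, :], mu[:, None], sd[:, None])
            mx = np.max(logp, axis=0)
            lse = mx + np.log(np.sum(np.exp(logp - mx), axis=0))
            ll = float(np.sum(lse))
            resp = np.exp(logp - lse)
            trace.append(ll)
            if len(trace) > 1:
                prev = trace[-2]
                if abs(ll - prev) <= tol * max(1.0, abs(prev)):
                    converged = True
                    break
            # M-step
            nk = resp.sum(axis=1)
            nk = np.maximum(nk, 1e-12)
            w = nk / x.size
            mu = resp @ x / nk
            var = np.einsum("kn,kn->k", resp, (x[None, :] - mu[:, None]) ** 2) / nk
            sd = np.sqrt(np.maximum(var, SIGMA_FLOOR**2))
        if not converged:
            log.warning("EM did not converge in %d iterations (restart %d); best-so-far kept",
                        max_iter, restart)
        params = MixtureParams(float(w[0]), float(mu[0]), float(sd[0]), float(mu[1]), float(sd[1]))
        fit = EMFit(params.ordered(), trace[-1], trace, len(trace), converged)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best if full_output else best.params


# ---------------------------------------------------------------------------
# Segment marginal likelihood
# ---------------------------------------------------------------------------

def _component_log_marginal(n, sum_x, sum_x2, mu, tau, sigma):
    """Log of integral prod_i N(x_i; s, sigma^2) N(s; mu, tau^2) ds.

    Closed form via completion of the square in s; vectorized over the
    sufficient statistics (n, sum_x, sum_x2).
    """
    s2 = sigma * sigma
    t2 = tau * tau
    a = n / s2 + 1.0 / t2
    b = sum_x / s2 + mu / t2
    c = sum_x2 / s2 + mu * mu / t2
    return -0.5 * n * (_LOG_2PI + math.log(s2)) - 0.5 * np.log(t2 * a) - 0.5 * (c - b * b / a)


def _check_g(g: DeviationParams) -> float:
    if g.sigma < SIGMA_FLOOR:
        raise ValueError(f"g.sigma = {g.sigma} below likelihood floor {SIGMA_FLOOR}")
    return g.sigma


def segment_log_marginal(x, f: MixtureParams, g: DeviationParams) -> float:
    """Closed-form log-probability of one segment's values in one tissue.

    Combines the two mixture components of f in log space (max-shifted sum),
    each via the conjugate normal-normal marginal over the segment effect.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("segment must contain at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment values must be finite")
    sigma = _check_g(g)
    n = x.size
    sum_x = float(np.sum(x))
    sum_x2 = float(np.sum(x * x))
    l1 = _component_log_marginal(n, sum_x, sum_x2, f.mu1, f.sigma1, sigma)
    l2 = _component_log_marginal(n, sum_x, sum_x2, f.mu2, f.sigma2, sigma)
    if f.phi == 1.0:
        return float(l1)
    if f.phi == 0.0:
        return float(l2)
    a = math.log(f.phi) + l1
    b = math.log1p(-f.phi) + l2
    m = max(a, b)
    return float(m + math.log(math.exp(a - m) + math.exp(b - m)))


def segment_log_marginal_quadrature(x, f: MixtureParams, g: DeviationParams) -> float:
    """Adaptive-quadrature evaluation of the defining integral (test oracle).

    Integrates over the segment effect s on a window covering both component
    means and the data, padded by 12 x max(sigma1, sigma2, sigma); the
    integrand is max-shifted in log space for numerical range.
    """
    x = np.asarray(x, dtype=float).ravel()
    sigma = _check_g(g)
    pad = 12.0 * max(f.sigma1, f.sigma2, sigma)
    lo = min(f.mu1, f.mu2, float(np.min(x))) - pad
    hi = max(f.mu1, f.mu2, float(np.max(x))) + pad

    def log_integrand(s):
        with np.errstate(divide="ignore"):
            return float(
                np.sum(stats.norm.logpdf(x - s, 0.0, sigma))
                + np.log(f.pdf(s))
            )

    # max-shift from a vectorized coarse scan of the log-integrand
    grid = np.linspace(lo, hi, 512)
    with np.errstate(divide="ignore"):  # f.pdf underflows to 0 in far tails
        grid_log = (
            np.sum(stats.norm.logpdf(x[None, :] - grid[:, None], 0.0, sigma), axis=1)
            + np.log(f.pdf(grid))
        )
    shift = float(np.max(grid_log))

    val, err = integrate.quad(
        lambda s: math.exp(log_integrand(s) - shift),
        lo,
        hi,
        limit=400,
        epsabs=0.0,
        epsrel=1e-10,
    )
    if val <= 0 or err > 1e-8 * val:
        raise RuntimeError(f"quadrature failed to converge (value {val}, abserr {err})")
    return shift + math.log(val)


def segmentation_loglik(
    matrix: ExpressionMatrix, seg: Segmentation, f: MixtureParams, g: DeviationParams
) -> float:
    """Total log-likelihood: sum of segment marginals over segments x tissues."""
    if seg.n_genes != matrix.n_genes:
        raise ValueError(
            f"segmentation covers {seg.n_genes} genes but matrix has {matrix.n_genes}"
        )
    bounds = seg.boundaries()
    total = 0.0
    for i, j in zip(bounds[:-1], bounds[1:]):
        for t in range(matrix.n_tissues):
            total += segment_log_marginal(matrix.values[i:j, t], f, g)
    return total


def bic_score(
    loglik: float, seg: Segmentation, n_data: int, n_free_dist_params: int = 1
) -> ScoredSegmentation:
    """BIC-style score: -2 loglik + K ln(n_data), K = segments + free params.

    f is fixed before the search, so by default only sigma counts as a free
    distribution parameter.  Lower score is better.
    """
    if n_data < 2:
        raise ValueError(f"n_data must be >= 2, got {n_data}")
    K = seg.n_segments + n_free_dist_params
    score = -2.0 * loglik + K * math.log(n_data)
    return ScoredSegmentation(seg, loglik, K, n_data, score)
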