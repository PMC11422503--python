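"""Poisson-binomial model of gene observation counts under genome incompleteness.

A gene with true population frequency ``theta`` is carried by each of ``N``
genomes independently with probability ``theta``, and an assembly with
completeness ``c_i`` retains any given gene with probability ``c_i``. The
number of times the gene is *observed* across the collection is therefore a
sum of independent Bernoulli trials with unequal success probabilities
``theta * c_1, ..., theta * c_N`` — a Poisson binomial random variable.

True gene frequencies across a pangenome follow the familiar U-shaped
spectrum (most genes near-universal or rare), modelled here with a
``Beta(a, b)`` prior with both shapes < 1 by default.

The threshold-adjustment rule: pick the largest integer count ``X*`` such
that a gene whose true frequency lies in the core region (``theta >= t_core``)
is observed ``X*`` times or fewer with probability at most ``alpha`` — the
false-negative rate. Genes observed strictly more than ``X*`` times are
called core. A mirrored rule bounds the false-positive rate for the rare
label. The tail probability marginalises ``theta`` over the prior truncated
to the region, either by Monte Carlo (default) or by exact quadrature over
the dynamic-programming pmf.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.stats import beta as beta_dist

__all__ = [
    "ThresholdConfig",
    "poisbin_pmf_exact",
    "poisbin_cdf",
    "sample_conditional_theta",
    "simulate_observation_counts",
    "adjust_core_threshold",
    "adjust_rare_threshold",
]

_MIN_REGION_MASS = 1e-12


@dataclass(frozen=True)
class ThresholdConfig:
    """Parameters of the threshold-adjustment procedure.

    Parameters
    ----------
    t_core : float
        Core frequency threshold in (0, 1]; a gene is truly core when its
        population frequency is at least this value. Default 0.95.
    t_rare : float
        Rare frequency threshold in [0, 1); truly rare genes have frequency
        at most this value. Default 0.05.
    alpha : float
        Error-rate bound in (0, 1): the false-negative rate for the core
        cutoff and the false-positive rate for the rare cutoff. Default 0.05.
    prior_a, prior_b : float
        Beta prior shape parameters for the gene-frequency spectrum.
        Defaults (0.5, 0.5) give a symmetric U shape.
    n_sims : int
        Monte Carlo sample size for tail-probability estimation.
    seed : int
        Seed for the single RNG stream used by the Monte Carlo estimator.
    method : {"montecarlo", "exact"}
        "montecarlo" samples (theta, X) pairs; "exact" integrates the
        dynamic-programming pmf over a Gauss-Legendre grid in the prior's
        quantile space (practical for N up to a couple of thousand).
    n_quad : int
        Quadrature node count for the exact method.
    fixed_theta : float or None
        If set, the prior is replaced by a point mass at this frequency
        (the fixed-theta rule; with complete genomes it reduces to the
        binomial alpha-quantile cutoff).
    """

    t_core: float = 0.95
    t_rare: float = 0.05
    alpha: float = 0.05
    prior_a: float = 0.5
    prior_b: float = 0.5
    n_sims: int = 100_000
    seed: int = 0
    method: Literal["montecarlo", "exact"] = "montecarlo"
    n_quad: int = 64
    fixed_theta: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.t_core <= 1.0:
            raise ValueError(f"t_core must be in (0, 1], got {self.t_core}")
        if not 0.0 <= self.t_rare < 1.0:
            raise ValueError(f"t_rare must be in [0, 1), got {self.t_rare}")
        if not self.t_rare < self.t_core:
            raise ValueError(
                f"t_rare ({self.t_rare}) must be below t_core ({self.t_core})"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("Beta prior shapes must be positive")
        if self.n_sims < 1:
            raise ValueError("n_sims must be a positive integer")
        if self.method not in ("montecarlo", "exact"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_quad < 1:
            raise ValueError("n_quad must be a positive integer")
        if self.fixed_theta is not None and not 0.0 <= self.fixed_theta <= 1.0:
            raise ValueError("fixed_theta must lie in [0, 1]")

    def with_(self, **kwargs) -> "ThresholdConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _as_prob_vector(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    return arr


def poisbin_pmf_exact(success_probs: Sequence[float]) -> np.ndarray:
    """Exact Poisson-binomial pmf by dynamic-programming convolution.

    Folds the N Bernoulli trials in one at a time; returns ``P(X = k)``
    for ``k = 0..N``. O(N^2) time, exact up to float rounding.
    """
    p = _as_prob_vector(success_probs, "success_probs")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for pi in p:
        pmf[1:] = pmf[1:] * (1.0 - pi) + pmf[:-1] * pi
        pmf[0] *= 1.0 - pi
    return pmf


def poisbin_cdf(success_probs: Sequence[float], k: int) -> float:
    """P(X <= k) for the Poisson binomial with the given success probabilities."""
    p = _as_prob_vector(success_probs, "success_probs")
    if not 0 <= k <= p.size:
        raise ValueError(f"k must be in [0, {p.size}], got {k}")
    return float(poisbin_pmf_exact(p)[: k + 1].sum())


def _truncation_quantiles(a: float, b: float, lo: float, hi: float) -> tuple[float, float]:
    q_lo = float(beta_dist.cdf(lo, a, b))
    q_hi = float(beta_dist.cdf(hi, a, b))
    if q_hi - q_lo < _MIN_REGION_MASS:
        raise ValueError(
            f"Beta({a}, {b}) prior mass on [{lo}, {hi}] is below {_MIN_REGION_MASS}; "
            "choose a prior with support in the region"
        )
    return q_lo, q_hi


def sample_conditional_theta(
    config: ThresholdConfig,
    region: Literal["core", "rare"],
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw true-frequency values from the Beta prior truncated to a region.

    ``region="core"`` conditions on ``theta >= t_core``; ``"rare"`` on
    ``theta <= t_rare``. Sampling is by inverse CDF on the restricted
    quantile interval, so it stays efficient however little prior mass the
    region holds.
    """
    if region == "core":
        lo, hi = config.t_core, 1.0
    elif region == "rare":
        lo, hi = 0.0, config.t_rare
    else:
        raise ValueError(f"region must be 'core' or 'rare', got {region!r}")
    if config.fixed_theta is not None:
        return np.full(n, config.fixed_theta)
    rng = np.random.default_rng(config.seed if rng is None else rng)
    q_lo, q_hi = _truncation_quantiles(config.prior_a, config.prior_b, lo, hi)
    u = rng.random(n)
    draws = beta_dist.ppf(q_lo + u * (q_hi - q_lo), config.prior_a, config.prior_b)
    return np.clip(draws, lo, hi)


def simulate_observation_counts(
    completeness: Sequence[float],
    theta_draws: Sequence[float],
    rng: np.random.Generator | int | None = None,
    chunk: int = 8192,
) -> np.ndarray:
    """One Poisson-binomial count realisation per theta draw.

    For each draw the N success probabilities are ``theta * c_i``; the
    returned counts lie in [0, N]. Work is chunked to bound memory at
    ``chunk * N`` uniforms.
    """
    c = _as_prob_vector(completeness, "completeness")
    thetas = _as_prob_vector(theta_draws, "theta_draws")
    rng = np.random.default_rng(rng)
    counts = np.empty(thetas.size, dtype=np.int64)
    for start in range(0, thetas.size, chunk):
        block = thetas[start : start + chunk, np.newaxis]
        u = rng.random((block.shape[0], c.size))
        counts[start : start + chunk] = (u < block * c).sum(axis=1)
    return counts


def _marginal_count_cdf_exact(
    completeness: np.ndarray, config: ThresholdConfig, lo: float, hi: float
) -> np.ndarray:
    """P(X <= k | theta in [lo, hi]) for k = 0..N by quadrature over the prior.

    Gauss-Legendre nodes are placed in the *quantile* space of the truncated
    Beta, so each node carries equal-footing prior mass even when the prior
    density diverges at the endpoints.
    """
    if config.fixed_theta is not None:
        nodes = np.array([config.fixed_theta])
        weights = np.array([1.0])
    else:
        q_lo, q_hi = _truncation_quantiles(config.prior_a, config.prior_b, lo, hi)
        x, w = leggauss(config.n_quad)
        u = (x + 1.0) / 2.0  # map to (0, 1)
        nodes = beta_dist.ppf(q_lo + u * (q_hi - q_lo), config.prior_a, config.prior_b)
        nodes = np.clip(nodes, lo, hi)
        weights = w / 2.0
    cdf = np.zeros(completeness.size + 1)
    for theta_k, w_k in zip(nodes, weights):
        cdf += w_k * np.cumsum(poisbin_pmf_exact(theta_k * completeness))
    return np.clip(cdf, 0.0, 1.0)


def _marginal_count_cdf_mc(
    completeness: np.ndarray, config: ThresholdConfig, region: Literal["core", "rare"]
) -> np.ndarray:
    """Monte Carlo estimate of the marginal count CDF over a prior region.

    A single seeded generator is consumed in a fixed order — all theta draws
    first, then the count realisations — so results are bit-reproducible
    per seed.
    """
    rng = np.random.default_rng(config.seed)
    thetas = sample_conditional_theta(config, region, config.n_sims, rng)
    counts = simulate_observation_counts(completeness, thetas, rng)
    hist = np.bincount(counts, minlength=completeness.size + 1)
    return np.cumsum(hist) / config.n_sims


def _marginal_count_cdf(
    completeness: np.ndarray, config: ThresholdConfig, region: Literal["core", "rare"]
) -> np.ndarray:
    if config.method == "exact":
        lo, hi = (config.t_core, 1.0) if region == "core" else (0.0, config.t_rare)
        return _marginal_count_cdf_exact(completeness, config, lo, hi)
    return _marginal_count_cdf_mc(completeness, config, region)


def adjust_core_threshold(
    completeness: Sequence[float], config: ThresholdConfig
) -> tuple[int, float]:
    """Completeness-adjusted core count cutoff.

    Returns ``(X_core, fnr_at_cutoff)`` where ``X_core`` is the largest
    integer with ``P(X <= X_core | theta >= t_core) <= alpha``; genes
    observed strictly more than ``X_core`` times are core. The sentinel
    ``X_core = -1`` means even a count of 0 would exceed the bound, i.e.
    every observed gene is core.
    """
    c = _as_prob_vector(completeness, "completeness")
    cdf = _marginal_count_cdf(c, config, "core")
    admissible = np.nonzero(cdf <= config.alpha)[0]
    if admissible.size == 0:
        return -1, 0.0
    x_core = int(admissible.max())
    return x_core, float(cdf[x_core])


def adjust_rare_threshold(
    completeness: Sequence[float], config: ThresholdConfig
) -> tuple[int, float]:
    """Completeness-adjusted rare count cutoff (mirror of the core rule).

    Returns ``(X_rare, fpr_at_cutoff)`` where ``X_rare`` is the smallest
    integer with ``P(X >= X_rare | theta <= t_rare) <= alpha``; genes
    observed strictly fewer than ``X_rare`` times are rare. ``X_rare`` can
    reach ``N + 1`` (everything rare) only in pathological configurations,
    since ``P(X >= N + 1) = 0`` always satisfies the bound.
    """
    c = _as_prob_vector(completeness, "completeness")
    cdf = _marginal_count_cdf(c, config, "rare")
    # sf[x] = P(X >= x) for x = 0..N+1
    sf = np.concatenate(([1.0], np.clip(1.0 - cdf, 0.0, 1.0)))
    x_rare = int(np.nonzero(sf <= config.alpha)[0].min())
    return x_rare, float(sf[x_rare])


def unadjusted_cutoffs(n_genomes: int, t_core: float, t_rare: float) -> tuple[int, int]:
    """Classical fixed-frequency cutoffs on the count scale.

    Core means observed frequency >= t_core, i.e. count >= ceil(t_core * N),
    so the largest non-core count is ``ceil(t_core * N) - 1``; rare means
    frequency < t_rare, i.e. count < ceil(t_rare * N).
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be positive")
    x_core = int(np.ceil(t_core * n_genomes)) - 1
    x_rare = int(np.ceil(t_rare * n_genomes))
    return x_core, x_rare
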