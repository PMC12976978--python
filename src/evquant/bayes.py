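"""Bayesian comparison of labelling proportions via beta posteriors.

Labelled/unlabelled particle counts under a condition are treated as
binomial outcomes with a uniform Beta(1, 1) prior, giving the posterior
Beta(successes + 1, failures + 1) — proper even for zero-event data.  Two
posteriors are compared by (i) the Monte Carlo distribution of p1 - p2
(mean and 95% credible interval from 200 000 paired draws) and (ii) the
exceedance probability

    P(p1 > p2) = int_0^1 pdf_1(x) * CDF_2(x) dx,

evaluated by adaptive numerical quadrature.  A two-sided summary
``p_same = 2 * min(P, 1 - P)`` condenses the exceedance into a
significance-like number, and ``compare_to_null`` tests a condition against
the no-signal hypothesis (zero successes, same failure count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import beta as beta_dist


@dataclass(frozen=True)
class BetaPosterior:
    """Beta(a, b) posterior over a labelling proportion."""

    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"shape parameters must be > 0, got ({self.a}, {self.b})")

    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def variance(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s**2 * (s + 1.0))

    def pdf(self, x):
        return beta_dist.pdf(x, self.a, self.b)

    def cdf(self, x):
        return beta_dist.cdf(x, self.a, self.b)

    def interval(self, mass: float = 0.95) -> tuple[float, float]:
        """Equal-tailed credible interval."""
        tail = (1.0 - mass) / 2.0
        return (
            float(beta_dist.ppf(tail, self.a, self.b)),
            float(beta_dist.ppf(1.0 - tail, self.a, self.b)),
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.a, self.b, size=n)


@dataclass(frozen=True)
class ComparisonResult:
    """Summary of a pairwise posterior comparison."""

    mean_difference: float
    ci95: tuple[float, float]
    prob_greater: float
    p_same: float
    n_mc: int
    seed: int


def posterior_from_counts(successes: float, failures: float) -> BetaPosterior:
    """Beta posterior after a uniform prior: Beta(successes + 1, failures + 1).

    Real-valued pseudo-counts (e.g. mean label counts over FOVs) are
    accepted; negative counts are rejected.
    """
    if successes < 0 or failures < 0:
        raise ValueError("counts must be >= 0")
    return BetaPosterior(a=float(successes) + 1.0, b=float(failures) + 1.0)


def prob_greater(p1: BetaPosterior, p2: BetaPosterior) -> float:
    """P(p1 > p2) by numerical quadrature of int pdf_1(x) CDF_2(x) dx."""
    points = sorted({p1.mean(), p2.mean()})
    points = [p for p in points if 0.0 < p < 1.0]
    val, _ = integrate.quad(
        lambda x: p1.pdf(x) * p2.cdf(x),
        0.0,
        1.0,
        epsabs=1e-10,
        epsrel=1e-10,
        limit=200,
        points=points or None,
    )
    return float(min(1.0, max(0.0, val)))


def p_same(p1: BetaPosterior, p2: BetaPosterior) -> float:
    """Two-sided tail summary 2*min(P(p1>p2), 1-P(p1>p2)), clamped to [0, 1]."""
    pg = prob_greater(p1, p2)
    return float(min(1.0, max(0.0, 2.0 * min(pg, 1.0 - pg))))


def difference_distribution(
    p1: BetaPosterior,
    p2: BetaPosterior,
    n_mc: int = 200_000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Monte Carlo mean and 95% credible interval of p1 - p2.

    Draws ``n_mc`` independent samples from each posterior; the interval is
    the 2.5th/97.5th percentile of the paired differences
    (linear-interpolation quantiles).  ``seed`` is required for
    reproducibility.
    """
    if seed is None:
        raise ValueError("seed is required (Monte Carlo results must be reproducible)")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if n_mc < 1000:
        warnings.warn(
            f"n_mc={n_mc} gives wide Monte Carlo error; use >= 1000 draws",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    diff = p1.sample(n_mc, rng) - p2.sample(n_mc, rng)
    lo, hi = np.quantile(diff, [0.025, 0.975])
    return float(diff.mean()), (float(lo), float(hi))


def compare_posteriors(
    p1: BetaPosterior,
    p2: BetaPosterior,
    n_mc: int = 200_000,
    seed: int | None = None,
) -> ComparisonResult:
    """Full pairwise comparison: MC difference, quadrature exceedance, p_same."""
    mean_diff, ci = difference_distribution(p1, p2, n_mc=n_mc, seed=seed)
    pg = prob_greater(p1, p2)
    return ComparisonResult(
        mean_difference=mean_diff,
        ci95=ci,
        prob_greater=pg,
        p_same=float(min(1.0, max(0.0, 2.0 * min(pg, 1.0 - pg)))),
        n_mc=n_mc,
        seed=int(seed),
    )


def compare_to_null(
    p1: BetaPosterior,
    failures_1: float,
    n_mc: int = 200_000,
    seed: int | None = None,
) -> ComparisonResult:
    """Compare a posterior against the no-signal null (0 successes, same failures)."""
    null = posterior_from_counts(0.0, failures_1)
    return compare_posteriors(p1, null, n_mc=n_mc, seed=seed)
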