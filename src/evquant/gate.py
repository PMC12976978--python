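"""Detection gate: one-sided two-sample Kolmogorov-Smirnov test.

Before any condition is analysed, its per-field-of-view EV counts must show
a substantial positive shift over the empty-lane negative control.  The gate
uses the one-sided statistic D+ = max_t [F_control(t) - F_sample(t)]
(large when the sample is stochastically greater than the control) and
requires p < 0.01.  With 6-12 FOVs per lane, asymptotic KS p-values are
unreliable, so the p-value is computed by exact permutation enumeration of
all C(n1+n2, n2) group assignments whenever n1 + n2 <= 16, and by the
one-sided asymptotic formula exp(-2 D^2 n1 n2 / (n1+n2)) otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

EXACT_LIMIT = 16  # exact enumeration while n_sample + n_control <= this


@dataclass(frozen=True)
class GateResult:
    ks_statistic: float
    p_value: float
    n_sample: int
    n_control: int
    method: str  # "exact" | "asymptotic"
    passed: bool | None = None
    threshold: float | None = None


def _sorted_pool(sample: np.ndarray, control: np.ndarray):
    pooled = np.concatenate([sample, control])
    is_control = np.concatenate(
        [np.zeros(len(sample), bool), np.ones(len(control), bool)]
    )
    order = np.argsort(pooled, kind="stable")
    return pooled[order], is_control[order]


def _d_plus_from_sorted(values: np.ndarray, is_control: np.ndarray,
                        n_sample: int, n_control: int) -> float:
    # evaluate right-continuous ECDFs after each run of tied values
    cum_c = np.cumsum(is_control)
    cum_s = np.arange(1, len(values) + 1) - cum_c
    valid = np.r_[values[:-1] != values[1:], True]
    d = cum_c / n_control - cum_s / n_sample
    return float(max(0.0, d[valid].max()))


@lru_cache(maxsize=64)
def _permutation_table(n_total: int, n_control: int) -> np.ndarray:
    """D+ contributions for every control-label assignment over sorted positions.

    Row c, column k holds F_control - F_sample evaluated just after sorted
    position k under assignment c; the caller masks out positions interior to
    tied runs and maximises.
    """
    combos = list(itertools.combinations(range(n_total), n_control))
    member = np.zeros((len(combos), n_total), dtype=bool)
    for i, combo in enumerate(combos):
        member[i, list(combo)] = True
    cum_c = np.cumsum(member, axis=1)
    k = np.arange(1, n_total + 1)
    n_sample = n_total - n_control
    return cum_c / n_control - (k - cum_c) / n_sample


def ks_one_tailed(sample_counts, control_counts) -> GateResult:
    """One-sided two-sample KS test that the sample exceeds the control.

    ``sample_counts`` and ``control_counts`` are per-FOV EV counts (any
    real-valued observations work).  Returns the D+ statistic and a p-value
    (exact permutation for small pooled sizes, asymptotic otherwise).
    """
    sample = np.asarray(sample_counts, dtype=float).ravel()
    control = np.asarray(control_counts, dtype=float).ravel()
    if len(sample) == 0 or len(control) == 0:
        raise ValueError("both samples must be non-empty")
    ns, nc = len(sample), len(control)
    values, is_control = _sorted_pool(sample, control)
    d_obs = _d_plus_from_sorted(values, is_control, ns, nc)

    if ns + nc <= EXACT_LIMIT:
        table = _permutation_table(ns + nc, nc)
        valid = np.r_[values[:-1] != values[1:], True]
        d_all = np.maximum(table[:, valid].max(axis=1), 0.0)
        p = float(np.mean(d_all >= d_obs - 1e-12))
        method = "exact"
    else:
        p = float(min(1.0, np.exp(-2.0 * d_obs**2 * ns * nc / (ns + nc))))
        method = "asymptotic"
    return GateResult(ks_statistic=d_obs, p_value=p, n_sample=ns,
                      n_control=nc, method=method)


def gate_condition(result: GateResult, threshold: float = 0.01) -> GateResult:
    """Apply the strict p < threshold detection rule to a KS result."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return replace(result, passed=result.p_value < threshold, threshold=threshold)
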