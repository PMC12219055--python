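"""Resampling and multiplicity machinery shared by all analysis stages.

Permutation tests follow the add-one convention p = (1 + n_extreme) /
(1 + n_iterations), so a Monte-Carlo p-value is never exactly zero and
retains finite-sample validity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "permutation_test_two_sample",
    "permutation_test_one_sample",
    "fdr_adjust",
    "binomial_exact_test",
    "spawn_seeds",
]

DEFAULT_N_ITERATIONS = 10_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of a resampling or exact test.

    statistic is the observed difference of means (two-sample), mean of
    paired differences (one-sample), or signed deviation k - n*p0
    (binomial). p_value lies in (0, 1]; for permutation tests it is
    bounded below by 1/(n_iterations + 1).
    """

    statistic: float
    p_value: float
    n_iterations: int
    seed: int | None = None


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan a master seed out into ``n`` independent per-call seeds.

    Uses a counter-based SeedSequence scheme; returned seeds fit in 31
    bits so they can be passed to any downstream generator.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _tail_count(null: np.ndarray, observed: float, sided: str) -> int:
    if sided == "two":
        return int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    if sided == "greater":
        return int(np.sum(null >= observed - 1e-12))
    if sided == "less":
        return int(np.sum(null <= observed + 1e-12))
    raise ValueError(f"sided must be 'two', 'greater' or 'less', got {sided!r}")


def permutation_test_two_sample(
    a,
    b,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int = 0,
    sided: str = "two",
) -> TestResult:
    """Two-sample permutation test for a difference in group means.

    Pools ``a`` and ``b``, redraws group labels ``n_iterations`` times, and
    compares the redrawn difference of means (|Δ| for two-sided) against
    the observed one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    observed = float(a.mean() - b.mean())
    # canonical form (sorted pool, minority-size split) makes the
    # resampled null identical under group-order swap and under adding a
    # constant to every value, not just identical in distribution
    pooled = np.sort(np.concatenate([a, b]))
    n_small = min(a.size, b.size)
    sign = 1.0 if a.size <= b.size else -1.0
    rng = np.random.default_rng(seed)
    null = np.empty(n_iterations)
    # chunked vectorized label redraws to bound memory
    chunk = max(1, min(n_iterations, 2_000_000 // max(pooled.size, 1)))
    done = 0
    while done < n_iterations:
        m = min(chunk, n_iterations - done)
        perms = rng.permuted(np.broadcast_to(pooled, (m, pooled.size)),
                             axis=1)
        null[done:done + m] = sign * (perms[:, :n_small].mean(axis=1)
                                      - perms[:, n_small:].mean(axis=1))
        done += m
    p = (1 + _tail_count(null, observed, sided)) / (1 + n_iterations)
    return TestResult(statistic=observed, p_value=min(p, 1.0),
                      n_iterations=n_iterations, seed=seed)


def permutation_test_one_sample(
    diffs,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int = 0,
    sided: str = "two",
) -> TestResult:
    """One-sample (sign-flip) permutation test of paired differences vs 0."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise ValueError("diffs must be non-empty")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    observed = float(diffs.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_iterations, diffs.size))
    null = (signs * diffs).mean(axis=1)
    p = (1 + _tail_count(null, observed, sided)) / (1 + n_iterations)
    return TestResult(statistic=observed, p_value=min(p, 1.0),
                      n_iterations=n_iterations, seed=seed)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return np.minimum(np.maximum(adjusted, p), 1.0)


def binomial_exact_test(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Two-sided exact binomial test by the minimum-likelihood method.

    Sums probabilities of all outcomes no more likely than the observed
    count ``k`` under Binomial(n, p0).
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    result = sps.binomtest(int(k), int(n), p=p0, alternative="two-sided")
    return TestResult(statistic=float(k - n * p0), p_value=float(result.pvalue),
                      n_iterations=0, seed=None)
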