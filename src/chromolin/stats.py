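"""Shared statistical tests: Welch's two-sample t, pooled two-proportion z,
two-tailed binomial, and an empirical type-I-error calibration harness.

All p-values are two-tailed.  Swapping the two groups leaves p unchanged and
flips the sign of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    __test__ = False  # not a pytest collection target

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def two_sample_t(x, y) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-tailed.

    Two zero-variance samples with equal means give t = 0, p = 1 by
    convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, 1.0, (len(x), len(y)), "two_sample_t")
        return TestResult(np.inf if np.mean(x) > np.mean(y) else -np.inf, 0.0,
                          (len(x), len(y)), "two_sample_t")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(t), float(p), (len(x), len(y)), "two_sample_t")


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pooled-variance two-proportion z-test, two-tailed."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        # both proportions degenerate and equal
        return TestResult(0.0, 1.0, (n1, n2), "two_proportion_z")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), (n1, n2), "two_proportion_z")


def binomial_two_tailed(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Two-tailed binomial test of k successes in n trials against p0.

    Exact for n < 100 (or degenerate p-hat); otherwise the normal
    approximation with the score statistic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    phat = k / n
    if n < 100 or phat in (0.0, 1.0):
        res = sps.binomtest(k, n, p0, alternative="two-sided")
        z = (phat - p0) / np.sqrt(p0 * (1 - p0) / n)
        return TestResult(float(z), float(res.pvalue), (n,), "binomial_two_tailed")
    z = (phat - p0) / np.sqrt(p0 * (1 - p0) / n)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), (n,), "binomial_two_tailed")


def between_replicate_sd(estimates) -> float:
    """SD over replicate-level point estimates (the figure-legend '+/- SD
    between experiments')."""
    est = np.asarray(estimates, float)
    if len(est) < 2:
        return float("nan")
    return float(np.std(est, ddof=1))


def type_i_error_suite(
    test: Callable[..., TestResult],
    null_generator: Callable[[np.random.Generator], tuple],
    alpha: float,
    reps: int,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of ``test`` at level ``alpha`` under a true
    null.  ``null_generator(rng)`` returns the argument tuple for one draw.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a meaningful calibration")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        args = null_generator(rng)
        if test(*args).p_value <= alpha:
            rejections += 1
    return rejections / reps
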