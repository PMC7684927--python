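"""Two-cohort comparison statistics and the Fisher-exact power simulation.

The proportion comparison is the pooled two-sample z-test ("binomial
proportions test"); demographics use Student's t from summary statistics;
study sizing uses Monte-Carlo power of the one-tailed Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest


@dataclass(frozen=True)
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    p1: float
    p2: float
    z: float
    p_value: float


def two_proportion_test(x1: int, n1: int, x2: int, n2: int, method: str = "z") -> ProportionTestResult:
    """Two-sided test of p1 == p2 from counts.

    method='z' (default): pooled two-proportion z-test, normal p-value;
    method='chi2_cc': chi-square with Yates continuity correction (z is
    then the signed square root of the statistic).

    Degenerate tables with zero pooled variance (all failures or all
    successes) give p = 1, z = 0.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(x1, n1, x2, n2, p1, p2, 0.0, 1.0)
    if method == "z":
        z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    elif method == "chi2_cc":
        table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
        chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
        z = float(np.sign(p1 - p2) * np.sqrt(chi2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return ProportionTestResult(x1, n1, x2, n2, p1, p2, float(z), float(p))


def t_test_means(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    equal_var: bool = True,
) -> "tuple[float, float]":
    """(t, two-sided p) for a two-sample t-test from summary statistics.

    Pooled-variance Student form by default; equal_var=False gives Welch.
    """
    if min(n1, n2) < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        return (0.0, 1.0) if mean1 == mean2 else (np.inf * np.sign(mean1 - mean2), 0.0)
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    return float(t), float(p)


@dataclass(frozen=True)
class PowerEstimate:
    baseline_rate: float
    relative_reduction: float
    n_per_arm: int
    alpha: float
    tails: str
    replicates: int
    seed: int
    power: float


def fisher_one_tailed_p(x1: np.ndarray, x2: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """One-tailed Fisher exact p for H1: rate in arm 2 < rate in arm 1.

    Conditional on the margins, x2 ~ hypergeometric; the one-tailed p is
    P(X2 <= x2). Vectorised over replicate count arrays; agrees with
    scipy.stats.fisher_exact(alternative='less') per table.
    """
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    return sps.hypergeom.cdf(x2, n1 + n2, x1 + x2, n2)


def fisher_power_simulation(
    baseline_rate: float,
    relative_reduction: float,
    n_per_arm: int,
    alpha: float = 0.04,
    tails: str = "one",
    replicates: int = 10_000,
    seed: int = 0,
) -> PowerEstimate:
    """Monte-Carlo power of the Fisher exact test for a proportion reduction.

    Arm 1 events ~ Binomial(n, baseline_rate); arm 2 events ~ Binomial(n,
    baseline_rate * (1 - relative_reduction)). Power is the fraction of
    replicates with p < alpha. Bit-reproducible under a fixed seed.
    """
    if not 0 < baseline_rate < 1:
        raise ValueError("baseline_rate must be in (0, 1)")
    reduced = baseline_rate * (1.0 - relative_reduction)
    if not 0 <= reduced < 1:
        raise ValueError("reduced rate must be in [0, 1)")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n_per_arm, baseline_rate, size=replicates)
    x2 = rng.binomial(n_per_arm, reduced, size=replicates)
    if tails == "one":
        p = fisher_one_tailed_p(x1, x2, n_per_arm, n_per_arm)
    else:
        lower = fisher_one_tailed_p(x1, x2, n_per_arm, n_per_arm)
        upper = sps.hypergeom.sf(x2 - 1, 2 * n_per_arm, x1 + x2, n_per_arm)
        p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    power = float(np.mean(p < alpha))
    return PowerEstimate(
        baseline_rate, relative_reduction, n_per_arm, alpha, tails, replicates, seed, power
    )
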