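"""Statistical toolkit: Welch from summaries, circular two-sample tests,
and the Hutchinson size-ratio null-model battery.

The circular tests operate on angles in degrees at the interface (radians
internally).  The size-ratio battery tests whether coexisting species' body
sizes are more regularly spaced than a uniform null with the community's
observed extremes held fixed — small variance/minimum metrics indicate
regular spacing (character displacement), hence lower-tail p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class CircularTestResult:
    statistic: float
    p_asymptotic: float | None
    p_randomization: float | None
    n_permutations: int | None
    seed: int | None


@dataclass(frozen=True)
class SizeRatioTest:
    variance_ratio: float
    variance_difference: float
    minimum_ratio: float
    minimum_difference: float
    p_values: dict
    null_means: dict
    iterations: int
    seed: int


def welch_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int) -> WelchResult:
    """Welch's two-sample t-test from summary statistics (two-sided), with
    the Welch–Satterthwaite degrees of freedom."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("sds must be >= 0 and not both zero")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=False)
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return WelchResult(t=float(res.statistic), df=float(df),
                       p=float(res.pvalue))


def _check_angles(a, b, minimum=4):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < minimum or b.size < minimum:
        raise ValueError(f"each sample needs at least {minimum} angles")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("angles must be finite (undefined angles excluded)")
    return a, b


def _watson_u2(a: np.ndarray, b: np.ndarray) -> float:
    # two-sample Watson U^2 on the pooled ordering
    n, m = a.size, b.size
    N = n + m
    pooled = np.concatenate([a, b])
    labels = np.concatenate([np.ones(n), np.zeros(m)])
    order = np.argsort(pooled, kind="stable")
    is_a = labels[order]
    d = np.cumsum(is_a) / n - np.cumsum(1 - is_a) / m
    return float(n * m / N ** 2 * (np.sum(d ** 2) - np.sum(d) ** 2 / N))


def _watson_tail(u2: float, terms: int = 50) -> float:
    # limiting distribution of U^2: P(U2 > u) = 2 sum (-1)^{k-1} exp(-2 k^2 pi^2 u)
    if u2 <= 0:
        return 1.0
    k = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k ** 2 * np.pi ** 2 * u2))
    return float(min(max(p, 0.0), 1.0))


def _mww_w(a: np.ndarray, b: np.ndarray) -> float:
    # uniform-scores (Mardia-Watson-Wheeler) statistic on circular ranks
    n, m = a.size, b.size
    N = n + m
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled, method="average")
    beta = 2.0 * np.pi * ranks / N
    ca, sa = np.cos(beta[:n]).sum(), np.sin(beta[:n]).sum()
    cb, sb = np.cos(beta[n:]).sum(), np.sin(beta[n:]).sum()
    return float(2.0 * ((ca ** 2 + sa ** 2) / n + (cb ** 2 + sb ** 2) / m))


def _randomization_p(stat_fn, a, b, n_permutations, seed, observed):
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n = a.size
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if stat_fn(perm[:n], perm[n:]) >= observed - 1e-12:
            count += 1
    return (1 + count) / (n_permutations + 1)


def watson_two_sample(angles_a, angles_b, mode: str = "asymptotic",
                      n_permutations: int = 999,
                      seed: int = 0) -> CircularTestResult:
    """Watson's two-sample U² test of homogeneity on the circle.

    ``mode`` is one of ``asymptotic``, ``randomization``, ``both``.  The
    asymptotic p uses the limiting U² tail series; the randomization p
    permutes group labels, p = (1 + #{U²_perm >= U²_obs}) / (B + 1).
    """
    a, b = _check_angles(angles_a, angles_b)
    a, b = np.radians(a) % (2 * np.pi), np.radians(b) % (2 * np.pi)
    u2 = _watson_u2(a, b)
    p_asym = _watson_tail(u2) if mode in ("asymptotic", "both") else None
    p_rand = None
    if mode in ("randomization", "both"):
        p_rand = _randomization_p(_watson_u2, a, b, n_permutations, seed, u2)
    if mode not in ("asymptotic", "randomization", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    return CircularTestResult(statistic=u2, p_asymptotic=p_asym,
                              p_randomization=p_rand,
                              n_permutations=(n_permutations if p_rand is not None else None),
                              seed=(seed if p_rand is not None else None))


def mardia_watson_wheeler(angles_a, angles_b, mode: str = "asymptotic",
                          n_permutations: int = 999,
                          seed: int = 0) -> CircularTestResult:
    """Mardia–Watson–Wheeler (uniform-scores) two-sample test.

    Large-sample p from the chi-square distribution with 2 df; randomization
    version permutes group labels.
    """
    a, b = _check_angles(angles_a, angles_b)
    a, b = np.radians(a) % (2 * np.pi), np.radians(b) % (2 * np.pi)
    w = _mww_w(a, b)
    p_asym = float(sps.chi2.sf(w, df=2)) if mode in ("asymptotic", "both") else None
    p_rand = None
    if mode in ("randomization", "both"):
        p_rand = _randomization_p(_mww_w, a, b, n_permutations, seed, w)
    if mode not in ("asymptotic", "randomization", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    return CircularTestResult(statistic=w, p_asymptotic=p_asym,
                              p_randomization=p_rand,
                              n_permutations=(n_permutations if p_rand is not None else None),
                              seed=(seed if p_rand is not None else None))


def _size_metrics(sizes: np.ndarray) -> tuple[float, float, float, float]:
    s = np.sort(sizes)
    ratios = s[1:] / s[:-1]          # larger / next larger, always >= 1
    diffs = np.diff(s)
    return (float(np.var(ratios, ddof=1)) if ratios.size > 1 else 0.0,
            float(np.var(diffs, ddof=1)) if diffs.size > 1 else 0.0,
            float(ratios.min()), float(diffs.min()))


def size_ratio_null_test(sizes, iterations: int = 1000,
                         seed: int = 0) -> SizeRatioTest:
    """Test regular spacing of body sizes against a uniform null.

    Observed metrics on the sorted sizes: variance of adjacent size ratios,
    variance of adjacent differences, minimum adjacent ratio, minimum
    adjacent difference.  Null communities keep the observed extremes fixed
    and redraw the interior sizes i.i.d. Uniform(min, max); lower-tail
    p = (1 + #{null <= observed}) / (iterations + 1) per metric.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size < 3:
        raise ValueError("need at least 3 sizes")
    if (sizes <= 0).any():
        raise ValueError("sizes must be positive")
    obs = _size_metrics(sizes)
    names = ("variance_ratio", "variance_difference",
             "minimum_ratio", "minimum_difference")
    lo, hi = sizes.min(), sizes.max()
    rng = np.random.default_rng(seed)
    counts = np.zeros(4)
    sums = np.zeros(4)
    k = sizes.size - 2
    for _ in range(iterations):
        interior = rng.uniform(lo, hi, size=k)
        null = _size_metrics(np.concatenate([[lo, hi], interior]))
        for i in range(4):
            sums[i] += null[i]
            if null[i] <= obs[i] + 1e-15:
                counts[i] += 1
    p = {nm: float((1 + c) / (iterations + 1)) for nm, c in zip(names, counts)}
    means = {nm: float(s / iterations) for nm, s in zip(names, sums)}
    return SizeRatioTest(variance_ratio=obs[0], variance_difference=obs[1],
                         minimum_ratio=obs[2], minimum_difference=obs[3],
                         p_values=p, null_means=means,
                         iterations=iterations, seed=seed)
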