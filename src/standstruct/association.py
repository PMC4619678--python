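"""Sign-concordance covariation and permutation tests on plot-level values.

The covariation statistic for paired plot-level variables (X_i, Y_i) is

    C = sum_{i<j} (X_i - X_j)(Y_i - Y_j) / sum_{i<j} |(X_i - X_j)(Y_i - Y_j)|

a pure sign-concordance measure over all plot pairs: C = 1 for entirely
positive (monotone) covariation, C = -1 for strictly negative covariation,
and undefined when the denominator vanishes (e.g. one variable constant).
Unlike a correlation coefficient it responds only to the direction of each
pairwise difference, so it detects monotone but not necessarily linear
relationships.

Inference is by permutation: Y is shuffled against X (one-sided, in the
direction of the observed sign of C), and differences of group means are
tested by random reassignment of the pooled values.  All Monte-Carlo
p-values use the add-one estimator (1 + #extreme) / (n_perm + 1); small
problems can be enumerated exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb, factorial

import numpy as np

from .pattern import PatternError


@dataclass(frozen=True)
class CovariationResult:
    name_x: str
    name_y: str
    x: np.ndarray
    y: np.ndarray
    c: float                    # nan when undefined
    undefined: bool
    p: float | None = None      # one-sided permutation p, direction of sign(c)
    n_perm: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class GroupDiffResult:
    label_a: str
    label_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    diff: float                 # mean(a) - mean(b)
    p: float                    # two-sided permutation p
    n_perm: int
    exact: bool = False
    seed: int | None = None


def _pair_products(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(len(x), k=1)
    return (x[i] - x[j]) * (y[i] - y[j])


def covariation(x, y) -> float:
    """Sign-concordance covariation C in [-1, 1]; nan when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PatternError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise PatternError("covariation needs at least 2 paired values")
    prod = _pair_products(x, y)
    denom = np.abs(prod).sum()
    if denom == 0:
        return float("nan")
    return float(prod.sum() / denom)


def covariation_test(x, y, n_perm: int = 10_000, seed=None,
                     name_x: str = "X", name_y: str = "Y") -> CovariationResult:
    """One-sided permutation test of C, tail in the observed direction.

    Y is permuted against X ``n_perm`` times; for C_obs >= 0 the p-value
    counts permutations with C >= C_obs, for C_obs < 0 those with
    C <= C_obs, both with the add-one estimator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c_obs = covariation(x, y)
    if np.isnan(c_obs):
        raise PatternError(
            f"C[{name_x} x {name_y}] is undefined (zero denominator); "
            "no permutation test possible")
    if len(x) == 2:
        warnings.warn("n = 2 gives a permutation p of only 0.5 or 1",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    i, j = np.triu_indices(len(x), k=1)
    dx = x[i] - x[j]
    perms = np.array([rng.permutation(y) for _ in range(n_perm)])
    dy = perms[:, i] - perms[:, j]
    prod = dx[None, :] * dy
    denom = np.abs(prod).sum(axis=1)
    with np.errstate(invalid="ignore"):
        c_perm = prod.sum(axis=1) / denom
    c_perm = np.where(denom == 0, 0.0, c_perm)
    extreme = (c_perm >= c_obs) if c_obs >= 0 else (c_perm <= c_obs)
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return CovariationResult(
        name_x=name_x, name_y=name_y, x=x, y=y, c=c_obs, undefined=False,
        p=float(p), n_perm=n_perm,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None)


def covariation_test_exact(x, y) -> float:
    """Exact one-sided p over all permutations of Y (n <= 8 recommended)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c_obs = covariation(x, y)
    if np.isnan(c_obs):
        raise PatternError("C undefined; no test possible")
    total = factorial(len(y))
    count = 0
    for perm in permutations(y):
        c = covariation(x, np.asarray(perm))
        c = 0.0 if np.isnan(c) else c
        if (c >= c_obs) if c_obs >= 0 else (c <= c_obs):
            count += 1
    return count / total


def group_mean_diff_test(values_a, values_b, n_perm: int = 10_000, seed=None,
                         label_a: str = "A", label_b: str = "B",
                         method: str = "auto") -> GroupDiffResult:
    """Two-sided permutation test of a difference of group means.

    ``Diff = mean(a) - mean(b)``; the null distribution comes from random
    reassignments of the pooled values to the two group sizes.  With
    ``method='auto'`` the test enumerates all C(n_a + n_b, n_a) assignments
    exactly when there are at most 20,000 of them, otherwise it samples
    ``n_perm`` reassignments and applies the add-one estimator.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise PatternError("both groups must be non-empty")
    diff_obs = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a = len(a)
    tol = 1e-12 * max(1.0, float(np.abs(pooled).max()))
    n_total = len(pooled)
    n_exact = comb(n_total, n_a)
    if method == "exact" or (method == "auto" and n_exact <= 20_000):
        count = 0
        idx_all = range(n_total)
        for pick in combinations(idx_all, n_a):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(pick)] = True
            d = pooled[mask].mean() - pooled[~mask].mean()
            if abs(d) >= abs(diff_obs) - tol:
                count += 1
        return GroupDiffResult(label_a, label_b, a, b, diff_obs,
                               p=count / n_exact, n_perm=n_exact, exact=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:n_a].mean() - perm[n_a:].mean()
        if abs(d) >= abs(diff_obs) - tol:
            count += 1
    return GroupDiffResult(
        label_a, label_b, a, b, diff_obs, p=(1 + count) / (n_perm + 1),
        n_perm=n_perm, exact=False,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None)


def apply_family_correction(p_values, alpha: float = 0.05,
                            m: int | None = None):
    """Bonferroni family correction: flags p < alpha/m and the new level.

    ``m`` defaults to the number of p-values supplied; pass it explicitly
    when the family is larger than the values at hand.  Returns
    ``(flags, threshold)``.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else int(m)
    if m < 1:
        raise PatternError("m must be >= 1")
    threshold = alpha / m
    return p < threshold, threshold
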