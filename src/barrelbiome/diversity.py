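"""Alpha and beta diversity with group testing.

Alpha diversity is the Shannon index in bits (log base 2, the QIIME
convention; the base is switchable).  Beta diversity is the Bray-Curtis
dissimilarity on rarefied counts, ordinated by classical principal
coordinate analysis (Gower centering + eigendecomposition) and tested by
PERMANOVA with a seeded permutation scheme.  When the permutation space of
the label multiset is small (<= ``max_exhaustive`` arrangements) PERMANOVA
enumerates it exhaustively, which matters at the n=2-per-group scale of
barrel experiments where Monte Carlo resolution is wasteful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sympy.utilities.iterables import multiset_permutations

from .table_io import OtuTable
from .rarefaction import RarefiedTable

__all__ = [
    "shannon",
    "GroupTestResult",
    "alpha_group_test",
    "bray_curtis",
    "Ordination",
    "pcoa",
    "PermanovaResult",
    "permanova",
]

_EPS = 1e-12


def shannon(sample_counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i over nonzero proportions."""
    x = np.asarray(sample_counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector of counts")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector has no defined diversity")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / math.log(base))).sum())


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    design: str
    levels: tuple[str, ...]
    df: tuple[float, ...]


def _ordered_levels(labels) -> tuple[list, list[np.ndarray]]:
    labels = [str(l) for l in labels]
    levels: list[str] = []
    for l in labels:
        if l not in levels:
            levels.append(l)
    arr = np.asarray(labels)
    return levels, [np.flatnonzero(arr == l) for l in levels]


def alpha_group_test(
    values, labels, design: str, equal_var: bool = True
) -> GroupTestResult:
    """Student's t (two levels) or one-way ANOVA F test on per-sample values.

    The t statistic follows the group1 - group2 sign convention, groups
    ordered by first appearance in ``labels``.  ``equal_var=False`` selects
    the Welch form.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(list(labels)):
        raise ValueError("values and labels differ in length")
    levels, groups = _ordered_levels(labels)
    if any(len(g) == 0 for g in groups):
        raise ValueError("every factor level needs at least one observation")
    if design == "two_group_t":
        if len(levels) != 2:
            raise ValueError(f"two_group_t requires exactly 2 levels, got {len(levels)}")
        a, b = values[groups[0]], values[groups[1]]
        if len(a) + len(b) - 2 < 1:
            raise ValueError("zero residual degrees of freedom")
        if np.var(a) + np.var(b) == 0:
            if a.mean() == b.mean():
                return GroupTestResult(0.0, 1.0, design, tuple(levels),
                                       (float(len(a) + len(b) - 2),))
            stat = math.inf if a.mean() > b.mean() else -math.inf
            return GroupTestResult(stat, 0.0, design, tuple(levels),
                                   (float(len(a) + len(b) - 2),))
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        return GroupTestResult(
            float(res.statistic), float(res.pvalue), design, tuple(levels),
            (float(res.df),),
        )
    if design == "one_way_anova":
        if len(levels) < 2:
            raise ValueError("one_way_anova requires at least 2 levels")
        n, g = len(values), len(levels)
        if n - g < 1:
            raise ValueError("zero residual degrees of freedom")
        grand = values.mean()
        ss_between = sum(len(idx) * (values[idx].mean() - grand) ** 2 for idx in groups)
        ss_within = sum(((values[idx] - values[idx].mean()) ** 2).sum() for idx in groups)
        df1, df2 = g - 1, n - g
        if ss_within <= _EPS * max(1.0, ss_between):
            if ss_between <= _EPS:
                return GroupTestResult(0.0, 1.0, design, tuple(levels), (df1, df2))
            return GroupTestResult(math.inf, 0.0, design, tuple(levels), (df1, df2))
        F = (ss_between / df1) / (ss_within / df2)
        p = float(stats.f.sf(F, df1, df2))
        return GroupTestResult(float(F), p, design, tuple(levels), (float(df1), float(df2)))
    raise ValueError(f"unknown design: {design!r}")


def bray_curtis(table: OtuTable | RarefiedTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples, on counts.

    d(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum x + sum y).
    """
    counts = table.counts.astype(float)
    sums = counts.sum(axis=0)
    if np.any(sums == 0):
        j = int(np.flatnonzero(sums == 0)[0])
        raise ValueError(f"all-zero sample column: {table.samples[j]!r}")
    condensed = pdist(counts.T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(table.samples))


def _as_distance_matrix(dm) -> DistanceMatrix:
    if isinstance(dm, DistanceMatrix):
        return dm
    arr = np.asarray(dm, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return DistanceMatrix(arr)  # also validates the zero diagonal


@dataclass(frozen=True)
class Ordination:
    """PCoA result: axes ordered by descending eigenvalue.

    ``coordinates`` keeps only positive-eigenvalue axes (scaled eigenvectors);
    ``eigenvalues`` retains the full spectrum, negative values included, so
    non-Euclidean distortion stays visible.  The sign of each axis is fixed
    so its largest-magnitude coordinate is positive.
    """

    samples: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix."""
    dm = _as_distance_matrix(dm)
    d = dm.data
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    d2 = d ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ d2 @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-9
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigvals[keep].sum()
    prop = eigvals[keep] / pos_sum if pos_sum > 0 else eigvals[keep]
    return Ordination(
        samples=tuple(dm.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    group_sizes: dict = field(compare=False)
    method: str = "monte_carlo"


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dm,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
    max_exhaustive: int = 10_000,
) -> PermanovaResult:
    """PERMANOVA pseudo-F with a permutation p-value.

    If the number of distinct label arrangements is at most
    ``max_exhaustive`` the full permutation distribution is enumerated and
    the p-value is exact (the observed arrangement counts itself); otherwise
    ``n_permutations`` seeded Monte Carlo permutations are drawn and
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    dm = _as_distance_matrix(dm)
    levels, groups = _ordered_levels(labels)
    n = dm.shape[0]
    if len(list(labels)) != n:
        raise ValueError("labels length does not match the distance matrix")
    if len(levels) < 2:
        raise ValueError("need at least 2 factor levels (no between-group df)")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one sample")
    if n <= len(levels):
        raise ValueError("need more samples than factor levels")
    codes = np.empty(n, dtype=np.int64)
    for g, idx in enumerate(groups):
        codes[idx] = g
    sizes = {lvl: len(idx) for lvl, idx in zip(levels, groups)}
    d2 = dm.data ** 2
    f_obs = _pseudo_f(d2, codes, len(levels))

    n_arrangements = math.factorial(n)
    for sz in sizes.values():
        n_arrangements //= math.factorial(sz)
    if n_arrangements <= max_exhaustive:
        hits = 0
        for arrangement in multiset_permutations(codes.tolist()):
            if _pseudo_f(d2, np.asarray(arrangement), len(levels)) >= f_obs - _EPS:
                hits += 1
        return PermanovaResult(
            pseudo_F=f_obs,
            p_value=hits / n_arrangements,
            n_permutations=n_arrangements,
            group_sizes=sizes,
            method="exhaustive",
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(levels)) >= f_obs - _EPS:
            hits += 1
    return PermanovaResult(
        pseudo_F=f_obs,
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        group_sizes=sizes,
        method="monte_carlo",
    )
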