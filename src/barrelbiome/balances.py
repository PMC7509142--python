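"""Balance construction over a Ward bipartition of genera.

The procedure mirrors the single top split of a balance-tree analysis:
zero counts are imputed so log-ratios are defined, genera are clustered
into two (anti-correlated) groups by Ward-linkage hierarchical clustering
of their standardized CLR profiles, and the isometric log-ratio (ILR)
coordinate contrasting the two groups is computed per sample,

    balance_j = sqrt(r s / (r + s)) * ln( g_num(j) / g_den(j) ),

with r, s the group sizes and g the within-group geometric mean.  The full
nested balance tree is deliberately out of scope; only the two-group split
is built.

Numerator/denominator assignment is a pure convention (the group holding
the lexicographically smallest genus label becomes the numerator), since a
balance's sign is arbitrary up to group swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio.stats.composition import multi_replace

from .diversity import GroupTestResult, alpha_group_test
from .table_io import OtuTable

__all__ = [
    "CompositionTable",
    "Bipartition",
    "BalanceVector",
    "impute_zeros",
    "ward_bipartition",
    "bipartition_from_annotations",
    "ilr_balance",
    "balance_group_test",
]


@dataclass(frozen=True)
class CompositionTable:
    """Strictly positive real values per (genus, sample) cell."""

    taxa: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.ascontiguousarray(self.values, dtype=float)
        if values.shape != (len(self.taxa), len(self.samples)):
            raise ValueError("values shape does not match taxa/samples")
        if not np.all(values > 0):
            i, j = np.argwhere(~(values > 0))[0]
            raise ValueError(
                f"non-positive value at ({self.taxa[i]!r}, {self.samples[j]!r})"
            )
        values.setflags(write=False)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class Bipartition:
    """Disjoint numerator/denominator genus sets covering all genera."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    linkage_history: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        num, den = set(self.numerator), set(self.denominator)
        if not num or not den:
            raise ValueError("both sides of a bipartition must be nonempty")
        if num & den:
            raise ValueError(f"sides overlap: {sorted(num & den)}")
        object.__setattr__(self, "numerator", tuple(self.numerator))
        object.__setattr__(self, "denominator", tuple(self.denominator))

    def side_of(self, genus: str) -> str:
        if genus in self.numerator:
            return "numerator"
        if genus in self.denominator:
            return "denominator"
        raise KeyError(f"genus {genus!r} not in bipartition")

    def swapped(self) -> "Bipartition":
        return Bipartition(self.denominator, self.numerator, self.linkage_history)


@dataclass(frozen=True)
class BalanceVector:
    samples: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.samples),):
            raise ValueError("one balance value per sample required")
        if not np.all(np.isfinite(values)):
            raise ValueError("balances must be finite")
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "values", values)


def impute_zeros(
    table: OtuTable,
    method: str = "pseudocount",
    pseudocount: float = 1.0,
) -> CompositionTable:
    """Replace zero counts so every cell is strictly positive.

    ``pseudocount``: add the pseudocount to every cell (counts scale).
    ``multiplicative_replacement``: per sample, zeros become delta
    (= ``pseudocount``) and nonzero proportions are rescaled to keep the unit
    sum (proportions scale).  Balances are per-sample scale-invariant, so the
    two scales are interchangeable downstream.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    counts = table.counts.astype(float)
    if method == "pseudocount":
        values = counts + pseudocount
    elif method == "multiplicative_replacement":
        sums = counts.sum(axis=0)
        if np.any(sums == 0):
            j = int(np.flatnonzero(sums == 0)[0])
            raise ValueError(f"all-zero sample column: {table.samples[j]!r}")
        props = (counts / sums).T  # samples x taxa, as composition rows
        values = np.atleast_2d(multi_replace(props, delta=pseudocount)).T
    else:
        raise ValueError(f"unknown imputation method: {method!r}")
    return CompositionTable(table.taxa, table.samples, values)


def _clr(values: np.ndarray) -> np.ndarray:
    logv = np.log(values)
    return logv - logv.mean(axis=0, keepdims=True)


def ward_bipartition(
    comp: CompositionTable, feature_distance: str = "clr_euclidean"
) -> Bipartition:
    """Split genera into two groups by Ward hierarchical clustering.

    ``clr_euclidean`` (default): Euclidean distance between per-genus CLR
    profiles z-scored across samples, so genera cluster by the shape of
    their trajectory rather than by abundance magnitude — this is what
    recovers anti-correlated groups.  ``proportion_correlation``:
    1 - Pearson r between per-genus proportion profiles.

    Ward merge ties are resolved deterministically (lowest cluster index
    first, the scipy convention), so the split is reproducible.
    """
    if len(comp.taxa) < 2:
        raise ValueError("need at least 2 taxa to bipartition")
    if feature_distance == "clr_euclidean":
        profiles = _clr(comp.values)
        mu = profiles.mean(axis=1, keepdims=True)
        sd = profiles.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0  # constant profiles carry no trajectory signal
        z = (profiles - mu) / sd
        merges = linkage(z, method="ward")
    elif feature_distance == "proportion_correlation":
        props = comp.values / comp.values.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(props)
        corr = np.nan_to_num(corr, nan=0.0)  # constant profiles: treat as uncorrelated
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        merges = linkage(squareform(dist, checks=False), method="ward")
    else:
        raise ValueError(f"unknown feature_distance: {feature_distance!r}")
    assignment = fcluster(merges, t=2, criterion="maxclust")
    group1 = tuple(t for t, a in zip(comp.taxa, assignment) if a == 1)
    group2 = tuple(t for t, a in zip(comp.taxa, assignment) if a == 2)
    if not group1 or not group2:  # all-identical profiles can collapse the cut
        group1, group2 = comp.taxa[:1], comp.taxa[1:]
    if min(group2) < min(group1):
        group1, group2 = group2, group1
    return Bipartition(numerator=group1, denominator=group2, linkage_history=merges)


def bipartition_from_annotations(table: OtuTable) -> Bipartition:
    """Build a bipartition from a table's per-genus annotation marks.

    The packaged tables carry the two printed group superscripts; the group
    holding the lexicographically smallest genus becomes the numerator, per
    the package-wide sign convention.
    """
    if not table.annotations:
        raise ValueError("table has no genus annotations")
    marks = sorted(set(table.annotations.values()))
    if len(marks) != 2:
        raise ValueError(f"expected exactly 2 annotation marks, got {marks}")
    g1 = tuple(t for t in table.taxa if table.annotations[t] == marks[0])
    g2 = tuple(t for t in table.taxa if table.annotations[t] == marks[1])
    if min(g2) < min(g1):
        g1, g2 = g2, g1
    return Bipartition(numerator=g1, denominator=g2)


def ilr_balance(comp: CompositionTable, part: Bipartition) -> BalanceVector:
    """The single ILR coordinate contrasting the bipartition's two groups."""
    covered = set(part.numerator) | set(part.denominator)
    if covered != set(comp.taxa):
        raise ValueError("bipartition does not cover exactly the table's taxa")
    pos = {t: i for i, t in enumerate(comp.taxa)}
    num_idx = [pos[t] for t in part.numerator]
    den_idx = [pos[t] for t in part.denominator]
    r, s = len(num_idx), len(den_idx)
    logv = np.log(comp.values)
    coef = np.sqrt(r * s / (r + s))
    values = coef * (logv[num_idx].mean(axis=0) - logv[den_idx].mean(axis=0))
    return BalanceVector(samples=comp.samples, values=values)


def balance_group_test(
    bal: BalanceVector, labels, design: str, equal_var: bool = True
) -> GroupTestResult:
    """t/ANOVA test on balance values; identical contract to alpha testing."""
    return alpha_group_test(bal.values, labels, design, equal_var=equal_var)
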