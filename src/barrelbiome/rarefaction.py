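"""Rarefaction: subsampling count tables to a common depth.

Each sample is subsampled independently WITHOUT replacement (multivariate
hypergeometric draw from the sample's reads), matching the single-rarefaction
semantics of the QIIME lineage of tools.  A single global seed is split per
sample by sample index, so runs are reproducible while samples stay
independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table_io import OtuTable

__all__ = ["RarefiedTable", "rarefy", "rarefaction_curve"]


@dataclass(frozen=True)
class RarefiedTable:
    """An OtuTable whose sample columns all sum exactly to ``depth``."""

    table: OtuTable
    depth: int
    seed: int

    def __post_init__(self) -> None:
        sums = self.table.sample_sums
        if not np.all(sums == self.depth):
            j = int(np.flatnonzero(sums != self.depth)[0])
            raise ValueError(
                f"sample {self.table.samples[j]!r} sums to {sums[j]}, "
                f"expected depth {self.depth}"
            )

    # convenience pass-throughs so rarefied tables can be used wherever an
    # OtuTable is expected
    @property
    def taxa(self):
        return self.table.taxa

    @property
    def samples(self):
        return self.table.samples

    @property
    def counts(self):
        return self.table.counts


def _sample_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> RarefiedTable:
    """Subsample every sample column to exactly ``depth`` reads.

    ``depth=None`` uses the minimum column sum of the input (the convention
    that produces a "rarefaction threshold of <min> sequences per sample").
    """
    sums = table.sample_sums
    if depth is None:
        depth = int(sums.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if np.any(sums < depth):
        j = int(np.argmin(sums))
        raise ValueError(
            f"depth {depth} exceeds the {sums[j]} reads of the shallowest "
            f"sample {table.samples[j]!r}"
        )
    rngs = _sample_rngs(seed, len(table.samples))
    out = np.empty_like(table.counts)
    for j, rng in enumerate(rngs):
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    rarefied = OtuTable(table.taxa, table.samples, out, table.annotations)
    return RarefiedTable(table=rarefied, depth=depth, seed=seed)


def rarefaction_curve(
    table: OtuTable,
    depths: list[int],
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean number of observed genera per sample at each subsampling depth.

    Returns a DataFrame (samples x depths) of means over ``replicates``
    independent draws; depths above a sample's total read count yield NaN for
    that sample.
    """
    depths = [int(d) for d in depths]
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    if depths != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    sums = table.sample_sums
    rngs = _sample_rngs(seed, len(table.samples))
    result = np.full((len(table.samples), len(depths)), np.nan)
    for j, rng in enumerate(rngs):
        col = table.counts[:, j]
        for k, d in enumerate(depths):
            if d > sums[j]:
                continue
            obs = [
                int(np.count_nonzero(rng.multivariate_hypergeometric(col, d)))
                for _ in range(replicates)
            ]
            result[j, k] = float(np.mean(obs))
    return pd.DataFrame(result, index=list(table.samples), columns=depths)
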