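"""Dirichlet-multinomial community simulator with a planted bipartition.

The generator emulates the structure the analysis assumes: two groups of
genera whose group-sum log2 ratio drifts linearly with aging time,

    log2( sum_num / sum_den )  =  base_log_ratio + time_slope * months_j,

with within-group genus weights following a geometric series (communities
dominated by one genus per group, as in wine).  Expected proportions are
perturbed by a Dirichlet draw (concentration = dispersion x expected
proportions, the standard overdispersed model for amplicon counts) and
counts are drawn multinomially at a fixed depth, so every sample column
sums exactly to ``depth``.

The contract is structural — a recoverable planted bipartition and a
monotone balance drift — not distributional fidelity to any particular
wine.  ``null_generate`` zeroes the time slope for type-I-error
calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .table_io import OtuTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "null_generate"]

_DEFAULT_MONTHS = (0, 0, 3, 3, 6, 6, 9, 9, 12)


@dataclass(frozen=True)
class SyntheticSpec:
    """Simulation parameters.

    Defaults mirror the scale of the barrel experiments: 9 samples over a
    0-12-month design, ~30,000 reads per sample, 20 genera split 10/10, a
    drift of 0.3 log2 units per month, moderate overdispersion
    (concentration 500) and geometric within-group evenness 0.8.
    """

    n_samples: int = 9
    n_genera: int = 20
    numerator_size: int = 10
    depth: int = 30_000
    base_log_ratio: float = 0.0
    time_slope: float = 0.3
    months: tuple[int, ...] = _DEFAULT_MONTHS
    dispersion: float = 500.0
    background_evenness: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_genera < 2:
            raise ValueError("n_genera must be >= 2")
        if not 1 <= self.numerator_size <= self.n_genera - 1:
            raise ValueError(
                f"numerator_size must lie in [1, {self.n_genera - 1}], "
                f"got {self.numerator_size}"
            )
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if len(self.months) != self.n_samples:
            raise ValueError("months must supply one value per sample")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.background_evenness <= 0:
            raise ValueError("background_evenness must be positive")
        if self.depth < self.n_genera:
            warnings.warn(
                "depth below n_genera: rare genera will rarely be observed",
                stacklevel=2,
            )


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the partition, expected signals and driver genera."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    expected_proportions: pd.DataFrame = field(compare=False)
    expected_log2_sum_ratio: np.ndarray = field(compare=False)
    expected_balance: np.ndarray = field(compare=False)
    drivers: tuple[str, ...]


def _geometric_weights(size: int, evenness: float) -> np.ndarray:
    w = evenness ** np.arange(size)
    return w / w.sum()


def generate(spec: SyntheticSpec) -> tuple[OtuTable, pd.DataFrame, GroundTruth]:
    """Draw one synthetic table; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_gen, n_num = spec.n_genera, spec.numerator_size
    taxa = tuple(f"g{i:02d}" for i in range(n_gen))
    perm = rng.permutation(n_gen)  # group membership decoupled from row order
    num_idx = np.sort(perm[:n_num])
    den_idx = np.sort(perm[n_num:])
    w_num = _geometric_weights(n_num, spec.background_evenness)
    w_den = _geometric_weights(n_gen - n_num, spec.background_evenness)

    months = np.asarray(spec.months, dtype=float)
    log2_ratio = spec.base_log_ratio + spec.time_slope * months
    q = 2.0 ** log2_ratio / (1.0 + 2.0 ** log2_ratio)  # numerator group share

    expected = np.zeros((n_gen, spec.n_samples))
    expected[num_idx] = np.outer(w_num, q)
    expected[den_idx] = np.outer(w_den, 1.0 - q)

    counts = np.zeros((n_gen, spec.n_samples), dtype=np.int64)
    for j in range(spec.n_samples):
        gamma = rng.gamma(spec.dispersion * expected[:, j])
        p = gamma / gamma.sum()
        counts[:, j] = rng.multinomial(spec.depth, p)

    # expected balance, by direct arithmetic on the expected proportions
    r, s = n_num, n_gen - n_num
    coef = np.sqrt(r * s / (r + s))
    gmean_num = np.exp(np.log(expected[num_idx]).mean(axis=0))
    gmean_den = np.exp(np.log(expected[den_idx]).mean(axis=0))
    expected_balance = coef * np.log(gmean_num / gmean_den)

    sample_ids = tuple(f"S{j:02d}" for j in range(spec.n_samples))
    table = OtuTable(taxa=taxa, samples=sample_ids, counts=counts)
    history = np.where(np.arange(spec.n_samples) % 2 == 0, "old", "new")
    meta = pd.DataFrame(
        {
            "cellar": "FB",
            "amplicon": "16S",
            "vessel": "barrel",
            "barrel_history": history,
            "months": np.asarray(spec.months, dtype=int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        numerator=tuple(taxa[i] for i in num_idx),
        denominator=tuple(taxa[i] for i in den_idx),
        expected_proportions=pd.DataFrame(
            expected, index=list(taxa), columns=list(sample_ids)
        ),
        expected_log2_sum_ratio=log2_ratio,
        expected_balance=expected_balance,
        drivers=(taxa[num_idx[0]], taxa[den_idx[0]]),  # dominant genus per side
    )
    return table, meta, truth


def null_generate(spec: SyntheticSpec) -> tuple[OtuTable, pd.DataFrame, GroundTruth]:
    """``generate`` with the time slope forced to zero (no planted effect)."""
    return generate(replace(spec, time_slope=0.0))
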