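"""Orchestration of the full per-cellar, per-amplicon analysis.

Two branches run side by side, as the study design dictates:

* diversity branch — rarefy to a common depth, Shannon alpha diversity with
  t/ANOVA factor tests, Bray-Curtis beta diversity, PCoA, PERMANOVA;
* compositional branch — zero imputation, Ward bipartition of genera, ILR
  balance per sample, factor tests on the balance, and the per-genus impact
  statistic.  This branch takes the input table as provided (unrarefied when
  unrarefied data are supplied; the packaged tables are already rarefied).

Factor definitions follow the barrel-experiment design:

* ``barrel_type`` — barrel samples at months where both an old- and a
  new-barrel sample exist (old vs new).
* ``time`` — barrel samples grouped by month (months with at least two
  samples), plus the bottle-aged samples as one extra group when present.
* ``bottled_wine`` — month-12 samples, barrel vs bottle.
"""

from __future__ import annotations

import hashlib
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .balances import balance_group_test, ilr_balance, impute_zeros, ward_bipartition
from .diversity import alpha_group_test, bray_curtis, pcoa, permanova, shannon
from .impact import compute_impact
from .rarefaction import rarefy
from .table_io import (
    FIXTURE_NAMES,
    OtuTable,
    load_fixture,
    read_metadata,
    read_otu_table,
    relative_abundance,
    validate_metadata,
)

__all__ = ["RunConfig", "factor_subset", "run_analysis", "summarize_abundance"]

logger = logging.getLogger("barrelbiome")

FACTORS = ("barrel_type", "time", "bottled_wine")
_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run (flat, YAML-serializable)."""

    out_dir: str
    fixture: str | None = None
    table: str | None = None
    metadata: str | None = None
    amplicon: str = "16S"
    factors: tuple[str, ...] = ("barrel_type", "time")
    depth: int | str | None = "auto"  # "auto", an int, or None to skip rarefaction
    seed: int = 0
    imputation: str = "pseudocount"
    pseudocount: float = 1.0
    feature_distance: str = "clr_euclidean"
    permutations: int = 999
    ratio: str = "sums"

    def __post_init__(self) -> None:
        if (self.fixture is None) == (self.table is None):
            raise ValueError("provide exactly one of 'fixture' or 'table'")
        if self.fixture is not None and self.fixture not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.fixture!r}")
        if self.table is not None and self.metadata is None:
            raise ValueError("'table' requires a 'metadata' path")
        bad = [f for f in self.factors if f not in FACTORS]
        if bad:
            raise ValueError(f"unknown factor(s) {bad}; known: {FACTORS}")
        object.__setattr__(self, "factors", tuple(self.factors))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "factors" in raw and isinstance(raw["factors"], list):
            raw["factors"] = tuple(raw["factors"])
        return cls(**raw)

    def echo(self, path: Path) -> None:
        data = asdict(self)
        data["factors"] = list(self.factors)
        data["version"] = __version__
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def factor_subset(meta: pd.DataFrame, factor: str) -> tuple[list[str], list[str]]:
    """Sample ids and labels for one design factor.

    Raises ValueError (naming the factor) when fewer than two levels remain
    after filtering.
    """
    if factor == "barrel_type":
        sub = meta[meta["vessel"] == "barrel"]
        by_month = sub.groupby("months")["barrel_history"].nunique()
        keep_months = by_month[by_month == 2].index
        sub = sub[sub["months"].isin(keep_months)]
        labels = sub["barrel_history"].tolist()
    elif factor == "time":
        sub = meta[meta["vessel"] == "barrel"]
        month_counts = sub["months"].value_counts()
        keep_months = month_counts[month_counts >= 2].index
        sub = sub[sub["months"].isin(keep_months)]
        labels = [f"month_{m}" for m in sub["months"]]
        bottles = meta[meta["vessel"] == "bottle"]
        if len(bottles) >= 2:
            sub = pd.concat([sub, bottles])
            labels += [f"bottle_{m}" for m in bottles["months"]]
    elif factor == "bottled_wine":
        sub = meta[(meta["months"] == 12) & meta["vessel"].isin(["barrel", "bottle"])]
        labels = sub["vessel"].tolist()
    else:
        raise ValueError(f"unknown factor {factor!r}; known: {FACTORS}")
    if len(set(labels)) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels after filtering")
    return list(sub.index), labels


def _load_inputs(config: RunConfig) -> tuple[OtuTable, pd.DataFrame]:
    if config.fixture is not None:
        return load_fixture(config.fixture)
    table = read_otu_table(config.table)
    meta = read_metadata(config.metadata)
    validate_metadata(meta, table)
    return table, meta


def _counts_digest(table: OtuTable) -> str:
    return hashlib.md5(table.counts.tobytes()).hexdigest()[:12]


def _write(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index,
                 lineterminator="\n")


def _stage(name: str, t0: float, **params) -> None:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage=%s elapsed=%.3fs %s", name, time.perf_counter() - t0, kv)


def run_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute both branches and write the report bundle to ``out_dir``.

    TSV outputs are deterministic given the config (byte-identical on
    re-run); the run log records seeds, parameters, input hashes and
    the package version.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_analysis(config, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_analysis(config: RunConfig, out_dir: Path) -> dict[str, pd.DataFrame]:
    t0 = time.perf_counter()
    logger.info("barrelbiome %s seed=%d", __version__, config.seed)
    config.echo(out_dir / "config_effective.yaml")
    table, meta = _load_inputs(config)
    _stage("load", t0, input_hash=_counts_digest(table), shape=table.shape)
    results: dict[str, pd.DataFrame] = {}

    # ---------------- diversity branch (rarefied counts) ----------------
    t = time.perf_counter()
    if config.depth is None:
        div_table = table
        depth_used = None
    else:
        depth = None if config.depth == "auto" else int(config.depth)
        rt = rarefy(table, depth=depth, seed=config.seed)
        div_table = rt.table
        depth_used = rt.depth
    _stage("rarefy", t, depth=depth_used, seed=config.seed)

    alpha = pd.DataFrame(
        {"shannon": [shannon(div_table.counts[:, j])
                     for j in range(len(div_table.samples))]},
        index=pd.Index(div_table.samples, name="sample_id"),
    )
    results["alpha"] = alpha
    dm = bray_curtis(div_table)
    ordination = pcoa(dm)
    coords = pd.DataFrame(
        ordination.coordinates,
        index=pd.Index(ordination.samples, name="sample_id"),
        columns=[f"PC{k + 1}" for k in range(ordination.coordinates.shape[1])],
    )
    results["pcoa_coordinates"] = coords
    results["distance_matrix"] = pd.DataFrame(
        dm.data, index=pd.Index(dm.ids, name="sample_id"), columns=list(dm.ids)
    )
    results["relative_abundance"] = relative_abundance(table)

    # ---------------- compositional branch (as-provided counts) ----------
    t = time.perf_counter()
    comp = impute_zeros(table, method=config.imputation, pseudocount=config.pseudocount)
    part = ward_bipartition(comp, feature_distance=config.feature_distance)
    bal = ilr_balance(comp, part)
    _stage("balances", t, imputation=config.imputation,
           feature_distance=config.feature_distance,
           numerator_size=len(part.numerator))
    results["bipartition"] = pd.DataFrame(
        {"side": [part.side_of(g) for g in table.taxa]},
        index=pd.Index(table.taxa, name="genus"),
    )
    results["balances"] = pd.DataFrame(
        {"balance": bal.values}, index=pd.Index(bal.samples, name="sample_id")
    )
    impacts = compute_impact(comp, part, ratio=config.ratio)
    impacts["rank"] = np.arange(1, len(impacts) + 1)
    results["impacts"] = impacts.set_index("genus")

    # ---------------- per-factor tests -----------------------------------
    perm_rows, test_rows = [], []
    for factor in config.factors:
        t = time.perf_counter()
        ids, labels = factor_subset(meta, factor)
        design = "two_group_t" if len(set(labels)) == 2 else "one_way_anova"
        alpha_res = alpha_group_test(alpha.loc[ids, "shannon"], labels, design)
        bal_by_sample = dict(zip(bal.samples, bal.values))
        bal_res = balance_group_test(
            type(bal)(tuple(ids), np.array([bal_by_sample[s] for s in ids])),
            labels,
            design,
        )
        sub_dm = dm.filter(ids)
        factor_seed = (config.seed * 100_003 + zlib.crc32(factor.encode())) % (2**31)
        perm_res = permanova(
            sub_dm, labels, n_permutations=config.permutations, seed=factor_seed
        )
        perm_rows.append(
            {
                "factor": factor,
                "pseudo_F": perm_res.pseudo_F,
                "p_value": perm_res.p_value,
                "n_permutations": perm_res.n_permutations,
                "method": perm_res.method,
                "n_samples": len(ids),
            }
        )
        for branch, res in ("alpha", alpha_res), ("balance", bal_res):
            test_rows.append(
                {
                    "factor": factor,
                    "branch": branch,
                    "design": res.design,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
        _stage("factor", t, factor=factor, design=design, n=len(ids),
               permanova_method=perm_res.method)
    results["permanova"] = pd.DataFrame(perm_rows)
    results["group_tests"] = pd.DataFrame(test_rows)

    _write(results["alpha"], out_dir / "alpha.tsv")
    _write(results["permanova"], out_dir / "permanova.tsv", index=False)
    _write(results["group_tests"], out_dir / "group_tests.tsv", index=False)
    _write(results["pcoa_coordinates"], out_dir / "pcoa_coordinates.tsv")
    _write(results["distance_matrix"], out_dir / "distance_matrix.tsv")
    _write(results["balances"], out_dir / "balances.tsv")
    _write(results["bipartition"], out_dir / "bipartition.tsv")
    _write(results["impacts"], out_dir / "impacts.tsv")
    _write(results["relative_abundance"], out_dir / "relative_abundance.tsv")
    _stage("done", t0)
    return results


def summarize_abundance(
    table: OtuTable, metadata: pd.DataFrame, group_by
) -> pd.DataFrame:
    """Per-genus, per-group mean relative abundance (long format).

    ``group_by`` is one metadata column or a list of columns; groups
    partition the samples and each group's genus means sum to 1.
    """
    cols = [group_by] if isinstance(group_by, str) else list(group_by)
    unknown = [c for c in cols if c not in metadata.columns]
    if unknown:
        raise ValueError(f"unknown factor column(s): {unknown}")
    props = relative_abundance(table)
    meta = metadata.loc[list(table.samples)]
    rows = []
    for key, sub in meta.groupby(cols, sort=True):
        key_t = key if isinstance(key, tuple) else (key,)
        group_label = "/".join(str(k) for k in key_t)
        mean_props = props[list(sub.index)].mean(axis=1)
        for genus, value in mean_props.items():
            rows.append(
                {"group": group_label, "genus": genus, "mean_proportion": float(value)}
            )
    return pd.DataFrame(rows)
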