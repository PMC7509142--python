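"""Genus-level OTU count tables and sample metadata.

The package ships, as named fixtures, the four rarefied genus-level count
tables from a 12-month red-wine aging survey at two Spanish cellars
(Priorat/FB and Rioja/ICVV), each profiled with 16S (bacteria) and ITS
(fungi) amplicons.  Sample metadata (cellar, vessel, barrel history, aging
time) is decoded from the sample acronyms rather than stored as a second
hand-typed table, so the acronym grammar is the single source of truth.

On-disk dialect for generic tables: UTF-8 TSV, one header row of sample
identifiers, first column holding genus labels, taxa as rows (a
``samples_as_rows`` orientation flag accommodates QIIME-style exports).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "TableValidationError",
    "FIXTURE_NAMES",
    "read_otu_table",
    "write_otu_table",
    "load_fixture",
    "decode_sample_id",
    "build_metadata",
    "read_metadata",
    "write_metadata",
    "relative_abundance",
]

CELLARS = frozenset({"FB", "ICVV"})
AMPLICONS = frozenset({"16S", "ITS"})
VESSELS = frozenset({"barrel", "bottle", "tank"})
BARREL_HISTORIES = frozenset({"new", "old", "not_applicable"})
MONTHS = frozenset({0, 3, 6, 9, 12})

METADATA_COLUMNS = ("cellar", "amplicon", "vessel", "barrel_history", "months")

FIXTURE_NAMES = ("fb_16s", "icvv_16s", "fb_its", "icvv_its")
_FIXTURE_AMPLICON = {
    "fb_16s": "16S",
    "icvv_16s": "16S",
    "fb_its": "ITS",
    "icvv_its": "ITS",
}


class TableValidationError(ValueError):
    """Raised when a count table or metadata table violates its contract."""


@dataclass(frozen=True)
class OtuTable:
    """A genus x sample matrix of non-negative integer counts.

    Parameters
    ----------
    taxa :
        Ordered genus labels (rows), unique.
    samples :
        Ordered sample identifiers (columns), unique.
    counts :
        Integer matrix of shape ``(len(taxa), len(samples))``.
    annotations :
        Optional per-genus annotation marks (e.g. the printed group
        superscripts of the source tables).  Stored verbatim, never
        interpreted by this module.
    """

    taxa: tuple[str, ...]
    samples: tuple[str, ...]
    counts: np.ndarray
    annotations: Mapping[str, str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxa)
        samples = tuple(str(s) for s in self.samples)
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(taxa), len(samples)):
            raise TableValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(taxa)} taxa, {len(samples)} samples)"
            )
        if counts.size == 0:
            raise TableValidationError("empty data region: no taxa or no samples")
        for label, kind in (_first_duplicate(taxa), "taxon"), (
            _first_duplicate(samples),
            "sample",
        ):
            if label is not None:
                raise TableValidationError(f"duplicate {kind} label: {label!r}")
        if not np.issubdtype(counts.dtype, np.integer):
            frac, _ = np.modf(counts.astype(float))
            if np.any(frac != 0) or not np.all(np.isfinite(counts.astype(float))):
                i, j = np.argwhere((frac != 0) | ~np.isfinite(counts.astype(float)))[0]
                raise TableValidationError(
                    f"non-integer count at ({taxa[i]!r}, {samples[j]!r}): "
                    f"{counts[i, j]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise TableValidationError(
                f"negative count at ({taxa[i]!r}, {samples[j]!r}): {counts[i, j]}"
            )
        counts = np.ascontiguousarray(counts, dtype=np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, annotations: Mapping[str, str] | None = None
    ) -> "OtuTable":
        """Build from a taxa-as-rows DataFrame (columns = sample ids)."""
        return cls(
            taxa=tuple(map(str, frame.index)),
            samples=tuple(map(str, frame.columns)),
            counts=frame.to_numpy(),
            annotations=annotations,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.taxa), columns=list(self.samples)
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        ids = list(sample_ids)
        pos = {s: k for k, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample identifiers: {missing}")
        idx = [pos[s] for s in ids]
        return OtuTable(self.taxa, tuple(ids), self.counts[:, idx], self.annotations)


def _first_duplicate(labels: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            return lab
        seen.add(lab)
    return None


def read_otu_table(path: str | Path, orientation: str = "taxa_as_rows") -> OtuTable:
    """Read a TSV count table.

    ``orientation="samples_as_rows"`` transposes QIIME-style exports so the
    returned table is always taxa-as-rows.
    """
    if orientation not in ("taxa_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.empty or frame.shape[1] == 0:
        raise TableValidationError(f"empty data region in {path}")
    if orientation == "samples_as_rows":
        frame = frame.T
    values = np.empty(frame.shape, dtype=np.int64)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col]):
            try:
                values[i, j] = int(str(raw).replace(",", ""))
            except (TypeError, ValueError):
                raise TableValidationError(
                    f"non-integer cell at ({frame.index[i]!r}, {col!r}): {raw!r}"
                ) from None
    return OtuTable(
        taxa=tuple(map(str, frame.index)),
        samples=tuple(map(str, frame.columns)),
        counts=values,
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write a table in the canonical taxa-as-rows TSV dialect."""
    frame = table.to_frame()
    frame.index.name = "taxon"
    frame.to_csv(path, sep="\t", lineterminator="\n")


# --------------------------------------------------------------------------
# sample-acronym grammar
# --------------------------------------------------------------------------

_CODE_INFO = {
    "BAO": ("barrel", "old"),
    "BAN": ("barrel", "new"),
    "BTO": ("bottle", "old"),
    "BTN": ("bottle", "new"),
    "FML": ("tank", "not_applicable"),
}
_SAMPLE_RE = re.compile(r"^(?:(FB|Rioja)_)?(BAO|BAN|BTO|BTN|FML)_?(\d+)$")


def decode_sample_id(sample_id: str, amplicon: str, default_cellar: str = "FB") -> dict:
    """Decode a sample acronym (e.g. ``Rioja_BTN12``) into factor levels.

    The grammar is ``[FB_|Rioja_]CODE[_]MONTHS`` with CODE one of BAO/BAN
    (barrel, old/new), BTO/BTN (bottle, from old/new barrel) and FML (the
    steel-tank malolactic-fermentation endpoint, month 0 only).
    """
    if amplicon not in AMPLICONS:
        raise ValueError(f"unknown amplicon: {amplicon!r}")
    m = _SAMPLE_RE.match(sample_id)
    if m is None:
        raise ValueError(f"sample id {sample_id!r} does not match the acronym grammar")
    prefix, code, months_str = m.groups()
    vessel, history = _CODE_INFO[code]
    months = int(months_str)
    if months not in MONTHS:
        raise ValueError(f"sample id {sample_id!r}: months {months} not in {sorted(MONTHS)}")
    if vessel == "tank" and months != 0:
        raise ValueError(f"sample id {sample_id!r}: tank (FML) samples exist only at month 0")
    if prefix is None:
        # FML (steel tank) occurs only in the ICVV design; other prefixless
        # acronyms fall back to the caller-supplied cellar.
        cellar = "ICVV" if code == "FML" else default_cellar
    else:
        cellar = {"FB": "FB", "Rioja": "ICVV"}[prefix]
    return {
        "sample_id": sample_id,
        "cellar": cellar,
        "amplicon": amplicon,
        "vessel": vessel,
        "barrel_history": history,
        "months": months,
    }


def build_metadata(sample_ids: Iterable[str], amplicon: str) -> pd.DataFrame:
    """Decode a collection of acronyms into a metadata table (one row each)."""
    rows = [decode_sample_id(s, amplicon) for s in sample_ids]
    meta = pd.DataFrame(rows).set_index("sample_id")
    validate_metadata(meta)
    return meta


def validate_metadata(meta: pd.DataFrame, table: OtuTable | None = None) -> None:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TableValidationError(f"metadata missing columns: {missing}")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise TableValidationError(f"duplicate sample_id in metadata: {dup!r}")
    for col, allowed in (
        ("cellar", CELLARS),
        ("amplicon", AMPLICONS),
        ("vessel", VESSELS),
        ("barrel_history", BARREL_HISTORIES),
    ):
        bad = set(meta[col]) - allowed
        if bad:
            raise TableValidationError(f"invalid {col} level(s): {sorted(bad)}")
    bad_months = set(meta["months"]) - MONTHS
    if bad_months:
        raise TableValidationError(f"invalid months value(s): {sorted(bad_months)}")
    tank = meta[meta["vessel"] == "tank"]
    if (tank["months"] != 0).any():
        raise TableValidationError("vessel=tank allowed only at months=0")
    if table is not None:
        absent = [s for s in table.samples if s not in meta.index]
        if absent:
            raise TableValidationError(f"samples missing from metadata: {absent}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    validate_metadata(meta)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", lineterminator="\n")


# --------------------------------------------------------------------------
# packaged fixtures
# --------------------------------------------------------------------------


def load_fixture(name: str) -> tuple[OtuTable, pd.DataFrame]:
    """Load one of the four packaged rarefied genus tables.

    Returns the count table (with the printed group marks preserved as
    ``annotations``) and the metadata decoded from the sample acronyms.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    ref = resources.files("barrelbiome").joinpath(f"data/{name}.tsv")
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    annotations = {str(t): str(g) for t, g in frame["group"].items()}
    counts = frame.drop(columns=["group"])
    table = OtuTable.from_frame(counts, annotations=annotations)
    meta = build_metadata(table.samples, _FIXTURE_AMPLICON[name])
    validate_metadata(meta, table)
    return table, meta


# --------------------------------------------------------------------------
# proportions
# --------------------------------------------------------------------------


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample proportions (each column sums to 1)."""
    sums = table.sample_sums
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise TableValidationError(
            f"all-zero sample column: {table.samples[zero[0]]!r}"
        )
    props = table.counts / sums[np.newaxis, :]
    return pd.DataFrame(props, index=list(table.taxa), columns=list(table.samples))
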