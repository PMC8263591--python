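"""Readers, writers, retention filters and normalization for paired-site cohorts.

The central container is :class:`AbundanceTable`, a taxa x samples matrix of
non-negative numbers in one of three modes: raw ``counts``, ``relative``
abundances (each sample column sums to 1) or ``per_1e5`` (each column sums to
1e5, the convention used for per-sample scaled genus abundances).  Sample
metadata links each column to a subject, a body site (uterus or vagina) and a
health group; a rooted phylogeny over the taxa supports UniFrac.

Boundary semantics of the retention filter follow the wording "observed
species less than 50 or Good's coverage lower than 0.8": both cut-offs are
strict, so a sample sitting exactly on either boundary is kept.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CohortError",
    "AbundanceTable",
    "SampleRecord",
    "PhyloTree",
    "read_abundance_table",
    "write_abundance_table",
    "filter_samples",
    "to_relative",
    "scale_per_1e5",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
    "validate_metadata_against_table",
    "validate_tree_against_table",
]

SITES = ("uterus", "vagina")
GROUPS = ("healthy", "endometritis", "other")
DELIVERY_MODES = ("vaginal", "cesarean", "none", "unknown")
MODES = ("counts", "relative", "per_1e5")

#: relative tolerance for "columns sum to 1" checks (double precision headroom)
REL_SUM_TOL = 1e-9
#: absolute tolerance for "columns sum to 1e5" checks
PER_1E5_SUM_TOL = 1e-6


class CohortError(ValueError):
    """Raised on malformed tables, metadata, or trees."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise CohortError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix with a mode flag.

    Parameters
    ----------
    taxon_ids, sample_ids
        Opaque unique labels for rows and columns.
    values
        2-D array of non-negative numbers, shape ``(len(taxon_ids),
        len(sample_ids))``.
    mode
        One of ``counts``, ``relative`` or ``per_1e5``.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mode: str = "counts"

    def __post_init__(self) -> None:
        self.taxon_ids = list(map(str, self.taxon_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.taxon_ids),
            len(self.sample_ids),
        ):
            raise CohortError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if self.mode not in MODES:
            raise CohortError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise CohortError("non-finite value in abundance table")
        if np.any(self.values < 0):
            t, s = np.argwhere(self.values < 0)[0]
            raise CohortError(
                f"negative value at taxon {self.taxon_ids[t]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.n_samples:
            sums = self.values.sum(axis=0)
            if self.mode == "relative" and not np.allclose(
                sums, 1.0, rtol=REL_SUM_TOL, atol=REL_SUM_TOL
            ):
                raise CohortError("relative-mode columns must sum to 1")
            if self.mode == "per_1e5" and not np.allclose(
                sums, 1e5, rtol=0, atol=PER_1E5_SUM_TOL
            ):
                raise CohortError("per_1e5-mode columns must sum to 1e5")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise CohortError(f"unknown sample id {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample_id)]

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return AbundanceTable(
            list(self.taxon_ids), list(sample_ids), self.values[:, idx], self.mode
        )

    def select_taxa(self, taxon_ids: Sequence[str]) -> "AbundanceTable":
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxon_ids if t not in pos]
        if missing:
            raise CohortError(f"unknown taxon ids: {missing}")
        idx = [pos[t] for t in taxon_ids]
        tab = AbundanceTable.__new__(AbundanceTable)
        tab.taxon_ids = list(taxon_ids)
        tab.sample_ids = list(self.sample_ids)
        tab.values = self.values[idx, :]
        # a taxon subset of a relative table no longer sums to 1; demote mode
        tab.mode = "counts" if self.mode == "counts" else self.mode
        if self.mode != "counts" and len(taxon_ids) != self.n_taxa:
            tab.mode = "counts"
        return tab

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mode: str = "counts") -> "AbundanceTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), mode)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(
            list(self.taxon_ids), list(self.sample_ids), self.values.copy(), self.mode
        )


@dataclass
class SampleRecord:
    """One row of the sample-metadata table."""

    sample_id: str
    subject_id: str
    site: str
    group: str
    age: float | None = None
    delivery_mode: str = "unknown"
    n_abortions: int | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise CohortError(
                f"sample {self.sample_id!r}: unknown site {self.site!r}; "
                f"expected one of {SITES}"
            )
        if self.group not in GROUPS:
            raise CohortError(
                f"sample {self.sample_id!r}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        if self.delivery_mode not in DELIVERY_MODES:
            raise CohortError(
                f"sample {self.sample_id!r}: unknown delivery_mode "
                f"{self.delivery_mode!r}; expected one of {DELIVERY_MODES}"
            )
        if self.n_abortions is not None and self.n_abortions < 0:
            raise CohortError(f"sample {self.sample_id!r}: n_abortions < 0")


@dataclass
class PhyloTree:
    """Rooted phylogeny whose tips are taxon ids, with branch lengths."""

    tree: TreeNode
    newick: str | None = None

    def __post_init__(self) -> None:
        names = self.tip_names
        _check_unique(names, "tip")
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                raise CohortError(
                    f"missing branch length on node {node.name!r} (UniFrac undefined)"
                )
            if node.length < 0:
                raise CohortError(f"negative branch length on node {node.name!r}")
        if self.tree.length is None:
            self.tree.length = 0.0

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths below the root."""
        return float(
            sum(n.length for n in self.tree.traverse(include_self=False))
        )


# ---------------------------------------------------------------------------
# abundance-table I/O


def read_abundance_table(path: str | Path) -> AbundanceTable:
    """Read a counts-mode table from TSV (header = sample ids, col 1 = taxa).

    Missing cells, non-numeric or negative values, and duplicated ids are
    errors (with row/column location where applicable) rather than silent
    repairs.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise CohortError(f"{path}: empty file, no samples")
    header = header_line.rstrip("\n").split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise CohortError(f"{path}: no samples")
    _check_unique(sample_ids, "sample")

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw = raw.replace("", np.nan)
    if raw.shape[0] == 0:
        raise CohortError(f"{path}: no samples (empty body)")
    taxon_ids = [str(t) for t in raw.index]
    _check_unique(taxon_ids, "taxon")

    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    missing = raw.isna()
    if missing.to_numpy().any():
        t, s = np.argwhere(missing.to_numpy())[0]
        raise CohortError(
            f"{path}: missing cell at taxon {taxon_ids[t]!r}, sample {sample_ids[s]!r}"
        )
    bad = numeric.isna().to_numpy() & ~missing.to_numpy()
    if bad.any():
        t, s = np.argwhere(bad)[0]
        raise CohortError(
            f"{path}: non-numeric value {raw.iloc[t, s]!r} at taxon "
            f"{taxon_ids[t]!r}, sample {sample_ids[s]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    if np.any(values < 0):
        t, s = np.argwhere(values < 0)[0]
        raise CohortError(
            f"{path}: negative value at taxon {taxon_ids[t]!r}, "
            f"sample {sample_ids[s]!r}"
        )
    return AbundanceTable(taxon_ids, sample_ids, values, mode="counts")


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.to_dataframe()
    # keep integral counts readable and bit-stable across a round trip
    if table.mode == "counts" and np.allclose(table.values, np.round(table.values)):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# retention filter and normalization


def filter_samples(
    table: AbundanceTable,
    min_observed: int = 50,
    min_goods: float = 0.8,
) -> tuple[AbundanceTable, list[str]]:
    """Drop shallow samples; keep those with observed taxa >= ``min_observed``
    and Good's coverage >= ``min_goods`` (both boundaries kept, the printed
    cut-offs being strict).

    Returns the retained table and the list of discarded sample ids.
    Requires counts mode (Good's coverage needs singleton counts).
    """
    if table.mode != "counts":
        raise CohortError("filter_samples requires a counts-mode table")
    from .diversity import goods_coverage, observed_taxa  # local: avoids cycle

    keep: list[str] = []
    dropped: list[str] = []
    for j, sid in enumerate(table.sample_ids):
        col = table.values[:, j]
        if col.sum() == 0:
            dropped.append(sid)
            continue
        if observed_taxa(col) >= min_observed and goods_coverage(col) >= min_goods:
            keep.append(sid)
        else:
            dropped.append(sid)
    return table.select_samples(keep), dropped


def _normalize(table: AbundanceTable, total: float, mode: str) -> AbundanceTable:
    if table.mode != "counts":
        raise CohortError(f"normalization requires counts mode, got {table.mode!r}")
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise CohortError(
            f"all-zero sample column: {table.sample_ids[zero[0]]!r}"
        )
    return AbundanceTable(
        list(table.taxon_ids),
        list(table.sample_ids),
        table.values / sums * total,
        mode,
    )


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Normalize each sample column to its total (columns sum to 1)."""
    return _normalize(table, 1.0, "relative")


def scale_per_1e5(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample column to 1e5 total, the per-100k-reads convention."""
    return _normalize(table, 1e5, "per_1e5")


# ---------------------------------------------------------------------------
# tree and metadata I/O


def read_tree(source: str | Path) -> PhyloTree:
    """Read a rooted newick tree with branch lengths.

    ``source`` may be a path or a literal newick string.
    """
    text: str
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.rstrip().endswith(";")
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    tree = TreeNode.read(io.StringIO(text), convert_underscores=False)
    return PhyloTree(tree, newick=text.strip())


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    if tree.newick is not None:
        Path(path).write_text(tree.newick + "\n", encoding="utf-8")
    else:
        tree.tree.write(str(path))


_META_COLUMNS = ("sample_id", "subject_id", "site", "group")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample-metadata TSV (controlled-vocabulary columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing metadata columns {missing}")
    records = []
    for _, row in df.iterrows():
        age = row.get("age", "")
        nab = row.get("n_abortions", "")
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                subject_id=row["subject_id"],
                site=row["site"],
                group=row["group"],
                age=float(age) if age not in ("", "NA") else None,
                delivery_mode=row.get("delivery_mode", "unknown") or "unknown",
                n_abortions=int(nab) if nab not in ("", "NA") else None,
            )
        )
    _check_unique([r.sample_id for r in records], "sample")
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.subject_id, r.site)
        if key in seen:
            raise CohortError(
                f"subject {r.subject_id!r} has more than one {r.site} sample"
            )
        seen.add(key)
    return records


def metadata_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = [vars(r) for r in records]
    if not rows:
        raise CohortError("no metadata records (all samples filtered out?)")
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records])
    df.to_csv(path, sep="\t", index=False)


def validate_metadata_against_table(
    records: Iterable[SampleRecord], table: AbundanceTable
) -> None:
    """Every metadata sample id must resolve to a column of the table."""
    cols = set(table.sample_ids)
    orphans = [r.sample_id for r in records if r.sample_id not in cols]
    if orphans:
        raise CohortError(f"metadata sample ids absent from table: {orphans}")


def validate_tree_against_table(tree: PhyloTree, table: AbundanceTable) -> None:
    """Warn about tree tips that have no row in the table (orphan tips)."""
    taxa = set(table.taxon_ids)
    orphans = [t for t in tree.tip_names if t not in taxa]
    if orphans:
        warnings.warn(
            f"{len(orphans)} tree tip(s) absent from the table: {orphans[:10]}",
            stacklevel=2,
        )
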