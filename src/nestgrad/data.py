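"""Domain types, delimited-text I/O, and community-matrix construction.

The raw input is a *long* (tidy) table with one row per sample-by-phylotype
occurrence.  Samples are pooled within groups (sites or treatments) into a
phylotype-by-group :class:`CommunityMatrix` whose cells count the number of
samples in which each phylotype occurred; the matrix can then be normalized to
percentage relative abundance, binarized, and sorted according to the gradient
hypothesis (columns by pH, rows by phylotype occurrence) before any nestedness
index is computed.

pH is stored and compared as a plain real number throughout, even though it is
a logarithmic quantity (-log10[H+]).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CELL_KINDS = ("presence", "count", "relative_abundance_percent")


class FormatError(ValueError):
    """Raised when an input file violates the expected layout or invariants."""


@dataclass(frozen=True)
class SampleRecord:
    """One sample-by-phylotype occurrence.

    ``clone_count`` defaults to 1, meaning presence only; a stored count of
    zero is rejected at read time (an unobserved phylotype has no row).
    """

    sample_id: str
    group_id: str
    ph: float | None
    phylotype_id: str
    clone_count: int = 1

    def __post_init__(self) -> None:
        if self.ph is not None and not (0.0 <= self.ph <= 14.0):
            raise ValueError(
                f"pH {self.ph} for sample {self.sample_id!r} outside [0, 14]"
            )
        if self.clone_count < 1:
            raise ValueError(
                f"clone_count must be >= 1, got {self.clone_count} for "
                f"({self.sample_id!r}, {self.phylotype_id!r})"
            )


@dataclass(frozen=True)
class GroupMetadata:
    """Per-group (site / treatment) metadata used downstream."""

    group_id: str
    n_samples: int
    mean_ph: float | None = None
    available_p: float | None = None  # mg kg^-1
    total_n: float | None = None  # g kg^-1
    total_c: float | None = None  # g kg^-1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"group {self.group_id!r}: n_samples must be >= 1")


@dataclass
class SampleTable:
    """Ordered collection of :class:`SampleRecord` plus group metadata."""

    records: list[SampleRecord]
    groups: dict[str, GroupMetadata] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.sample_id, rec.phylotype_id)
            if key in seen:
                raise FormatError(f"duplicated (sample_id, phylotype) pair {key}")
            seen.add(key)
        if not self.groups:
            self.groups = self._derive_groups()
        else:
            missing = {r.group_id for r in self.records} - set(self.groups)
            if missing:
                raise FormatError(f"records reference unknown groups: {sorted(missing)}")

    def _derive_groups(self) -> dict[str, GroupMetadata]:
        by_group: dict[str, dict[str, float | None]] = {}
        for rec in self.records:
            by_group.setdefault(rec.group_id, {})[rec.sample_id] = rec.ph
        out = {}
        for gid, samples in by_group.items():
            phs = [p for p in samples.values() if p is not None]
            out[gid] = GroupMetadata(
                group_id=gid,
                n_samples=len(samples),
                mean_ph=float(np.mean(phs)) if phs else None,
            )
        return out

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.sample_id not in out:
                out.append(rec.sample_id)
        return out

    @property
    def phylotype_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.phylotype_id not in out:
                out.append(rec.phylotype_id)
        return out

    def sample_ph(self) -> dict[str, float | None]:
        return {rec.sample_id: rec.ph for rec in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "group": [r.group_id for r in self.records],
                "ph": [r.ph for r in self.records],
                "phylotype": [r.phylotype_id for r in self.records],
                "count": [r.clone_count for r in self.records],
            }
        )


@dataclass
class CommunityMatrix:
    """Phylotypes (rows) by groups (columns) community matrix.

    ``col_gradient`` carries the per-column gradient value (e.g. mean soil pH)
    used for hypothesis ordering; ``row_occurrence`` carries, per phylotype,
    the total number of samples (over all groups) in which it occurred.
    """

    row_labels: list[str]
    col_labels: list[str]
    cells: np.ndarray
    cell_kind: str
    col_gradient: np.ndarray | None = None
    row_occurrence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D matrix")
        r, c = self.cells.shape
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lengths do not match matrix shape")
        if self.cell_kind not in CELL_KINDS:
            raise ValueError(f"cell_kind must be one of {CELL_KINDS}")
        if (self.cells < 0).any():
            raise ValueError("negative cell values")
        if self.cell_kind == "presence" and not np.isin(self.cells, (0.0, 1.0)).all():
            raise ValueError("presence matrix must be 0/1")
        if self.cell_kind == "relative_abundance_percent" and (self.cells > 100).any():
            raise ValueError("relative abundance must be <= 100")
        if self.col_gradient is not None:
            self.col_gradient = np.asarray(self.col_gradient, dtype=float)
            if self.col_gradient.shape != (c,):
                raise ValueError("col_gradient length must equal number of columns")
        if self.row_occurrence is not None:
            self.row_occurrence = np.asarray(self.row_occurrence)
            if self.row_occurrence.shape != (r,):
                raise ValueError("row_occurrence length must equal number of rows")
            if (self.row_occurrence < 0).any():
                raise ValueError("row_occurrence must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def copy(self, **overrides) -> "CommunityMatrix":
        kw = dict(
            row_labels=list(self.row_labels),
            col_labels=list(self.col_labels),
            cells=self.cells.copy(),
            cell_kind=self.cell_kind,
            col_gradient=None if self.col_gradient is None else self.col_gradient.copy(),
            row_occurrence=None if self.row_occurrence is None else self.row_occurrence.copy(),
        )
        kw.update(overrides)
        return CommunityMatrix(**kw)

    def drop_empty(self) -> "CommunityMatrix":
        """Drop all-zero rows and columns (logged), returning a new matrix."""
        keep_r = self.cells.sum(axis=1) > 0
        keep_c = self.cells.sum(axis=0) > 0
        if keep_r.all() and keep_c.all():
            return self
        dropped_rows = [l for l, k in zip(self.row_labels, keep_r) if not k]
        dropped_cols = [l for l, k in zip(self.col_labels, keep_c) if not k]
        if dropped_rows:
            logger.warning("dropping %d empty rows: %s", len(dropped_rows), dropped_rows)
        if dropped_cols:
            logger.warning("dropping %d empty columns: %s", len(dropped_cols), dropped_cols)
        return CommunityMatrix(
            row_labels=[l for l, k in zip(self.row_labels, keep_r) if k],
            col_labels=[l for l, k in zip(self.col_labels, keep_c) if k],
            cells=self.cells[np.ix_(keep_r, keep_c)],
            cell_kind=self.cell_kind,
            col_gradient=None if self.col_gradient is None else self.col_gradient[keep_c],
            row_occurrence=None if self.row_occurrence is None else self.row_occurrence[keep_r],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.row_labels, columns=self.col_labels)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = ("sample_id", "group", "ph", "phylotype")


def read_sample_table(path: str | Path, sep: str = "\t") -> SampleTable:
    """Read a long-format sample table (TSV by default, UTF-8, header row).

    Columns: ``sample_id``, ``group``, ``ph``, ``phylotype`` and optionally
    ``count`` (defaulting to 1 = presence only).  Unknown columns are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        raw_ph = getattr(row, "ph")
        if raw_ph is None or (isinstance(raw_ph, float) and np.isnan(raw_ph)) or str(raw_ph).strip() in ("", "NA"):
            ph: float | None = None
        else:
            try:
                ph = float(raw_ph)
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: non-numeric ph value {raw_ph!r}") from exc
        count = 1
        if "count" in df.columns:
            raw = getattr(row, "count")
            if raw is not None and str(raw).strip() not in ("", "nan", "NA"):
                try:
                    count = int(raw)
                except ValueError as exc:
                    raise FormatError(f"{path}:{i}: non-integer count {raw!r}") from exc
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row.sample_id),
                    group_id=str(row.group),
                    ph=ph,
                    phylotype_id=str(row.phylotype),
                    clone_count=count,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from exc
    return SampleTable(records=records)


def write_sample_table(table: SampleTable, path: str | Path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)


def read_matrix(path: str | Path, sep: str = "\t") -> CommunityMatrix:
    """Read a pre-pooled wide matrix: first column phylotype id, remaining
    columns group ids.  An optional ``#gradient:`` comment line carries the
    per-column gradient (pH) values; a JSON sidecar ``<path>.meta.json``, if
    present, carries :class:`GroupMetadata` (``n_samples`` per group).
    """
    path = Path(path)
    gradient: np.ndarray | None = None
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#gradient:"):
            gradient = np.array([float(v) for v in line[len("#gradient:"):].split()])
        elif not line.startswith("#"):
            data_lines.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(data_lines)), sep=sep, index_col=0)
    cells = df.to_numpy(dtype=float)
    kind = "presence" if np.isin(cells, (0.0, 1.0)).all() else "count"
    if gradient is not None and len(gradient) != df.shape[1]:
        raise FormatError(f"{path}: #gradient: has {len(gradient)} values for {df.shape[1]} columns")
    m = CommunityMatrix(
        row_labels=[str(x) for x in df.index],
        col_labels=[str(x) for x in df.columns],
        cells=cells,
        cell_kind=kind,
        col_gradient=gradient,
        row_occurrence=None,
    )
    return m


def write_matrix(m: CommunityMatrix, path: str | Path, sep: str = "\t") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if m.col_gradient is not None:
            fh.write("#gradient: " + " ".join(f"{v:g}" for v in m.col_gradient) + "\n")
        m.to_frame().to_csv(fh, sep=sep)


def read_group_metadata(path: str | Path) -> dict[str, GroupMetadata]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {
        gid: GroupMetadata(
            group_id=gid,
            n_samples=int(entry["n_samples"]),
            mean_ph=entry.get("mean_ph"),
            available_p=entry.get("available_p"),
            total_n=entry.get("total_n"),
            total_c=entry.get("total_c"),
        )
        for gid, entry in raw.items()
    }


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------


def pool_to_matrix(
    table: SampleTable,
    grouping: Mapping[str, str] | None = None,
) -> CommunityMatrix:
    """Pool per-sample presence/absence within groups into an occurrence-count
    matrix.

    Cell (p, g) is the number of distinct samples in group g in which
    phylotype p occurred (clone counts collapse to presence before pooling).
    ``row_occurrence`` is the total number of samples, over all groups, in
    which each phylotype occurred; ``col_gradient`` is the mean pH of the
    samples in each group.
    """
    if not table.records:
        raise ValueError("cannot pool an empty sample table")
    if grouping is None:
        grouping = {r.sample_id: r.group_id for r in table.records}
    for rec in table.records:
        if rec.sample_id not in grouping:
            raise ValueError(f"sample {rec.sample_id!r} missing from grouping")

    phylos = table.phylotype_ids
    groups = list(dict.fromkeys(grouping[s] for s in table.sample_ids))
    p_idx = {p: i for i, p in enumerate(phylos)}
    g_idx = {g: j for j, g in enumerate(groups)}

    present: set[tuple[str, str]] = {(r.phylotype_id, r.sample_id) for r in table.records}
    cells = np.zeros((len(phylos), len(groups)))
    occurrence = np.zeros(len(phylos), dtype=int)
    for p, s in present:
        cells[p_idx[p], g_idx[grouping[s]]] += 1
        occurrence[p_idx[p]] += 1

    ph_by_sample = table.sample_ph()
    gradient = np.full(len(groups), np.nan)
    for g, j in g_idx.items():
        phs = [
            ph_by_sample[s]
            for s in table.sample_ids
            if grouping[s] == g and ph_by_sample[s] is not None
        ]
        if phs:
            gradient[j] = float(np.mean(phs))

    m = CommunityMatrix(
        row_labels=phylos,
        col_labels=groups,
        cells=cells,
        cell_kind="count",
        col_gradient=gradient if not np.isnan(gradient).all() else None,
        row_occurrence=occurrence,
    )
    return m.drop_empty()


def normalize_relative_abundance(
    m: CommunityMatrix,
    sizes: Mapping[str, GroupMetadata | int],
) -> CommunityMatrix:
    """Convert occurrence counts to percentage relative abundance by dividing
    each column by its group's sample number (columns of different depth
    become comparable)."""
    if m.cell_kind != "count":
        raise ValueError(f"expected a count matrix, got {m.cell_kind}")
    n = np.empty(len(m.col_labels))
    for j, g in enumerate(m.col_labels):
        if g not in sizes:
            raise ValueError(f"no sample size for group {g!r}")
        entry = sizes[g]
        n[j] = entry.n_samples if isinstance(entry, GroupMetadata) else int(entry)
        if n[j] <= 0:
            raise ValueError(f"group {g!r} has non-positive sample number")
    cells = 100.0 * m.cells / n[np.newaxis, :]
    return m.copy(cells=cells, cell_kind="relative_abundance_percent")


def to_presence_absence(m: CommunityMatrix) -> CommunityMatrix:
    """Binarize: cell = 1 where the input cell is positive. Idempotent."""
    return m.copy(cells=(m.cells > 0).astype(float), cell_kind="presence")


def _tiebreak_order(primary: np.ndarray, secondary: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Descending on primary, then descending secondary, then label ascending."""
    keys = sorted(
        range(len(labels)),
        key=lambda i: (-primary[i], -secondary[i], labels[i]),
    )
    return np.array(keys, dtype=int)


def sort_columns_by_gradient(m: CommunityMatrix, descending: bool = True) -> CommunityMatrix:
    """Permute columns by gradient value (default: descending pH, highest-pH
    leftmost).  Ties broken by column marginal total descending, then label."""
    if m.col_gradient is None or np.isnan(m.col_gradient).any():
        raise ValueError("column gradient values are required for gradient sorting")
    grad = m.col_gradient if descending else -m.col_gradient
    order = _tiebreak_order(grad, m.cells.sum(axis=0), m.col_labels)
    return m.copy(
        cells=m.cells[:, order],
        col_labels=[m.col_labels[i] for i in order],
        col_gradient=m.col_gradient[order],
    )


def sort_rows_by_occurrence(m: CommunityMatrix) -> CommunityMatrix:
    """Permute rows by phylotype occurrence descending (most widespread on
    top).  Ties broken by row marginal total descending, then label."""
    if m.row_occurrence is None:
        raise ValueError("row_occurrence is required for occurrence sorting")
    order = _tiebreak_order(
        np.asarray(m.row_occurrence, dtype=float), m.cells.sum(axis=1), m.row_labels
    )
    return m.copy(
        cells=m.cells[order, :],
        row_labels=[m.row_labels[i] for i in order],
        row_occurrence=m.row_occurrence[order],
    )


def concat_column_blocks(blocks: Iterable[CommunityMatrix]) -> CommunityMatrix:
    """Concatenate column blocks sharing the same row set (e.g. the combined
    two-inoculum layout: neutral-soil columns left, acidic-soil right, each
    block sorted by pH internally)."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no blocks to concatenate")
    first = blocks[0]
    for b in blocks[1:]:
        if b.row_labels != first.row_labels:
            raise ValueError("column blocks must share identical row labels")
        if b.cell_kind != first.cell_kind:
            raise ValueError("column blocks must share the same cell kind")
    grads = [b.col_gradient for b in blocks]
    return CommunityMatrix(
        row_labels=list(first.row_labels),
        col_labels=[l for b in blocks for l in b.col_labels],
        cells=np.hstack([b.cells for b in blocks]),
        cell_kind=first.cell_kind,
        col_gradient=None if any(g is None for g in grads) else np.concatenate(grads),
        row_occurrence=first.row_occurrence,
    )
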