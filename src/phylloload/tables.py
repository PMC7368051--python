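"""Count tables and sample metadata.

The two on-disk artifacts everything else consumes: a family-by-sample
count table (TSV, taxa as rows) and a per-sample metadata table carrying
the plant chromosomal read count used as the inherent spike-in, plus any
grouping variables (site, season, batch).

Tables are tab-separated UTF-8, first header token ``taxon``, no quoting;
taxon labels may contain spaces but never tabs.  An optional first line
``# mode=<mode>`` records the table's normalization state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("phylloload")

#: Recognised normalization states of a feature table.
MODES = frozenset(
    {"raw_counts", "plant_scaled", "relative", "fourth_root", "clr", "load_corrected"}
)

_CLOSURE_TOL = 1e-9


class TableError(ValueError):
    """Raised when a table or metadata file violates an invariant."""


@dataclass
class FeatureTable:
    """A taxa x samples matrix of abundances with a normalization mode tag.

    Parameters
    ----------
    data:
        DataFrame with taxon labels as the index and sample IDs as columns.
        Row and column order are preserved and meaningful.
    mode:
        One of :data:`MODES`.  Values must be finite, and non-negative for
        every mode except ``clr``.  ``relative`` additionally requires every
        non-empty sample column to sum to a common closure constant.
    """

    data: pd.DataFrame
    mode: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise TableError(f"unknown table mode {self.mode!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise TableError("empty table")
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise TableError(f"duplicate taxon label(s): {dup}")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ID(s): {dup}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableError("non-numeric values in table")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise TableError(
                f"non-finite value at taxon {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.mode != "clr" and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise TableError(
                f"negative value at taxon {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.mode == "relative":
            sums = values.sum(axis=0)
            nonempty = sums > 0
            if nonempty.any():
                ref = sums[nonempty][0]
                if not np.allclose(sums[nonempty], ref, rtol=0, atol=_CLOSURE_TOL):
                    raise TableError(
                        "relative table columns do not share a closure constant"
                    )

    # -- convenience accessors -------------------------------------------------

    @property
    def taxon_labels(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, mode: str | None = None) -> "FeatureTable":
        """Return a new table with replaced data (and optionally mode)."""
        return FeatureTable(data, mode if mode is not None else self.mode)


@dataclass
class SampleMetadata:
    """Per-sample metadata: plant chromosomal read counts and group labels.

    ``data`` is indexed by sample ID and always carries an integer
    ``plant_reads`` column (the P_i denominator of plant-chromosome
    scaling); any further columns (site, season, batch, ...) ride along.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if "plant_reads" not in self.data.columns:
            raise TableError("metadata missing required column 'plant_reads'")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ID(s) in metadata: {dup}")
        pr = self.data["plant_reads"]
        try:
            pr = pr.astype("int64")
        except (TypeError, ValueError) as exc:
            raise TableError(f"plant_reads not integer: {exc}") from exc
        if (pr < 0).any():
            bad = self.data.index[pr < 0].tolist()
            raise TableError(f"negative plant_reads for sample(s): {bad}")
        self.data = self.data.assign(plant_reads=pr)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def plant_reads(self) -> pd.Series:
        return self.data["plant_reads"]


# -- I/O ----------------------------------------------------------------------


def read_feature_table(path, mode_hint: str = "raw_counts") -> FeatureTable:
    """Read a TSV count table (taxa as rows, samples as columns).

    A leading ``# mode=<mode>`` comment line overrides *mode_hint*.  Cells
    must be numeric and present; missing or non-numeric cells are reported
    with their row/column coordinates rather than silently zero-filled.
    """
    mode = mode_hint
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            token = first.lstrip("#").strip()
            if token.startswith("mode="):
                mode = token[len("mode="):].strip()
            header_line = fh.readline()
        else:
            header_line = first
        header = header_line.rstrip("\n").split("\t")
        if len(header) < 2:
            raise TableError("table has no sample columns")
        sample_ids = header[1:]
        labels: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            label = parts[0]
            cells = parts[1:]
            if len(cells) != len(sample_ids):
                raise TableError(
                    f"row {label!r}: expected {len(sample_ids)} cells, got {len(cells)}"
                )
            vals = []
            for sid, cell in zip(sample_ids, cells):
                if cell == "":
                    raise TableError(f"missing cell at taxon {label!r}, sample {sid!r}")
                try:
                    vals.append(float(cell))
                except ValueError as exc:
                    raise TableError(
                        f"non-numeric cell at taxon {label!r}, sample {sid!r}: {cell!r}"
                    ) from exc
            if label in labels:
                raise TableError(f"duplicate taxon label: {label!r}")
            labels.append(label)
            rows.append(vals)
    if not rows:
        raise TableError("empty table")
    arr = np.asarray(rows, dtype=float)
    if mode == "raw_counts" and np.array_equal(arr, np.round(arr)):
        arr = arr.astype("int64")
    df = pd.DataFrame(arr, index=pd.Index(labels, name="taxon"), columns=sample_ids)
    return FeatureTable(df, mode)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table as TSV with a ``# mode=`` header comment.

    Floats are rendered with 17 significant digits so that read-after-write
    reproduces them bit-for-bit; integer count tables stay integer.
    """
    values = table.values
    integral = np.issubdtype(values.dtype, np.integer)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mode={table.mode}\n")
        fh.write("taxon\t" + "\t".join(map(str, table.sample_ids)) + "\n")
        for label, row in zip(table.taxon_labels, values):
            if integral:
                cells = "\t".join(str(int(v)) for v in row)
            else:
                cells = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{label}\t{cells}\n")


def read_sample_metadata(path) -> SampleMetadata:
    """Read the per-sample metadata TSV (requires sample_id, plant_reads)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    for col in ("sample_id", "plant_reads"):
        if col not in df.columns:
            raise TableError(f"metadata missing required column {col!r}")
    raw = df["plant_reads"]
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.isna().any():
        bad = df.loc[numeric.isna(), "sample_id"].tolist()
        raise TableError(f"non-integer plant_reads for sample(s): {bad}")
    df = df.assign(plant_reads=numeric).set_index("sample_id")
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


def validate_pairing(
    table: FeatureTable, meta: SampleMetadata
) -> tuple[FeatureTable, SampleMetadata]:
    """Restrict a table and its metadata to shared sample IDs, table order.

    Logs how many samples are dropped from each side; raises if the
    intersection is empty.  Idempotent.
    """
    table_ids = table.sample_ids
    meta_ids = set(meta.sample_ids)
    shared = [s for s in table_ids if s in meta_ids]
    if not shared:
        raise TableError("no shared sample IDs between table and metadata")
    dropped_table = len(table_ids) - len(shared)
    dropped_meta = len(meta_ids) - len(shared)
    if dropped_table or dropped_meta:
        logger.info(
            "validate_pairing: dropped %d sample(s) from table, %d from metadata",
            dropped_table,
            dropped_meta,
        )
    new_table = table.with_data(table.data.loc[:, shared])
    new_meta = SampleMetadata(meta.data.loc[shared].copy())
    return new_table, new_meta
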