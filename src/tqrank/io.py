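"""Core data containers and tabular input/output.

The pipeline works on three plain-text artefacts:

* a genes × samples count table (TSV, or MatrixMarket with sidecar id files),
* a sample sheet assigning each sample to an embryo (batch) and a cell type,
* a ranked pattern-call table written after discovery.

Counts are whole-number read tallies per gene per cell; spike-in rows
(External RNA Controls Consortium standards by default) are identified by a
gene-id prefix so downstream steps can exclude them from biological totals.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .celltypes import CANONICAL_CELL_TYPES, validate_cell_types

DEFAULT_SPIKE_PREFIX = "ERCC-"


@dataclass
class CountMatrix:
    """Non-negative integer counts, genes in rows and samples in columns.

    ``counts`` is a pandas DataFrame indexed by gene id with sample-id
    columns; ``is_spike`` flags genes whose id starts with ``spike_prefix``.
    """

    counts: pd.DataFrame
    spike_prefix: str = DEFAULT_SPIKE_PREFIX
    is_spike: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id(s): {dupes}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))
                g, s = bad[0]
                raise ValueError(
                    f"non-integer count for gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count for gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if self.is_spike is None:
            self.is_spike = pd.Series(
                self.counts.index.str.startswith(self.spike_prefix),
                index=self.counts.index,
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleSheet:
    """Sample → (embryo, cell type[, platform]) assignment.

    Each (embryo, cell_type, platform) triple may occur at most once, so the
    embryo label defines the replicate structure of every cell type.
    """

    table: pd.DataFrame
    cell_types: tuple[str, ...] = CANONICAL_CELL_TYPES

    def __post_init__(self) -> None:
        required = {"sample_id", "embryo", "cell_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")
        self.table = self.table.copy()
        self.table["sample_id"] = self.table["sample_id"].astype(str)
        self.table["embryo"] = self.table["embryo"].astype(str)
        if "platform" not in self.table.columns:
            self.table["platform"] = ""
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        validate_cell_types(self.table["cell_type"], self.cell_types)
        triple = self.table[["embryo", "cell_type", "platform"]]
        if triple.duplicated().any():
            dupes = triple[triple.duplicated()].to_dict("records")
            raise ValueError(f"duplicate (embryo, cell_type, platform) triple(s): {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def embryos(self) -> list[str]:
        return sorted(self.table["embryo"].unique())

    @property
    def platforms(self) -> list[str]:
        return sorted(self.table["platform"].unique())

    def filter_platform(self, platform: str) -> "SampleSheet":
        sub = self.table[self.table["platform"] == platform]
        if sub.empty:
            raise ValueError(
                f"no samples with platform {platform!r}; available: {self.platforms}"
            )
        return SampleSheet(sub.reset_index(drop=True), cell_types=self.cell_types)

    def lookup(self, sample_id: str) -> tuple[str, str]:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row.iloc[0]["embryo"], row.iloc[0]["cell_type"]


@dataclass
class PatternCall:
    """One gene's ON/OFF call: bit vector, pooled replicate values and TQR.

    ``pattern`` is ordered by the canonical cell-type order; ``on_values``
    and ``off_values`` are the pooled per-replicate φ values of the two
    clusters.  The two-cluster cut never leaves a side empty, and the ON
    side is the one with the larger pooled mean.
    """

    gene_id: str
    pattern: tuple[int, ...]
    tqr: float
    on_values: tuple[float, ...] | None = None
    off_values: tuple[float, ...] | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        self.pattern = tuple(int(b) for b in self.pattern)
        if any(b not in (0, 1) for b in self.pattern):
            raise ValueError(f"pattern bits must be 0/1, got {self.pattern}")
        n_on = sum(self.pattern)
        if not 1 <= n_on <= len(self.pattern) - 1:
            raise ValueError(
                f"gene {self.gene_id}: ON side must contain 1..{len(self.pattern) - 1} "
                f"cells, got {n_on}"
            )
        if self.on_values is not None and self.off_values is not None:
            if np.mean(self.on_values) < np.mean(self.off_values):
                raise ValueError(
                    f"gene {self.gene_id}: mean(on_values) < mean(off_values)"
                )

    @property
    def pattern_string(self) -> str:
        return "".join(str(b) for b in self.pattern)


def read_count_table(path: str | Path,
                     spike_prefix: str = DEFAULT_SPIKE_PREFIX) -> CountMatrix:
    """Read a TSV count table (gene ids in the first column, header row of
    sample ids).  Row and column order are preserved; parse errors name the
    offending gene and sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric count for gene {gene!r}, sample {col!r} in {path}"
            )
        numeric[col] = converted
    return CountMatrix(numeric, spike_prefix=spike_prefix)


def read_count_mtx(mtx_path: str | Path,
                   genes_path: str | Path,
                   samples_path: str | Path,
                   spike_prefix: str = DEFAULT_SPIKE_PREFIX) -> CountMatrix:
    """Read a MatrixMarket count matrix with gene/sample sidecar files
    (one id per line), the standard sparse dialect for large matrices.
    """
    mat = scipy.io.mmread(str(mtx_path)).toarray()
    genes = [line.split("\t")[0] for line in _read_lines(genes_path)]
    samples = [line.split("\t")[0] for line in _read_lines(samples_path)]
    if mat.shape != (len(genes), len(samples)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes × "
            f"{len(samples)} samples"
        )
    df = pd.DataFrame(mat, index=genes, columns=samples)
    return CountMatrix(df, spike_prefix=spike_prefix)


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_sample_sheet(path: str | Path,
                      cell_types: Sequence[str] = CANONICAL_CELL_TYPES) -> SampleSheet:
    """Read a sample sheet TSV with columns sample_id, embryo, cell_type
    and optionally platform."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return SampleSheet(df, cell_types=tuple(cell_types))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    cols = ["sample_id", "embryo", "cell_type", "platform"]
    sheet.table[cols].to_csv(path, sep="\t", index=False)


def write_count_table(counts: CountMatrix, path: str | Path) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="gene_id")


def write_pattern_calls(calls: Sequence[PatternCall], path: str | Path,
                        cell_types: Sequence[str] = CANONICAL_CELL_TYPES) -> None:
    """Write ranked calls as TSV: gene_id, one 0/1 column per cell type in
    canonical order, tqr (12 significant digits) and rank.

    Calls must be sorted by rank with no duplicates; reading the file back
    reproduces patterns and ranks bit-exactly.
    """
    ranks = [c.rank for c in calls]
    if any(r is None for r in ranks):
        raise ValueError("all calls must have a rank before serialisation")
    if len(set(ranks)) != len(ranks):
        raise ValueError("duplicate ranks in pattern calls")
    if list(ranks) != sorted(ranks):  # type: ignore[type-var]
        raise ValueError("calls must be sorted by rank")
    header = ["gene_id", *cell_types, "tqr", "rank"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for call in calls:
            if len(call.pattern) != len(cell_types):
                raise ValueError(
                    f"gene {call.gene_id}: pattern length {len(call.pattern)} "
                    f"does not match {len(cell_types)} cell types"
                )
            bits = "\t".join(str(b) for b in call.pattern)
            fh.write(f"{call.gene_id}\t{bits}\t{call.tqr:.12g}\t{call.rank}\n")


def read_pattern_calls(path: str | Path,
                       cell_types: Sequence[str] = CANONICAL_CELL_TYPES) -> list[PatternCall]:
    """Read back a pattern-call table written by :func:`write_pattern_calls`.

    Pooled replicate values are not serialised, so ``on_values`` and
    ``off_values`` are ``None`` on the returned calls.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    expected = ["gene_id", *cell_types, "tqr", "rank"]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected columns {list(df.columns)}; expected {expected}")
    calls = []
    for _, row in df.iterrows():
        calls.append(PatternCall(
            gene_id=row["gene_id"],
            pattern=tuple(int(row[ct]) for ct in cell_types),
            tqr=float(row["tqr"]),
            rank=int(row["rank"]),
        ))
    return calls


def calls_to_frame(calls: Sequence[PatternCall],
                   cell_types: Sequence[str] = CANONICAL_CELL_TYPES) -> pd.DataFrame:
    """Tabular view of calls (gene_id, per-cell bits, tqr, rank)."""
    rows = []
    for c in calls:
        row = {"gene_id": c.gene_id, "tqr": c.tqr, "rank": c.rank}
        row.update(dict(zip(cell_types, c.pattern)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene_id", *cell_types, "tqr", "rank"])
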