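"""Readers, writers and expression preprocessing.

Series matrices travel as wide CSV/TSV: a header row of time labels and a
first column of series identifiers.  Replicate-level RNA-seq counts travel
as long CSV (gene, time, replicate, count[, total_reads, ambiguous_reads])
and are reduced to one expression value per gene and time point by weighted
log2 averaging over replicates.  All text is UTF-8 with '.' decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import TimeSeriesMatrix

__all__ = [
    "CountsTable",
    "read_series_matrix",
    "write_series_matrix",
    "read_counts_long",
    "preprocess_expression",
    "zero_count_filter",
]

log = logging.getLogger("rwmix")


@dataclass(frozen=True)
class CountsTable:
    """Replicate-level count data: genes x time points x replicates.

    ``total_reads`` and ``ambiguous_reads`` (per measurement, i.e. per
    time-point/replicate pair) are optional sequencing-run metadata used by
    the weighted averaging; without them the weighting degrades to unity.
    """

    counts: np.ndarray  # (G, T, R) non-negative integers
    gene_ids: tuple[str, ...]
    time_labels: np.ndarray  # (T,)
    replicate_ids: tuple[str, ...]  # (R,)
    total_reads: np.ndarray | None = None  # (T, R)
    ambiguous_reads: np.ndarray | None = None  # (T, R)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError("counts must be genes x time x replicates")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        G, T, R = counts.shape
        if len(self.gene_ids) != G or len(self.replicate_ids) != R:
            raise ValueError("id lengths do not match the counts array")
        time_labels = np.asarray(self.time_labels, dtype=float)
        if time_labels.shape != (T,):
            raise ValueError("time_labels length mismatch")
        for name in ("total_reads", "ambiguous_reads"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (T, R):
                    raise ValueError(f"{name} must be time x replicates")
                object.__setattr__(self, name, v)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "time_labels", time_labels)
        object.__setattr__(
            self, "replicate_ids", tuple(str(r) for r in self.replicate_ids)
        )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


def _sniff_sep(path: Path) -> str:
    head = path.open("r", encoding="utf-8").readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_series_matrix(path, orientation: str = "rows_are_series") -> TimeSeriesMatrix:
    """Parse a wide CSV/TSV matrix, transposing when columns are the series.

    The first column holds identifiers and the header row holds time labels
    (numeric, else replaced by ordinal indices 1..d).  Any empty or
    non-numeric cell raises an error naming its row and column.
    """
    if orientation not in ("rows_are_series", "columns_are_series"):
        raise ValueError("orientation must be rows_are_series or columns_are_series")
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate identifiers: {dupes}")
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                    raise ValueError
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"missing or non-numeric cell at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
    if orientation == "columns_are_series":
        series_ids = [str(c) for c in df.columns]
        time_ids = [str(i) for i in df.index]
        values = values.T
    else:
        series_ids = [str(i) for i in df.index]
        time_ids = [str(c) for c in df.columns]
    try:
        time_labels = np.asarray([float(t) for t in time_ids])
        if not np.all(np.diff(time_labels) > 0):
            raise ValueError
    except ValueError:
        time_labels = np.arange(1.0, len(time_ids) + 1.0)
    return TimeSeriesMatrix(values, series_ids=series_ids, time_labels=time_labels)


def write_series_matrix(X: TimeSeriesMatrix, path) -> None:
    df = pd.DataFrame(
        X.values,
        index=list(X.series_ids),
        columns=[_fmt_time(t) for t in X.time_labels],
    )
    df.index.name = "series_id"
    df.to_csv(Path(path))


def _fmt_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else repr(float(t))


def read_counts_long(path) -> CountsTable:
    """Long CSV (gene, time, replicate, count[, total_reads, ambiguous_reads])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"gene", "time", "replicate", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"counts file needs columns {sorted(required)}")
    genes = list(dict.fromkeys(df["gene"].astype(str)))
    times = np.sort(df["time"].unique())
    reps = list(dict.fromkeys(df["replicate"].astype(str)))
    gi = {g: i for i, g in enumerate(genes)}
    ti = {t: i for i, t in enumerate(times)}
    ri = {r: i for i, r in enumerate(reps)}
    counts = np.zeros((len(genes), len(times), len(reps)), dtype=np.int64)
    seen = np.zeros_like(counts, dtype=bool)
    for row in df.itertuples(index=False):
        i, j, k = gi[str(row.gene)], ti[row.time], ri[str(row.replicate)]
        counts[i, j, k] = int(row.count)
        seen[i, j, k] = True
    if not seen.all():
        raise ValueError("replicate structure is not rectangular (missing cells)")
    meta = {}
    for name in ("total_reads", "ambiguous_reads"):
        if name in df.columns:
            arr = np.zeros((len(times), len(reps)))
            for row in df.itertuples(index=False):
                arr[ti[row.time], ri[str(row.replicate)]] = getattr(row, name)
            meta[name] = arr
    return CountsTable(
        counts=counts,
        gene_ids=genes,
        time_labels=times.astype(float),
        replicate_ids=reps,
        total_reads=meta.get("total_reads"),
        ambiguous_reads=meta.get("ambiguous_reads"),
    )


def preprocess_expression(table: CountsTable, pseudocount: float = 1.0) -> TimeSeriesMatrix:
    """Weighted log2 replicate averaging into a genes x time matrix.

    Each measurement m (one time point of one replicate) gets a scale factor
    s_m chosen so its ambiguous-or-failed read fraction matches the grand
    mean fraction across measurements; expression(g, t) is then the mean
    over replicates of log2(s_m * count + pseudocount).  Without read
    metadata all scales are 1 and a warning is logged.
    """
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    T, R = table.counts.shape[1:]
    if table.total_reads is None or table.ambiguous_reads is None:
        log.warning(
            "no read metadata on counts table; replicate weighting disabled (s = 1)"
        )
        scales = np.ones((T, R))
    else:
        frac = table.ambiguous_reads / table.total_reads
        target = float(frac.mean())
        scales = np.ones((T, R))
        if target > 0:
            mask = frac > 0
            scales[mask] = target / frac[mask]
    expr = np.log2(scales[None, :, :] * table.counts + pseudocount).mean(axis=2)
    return TimeSeriesMatrix(
        expr, series_ids=table.gene_ids, time_labels=table.time_labels
    )


def zero_count_filter(table: CountsTable) -> tuple[CountsTable, tuple[str, ...]]:
    """Drop the genes never counted in any replicate at any time point.

    Genes with all-zero counts carry no expression signal yet attract the
    latent centres towards the floor of the data; removing exactly those
    (and only those) genes keeps every gene with even a single read.
    """
    keep = (table.counts > 0).any(axis=(1, 2))
    removed = tuple(g for g, k in zip(table.gene_ids, keep) if not k)
    kept = CountsTable(
        counts=table.counts[keep],
        gene_ids=tuple(g for g, k in zip(table.gene_ids, keep) if k),
        time_labels=table.time_labels,
        replicate_ids=table.replicate_ids,
        total_reads=table.total_reads,
        ambiguous_reads=table.ambiguous_reads,
    )
    return kept, removed
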