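"""Readers, writers and core containers for the formats the pipeline touches.

Genomic intervals are uniformly 0-based, half-open ``[start, end)`` — the BED
convention — everywhere in this package.  Activity-monitor text follows the
TriKinetics DAM layout (tab-separated: reading index, date, time, status,
then one count column per channel); the status convention is ``1`` = OK.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("flymb")

DIRECTIONS = ("up", "down", "none")

_INTERVAL_COLUMNS = ["chrom", "start", "end", "name", "score", "fdr", "fold_change", "direction"]


class FormatError(ValueError):
    """A file did not conform to its declared format."""


# ---------------------------------------------------------------------------
# IntervalSet
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Strandless genomic intervals with optional score / FDR / fold-change.

    Backed by a :class:`pandas.DataFrame` with columns ``chrom, start, end,
    name, score, fdr, fold_change, direction``.  ``fold_change`` is stored as
    a linear ratio >= 1 with the sign of the change carried separately in
    ``direction`` ({'up', 'down', 'none'}), so a threshold like "fold change
    > 1.25" applies symmetrically to increases and reductions.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
        if missing:
            raise ValueError(f"IntervalSet frame missing columns: {missing}")
        for col, default in (("name", ""), ("score", np.nan),
                             ("fdr", np.nan), ("fold_change", np.nan),
                             ("direction", "none")):
            if col not in df.columns:
                df[col] = default
        if len(df):
            df["name"] = df["name"].fillna("")
            df["direction"] = df["direction"].fillna("none")
        if len(df):
            if df["chrom"].isna().any() or df["start"].isna().any() or df["end"].isna().any():
                raise ValueError("chrom/start/end may not contain missing values")
            starts = df["start"].to_numpy()
            ends = df["end"].to_numpy()
            if (starts < 0).any():
                raise ValueError("negative start coordinate")
            bad = np.nonzero(starts >= ends)[0]
            if bad.size:
                raise ValueError(f"start >= end for record(s) at index {bad.tolist()}")
        self.df = df.reset_index(drop=True)[_INTERVAL_COLUMNS].astype(
            {"start": np.int64, "end": np.int64}
        )

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "IntervalSet":
        """Build from (chrom, start, end[, name[, score[, fdr[, fold_change[, direction]]]]])."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            row = dict(zip(_INTERVAL_COLUMNS, rec))
            rows.append(row)
        df = pd.DataFrame(rows, columns=_INTERVAL_COLUMNS)
        if not len(rows):
            df = cls.empty().df
        return cls(df)

    @classmethod
    def empty(cls) -> "IntervalSet":
        df = pd.DataFrame({
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=str),
            "score": pd.Series(dtype=float),
            "fdr": pd.Series(dtype=float),
            "fold_change": pd.Series(dtype=float),
            "direction": pd.Series(dtype=str),
        })
        return cls(df)

    def sort(self) -> "IntervalSet":
        return IntervalSet(
            self.df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        )

    @property
    def records(self) -> list[tuple]:
        return list(self.df.itertuples(index=False, name=None))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a, b = self.sort().df, other.sort().df
        if len(a) != len(b):
            return False
        if not len(a):
            return True
        core = a[["chrom", "start", "end", "name", "direction"]].equals(
            b[["chrom", "start", "end", "name", "direction"]]
        )
        nums = all(
            np.allclose(a[c].to_numpy(float), b[c].to_numpy(float), equal_nan=True)
            for c in ("score", "fdr", "fold_change")
        )
        return core and nums


def read_bed(path: str | Path, dialect: str = "bed6plus") -> IntervalSet:
    """Read a BED file (0-based half-open) into an :class:`IntervalSet`.

    ``dialect='bed3'`` keeps only chrom/start/end; ``'bed6plus'`` additionally
    reads name and score and, when present, trailing ``fdr``, ``fold_change``
    and ``direction`` columns (columns 7-9, as written by :func:`write_bed`).
    ``track``/``browser``/``#`` lines are skipped.  Strand columns, if any,
    are not interpreted: no operation in this pipeline is strand-aware.
    """
    if dialect not in ("bed3", "bed6plus"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            row: dict = {"chrom": chrom, "start": start, "end": end,
                         "name": "", "score": np.nan, "fdr": np.nan,
                         "fold_change": np.nan, "direction": "none"}
            if dialect == "bed6plus":
                if len(fields) > 3:
                    row["name"] = fields[3]
                if len(fields) > 4 and fields[4] not in (".", ""):
                    row["score"] = float(fields[4])
                # column 6 is strand: preserved in file, ignored here
                if len(fields) > 6 and fields[6] not in (".", ""):
                    row["fdr"] = float(fields[6])
                if len(fields) > 7 and fields[7] not in (".", ""):
                    row["fold_change"] = float(fields[7])
                if len(fields) > 8 and fields[8] in DIRECTIONS:
                    row["direction"] = fields[8]
            rows.append(row)
    if not rows:
        return IntervalSet.empty()
    return IntervalSet(pd.DataFrame(rows, columns=_INTERVAL_COLUMNS))


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write an :class:`IntervalSet` as BED6+3 (name, score, '.', fdr, fold_change, direction).

    ``read_bed(write_bed(x), 'bed6plus')`` reproduces ``x`` record for record.
    """
    with open(path, "w") as fh:
        for chrom, start, end, name, score, fdr, fc, direction in intervals.records:
            fields = [chrom, str(start), str(end), name or ".",
                      "." if pd.isna(score) else repr(float(score)),
                      ".",
                      "." if pd.isna(fdr) else repr(float(fdr)),
                      "." if pd.isna(fc) else repr(float(fc)),
                      direction]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GeneTable
# ---------------------------------------------------------------------------

@dataclass
class GeneTable:
    """Per-gene expression summary: means in two conditions, log2 fold change, adjusted p."""

    df: pd.DataFrame  # columns: gene_id, mean_a, mean_b, log2fc, padj

    def __post_init__(self) -> None:
        required = ["gene_id", "log2fc"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"GeneTable missing columns: {missing}")
        for col in ("mean_a", "mean_b", "padj"):
            if col not in self.df.columns:
                self.df[col] = np.nan
        dupes = self.df["gene_id"][self.df["gene_id"].duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate gene_id(s): {sorted(set(dupes))}")
        padj = self.df["padj"].to_numpy(float)
        ok = np.isnan(padj) | ((padj >= 0) & (padj <= 1))
        if not ok.all():
            raise ValueError("padj outside [0, 1]")
        self.df = self.df.reset_index(drop=True)[["gene_id", "mean_a", "mean_b", "log2fc", "padj"]]

    def __len__(self) -> int:
        return len(self.df)


DEFAULT_GENE_SCHEMA = {
    "gene_id": "gene_id",
    "mean_a": "mean_a",
    "mean_b": "mean_b",
    "log2fc": "log2fc",
    "padj": "padj",
}


def read_gene_table(path: str | Path, schema: Mapping[str, str] | None = None) -> GeneTable:
    """Read a headered TSV of DESeq2-style per-gene results.

    ``schema`` maps internal names (gene_id, mean_a, mean_b, log2fc, padj) to
    the column names present in the file; ``mean_a``/``mean_b``/``padj`` are
    optional and come back missing when unmapped or absent.
    """
    schema = dict(DEFAULT_GENE_SCHEMA if schema is None else schema)
    raw = pd.read_csv(path, sep="\t")
    for key in ("gene_id", "log2fc"):
        col = schema.get(key)
        if col is None or col not in raw.columns:
            raise FormatError(f"{path}: required column {key!r} (mapped to {col!r}) not found")
    out = pd.DataFrame({"gene_id": raw[schema["gene_id"]].astype(str),
                        "log2fc": raw[schema["log2fc"]].astype(float)})
    for key in ("mean_a", "mean_b", "padj"):
        col = schema.get(key)
        out[key] = raw[col].astype(float) if col in raw.columns else np.nan
    return GeneTable(out)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ActivityMatrix (TriKinetics DAM)
# ---------------------------------------------------------------------------

@dataclass
class ActivityMatrix:
    """Per-minute beam-crossing counts for a bank of flies.

    ``counts`` is minutes x channels; ``timestamps`` is a uniform 1-minute
    DatetimeIndex; ``regime`` labels each minute 'LD' (12h:12h light/dark) or
    'DD' (constant darkness); ``lights_on``/``lights_off`` are hours of day.
    """

    counts: np.ndarray
    timestamps: pd.DatetimeIndex
    lights_on: float = 8.0
    lights_off: float = 20.0
    regime: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be minutes x channels")
        if (self.counts < 0).any():
            raise ValueError("negative activity counts")
        if len(self.timestamps) != self.counts.shape[0]:
            raise ValueError("timestamps length != number of minutes")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8)
            if not (deltas == 60_000_000_000).all():
                raise FormatError("timestamps are not uniformly spaced at 1 minute")
        if self.regime is None:
            self.regime = np.full(self.counts.shape[0], "LD", dtype=object)
        self.regime = np.asarray(self.regime, dtype=object)
        if len(self.regime) != self.counts.shape[0]:
            raise ValueError("regime length != number of minutes")

    @property
    def n_minutes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_flies(self) -> int:
        return self.counts.shape[1]

    def is_day(self) -> np.ndarray:
        """Boolean mask of minutes that fall in the (objective) day phase."""
        hours = self.timestamps.hour + self.timestamps.minute / 60.0
        return (hours >= self.lights_on) & (hours < self.lights_off)

    def subset_regime(self, regime: str) -> "ActivityMatrix":
        mask = self.regime == regime
        return ActivityMatrix(self.counts[mask], self.timestamps[mask],
                              self.lights_on, self.lights_off, self.regime[mask])


def read_dam_monitor(path: str | Path, n_channels: int = 32,
                     lights_on: float = 8.0, lights_off: float = 20.0) -> ActivityMatrix:
    """Parse a TriKinetics DAM monitor text file.

    Expected layout per tab-separated row: reading index, date (``D Mon YY``),
    time (``HH:MM:SS``), status, then ``n_channels`` count columns.  Rows with
    a non-OK status (anything but 1) are dropped and counted in the log rather
    than raising, matching permissive monitor-file practice.
    """
    rows, times = [], []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4 + n_channels:
                raise FormatError(
                    f"{path}: line {lineno}: expected {4 + n_channels} columns, got {len(fields)}")
            status = fields[3].strip()
            if status != "1":
                n_dropped += 1
                continue
            try:
                ts = pd.to_datetime(f"{fields[1]} {fields[2]}", format="%d %b %y %H:%M:%S")
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad date/time") from exc
            try:
                counts = [int(v) for v in fields[4:]]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer count") from exc
            times.append(ts)
            rows.append(counts)
    if n_dropped:
        logger.info("read_dam_monitor: dropped %d row(s) with non-OK status", n_dropped)
    if not rows:
        raise FormatError(f"{path}: no valid data rows")
    idx = pd.DatetimeIndex(times)
    if len(idx) > 1 and (np.diff(idx.asi8) <= 0).any():
        raise FormatError(f"{path}: timestamps not strictly increasing")
    return ActivityMatrix(np.asarray(rows, dtype=np.int64), idx, lights_on, lights_off)


def write_dam_monitor(matrix: ActivityMatrix, path: str | Path) -> None:
    """Write an :class:`ActivityMatrix` in the TriKinetics row layout (all rows OK)."""
    with open(path, "w") as fh:
        for i, (ts, row) in enumerate(zip(matrix.timestamps, matrix.counts), start=1):
            date = ts.strftime("%d %b %y").lstrip("0")
            fields = [str(i), date, ts.strftime("%H:%M:%S"), "1"]
            fields += [str(int(v)) for v in row]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds and defaults for every stage, serializable to/from YAML."""

    # differential-peak filtering
    peak_fdr_max: float = 0.05
    peak_fc_min: float = 1.25
    # sleep
    min_bout_minutes: int = 5
    inactivity_threshold: int = 1
    # circadian
    period_lo_hours: float = 10.0
    period_hi_hours: float = 40.0
    oversample: int = 4
    rhythm_alpha: float = 0.05
    # FRET
    af_floor: float = 1.0
    ratio_orientation: str = "cfp_over_yfp"
    # randomization
    n_replicates: int = 10_000
    randomization_scheme: str = "permutation"
    # overlap statistics
    universe_size: int = 13_986
    min_term_size: int = 25
    max_term_size: int = 250
    enrich_alpha: float = 0.05
    # annotation
    upstream_window: int = 2_000
    annotation_mode: str = "nearest_tss"
    de_padj_max: float = 0.05
    # enrichment call (tissue A vs tissue B)
    enrich_min_fold: float = 2.0
    enrich_padj_max: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.peak_fdr_max <= 1):
            raise ValueError("peak_fdr_max must be in (0, 1]")
        if self.peak_fc_min <= 1:
            raise ValueError("peak_fc_min must exceed 1")
        if self.min_bout_minutes < 1:
            raise ValueError("min_bout_minutes must be >= 1")
        if self.n_replicates < 100:
            raise ValueError("n_replicates must be >= 100")
        if self.ratio_orientation not in ("cfp_over_yfp", "yfp_over_cfp"):
            raise ValueError("unknown ratio orientation")
        if self.randomization_scheme not in ("permutation", "bootstrap"):
            raise ValueError("unknown randomization scheme")
        if self.min_term_size > self.max_term_size:
            raise ValueError("min_term_size > max_term_size")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = source
        data = yaml.safe_load(text) or {}
        return cls(**data)
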