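"""Read/write fragment-analysis peak tables and sample manifests.

Peak tables are tab-delimited exports in the style of capillary-
electrophoresis genotyping software ("Genotypes table" exports): one row
per sized peak carrying sample, locus, size (bp) and height columns.
Exact column names differ between export configurations, so the mapping is
carried by :class:`Dialect` and can be adapted to real exports without
touching the parser.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("sample_id", "genotype", "replicate", "day")


@dataclass(frozen=True)
class Peak:
    """One sized, height-annotated electropherogram peak."""

    size_bp: float
    height: float
    area: float | None = None

    def __post_init__(self) -> None:
        if not self.size_bp > 0:
            raise ValueError(f"peak size must be positive, got {self.size_bp}")
        if self.height < 0:
            raise ValueError(f"peak height must be >= 0, got {self.height}")
        if self.area is not None and self.area < 0:
            raise ValueError(f"peak area must be >= 0, got {self.area}")


@dataclass
class PeakTable:
    """All peaks of one (sample, locus) combination, sorted by size.

    ``day`` is the optional time-course day the sample was drawn on; it is
    carried through I/O so downstream kinetics can pair tables without a
    manifest lookup.
    """

    sample_id: str
    locus: str
    peaks: list[Peak] = field(default_factory=list)
    day: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id or not self.locus:
            raise ValueError("sample_id and locus must be non-empty")
        self.peaks = sorted(self.peaks, key=lambda p: p.size_bp)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for tab-delimited peak-table exports."""

    sample: str = "sample"
    locus: str = "locus"
    size: str = "size_bp"
    height: str = "height"
    area: str = "area"
    day: str = "day"
    delimiter: str = "\t"

    @property
    def required(self) -> tuple[str, ...]:
        return (self.sample, self.locus, self.size, self.height)


@dataclass(frozen=True)
class RowError:
    """A malformed data row, reported with its 1-based line number."""

    line: int
    message: str


def read_peak_table(
    path: str | Path,
    dialect: Dialect = Dialect(),
    strict: bool = False,
    errors: list[RowError] | None = None,
) -> list[PeakTable]:
    """Parse a peak-table file into one :class:`PeakTable` per (sample, locus).

    Malformed rows (non-numeric size/height, negative values) are collected
    with their line numbers and logged; in ``strict`` mode the first one
    raises :class:`FormatError` instead.  A missing mandatory column always
    raises :class:`FormatError`.  Pass ``errors`` to receive the collected
    :class:`RowError` records.
    """
    path = Path(path)
    collected: list[RowError] = [] if errors is None else errors
    groups: dict[tuple[str, str, float | None], list[Peak]] = {}

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header")
        missing = [c for c in dialect.required if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        has_area = dialect.area in reader.fieldnames
        has_day = dialect.day in reader.fieldnames

        for lineno, row in enumerate(reader, start=2):
            try:
                size = float(row[dialect.size])
                height = float(row[dialect.height])
                area_raw = row.get(dialect.area, "") if has_area else ""
                area = float(area_raw) if area_raw not in ("", None) else None
                day_raw = row.get(dialect.day, "") if has_day else ""
                day = float(day_raw) if day_raw not in ("", None) else None
                peak = Peak(size_bp=size, height=height, area=area)
            except (TypeError, ValueError) as exc:
                err = RowError(line=lineno, message=str(exc))
                if strict:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
                collected.append(err)
                log.warning("%s:%d: skipping malformed row (%s)", path, lineno, exc)
                continue
            key = (row[dialect.sample], row[dialect.locus], day)
            groups.setdefault(key, []).append(peak)

    if not groups:
        log.warning("%s: no data rows found (header-only file?)", path)
    return [
        PeakTable(sample_id=s, locus=l, peaks=pks, day=d)
        for (s, l, d), pks in groups.items()
    ]


def write_peak_table(
    tables: Sequence[PeakTable],
    path: str | Path,
    dialect: Dialect = Dialect(),
) -> Path:
    """Write tables to a tab-delimited file; inverse of :func:`read_peak_table`.

    Floats are serialized with 10 significant digits so a round-trip
    preserves values far beyond the assay's sizing precision.  The ``day``
    and ``area`` columns are emitted only if any table/peak carries them.
    """
    path = Path(path)
    has_day = any(t.day is not None for t in tables)
    has_area = any(p.area is not None for t in tables for p in t.peaks)

    header = [dialect.sample, dialect.locus]
    if has_day:
        header.append(dialect.day)
    header += [dialect.size, dialect.height]
    if has_area:
        header.append(dialect.area)

    def fmt(x: float) -> str:
        return format(x, ".10g")

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(header)
        for t in tables:
            for p in t.peaks:
                row = [t.sample_id, t.locus]
                if has_day:
                    row.append("" if t.day is None else fmt(t.day))
                row += [fmt(p.size_bp), fmt(p.height)]
                if has_area:
                    row.append("" if p.area is None else fmt(p.area))
                writer.writerow(row)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV with columns sample_id, genotype, replicate, day."""
    df = pd.read_csv(path, dtype={"sample_id": str, "genotype": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {missing}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing column(s) {missing}")
    df.to_csv(path, index=False)
    return Path(path)


def concat_tables(tables_iter: Iterable[list[PeakTable]]) -> list[PeakTable]:
    """Flatten several read results into one list (convenience for globs)."""
    out: list[PeakTable] = []
    for tables in tables_iter:
        out.extend(tables)
    return out


def with_day(table: PeakTable, day: float) -> PeakTable:
    """Return a copy of ``table`` annotated with a time-course day."""
    return replace(table, day=day)
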