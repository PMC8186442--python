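"""Data model and I/O for repeated-pull relative-search-volume (RSV) matrices.

A *pull matrix* records the same Google-Trends-style query, geography and
investigation period downloaded ("pulled") on several consecutive collection
days.  Rows are geographic series (cities, regions or countries), columns are
collection dates, and cells hold the RSV in [0, 100] that the unit showed on
that pull day — or nothing at all, when the provider omitted the unit from
that day's ranking.  Those blanks are the *anomalies* the audit modules work
on, so they are preserved exactly (as NaN) and never imputed.

The on-disk format is a wide UTF-8 CSV: first column header ``unit``,
remaining headers ISO-8601 collection dates, empty string = missing cell.

Four bundled fixtures transcribe published repeated-pull tables for the
query *coronavirus + covid* (Italian and international cities, two
investigation periods in 2020); see :func:`load_fixture`.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import FixtureNotFoundError, FormatError, ValidationError

__all__ = [
    "MISSING",
    "PullMatrix",
    "SeriesRow",
    "ExternalSeries",
    "read_pull_matrix",
    "write_pull_matrix",
    "read_external_series",
    "load_fixture",
    "write_report",
]

#: Sentinel for an absent cell (a unit missing from one pull day).
MISSING = float("nan")

UnitLevel = Literal["city", "region", "country"]

_FIXTURE_META: dict[str, dict] = {
    # Italian cities, investigation period 1 Feb – 4 Dec 2020, pulled daily
    # 14–26 Dec 2020.
    "table2": dict(
        query="coronavirus + covid", geo_scope="IT", unit_level="city",
        period_start=dt.date(2020, 2, 1), period_end=dt.date(2020, 12, 4),
    ),
    # Italian cities, period 20 Feb – 18 May 2020, pulled 14–26 Dec 2020.
    "table3": dict(
        query="coronavirus + covid", geo_scope="IT", unit_level="city",
        period_start=dt.date(2020, 2, 20), period_end=dt.date(2020, 5, 18),
    ),
    # International cities, period 1, pulled 16–26 Dec 2020.
    "table4": dict(
        query="coronavirus + covid", geo_scope="world", unit_level="city",
        period_start=dt.date(2020, 2, 1), period_end=dt.date(2020, 12, 4),
    ),
    # International cities, period 2, pulled 16–27 Dec 2020.
    "table5": dict(
        query="coronavirus + covid", geo_scope="world", unit_level="city",
        period_start=dt.date(2020, 2, 20), period_end=dt.date(2020, 5, 18),
    ),
}


def normalize_unit(name: str) -> str:
    """Canonical key for joining unit names across hand-entered tables."""
    return " ".join(name.split()).casefold()


@dataclasses.dataclass(frozen=True)
class SeriesRow:
    """One geographic series: a unit name and its per-pull-day RSVs.

    ``values`` has one entry per collection date; missing cells are NaN.
    """

    name: str
    values: tuple[float, ...]

    @property
    def n_present(self) -> int:
        return sum(1 for v in self.values if not math.isnan(v))

    @property
    def n_missing(self) -> int:
        return len(self.values) - self.n_present

    @property
    def present_values(self) -> list[float]:
        return [v for v in self.values if not math.isnan(v)]


@dataclasses.dataclass(frozen=True)
class PullMatrix:
    """Series × collection-day RSV grid with metadata.

    Parameters
    ----------
    query, geo_scope, unit_level
        What was searched, where, and at which geographic granularity.
    period_start, period_end
        The fixed investigation period every pull covers.
    data
        DataFrame indexed by unit name, columns = collection dates
        (``datetime.date``, strictly increasing), float cells in [0, 100]
        with NaN for missing.
    """

    query: str
    geo_scope: str
    unit_level: UnitLevel
    period_start: dt.date
    period_end: dt.date
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate unit name(s): {dupes}")
        if any(not str(u).strip() for u in df.index):
            raise ValidationError("empty unit name")
        dates = list(df.columns)
        if any(dates[k] >= dates[k + 1] for k in range(len(dates) - 1)):
            raise ValidationError(
                "collection dates must be strictly increasing")
        vals = df.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 100)  # NaN compares False: missing is fine
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"RSV out of [0, 100]: unit {df.index[i]!r}, "
                f"date {dates[j]}, value {vals[i, j]!r}")

    # -- views ---------------------------------------------------------------

    @property
    def units(self) -> list[str]:
        return list(self.data.index)

    @property
    def collection_dates(self) -> list[dt.date]:
        return list(self.data.columns)

    @property
    def n_series(self) -> int:
        return len(self.data.index)

    @property
    def n_days(self) -> int:
        return len(self.data.columns)

    @property
    def series(self) -> list[SeriesRow]:
        return list(self.iter_series())

    def iter_series(self) -> Iterator[SeriesRow]:
        for name, row in zip(self.data.index, self.data.to_numpy(dtype=float)):
            yield SeriesRow(name=str(name), values=tuple(float(v) for v in row))

    def row(self, unit: str) -> SeriesRow:
        key = normalize_unit(unit)
        for sr in self.iter_series():
            if normalize_unit(sr.name) == key:
                return sr
        raise KeyError(unit)

    def subset(self, units: list[str]) -> "PullMatrix":
        """New matrix containing exactly ``units`` in the given order."""
        return dataclasses.replace(self, data=self.data.loc[units].copy())

    def equals(self, other: "PullMatrix") -> bool:
        """Cell-for-cell equality including the missingness pattern."""
        return (
            self.units == other.units
            and self.collection_dates == other.collection_dates
            and np.array_equal(
                self.data.to_numpy(dtype=float),
                other.data.to_numpy(dtype=float),
                equal_nan=True,
            )
        )


@dataclasses.dataclass(frozen=True)
class ExternalSeries:
    """One numeric value per geographic unit, e.g. cumulative epidemic cases
    over the investigation period.  Unit names are matched case-insensitively
    after whitespace trimming when joined with a :class:`PullMatrix`."""

    label: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"external value for {k!r} must be finite and >= 0, "
                    f"got {v!r}")

    def get(self, unit: str) -> float | None:
        key = normalize_unit(unit)
        for k, v in self.values.items():
            if normalize_unit(k) == key:
                return float(v)
        return None


# -- readers / writers -------------------------------------------------------

def _parse_header(cols: list[str], where: str) -> list[dt.date]:
    if not cols or cols[0].strip().lower() != "unit":
        raise FormatError(
            f"{where}: first header must be 'unit', got {cols[:1]!r}")
    if len(cols) < 2:
        raise FormatError(f"{where}: no collection-date columns")
    try:
        return [dt.date.fromisoformat(c.strip()) for c in cols[1:]]
    except ValueError as exc:
        raise FormatError(f"{where}: bad collection-date header: {exc}") from exc


def read_pull_matrix(
    path: str | Path,
    *,
    query: str = "",
    geo_scope: str = "",
    unit_level: UnitLevel = "city",
    period_start: dt.date | None = None,
    period_end: dt.date | None = None,
) -> PullMatrix:
    """Read a wide-format pull-matrix CSV.

    Header row = ``unit`` followed by ISO-8601 collection dates; one row per
    geographic series; empty cells denote missing RSVs and are preserved as
    NaN (never imputed).  Metadata not present in the CSV (query, geography,
    investigation period) can be supplied via keywords.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    dates = _parse_header(list(df.columns), str(path))
    units = [u.strip() for u in df.iloc[:, 0]]
    cells = df.iloc[:, 1:].map(lambda s: MISSING if s.strip() == "" else s)
    try:
        values = cells.astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric RSV cell: {exc}") from exc
    data = pd.DataFrame(values, index=pd.Index(units, name="unit"),
                        columns=dates)
    if period_start is None:
        period_start = dates[0]
    if period_end is None:
        period_end = dates[-1]
    return PullMatrix(
        query=query, geo_scope=geo_scope, unit_level=unit_level,
        period_start=period_start, period_end=period_end, data=data,
    )


def write_pull_matrix(pm: PullMatrix, path: str | Path) -> None:
    """Write ``pm`` in the wide CSV dialect (round-trips exactly: integers
    stay integers, missing cells stay empty)."""
    def fmt(v: float) -> str:
        if math.isnan(v):
            return ""
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    lines = ["unit," + ",".join(d.isoformat() for d in pm.collection_dates)]
    for sr in pm.iter_series():
        lines.append(sr.name + "," + ",".join(fmt(v) for v in sr.values))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_external_series(path: str | Path, label: str = "") -> ExternalSeries:
    """Read a two-column ``unit,value`` CSV (with or without a header row)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly 2 columns")
    rows = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    head = str(df.columns[1]).strip()
    try:  # headerless file: pandas put the first data row in the header
        float(head)
        rows.insert(0, (str(df.columns[0]), head))
    except ValueError:
        pass
    values: dict[str, float] = {}
    for unit, raw in rows:
        unit = str(unit).strip()
        try:
            values[unit] = float(raw)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: non-numeric value for {unit!r}: {raw!r}") from exc
    return ExternalSeries(label=label or path.stem, values=values)


def load_fixture(name: str) -> PullMatrix:
    """Load one of the bundled repeated-pull tables.

    ``table2``/``table3``: 24 Italian cities × 13 pull days (14–26 Dec 2020)
    for investigation periods 1 and 2.  ``table4``/``table5``: 22 and 21
    international cities over 11 and 12 pull days.  Blanks in the printed
    tables are missing cells.
    """
    if name not in _FIXTURE_META:
        raise FixtureNotFoundError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_META)}")
    ref = resources.files("rsvstab") / "fixtures" / f"{name}.csv"
    with resources.as_file(ref) as p:
        return read_pull_matrix(p, **_FIXTURE_META[name])


# -- report serialization ----------------------------------------------------

def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize any rsvstab report object.

    ``json`` round-trips every numeric field at full double precision via the
    report's ``to_dict``; ``text`` writes the human-readable table from the
    report's ``to_text``.
    """
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(report.to_dict(), indent=2, allow_nan=True) + "\n",
            encoding="utf-8")
    elif format == "text":
        path.write_text(report.to_text() + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")
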