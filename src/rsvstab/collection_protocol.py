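"""Incremental decision engine for robust daily collection of RSVs.

The engine turns a recommended collection discipline into code.  Pull the
same query/geography/period once per day and feed each day's column in:

1. *Monitoring*: watch the accumulating matrix for stability — no missing
   units and no dramatic level change (a jump of more than
   ``drama_threshold`` RSV units against a series' running mean).  Any such
   event resets the stability streak.
2. *Extending*: once the trend has been stable for ``min_stable_days``
   consecutive days (default 7), keep pulling until the series' mean RSVs
   become mutually distinguishable under the Welch confidence screen.
3. *Concluding*: when no series is confident with more than 20% of its
   peers, publish each series' mean RSV with its 95% confidence interval
   instead of any single-day snapshot.  If some series look non-normal,
   at least ``min_extractions_nonnormal`` pulls (default 30) are required
   before concluding, so the central-limit behaviour of the means can be
   relied on.

``conclude`` returns a report whose ``decision`` is ``"reliable"``,
``"unreliable"`` (confidence screen failed) or ``"continue"`` (the only
blocker is the 30-extraction normality gate — keep pulling).  Day-by-day
correlation against an external series, when one is supplied, is delegated
to :mod:`rsvstab.correlation_stability` and embedded in the report.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import ExternalSeries, PullMatrix, normalize_unit
from .correlation_stability import CorrelationTrace, correlation_by_day, \
    flag_outlier_days
from .errors import StateError, ValidationError
from .stability_stats import ConfidenceReport, SeriesStability, \
    confidence_report, summarize_series

__all__ = ["ProtocolState", "ProtocolReport", "start_protocol", "ingest_day",
           "conclude"]

DEFAULT_MIN_STABLE_DAYS = 7
DEFAULT_MIN_EXTRACTIONS_NONNORMAL = 30
DEFAULT_DRAMA_THRESHOLD = 10.0

PHASES = ("monitoring", "extending", "concluded_reliable",
          "concluded_unreliable")


@dataclasses.dataclass(frozen=True)
class ProtocolState:
    """Immutable engine state; :func:`ingest_day` returns a new one."""

    units: tuple[str, ...]
    collection_dates: tuple[dt.date, ...]
    #: row-major values aligned with (units, collection_dates); NaN = missing
    values: tuple[tuple[float, ...], ...]
    phase: str
    stable_streak: int
    min_stable_days: int = DEFAULT_MIN_STABLE_DAYS
    min_extractions_nonnormal: int = DEFAULT_MIN_EXTRACTIONS_NONNORMAL
    drama_threshold: float = DEFAULT_DRAMA_THRESHOLD
    query: str = ""
    geo_scope: str = ""
    unit_level: str = "region"
    period_start: dt.date | None = None
    period_end: dt.date | None = None

    @property
    def days_observed(self) -> int:
        return len(self.collection_dates)

    @property
    def matrix_so_far(self) -> PullMatrix:
        if not self.collection_dates:
            raise StateError("no pull days ingested yet")
        data = pd.DataFrame(
            np.array(self.values, dtype=float),
            index=pd.Index(self.units, name="unit"),
            columns=list(self.collection_dates))
        return PullMatrix(
            query=self.query, geo_scope=self.geo_scope,
            unit_level=self.unit_level,  # type: ignore[arg-type]
            period_start=self.period_start or self.collection_dates[0],
            period_end=self.period_end or self.collection_dates[-1],
            data=data)

    def to_dict(self) -> dict:
        return {
            "units": list(self.units),
            "collection_dates": [d.isoformat()
                                 for d in self.collection_dates],
            "values": [[None if math.isnan(v) else v for v in row]
                       for row in self.values],
            "phase": self.phase,
            "stable_streak": self.stable_streak,
            "min_stable_days": self.min_stable_days,
            "min_extractions_nonnormal": self.min_extractions_nonnormal,
            "drama_threshold": self.drama_threshold,
            "query": self.query,
            "geo_scope": self.geo_scope,
            "unit_level": self.unit_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolState":
        return cls(
            units=tuple(d["units"]),
            collection_dates=tuple(dt.date.fromisoformat(s)
                                   for s in d["collection_dates"]),
            values=tuple(tuple(float("nan") if v is None else float(v)
                               for v in row) for row in d["values"]),
            phase=d["phase"],
            stable_streak=int(d["stable_streak"]),
            min_stable_days=int(d["min_stable_days"]),
            min_extractions_nonnormal=int(d["min_extractions_nonnormal"]),
            drama_threshold=float(d["drama_threshold"]),
            query=d.get("query", ""),
            geo_scope=d.get("geo_scope", ""),
            unit_level=d.get("unit_level", "region"),
        )


def start_protocol(
    units: list[str],
    *,
    min_stable_days: int = DEFAULT_MIN_STABLE_DAYS,
    min_extractions_nonnormal: int = DEFAULT_MIN_EXTRACTIONS_NONNORMAL,
    drama_threshold: float = DEFAULT_DRAMA_THRESHOLD,
    query: str = "",
    geo_scope: str = "",
    unit_level: str = "region",
) -> ProtocolState:
    """Fresh monitoring state over a fixed universe of geographic units."""
    if not units:
        raise ValidationError("unit universe must be non-empty")
    return ProtocolState(
        units=tuple(units), collection_dates=(), values=tuple(() for _ in units),
        phase="monitoring", stable_streak=0,
        min_stable_days=min_stable_days,
        min_extractions_nonnormal=min_extractions_nonnormal,
        drama_threshold=drama_threshold,
        query=query, geo_scope=geo_scope, unit_level=unit_level)


def ingest_day(
    state: ProtocolState,
    date: dt.date,
    new_column: Mapping[str, float],
) -> ProtocolState:
    """Append one pull day and update the stability streak.

    The streak resets to 0 when the column misses any unit of the universe
    (absent key or NaN) or when any unit's RSV jumps by more than
    ``drama_threshold`` against its running mean over previous days; a zero
    jump is never dramatic.  Otherwise it increments, and the phase moves
    from monitoring to extending once the streak reaches
    ``min_stable_days``.  Concluded states accept no further days.
    """
    if state.phase.startswith("concluded"):
        raise StateError(f"cannot ingest into phase {state.phase!r}")
    if date in state.collection_dates:
        raise ValidationError(f"duplicate collection date {date}")
    if state.collection_dates and date <= state.collection_dates[-1]:
        raise ValidationError(
            f"collection date {date} not after {state.collection_dates[-1]}")
    lookup = {normalize_unit(k): float(v) for k, v in new_column.items()}
    unknown = set(lookup) - {normalize_unit(u) for u in state.units}
    if unknown:
        raise ValidationError(f"units outside the universe: {sorted(unknown)}")

    stable = True
    col: list[float] = []
    for unit, past in zip(state.units, state.values):
        v = lookup.get(normalize_unit(unit), float("nan"))
        col.append(v)
        if math.isnan(v):
            stable = False
            continue
        present = [x for x in past if not math.isnan(x)]
        if present:
            running_mean = sum(present) / len(present)
            if abs(v - running_mean) > state.drama_threshold:
                stable = False

    streak = state.stable_streak + 1 if stable else 0
    phase = state.phase
    if phase == "monitoring" and streak >= state.min_stable_days:
        phase = "extending"
    return dataclasses.replace(
        state,
        collection_dates=state.collection_dates + (date,),
        values=tuple(past + (v,) for past, v in zip(state.values, col)),
        stable_streak=streak,
        phase=phase)


@dataclasses.dataclass(frozen=True)
class ProtocolReport:
    """Outcome of :func:`conclude`.

    ``decision`` is ``reliable``, ``unreliable`` or ``continue``.  For a
    reliable conclusion, ``series`` carries the recommended published
    values: each series' mean RSV with its 95% confidence interval.
    """

    decision: str
    reasons: tuple[str, ...]
    days_observed: int
    series: tuple[SeriesStability, ...]
    confidence: ConfidenceReport
    correlation: CorrelationTrace | None = None

    def to_dict(self) -> dict:
        return {
            "report": "protocol",
            "decision": self.decision,
            "reasons": list(self.reasons),
            "days_observed": self.days_observed,
            "series": [s.to_dict() for s in self.series],
            "confidence": self.confidence.to_dict(include_pairs=False),
            "correlation": None if self.correlation is None
                else self.correlation.to_dict(),
        }

    def to_text(self) -> str:
        lines = [f"protocol decision: {self.decision} "
                 f"(after {self.days_observed} pull days)"]
        lines += [f"  - {r}" for r in self.reasons]
        if self.decision == "reliable":
            lines.append("recommended published values (mean RSV, 95% CI):")
            for s in self.series:
                lo, hi = s.ci95 if s.ci95 else (s.mean, s.mean)
                lines.append(
                    f"  {s.unit_name}: {s.mean:.1f} [{lo:.1f}, {hi:.1f}]")
        if self.correlation is not None:
            lines.append("")
            lines.append(self.correlation.to_text())
        return "\n".join(lines)


def conclude(
    state: ProtocolState,
    external: ExternalSeries | None = None,
) -> tuple[ProtocolState, ProtocolReport]:
    """Attempt to conclude an extending collection run.

    Reliable iff the Welch confidence screen passes (no series confident
    with more than 20% of its peers) and either every series looks normal
    (Shapiro–Wilk, where applicable) or at least
    ``min_extractions_nonnormal`` pulls have been made.  A failed screen
    concludes unreliable; a passed screen short of the normality gate
    returns ``continue`` and leaves the state extending.
    """
    if state.phase != "extending":
        raise StateError(
            f"conclude requires phase 'extending', state is {state.phase!r}")
    pm = state.matrix_so_far
    summaries = tuple(summarize_series(pm))
    conf = confidence_report(pm)
    trace: CorrelationTrace | None = None
    if external is not None:
        trace = flag_outlier_days(correlation_by_day(pm, external, "spearman"))

    reasons: list[str] = []
    if conf.dataset_unreliable:
        offenders = [u for u, f in conf.per_series_confident_fraction.items()
                     if f > conf.confidence_threshold]
        reasons.append(
            "confidence screen failed: "
            + ", ".join(f"{u} ({100 * conf.per_series_confident_fraction[u]:.0f}%"
                        " of peers confident)" for u in offenders))
        decision, phase = "unreliable", "concluded_unreliable"
    else:
        non_normal = [s.unit_name for s in summaries if s.non_normal]
        if non_normal and state.days_observed < state.min_extractions_nonnormal:
            reasons.append(
                f"non-normal series ({', '.join(non_normal)}) with only "
                f"{state.days_observed} extractions; "
                f"{state.min_extractions_nonnormal} required — keep pulling")
            decision, phase = "continue", "extending"
        else:
            reasons.append("series means mutually distinguishable; "
                           "publish means with 95% CIs")
            if non_normal:
                reasons.append(
                    f"non-normal series present but {state.days_observed} "
                    f">= {state.min_extractions_nonnormal} extractions made")
            decision, phase = "reliable", "concluded_reliable"

    new_state = dataclasses.replace(state, phase=phase)
    report = ProtocolReport(
        decision=decision, reasons=tuple(reasons),
        days_observed=state.days_observed, series=summaries,
        confidence=conf, correlation=trace)
    return new_state, report
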