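"""Day-by-day correlation stability between RSVs and an external series.

For every collection day the Pearson (R) or Spearman (r) correlation is
computed across geographic units between that day's RSVs and a single
external value per unit (e.g. cumulative epidemic cases over the
investigation period).  If RSVs were stable, the coefficient would be the
same whichever day the data was pulled; the spread across days — summarised
by the [min, max] range and the percentage increase

    Δ = (u_f − u_0) / u_0 · 100

between the range endpoints — quantifies how much a conclusion drawn from a
single-day snapshot can drift.  On an unordered interval the baseline u_0 is
the endpoint of smaller magnitude, so |Δ| reads as "how much larger the
bigger-magnitude endpoint is".

Single extreme days can dominate the range, so days whose coefficient lies
more than k·MAD from the median (MAD scaled by 1.4826 for Gaussian
consistency, k = 3 by default) can be flagged as outliers and the range and
Δ recomputed without them.  This median/MAD rule is this package's own
operationalisation of outlier screening, exposed as such in reports.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math

import numpy as np
from scipy import stats

from .core_io import ExternalSeries, PullMatrix
from .errors import InsufficientDataError, ValidationError

__all__ = ["CorrelationTrace", "percent_increase", "interval_delta",
           "correlation_by_day", "flag_outlier_days"]

DEFAULT_MAD_K = 3.0
_MAD_SCALE = 1.4826  # Gaussian-consistency factor
MIN_UNITS_PER_DAY = 3


def percent_increase(u0: float, uf: float) -> float:
    """Percentage increase Δ = (uf − u0)/u0 · 100.

    Signed; take ``abs`` for the magnitude |Δ|.  A zero baseline is an
    error, not infinity.
    """
    if u0 == 0:
        raise ValidationError("percentage increase undefined for baseline 0")
    return (uf - u0) / u0 * 100.0


def interval_delta(a: float, b: float) -> float:
    """Δ between the endpoints of an unordered interval [a, b].

    The baseline u_0 is the endpoint of smaller magnitude (ties broken
    towards the smaller value), the other endpoint is u_f.
    """
    u0, uf = sorted((a, b), key=lambda v: (abs(v), v))
    return percent_increase(u0, uf)


@dataclasses.dataclass(frozen=True)
class CorrelationTrace:
    """Per-collection-day correlation coefficients and their stability.

    ``per_day`` maps each retained collection date to ``(coefficient,
    n_units)``; ``skipped_days`` maps dropped dates to the reason (fewer
    than 3 joined units, or an undefined coefficient).  ``delta_pct`` is the
    signed Δ between the range endpoints, None when the baseline endpoint
    is 0.  ``outlier_days``/``trimmed_*`` are filled by
    :func:`flag_outlier_days` and empty/None before it runs.
    """

    method: str
    external_label: str
    per_day: dict[dt.date, tuple[float, int]]
    skipped_days: dict[dt.date, str]
    range: tuple[float, float]
    delta_pct: float | None
    outlier_days: tuple[dt.date, ...] = ()
    trimmed_range: tuple[float, float] | None = None
    trimmed_delta_pct: float | None = None
    mad_k: float | None = None
    notices: tuple[str, ...] = ()

    @property
    def abs_delta_pct(self) -> float | None:
        return None if self.delta_pct is None else abs(self.delta_pct)

    @property
    def abs_trimmed_delta_pct(self) -> float | None:
        return None if self.trimmed_delta_pct is None \
            else abs(self.trimmed_delta_pct)

    @property
    def coefficients(self) -> list[float]:
        return [c for c, _ in self.per_day.values()]

    def to_dict(self) -> dict:
        return {
            "report": "correlation",
            "method": self.method,
            "external_label": self.external_label,
            "per_day": {d.isoformat(): {"coefficient": c, "n_units": n}
                        for d, (c, n) in self.per_day.items()},
            "skipped_days": {d.isoformat(): why
                             for d, why in self.skipped_days.items()},
            "range": list(self.range),
            "delta_pct": self.delta_pct,
            "abs_delta_pct": self.abs_delta_pct,
            "outlier_days": [d.isoformat() for d in self.outlier_days],
            "trimmed_range": None if self.trimmed_range is None
                else list(self.trimmed_range),
            "trimmed_delta_pct": self.trimmed_delta_pct,
            "mad_k": self.mad_k,
            "notices": list(self.notices),
        }

    def to_text(self) -> str:
        lines = [f"{self.method} correlation vs {self.external_label}",
                 "date         coefficient  n_units"]
        outliers = set(self.outlier_days)
        for d, (c, n) in self.per_day.items():
            mark = "  * outlier day" if d in outliers else ""
            lines.append(f"{d.isoformat()}   {c:>+10.2f}  {n:>7d}{mark}")
        for d, why in self.skipped_days.items():
            lines.append(f"{d.isoformat()}      skipped  ({why})")
        lo, hi = self.range
        dtxt = "undefined (zero baseline)" if self.delta_pct is None \
            else f"|Delta| = {abs(self.delta_pct):+.1f}%"
        lines.append(f"range [{lo:.2f}, {hi:.2f}], {dtxt}")
        if self.trimmed_range is not None:
            lo, hi = self.trimmed_range
            dtxt = "undefined" if self.trimmed_delta_pct is None \
                else f"|Delta| = {abs(self.trimmed_delta_pct):+.1f}%"
            lines.append(
                f"without outlier days (median +/- {self.mad_k}*MAD rule, "
                f"a package extension): [{lo:.2f}, {hi:.2f}], {dtxt}")
        lines.extend(self.notices)
        return "\n".join(lines)


def _interval_delta_or_none(a: float, b: float) -> float | None:
    try:
        return interval_delta(a, b)
    except ValidationError:
        return None


def correlation_by_day(
    pm: PullMatrix, ext: ExternalSeries, method: str = "pearson"
) -> CorrelationTrace:
    """Correlate each collection day's RSVs with ``ext`` across units.

    For every collection date, units contributing are those with a present
    RSV that day and an external value (names joined case-insensitively).
    Days with fewer than 3 joined units, or with a degenerate (constant)
    input on either side, are skipped and listed.  Spearman uses average
    ranks for ties.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    ext_by_unit = {u: ext.get(u) for u in pm.units}
    per_day: dict[dt.date, tuple[float, int]] = {}
    skipped: dict[dt.date, str] = {}
    values = pm.data.to_numpy(dtype=float)
    for j, day in enumerate(pm.collection_dates):
        xs, ys = [], []
        for i, unit in enumerate(pm.units):
            v, e = values[i, j], ext_by_unit[unit]
            if e is not None and not math.isnan(v):
                xs.append(v)
                ys.append(e)
        if len(xs) < MIN_UNITS_PER_DAY:
            skipped[day] = f"only {len(xs)} joined units (< 3)"
            continue
        if len(set(xs)) == 1 or len(set(ys)) == 1:
            skipped[day] = "constant input, coefficient undefined"
            continue
        if method == "pearson":
            coef = float(stats.pearsonr(xs, ys).statistic)
        else:
            coef = float(stats.spearmanr(xs, ys).statistic)
        per_day[day] = (coef, len(xs))
    if not per_day:
        raise InsufficientDataError(
            "no collection day retains >= 3 joined units with a defined "
            "coefficient")
    coefs = [c for c, _ in per_day.values()]
    lo, hi = min(coefs), max(coefs)
    return CorrelationTrace(
        method=method,
        external_label=ext.label,
        per_day=per_day,
        skipped_days=skipped,
        range=(lo, hi),
        delta_pct=_interval_delta_or_none(lo, hi),
    )


def flag_outlier_days(
    trace: CorrelationTrace, k: float = DEFAULT_MAD_K
) -> CorrelationTrace:
    """Flag days whose coefficient sits > k·MAD from the median.

    The MAD is scaled by 1.4826; with zero MAD any deviation from the
    median is flagged (a constant trace flags nothing).  Needs at least 5
    retained days — with fewer, flagging is skipped with a notice rather
    than an error.  The trimmed range/Δ are recomputed over the remaining
    days and never widen the original range.
    """
    if len(trace.per_day) < 5:
        return dataclasses.replace(
            trace, mad_k=k,
            notices=trace.notices + (
                f"outlier flagging skipped: only {len(trace.per_day)} "
                "retained days (< 5)",))
    coefs = np.array(trace.coefficients)
    med = float(np.median(coefs))
    dev = np.abs(coefs - med)
    cutoff = k * _MAD_SCALE * float(np.median(dev))
    out = [day for day, d in zip(trace.per_day, dev) if d > cutoff]
    kept = [c for day, (c, _) in trace.per_day.items() if day not in set(out)]
    lo, hi = min(kept), max(kept)
    return dataclasses.replace(
        trace,
        outlier_days=tuple(out),
        trimmed_range=(lo, hi),
        trimmed_delta_pct=_interval_delta_or_none(lo, hi),
        mad_k=k,
    )
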