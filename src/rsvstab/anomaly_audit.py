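"""Anomaly detection and exclusion for repeated-pull RSV matrices.

A geographic series is *anomalous* when its RSV appears only on some pull
days, i.e. the series has at least one missing cell in the pull matrix.
Anomalous series are excluded from downstream statistics; when the anomalous
fraction of the sample exceeds 20% the whole dataset is excluded.  Exceeding
is strict: a rate of exactly the threshold does not exclude.
"""

from __future__ import annotations

import dataclasses

from .core_io import PullMatrix, normalize_unit
from .errors import ConsistencyError, ValidationError

__all__ = ["SeriesAnomaly", "AnomalyReport", "detect_anomalies",
           "drop_anomalous"]

#: Default fraction of anomalous series above which the dataset is excluded.
DEFAULT_ANOMALY_THRESHOLD = 0.20


@dataclasses.dataclass(frozen=True)
class SeriesAnomaly:
    unit_name: str
    missing_count: int
    present_count: int
    is_anomalous: bool
    #: no present cells at all: unusable for any statistic
    is_unusable: bool


@dataclasses.dataclass(frozen=True)
class AnomalyReport:
    """Per-series missingness counts and the dataset exclusion verdict."""

    per_series: tuple[SeriesAnomaly, ...]
    n_series: int
    n_days: int
    n_anomalous: int
    anomaly_rate: float
    threshold: float
    dataset_excluded: bool

    def __getitem__(self, unit: str) -> SeriesAnomaly:
        key = normalize_unit(unit)
        for sa in self.per_series:
            if normalize_unit(sa.unit_name) == key:
                return sa
        raise KeyError(unit)

    @property
    def anomalous_units(self) -> list[str]:
        return [sa.unit_name for sa in self.per_series if sa.is_anomalous]

    def to_dict(self) -> dict:
        return {
            "report": "anomaly",
            "n_series": self.n_series,
            "n_days": self.n_days,
            "n_anomalous": self.n_anomalous,
            "anomaly_rate": self.anomaly_rate,
            "threshold": self.threshold,
            "dataset_excluded": self.dataset_excluded,
            "per_series": {
                sa.unit_name: {
                    "missing_count": sa.missing_count,
                    "present_count": sa.present_count,
                    "is_anomalous": sa.is_anomalous,
                    "is_unusable": sa.is_unusable,
                }
                for sa in self.per_series
            },
        }

    def to_text(self) -> str:
        width = max([4] + [len(sa.unit_name) for sa in self.per_series])
        lines = [
            f"{'unit':<{width}}  missing  present  anomalous",
            "-" * (width + 30),
        ]
        for sa in self.per_series:
            mark = "yes" + (" (unusable)" if sa.is_unusable else "") \
                if sa.is_anomalous else "no"
            lines.append(
                f"{sa.unit_name:<{width}}  {sa.missing_count:>7d}  "
                f"{sa.present_count:>7d}  {mark}")
        lines.append("")
        lines.append(
            f"anomalous series: {self.n_anomalous}/{self.n_series} "
            f"({100 * self.anomaly_rate:.1f}%), threshold "
            f"{100 * self.threshold:.0f}% -> dataset "
            + ("EXCLUDED" if self.dataset_excluded else "retained"))
        return "\n".join(lines)


def detect_anomalies(
    pm: PullMatrix, threshold: float = DEFAULT_ANOMALY_THRESHOLD
) -> AnomalyReport:
    """Flag every series with at least one missing pull day.

    The dataset is excluded when the anomalous fraction strictly exceeds
    ``threshold`` (default 20%).
    """
    if pm.n_series < 1 or pm.n_days < 1:
        raise ValidationError("pull matrix must have >= 1 series and >= 1 day")
    per_series = tuple(
        SeriesAnomaly(
            unit_name=sr.name,
            missing_count=sr.n_missing,
            present_count=sr.n_present,
            is_anomalous=sr.n_missing >= 1,
            is_unusable=sr.n_present == 0,
        )
        for sr in pm.iter_series()
    )
    n_anomalous = sum(sa.is_anomalous for sa in per_series)
    rate = n_anomalous / pm.n_series
    return AnomalyReport(
        per_series=per_series,
        n_series=pm.n_series,
        n_days=pm.n_days,
        n_anomalous=n_anomalous,
        anomaly_rate=rate,
        threshold=threshold,
        dataset_excluded=rate > threshold,
    )


def drop_anomalous(pm: PullMatrix, report: AnomalyReport) -> PullMatrix:
    """Return ``pm`` restricted to its non-anomalous series, order preserved.

    ``report`` must have been produced from ``pm`` (same unit set), else a
    :class:`ConsistencyError` is raised.  Cell values are never altered.
    """
    report_units = {normalize_unit(sa.unit_name) for sa in report.per_series}
    matrix_units = {normalize_unit(u) for u in pm.units}
    if report_units != matrix_units:
        raise ConsistencyError(
            "anomaly report and pull matrix describe different unit sets")
    anomalous = {normalize_unit(u) for u in report.anomalous_units}
    keep = [u for u in pm.units if normalize_unit(u) not in anomalous]
    return pm.subset(keep)
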