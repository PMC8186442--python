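"""Per-series Gaussian stability summaries and the Welch-t confidence screen.

Each geographic series i is summarised by a Gaussian model of its day-to-day
pull variation: mean x̄ᵢ, sample SD σᵢ (n−1 denominator), SEMᵢ = σᵢ/√n and a
95% confidence interval x̄ᵢ ± 1.96·SEMᵢ clipped to the RSV scale [0, 100].
Normality of the daily draws is screened with the Shapiro–Wilk test at
α = .05 (indicative; borderline p-values near α are flagged separately).

Two series are *confident* — statistically indistinguishable under the
screen — when the magnitude of the Welch statistic

    t = |x̄_a − x̄_b| / σ̃,      σ̃ = √(SEM_a² + SEM_b²)

falls below 1.5.  A dataset is deemed unreliable when at least one series is
confident with more than 20% of its peers, because ranked comparisons among
its units then depend on the day the data happened to be pulled.  The 1.5
cut and the 20% confidence threshold are heuristic screens, not hypothesis
tests; no multiple-testing correction is applied across the pairs.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

from scipy import stats

from .core_io import PullMatrix
from .errors import InsufficientDataError

__all__ = ["SeriesStability", "ConfidencePair", "ConfidenceReport",
           "summarize_series", "welch_pair", "confidence_report"]

DEFAULT_T_THRESHOLD = 1.5
DEFAULT_CONFIDENCE_THRESHOLD = 0.20
SHAPIRO_ALPHA = 0.05
#: p-values this close to alpha get a "borderline" flag in report text.
SHAPIRO_BORDERLINE = (0.04, 0.06)
_Z95 = 1.96


@dataclasses.dataclass(frozen=True)
class SeriesStability:
    """Gaussian summary of one series' pull-to-pull variation.

    ``sd``/``sem``/``ci95`` are None when n < 2; ``shapiro_p`` and
    ``non_normal`` are None when the test is not applicable (n < 3 or a
    zero-variance series, for which normality is undefined).
    """

    unit_name: str
    n: int
    mean: float
    sd: float | None
    sem: float | None
    ci95: tuple[float, float] | None
    shapiro_p: float | None
    non_normal: bool | None
    shapiro_borderline: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _summarize_row(name: str, values: list[float]) -> SeriesStability:
    n = len(values)
    if n == 0:
        raise InsufficientDataError(
            f"series {name!r} has no present cells; run the anomaly audit "
            "and drop unusable series first")
    mean = sum(values) / n
    if n < 2:
        return SeriesStability(name, n, mean, None, None, None, None, None)
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    sem = sd / math.sqrt(n)
    ci = (max(0.0, mean - _Z95 * sem), min(100.0, mean + _Z95 * sem))
    if n >= 3 and sd > 0:
        p = float(stats.shapiro(values).pvalue)
        non_normal = p < SHAPIRO_ALPHA
        borderline = SHAPIRO_BORDERLINE[0] <= p <= SHAPIRO_BORDERLINE[1]
    else:
        p, non_normal, borderline = None, None, False
    return SeriesStability(name, n, mean, sd, sem, ci, p, non_normal,
                           borderline)


def summarize_series(pm: PullMatrix) -> list[SeriesStability]:
    """One :class:`SeriesStability` per series of ``pm``, in matrix order.

    Every series must have at least one present cell (unusable series are an
    anomaly-audit concern and must be removed before summarising).
    """
    return [_summarize_row(sr.name, sr.present_values)
            for sr in pm.iter_series()]


@dataclasses.dataclass(frozen=True)
class ConfidencePair:
    """Welch comparison of two series' mean RSVs.

    ``t`` is reported as a magnitude, so the pair is unordered: (a, b) and
    (b, a) are identical.  ``sigma_tilde`` is the Welch standard error of the
    mean difference.
    """

    unit_a: str
    unit_b: str
    t: float
    sigma_tilde: float
    confident: bool


def welch_pair(
    a: SeriesStability, b: SeriesStability,
    t_threshold: float = DEFAULT_T_THRESHOLD,
) -> ConfidencePair:
    """Welch screen for one pair: confident iff |t| < ``t_threshold``.

    Degenerate variances are resolved by the means alone: with σ̃ = 0, equal
    means give t = 0 (confident) and distinct means give t = +inf.
    """
    for s in (a, b):
        if s.n < 2:
            raise InsufficientDataError(
                f"series {s.unit_name!r} has n={s.n} < 2 present pulls; "
                "Welch comparison undefined")
    assert a.sem is not None and b.sem is not None
    sigma_tilde = math.hypot(a.sem, b.sem)
    diff = abs(a.mean - b.mean)
    if sigma_tilde == 0.0:
        t = 0.0 if diff == 0.0 else math.inf
    else:
        t = diff / sigma_tilde
    return ConfidencePair(a.unit_name, b.unit_name, t, sigma_tilde,
                          confident=t < t_threshold)


@dataclasses.dataclass(frozen=True)
class ConfidenceReport:
    """All pairwise Welch screens plus the dataset reliability verdict."""

    pairs: tuple[ConfidencePair, ...]
    per_series_confident_fraction: dict[str, float]
    max_fraction_unit: str
    dataset_unreliable: bool
    t_threshold: float
    confidence_threshold: float

    @property
    def max_fraction(self) -> float:
        return self.per_series_confident_fraction[self.max_fraction_unit]

    def to_dict(self, include_pairs: bool = True) -> dict:
        out = {
            "report": "confidence",
            "t_threshold": self.t_threshold,
            "confidence_threshold": self.confidence_threshold,
            "per_series_confident_fraction":
                dict(self.per_series_confident_fraction),
            "max_fraction_unit": self.max_fraction_unit,
            "max_fraction": self.max_fraction,
            "dataset_unreliable": self.dataset_unreliable,
        }
        if include_pairs:
            out["pairs"] = [dataclasses.asdict(p) for p in self.pairs]
        return out

    def to_text(self) -> str:
        fracs = self.per_series_confident_fraction
        width = max([4] + [len(u) for u in fracs])
        lines = [f"{'unit':<{width}}  confident fraction",
                 "-" * (width + 20)]
        for unit, f in fracs.items():
            flag = "  <-- exceeds threshold" \
                if f > self.confidence_threshold else ""
            lines.append(f"{unit:<{width}}  {100 * f:>6.1f}%{flag}")
        lines.append("")
        lines.append(
            f"verdict: dataset "
            + ("UNRELIABLE" if self.dataset_unreliable else "reliable")
            + f" (confidence threshold {100 * self.confidence_threshold:.0f}%"
            f", |t| < {self.t_threshold})")
        return "\n".join(lines)


def confidence_report(
    pm: PullMatrix,
    t_threshold: float = DEFAULT_T_THRESHOLD,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> ConfidenceReport:
    """Evaluate all N(N−1)/2 Welch pairs of ``pm`` and issue the verdict.

    A series' confident fraction is the share of its N−1 partners with
    |t| < ``t_threshold``; the dataset is unreliable when any fraction
    strictly exceeds ``confidence_threshold``.  Intended to be run after
    :func:`rsvstab.anomaly_audit.drop_anomalous`.
    """
    summaries = summarize_series(pm)
    eligible = [s for s in summaries if s.n >= 2]
    if len(eligible) < 2:
        raise InsufficientDataError(
            f"need >= 2 series with >= 2 present pulls, have {len(eligible)}")
    if len(eligible) < len(summaries):
        short = [s.unit_name for s in summaries if s.n < 2]
        raise InsufficientDataError(
            f"series with < 2 present pulls: {short}; drop anomalous series "
            "before the confidence screen")
    pairs = tuple(welch_pair(a, b, t_threshold)
                  for a, b in itertools.combinations(summaries, 2))
    n = len(summaries)
    confident_partners = {s.unit_name: 0 for s in summaries}
    for p in pairs:
        if p.confident:
            confident_partners[p.unit_a] += 1
            confident_partners[p.unit_b] += 1
    fractions = {u: c / (n - 1) for u, c in confident_partners.items()}
    max_unit = max(fractions, key=lambda u: (fractions[u], u))
    return ConfidenceReport(
        pairs=pairs,
        per_series_confident_fraction=fractions,
        max_fraction_unit=max_unit,
        dataset_unreliable=any(f > confidence_threshold
                               for f in fractions.values()),
        t_threshold=t_threshold,
        confidence_threshold=confidence_threshold,
    )
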