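import dataclasses
import itertools
import math
import random
import statistics

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rsvstab as rs
from conftest import make_pm


def summary_of(values, name="x"):
    return rs.summarize_series(make_pm({name: list(values)}))[0]


def test_bari_summary_matches_direct_arithmetic(table2):
    vals = table2.row("Bari").present_values
    s = [x for x in rs.summarize_series(table2) if x.unit_name == "Bari"][0]
    assert s.n == 13
    assert s.mean == pytest.approx(statistics.mean(vals))
    assert s.sd == pytest.approx(statistics.stdev(vals))  # n-1 denominator
    assert s.sem == pytest.approx(statistics.stdev(vals) / math.sqrt(13))
    lo, hi = s.ci95
    assert lo == pytest.approx(s.mean - 1.96 * s.sem)
    assert hi == pytest.approx(s.mean + 1.96 * s.sem)


def test_milan_is_a_zero_variance_peak(table5):
    s = summary_of(table5.row("Milan").present_values, "Milan")
    assert (s.mean, s.sd, s.sem) == (100.0, 0.0, 0.0)
    assert s.ci95 == (100.0, 100.0)
    assert s.shapiro_p is None and s.non_normal is None


def test_constant_series_has_no_normality_verdict():
    s = summary_of([50, 50, 50])
    assert s.sd == 0.0 and s.shapiro_p is None


def test_single_pull_series_has_undefined_spread():
    s = summary_of([77])
    assert s.mean == 77.0
    assert s.sd is None and s.sem is None and s.ci95 is None


def test_empty_series_is_a_contract_error():
    with pytest.raises(rs.InsufficientDataError):
        rs.summarize_series(make_pm({"gone": [None, None]}))


def test_ci_clipped_to_rsv_scale():
    s = summary_of([100, 98, 100, 100, 99])
    assert s.ci95[1] == 100.0
    assert s.ci95[0] < 100.0


def test_shapiro_flags_clearly_non_gaussian_series():
    heavy = [10] * 14 + [60]  # one extreme spike
    s = summary_of(heavy)
    assert s.shapiro_p < 0.05 and s.non_normal


def test_welch_identical_series_fully_confident():
    a = summary_of([90, 91, 92, 93])
    p = rs.welch_pair(a, a)
    assert p.t == 0.0 and p.confident


def test_welch_degenerate_variances_resolved_by_means():
    a = summary_of([100, 100, 100])
    b = summary_of([90, 90, 90])
    p = rs.welch_pair(a, b)
    assert math.isinf(p.t) and not p.confident
    assert rs.welch_pair(a, summary_of([100, 100])).t == 0.0


def test_welch_bari_bologna_matches_direct_formula(table2):
    xa = table2.row("Bari").present_values
    xb = table2.row("Bologna").present_values
    sems = [statistics.stdev(x) / math.sqrt(len(x)) for x in (xa, xb)]
    sigma_tilde = math.sqrt(sems[0] ** 2 + sems[1] ** 2)
    expected_t = abs(statistics.mean(xa) - statistics.mean(xb)) / sigma_tilde
    summaries = {s.unit_name: s for s in rs.summarize_series(table2)}
    p = rs.welch_pair(summaries["Bari"], summaries["Bologna"])
    assert p.sigma_tilde == pytest.approx(sigma_tilde)
    assert p.t == pytest.approx(expected_t)
    # symmetry
    q = rs.welch_pair(summaries["Bologna"], summaries["Bari"])
    assert (q.t, q.sigma_tilde, q.confident) == (p.t, p.sigma_tilde,
                                                 p.confident)


def test_welch_requires_two_pulls_each():
    with pytest.raises(rs.InsufficientDataError, match="solo"):
        rs.welch_pair(summary_of([1, 2], "ok"), summary_of([5], "solo"))


@given(st.lists(st.floats(1, 10), min_size=3, max_size=10),
       st.lists(st.floats(1, 10), min_size=3, max_size=10),
       st.floats(0.1, 10))
def test_welch_t_is_scale_invariant(xs, ys, c):
    # degenerate spreads are float-fragile and covered separately
    from hypothesis import assume
    assume(statistics.variance(xs) > 1e-6)
    assume(statistics.variance(ys) > 1e-6)
    base = rs.welch_pair(summary_of(xs, "a"), summary_of(ys, "b"))
    scaled = rs.welch_pair(summary_of([c * v for v in xs], "a"),
                           summary_of([c * v for v in ys], "b"))
    assert scaled.t == pytest.approx(base.t, rel=1e-6, abs=1e-9)


def test_welch_t_monotone_in_mean_gap():
    base = [88, 90, 92, 94]
    ts = [rs.welch_pair(summary_of(base, "a"),
                        summary_of([v + shift for v in base], "b")).t
          for shift in (0, 1, 2, 4)]
    assert ts == sorted(ts)


def brute_force_report(pm, t_threshold=1.5, confidence_threshold=0.20):
    """Independent double-loop oracle using the statistics module."""
    rows = {sr.name: sr.present_values for sr in pm.iter_series()}
    names = list(rows)
    confident = {u: 0 for u in names}
    pair_t = {}
    for a, b in itertools.combinations(names, 2):
        xa, xb = rows[a], rows[b]
        st_ = math.sqrt(statistics.variance(xa) / len(xa)
                        + statistics.variance(xb) / len(xb))
        d = abs(statistics.mean(xa) - statistics.mean(xb))
        t = (0.0 if d == 0 else math.inf) if st_ == 0 else d / st_
        pair_t[(a, b)] = t
        if t < t_threshold:
            confident[a] += 1
            confident[b] += 1
    frac = {u: confident[u] / (len(names) - 1) for u in names}
    return pair_t, frac, any(f > confidence_threshold for f in frac.values())


def test_two_cluster_design_trips_the_screen():
    pm, truth = rs.generate(rs.scenario("two_cluster", seed=11))
    rep = rs.confidence_report(pm)
    pair_t, frac, unreliable = brute_force_report(pm)
    for p in rep.pairs:
        key = (p.unit_a, p.unit_b)
        expected = pair_t.get(key, pair_t.get(key[::-1]))
        assert p.t == pytest.approx(expected)
    assert rep.per_series_confident_fraction == pytest.approx(frac)
    assert rep.dataset_unreliable and unreliable
    # cross-cluster pairs (true means 20 vs 80) are never confident
    cluster = {u: mu for u, mu in zip(truth.units, truth.mu)}
    for p in rep.pairs:
        if cluster[p.unit_a] != cluster[p.unit_b]:
            assert not p.confident
    # within-cluster partners are confident: fraction 2/5 per series
    assert set(rep.per_series_confident_fraction.values()) == {2 / 5}


def test_total_separation_is_reliable():
    pm = make_pm({f"u{k}": [10 * k + d for d in (0, 0.5, 1, 0.2)]
                  for k in range(1, 6)})
    rep = rs.confidence_report(pm)
    assert set(rep.per_series_confident_fraction.values()) == {0.0}
    assert not rep.dataset_unreliable


def test_coincident_copies_are_fully_confident():
    row = [80, 82, 84, 85]
    pm = make_pm({f"u{k}": row for k in range(4)})
    rep = rs.confidence_report(pm)
    assert set(rep.per_series_confident_fraction.values()) == {1.0}
    assert rep.dataset_unreliable


def test_confidence_report_needs_two_eligible_series():
    with pytest.raises(rs.InsufficientDataError):
        rs.confidence_report(make_pm({"a": [1, 2, 3]}))
    with pytest.raises(rs.InsufficientDataError):
        rs.confidence_report(make_pm({"a": [1, 2], "b": [3, None]}))


@pytest.mark.parametrize("seed", range(20))
def test_confidence_report_equals_brute_force(seed):
    rng = random.Random(seed)
    n_units = rng.randint(2, 8)
    n_days = rng.randint(2, 10)
    pm = make_pm({
        f"u{k}": [round(rng.uniform(0, 100), 1) for _ in range(n_days)]
        for k in range(n_units)})
    rep = rs.confidence_report(pm)
    _, frac, unreliable = brute_force_report(pm)
    assert rep.per_series_confident_fraction == pytest.approx(frac)
    assert rep.dataset_unreliable == unreliable


def test_sigma_recovery_under_pinned_peak_normalization():
    """With the day maximum pinned by a calm top unit, the sample SD of each
    normalized series recovers its true daily sigma=5 well within [3.5, 6.5]
    (20-replicate smoke check; the full binomial sweep runs in acceptance)."""
    cfg = rs.SyntheticTruth(
        mu=tuple(np.linspace(40, 75, 10)) + (100.0,),
        sigma=(5.0,) * 10 + (0.0,), anomaly_prob=(0.0,) * 11,
        n_days=30, quantize=False)
    hits = total = 0
    for seed in range(20):
        pm, _ = rs.generate(dataclasses.replace(cfg, seed=seed))
        for s, sig in zip(rs.summarize_series(pm), cfg.sigma):
            if sig == 5.0:
                total += 1
                hits += 3.5 <= s.sd <= 6.5
    assert hits / total >= 0.95
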