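"""Calendar assembly, environmental overlays and synchrony summaries."""

import numpy as np
import pandas as pd
import pytest

from phenocal import calendars as cal
from phenocal.circstats import CircularSample
from phenocal.synthetic import sample_angles


def _records(counts_by_unit):
    """Flowering-record frame with one species per (region, zone) unit."""
    rows = []
    rng = np.random.default_rng(0)
    for (species, region, zone), n in counts_by_unit.items():
        for _ in range(n):
            rows.append({"species": species, "region": region, "zone": zone,
                         "angle": float(rng.uniform(0, 360))})
    return pd.DataFrame(rows)


def test_pooling_respects_min_record_rule():
    df = _records({("a", 1, "WSA"): 19, ("b", 1, "WSA"): 20, ("c", 1, "WSA"): 21})
    samples, excluded = cal.pool_records(df, "species_region_zone", min_n=20)
    kept = {s.context_dict["species"] for s in samples}
    assert kept == {"b", "c"}  # 19 records is one short of the threshold
    assert excluded["n"].tolist() == [19]


def test_pooling_conserves_record_counts():
    df = _records({("a", 1, "WSA"): 25, ("b", 1, "WSA"): 30, ("c", 2, "ESA"): 40})
    samples, _ = cal.pool_records(df, "region", min_n=20)
    assert sum(s.n for s in samples) == 95
    region1 = next(s for s in samples if s.context_dict["region"] == 1)
    assert region1.n == 55  # pooled over both species


def test_pooling_empty_scope():
    df = _records({("a", 1, "WSA"): 5})
    samples, excluded = cal.pool_records(df, "region", min_n=20)
    assert samples == [] and len(excluded) == 1


def test_pool_unknown_scope():
    with pytest.raises(ValueError):
        cal.pool_records(_records({("a", 1, "WSA"): 30}), "continent")


@pytest.mark.parametrize("precip, expected", [
    ([120.0] * 12, set()),
    ([120] * 5 + [99] + [120] * 6, {6}),          # strictly below 100
    ([100.0] * 12, set()),                         # exactly 100 is not dry
    ([50] * 3 + [150] * 9, {1, 2, 3}),
])
def test_dry_months_threshold(precip, expected):
    assert cal.dry_months(precip) == expected


@pytest.mark.parametrize("series, expected", [
    ([1, 2, 5, 2, 1, 1, 1, 2, 6, 2, 1, 1], {3, 9}),  # maxima in Mar and Sep
    ([1.0] * 12, set()),                              # constant: no peaks
    ([1, 1, 1, 1, 1, 9, 1, 1, 1, 1, 1, 1], {6}),
    ([5, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 4], {1}),      # wrap-around peak at Jan
    ([1, 7, 7, 1, 1, 1, 1, 1, 1, 1, 1, 1], {2}),      # plateau -> first month
])
def test_irradiance_peak_months(series, expected):
    assert cal.irradiance_peak_months(series) == expected


def test_coincidence_window():
    assert cal.coincidence([4], {3}, window=1) == [True]       # adjacent month
    assert cal.coincidence([7], {3, 10}, window=1) == [False]  # two months away
    assert cal.coincidence([12], {1}, window=1) == [True]      # circular adjacency
    assert cal.coincidence([5], set(), window=1) == [False]    # empty set


def test_normalized_proportions():
    assert cal.normalized_proportions({"A": 40, "B": 20}) == {"A": 1.0, "B": 0.5}
    assert cal.normalized_proportions({"only": 7}) == {"only": 1.0}
    assert cal.normalized_proportions({"x": 5, "y": 5}) == {"x": 1.0, "y": 1.0}
    with pytest.raises(ValueError):
        cal.normalized_proportions({"x": 0})


def _sample(angles, **ctx):
    s = CircularSample(np.asarray(angles, float), context="test")
    s.context_dict = {"scope": "species_region_zone", **ctx}
    return s


def test_build_calendar_recovers_unimodal_october_peak():
    # mu = 275 degrees lies in October under the 30-degrees-per-month scale
    ang = sample_angles("M2A", {"mu1": 275.0, "k1": 3.0}, n=200, seed=42)
    calendar = cal.build_calendar(_sample(ang, species="sp", region=1, zone="WSA"),
                                  precip=[120.0] * 12, seed=1, runs=30, threshold=22)
    assert calendar.pattern == "unimodal"
    assert len(calendar.peak_dates) == 1
    month, day = calendar.peak_dates[0]
    assert month == 10 and day <= 10  # early October
    assert sum(calendar.monthly_counts) == calendar.n == 200


def test_build_calendar_uniform_has_no_peaks():
    ang = sample_angles("M1", {}, n=300, seed=7)
    calendar = cal.build_calendar(_sample(ang, species="u", region=2, zone="ESA"),
                                  precip=[80.0] * 12, seed=2, runs=30, threshold=22)
    assert calendar.pattern == "uniform"
    assert calendar.peak_dates == [] and calendar.peak_angles == []
    assert calendar.drought_coincidence == []


def test_monthly_counts_all_in_march():
    ang = np.full(25, 70.0)  # 70 degrees = mid-March
    calendar = cal.build_calendar(_sample(ang, species="m", region=1, zone="WSA"),
                                  seed=3, runs=10, threshold=7)
    expected = [0, 0, 25] + [0] * 9
    assert calendar.monthly_counts == expected


def _fake_calendar(pattern, peaks, species="sp", region=1, zone="WSA", n=30,
                   irr_coinc=None):
    from phenocal.circstats import ModelFit, ConsensusResult
    model = {"uniform": "M1", "unimodal": "M2A", "bimodal": "M5B"}[pattern]
    fit = ModelFit(model=model, mu1=peaks[0] if peaks else 0.0, k1=1.0,
                   mu2=peaks[1] if len(peaks) > 1 else None,
                   k2=1.0 if len(peaks) > 1 else None,
                   lam=0.6 if len(peaks) > 1 else None,
                   logL=0.0, AIC=0.0, converged=True)
    cons = ConsensusResult(runs=10, win_counts={model: 10}, consistent=True,
                           final_model=model, fallback_used=False, final_fit=fit)
    months = [cal._angle_month(a) for a in peaks]
    return cal.Calendar(
        context={"scope": "species_region_zone", "species": species,
                 "region": region, "zone": zone},
        n=n, monthly_counts=[n] + [0] * 11, consensus=cons, pattern=pattern,
        peak_angles=list(peaks), peak_dates=[(m, 15) for m in months],
        irradiance_peak_months={3, 10} if irr_coinc is not None else None,
        irradiance_coincidence=irr_coinc,
    )


def test_summarize_synchrony_counts_balance():
    cals = [_fake_calendar("uniform", []),
            _fake_calendar("unimodal", [100.0]),
            _fake_calendar("bimodal", [70.0, 280.0], irr_coinc=[True, True])]
    summary = cal.summarize_synchrony(cals)
    assert summary.pattern_counts == {"uniform": 1, "unimodal": 1, "bimodal": 1}
    assert sum(summary.pattern_counts.values()) == summary.n_calendars
    assert summary.bimodal_irradiance_fraction == 1.0


def test_summarize_all_uniform_has_empty_histogram():
    summary = cal.summarize_synchrony([_fake_calendar("uniform", [])] * 3)
    assert summary.peak_month_histogram == {}


def test_cross_region_consistent_when_peaks_close():
    a = _fake_calendar("unimodal", [100.0], region=1)
    b = _fake_calendar("unimodal", [110.0], region=2)
    assert cal.compare_across_regions([a, b])["verdict"] == "consistent"


def test_cross_region_variable_on_pattern_or_date_mismatch():
    a = _fake_calendar("unimodal", [100.0], region=1)
    b = _fake_calendar("bimodal", [100.0, 280.0], region=2)
    assert cal.compare_across_regions([a, b])["verdict"] == "variable"
    c = _fake_calendar("unimodal", [190.0], region=2)
    assert cal.compare_across_regions([a, c])["verdict"] == "variable"


def test_cross_region_verdict_is_order_invariant():
    cals = [_fake_calendar("bimodal", [70.0, 280.0], region=1),
            _fake_calendar("bimodal", [75.0, 285.0], region=2),
            _fake_calendar("bimodal", [282.0, 68.0], region=3)]  # swapped peaks
    verdicts = {cal.compare_across_regions(list(p))["verdict"]
                for p in ([0, 1, 2], [2, 0, 1], [1, 2, 0])
                for p in [[cals[i] for i in p]]}
    assert verdicts == {"consistent"}


def test_render_calendar_writes_figure(tmp_path):
    from phenocal.plotting import render_calendar
    uni = _fake_calendar("uniform", [])
    bi = _fake_calendar("bimodal", [70.0, 280.0])
    p1 = render_calendar(uni, tmp_path / "uniform.png")
    p2 = render_calendar(bi, tmp_path / "bimodal.png")
    assert p1.stat().st_size > 0 and p2.stat().st_size > 0
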