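"""The circular analysis core: date mapping, the 10-model lattice, MLE,
AIC selection and the consensus procedure."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import i0

from phenocal import circstats as cs
from tests.conftest import vm_degrees


# ---------------------------------------------------------------------- dates

@pytest.mark.parametrize("month, day, expected", [
    (1, 1, 0.0),                      # 1 January anchors the circle
    (7, 1, 180.0),                    # six months = 180 degrees
    (2, 1, 30.0),                     # each month spans 30 degrees
    (12, 31, 330.0 + 30.0 * 30 / 31), # ~359.03, just short of wrapping
    (1, None, 30.0 * 14 / 31),        # missing day -> mid-month (15th)
])
def test_date_to_angle(month, day, expected):
    assert cs.date_to_angle(month, day) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("month, day", [(0, 1), (13, 1), (4, 31), (1, 0), (2, 30)])
def test_date_to_angle_rejects_invalid(month, day):
    with pytest.raises(ValueError):
        cs.date_to_angle(month, day)


@given(st.integers(1, 12), st.integers(1, 28))
def test_angle_round_trips_to_its_date(month, day):
    assert cs.angle_to_month_day(cs.date_to_angle(month, day)) == (month, day)


def test_december_vs_january_is_one_month_circularly():
    # mid-December and mid-January flower a month apart on the circle,
    # though they are 11 months apart within a calendar year
    assert cs.circular_separation(345.0, 15.0) == pytest.approx(30.0)


@given(st.floats(0, 360, allow_nan=False), st.floats(0, 360, allow_nan=False))
def test_circular_separation_is_a_symmetric_semi_metric(a, b):
    d = cs.circular_separation(a, b)
    assert 0.0 <= d <= 180.0
    assert d == pytest.approx(cs.circular_separation(b, a))
    assert cs.circular_separation(a, a) == 0.0


def test_circular_mean_two_points():
    mean, r = cs.circular_mean([0.0, 90.0])
    assert mean == pytest.approx(45.0)
    assert r == pytest.approx(math.cos(math.radians(45.0)))


def test_circular_mean_degenerate_cases():
    _, r = cs.circular_mean([77.0] * 10)
    assert r == pytest.approx(1.0)
    mean, r = cs.circular_mean([0.0, 180.0])
    assert r == pytest.approx(0.0, abs=1e-9)
    assert math.isnan(mean)
    with pytest.raises(ValueError):
        cs.circular_mean([])


# -------------------------------------------------------------- model lattice

def test_lattice_is_one_uniform_three_unimodal_six_bimodal():
    fams = [s.family for s in cs.MODEL_SPECS.values()]
    assert len(cs.MODEL_SPECS) == 10
    assert fams.count("uniform") == 1
    assert fams.count("unimodal") == 3
    assert fams.count("bimodal") == 6


def test_free_parameter_counts():
    expected = {"M1": 0, "M2A": 2, "M2B": 2, "M2C": 3, "M3A": 2,
                "M3B": 3, "M4A": 3, "M4B": 4, "M5A": 4, "M5B": 5}
    assert {m: s.free_params for m, s in cs.MODEL_SPECS.items()} == expected


def test_uniform_density_value():
    assert cs.model_density(123.4, (0, 0, 0, 0, 1.0)) == pytest.approx(1 / (2 * math.pi))


def test_von_mises_density_at_mode():
    # VM(mu; mu, k=1) = e / (2*pi*I0(1))
    val = cs.model_density(90.0, (90.0, 1.0, 0.0, 0.0, 1.0))
    assert val == pytest.approx(math.e / (2 * math.pi * i0(1.0)), rel=1e-12)


def test_von_mises_density_symmetric_about_mode():
    for delta in (10.0, 55.0, 170.0):
        left = cs.model_density((90.0 - delta) % 360, (90.0, 2.5, 0, 0, 1.0))
        right = cs.model_density((90.0 + delta) % 360, (90.0, 2.5, 0, 0, 1.0))
        assert left == pytest.approx(right, rel=1e-12)


def test_all_densities_normalize(rng):
    theta = np.linspace(0.0, 360.0, 40001)
    for mid, spec in cs.MODEL_SPECS.items():
        anchors, k_scale = [123.0, 10.0], 3.0
        x = cs._random_start(spec, rng, anchors, k_scale)
        dens = cs.model_density(theta, spec.full_params(x))
        integral = np.trapezoid(dens, np.radians(theta))
        assert integral == pytest.approx(1.0, abs=1e-6), mid


# ------------------------------------------------------------- log-likelihood

def test_uniform_neg_loglik_closed_form(rng):
    ang = rng.uniform(0, 360, 100)
    assert cs.neg_loglik(ang, "M1", np.array([])) == pytest.approx(
        100 * math.log(2 * math.pi))


def test_unimodal_with_zero_concentration_nests_uniform(rng):
    ang = rng.uniform(0, 360, 57)
    m1 = cs.neg_loglik(ang, "M1", np.array([]))
    m2a = cs.neg_loglik(ang, "M2A", np.array([200.0, 0.0]))
    assert m2a == pytest.approx(m1, rel=1e-12)


def test_optimizer_matches_brute_force_grid(rng):
    # independent oracle: exhaustive coarse grid over (mu, k)
    ang = vm_degrees(rng, 200.0, 1.5, 30)
    for mid in ("M2A", "M3A"):
        fit = cs.fit_model(ang, mid, n_starts=8, seed=7)
        grid_best = min(
            cs.neg_loglik(ang, mid, np.array([mu, k]))
            for mu in np.arange(0, 360, 2.0)
            for k in np.arange(0.0, 12.0, 0.05)
        )
        assert grid_best >= -fit.logL - 1e-3, mid


def test_fit_recovers_unimodal_parameters(unimodal_sample):
    fit = cs.fit_model(unimodal_sample, "M2A", seed=3)
    assert cs.circular_separation(fit.mu1, 120.0) <= 5.0
    assert 1.6 <= fit.k1 <= 2.4
    assert fit.converged
    assert fit.AIC == pytest.approx(2 * 2 - 2 * fit.logL)


def test_uniform_fit_is_closed_form(rng):
    ang = rng.uniform(0, 360, 83)
    fit = cs.fit_model(ang, "M1", seed=0)
    assert fit.logL == pytest.approx(-83 * math.log(2 * math.pi))
    assert fit.AIC == pytest.approx(2 * 83 * math.log(2 * math.pi))


def test_full_model_dominates_nested_models(rng):
    ang = np.concatenate([vm_degrees(rng, 30, 2, 80), vm_degrees(rng, 210, 2, 70)])
    fits = {m: cs.fit_model(ang, m, n_starts=8, seed=11) for m in cs.MODEL_SPECS}
    for m in ("M1", "M2A", "M2C", "M3A", "M3B", "M4A", "M5A"):
        assert fits["M5B"].logL >= fits[m].logL - 1e-6, m


def test_rotation_equivariance(rng):
    ang = vm_degrees(rng, 100.0, 2.5, 200)
    delta = 73.0
    for mid in ("M2A", "M3A"):
        base = cs.fit_model(ang, mid, n_starts=8, seed=5)
        shifted = cs.fit_model((ang + delta) % 360, mid, n_starts=8, seed=5)
        assert cs.circular_separation(shifted.mu1, (base.mu1 + delta) % 360) < 0.1
        assert shifted.logL == pytest.approx(base.logL, abs=1e-6)


def test_canonical_lambda_reports_dominant_component_first(rng):
    # 70/30 mixture: whichever component the optimizer labels first,
    # the reported lambda must be >= 0.5 and mu1 near the dominant peak
    ang = np.concatenate([vm_degrees(rng, 60, 3, 140), vm_degrees(rng, 240, 3, 60)])
    fit = cs.fit_model(ang, "M3B", n_starts=8, seed=2)
    assert fit.lam >= 0.5
    assert cs.circular_separation(fit.mu1, 60.0) < 15.0


# ------------------------------------------------------------ model selection

def test_select_uniform_data_yields_uniform(rng):
    sel = cs.select_model(rng.uniform(0, 360, 1000), seed=4)
    assert sel.best.family == "uniform"
    assert sel.delta_aic[sel.best_id] == 0.0


def test_select_unimodal_data_yields_unimodal(rng):
    sel = cs.select_model(vm_degrees(rng, 90, 3, 500), seed=4)
    assert sel.best.family == "unimodal"


def test_select_bimodal_data_yields_bimodal(rng):
    ang = np.concatenate([vm_degrees(rng, 0, 3, 300), vm_degrees(rng, 180, 3, 300)])
    sel = cs.select_model(ang, seed=4)
    assert sel.best.family == "bimodal"


def test_selection_needs_five_observations():
    with pytest.raises(ValueError):
        cs.select_model([10.0, 20.0, 30.0, 40.0], seed=0)


# ---------------------------------------------------------------- consensus

def test_consensus_threshold_is_strict():
    assert not cs.consensus_consistent({"A": 75, "B": 25}, threshold=75)
    assert cs.consensus_consistent({"A": 76, "B": 24}, threshold=75)


def test_consensus_on_strong_signal_is_unanimous(rng):
    ang = vm_degrees(rng, 250, 3, 500)
    res = cs.run_consensus(ang, runs=100, threshold=75, seed=9)
    assert res.consistent and not res.fallback_used
    assert res.win_counts[res.final_model] == 100
    assert cs.MODEL_SPECS[res.final_model].family == "unimodal"
    assert sum(res.win_counts.values()) == res.runs


def test_consensus_rejects_bad_arguments(rng):
    ang = rng.uniform(0, 360, 50)
    with pytest.raises(ValueError):
        cs.run_consensus(ang, runs=10, threshold=10, seed=0)


def test_fallback_picks_lowest_median_aic_among_top_models():
    wins = {"M3A": 40, "M4A": 35, "M5A": 25}
    aics = {"M3A": [210.0] * 40, "M4A": [205.0] * 35, "M5A": [220.0] * 25}
    assert cs.fallback_most_prevalent(wins, aics) == "M4A"


def test_fallback_ties_break_to_fewer_parameters():
    wins = {"M2A": 60, "M2C": 40}  # 2 vs 3 free parameters
    aics = {"M2A": [150.0] * 60, "M2C": [150.0] * 40}
    assert cs.fallback_most_prevalent(wins, aics) == "M2A"


def test_fallback_refuses_consistent_input():
    with pytest.raises(ValueError):
        cs.fallback_most_prevalent({"M1": 76, "M2A": 24}, {"M1": [1.0], "M2A": [2.0]})


# -------------------------------------------------------------------- peaks

def test_peaks_per_family():
    mk = lambda m, **kw: cs.ModelFit(model=m, logL=0.0, AIC=0.0, converged=True,
                                     mu1=kw.get("mu1", 0.0), k1=1.0,
                                     mu2=kw.get("mu2"), k2=kw.get("k2"),
                                     lam=kw.get("lam"))
    assert cs.peaks_from_fit(mk("M1")) == []
    assert cs.peaks_from_fit(mk("M2A", mu1=275.0)) == [275.0]
    assert cs.peaks_from_fit(mk("M4B", mu1=90.0, mu2=270.0, k2=1.0, lam=0.6)) == [90.0, 270.0]
    assert cs.peaks_from_fit(mk("M5B", mu1=30.0, mu2=140.0, k2=1.0, lam=0.6)) == [30.0, 140.0]
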