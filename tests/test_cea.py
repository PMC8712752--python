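"""Incremental analysis, CEAC, DSA and PSA machinery."""

import numpy as np
import pytest

from evtcea.cea import (ceac, deaths_per_10k, draw_parameters, incremental,
                        one_way_dsa, probability_cost_effective, PSAParameter,
                        run_psa, tornado_frame, validate_long_term)
from evtcea.engine import run_arm
from evtcea.pipeline import scaled_spec
from evtcea.registry import generate_registry
from evtcea.types import ArmResult, ConfigurationError


def arm(name, cost, qaly, deaths=0.5, ly=None):
    return ArmResult(strategy=name, n=1000, mean_cost=cost, mean_qaly=qaly,
                     mean_ly=ly if ly is not None else qaly + 1.0,
                     mean_ly_undiscounted=qaly + 2.0, mean_deaths=deaths,
                     mean_mi=0.2, mean_stroke=0.7)


# ---------------------------------------------------------------------------
# incremental analysis
# ---------------------------------------------------------------------------

def test_incremental_worked_example_dominated(table2):
    inc = incremental(table2["evt_defuse3_neg"], table2["med_defuse3_pos"])
    assert inc.delta_cost == pytest.approx(8955.0)
    assert inc.delta_qaly == pytest.approx(-1.02)
    assert inc.classification == "dominated"
    assert inc.nmb == pytest.approx(50_000 * -1.02 - 8955.0)


def test_incremental_mortality_override(table2):
    inc = incremental(table2["evt_dawn_neg"], table2["med_dawn_neg"])
    assert inc.delta_cost == pytest.approx(12_987.0)
    assert inc.delta_qaly == pytest.approx(0.95)
    assert inc.icer == pytest.approx(13_670.5, abs=0.5)
    # nominally cost-effective at 50k, but EVT kills more patients
    assert inc.classification == "mortality_dominated"
    plain = incremental(table2["evt_dawn_neg"], table2["med_dawn_neg"],
                        mortality_override=False)
    assert plain.classification == "cost_effective"


def test_incremental_classifications():
    base = arm("b", 50_000.0, 7.0)
    assert incremental(arm("a", 45_000.0, 8.0, deaths=0.4), base).classification == "dominant"
    assert incremental(arm("a", 55_000.0, 6.0), base).classification == "dominated"
    assert incremental(arm("a", 60_000.0, 7.5, deaths=0.4), base).classification == "cost_effective"
    assert incremental(arm("a", 60_000.0, 7.5, deaths=0.6), base).classification == "mortality_dominated"
    assert incremental(arm("a", 80_000.0, 7.1), base).classification == "not_cost_effective"
    assert incremental(base, base).icer is None


def test_incremental_antisymmetry(table2):
    for a in table2.values():
        for b in table2.values():
            ab = incremental(a, b)
            ba = incremental(b, a)
            assert ab.delta_cost == pytest.approx(-ba.delta_cost)
            assert ab.delta_qaly == pytest.approx(-ba.delta_qaly)
            assert ab.nmb == pytest.approx(-ba.nmb)


def test_deaths_per_10k(table2):
    assert deaths_per_10k(table2["evt_defuse3_neg"]) == 7300
    assert deaths_per_10k(table2["evt_dawn_neg"]) == 7520
    bad = arm("x", 0.0, 1.0)
    bad.mean_deaths = 1.5  # bypass the constructor check to exercise the guard
    with pytest.raises(ConfigurationError):
        deaths_per_10k(bad)


# ---------------------------------------------------------------------------
# CEAC
# ---------------------------------------------------------------------------

def test_ceac_hand_count_and_limits():
    dc = np.array([100.0, -50.0, 30.0, 200.0])
    de = np.array([1.0, -2.0, 3.0, -1.0])
    got = ceac(dc, de, [0.0, 50.0, 1e9])
    # w=0: NMB = -dc, positive only for the -50 draw
    assert got.prob_cost_effective.iloc[0] == 0.25
    # w=50: NMB = [-50, -150, 120, -250]
    assert got.prob_cost_effective.iloc[1] == 0.25
    # w -> inf: sign of dE
    assert got.prob_cost_effective.iloc[2] == (de > 0).mean() == 0.5
    with pytest.raises(ConfigurationError):
        ceac([], [], [0.0])


def test_ceac_monotone_for_effective_draws():
    rng = np.random.default_rng(0)
    dc = rng.normal(10_000, 3000, 500)
    de = np.abs(rng.normal(1.0, 0.3, 500))  # all draws gain QALYs
    grid = np.arange(0, 100_001, 5000)
    probs = ceac(dc, de, grid).prob_cost_effective.to_numpy()
    assert (np.diff(probs) >= 0).all()
    assert probs[-1] == 1.0


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis
# ---------------------------------------------------------------------------

def test_dsa_bracketing_enforced(params):
    with pytest.raises(ConfigurationError, match="bracket"):
        one_way_dsa(params, [("discount_rate", 0.05, 0.10)], lambda p: 0.0)


def test_dsa_analytic_oracle(params):
    """Discounted 25-year QALY flow at utility mRS0 as the outcome."""
    from evtcea.economics import discounted_flow

    def evaluate(p):
        return discounted_flow(p.get_param("utility.mrs0"),
                               p.discount.annual_rate, 0.0, 25.0)

    entries = one_way_dsa(params, [("discount_rate", 0.0, 0.05),
                                   ("utility.mrs0", 0.95, 0.95)], evaluate)
    table = tornado_frame(entries).set_index("parameter")
    # zero-width range produces zero spread and ranks last
    assert table.loc["utility.mrs0", "spread"] == 0.0
    assert entries[0].parameter == "discount_rate"
    assert table.loc["discount_rate", "low_result"] == pytest.approx(0.95 * 25.0)
    assert table.loc["discount_rate", "low_result"] > table.loc["discount_rate", "high_result"]


def test_dsa_simulation_discount_monotonic(params, small_cohort):
    def evaluate(p):
        return run_arm(small_cohort, p.simulation_config(400, 7), p.costs,
                       p.utilities, p.discount).mean_qaly

    entries = one_way_dsa(params, [("discount_rate", 0.0, 0.05)], evaluate)
    e = entries[0]
    assert e.low_result > e.high_result  # heavier discounting shrinks QALYs
    assert e.spread > 0


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def test_psa_parameter_families():
    rng = np.random.default_rng(42)
    g = PSAParameter("cost.mi_hospitalization", "gamma", 0.15)
    draws = np.array([g.draw(8000.0, rng) for _ in range(4000)])
    assert draws.mean() == pytest.approx(8000.0, rel=0.02)
    assert draws.std() == pytest.approx(0.15 * 8000.0, rel=0.10)
    assert (draws > 0).all()

    b = PSAParameter("p_fatal_mi", "beta", 0.10)
    draws = np.array([b.draw(0.25, rng) for _ in range(4000)])
    assert ((draws > 0) & (draws < 1)).all()
    assert draws.mean() == pytest.approx(0.25, rel=0.02)

    ln = PSAParameter("hazard.mi.rate", "lognormal", 0.15)
    draws = np.array([ln.draw(0.02, rng) for _ in range(4000)])
    assert draws.mean() == pytest.approx(0.02, rel=0.02)

    assert PSAParameter("x", "gamma", 0.0).draw(5.0, rng) == 5.0
    with pytest.raises(ConfigurationError):
        PSAParameter("p", "beta", 0.1).draw(1.5, rng)
    with pytest.raises(ConfigurationError):
        PSAParameter("p", "cauchy", 0.1).draw(1.0, rng)


def test_draw_parameters_respects_structure(params, psa_manifest):
    rng = np.random.default_rng(7)
    for _ in range(25):
        drawn = draw_parameters(psa_manifest, params, rng)
        u = drawn.utilities.utilities
        assert (np.diff(u) <= 1e-12).all()
        assert 0 <= drawn.fatality.p_fatal_mi <= 1
        assert drawn.recurrent_stroke.rate > 0 or drawn.recurrent_stroke.baseline > 0
    # degenerate manifest reproduces the base point exactly
    degenerate = [PSAParameter(p.parameter, p.family, 0.0) for p in psa_manifest]
    same = draw_parameters(degenerate, params, rng)
    for p in psa_manifest:
        assert same.get_param(p.parameter) == pytest.approx(
            params.get_param(p.parameter), rel=1e-12)


def test_run_psa_deterministic_and_crn(params, psa_manifest, cohort_spec):
    cohorts = generate_registry(scaled_spec(cohort_spec, 400), seed=5)
    a = cohorts[cohorts.arm == "evt_defuse3_pos"]
    b = cohorts[cohorts.arm == "med_defuse3_pos"]
    one = run_psa(psa_manifest, params, a, b, n_draws=12, n_patients=400, seed=9)
    two = run_psa(psa_manifest, params, a, b, n_draws=12, n_patients=400, seed=9)
    np.testing.assert_array_equal(one.delta_cost, two.delta_cost)
    np.testing.assert_array_equal(one.delta_qaly, two.delta_qaly)
    assert 0.0 <= probability_cost_effective(one) <= 1.0

    # common random numbers reduce the Monte-Carlo variance of dE across
    # replicate patient seeds, versus independent streams per arm
    shared, indep = [], []
    for s in range(16):
        ra = run_arm(a, params.simulation_config(400, s), params.costs,
                     params.utilities, params.discount)
        rb_s = run_arm(b, params.simulation_config(400, s), params.costs,
                       params.utilities, params.discount)
        rb_i = run_arm(b, params.simulation_config(400, 10_000 + s), params.costs,
                       params.utilities, params.discount)
        shared.append(ra.mean_qaly - rb_s.mean_qaly)
        indep.append(ra.mean_qaly - rb_i.mean_qaly)
    assert np.var(shared) < np.var(indep)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

def test_validate_long_term_report(params, cohort_spec):
    cohorts = generate_registry(scaled_spec(cohort_spec, 2000), seed=4)
    report = validate_long_term(cohorts[cohorts.arm == "med_defuse3_pos"],
                                params, n_patients=2000, seed=4)
    assert set(report) >= {"survival_5y", "qaly_5y", "ly_5y", "n"}
    assert 0.0 < report["survival_5y"] < 1.0
    assert report["qaly_5y"] <= report["ly_5y"]
    assert report["anchor_model_survival_5y_pct"] == 51.8
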