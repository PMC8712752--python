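"""Discrete-event engine: oracles, trace invariants, scalar/vector agreement."""

import numpy as np
import pandas as pd
import pytest

from evtcea.economics import accrue_trace
from evtcea.engine import (SimulationConfig, run_arm, simulate_cohort,
                           simulate_patient)
from evtcea.hazards import MortalityTable
from evtcea.types import ConfigurationError, FatalityRules, HazardSpec

RATE_OFF = 1e-12  # effectively never fires within any horizon


def zero_mortality():
    rows = [{"age": 0.0, "sex": s, "noncvd_hazard": 0.0, "cvd_hazard": 0.0}
            for s in ("male", "female")]
    return MortalityTable(pd.DataFrame(rows))


def make_config(mortality=None, rs_rate=RATE_OFF, mi_rate=RATE_OFF,
                p_fatal_rs=0.25, p_fatal_mi=0.25, n=100, horizon=25.0, seed=0):
    return SimulationConfig(
        mortality=mortality or zero_mortality(),
        fatality=FatalityRules(p_fatal_rs, p_fatal_mi),
        recurrent_stroke=HazardSpec("recurrent_stroke", "exponential", rate=rs_rate),
        mi=HazardSpec("mi", "exponential", rate=mi_rate),
        n_patients=n, horizon_years=horizon, seed=seed,
    )


def uniform_cohort(n, age=68.0, sex="male", mrs=2):
    return pd.DataFrame({"age": age, "sex": sex, "mrs_90d": mrs,
                         "treatment": "none"}, index=range(n))


# ---------------------------------------------------------------------------
# scalar path
# ---------------------------------------------------------------------------

def test_null_process_reaches_horizon():
    config = make_config()
    tr = simulate_patient(2, 68.0, "male", config, np.random.default_rng(0))
    assert tr.death_time is None
    assert [(e.time, e.kind, e.mrs) for e in tr.events] == [(25.0, "horizon_end", 2)]


def test_day90_death_is_immediate():
    tr = simulate_patient(6, 68.0, "male", make_config(), np.random.default_rng(0))
    assert tr.death_time == 0.0
    assert [(e.time, e.kind, e.mrs) for e in tr.events] == [(0.0, "cvd_death", 6)]


def test_forced_fatal_mi():
    config = make_config(mi_rate=200.0, p_fatal_mi=1.0)
    tr = simulate_patient(1, 68.0, "male", config, np.random.default_rng(4))
    assert len(tr.events) == 1
    ev = tr.events[0]
    assert ev.kind == "mi" and ev.mrs == 6
    assert tr.death_time == ev.time and ev.time < 1.0


def test_nonfatal_stroke_never_improves_mrs():
    config = make_config(rs_rate=0.5, p_fatal_rs=0.0, seed=1)
    for seed in range(30):
        tr = simulate_patient(3, 60.0, "female", config,
                              np.random.default_rng(seed))
        tr.validate()
        states = [e.mrs for e in tr.events if e.kind == "recurrent_stroke"]
        assert all(b >= a for a, b in zip([3] + states, states))


def test_trace_invariants_and_qaly_bound(params):
    config = params.simulation_config(1, seed=0)
    for seed in range(200):
        rng = np.random.default_rng(seed)
        mrs = seed % 7
        tr = simulate_patient(mrs, 50.0 + (seed % 40), "male" if seed % 2 else "female",
                              config, rng, patient_id=f"p{seed}")
        tr.validate()
        assert tr.events[-1].time <= config.horizon_years
        cost, qaly, ly, ly_un = accrue_trace(tr, params.costs, params.utilities,
                                             params.discount)
        assert qaly <= ly + 1e-9
        assert ly <= ly_un + 1e-9
        assert cost >= 0.0


def test_invalid_inputs_rejected():
    with pytest.raises(ConfigurationError):
        simulate_patient(7, 68.0, "male", make_config(), np.random.default_rng(0))
    with pytest.raises(ConfigurationError):
        make_config(n=0)
    with pytest.raises(ConfigurationError):
        make_config(horizon=0.0)
    bad = make_config()
    with pytest.raises(ConfigurationError):
        SimulationConfig(mortality=bad.mortality, fatality=bad.fatality,
                         recurrent_stroke=bad.recurrent_stroke, mi=bad.mi,
                         severity_probs=np.array([0.5, 0.5, 0.1, 0, 0, 0]))


# ---------------------------------------------------------------------------
# vectorised path
# ---------------------------------------------------------------------------

def test_cohort_reproducible_and_extension_stable(params):
    cohort = uniform_cohort(200)
    config = params.simulation_config(200, seed=11)
    a = simulate_cohort(cohort, config, params.costs, params.utilities, params.discount)
    b = simulate_cohort(cohort, config, params.costs, params.utilities, params.discount)
    for k in ("cost", "qaly", "death_time"):
        np.testing.assert_array_equal(a[k], b[k])
    # enlarging the cohort never perturbs existing patients' streams
    half = params.simulation_config(100, seed=11)
    c = simulate_cohort(cohort.head(100), half, params.costs, params.utilities,
                        params.discount)
    for k in ("cost", "qaly", "death_time"):
        np.testing.assert_array_equal(a[k][:100], c[k])


def test_cohort_empty_rejected(params):
    with pytest.raises(ConfigurationError, match="empty"):
        simulate_cohort(uniform_cohort(0), params.simulation_config(10, 0),
                        params.costs, params.utilities, params.discount)


def test_all_day90_deaths(params):
    cohort = uniform_cohort(50, mrs=6)
    cohort["treatment"] = "EVT_only"
    arm = run_arm(cohort, params.simulation_config(50, 0), params.costs,
                  params.utilities, params.discount, "dead_arm")
    assert arm.mean_qaly == 0.0 and arm.mean_ly == 0.0
    assert arm.mean_deaths == 1.0
    assert arm.mean_cost == params.costs.index_acute_cost["EVT_only"]


def test_survival_matches_closed_form(params):
    """Background mortality only: simulated survival equals the table's."""
    n = 100_000
    cohort = uniform_cohort(n, age=68.0, sex="male", mrs=2)
    config = make_config(mortality=params.mortality, n=n, seed=3)
    out = simulate_cohort(cohort, config, params.costs, params.utilities,
                          params.discount)
    death = np.where(np.isfinite(out["death_time"]), out["death_time"], np.inf)
    table = params.mortality
    grid = np.linspace(0.5, 24.5, 49)
    s_exact = (table.survival(68.0, grid, "male", "noncvd")
               * table.survival(68.0, grid, "male", "cvd"))
    s_hat = np.array([(death > t).mean() for t in grid])
    assert np.abs(s_hat - s_exact).max() < 0.01


def test_scalar_and_vector_paths_agree(params):
    """Both implementations draw from the same distributions."""
    n = 4000
    cohort = uniform_cohort(n, age=70.0, sex="female", mrs=2)
    config = params.simulation_config(n, seed=17)
    out = simulate_cohort(cohort, config, params.costs, params.utilities,
                          params.discount)

    rng = np.random.default_rng(99)
    scalars = np.empty((n, 2))
    for i in range(n):
        tr = simulate_patient(2, 70.0, "female", config, rng)
        cost, qaly, _, _ = accrue_trace(tr, params.costs, params.utilities,
                                        params.discount)
        scalars[i] = cost, qaly
    for vec, ref in ((out["cost"], scalars[:, 0]), (out["qaly"], scalars[:, 1])):
        se = np.sqrt(vec.var(ddof=1) / n + ref.var(ddof=1) / n)
        assert abs(vec.mean() - ref.mean()) < 4 * se


def test_qaly_never_exceeds_ly(params, small_cohort):
    out = simulate_cohort(small_cohort, params.simulation_config(400, 5),
                          params.costs, params.utilities, params.discount)
    assert (out["qaly"] <= out["ly"] + 1e-9).all()
    assert (out["ly"] <= out["ly_undiscounted"] + 1e-9).all()
    assert (out["cost"] >= 0).all()
    finite = np.isfinite(out["death_time"])
    assert (out["death_time"][finite] <= 25.0 + 1e-9).all()


def test_doubling_n_is_stable(params, small_cohort):
    a = run_arm(small_cohort, params.simulation_config(4000, 23), params.costs,
                params.utilities, params.discount)
    b = run_arm(small_cohort, params.simulation_config(8000, 23), params.costs,
                params.utilities, params.discount)
    se = np.hypot(a.se_qaly, b.se_qaly)
    assert abs(a.mean_qaly - b.mean_qaly) < 3 * se


def test_resampling_is_seeded(params, small_cohort):
    a = simulate_cohort(small_cohort, params.simulation_config(900, 31),
                        params.costs, params.utilities, params.discount)
    b = simulate_cohort(small_cohort, params.simulation_config(900, 31),
                        params.costs, params.utilities, params.discount)
    np.testing.assert_array_equal(a["initial_mrs"], b["initial_mrs"])
    np.testing.assert_array_equal(a["age"], b["age"])
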