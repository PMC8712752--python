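"""Discrete-event simulation of the post-Day-90 life course.

Each patient starts on Day 90 in one of seven modified-Rankin states (mRS 6
is carried as an immediate death, accruing index costs only).  Survivors face
four competing clocks: recurrent stroke, myocardial infarction, background
cardiovascular death and background non-CVD death.  The earliest clock fires;
non-fatal strokes/MIs apply a Bernoulli case-fatality rule, survivors
re-enter the loop with clocks resampled (memoryless renewal) and age
advanced; simulation stops at death or the horizon.

Two implementations share the sampling formulas: ``simulate_patient``
produces a full per-patient :class:`~evtcea.types.EventTrace` for audit, and
``simulate_cohort`` runs a whole arm as array operations with per-(patient,
round) uniforms drawn from a counter-based generator keyed on (seed, round),
so each patient's stream is unaffected by every other patient — the common-
random-numbers alignment the probabilistic sensitivity analysis exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import CostSchedule, DiscountSpec, UtilitySchedule
from .hazards import HazardSpec, MortalityTable, sample_event_time
from .types import ArmResult, ConfigurationError, EventTrace, FatalityRules, TraceEvent

_TINY = np.finfo(float).tiny

# simultaneous candidate clocks (measure zero) resolve in this order:
# death events take priority over non-fatal events
_EVENT_PRIORITY = ("noncvd_death", "cvd_death", "recurrent_stroke", "mi")


@dataclass
class SimulationConfig:
    """Everything the engine needs besides the cohort itself."""

    mortality: MortalityTable
    fatality: FatalityRules
    recurrent_stroke: HazardSpec
    mi: HazardSpec
    n_patients: int = 50_000
    horizon_years: float = 25.0
    seed: int = 0
    severity_probs: np.ndarray = field(
        default_factory=lambda: np.array([0.10, 0.15, 0.15, 0.20, 0.25, 0.15]))

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.horizon_years <= 0:
            raise ConfigurationError("horizon must be positive")
        p = np.asarray(self.severity_probs, float)
        if len(p) != 6 or p.min() < 0 or abs(p.sum() - 1) > 1e-9:
            raise ConfigurationError(
                "recurrent-severity distribution must be 6 probabilities summing to 1")
        self.severity_probs = p


def _round_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key))))


def _draw_time(spec: HazardSpec, u: np.ndarray) -> np.ndarray:
    u = np.maximum(u, _TINY)
    if spec.distribution == "exponential":
        return -np.log(u) / spec.rate
    a, b = spec.shape, spec.baseline
    if abs(a) < 1e-12:
        return -np.log(u) / b
    arg = 1.0 - (a / b) * np.log(u)
    with np.errstate(invalid="ignore"):
        return np.where(arg > 0, np.log(np.maximum(arg, _TINY)) / a, np.inf)


# ---------------------------------------------------------------------------
# per-patient reference path
# ---------------------------------------------------------------------------

def simulate_patient(initial_mrs: int, age: float, sex: str,
                     config: SimulationConfig,
                     rng: np.random.Generator,
                     patient_id: str = "p0") -> EventTrace:
    """Simulate one life course, returning the full event trace."""
    if initial_mrs not in range(7):
        raise ConfigurationError(f"initial mRS must be 0..6, got {initial_mrs}")
    horizon = config.horizon_years
    if initial_mrs == 6:
        # dead at Day 90: the index stroke is carried as a CVD death at t = 0
        return EventTrace(patient_id, 6, [TraceEvent(0.0, "cvd_death", 6)], 0.0)
    sev_cdf = np.cumsum(config.severity_probs)
    events: list[TraceEvent] = []
    t, state = 0.0, initial_mrs
    while True:
        current_age = age + t
        candidates = {
            "noncvd_death": config.mortality.sample_death_time(current_age, sex, "noncvd", rng=rng),
            "cvd_death": config.mortality.sample_death_time(current_age, sex, "cvd", rng=rng),
            "recurrent_stroke": sample_event_time(config.recurrent_stroke, rng),
            "mi": sample_event_time(config.mi, rng),
        }
        kind = min(_EVENT_PRIORITY, key=lambda k: candidates[k])
        dt = candidates[kind]
        if t + dt >= horizon or not np.isfinite(dt):
            events.append(TraceEvent(horizon, "horizon_end", state))
            return EventTrace(patient_id, initial_mrs, events, None)
        t = t + dt
        if kind in ("noncvd_death", "cvd_death"):
            events.append(TraceEvent(t, kind, 6))
            return EventTrace(patient_id, initial_mrs, events, t)
        if kind == "recurrent_stroke":
            if rng.random() < config.fatality.p_fatal_recurrent_stroke:
                events.append(TraceEvent(t, "recurrent_stroke", 6))
                return EventTrace(patient_id, initial_mrs, events, t)
            severity = int(np.searchsorted(sev_cdf, rng.random(), side="right"))
            state = max(state, severity)
            events.append(TraceEvent(t, "recurrent_stroke", state))
        else:  # mi
            if rng.random() < config.fatality.p_fatal_mi:
                events.append(TraceEvent(t, "mi", 6))
                return EventTrace(patient_id, initial_mrs, events, t)
            events.append(TraceEvent(t, "mi", state))


# ---------------------------------------------------------------------------
# vectorised arm simulation
# ---------------------------------------------------------------------------

def _flow(value, rate, t1, t2):
    if rate == 0:
        return value * (t2 - t1)
    return value * (np.exp(-rate * t1) - np.exp(-rate * t2)) / rate


def simulate_cohort(cohort: pd.DataFrame, config: SimulationConfig,
                    costs: CostSchedule, utilities: UtilitySchedule,
                    discount: DiscountSpec) -> dict[str, np.ndarray]:
    """Simulate an arm; returns per-patient arrays.

    The cohort is resampled with replacement up to ``config.n_patients``
    (seeded), then all patients advance in synchronous rounds: one round
    draws every patient's four candidate clocks, fires the earliest, accrues
    the elapsed interval's discounted costs/QALYs and processes the event.
    """
    if len(cohort) == 0:
        raise ConfigurationError("cohort is empty")
    seed, horizon, r = config.seed, config.horizon_years, discount.annual_rate
    n = config.n_patients
    if n != len(cohort):
        rng = _round_rng(seed, 3, 0)
        idx = rng.integers(0, len(cohort), size=n)
        cohort = cohort.iloc[idx].reset_index(drop=True)
    else:
        cohort = cohort.reset_index(drop=True)

    age0 = cohort["age"].to_numpy(float)
    male = (cohort["sex"].astype(str) == "male").to_numpy()
    state = cohort["mrs_90d"].to_numpy(int).copy()
    treatment = cohort["treatment"].astype(str).to_numpy()

    util = utilities.full()
    mgmt = np.concatenate([costs.annual_management_cost, [0.0]])
    index_cost = np.array([costs.index_acute_cost.get(t, 0.0) for t in treatment])

    cost = index_cost.copy()
    qaly = np.zeros(n)
    ly = np.zeros(n)
    ly_un = np.zeros(n)
    n_mi = np.zeros(n)
    n_stroke = np.zeros(n)
    death_time = np.full(n, np.nan)
    post_mi = np.zeros(n, bool)
    dec_end = np.zeros(n)
    t_now = np.zeros(n)

    active = state != 6
    death_time[~active] = 0.0  # Day-90 deaths: index cost only

    sev_cdf = np.cumsum(config.severity_probs)
    dur = utilities.decrement_duration
    dec = utilities.event_decrement
    p_rs, p_mi = config.fatality.p_fatal_recurrent_stroke, config.fatality.p_fatal_mi

    round_idx = 0
    while active.any():
        rng = _round_rng(seed, 4, round_idx)
        # row-major (n, 6): patient i consumes a contiguous block of 6
        # uniforms per round, so enlarging the cohort never perturbs the
        # streams of existing patients
        u = rng.random((n, 6)).T
        round_idx += 1
        ii = np.flatnonzero(active)
        ages = age0[ii] + t_now[ii]

        t_ncd = np.empty(ii.size)
        t_cvd = np.empty(ii.size)
        for sex, mask in (("male", male[ii]), ("female", ~male[ii])):
            if mask.any():
                t_ncd[mask] = config.mortality.sample_death_time(
                    ages[mask], sex, "noncvd", u=u[0, ii][mask])
                t_cvd[mask] = config.mortality.sample_death_time(
                    ages[mask], sex, "cvd", u=u[1, ii][mask])
        t_rs = _draw_time(config.recurrent_stroke, u[2, ii])
        t_mi = _draw_time(config.mi, u[3, ii])

        cand = np.stack([t_ncd, t_cvd, t_rs, t_mi])  # priority order
        which = np.argmin(cand, axis=0)              # first minimum: deaths win ties
        dt = cand[which, np.arange(ii.size)]
        t_event = t_now[ii] + dt
        reached = (t_event >= horizon) | ~np.isfinite(dt)
        t_stop = np.where(reached, horizon, t_event)

        # accrue the interval [t_now, t_stop) in the pre-event state
        t1, t2 = t_now[ii], t_stop
        s = state[ii]
        u_s = util[s]
        m_s = mgmt[s] + np.where(post_mi[ii], costs.post_mi_annual_cost, 0.0)
        qaly[ii] += _flow(u_s, r, t1, t2)
        d_hi = np.minimum(np.maximum(dec_end[ii], t1), t2)
        qaly[ii] -= _flow(dec, r, t1, d_hi)
        cost[ii] += _flow(m_s, r, t1, t2)
        ly[ii] += _flow(1.0, r, t1, t2)
        ly_un[ii] += t2 - t1
        t_now[ii] = t_stop

        # horizon reached
        done = ii[reached]
        active[done] = False

        live = ~reached
        jj = ii[live]
        w = which[live]
        te = t_event[live]
        disc = np.exp(-r * te) if r > 0 else np.ones_like(te)

        # background deaths (priority rows 0, 1)
        bg = w <= 1
        death_time[jj[bg]] = te[bg]
        active[jj[bg]] = False

        # recurrent stroke (row 2)
        rs = w == 2
        if rs.any():
            k = jj[rs]
            n_stroke[k] += 1
            fatal = u[4, k] < p_rs
            sev = np.searchsorted(sev_cdf, np.minimum(u[5, k], 1 - 1e-12), side="right")
            new_state = np.where(fatal, 6, np.maximum(state[k], sev))
            cost[k] += costs.acute_recurrent_stroke_cost[new_state] * disc[rs]
            state[k] = np.where(fatal, state[k], new_state)
            death_time[k[fatal]] = te[rs][fatal]
            active[k[fatal]] = False
            dec_end[k[~fatal]] = te[rs][~fatal] + dur

        # myocardial infarction (row 3)
        mi = w == 3
        if mi.any():
            k = jj[mi]
            n_mi[k] += 1
            fatal = u[4, k] < p_mi
            cost[k] += costs.mi_hospitalization_cost * disc[mi]
            death_time[k[fatal]] = te[mi][fatal]
            active[k[fatal]] = False
            post_mi[k[~fatal]] = True
            dec_end[k[~fatal]] = te[mi][~fatal] + dur

        if round_idx > 100_000:
            raise RuntimeError("simulation failed to terminate")

    return {
        "cost": cost, "qaly": qaly, "ly": ly, "ly_undiscounted": ly_un,
        "death_time": death_time, "n_mi": n_mi, "n_stroke": n_stroke,
        "initial_mrs": cohort["mrs_90d"].to_numpy(int),
        "age": age0, "treatment": treatment,
    }


def run_arm(cohort: pd.DataFrame, config: SimulationConfig,
            costs: CostSchedule, utilities: UtilitySchedule,
            discount: DiscountSpec, strategy: str = "arm") -> ArmResult:
    """Simulate an arm and aggregate to per-patient means with Monte-Carlo SEs."""
    out = simulate_cohort(cohort, config, costs, utilities, discount)
    n = len(out["cost"])
    died = np.isfinite(out["death_time"])
    return ArmResult(
        strategy=strategy,
        n=n,
        mean_cost=float(out["cost"].mean()),
        mean_qaly=float(out["qaly"].mean()),
        mean_ly=float(out["ly"].mean()),
        mean_ly_undiscounted=float(out["ly_undiscounted"].mean()),
        mean_deaths=float(died.mean()),
        mean_mi=float(out["n_mi"].mean()),
        mean_stroke=float(out["n_stroke"].mean()),
        se_cost=float(out["cost"].std(ddof=1) / np.sqrt(n)),
        se_qaly=float(out["qaly"].std(ddof=1) / np.sqrt(n)),
        se_ly=float(out["ly"].std(ddof=1) / np.sqrt(n)),
    )
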