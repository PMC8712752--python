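"""Costs, utilities and discounting.

Costs are in 2018 Australian dollars (the reporting converter applies the
2018 average exchange rate, 1 AUD = 0.75 USD).  Health outcomes are
quality-adjusted life years: life-years weighted by an mRS-state utility on
the 0-1 dead/perfect-health scale, with a temporary utility decrement after
each cardiovascular event.  Discounting is continuous at an annual rate
(default 3%/year), the natural convention for a continuous-time simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ConfigurationError, DataError, EventTrace, TREATMENTS

AUD_TO_USD_2018 = 0.75


def aud_to_usd(value_aud: float) -> float:
    """Report-time currency conversion at the fixed 2018 rate."""
    return value_aud * AUD_TO_USD_2018


def discounted_flow(annual_value, rate: float, t_start, t_end):
    """Present value of a constant flow over [t_start, t_end] years.

    Continuous discounting: v * (e^{-r t1} - e^{-r t2}) / r, reducing to
    v * (t2 - t1) at r = 0.
    """
    t_start, t_end = np.asarray(t_start, float), np.asarray(t_end, float)
    if np.any(t_end < t_start):
        raise ConfigurationError("reversed discounting interval")
    if rate < 0:
        raise ConfigurationError("discount rate must be >= 0")
    if rate == 0:
        return annual_value * (t_end - t_start)
    return annual_value * (np.exp(-rate * t_start) - np.exp(-rate * t_end)) / rate


def discounted_point(value, rate: float, t):
    """Present value of a lump sum at time t: value * e^{-r t}."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ConfigurationError("lump-sum time must be >= 0")
    return value * np.exp(-rate * t)


@dataclass
class DiscountSpec:
    annual_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ConfigurationError("discount rate must be >= 0")


@dataclass
class CostSchedule:
    """All model costs, AUD-2018.

    ``index_acute_cost`` is the Day-0 lump per treatment arm (EVT arms
    include the thrombectomy procedure).  ``acute_recurrent_stroke_cost`` is
    indexed by the severity (mRS) of the recurrent stroke, entry 6 being a
    fatal recurrence.  ``annual_management_cost`` (mRS 0-5) and the post-MI
    annual cost accrue continuously while alive.
    """

    index_acute_cost: dict[str, float]
    acute_recurrent_stroke_cost: np.ndarray  # by mRS 0..6
    mi_hospitalization_cost: float
    annual_management_cost: np.ndarray       # by mRS 0..5
    post_mi_annual_cost: float

    def __post_init__(self) -> None:
        self.acute_recurrent_stroke_cost = np.asarray(self.acute_recurrent_stroke_cost, float)
        self.annual_management_cost = np.asarray(self.annual_management_cost, float)
        if len(self.acute_recurrent_stroke_cost) != 7:
            raise ConfigurationError("acute_recurrent_stroke_cost needs 7 entries (mRS 0-6)")
        if len(self.annual_management_cost) != 6:
            raise ConfigurationError("annual_management_cost needs 6 entries (mRS 0-5)")
        for t in self.index_acute_cost:
            if t not in TREATMENTS:
                raise ConfigurationError(f"unknown treatment arm {t!r} in cost schedule")
        vals = np.concatenate([
            self.acute_recurrent_stroke_cost, self.annual_management_cost,
            [self.mi_hospitalization_cost, self.post_mi_annual_cost],
            list(self.index_acute_cost.values()),
        ])
        if (np.asarray(vals) < 0).any():
            raise ConfigurationError("costs must be non-negative")


@dataclass
class UtilitySchedule:
    """Utility by mRS state (0-5; mRS 6 = death = 0), with a CVD-event decrement.

    Utilities live on the cardinal 0-1 scale where 0 is death; values down to
    -0.2 (worse than death) are permitted and must be non-increasing in mRS.
    The decrement is subtracted for ``decrement_duration`` years after each
    cardiovascular event; a new event restarts (does not stack) the window.
    """

    utilities: np.ndarray  # mRS 0..5
    event_decrement: float = 0.1
    decrement_duration: float = 1.0

    def __post_init__(self) -> None:
        self.utilities = np.asarray(self.utilities, float)
        if len(self.utilities) != 6:
            raise ConfigurationError("utilities need 6 entries (mRS 0-5)")
        if self.utilities.max() > 1.0 or self.utilities.min() < -0.2:
            raise ConfigurationError("utilities must lie in [-0.2, 1]")
        if np.any(np.diff(self.utilities) > 1e-12):
            raise ConfigurationError("utilities must be non-increasing in mRS")
        if self.event_decrement < 0 or self.decrement_duration < 0:
            raise ConfigurationError("decrement and duration must be >= 0")

    def full(self) -> np.ndarray:
        """Utilities for mRS 0..6 (state 6, death, has utility 0)."""
        return np.concatenate([self.utilities, [0.0]])


def accrue_trace(trace: EventTrace, costs: CostSchedule,
                 utilities: UtilitySchedule, discount: DiscountSpec,
                 treatment: str = "none") -> tuple[float, float, float, float]:
    """Discounted (cost, QALY, LY) and undiscounted LY for one life course.

    The index acute cost is a lump at t = 0; state utility and annual
    management cost integrate between events; event lump costs discount at
    the event time; the CVD-event decrement covers [t_event, t_event +
    duration] clipped to the next event, death or the horizon.
    """
    trace.validate()
    r = discount.annual_rate
    util = utilities.full()
    if trace.initial_mrs not in range(7):
        raise DataError(f"unknown initial state {trace.initial_mrs}")
    cost = float(costs.index_acute_cost.get(treatment, 0.0))
    qaly = ly = ly_un = 0.0
    state = trace.initial_mrs
    post_mi = False
    dec_end = 0.0
    t_prev = 0.0
    dead = state == 6
    for ev in trace.events:
        t = ev.time
        if not dead and t > t_prev:
            u = util[state]
            mgmt = costs.annual_management_cost[state] + (costs.post_mi_annual_cost if post_mi else 0.0)
            qaly += float(discounted_flow(u, r, t_prev, t))
            if dec_end > t_prev:
                d_hi = min(dec_end, t)
                qaly -= float(discounted_flow(utilities.event_decrement, r, t_prev, d_hi))
            cost += float(discounted_flow(mgmt, r, t_prev, t))
            ly += float(discounted_flow(1.0, r, t_prev, t))
            ly_un += t - t_prev
        if ev.kind == "recurrent_stroke":
            cost += float(discounted_point(costs.acute_recurrent_stroke_cost[ev.mrs], r, t))
            if ev.mrs == 6:
                dead = True
            else:
                state = ev.mrs
                dec_end = t + utilities.decrement_duration
        elif ev.kind == "mi":
            cost += float(discounted_point(costs.mi_hospitalization_cost, r, t))
            if ev.mrs == 6:
                dead = True
            else:
                post_mi = True
                dec_end = t + utilities.decrement_duration
        elif ev.kind in ("cvd_death", "noncvd_death"):
            dead = True
        elif ev.kind != "horizon_end":
            raise DataError(f"unknown event kind {ev.kind!r}")
        t_prev = t
    return cost, qaly, ly, ly_un
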