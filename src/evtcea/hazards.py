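"""Time-to-event machinery for the discrete-event simulation.

Long-term event risks are expressed as constant (exponential) hazards, with a
Gompertz alternative for scenario analysis, and as an age- and sex-indexed
mortality table for background cardiovascular (CVD) and non-CVD death.  All
samplers are inverse-transform so a fixed uniform stream gives a fixed event
stream (the common-random-numbers property the probabilistic sensitivity
analysis relies on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ConfigurationError, HazardSpec

_TINY = np.finfo(float).tiny


def calibrate_exponential(cumulative_risk: float, horizon_years: float) -> float:
    """Constant hazard reproducing a cumulative risk over a horizon.

    rate = -ln(1 - p) / t, so that 1 - exp(-rate * t) round-trips to p.
    """
    if not 0.0 < cumulative_risk < 1.0:
        raise ConfigurationError(
            f"cumulative risk must lie in (0,1), got {cumulative_risk}")
    if horizon_years <= 0:
        raise ConfigurationError("horizon must be positive")
    return -np.log1p(-cumulative_risk) / horizon_years


def sample_event_time(spec: HazardSpec, rng: np.random.Generator,
                      size: int | None = None):
    """Inverse-transform sample of the event time, in years.

    Exponential: T = -ln(U)/rate.  Gompertz with hazard b*exp(a*t):
    T = (1/a) * ln(1 - (a/b) * ln U); for a < 0 the distribution is
    defective and draws beyond the defective mass return +inf (the event
    never occurs).  a -> 0 recovers the exponential(b).
    """
    u = rng.random(size) if size is not None else rng.random()
    u = np.maximum(u, _TINY)
    if spec.distribution == "exponential":
        return -np.log(u) / spec.rate
    a, b = spec.shape, spec.baseline
    if abs(a) < 1e-12:
        return -np.log(u) / b
    arg = 1.0 - (a / b) * np.log(u)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(arg > 0, np.log(np.maximum(arg, _TINY)) / a, np.inf)
    if size is None:
        return float(t)
    return t


@dataclass
class MortalityTable:
    """Age-indexed annual death hazards (non-CVD and CVD) per sex.

    Hazards are piecewise constant over one-year age bands; ages beyond the
    table carry the last tabulated value, ages below it the first.
    """

    frame: pd.DataFrame  # columns: age, sex, noncvd_hazard, cvd_hazard

    def __post_init__(self) -> None:
        need = {"age", "sex", "noncvd_hazard", "cvd_hazard"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"mortality table missing columns {sorted(missing)}")
        if (self.frame[["noncvd_hazard", "cvd_hazard"]].to_numpy() < 0).any():
            raise ConfigurationError("mortality table contains a negative hazard")
        self._knots: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for sex, g in self.frame.groupby("sex"):
            g = g.sort_values("age")
            if g.age.duplicated().any():
                raise ConfigurationError(f"duplicate ages in mortality table for {sex}")
            ages = g.age.to_numpy(float)
            for cause, col in (("noncvd", "noncvd_hazard"), ("cvd", "cvd_hazard")):
                h = g[col].to_numpy(float)
                # extend the first band down to age 0 so every age is covered
                a = np.concatenate([[0.0], ages]) if ages[0] > 0 else ages
                hz = np.concatenate([[h[0]], h]) if ages[0] > 0 else h
                cum = np.concatenate([[0.0], np.cumsum(hz[:-1] * np.diff(a))])
                self._knots[(str(sex), cause)] = (a, hz, cum)

    @property
    def max_age(self) -> float:
        return float(self.frame.age.max())

    def _k(self, sex: str, cause: str):
        try:
            return self._knots[(sex, cause)]
        except KeyError:
            raise ConfigurationError(f"mortality table has no rows for sex={sex!r}")

    def hazard(self, age, sex: str, cause: str):
        a, hz, _ = self._k(sex, cause)
        idx = np.clip(np.searchsorted(a, age, side="right") - 1, 0, len(a) - 1)
        return hz[idx]

    def cumulative_hazard(self, age, sex: str, cause: str):
        """Integral of the hazard from age 0 to ``age``."""
        a, hz, cum = self._k(sex, cause)
        age = np.asarray(age, dtype=float)
        idx = np.clip(np.searchsorted(a, age, side="right") - 1, 0, len(a) - 1)
        return cum[idx] + hz[idx] * (age - a[idx])

    def survival(self, age0: float, t, sex: str, cause: str):
        """Probability of surviving the cause from ``age0`` to ``age0 + t``."""
        h0 = self.cumulative_hazard(age0, sex, cause)
        return np.exp(-(self.cumulative_hazard(np.asarray(age0 + np.asarray(t)), sex, cause) - h0))

    def inverse_cumulative_hazard(self, y, sex: str, cause: str):
        """Age at which the cumulative hazard from age 0 first reaches ``y``."""
        a, hz, cum = self._k(sex, cause)
        y = np.asarray(y, dtype=float)
        idx = np.clip(np.searchsorted(cum, y, side="right") - 1, 0, len(a) - 1)
        h = hz[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            age = np.where(h > 0, a[idx] + (y - cum[idx]) / h, np.inf)
        # a zero tail hazard means the residual mass is never realised
        return age

    def sample_death_time(self, age0, sex: str, cause: str,
                          rng: np.random.Generator | None = None,
                          u=None):
        """Years until death from ``cause`` for someone aged ``age0``.

        Piecewise-constant-hazard inversion: with E ~ Exp(1), the death age
        solves H(age) = H(age0) + E.  A flat (constant-hazard) table reduces
        to an exponential draw.
        """
        if u is None:
            u = rng.random(np.shape(age0) if np.ndim(age0) else None)
        e = -np.log(np.maximum(u, _TINY))
        target = self.cumulative_hazard(age0, sex, cause) + e
        t = self.inverse_cumulative_hazard(target, sex, cause) - np.asarray(age0, float)
        return np.maximum(t, 0.0)


def make_default_mortality(
    ref_age: float = 69.0,
    noncvd_at_ref: float = 0.031,
    cvd_at_ref: float = 0.0210,
    noncvd_growth: float = 0.09,
    cvd_growth: float = 0.07,
    male_multiplier: float = 1.15,
    female_multiplier: float = 0.88,
    ages=range(18, 101),
    hazard_cap: float = 0.7,
) -> MortalityTable:
    """Gompertz-shaped post-stroke mortality defaults (assumed, overridable).

    Rates are anchored at the cohort reference age and grow exponentially
    with age, matching the shape of national life tables scaled to the
    elevated absolute mortality observed after ischaemic stroke.
    """
    rows = []
    for sex, mult in (("male", male_multiplier), ("female", female_multiplier)):
        for a in ages:
            rows.append({
                "age": float(a),
                "sex": sex,
                "noncvd_hazard": min(mult * noncvd_at_ref * np.exp(noncvd_growth * (a - ref_age)), hazard_cap),
                "cvd_hazard": min(mult * cvd_at_ref * np.exp(cvd_growth * (a - ref_age)), hazard_cap),
            })
    return MortalityTable(pd.DataFrame(rows))
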