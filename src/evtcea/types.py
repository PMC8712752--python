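"""Domain types shared across the pipeline.

The model works at three granularities: a :class:`PatientRecord` is one row of
the synthetic registry (baseline characteristics and the 90-day modified
Rankin Scale outcome); an :class:`EventTrace` is one simulated life course
from Day 90 onward; an :class:`ArmResult` aggregates a treatment strategy's
discounted costs, QALYs, life-years and event counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MRS_STATES = tuple(range(7))  #: modified Rankin Scale levels 0 (no symptoms) .. 6 (dead)
TREATMENTS = ("EVT_only", "EVT_plus_tPA", "tPA_only", "none")
SEXES = ("male", "female")
EVENT_KINDS = ("recurrent_stroke", "mi", "cvd_death", "noncvd_death", "horizon_end")
FATAL_KINDS = frozenset({"cvd_death", "noncvd_death"})


class ConfigurationError(ValueError):
    """A parameter file, cohort spec or run configuration is invalid."""


class DataError(ValueError):
    """An input record or trace violates its declared invariants."""


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic registry row.

    Volumes are CT-perfusion estimates in millilitres; ``penumbra_volume`` is
    the salvageable tissue, ``perfusion_lesion_volume - core_volume``.
    """

    id: str
    age: float
    sex: str
    nihss: int
    core_volume: float
    perfusion_lesion_volume: float
    penumbra_volume: float
    occlusion_site: str
    onset_to_imaging: float
    treatment: str
    mrs_90d: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataError(f"unknown sex {self.sex!r} for patient {self.id}")
        if self.treatment not in TREATMENTS:
            raise DataError(f"unknown treatment {self.treatment!r} for patient {self.id}")
        if self.mrs_90d not in MRS_STATES:
            raise DataError(f"mrs_90d must be 0..6, got {self.mrs_90d} for patient {self.id}")
        if not 0 <= self.nihss <= 42:
            raise DataError(f"nihss must be 0..42, got {self.nihss} for patient {self.id}")
        if min(self.core_volume, self.perfusion_lesion_volume) < 0:
            raise DataError(f"negative lesion volume for patient {self.id}")
        if self.penumbra_volume < -1e-6:
            raise DataError(f"negative penumbra volume for patient {self.id}")
        if self.onset_to_imaging <= 270:
            raise DataError(
                f"onset_to_imaging must exceed 270 min (late window), got "
                f"{self.onset_to_imaging} for patient {self.id}"
            )


@dataclass(frozen=True)
class EligibilityFlags:
    """Trial perfusion-imaging eligibility for one patient."""

    defuse3_positive: bool
    dawn_positive: bool
    target_mismatch: bool
    large_core: bool


@dataclass
class ArmMarginals:
    """Table-1-style marginal distributions for one cohort arm."""

    n: int
    age_mean: float
    age_sd: float
    age_bounds: tuple[float, float] = (18.0, 100.0)
    male_prop: float = 0.5
    nihss_median: float = 16.0
    nihss_iqr: tuple[float, float] = (11.0, 21.0)
    core_median: float = 19.0
    core_iqr: tuple[float, float] = (8.0, 36.0)
    perfusion_median: float = 112.0
    perfusion_iqr: tuple[float, float] = (76.0, 149.0)
    ica_prop: float = 0.33
    onset_to_ctp_mean: float = 350.0
    onset_to_ctp_sd: float = 85.0
    treatment_probs: dict[str, float] = field(
        default_factory=lambda: {"none": 1.0}
    )
    mrs_90d_probs: Sequence[float] = field(
        default_factory=lambda: [1 / 7.0] * 7
    )

    def validate(self, arm: str = "?") -> None:
        if self.n < 1:
            raise ConfigurationError(f"arm {arm!r}: size must be >= 1, got {self.n}")
        for name, probs in (
            ("mrs_90d_probs", list(self.mrs_90d_probs)),
            ("treatment_probs", list(self.treatment_probs.values())),
        ):
            probs = np.asarray(probs, dtype=float)
            # tolerance 1e-3 admits published frequency tables rounded to 4
            # decimals; the generator renormalises exactly before sampling
            if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-3:
                raise ConfigurationError(
                    f"arm {arm!r}: {name} must be a probability vector summing to 1, "
                    f"got sum {probs.sum():.12f}"
                )
        if len(list(self.mrs_90d_probs)) != 7:
            raise ConfigurationError(f"arm {arm!r}: mrs_90d_probs needs 7 entries")
        for t in self.treatment_probs:
            if t not in TREATMENTS:
                raise ConfigurationError(f"arm {arm!r}: unknown treatment {t!r}")
        for p in (self.male_prop, self.ica_prop):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"arm {arm!r}: proportion outside [0,1]")
        if self.age_sd < 0:
            raise ConfigurationError(f"arm {arm!r}: age_sd must be >= 0")


@dataclass
class CohortSpec:
    """Marginal distributions for every arm plus the generator seed."""

    arms: dict[str, ArmMarginals]
    seed: int = 0

    def validate(self) -> None:
        if not self.arms:
            raise ConfigurationError("cohort spec defines no arms")
        for arm, marg in self.arms.items():
            marg.validate(arm)


@dataclass(frozen=True)
class HazardSpec:
    """Time-to-event distribution for a recurrent-event process.

    ``rate`` is the exponential hazard per year.  For the Gompertz
    alternative the hazard is ``baseline * exp(shape * t)``; ``shape`` may be
    negative (defective distribution, events may never occur).
    """

    event: str
    distribution: str = "exponential"
    rate: float = 0.0
    shape: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.distribution not in ("exponential", "gompertz"):
            raise ConfigurationError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "exponential" and self.rate <= 0:
            raise ConfigurationError(f"{self.event}: exponential rate must be > 0")
        if self.distribution == "gompertz" and self.baseline <= 0:
            raise ConfigurationError(f"{self.event}: Gompertz baseline must be > 0")


@dataclass(frozen=True)
class FatalityRules:
    """Probability that an incident event is immediately fatal."""

    p_fatal_recurrent_stroke: float
    p_fatal_mi: float

    def __post_init__(self) -> None:
        for name in ("p_fatal_recurrent_stroke", "p_fatal_mi"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")


@dataclass(frozen=True)
class TraceEvent:
    time: float  # years since Day 90
    kind: str
    mrs: int  # post-event modified Rankin state


@dataclass
class EventTrace:
    """One simulated life course from Day 90 to death or the horizon."""

    patient_id: str
    initial_mrs: int
    events: list[TraceEvent]
    death_time: Optional[float]

    def validate(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DataError(f"trace {self.patient_id}: event times not strictly increasing")
        # a death is a background-death event or any event leaving mRS 6
        # (fatal recurrences keep their causal kind with post-event mRS 6)
        for i, ev in enumerate(self.events):
            is_death = ev.kind in FATAL_KINDS or ev.mrs == 6
            if is_death and i != len(self.events) - 1:
                raise DataError(f"trace {self.patient_id}: events recorded after death")
        if not self.events:
            raise DataError(f"trace {self.patient_id}: empty trace")
        last = self.events[-1]
        if last.kind in FATAL_KINDS or last.mrs == 6:
            if self.death_time != last.time:
                raise DataError(f"trace {self.patient_id}: death_time mismatch")
        elif last.kind != "horizon_end":
            raise DataError(f"trace {self.patient_id}: trace must end in death or horizon_end")


@dataclass
class ArmResult:
    """Per-strategy aggregate over all simulated patients."""

    strategy: str
    n: int
    mean_cost: float
    mean_qaly: float
    mean_ly: float
    mean_ly_undiscounted: float
    mean_deaths: float
    mean_mi: float
    mean_stroke: float
    se_cost: float = float("nan")
    se_qaly: float = float("nan")
    se_ly: float = float("nan")

    def __post_init__(self) -> None:
        if self.mean_qaly > self.mean_ly + 1e-9:
            raise DataError(f"{self.strategy}: QALYs exceed life-years")
        if not 0 <= self.mean_deaths <= 1:
            raise DataError(f"{self.strategy}: mean deaths per patient outside [0,1]")


@dataclass
class IncrementalResult:
    """Incremental comparison of strategy A against comparator B."""

    strategy_a: str
    strategy_b: str
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    classification: str
    nmb: float
    wtp: float


@dataclass
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    low_result: float
    high_result: float

    @property
    def spread(self) -> float:
        return abs(self.high_result - self.low_result)


@dataclass
class PSAOutput:
    """Probabilistic sensitivity analysis output for one comparison."""

    strategy_a: str
    strategy_b: str
    delta_cost: np.ndarray  # per-draw incremental cost
    delta_qaly: np.ndarray  # per-draw incremental QALYs
    ceac_wtp: np.ndarray
    ceac_prob: np.ndarray
    n_draws: int
    seed: int
    manifest: "object" = None
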