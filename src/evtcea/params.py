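"""Parameter loading, validation and the model parameter bundle.

All model inputs ship as delimited tables under ``evtcea/data`` — costs and
utilities by mRS state, the age/sex mortality table, event-risk parameters,
the PSA distribution manifest and the DSA ranges — plus YAML files for the
cohort marginals and the trial-criteria thresholds.  Rows marked
``assumed=true`` are literature-class defaults standing in for unpublished
model inputs; a startup warning lists them, and every value can be
overridden by pointing :class:`ParameterFileSet` at edited copies.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cea import PSAParameter
from .economics import CostSchedule, DiscountSpec, UtilitySchedule
from .engine import SimulationConfig
from .hazards import HazardSpec, MortalityTable, calibrate_exponential
from .registry import DawnBand, DawnCriteria, Defuse3Criteria
from .types import ArmMarginals, ArmResult, CohortSpec, ConfigurationError, FatalityRules

DATA_DIR = resources.files("evtcea") / "data"


def _data_path(name: str) -> Path:
    return Path(str(DATA_DIR / name))


@dataclass
class ParameterFileSet:
    """Paths to every parameter table; defaults point at the packaged files."""

    costs: Path = field(default_factory=lambda: _data_path("costs.csv"))
    utilities: Path = field(default_factory=lambda: _data_path("utilities.csv"))
    mortality: Path = field(default_factory=lambda: _data_path("mortality.csv"))
    risks: Path = field(default_factory=lambda: _data_path("risks.csv"))
    severity: Path = field(default_factory=lambda: _data_path("severity.csv"))
    cohort: Path = field(default_factory=lambda: _data_path("cohort_table1.yaml"))
    criteria: Path = field(default_factory=lambda: _data_path("criteria.yaml"))
    psa_manifest: Path = field(default_factory=lambda: _data_path("psa_manifest.csv"))
    dsa_ranges: Path = field(default_factory=lambda: _data_path("dsa_ranges.csv"))

    def validate_exists(self) -> None:
        for name in self.__dataclass_fields__:
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigurationError(f"parameter file missing: {name} -> {p}")


@dataclass
class ParameterSet:
    """All model inputs for one simulation scenario.

    Mutated only through :meth:`with_param`, which returns a modified copy so
    sensitivity analyses never perturb the base case in place.
    """

    costs: CostSchedule
    utilities: UtilitySchedule
    fatality: FatalityRules
    recurrent_stroke: HazardSpec
    mi: HazardSpec
    mortality: MortalityTable
    discount: DiscountSpec
    severity_probs: np.ndarray
    horizon_years: float = 25.0
    composite_5y_risk: float = 0.174
    mi_fraction: float = 0.45
    assumptions: list[str] = field(default_factory=list)
    scales: dict[str, float] = field(default_factory=dict)

    # -- parameter addressing -------------------------------------------------

    def get_param(self, path: str) -> float:
        if path == "discount_rate":
            return self.discount.annual_rate
        if path == "horizon_years":
            return self.horizon_years
        if path == "p_fatal_recurrent_stroke":
            return self.fatality.p_fatal_recurrent_stroke
        if path == "p_fatal_mi":
            return self.fatality.p_fatal_mi
        if path == "hazard.recurrent_stroke.rate":
            return self.recurrent_stroke.rate if self.recurrent_stroke.distribution == "exponential" \
                else self.recurrent_stroke.baseline
        if path == "hazard.mi.rate":
            return self.mi.rate
        if path == "utility.event_decrement":
            return self.utilities.event_decrement
        if path == "utility.decrement_duration":
            return self.utilities.decrement_duration
        if path.startswith("utility.mrs"):
            return float(self.utilities.utilities[int(path.removeprefix("utility.mrs"))])
        if path.startswith("cost.index."):
            return self.costs.index_acute_cost[path.removeprefix("cost.index.")]
        if path == "cost.mi_hospitalization":
            return self.costs.mi_hospitalization_cost
        if path == "cost.post_mi_annual":
            return self.costs.post_mi_annual_cost
        if path in ("cost.acute_recurrent_stroke.scale", "cost.annual_management.scale",
                    "mortality.scale"):
            return self.scales.get(path, 1.0)
        if path.startswith("cost.acute_recurrent_stroke."):
            return float(self.costs.acute_recurrent_stroke_cost[
                int(path.removeprefix("cost.acute_recurrent_stroke."))])
        if path.startswith("cost.annual_management."):
            return float(self.costs.annual_management_cost[
                int(path.removeprefix("cost.annual_management."))])
        raise ConfigurationError(f"unknown parameter path {path!r}")

    def with_param(self, path: str, value: float) -> "ParameterSet":
        ps = copy.deepcopy(self)
        if path == "discount_rate":
            ps.discount = DiscountSpec(annual_rate=float(value))
        elif path == "horizon_years":
            if value <= 0:
                raise ConfigurationError("horizon must be positive")
            ps.horizon_years = float(value)
        elif path == "p_fatal_recurrent_stroke":
            ps.fatality = replace(ps.fatality, p_fatal_recurrent_stroke=float(value))
        elif path == "p_fatal_mi":
            ps.fatality = replace(ps.fatality, p_fatal_mi=float(value))
        elif path == "hazard.recurrent_stroke.rate":
            if ps.recurrent_stroke.distribution == "exponential":
                ps.recurrent_stroke = replace(ps.recurrent_stroke, rate=float(value))
            else:
                ps.recurrent_stroke = replace(ps.recurrent_stroke, baseline=float(value))
        elif path == "hazard.mi.rate":
            ps.mi = replace(ps.mi, rate=float(value))
        elif path == "utility.event_decrement":
            ps.utilities = UtilitySchedule(ps.utilities.utilities, float(value),
                                           ps.utilities.decrement_duration)
        elif path == "utility.decrement_duration":
            ps.utilities = UtilitySchedule(ps.utilities.utilities,
                                           ps.utilities.event_decrement, float(value))
        elif path.startswith("utility.mrs"):
            u = ps.utilities.utilities.copy()
            u[int(path.removeprefix("utility.mrs"))] = float(value)
            ps.utilities = UtilitySchedule(u, ps.utilities.event_decrement,
                                           ps.utilities.decrement_duration)
        elif path.startswith("cost.index."):
            key = path.removeprefix("cost.index.")
            if key not in ps.costs.index_acute_cost:
                raise ConfigurationError(f"unknown treatment arm {key!r}")
            ps.costs.index_acute_cost[key] = float(value)
        elif path == "cost.mi_hospitalization":
            ps.costs.mi_hospitalization_cost = float(value)
        elif path == "cost.post_mi_annual":
            ps.costs.post_mi_annual_cost = float(value)
        elif path == "cost.acute_recurrent_stroke.scale":
            old = ps.scales.get(path, 1.0)
            ps.costs.acute_recurrent_stroke_cost = (
                ps.costs.acute_recurrent_stroke_cost * (float(value) / old))
            ps.scales[path] = float(value)
        elif path == "cost.annual_management.scale":
            old = ps.scales.get(path, 1.0)
            ps.costs.annual_management_cost = (
                ps.costs.annual_management_cost * (float(value) / old))
            ps.scales[path] = float(value)
        elif path == "mortality.scale":
            old = ps.scales.get(path, 1.0)
            frame = ps.mortality.frame.copy()
            for col in ("noncvd_hazard", "cvd_hazard"):
                frame[col] = frame[col] * (float(value) / old)
            ps.mortality = MortalityTable(frame)
            ps.scales[path] = float(value)
        elif path.startswith("cost.acute_recurrent_stroke."):
            c = ps.costs.acute_recurrent_stroke_cost.copy()
            c[int(path.removeprefix("cost.acute_recurrent_stroke."))] = float(value)
            ps.costs.acute_recurrent_stroke_cost = c
        elif path.startswith("cost.annual_management."):
            c = ps.costs.annual_management_cost.copy()
            c[int(path.removeprefix("cost.annual_management."))] = float(value)
            ps.costs.annual_management_cost = c
        else:
            raise ConfigurationError(f"unknown parameter path {path!r}")
        return ps

    def with_utilities(self, values) -> "ParameterSet":
        """Replace the whole mRS utility vector in one step."""
        ps = copy.deepcopy(self)
        ps.utilities = UtilitySchedule(np.asarray(values, float),
                                       ps.utilities.event_decrement,
                                       ps.utilities.decrement_duration)
        return ps

    def simulation_config(self, n_patients: int, seed: int) -> SimulationConfig:
        return SimulationConfig(
            mortality=self.mortality, fatality=self.fatality,
            recurrent_stroke=self.recurrent_stroke, mi=self.mi,
            n_patients=n_patients, horizon_years=self.horizon_years, seed=seed,
            severity_probs=self.severity_probs.copy(),
        )


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def _read_csv(path, required: set[str]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    return frame


def _collect_assumed(frame: pd.DataFrame, path, label_cols) -> list[str]:
    if "assumed" not in frame.columns:
        return []
    rows = frame[frame["assumed"].astype(str).str.lower().isin(("true", "1", "yes"))]
    return [f"{Path(str(path)).name}: " + "/".join(str(r[c]) for c in label_cols)
            for _, r in rows.iterrows()]


def load_cost_schedule(path) -> tuple[CostSchedule, list[str]]:
    frame = _read_csv(path, {"kind", "key", "value_aud_2018"})
    def rows(kind):
        return frame[frame["kind"] == kind]
    try:
        index = {r.key: float(r.value_aud_2018) for r in rows("index_acute").itertuples()}
        acute = np.zeros(7)
        for r in rows("acute_recurrent_stroke").itertuples():
            acute[int(r.key)] = float(r.value_aud_2018)
        mgmt = np.zeros(6)
        for r in rows("annual_management").itertuples():
            mgmt[int(r.key)] = float(r.value_aud_2018)
        mi = float(rows("mi_hospitalization").value_aud_2018.iloc[0])
        post_mi = float(rows("post_mi_annual").value_aud_2018.iloc[0])
    except (ValueError, IndexError) as exc:
        raise ConfigurationError(f"{path}: malformed cost table ({exc})") from exc
    sched = CostSchedule(index, acute, mi, mgmt, post_mi)
    return sched, _collect_assumed(frame, path, ["kind", "key"])


def load_utility_schedule(path) -> tuple[UtilitySchedule, list[str]]:
    frame = _read_csv(path, {"key", "value"})
    vals = dict(zip(frame.key, frame.value.astype(float)))
    try:
        utilities = np.array([vals[f"mrs{k}"] for k in range(6)])
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing utility for state {exc}") from exc
    sched = UtilitySchedule(
        utilities,
        event_decrement=float(vals.get("event_decrement", 0.1)),
        decrement_duration=float(vals.get("decrement_duration_years", 1.0)),
    )
    return sched, _collect_assumed(frame, path, ["key"])


def load_mortality_table(path, max_age_notice: float = 90.0) -> MortalityTable:
    frame = _read_csv(path, {"age", "sex", "noncvd_hazard", "cvd_hazard"})
    table = MortalityTable(frame)
    if table.max_age < max_age_notice:
        warnings.warn(
            f"mortality table ends at age {table.max_age:.0f}; "
            "older ages use last-value extrapolation")
    return table


def load_risks(path) -> tuple[dict[str, float], list[str]]:
    frame = _read_csv(path, {"parameter", "value"})
    vals = dict(zip(frame.parameter, frame.value.astype(float)))
    for p in ("p_fatal_recurrent_stroke", "p_fatal_mi"):
        if not 0 <= vals.get(p, -1) <= 1:
            raise ConfigurationError(f"{path}: {p} must be a probability in [0,1]")
    return vals, _collect_assumed(frame, path, ["parameter"])


def load_severity(path) -> tuple[np.ndarray, list[str]]:
    frame = _read_csv(path, {"mrs", "probability"})
    p = np.zeros(6)
    for r in frame.itertuples():
        p[int(r.mrs)] = float(r.probability)
    if p.min() < 0 or abs(p.sum() - 1) > 1e-6:
        raise ConfigurationError(f"{path}: severity probabilities must sum to 1")
    return p / p.sum(), _collect_assumed(frame, path, ["mrs"])


def load_psa_manifest(path) -> list[PSAParameter]:
    frame = _read_csv(path, {"parameter", "family", "cv"})
    out = []
    for r in frame.itertuples():
        if r.family not in ("gamma", "beta", "lognormal"):
            raise ConfigurationError(f"{path}: unsupported family {r.family!r}")
        out.append(PSAParameter(r.parameter, r.family, float(r.cv)))
    return out


def load_dsa_ranges(path) -> list[tuple[str, float, float]]:
    frame = _read_csv(path, {"parameter", "low", "high"})
    return [(r.parameter, float(r.low), float(r.high)) for r in frame.itertuples()]


def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    arms = {}
    for name, a in raw["arms"].items():
        mrs = np.asarray(a["mrs_90d_probs"], dtype=float)
        arms[name] = ArmMarginals(
            n=int(a["n"]),
            age_mean=float(a["age_mean"]), age_sd=float(a["age_sd"]),
            age_bounds=tuple(a.get("age_bounds", (18.0, 100.0))),
            male_prop=float(a["male_prop"]),
            nihss_median=float(a["nihss_median"]), nihss_iqr=tuple(a["nihss_iqr"]),
            core_median=float(a["core_median"]), core_iqr=tuple(a["core_iqr"]),
            perfusion_median=float(a["perfusion_median"]),
            perfusion_iqr=tuple(a["perfusion_iqr"]),
            ica_prop=float(a["ica_prop"]),
            onset_to_ctp_mean=float(a["onset_to_ctp_mean"]),
            onset_to_ctp_sd=float(a["onset_to_ctp_sd"]),
            treatment_probs={k: float(v) for k, v in a["treatment_probs"].items()},
            mrs_90d_probs=mrs,
        )
    spec = CohortSpec(arms=arms, seed=int(raw.get("seed", 0)))
    spec.validate()
    return spec


def load_criteria(path) -> tuple[Defuse3Criteria, DawnCriteria]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    d3 = raw.get("defuse3", {})
    dawn = raw.get("dawn", {})
    defuse3 = Defuse3Criteria(
        core_max=float(d3.get("core_max", 70.0)),
        mismatch_ratio_min=float(d3.get("mismatch_ratio_min", 1.8)),
        mismatch_volume_min=float(d3.get("mismatch_volume_min", 15.0)),
    )
    bands = tuple(
        DawnBand(float(b["age_min"]), float(b["age_max"]),
                 int(b["nihss_min"]), float(b["core_max"]))
        for b in dawn.get("bands", [])
    ) or DawnCriteria().bands
    return defuse3, DawnCriteria(bands=bands, nihss_floor=int(dawn.get("nihss_floor", 10)))


def load_table2_fixture(path=None) -> dict[str, ArmResult]:
    """Published base-case aggregates, packaged as a worked-example fixture."""
    path = path or _data_path("table2_base_case.csv")
    frame = _read_csv(path, {"strategy", "qalys", "lys", "costs", "deaths", "mi", "stroke"})
    out = {}
    for r in frame.itertuples():
        out[r.strategy] = ArmResult(
            strategy=r.strategy, n=50_000,
            mean_cost=float(r.costs), mean_qaly=float(r.qalys), mean_ly=float(r.lys),
            mean_ly_undiscounted=float(r.lys),
            mean_deaths=float(r.deaths), mean_mi=float(r.mi), mean_stroke=float(r.stroke),
        )
    return out


def load_parameters(files: ParameterFileSet | None = None,
                    recurrence_distribution: str = "exponential",
                    warn_assumptions: bool = True) -> ParameterSet:
    """Load, validate and bundle every model input.

    The MI hazard is the configured fraction of the composite MI/vascular-
    death process, an exponential calibrated so the composite cumulative
    incidence reproduces the published 5-year risk.
    """
    files = files or ParameterFileSet()
    files.validate_exists()
    costs, a1 = load_cost_schedule(files.costs)
    utilities, a2 = load_utility_schedule(files.utilities)
    mortality = load_mortality_table(files.mortality)
    risks, a3 = load_risks(files.risks)
    severity, a4 = load_severity(files.severity)

    composite_risk = risks["composite_mi_vascular_5y_risk"]
    composite_rate = calibrate_exponential(composite_risk, risks["composite_horizon_years"])
    mi_fraction = risks["mi_fraction_of_composite"]
    if not 0 < mi_fraction < 1:
        raise ConfigurationError("mi_fraction_of_composite must lie in (0,1)")
    mi_spec = HazardSpec("mi", "exponential", rate=mi_fraction * composite_rate)
    if recurrence_distribution == "exponential":
        rs_spec = HazardSpec("recurrent_stroke", "exponential",
                             rate=risks["recurrent_stroke_rate_per_year"])
    elif recurrence_distribution == "gompertz":
        rs_spec = HazardSpec("recurrent_stroke", "gompertz",
                             shape=risks["recurrent_stroke_gompertz_shape"],
                             baseline=risks["recurrent_stroke_gompertz_baseline"])
    else:
        raise ConfigurationError(
            f"unknown recurrence distribution {recurrence_distribution!r}")

    assumptions = a1 + a2 + a3 + a4
    if warn_assumptions and assumptions:
        warnings.warn(
            f"{len(assumptions)} parameter values are assumed defaults "
            "(not sourced from the study); override via ParameterFileSet. "
            "First few: " + "; ".join(assumptions[:5]))
    return ParameterSet(
        costs=costs, utilities=utilities,
        fatality=FatalityRules(risks["p_fatal_recurrent_stroke"], risks["p_fatal_mi"]),
        recurrent_stroke=rs_spec, mi=mi_spec, mortality=mortality,
        discount=DiscountSpec(0.03), severity_probs=severity,
        horizon_years=25.0,
        composite_5y_risk=composite_risk, mi_fraction=mi_fraction,
        assumptions=assumptions,
    )


def default_parameters(**kwargs) -> ParameterSet:
    """The packaged base case; assumption warnings suppressed for library use."""
    return load_parameters(warn_assumptions=False, **kwargs)
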