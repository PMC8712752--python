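"""End-to-end orchestration of the base case and sensitivity analyses.

The base case simulates eight strategies — thrombectomy vs medical treatment,
stratified by DEFUSE 3 / DAWN criteria status — each as 50,000 patients
resampled from the corresponding cohort arm, and reports the published
table's layout: per-arm discounted QALYs, life-years, costs and mean event
counts, with incremental results for the criteria-positive and
criteria-negative comparisons against the criteria-positive medical
comparator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import DEFAULT_WTP, incremental, deaths_per_10k, run_psa, probability_cost_effective
from .engine import run_arm
from .params import ParameterFileSet, ParameterSet
from .registry import generate_registry
from .types import ArmResult, CohortSpec, ConfigurationError, IncrementalResult

ARM_ORDER = [
    "evt_defuse3_pos", "evt_defuse3_neg", "med_defuse3_pos", "med_defuse3_neg",
    "evt_dawn_pos", "evt_dawn_neg", "med_dawn_pos", "med_dawn_neg",
]

#: intervention vs comparator pairs reported in the base case
BASE_COMPARISONS = [
    ("evt_defuse3_pos", "med_defuse3_pos"),
    ("evt_defuse3_neg", "med_defuse3_pos"),
    ("evt_defuse3_pos", "med_defuse3_neg"),
    ("evt_defuse3_neg", "med_defuse3_neg"),
    ("evt_dawn_pos", "med_dawn_pos"),
    ("evt_dawn_neg", "med_dawn_pos"),
    ("evt_dawn_pos", "med_dawn_neg"),
    ("evt_dawn_neg", "med_dawn_neg"),
]


def scaled_spec(spec: CohortSpec, n_per_arm: int) -> CohortSpec:
    """Copy of the cohort spec with every arm generated at the simulated size.

    The modelled population is drawn from the cohort's marginal
    distributions, not resampled from the small registry arms, so arm-level
    Monte-Carlo noise scales with the simulated n rather than the
    registry n.
    """
    import copy
    out = copy.deepcopy(spec)
    for marg in out.arms.values():
        marg.n = int(n_per_arm)
    return out


def _arm_seed(seed: int, arm: str) -> int:
    """Stable per-arm substream below 2^31."""
    digest = hashlib.sha256(f"{seed}:{arm}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def simulate_strategies(cohorts: pd.DataFrame, params: ParameterSet,
                        n_patients: int, seed: int,
                        arms: list[str] | None = None,
                        common_random_numbers: bool = True) -> dict[str, ArmResult]:
    """Simulate each requested arm of a generated registry.

    With ``common_random_numbers`` every arm shares one patient-level seed, so
    between-arm differences reflect the cohorts, not sampling noise;
    otherwise each arm gets an independent substream.
    """
    arms = arms or [a for a in ARM_ORDER if a in set(cohorts["arm"])]
    results: dict[str, ArmResult] = {}
    for arm in arms:
        cohort = cohorts[cohorts["arm"] == arm]
        if cohort.empty:
            raise ConfigurationError(f"no records in arm {arm!r}")
        arm_seed = seed if common_random_numbers else _arm_seed(seed, arm)
        config = params.simulation_config(n_patients, arm_seed)
        results[arm] = run_arm(cohort, config, params.costs, params.utilities,
                               params.discount, strategy=arm)
    return results


def base_case(spec: CohortSpec, params: ParameterSet, n_patients: int = 50_000,
              seed: int = 0, wtp: float = DEFAULT_WTP) -> "BaseCaseResult":
    cohorts = generate_registry(scaled_spec(spec, n_patients), seed=seed)
    results = simulate_strategies(cohorts, params, n_patients, seed)
    incrementals = [
        incremental(results[a], results[b], wtp=wtp)
        for a, b in BASE_COMPARISONS if a in results and b in results
    ]
    return BaseCaseResult(arms=results, incrementals=incrementals,
                          n_patients=n_patients, seed=seed, wtp=wtp)


@dataclass
class BaseCaseResult:
    arms: dict[str, ArmResult]
    incrementals: list[IncrementalResult]
    n_patients: int
    seed: int
    wtp: float

    def arm_table(self) -> pd.DataFrame:
        """Base-case table: one strategy per row."""
        rows = []
        for name, r in self.arms.items():
            rows.append({
                "strategy": name, "n": r.n,
                "total_qalys": round(r.mean_qaly, 2),
                "total_lys": round(r.mean_ly, 2),
                "total_costs": round(r.mean_cost),
                "deaths": round(r.mean_deaths, 3),
                "mi": round(r.mean_mi, 3),
                "stroke": round(r.mean_stroke, 3),
                "deaths_per_10k": deaths_per_10k(r),
            })
        return pd.DataFrame(rows)

    def incremental_table(self) -> pd.DataFrame:
        rows = []
        for inc in self.incrementals:
            rows.append({
                "intervention": inc.strategy_a, "comparator": inc.strategy_b,
                "delta_cost": round(inc.delta_cost), "delta_qaly": round(inc.delta_qaly, 2),
                "icer": None if inc.icer is None else round(inc.icer),
                "classification": inc.classification,
                "nmb_at_wtp": round(inc.nmb), "wtp": self.wtp,
            })
        return pd.DataFrame(rows)


@dataclass
class RunManifest:
    """Traceability record written beside every output artifact."""

    seed: int
    software_version: str = __version__
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    parameter_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def create(cls, seed: int, files: ParameterFileSet | None = None) -> "RunManifest":
        files = files or ParameterFileSet()
        digests = {}
        for name in files.__dataclass_fields__:
            p = Path(getattr(files, name))
            if p.exists():
                digests[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        return cls(seed=seed, parameter_digests=digests)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
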