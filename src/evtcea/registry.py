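"""Synthetic late-window stroke registry.

Generates patient-level records whose marginals reproduce a published
baseline table for an observational late-window (>4.5 h from onset) cohort of
large-vessel-occlusion strokes: per-arm age (truncated normal), sex,
baseline NIHSS (negative-binomial fitted to median/IQR by quantile
matching), CT-perfusion core and perfusion-lesion volumes (log-normals
fitted to median/IQR), occlusion site, treatment mix and the 3-month
modified Rankin Scale distribution.  Each record is classified against the
DEFUSE 3 and DAWN perfusion-imaging eligibility criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import inf, log

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ArmMarginals,
    CohortSpec,
    EligibilityFlags,
    MRS_STATES,
    PatientRecord,
    TREATMENTS,
)

_Z75 = stats.norm.ppf(0.75)

REGISTRY_COLUMNS = [
    "id", "arm", "age", "sex", "nihss", "core_volume",
    "perfusion_lesion_volume", "penumbra_volume", "occlusion_site",
    "onset_to_imaging", "treatment", "mrs_90d",
]


# ---------------------------------------------------------------------------
# quantile-matching fits
# ---------------------------------------------------------------------------

def lognormal_from_quartiles(median: float, q25: float, q75: float) -> tuple[float, float]:
    """Return (mu, sigma) of the log-normal with the given median and IQR.

    The median pins mu = ln(median); the interquartile range pins
    sigma = ln(q75/q25) / (2 * z_{0.75}).  A degenerate IQR gives sigma = 0.
    """
    if median <= 0 or q25 <= 0 or q75 < q25:
        raise ValueError(f"invalid quartiles (median={median}, q25={q25}, q75={q75})")
    sigma = log(q75 / q25) / (2.0 * _Z75) if q75 > q25 else 0.0
    return log(median), sigma


def nbinom_from_quartiles(
    median: float, q25: float, q75: float, upper: int = 42
) -> tuple[float, float]:
    """Fit a negative-binomial (n, p) to discrete quartiles.

    Grid search over the mean and dispersion minimising the summed absolute
    quantile error — discrete quantiles make the objective piecewise
    constant, so a direct search is more robust than gradient methods.
    """
    if not 0 <= q25 <= median <= q75 <= upper:
        raise ValueError("quartiles must satisfy 0 <= q25 <= median <= q75")
    mus = np.linspace(max(median * 0.5, 0.5), min(median * 1.8 + 2, upper), 60)
    ks = np.geomspace(0.5, 200.0, 40)  # dispersion; large k -> Poisson-like
    mu_g, k_g = np.meshgrid(mus, ks)
    n = k_g
    p = k_g / (k_g + mu_g)
    err = (
        np.abs(stats.nbinom.ppf(0.5, n, p) - median)
        + np.abs(stats.nbinom.ppf(0.25, n, p) - q25)
        + np.abs(stats.nbinom.ppf(0.75, n, p) - q75)
    )
    i = np.unravel_index(np.argmin(err), err.shape)
    return float(n[i]), float(p[i])


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_arm(name: str, marg: ArmMarginals, rng: np.random.Generator) -> pd.DataFrame:
    marg.validate(name)
    n = marg.n

    age = _truncnorm(rng, marg.age_mean, marg.age_sd, *marg.age_bounds, size=n)
    sex = np.where(rng.random(n) < marg.male_prop, "male", "female")

    nb_n, nb_p = nbinom_from_quartiles(marg.nihss_median, *marg.nihss_iqr)
    nihss = np.clip(stats.nbinom.rvs(nb_n, nb_p, size=n, random_state=rng), 0, 42)

    core_mu, core_sig = lognormal_from_quartiles(marg.core_median, *marg.core_iqr)
    perf_mu, perf_sig = lognormal_from_quartiles(marg.perfusion_median, *marg.perfusion_iqr)
    core = np.exp(rng.normal(core_mu, core_sig, size=n))
    perfusion = np.exp(rng.normal(perf_mu, perf_sig, size=n))
    # the registry records perfusion lesion >= core; clip so penumbra >= 0
    perfusion = np.maximum(perfusion, core)
    penumbra = perfusion - core

    site = np.where(rng.random(n) < marg.ica_prop, "ICA", "M1")
    onset = _truncnorm(rng, marg.onset_to_ctp_mean, marg.onset_to_ctp_sd,
                       270.0 + 1e-9, 1440.0, size=n)

    tx_names = list(marg.treatment_probs)
    tx_probs = np.array([marg.treatment_probs[t] for t in tx_names], dtype=float)
    treatment = rng.choice(tx_names, size=n, p=tx_probs / tx_probs.sum())

    mrs_probs = np.asarray(marg.mrs_90d_probs, dtype=float)
    mrs = rng.choice(np.arange(7), size=n, p=mrs_probs / mrs_probs.sum())

    return pd.DataFrame({
        "id": [f"{name}-{i:06d}" for i in range(n)],
        "arm": name,
        "age": age,
        "sex": sex,
        "nihss": nihss.astype(int),
        "core_volume": core,
        "perfusion_lesion_volume": perfusion,
        "penumbra_volume": penumbra,
        "occlusion_site": site,
        "onset_to_imaging": onset,
        "treatment": treatment,
        "mrs_90d": mrs.astype(int),
    })


def generate_registry(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic registry; identical (spec, seed) gives identical output."""
    spec.validate()
    if seed is None:
        seed = spec.seed
    frames = []
    for k, (name, marg) in enumerate(spec.arms.items()):
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(
            entropy=int(seed), spawn_key=(1, k))))
        frames.append(generate_arm(name, marg, rng))
    return pd.concat(frames, ignore_index=True)


def records_from_frame(frame: pd.DataFrame) -> list[PatientRecord]:
    cols = [c for c in REGISTRY_COLUMNS if c != "arm"]
    return [PatientRecord(**{c: row[c] for c in cols})
            for row in frame.to_dict("records")]


def write_registry(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_registry(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(REGISTRY_COLUMNS) - set(frame.columns) - {"arm"}
    if missing:
        raise ValueError(f"registry file missing columns: {sorted(missing)}")
    return frame


# ---------------------------------------------------------------------------
# trial perfusion-imaging criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Defuse3Criteria:
    """DEFUSE 3 imaging selection: small core, large perfusion mismatch."""

    core_max: float = 70.0          # ml, positive requires core < core_max
    mismatch_ratio_min: float = 1.8
    mismatch_volume_min: float = 15.0  # ml


@dataclass(frozen=True)
class DawnBand:
    age_min: float
    age_max: float
    nihss_min: int
    core_max: float  # ml, strict less-than


@dataclass(frozen=True)
class DawnCriteria:
    """DAWN clinical-core mismatch groups (age band, NIHSS floor, core cap)."""

    bands: tuple[DawnBand, ...] = (
        DawnBand(80.0, inf, 10, 21.0),   # group A: age >= 80
        DawnBand(0.0, 80.0, 10, 31.0),   # group B: age < 80
        DawnBand(0.0, 80.0, 20, 51.0),   # group C: age < 80, severe
    )
    nihss_floor: int = 10


LARGE_CORE_ML = 70.0  # "core volume > 70 ml" flag, strict


def classify_defuse3(record, criteria: Defuse3Criteria | None = None) -> bool:
    """True iff the record meets the DEFUSE 3 perfusion-mismatch criteria.

    Requires core < core_max, perfusion/core mismatch ratio >= floor and
    mismatch (penumbra) volume >= floor.  A zero perfusion lesion cannot show
    target mismatch and classifies negative.
    """
    c = criteria or Defuse3Criteria()
    core = record.core_volume
    perf = record.perfusion_lesion_volume
    if core < 0 or perf < 0:
        raise ValueError("lesion volumes must be non-negative")
    if perf == 0:
        warnings.warn("zero perfusion lesion: mismatch ratio undefined, classified negative")
        return False
    if core >= c.core_max:
        return False
    mismatch_volume = perf - core
    ratio = inf if core == 0 else perf / core
    return ratio >= c.mismatch_ratio_min and mismatch_volume >= c.mismatch_volume_min


def classify_dawn(record, criteria: DawnCriteria | None = None) -> bool:
    """True iff (age, NIHSS, core) falls in a DAWN clinical-core mismatch band.

    Core caps are strict less-than: a 21 ml core fails the >=80-years band.
    An NIHSS below the severity floor is negative, not an error.
    """
    c = criteria or DawnCriteria()
    if record.nihss < c.nihss_floor:
        return False
    for band in c.bands:
        if (band.age_min <= record.age < band.age_max
                and record.nihss >= band.nihss_min
                and record.core_volume < band.core_max):
            return True
    return False


def eligibility_flags(record, defuse3: Defuse3Criteria | None = None,
                      dawn: DawnCriteria | None = None) -> EligibilityFlags:
    d3 = defuse3 or Defuse3Criteria()
    perf = record.perfusion_lesion_volume
    mismatch = (
        perf > 0
        and (perf - record.core_volume) >= d3.mismatch_volume_min
        and (record.core_volume == 0 or perf / record.core_volume >= d3.mismatch_ratio_min)
    )
    return EligibilityFlags(
        defuse3_positive=classify_defuse3(record, d3) if perf > 0 else False,
        dawn_positive=classify_dawn(record, dawn),
        target_mismatch=bool(mismatch),
        large_core=record.core_volume > LARGE_CORE_ML,
    )


def classify_frame(frame: pd.DataFrame, defuse3: Defuse3Criteria | None = None,
                   dawn: DawnCriteria | None = None) -> pd.DataFrame:
    """Append eligibility flag columns to a registry frame."""
    flags = [eligibility_flags(row, defuse3, dawn) for row in frame.itertuples()]
    out = frame.copy()
    out["defuse3_positive"] = [f.defuse3_positive for f in flags]
    out["dawn_positive"] = [f.dawn_positive for f in flags]
    out["target_mismatch"] = [f.target_mismatch for f in flags]
    out["large_core"] = [f.large_core for f in flags]
    return out


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def _median_iqr(x: pd.Series) -> str:
    return f"{x.median():.1f} ({x.quantile(0.25):.1f}-{x.quantile(0.75):.1f})"


def summarize_cohort(frame: pd.DataFrame) -> pd.DataFrame:
    """Baseline-table-style summary: one column per arm.

    Mean (SD) for age, median (IQR) for NIHSS and volumes, n (%) for
    categorical fields.  Empty arms produce n = 0 with null statistics.
    """
    if "arm" not in frame.columns:
        frame = frame.assign(arm="all")
    rows: dict[str, dict[str, object]] = {}
    for arm, g in frame.groupby("arm", sort=True):
        col: dict[str, object] = {"n": len(g)}
        if len(g) == 0:
            rows[arm] = col
            continue
        col["age_mean_sd"] = f"{g.age.mean():.1f} ({g.age.std(ddof=1):.2f})" \
            if len(g) > 1 else f"{g.age.mean():.1f} (nan)"
        col["male_n_pct"] = f"{(g.sex == 'male').sum()} ({100 * (g.sex == 'male').mean():.1f}%)"
        col["nihss_median_iqr"] = _median_iqr(g.nihss)
        col["core_median_iqr"] = _median_iqr(g.core_volume)
        col["perfusion_median_iqr"] = _median_iqr(g.perfusion_lesion_volume)
        col["penumbra_median_iqr"] = _median_iqr(g.penumbra_volume)
        col["onset_to_ctp_mean_sd"] = f"{g.onset_to_imaging.mean():.0f} ({g.onset_to_imaging.std(ddof=1):.0f})" \
            if len(g) > 1 else f"{g.onset_to_imaging.mean():.0f} (nan)"
        for tx in TREATMENTS:
            k = (g.treatment == tx).sum()
            col[f"treatment_{tx}"] = f"{k} ({100 * k / len(g):.1f}%)"
        for site in ("ICA", "M1"):
            k = (g.occlusion_site == site).sum()
            col[f"occlusion_{site}"] = f"{k} ({100 * k / len(g):.1f}%)"
        for m in MRS_STATES:
            k = (g.mrs_90d == m).sum()
            col[f"mrs_{m}"] = f"{k} ({100 * k / len(g):.2f}%)"
        if "large_core" in g.columns:
            k = g.large_core.sum()
            col["large_core"] = f"{k} ({100 * k / len(g):.1f}%)"
        rows[arm] = col
    return pd.DataFrame(rows)
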