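"""Propensity-score nearest-neighbour matching with balance diagnostics.

The propensity score is a logistic regression of treatment assignment on
baseline covariates (default: age, sex, baseline NIHSS, CT-perfusion core
volume).  Treated patients are matched to the nearest control on the score,
greedily in descending treated-score order, optionally within a caliper and
with or without replacement.  Balance is reported as standardized mean
differences before and after matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import ConfigurationError

DEFAULT_COVARIATES = ["age", "sex", "nihss", "core_volume"]


@dataclass
class PropensityModel:
    covariates: list[str]
    coefficients: pd.Series       # intercept + per-covariate weights
    scores: pd.Series             # indexed by patient id, strictly in (0,1)
    converged: bool = True

    def __post_init__(self) -> None:
        s = self.scores.to_numpy()
        if not np.isfinite(s).all() or np.any(s <= 0) or np.any(s >= 1):
            raise ConfigurationError("propensity scores must lie strictly inside (0,1)")


@dataclass
class MatchedSet:
    pairs: list[tuple[str, str]]           # (treated id, control id)
    unmatched_treated: list[str]
    unmatched_control: list[str]
    caliper: float | None
    with_replacement: bool
    distances: list[float] = field(default_factory=list)

    def to_frame(self, scores: pd.Series | None = None) -> pd.DataFrame:
        out = pd.DataFrame(self.pairs, columns=["treated_id", "control_id"])
        out["distance"] = self.distances
        if scores is not None:
            out["score_treated"] = scores.loc[out.treated_id].to_numpy()
            out["score_control"] = scores.loc[out.control_id].to_numpy()
        return out


def _design_matrix(frame: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=frame.index)
    for c in covariates:
        col = frame[c]
        if col.dtype == object or col.dtype.name in ("category", "bool"):
            # binary-encode; registry sex is male/female
            levels = sorted(col.astype(str).unique())
            ref = levels[0]
            for lev in levels[1:]:
                X[f"{c}[{lev}]"] = (col.astype(str) == lev).astype(float)
            if len(levels) == 1:
                X[f"{c}[{ref}]"] = 0.0
        else:
            X[c] = col.astype(float)
    return X


def _separating_covariate(X: pd.DataFrame, treated: np.ndarray) -> str | None:
    for c in X.columns:
        t, u = X[c].to_numpy()[treated], X[c].to_numpy()[~treated]
        if t.min() > u.max() or u.min() > t.max():
            return c
    return None


def fit_propensity(frame: pd.DataFrame, covariates: list[str] | None = None,
                   treated_col: str = "treated") -> PropensityModel:
    """Maximum-likelihood logistic fit of treatment on covariates.

    Raises a diagnostic error on perfect separation, naming the separating
    covariate when one covariate alone separates the groups.
    """
    covariates = list(covariates or DEFAULT_COVARIATES)
    missing = [c for c in covariates if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"covariates not in data: {missing}")
    y = frame[treated_col].astype(int).to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ConfigurationError("need at least 2 patients in each treatment group")
    X = _design_matrix(frame, covariates)
    if not np.isfinite(X.to_numpy()).all():
        raise ConfigurationError("non-finite covariate values")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        sep = _separating_covariate(X, y.astype(bool))
        raise ConfigurationError(
            f"propensity model failed ({exc}); "
            + (f"covariate {sep!r} perfectly separates the groups" if sep
               else "check for separation or collinearity")
        ) from exc
    sep = _separating_covariate(X, y.astype(bool))
    if sep is not None:
        raise ConfigurationError(f"covariate {sep!r} perfectly separates the groups")
    scores = pd.Series(np.clip(np.asarray(res.predict(Xc)), 1e-12, 1 - 1e-12),
                       index=frame["id"].to_numpy() if "id" in frame.columns else frame.index)
    return PropensityModel(
        covariates=covariates,
        coefficients=pd.Series(res.params.to_numpy(), index=Xc.columns),
        scores=scores,
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def nearest_neighbor_match(
    model: PropensityModel,
    treated_ids,
    control_ids,
    caliper: float | None = None,
    with_replacement: bool = False,
    seed: int = 0,
) -> MatchedSet:
    """Greedy nearest-neighbour match on the propensity score.

    Treated patients are processed in descending score order; each takes the
    control minimising the absolute score difference, subject to the caliper.
    Equidistant controls are broken by a seeded shuffle (first in shuffled
    order wins), which makes the result deterministic for a given seed.
    Treated patients with no admissible control are reported unmatched.
    """
    scores = model.scores
    treated_ids = list(treated_ids)
    control_ids = list(control_ids)
    t_order = sorted(treated_ids, key=lambda i: (-scores.loc[i], str(i)))
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(2,))))
    shuffled = list(rng.permutation(np.asarray(control_ids, dtype=object)))
    c_rank = {cid: r for r, cid in enumerate(shuffled)}

    available = set(control_ids)
    pairs: list[tuple[str, str]] = []
    dists: list[float] = []
    unmatched_t: list[str] = []
    for tid in t_order:
        ts = scores.loc[tid]
        best, best_d = None, np.inf
        pool = available if not with_replacement else control_ids
        for cid in pool:
            d = abs(scores.loc[cid] - ts)
            if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and best is not None
                                      and c_rank[cid] < c_rank[best]):
                best, best_d = cid, d
        if best is None or (caliper is not None and best_d > caliper + 1e-15):
            unmatched_t.append(tid)
            continue
        pairs.append((tid, best))
        dists.append(float(best_d))
        if not with_replacement:
            available.discard(best)
    matched_controls = {c for _, c in pairs}
    return MatchedSet(
        pairs=pairs,
        unmatched_treated=unmatched_t,
        unmatched_control=[c for c in control_ids if c not in matched_controls],
        caliper=caliper,
        with_replacement=with_replacement,
        distances=dists,
    )


def standardized_mean_difference(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """(mean_t - mean_c) / pooled SD; 0 with a warning when the pooled SD is 0."""
    x_t, x_c = np.asarray(x_t, float), np.asarray(x_c, float)
    v_t = x_t.var(ddof=1) if len(x_t) > 1 else 0.0
    v_c = x_c.var(ddof=1) if len(x_c) > 1 else 0.0
    pooled = np.sqrt((v_t + v_c) / 2.0)
    if pooled == 0:
        import warnings
        warnings.warn("zero pooled SD; SMD reported as 0")
        return 0.0
    return float((x_t.mean() - x_c.mean()) / pooled)


def balance_diagnostics(matched: MatchedSet, frame: pd.DataFrame,
                        covariates: list[str] | None = None,
                        treated_col: str = "treated") -> pd.DataFrame:
    """Per-covariate SMD before vs after matching, plus score summaries."""
    if not matched.pairs:
        raise ConfigurationError("matched set has no pairs")
    covariates = list(covariates or DEFAULT_COVARIATES)
    idx = frame.set_index("id") if "id" in frame.columns else frame
    X = _design_matrix(idx, covariates)
    treated_mask = idx[treated_col].astype(bool)
    t_ids = [t for t, _ in matched.pairs]
    c_ids = [c for _, c in matched.pairs]
    rows = []
    for c in X.columns:
        pre = standardized_mean_difference(
            X.loc[treated_mask, c], X.loc[~treated_mask, c])
        post = standardized_mean_difference(X.loc[t_ids, c], X.loc[c_ids, c])
        rows.append({"covariate": c, "smd_pre": pre, "smd_post": post})
    return pd.DataFrame(rows)
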