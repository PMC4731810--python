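"""Nest-fate statistics: pooled group summaries, median splits,
Kaplan–Meier curves with Greenwood confidence bands, fixed-effects Cox
proportional hazards, and a fixed-effects logistic interaction model.

Nests enter the risk set when found and leave at predation (the event),
hatching, or censoring (desertion, trampling, end of field season, unknown
fate); censored nests inform the model up to their last known date.
Hatching is treated as censoring for the predation hazard. The Cox model
is fixed-effects (species may enter as strata); frailty/random-effects
models are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import survival_table_from_events

__all__ = [
    "NestOutcome",
    "SpeciesSummary",
    "pooled_group_stats",
    "median_split",
    "kaplan_meier",
    "cox_ph",
    "logistic_interaction",
    "outcomes_to_frame",
]

Z_95 = 1.959963984540054


@dataclass
class NestOutcome:
    """Fate of one nest: observation time in days, whether it ended in
    predation (event=1) or was censored/hatched (event=0)."""

    nest_id: str
    species: str
    time_days: float
    event: int
    censor_reason: str = ""

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("observation time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def outcomes_to_frame(outcomes: list[NestOutcome]) -> pd.DataFrame:
    return pd.DataFrame([{
        "nest_id": o.nest_id, "species": o.species,
        "time_days": o.time_days, "event": o.event,
        "censor_reason": o.censor_reason} for o in outcomes])


@dataclass
class SpeciesSummary:
    """Per-species summary row (n, mean, min, max, sd) of any metric,
    e.g. flight initiation distance."""

    species: str
    n: int
    mean: float
    min: float
    max: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def pooled_group_stats(summaries: list[SpeciesSummary]
                       ) -> tuple[int, float, float]:
    """Pool per-species summary rows into group totals.

    Pooled mean is the sample-size-weighted mean of species means; pooled
    variance combines within-species and between-species terms:

        s² = [Σ(nᵢ−1)sᵢ² + Σ nᵢ(mᵢ − m̄)²] / (N − 1)

    Single-observation groups contribute nothing to the within term.
    """
    if not summaries:
        raise ValueError("no summaries to pool")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean for s in summaries], dtype=float)
    sd = np.array([s.sd for s in summaries], dtype=float)
    total = n.sum()
    pooled_mean = float((n * m).sum() / total)
    if total <= 1:
        return int(total), pooled_mean, float(sd[0])
    within = ((n - 1) * sd ** 2)[n > 1].sum()
    between = (n * (m - pooled_mean) ** 2).sum()
    pooled_sd = float(np.sqrt((within + between) / (total - 1)))
    return int(total), pooled_mean, pooled_sd


def median_split(values) -> np.ndarray:
    """Label each value 'high' or 'low' relative to the sample median;
    ties with the median go to 'low'."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("median split needs at least 2 values")
    med = np.median(values)
    return np.where(values > med, "high", "low")


def kaplan_meier(df: pd.DataFrame, groups=None,
                 time_col: str = "time_days", event_col: str = "event"
                 ) -> pd.DataFrame:
    """Product-limit survival curves per group with 95% confidence bands.

    Returns a tidy frame (group, time, survival, ci_low, ci_high). The
    variance is Greenwood's; the band is the log-transformed interval
    exp(ln Ŝ ± 1.96·√V̂) with V̂ = Σ d/(n(n−d)), clipped to [0, 1].
    """
    if groups is None:
        groups = np.repeat("all", len(df))
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        sub = df[groups == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col])
        table = survival_table_from_events(sub[time_col], sub[event_col])
        at_risk = table["at_risk"].to_numpy(dtype=float)
        died = table["observed"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(at_risk > died,
                             died / (at_risk * (at_risk - died)), np.inf)
        cumvar = np.cumsum(terms)
        surv = kmf.survival_function_at_times(table.index).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            log_s = np.log(np.clip(surv, 1e-300, None))
            half = Z_95 * np.sqrt(cumvar)
            lo = np.where(surv > 0, np.exp(log_s - half), 0.0)
            hi = np.where(surv > 0, np.exp(log_s + half), 0.0)
        for t, s, l, u in zip(table.index, surv, lo, hi):
            rows.append({"group": g, "time": float(t), "survival": float(s),
                         "ci_low": float(min(max(l, 0.0), 1.0)),
                         "ci_high": float(min(max(u, 0.0), 1.0))})
    return pd.DataFrame(rows)


def cox_ph(df: pd.DataFrame, covariates: list[str],
           time_col: str = "time_days", event_col: str = "event",
           strata: str | None = None) -> dict:
    """Fixed-effects Cox proportional-hazards fit.

    Covariates are standardized internally (zero mean, unit SD); the
    partial likelihood uses the Efron approximation for tied event times
    and is maximized by Newton–Raphson. Returns per-covariate coefficient
    (on the standardized scale), standard error from the observed
    information, and Z = β/SE.
    """
    if df[event_col].sum() < 1:
        raise ValueError("Cox model needs at least one event")
    cols = [time_col, event_col] + list(covariates)
    if strata is not None:
        cols.append(strata)
    work = df[cols].copy()
    for c in covariates:
        x = work[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"covariate {c!r} contains non-finite values")
        sd = x.std()
        if sd == 0:
            raise ValueError(f"covariate {c!r} is constant")
        work[c] = (x - x.mean()) / sd
    cph = CoxPHFitter()
    cph.fit(work, duration_col=time_col, event_col=event_col,
            strata=strata)
    out = {}
    for c in covariates:
        out[c] = {"beta": float(cph.params_[c]),
                  "se": float(cph.standard_errors_[c]),
                  "z": float(cph.params_[c] / cph.standard_errors_[c])}
    out["n"] = int(len(work))
    out["n_events"] = int(work[event_col].sum())
    return out


def logistic_interaction(df: pd.DataFrame, outcome_col: str,
                         x_col: str, y_col: str) -> dict:
    """Fixed-effects logistic regression of a binary fate on two metrics
    and their interaction (x + y + x:y).

    An approximation to a mixed-effects interaction analysis: no random
    effects are fitted, which the returned dict states explicitly.
    """
    import statsmodels.api as sm

    X = pd.DataFrame({
        x_col: df[x_col].astype(float),
        y_col: df[y_col].astype(float),
    })
    X[f"{x_col}:{y_col}"] = X[x_col] * X[y_col]
    X = sm.add_constant(X)
    model = sm.Logit(df[outcome_col].astype(float), X).fit(disp=False)
    return {
        "model": "fixed-effects logistic approximation (no random effects)",
        "params": model.params.to_dict(),
        "bse": model.bse.to_dict(),
        "pvalues": model.pvalues.to_dict(),
    }
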