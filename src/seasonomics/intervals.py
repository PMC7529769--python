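"""Interval-wise two-group trajectory testing (IR vs IS).

For each analyte, a cyclic-spline seasonal model is fitted separately
to the insulin-resistant and insulin-sensitive groups (covariates age
and BMI; subject random intercepts). The year is discretized to T grid
points; each of the T-1 intervals gets a studentized area statistic

    stat[t, t+1] = (A1[t, t+1] - A2[t, t+1])
                   / sqrt( ((SE1_t + SE1_{t+1})/2)^2 + ((SE2_t + SE2_{t+1})/2)^2 )

where A_k is the trapezoid area under group k's curve over the unit
interval and SE its pointwise standard error. Group labels are then
permuted B times (by default at the subject level, so a subject's
visits move together), both curves refitted per permutation, and each
observed statistic is referred to the POOL of all B x (T-1) null
statistics: p = (# null values more extreme in the observed sign's
direction) / (B * (T-1)). Per-feature BH adjustment across intervals
and an adjusted-p < alpha/2 rule give the significant intervals; a
feature is "global" when every interval is significant, "partial" when
only some are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .seasonal import ModelSpec, SeasonalFit, TooFewObservations, fit_seasonal_model

PERIOD = 365
GROUPS = ("IR", "IS")

#: coarser default smoothing grid for the many refits a permutation
#: null requires; the model is otherwise identical to ModelSpec's
GROUP_SPEC = ModelSpec(lambda_grid=tuple(np.logspace(-4, 6, 12)),
                       subject_ridge_grid=tuple(np.logspace(-2, 2, 4)),
                       covariates=("age", "bmi"))


class IntervalError(RuntimeError):
    pass


@dataclass
class GroupFit:
    label: str
    grid_days: np.ndarray      # (T,)
    fitted: np.ndarray         # (T,)
    se: np.ndarray             # (T,)
    fit: SeasonalFit | None = None


@dataclass
class IntervalStatistics:
    grid_days: np.ndarray
    statistics: np.ndarray     # (T-1,)
    area_1: np.ndarray
    area_2: np.ndarray


@dataclass
class NullPool:
    statistics: np.ndarray     # (B, T-1)
    unit: str
    seed: int | None

    @property
    def B(self) -> int:
        return self.statistics.shape[0]


@dataclass
class IntervalResult:
    feature_id: str | None
    grid_days: np.ndarray
    statistics: np.ndarray
    pvalues: np.ndarray
    adjusted: np.ndarray
    significant: np.ndarray    # adjusted p < alpha/2
    classification: str        # global | partial | none
    significant_ranges: list[tuple[float, float]]
    alpha: float


def grid_days(T: int = 52) -> np.ndarray:
    """T timepoints evenly covering days 1..365."""
    if T < 2:
        raise IntervalError("grid needs at least 2 timepoints")
    return np.linspace(1.0, float(PERIOD), T)


def fit_group_curves(
    values,
    visits: pd.DataFrame,
    T: int = 52,
    spec: ModelSpec = GROUP_SPEC,
    labels: np.ndarray | None = None,
) -> tuple[GroupFit, GroupFit]:
    """Fit the seasonal model per group and evaluate on the shared grid.

    ``labels`` overrides the visit table's group column (used by the
    permutation machinery). Raises naming the group when one side has
    too few observations.
    """
    y = np.asarray(values, dtype=float)
    lab = visits["group"].to_numpy() if labels is None else np.asarray(labels)
    g = grid_days(T)
    out = []
    for name in GROUPS:
        mask = lab == name
        if not mask.any():
            raise IntervalError(f"group {name} is empty")
        try:
            fit = fit_seasonal_model(y[mask], visits.loc[mask], spec,
                                     feature_id=name)
        except TooFewObservations as exc:
            raise IntervalError(f"group {name}: {exc}") from exc
        f, sd = fit.predict_curve(g)
        out.append(GroupFit(label=name, grid_days=g, fitted=f, se=sd, fit=fit))
    return out[0], out[1]


def interval_statistics(fit1: GroupFit, fit2: GroupFit) -> IntervalStatistics:
    """Studentized per-interval area differences between the two fits.

    Areas use the trapezoid rule over the unit interval; the statistic
    is antisymmetric under swapping the groups. Intervals where both
    groups have zero SE are defined as 0 when the area difference is
    also zero, and are an error otherwise.
    """
    if not np.array_equal(fit1.grid_days, fit2.grid_days):
        raise IntervalError("group fits use different grids")
    a1 = 0.5 * (fit1.fitted[:-1] + fit1.fitted[1:])
    a2 = 0.5 * (fit2.fitted[:-1] + fit2.fitted[1:])
    s1 = 0.5 * (fit1.se[:-1] + fit1.se[1:])
    s2 = 0.5 * (fit2.se[:-1] + fit2.se[1:])
    denom = np.sqrt(s1 ** 2 + s2 ** 2)
    num = a1 - a2
    zero = denom == 0.0
    if np.any(zero & (np.abs(num) > 1e-12)):
        raise IntervalError("zero standard error with nonzero area difference")
    stats = np.zeros_like(num)
    np.divide(num, denom, out=stats, where=~zero)
    return IntervalStatistics(grid_days=fit1.grid_days, statistics=stats,
                              area_1=a1, area_2=a2)


def permutation_null(
    values,
    visits: pd.DataFrame,
    B: int = 200,
    unit: str = "subject",
    seed: int | None = 0,
    T: int = 52,
    spec: ModelSpec = GROUP_SPEC,
) -> NullPool:
    """Null statistics from B group-label permutations.

    ``unit="subject"`` shuffles the subject-to-label assignment so all
    of a subject's visits keep one label; ``unit="sample"`` shuffles
    per-visit labels (literal label permutation).
    """
    if B < 1:
        raise IntervalError("B must be >= 1")
    if unit not in ("subject", "sample"):
        raise IntervalError("unit must be 'subject' or 'sample'")
    rng = np.random.default_rng(seed)
    null = np.empty((B, T - 1))
    for b in range(B):
        perm = permuted_labels(visits, unit, rng)
        f1, f2 = fit_group_curves(values, visits, T=T, spec=spec, labels=perm)
        null[b] = interval_statistics(f1, f2).statistics
    return NullPool(statistics=null, unit=unit, seed=seed)


def permuted_labels(visits: pd.DataFrame, unit: str,
                    rng: np.random.Generator) -> np.ndarray:
    """One permutation of the group labels at the chosen unit."""
    group = visits["group"].to_numpy()
    if unit == "subject":
        codes, subjects = pd.factorize(visits["subject_id"])
        subj_label = pd.Series(group).groupby(codes).first().to_numpy()
        return subj_label[rng.permutation(len(subjects))][codes]
    return group[rng.permutation(len(group))]


def interval_pvalues(observed: IntervalStatistics, null: NullPool) -> np.ndarray:
    """Pooled one-direction exceedance p-values.

    Every observed interval statistic is compared against the pooled
    B x (T-1) null values: the p-value is the fraction of null values
    strictly greater (observed >= 0) or strictly smaller (observed < 0)
    than it. Zero p-values are kept as the count produces them.
    """
    pool = null.statistics.ravel()
    if pool.size == 0:
        raise IntervalError("empty permutation pool")
    if null.statistics.shape[1] != len(observed.statistics):
        raise IntervalError("null pool grid does not match the observed grid")
    obs = observed.statistics
    p = np.empty_like(obs)
    pos = obs >= 0
    p[pos] = (pool[None, :] > obs[pos, None]).sum(axis=1)
    p[~pos] = (pool[None, :] < obs[~pos, None]).sum(axis=1)
    return p / pool.size


def _ranges_from_mask(mask: np.ndarray, grid: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous significant day ranges; wrap across day 365 -> 1 merged."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    n_int = len(mask)
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == n_int - 1:
        first = runs.pop(0)
        last = runs.pop()
        runs.append((last[0], first[1]))  # wrap-around range
    out = []
    for a, b in runs:
        out.append((float(grid[a]), float(grid[(b + 1) % len(grid)])))
    return out


def call_significant(
    pvalues: np.ndarray,
    grid: np.ndarray,
    alpha: float = 0.05,
    statistics: np.ndarray | None = None,
    feature_id: str | None = None,
) -> IntervalResult:
    """BH-adjust per-feature interval p-values and call significance.

    Intervals with adjusted p < alpha/2 are significant (the pooled
    exceedance p is one-directional, so alpha/2 yields two-sided
    control at alpha). Classification: "global" if every interval is
    significant, "partial" if at least one but not all, else "none".
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise IntervalError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    mask = adjusted < alpha / 2.0
    if mask.all():
        classification = "global"
    elif mask.any():
        classification = "partial"
    else:
        classification = "none"
    return IntervalResult(
        feature_id=feature_id, grid_days=np.asarray(grid, float),
        statistics=np.asarray(statistics, float) if statistics is not None else np.full_like(p, np.nan),
        pvalues=p, adjusted=adjusted, significant=mask,
        classification=classification,
        significant_ranges=_ranges_from_mask(mask, np.asarray(grid, float)),
        alpha=alpha)


def run_interval_test(
    values,
    visits: pd.DataFrame,
    B: int = 200,
    T: int = 52,
    alpha: float = 0.05,
    unit: str = "subject",
    seed: int | None = 0,
    spec: ModelSpec = GROUP_SPEC,
    feature_id: str | None = None,
) -> IntervalResult:
    """End-to-end interval test for one feature (fit, permute, call)."""
    f1, f2 = fit_group_curves(values, visits, T=T, spec=spec)
    obs = interval_statistics(f1, f2)
    null = permutation_null(values, visits, B=B, unit=unit, seed=seed, T=T, spec=spec)
    p = interval_pvalues(obs, null)
    return call_significant(p, obs.grid_days, alpha=alpha,
                            statistics=obs.statistics, feature_id=feature_id)
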