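"""Microbiome richness and its seasonality.

Per-sample richness is estimated with Chao1 (bias-corrected by
default) at any taxonomic level obtained by summing counts along a
genus -> phylum lineage map, and the resulting richness series is fed
through the same cyclic-spline seasonal model as any other analyte.
The headline summary is the winter-vs-summer contrast of the fitted
annual richness curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .cohort import SUMMER_DAYS, WINTER_DAYS
from .seasonal import ModelSpec, SeasonalFit, fit_feature

log = logging.getLogger(__name__)

LEVELS = ("genus", "family", "order", "class", "phylum")


class DiversityError(ValueError):
    pass


def aggregate_taxa(counts: pd.DataFrame, taxonomy: pd.DataFrame,
                   level: str) -> pd.DataFrame:
    """Sum counts within groups of one taxonomic level.

    ``counts`` is samples x taxa; ``taxonomy`` maps column ``taxon`` to
    lineage columns. Taxa without a lineage entry are bucketed as
    "unclassified". Per-sample totals are conserved.
    """
    if level not in LEVELS:
        raise DiversityError(f"unknown taxonomic level {level!r}; expected one of {LEVELS}")
    lineage = taxonomy.set_index("taxon")[level]
    groups = pd.Index(counts.columns).map(lambda t: lineage.get(t, "unclassified"))
    return counts.T.groupby(groups.to_numpy()).sum().T


def chao1(sample_counts, bias_corrected: bool = True) -> float:
    """Chao1 richness of one sample's counts.

    Classic form S_obs + F1^2 / (2 F2) when doubletons exist; the
    bias-corrected form S_obs + F1 (F1 - 1) / (2 (F2 + 1)) is the
    default and the fallback at F2 = 0. All-zero samples estimate 0.
    """
    c = np.asarray(sample_counts)
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise DiversityError("counts must be non-negative integers")
    c = c.astype(int)
    if c.sum() == 0:
        log.warning("all-zero sample: Chao1 reported as 0")
        return 0.0
    return float(_skbio_chao1(c, bias_corrected=bias_corrected))


@dataclass
class DiversitySeasonality:
    """Fitted richness seasonality with its winter-summer contrast."""

    fit: SeasonalFit
    pvalue: float
    winter_mean: float
    summer_mean: float

    @property
    def winter_summer_contrast(self) -> float:
        return self.winter_mean - self.summer_mean


def chao1_table(counts: pd.DataFrame, bias_corrected: bool = True,
                level: str | None = None) -> pd.DataFrame:
    """Per-sample observed richness and Chao1 for a counts matrix."""
    arr = counts.to_numpy()
    obs = (arr > 0).sum(axis=1)
    est = [chao1(row, bias_corrected=bias_corrected) for row in arr]
    return pd.DataFrame({
        "sample_id": counts.index, "level": level or "taxon",
        "observed_richness": obs, "chao1": est})


def diversity_seasonality(
    estimates: pd.DataFrame,
    visits: pd.DataFrame,
    spec: ModelSpec | None = None,
    column: str = "chao1",
) -> DiversitySeasonality:
    """Seasonality of a per-sample richness series.

    ``estimates`` (sample_id + richness column) is joined to the visit
    table, the standard seasonal model is fitted, and the fitted annual
    curve is contrasted between winter (days 1-60 and 335-365) and
    summer (days 152-244).
    """
    merged = visits.merge(estimates[["sample_id", column]], on="sample_id",
                          how="inner")
    if merged.empty:
        raise DiversityError("no overlap between estimates and visits")
    fit = fit_feature(merged[column].to_numpy(), merged, spec,
                      feature_id=column)
    curve = fit.fitted_curve
    winter = float(curve[WINTER_DAYS - 1].mean())
    summer = float(curve[SUMMER_DAYS - 1].mean())
    return DiversitySeasonality(fit=fit, pvalue=fit.pvalue,
                                winter_mean=winter, summer_mean=summer)
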