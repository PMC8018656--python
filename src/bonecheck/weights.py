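"""Skeleton-weight compliance audit.

Paired farm/port weights screen consignments for laundering: cleaning
and desiccation make exported skeletons *lighter*, so a port weight more
than a threshold (default 0.6 kg) heavier than its farm weight is
flagged for investigation. The threshold is applied to the nett
(packaging-corrected) port weight; when per-skeleton packaging was not
recorded, a configured trader-mean packaging weight is subtracted
instead. Each flag triggers an investigation rather than a statistical
claim, so no multiple-testing correction is applied.

Year-stratified consignment regressions (skeleton count on nett
consignment weight, ordinary least squares) provide a rapid estimate of
the number of skeletons in a consignment; mean skeleton weights drift
between years, so estimates across year groups carry a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .genodata import WeightRecord

__all__ = [
    "WeightAudit",
    "ConsignmentFit",
    "CountEstimate",
    "CrossYearWarning",
    "audit_pairs",
    "fit_consignments",
    "estimate_count",
]


class CrossYearWarning(UserWarning):
    """Count estimated with a regression fitted on a different year group."""


@dataclass
class WeightAudit:
    pairs: pd.DataFrame            # tag, trader, farm_kg, port_nett_kg, delta_kg, flag
    threshold_kg: float
    n_pairs: int
    n_flagged: int
    paired_t: float
    paired_t_p: float
    trader_anova_F: float | None = None
    trader_anova_p: float | None = None
    site_means: dict = field(default_factory=dict)

    @property
    def flagged_tags(self) -> list[str]:
        return list(self.pairs.loc[self.pairs["flag"], "tag"])


def audit_pairs(
    weight_records: Sequence[WeightRecord],
    threshold_kg: float = 0.6,
    default_packaging_kg: float | Mapping[str, float] = 0.0,
) -> WeightAudit:
    """Paired farm/port audit over records with a port weight.

    delta = port nett - farm; flag iff delta > threshold. Also reports
    the paired t-test of farm vs port means and a one-way ANOVA of farm
    weights by trader (where >= 2 traders have >= 2 records each).
    """
    if threshold_kg <= 0:
        raise ValueError("threshold must be positive")
    rows = []
    for rec in weight_records:
        if rec.port_gross_weight_kg is None:
            continue
        if rec.packaging_weight_kg is not None:
            nett = rec.port_gross_weight_kg - rec.packaging_weight_kg
        else:
            if isinstance(default_packaging_kg, Mapping):
                pack = default_packaging_kg.get(rec.trader_id, 0.0)
            else:
                pack = default_packaging_kg
            nett = rec.port_gross_weight_kg - pack
        delta = nett - rec.farm_weight_kg
        rows.append(
            {
                "tag": rec.tag,
                "trader": rec.trader_id,
                "farm_kg": rec.farm_weight_kg,
                "port_nett_kg": nett,
                "delta_kg": delta,
                "flag": delta > threshold_kg,
            }
        )
    if not rows:
        raise ValueError("no complete farm/port weight pairs")
    pairs = pd.DataFrame(rows)
    if len(pairs) >= 2:
        t_stat, t_p = stats.ttest_rel(pairs["farm_kg"], pairs["port_nett_kg"])
    else:
        t_stat, t_p = float("nan"), float("nan")
    anova_F = anova_p = None
    groups = [g["farm_kg"].to_numpy() for _, g in pairs.groupby("trader") if len(g) >= 2]
    if len(groups) >= 2:
        anova_F, anova_p = stats.f_oneway(*groups)
        anova_F, anova_p = float(anova_F), float(anova_p)
    site_means = {
        "farm": {
            "mean": float(pairs["farm_kg"].mean()),
            "sd": float(pairs["farm_kg"].std(ddof=1)) if len(pairs) > 1 else 0.0,
        },
        "port_nett": {
            "mean": float(pairs["port_nett_kg"].mean()),
            "sd": float(pairs["port_nett_kg"].std(ddof=1)) if len(pairs) > 1 else 0.0,
        },
    }
    return WeightAudit(
        pairs=pairs,
        threshold_kg=threshold_kg,
        n_pairs=len(pairs),
        n_flagged=int(pairs["flag"].sum()),
        paired_t=float(t_stat),
        paired_t_p=float(t_p),
        trader_anova_F=anova_F,
        trader_anova_p=anova_p,
        site_means=site_means,
    )


@dataclass
class ConsignmentFit:
    year_group: str
    slope: float
    intercept: float
    slope_se: float
    resid_sd: float
    n: int
    x_min: float
    x_max: float
    _results: object = field(repr=False, default=None)


def fit_consignments(
    consignments: pd.DataFrame | Sequence[tuple],
    year_group: str,
) -> ConsignmentFit:
    """OLS of skeleton count on nett consignment weight.

    `consignments` is a DataFrame with columns nett_weight_kg and
    n_skeletons (or an iterable of (nett_weight_kg, n_skeletons) pairs).
    """
    if not isinstance(consignments, pd.DataFrame):
        consignments = pd.DataFrame(
            consignments, columns=["nett_weight_kg", "n_skeletons"]
        )
    if len(consignments) < 3:
        raise ValueError("need >= 3 consignments to fit")
    x = consignments["nett_weight_kg"].to_numpy(float)
    y = consignments["n_skeletons"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all consignment weights equal")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return ConsignmentFit(
        year_group=year_group,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        resid_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        n=len(x),
        x_min=float(x.min()),
        x_max=float(x.max()),
        _results=res,
    )


@dataclass
class CountEstimate:
    count: int                 # point estimate rounded to nearest integer
    point: float               # unrounded
    pi_low: float
    pi_high: float
    alpha: float
    cross_year: bool = False


def estimate_count(
    fit: ConsignmentFit,
    nett_weight: float,
    year_group: str | None = None,
    alpha: float = 0.05,
) -> CountEstimate:
    """Predicted skeleton count for a consignment of the given nett weight,
    with an OLS prediction interval (unrounded). A query from a different
    year group than the fit emits :class:`CrossYearWarning`."""
    if nett_weight <= 0:
        raise ValueError("nett weight must be positive")
    cross = year_group is not None and year_group != fit.year_group
    if cross:
        warnings.warn(
            f"count estimated with the {fit.year_group!r} regression for a "
            f"{year_group!r} consignment; year-on-year weight drift makes "
            "cross-year regressions unreliable",
            CrossYearWarning,
            stacklevel=2,
        )
    pred = fit._results.get_prediction([1.0, nett_weight])
    frame = pred.summary_frame(alpha=alpha)
    point = float(frame["mean"].iloc[0])
    lo = float(frame["obs_ci_lower"].iloc[0])
    hi = float(frame["obs_ci_upper"].iloc[0])
    return CountEstimate(
        count=int(round(point)),
        point=point,
        pi_low=lo,
        pi_high=hi,
        alpha=alpha,
        cross_year=cross,
    )
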