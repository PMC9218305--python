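"""Precision-weighted prevalence, within-district dispersion and agreement.

A unit's precision-weighted prevalence plugs the posterior-mean random
effects into the inverse logit: for small area j in district k, state l,

    prev_jkl = 100 * expit(beta0 + c_jkl + d_kl + s_l)            (%)

and for a district the small-area residual is dropped.  Because posterior
means of random effects are shrunken toward zero, small noisy units are
pulled toward their parent's estimate — the empirical-Bayes borrowing of
strength that makes these estimates usable for 640+ districts.

Within-district small-area inequality is the sample SD of a district's
small-area prevalences.  The module also computes the district-level
prevalence-vs-SD Pearson correlation (nationally and by state) and the
individual-level agreement between the weighed and reported outcomes
(sensitivity, specificity and the single-threshold ROC area).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import pearsonr

from .mcmc import ModelFit

__all__ = [
    "precision_weighted_small_area",
    "precision_weighted_district",
    "within_district_sd",
    "prevalence_sd_correlation",
    "binary_agreement",
]

log = logging.getLogger(__name__)


def precision_weighted_small_area(fit: ModelFit) -> pd.DataFrame:
    """Precision-weighted prevalence (%) for every small area in the fit.

    Columns: cluster_id, district_id, state_id, prevalence_pct, n_children.
    """
    u = fit.units.copy()
    eta = fit.beta0 + u["cluster_id"].map(fit.resid_cluster).to_numpy()
    missing = u.loc[np.isnan(eta), "cluster_id"]
    if len(missing):
        raise KeyError(f"no posterior residual for cluster(s) {list(missing[:3])}")
    if fit.resid_district is not None:
        eta = eta + u["district_id"].map(fit.resid_district).to_numpy()
    if fit.resid_state is not None:
        eta = eta + u["state_id"].map(fit.resid_state).to_numpy()
    u["prevalence_pct"] = 100.0 * expit(eta)
    return u[["cluster_id", "district_id", "state_id", "prevalence_pct", "n_children"]]


def precision_weighted_district(fit: ModelFit) -> pd.DataFrame:
    """Precision-weighted prevalence (%) per district (small-area residual dropped)."""
    u = (
        fit.units.groupby(["state_id", "district_id"], sort=True)["n_children"]
        .agg(n_children="sum", n_clusters="size")
        .reset_index()
    )
    eta = np.full(len(u), fit.beta0)
    if fit.resid_district is not None:
        eta = eta + u["district_id"].map(fit.resid_district).to_numpy()
    if fit.resid_state is not None:
        eta = eta + u["state_id"].map(fit.resid_state).to_numpy()
    u["prevalence_pct"] = 100.0 * expit(eta)
    return u[["district_id", "state_id", "prevalence_pct", "n_children", "n_clusters"]]


def within_district_sd(
    cluster_estimates: pd.DataFrame,
    district_estimates: pd.DataFrame | None = None,
    aspirational: pd.Series | None = None,
) -> pd.DataFrame:
    """District summaries: prevalence, within-district small-area SD, counts.

    The SD is the n-1 sample standard deviation of the district's small-area
    prevalence estimates; districts with a single small area get a missing SD
    (logged).  District prevalence comes from ``district_estimates`` when
    given, else it is the unweighted mean of the small-area estimates.  An
    optional ``aspirational`` flag (indexed by district_id) is carried
    through.
    """
    g = (
        cluster_estimates.groupby(["state_id", "district_id"], sort=True)["prevalence_pct"]
        .agg(mean_cluster_prev="mean", sd="std", n_clusters="size")
        .reset_index()
    )
    single = g["n_clusters"] < 2
    if single.any():
        log.warning(
            "%d district(s) have a single small area; SD undefined", int(single.sum())
        )
    if district_estimates is not None:
        g = g.merge(
            district_estimates[["district_id", "prevalence_pct"]], on="district_id"
        )
    else:
        g["prevalence_pct"] = g["mean_cluster_prev"]
    g = g[["district_id", "state_id", "prevalence_pct", "sd", "n_clusters"]]
    if aspirational is not None:
        g["aspirational"] = g["district_id"].map(aspirational).fillna(0).astype(int)
    return g


def prevalence_sd_correlation(
    summaries: pd.DataFrame, group_by_state: bool = False
) -> pd.DataFrame:
    """Pearson r between district prevalence and within-district SD.

    Districts without a defined SD are dropped.  Groups (national, or each
    state when ``group_by_state``) need >= 3 districts and non-degenerate
    coordinates; otherwise r is missing and a warning is logged.
    """
    d = summaries.dropna(subset=["sd"])
    groups = [("all", d)] if not group_by_state else list(d.groupby("state_id"))
    rows = []
    for key, sub in groups:
        r = np.nan
        if len(sub) < 3:
            log.warning("group %s has %d districts with SD; need >= 3", key, len(sub))
        elif sub["prevalence_pct"].nunique() == 1 or sub["sd"].nunique() == 1:
            log.warning("group %s has zero variance in prevalence or SD", key)
        else:
            r = float(pearsonr(sub["prevalence_pct"], sub["sd"]).statistic)
        rows.append({"group": key, "n_districts": len(sub), "r": r})
    return pd.DataFrame(rows)


def binary_agreement(
    lbw_flags: np.ndarray | pd.Series, sbs_flags: np.ndarray | pd.Series
) -> dict[str, float]:
    """Agreement of the reported-size outcome with the weighed outcome.

    Treats small birth size as a single binary test for low birth weight:
    sensitivity = P(SBS=1 | LBW=1), specificity = P(SBS=0 | LBW=0), and the
    ROC area of a single binary predictor is (sensitivity + specificity) / 2.
    Sensitivity/specificity are percentages; the area is a proportion.
    """
    lbw = np.asarray(lbw_flags, dtype=float)
    sbs = np.asarray(sbs_flags, dtype=float)
    if lbw.shape != sbs.shape:
        raise ValueError("flag vectors must have equal length")
    if np.isnan(lbw).any() or np.isnan(sbs).any():
        raise ValueError("flag vectors must not contain missing values")

    pos = lbw == 1
    out = {"sensitivity_pct": np.nan, "specificity_pct": np.nan, "roc_area": np.nan}
    if not pos.any():
        log.warning("no positive cases; sensitivity undefined")
        return out
    out["sensitivity_pct"] = 100.0 * float(sbs[pos].mean())
    if (~pos).any():
        out["specificity_pct"] = 100.0 * float(1.0 - sbs[~pos].mean())
        out["roc_area"] = (out["sensitivity_pct"] + out["specificity_pct"]) / 200.0
    else:
        log.warning("no negative cases; specificity undefined")
    return out
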