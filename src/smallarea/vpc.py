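"""Variance partitioning for nested latent-variable logistic models.

Under the threshold (latent-variable) convention a binary logistic outcome
has a fixed child-level residual variance of pi^2/3 ≈ 3.29.  The geographic
variance is the sum of the state, district and small-area latent variance
components; the share of level z is 100 * sigma2_z / (sigma2_c + sigma2_d +
sigma2_s).  The child-level constant is reported alongside but excluded from
the geographic denominator.  Within one state the small-area share is
100 * sigma2_c / (sigma2_c + sigma2_d); states with a single district have no
between-district variance to attribute, so their small-area share is 100% by
construction.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .mcmc import ModelFit

__all__ = [
    "geographic_vpc",
    "within_state_small_area_share",
    "latent_level1_variance",
    "vpc_from_fit",
    "state_vpc_table",
    "round_half_away",
]

_LEVELS = ("small_area", "district", "state")


def round_half_away(x) -> int | np.ndarray:
    """Round to the nearest integer with ties going away from zero."""
    r = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return int(r) if np.isscalar(x) else r.astype(int)


def latent_level1_variance() -> float:
    """The fixed child-level latent variance pi^2/3 (≈ 3.29)."""
    return math.pi**2 / 3.0


def geographic_vpc(
    sigma2_cluster: float,
    sigma2_district: float,
    sigma2_state: float,
    ci: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Percentage shares of total geographic variance by level.

    Returns one row per level (small_area, district, state) with the
    variance, its optional 95% interval, the exact share and the rounded
    integer share.  Shares always sum to 100 before rounding.
    """
    v = np.array([sigma2_cluster, sigma2_district, sigma2_state], dtype=float)
    if (v < 0).any():
        raise ValueError("variance components must be >= 0")
    total = v.sum()
    if total == 0:
        raise ValueError("all variance components are zero; shares are undefined")
    share = 100.0 * v / total
    out = pd.DataFrame(
        {
            "level": _LEVELS,
            "variance": v,
            "share_pct": share,
            "share_pct_rounded": round_half_away(share),
        }
    )
    if ci is not None:
        out["ci_low"] = [ci.get(lvl, (np.nan, np.nan))[0] for lvl in _LEVELS]
        out["ci_high"] = [ci.get(lvl, (np.nan, np.nan))[1] for lvl in _LEVELS]
    return out


def within_state_small_area_share(
    sigma2_cluster: float,
    sigma2_district: float | None,
    single_district: bool = False,
) -> float:
    """Small-area share (%) of a state's geographic variance.

    Single-district states carry all their geographic variance at the
    small-area level and return exactly 100.
    """
    if single_district:
        return 100.0
    if sigma2_cluster < 0 or sigma2_district is None or sigma2_district < 0:
        raise ValueError("variance components must be >= 0")
    total = sigma2_cluster + sigma2_district
    if total == 0:
        raise ValueError(
            "both variance components are zero in a multi-district state; share undefined"
        )
    return 100.0 * sigma2_cluster / total


def vpc_from_fit(fit: ModelFit) -> pd.DataFrame:
    """Geographic VPC table from a 4-level posterior summary."""
    if fit.n_levels != 4:
        raise ValueError("national VPC needs a 4-level fit")
    ci = {}
    for lvl, name in zip(_LEVELS, ("sigma2_cluster", "sigma2_district", "sigma2_state")):
        row = fit.scalars.loc[fit.scalars["name"] == name].iloc[0]
        ci[lvl] = (row["ci_low"], row["ci_high"])
    return geographic_vpc(fit.sigma2_cluster, fit.sigma2_district, fit.sigma2_state, ci=ci)


def state_vpc_table(fits: dict[str, ModelFit]) -> pd.DataFrame:
    """Per-state small-area shares from state-specific fits."""
    rows = []
    for state in sorted(fits):
        fit = fits[state]
        share = within_state_small_area_share(
            fit.sigma2_cluster, fit.sigma2_district, fit.single_district
        )
        rows.append(
            {
                "state_id": state,
                "sigma2_cluster": fit.sigma2_cluster,
                "sigma2_district": fit.sigma2_district,
                "single_district": fit.single_district,
                "small_area_share_pct": share,
                "small_area_share_pct_rounded": round_half_away(share),
            }
        )
    return pd.DataFrame(rows)
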