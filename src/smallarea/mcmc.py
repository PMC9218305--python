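"""Bayesian multilevel logistic regression by Gibbs sampling.

The model is an intercept-only random-effects logistic regression on a
strictly nested hierarchy.  For the national 4-level model the latent
propensity of child i in small area j, district k, state l is

    psi_ijkl = beta0 + c_jkl + d_kl + s_l,
    c ~ N(0, sigma2_cluster), d ~ N(0, sigma2_district), s ~ N(0, sigma2_state),

with Y ~ Bernoulli(expit(psi)).  State-specific models drop the state level
(3 levels: child, small area, district); single-district states drop the
district level too (2 levels).

Sampling uses Pólya-Gamma data augmentation: conditional on one latent
omega_i ~ PG(1, psi_i) per child, every full conditional is Gaussian or
inverse-gamma, giving a pure Gibbs sweep with no tuning.  Because all
children of a small area share one linear predictor, their omegas enter only
through per-area sums, drawn directly as PG(n_area, psi_area) variates.

Priors: improper flat on beta0; inverse-gamma(0.001, 0.001) on each variance
component (configurable).  Starting values use an empirical-logit method of
moments.  Chains are fully reproducible from the spec seed, and all per-unit
randomness is keyed to sorted unit IDs, so record order never matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import arviz as az
import numpy as np
import pandas as pd
from numba import njit
from .pg import pg_sum_grouped

__all__ = [
    "ModelSpec",
    "PosteriorChain",
    "ModelFit",
    "initialize",
    "fit_mcmc",
    "summarize_chain",
    "fit_state_specific",
]

log = logging.getLogger(__name__)

_VARIANCE_FLOOR = 0.01


@dataclass(frozen=True)
class ModelSpec:
    """MCMC run configuration.

    Defaults follow the study protocol: 5,000 monitored iterations after a
    burn-in of 500, no thinning.
    """

    n_levels: int = 4
    burn_in: int = 500
    monitored: int = 5000
    thinning: int = 1
    prior_shape: float = 0.001
    prior_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels not in (2, 3, 4):
            raise ValueError("n_levels must be 2, 3 or 4")
        if self.monitored < 100:
            raise ValueError("monitored must be >= 100")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PosteriorChain:
    """Monitored draws of the scalars plus running means of every residual."""

    beta0: np.ndarray
    sigma2_cluster: np.ndarray
    sigma2_district: np.ndarray | None
    sigma2_state: np.ndarray | None
    resid_cluster: pd.Series  # posterior-mean c, indexed by cluster_id
    resid_district: pd.Series | None
    resid_state: pd.Series | None
    spec: ModelSpec
    units: pd.DataFrame  # cluster_id, district_id, state_id, n_children
    single_district: bool = False


@dataclass
class ModelFit:
    """Posterior summary of one fitted model."""

    scalars: pd.DataFrame  # name, mean, ci_low, ci_high, ess
    beta0: float
    sigma2_cluster: float
    sigma2_district: float | None
    sigma2_state: float | None
    resid_cluster: pd.Series
    resid_district: pd.Series | None
    resid_state: pd.Series | None
    units: pd.DataFrame
    n_levels: int
    single_district: bool = False

    @property
    def variances(self) -> dict[str, float]:
        out = {"sigma2_cluster": self.sigma2_cluster}
        if self.sigma2_district is not None:
            out["sigma2_district"] = self.sigma2_district
        if self.sigma2_state is not None:
            out["sigma2_state"] = self.sigma2_state
        return out


# ---------------------------------------------------------------------------
# Data preparation


def _index_sample(sample: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the child-level sample to one row per small area.

    Returns a frame sorted by cluster_id with columns n, y, district index
    and state index, validating binary outcomes and strict nesting.
    """
    y = sample["outcome"]
    if not y.isin([0, 1]).all():
        raise ValueError("outcome must be binary 0/1 with no missing values")

    g = (
        sample.groupby(["state_id", "district_id", "cluster_id"], sort=True)["outcome"]
        .agg(n="size", y="sum")
        .reset_index()
    )
    if g["cluster_id"].duplicated().any():
        raise ValueError("hierarchy not nested: a cluster appears under multiple districts")
    d2s = g[["district_id", "state_id"]].drop_duplicates()
    if d2s["district_id"].duplicated().any():
        raise ValueError("hierarchy not nested: a district appears under multiple states")

    total = g["y"].sum()
    if total == 0 or total == g["n"].sum():
        raise ValueError("outcome is constant (all 0 or all 1); the model is degenerate")

    g = g.sort_values("cluster_id", kind="stable").reset_index(drop=True)
    g["district_idx"] = pd.factorize(g["district_id"], sort=True)[0]
    d2s = d2s.sort_values("district_id")
    g.attrs["state_of_district"] = pd.factorize(d2s["state_id"], sort=True)[0].astype(
        np.int64
    )
    g.attrs["district_ids"] = np.sort(g["district_id"].unique())
    g.attrs["state_ids"] = np.sort(g["state_id"].unique())
    return g


def _logit_dispersion(y: np.ndarray, n: np.ndarray) -> float:
    """Between-unit variance of empirical logits net of binomial noise."""
    el = np.log((y + 0.5) / (n - y + 0.5))
    noise = 1.0 / (y + 0.5) + 1.0 / (n - y + 0.5)
    if len(el) < 2:
        return 0.0
    return float(np.var(el, ddof=1) - noise.mean())


def initialize(sample: pd.DataFrame, n_levels: int = 4) -> dict[str, float]:
    """Empirical-logit starting values for the intercept and variances.

    beta0 starts at the empirical logit of the overall prevalence (0.5
    continuity correction).  Each variance starts at the between-unit
    variance of that level's empirical logits minus the mean binomial noise;
    because a lower level's logits also carry the dispersion of the levels
    above it, the higher-level starts are subtracted off top-down, and every
    start is floored at 0.01.
    """
    g = _index_sample(sample)
    for label, col, needed in [
        ("state", "state_id", n_levels >= 4),
        ("district", "district_id", n_levels >= 3),
    ]:
        if needed and g[col].nunique() < 2:
            raise ValueError(
                f"only one {label} in the sample: fit the {n_levels - 1}-level model instead"
            )
    if g["cluster_id"].nunique() < 2:
        raise ValueError("need at least 2 small areas to fit a multilevel model")

    n_tot, y_tot = g["n"].sum(), g["y"].sum()
    starts = {"beta0": float(np.log((y_tot + 0.5) / (n_tot - y_tot + 0.5)))}

    above = 0.0
    if n_levels >= 4:
        s = g.groupby("state_id")[["y", "n"]].sum()
        v = _logit_dispersion(s["y"].to_numpy(float), s["n"].to_numpy(float))
        starts["sigma2_state"] = max(v, _VARIANCE_FLOOR)
        above = starts["sigma2_state"]
    if n_levels >= 3:
        d = g.groupby("district_id")[["y", "n"]].sum()
        v = _logit_dispersion(d["y"].to_numpy(float), d["n"].to_numpy(float)) - above
        starts["sigma2_district"] = max(v, _VARIANCE_FLOOR)
        above += starts["sigma2_district"]
    v = _logit_dispersion(g["y"].to_numpy(float), g["n"].to_numpy(float)) - above
    starts["sigma2_cluster"] = max(v, _VARIANCE_FLOOR)
    return starts


# ---------------------------------------------------------------------------
# Gibbs kernel


@njit(cache=True)
def _inv_gamma(shape, rate, gen):
    return 1.0 / gen.gamma(shape, 1.0 / rate)


@njit(cache=True)
def _gibbs_kernel(
    n_c,  # int64[J] children per cluster
    kappa_c,  # float64[J] sum(y) - n/2 per cluster
    dist_of_cluster,  # int64[J]
    state_of_district,  # int64[K]
    n_states,  # int
    has_district,  # bool
    has_state,  # bool
    beta0,
    sc2,
    sd2,
    ss2,
    a0,
    b0,
    burn_in,
    monitored,
    thin,
    gen,
):
    J = n_c.shape[0]
    K = state_of_district.shape[0]
    L = n_states

    c = np.zeros(J)
    d = np.zeros(K)
    s = np.zeros(L)

    n_keep = monitored // thin
    beta0_ch = np.empty(n_keep)
    sc2_ch = np.empty(n_keep)
    sd2_ch = np.empty(n_keep)
    ss2_ch = np.empty(n_keep)
    c_sum = np.zeros(J)
    d_sum = np.zeros(K)
    s_sum = np.zeros(L)

    psi = np.empty(J)
    kept = 0
    for it in range(burn_in + monitored):
        # linear predictor per small area (shared by its children)
        for j in range(J):
            v = beta0 + c[j]
            if has_district:
                v += d[dist_of_cluster[j]]
                if has_state:
                    v += s[state_of_district[dist_of_cluster[j]]]
            psi[j] = v
        omega = pg_sum_grouped(n_c, psi, gen)

        # small-area residuals
        for j in range(J):
            rest = psi[j] - c[j]
            prec = omega[j] + 1.0 / sc2
            mean = (kappa_c[j] - omega[j] * rest) / prec
            c[j] = mean + gen.standard_normal() / np.sqrt(prec)

        if has_district:
            A = np.zeros(K)
            B = np.zeros(K)
            for j in range(J):
                k = dist_of_cluster[j]
                rest = beta0 + c[j]
                if has_state:
                    rest += s[state_of_district[k]]
                A[k] += omega[j]
                B[k] += kappa_c[j] - omega[j] * rest
            for k in range(K):
                prec = A[k] + 1.0 / sd2
                d[k] = B[k] / prec + gen.standard_normal() / np.sqrt(prec)

        if has_state:
            A = np.zeros(L)
            B = np.zeros(L)
            for j in range(J):
                k = dist_of_cluster[j]
                l = state_of_district[k]
                rest = beta0 + c[j] + d[k]
                A[l] += omega[j]
                B[l] += kappa_c[j] - omega[j] * rest
            for l in range(L):
                prec = A[l] + 1.0 / ss2
                s[l] = B[l] / prec + gen.standard_normal() / np.sqrt(prec)

        # intercept (flat prior)
        At = 0.0
        Bt = 0.0
        for j in range(J):
            rest = c[j]
            if has_district:
                rest += d[dist_of_cluster[j]]
                if has_state:
                    rest += s[state_of_district[dist_of_cluster[j]]]
            At += omega[j]
            Bt += kappa_c[j] - omega[j] * rest
        beta0 = Bt / At + gen.standard_normal() / np.sqrt(At)

        # variance components
        sc2 = _inv_gamma(a0 + 0.5 * J, b0 + 0.5 * np.dot(c, c), gen)
        if has_district:
            sd2 = _inv_gamma(a0 + 0.5 * K, b0 + 0.5 * np.dot(d, d), gen)
        if has_state:
            ss2 = _inv_gamma(a0 + 0.5 * L, b0 + 0.5 * np.dot(s, s), gen)

        if it >= burn_in:
            m = it - burn_in
            c_sum += c
            d_sum += d
            s_sum += s
            if m % thin == 0 and kept < n_keep:
                beta0_ch[kept] = beta0
                sc2_ch[kept] = sc2
                sd2_ch[kept] = sd2
                ss2_ch[kept] = ss2
                kept += 1

    inv_m = 1.0 / monitored
    return (
        beta0_ch,
        sc2_ch,
        sd2_ch,
        ss2_ch,
        c_sum * inv_m,
        d_sum * inv_m,
        s_sum * inv_m,
    )


def fit_mcmc(sample: pd.DataFrame, spec: ModelSpec) -> PosteriorChain:
    """Run the Gibbs sampler on a child-level analysis sample.

    The sample needs ``state_id``, ``district_id``, ``cluster_id`` and a
    binary ``outcome`` column with no missing values.  Returns the monitored
    chain; pass it to :func:`summarize_chain` for posterior summaries.
    """
    g = _index_sample(sample)
    starts = initialize(sample, n_levels=spec.n_levels)

    has_district = spec.n_levels >= 3
    has_state = spec.n_levels >= 4
    state_of_district = g.attrs["state_of_district"]
    n_states = len(g.attrs["state_ids"])

    gen = np.random.default_rng(spec.seed)
    beta0_ch, sc2_ch, sd2_ch, ss2_ch, c_mean, d_mean, s_mean = _gibbs_kernel(
        g["n"].to_numpy(np.int64),
        (g["y"] - g["n"] / 2.0).to_numpy(np.float64),
        g["district_idx"].to_numpy(np.int64),
        state_of_district,
        n_states,
        has_district,
        has_state,
        starts["beta0"],
        starts["sigma2_cluster"],
        starts.get("sigma2_district", 1.0),
        starts.get("sigma2_state", 1.0),
        spec.prior_shape,
        spec.prior_rate,
        spec.burn_in,
        spec.monitored,
        spec.thinning,
        gen,
    )

    district_ids = g.attrs["district_ids"]
    state_ids = g.attrs["state_ids"]
    units = g[["cluster_id", "district_id", "state_id", "n"]].rename(
        columns={"n": "n_children"}
    )
    return PosteriorChain(
        beta0=beta0_ch,
        sigma2_cluster=sc2_ch,
        sigma2_district=sd2_ch if has_district else None,
        sigma2_state=ss2_ch if has_state else None,
        resid_cluster=pd.Series(c_mean, index=g["cluster_id"], name="resid"),
        resid_district=(
            pd.Series(d_mean, index=district_ids, name="resid") if has_district else None
        ),
        resid_state=pd.Series(s_mean, index=state_ids, name="resid") if has_state else None,
        spec=spec,
        units=units,
    )


# ---------------------------------------------------------------------------
# Summaries


def _ci(draws: np.ndarray) -> tuple[float, float]:
    # equal-tailed 95% interval, linear-interpolation percentiles
    lo, hi = np.percentile(draws, [2.5, 97.5], method="linear")
    return float(lo), float(hi)


def _ess(draws: np.ndarray) -> float:
    if np.allclose(draws, draws[0]):
        return float(len(draws))
    return float(az.ess(np.asarray(draws)))


def summarize_chain(chain: PosteriorChain) -> ModelFit:
    """Posterior means, equal-tailed 95% credible intervals and ESS."""
    if len(chain.beta0) == 0:
        raise ValueError("empty chain")
    rows = []
    scalars = {"beta0": chain.beta0, "sigma2_cluster": chain.sigma2_cluster}
    if chain.sigma2_district is not None:
        scalars["sigma2_district"] = chain.sigma2_district
    if chain.sigma2_state is not None:
        scalars["sigma2_state"] = chain.sigma2_state
    for name, draws in scalars.items():
        lo, hi = _ci(draws)
        rows.append(
            {"name": name, "mean": float(np.mean(draws)), "ci_low": lo, "ci_high": hi,
             "ess": _ess(draws)}
        )
    table = pd.DataFrame(rows)

    return ModelFit(
        scalars=table,
        beta0=float(np.mean(chain.beta0)),
        sigma2_cluster=float(np.mean(chain.sigma2_cluster)),
        sigma2_district=(
            float(np.mean(chain.sigma2_district)) if chain.sigma2_district is not None else None
        ),
        sigma2_state=(
            float(np.mean(chain.sigma2_state)) if chain.sigma2_state is not None else None
        ),
        resid_cluster=chain.resid_cluster,
        resid_district=chain.resid_district,
        resid_state=chain.resid_state,
        units=chain.units,
        n_levels=chain.spec.n_levels,
        single_district=chain.single_district,
    )


def fit_state_specific(sample: pd.DataFrame, spec: ModelSpec) -> dict[str, ModelFit]:
    """Fit one within-state model per state.

    States with >= 2 districts get the 3-level model (child, small area,
    district); single-district states are fitted 2-level and flagged, so the
    variance-partition stage reports their small-area share as 100%.  States
    with a single small area cannot support a multilevel model and are
    skipped with a warning.  Per-state seeds are split from ``spec.seed`` in
    sorted state order.
    """
    states = np.sort(sample["state_id"].unique())
    seeds = np.random.SeedSequence(spec.seed).spawn(len(states))
    fits: dict[str, ModelFit] = {}
    for state, seed_seq in zip(states, seeds):
        sub = sample[sample["state_id"] == state]
        n_districts = sub["district_id"].nunique()
        n_clusters = sub["cluster_id"].nunique()
        seed = int(seed_seq.generate_state(1)[0] % (2**31))
        if n_clusters < 2:
            log.warning("state %s has a single small area; skipped", state)
            continue
        if n_districts >= 2:
            sub_spec = replace(spec, n_levels=3, seed=seed)
            chain = fit_mcmc(sub, sub_spec)
        else:
            sub_spec = replace(spec, n_levels=2, seed=seed)
            chain = fit_mcmc(sub, sub_spec)
            chain.single_district = True
        fits[state] = summarize_chain(chain)
    return fits
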