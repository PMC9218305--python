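"""Synthetic generation of nested child-level birth-outcome data.

The generator emulates the structure of a large Indian household survey:
children nested in small areas (survey clusters of ~22 households), small
areas in districts, districts in states.  Outcomes follow a 4-level
random-intercept logistic model with known ground truth, so every downstream
stage — recoding, MCMC fitting, variance partitioning, small-area estimation —
can be tested against parameters that are actually known.

A missingness stage reproduces the salient features of real birth-weight
data: a large marginal missing fraction, a socioeconomic gradient (poorer
clusters more likely to be missing), and whole clusters that are 100%
missing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SimulationTruth",
    "MissingnessSpec",
    "PROFILES",
    "generate_hierarchy",
    "simulate_outcomes",
    "apply_missingness",
    "write_records_csv",
    "read_records_csv",
    "write_truth_json",
    "read_truth_json",
]

SIZE_LABELS = (
    "very_small",
    "smaller_than_average",
    "average",
    "larger_than_average",
    "very_large",
)

# Design profiles.  "nfhs-small" is a scaled-down survey: ~30 states with a
# handful to a dozen districts each, 4-8 small areas per district, the
# survey's fixed take of 22 children per small area (~40k children in all).
PROFILES: dict[str, dict] = {
    "nfhs-small": dict(
        n_states=30,
        districts_per_state=(5, 15),
        clusters_per_district=(4, 8),
        children_per_cluster=22,
    ),
    "tiny": dict(
        n_states=4,
        districts_per_state=(2, 4),
        clusters_per_district=(3, 5),
        children_per_cluster=22,
    ),
}


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of the latent 4-level logistic model.

    ``beta0`` is the log-odds intercept; the three variances are the latent
    (logit-scale) variance components of state, district and small-area
    random intercepts.
    """

    beta0: float
    sigma2_state: float
    sigma2_district: float
    sigma2_cluster: float
    seed: int
    vsbs_ratio: float = 0.25

    def __post_init__(self) -> None:
        for name in ("sigma2_state", "sigma2_district", "sigma2_cluster"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class MissingnessSpec:
    """How to blank birth weight / size in the generated records.

    ``cluster_gradient`` is the log-odds shift in a child's missingness per
    unit of its cluster's deprivation score (centred at 0.5), so a positive
    gradient concentrates missingness in deprived clusters while the marginal
    rate stays at ``p_missing_weight``.  ``p_cluster_all_missing`` forces that
    share of clusters to 100% missing birth weight.
    """

    p_missing_weight: float = 0.0
    p_missing_size: float = 0.0
    cluster_gradient: float = 0.0
    p_cluster_all_missing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_missing_weight", "p_missing_size", "p_cluster_all_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _as_range(value, level: str) -> tuple[int, int]:
    if np.isscalar(value):
        lo = hi = int(value)
    else:
        lo, hi = int(value[0]), int(value[1])
        if lo > hi:
            raise ValueError(f"{level}: range low {lo} exceeds high {hi}")
    if lo < 1:
        raise ValueError(f"{level}: count must be >= 1, got {lo}")
    return lo, hi


def generate_hierarchy(
    n_states: int,
    districts_per_state,
    clusters_per_district,
    children_per_cluster,
    seed: int,
) -> pd.DataFrame:
    """Build a strictly nested (state, district, cluster, child) index.

    Per-level counts may be a single int or an inclusive ``(low, high)``
    range drawn uniformly.  One RNG stream per level is split from the master
    seed, so changing e.g. ``children_per_cluster`` does not perturb the
    district/cluster draw.

    Returns a DataFrame with one row per child and columns ``state_id``,
    ``district_id``, ``cluster_id``, ``child_id``.
    """
    if int(n_states) < 1:
        raise ValueError(f"n_states: count must be >= 1, got {n_states}")
    d_lo, d_hi = _as_range(districts_per_state, "districts_per_state")
    c_lo, c_hi = _as_range(clusters_per_district, "clusters_per_district")
    k_lo, k_hi = _as_range(children_per_cluster, "children_per_cluster")

    rng_d, rng_c, rng_k = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)
    ]
    n_states = int(n_states)

    rows_state, rows_district, rows_cluster, rows_child = [], [], [], []
    for s in range(n_states):
        sid = f"S{s + 1:02d}"
        n_d = int(rng_d.integers(d_lo, d_hi + 1))
        for d in range(n_d):
            did = f"{sid}-D{d + 1:02d}"
            n_c = int(rng_c.integers(c_lo, c_hi + 1))
            for c in range(n_c):
                cid = f"{did}-C{c + 1:03d}"
                n_k = int(rng_k.integers(k_lo, k_hi + 1))
                for k in range(n_k):
                    rows_state.append(sid)
                    rows_district.append(did)
                    rows_cluster.append(cid)
                    rows_child.append(f"{cid}-K{k + 1:02d}")
    return pd.DataFrame(
        {
            "state_id": rows_state,
            "district_id": rows_district,
            "cluster_id": rows_cluster,
            "child_id": rows_child,
        }
    )


def simulate_outcomes(hierarchy: pd.DataFrame, truth: SimulationTruth) -> pd.DataFrame:
    """Simulate one binary outcome per child from the 4-level latent model.

    Each state, district and cluster receives a Gaussian random intercept
    (variance ``sigma2_state`` / ``sigma2_district`` / ``sigma2_cluster``);
    the child's success probability is inverse-logit of their sum plus
    ``beta0``.  Birth weight and the 5-category reported size are then filled
    in consistently with the outcome: weight < 2500 g iff outcome 1, size in
    {very_small, smaller_than_average} iff outcome 1.  A share ``vsbs_ratio``
    of positive children is labelled very_small to exercise the severe-size
    path.  A uniform(0,1) cluster-level deprivation score is attached for the
    missingness stage.

    Residuals are drawn in sorted unit-ID order, so the output is invariant
    to the row order of ``hierarchy``.
    """
    if len(hierarchy) == 0:
        raise ValueError("hierarchy is empty")
    _check_nesting(hierarchy)

    ss = np.random.SeedSequence(truth.seed).spawn(5)
    rng_s, rng_d, rng_c, rng_y, rng_fill = [np.random.default_rng(s) for s in ss]

    h = hierarchy.sort_values("child_id", kind="stable").reset_index(drop=True)
    states = np.sort(h["state_id"].unique())
    districts = np.sort(h["district_id"].unique())
    clusters = np.sort(h["cluster_id"].unique())

    eff_s = dict(zip(states, rng_s.normal(0.0, np.sqrt(truth.sigma2_state), len(states))))
    eff_d = dict(zip(districts, rng_d.normal(0.0, np.sqrt(truth.sigma2_district), len(districts))))
    eff_c = dict(zip(clusters, rng_c.normal(0.0, np.sqrt(truth.sigma2_cluster), len(clusters))))

    psi = (
        truth.beta0
        + h["state_id"].map(eff_s).to_numpy()
        + h["district_id"].map(eff_d).to_numpy()
        + h["cluster_id"].map(eff_c).to_numpy()
    )
    p = expit(psi)
    y = (rng_y.random(len(h)) < p).astype(np.int64)

    # Magnitudes are only ever thresholded downstream, so uniform fills are
    # sufficient: LBW children 1200-2499 g, others 2500-4200 g.
    w = np.where(
        y == 1,
        rng_fill.uniform(1200.0, 2499.0, len(h)),
        rng_fill.uniform(2500.0, 4200.0, len(h)),
    ).round(0)

    u = rng_fill.random(len(h))
    size = np.where(
        y == 1,
        np.where(u < truth.vsbs_ratio, "very_small", "smaller_than_average"),
        # non-SBS split average / larger / very large at 0.8 / 0.15 / 0.05
        np.where(u < 0.8, "average", np.where(u < 0.95, "larger_than_average", "very_large")),
    )

    dep = dict(zip(clusters, rng_fill.random(len(clusters))))
    out = h.copy()
    out["outcome"] = y
    out["birth_weight_g"] = w
    out["birth_size"] = size
    out["deprivation_score"] = out["cluster_id"].map(dep).round(6)
    return out


def apply_missingness(records: pd.DataFrame, spec: MissingnessSpec) -> pd.DataFrame:
    """Blank birth weight / size fields according to ``spec``.

    Weight missingness is a per-child Bernoulli whose cluster-level log-odds
    are tilted by ``cluster_gradient * (deprivation - 0.5)``; the tilt
    intercept is solved numerically so the marginal rate stays at
    ``p_missing_weight``.  A fraction ``p_cluster_all_missing`` of clusters
    (chosen at random) is forced to 100% missing weight on top.  Half of the
    blanked size responses are recorded as ``dont_know`` rather than empty,
    mirroring how the survey codes them.
    """
    out = records.copy()
    rng = np.random.default_rng(spec.seed)
    n = len(out)

    if "deprivation_score" not in out.columns:
        clusters = np.sort(out["cluster_id"].unique())
        dep = dict(zip(clusters, rng.random(len(clusters))))
        out["deprivation_score"] = out["cluster_id"].map(dep)

    if spec.p_missing_weight > 0.0:
        p_c = _tilted_rates(out, spec.p_missing_weight, spec.cluster_gradient)
        miss_w = rng.random(n) < p_c
        out.loc[miss_w, "birth_weight_g"] = np.nan

    if spec.p_cluster_all_missing > 0.0:
        clusters = np.sort(out["cluster_id"].unique())
        n_force = int(round(spec.p_cluster_all_missing * len(clusters)))
        forced = rng.choice(clusters, size=n_force, replace=False)
        out.loc[out["cluster_id"].isin(forced), "birth_weight_g"] = np.nan

    if spec.p_missing_size > 0.0:
        miss_s = rng.random(n) < spec.p_missing_size
        dk = rng.random(n) < 0.5
        out.loc[miss_s & dk, "birth_size"] = "dont_know"
        out.loc[miss_s & ~dk, "birth_size"] = None
    return out


def _tilted_rates(records: pd.DataFrame, p: float, gradient: float) -> np.ndarray:
    """Per-child missingness probabilities with a cluster SES tilt.

    Solves for the intercept a such that mean(expit(a + g*(dep-0.5))) == p
    over the actual children, then returns the per-child probabilities.
    """
    x = gradient * (records["deprivation_score"].to_numpy() - 0.5)
    if gradient == 0.0 or p in (0.0, 1.0):
        return np.full(len(records), p)
    a = brentq(lambda a: expit(a + x).mean() - p, -40.0, 40.0)
    return expit(a + x)


def _check_nesting(df: pd.DataFrame) -> None:
    if df.groupby("cluster_id")["district_id"].nunique().max() > 1:
        raise ValueError("hierarchy not nested: a cluster maps to multiple districts")
    if df.groupby("district_id")["state_id"].nunique().max() > 1:
        raise ValueError("hierarchy not nested: a district maps to multiple states")


# ---------------------------------------------------------------------------
# Serialisation

CSV_COLUMNS = [
    "state_id",
    "district_id",
    "cluster_id",
    "child_id",
    "birth_weight_g",
    "birth_size",
    "deprivation_score",
]


def write_records_csv(records: pd.DataFrame, path) -> None:
    """Write the child-level CSV (empty field = missing, never '.')."""
    cols = [c for c in CSV_COLUMNS if c in records.columns]
    records[cols].to_csv(path, index=False, float_format="%.6g", na_rep="")


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"state_id": str, "district_id": str, "cluster_id": str, "child_id": str},
        keep_default_na=False,
        na_values=[""],
    )
    if "birth_weight_g" in df.columns:
        df["birth_weight_g"] = pd.to_numeric(df["birth_weight_g"], errors="raise")
    return df


def write_truth_json(truth: SimulationTruth, path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=2) + "\n")


def read_truth_json(path) -> SimulationTruth:
    return SimulationTruth(**json.loads(Path(path).read_text()))
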