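"""End-to-end analysis pipeline on one configuration.

``run_report`` chains every stage — simulate, apply missingness, recode,
fit the national 4-level model, fit state-specific models, partition
variance, estimate small-area/district prevalence, correlate, classify —
and writes a results directory of CSV/JSON files.  All randomness is split
from one master seed, and floats are written with a fixed format, so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit

from . import estimates, policy, vpc
from .mcmc import ModelSpec, fit_mcmc, fit_state_specific, summarize_chain
from .recode import add_outcomes, build_analysis_sample
from .simulate import (
    MissingnessSpec,
    SimulationTruth,
    apply_missingness,
    generate_hierarchy,
    simulate_outcomes,
    write_records_csv,
    write_truth_json,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_report"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

DEFAULT_CONFIG: dict = {
    "design": {
        "n_states": 6,
        "districts_per_state": [4, 8],
        "clusters_per_district": [4, 6],
        "children_per_cluster": 22,
    },
    "truth": {
        "prevalence": 0.176,
        "sigma2_state": 0.18,
        "sigma2_district": 0.07,
        "sigma2_cluster": 0.28,
    },
    "missingness": {
        "p_missing_weight": 0.254,
        "p_missing_size": 0.02,
        "cluster_gradient": 1.0,
        "p_cluster_all_missing": 0.02,
    },
    "outcome": "lbw",
    "model": {"burn_in": 500, "monitored": 5000, "thinning": 1},
    "state_fits": True,
    "aspirational_fraction": 0.175,
    "seed": 1,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge the default config with an optional YAML file and overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        cfg = _deep_merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")


def run_report(config: dict, outdir, seed: int | None = None) -> dict:
    """Run the full pipeline; returns the main result tables in memory.

    ``seed`` overrides ``config['seed']``.  Sub-seeds for the hierarchy,
    outcome simulation, missingness, model fitting and the synthetic
    aspirational flag are split deterministically from the master seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _deep_merge(DEFAULT_CONFIG, config)
    master = int(cfg["seed"] if seed is None else seed)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(master).spawn(5)]

    # --- simulate
    hierarchy = generate_hierarchy(**cfg["design"], seed=sub[0])
    tr = dict(cfg["truth"])
    beta0 = tr.pop("beta0", None)
    if beta0 is None:
        beta0 = float(logit(tr.pop("prevalence")))
    else:
        tr.pop("prevalence", None)
    truth = SimulationTruth(beta0=beta0, seed=sub[1], **tr)
    records = simulate_outcomes(hierarchy, truth)
    write_truth_json(truth, outdir / "truth.json")
    records = apply_missingness(records, MissingnessSpec(**cfg["missingness"], seed=sub[2]))
    write_records_csv(records, outdir / "data.csv")

    # --- recode
    recoded = add_outcomes(records)
    both = recoded.dropna(subset=["lbw", "sbs"])
    agreement = estimates.binary_agreement(both["lbw"], both["sbs"])
    (outdir / "agreement.json").write_text(json.dumps(agreement, indent=2) + "\n")
    sample, excl = build_analysis_sample(recoded, cfg["outcome"])
    excl.to_json(outdir / "exclusions.json")
    _write_csv(
        sample[
            ["state_id", "district_id", "cluster_id", "child_id", "outcome"]
        ],
        outdir / "sample.csv",
    )

    # --- fit national model
    spec = ModelSpec(n_levels=4, seed=sub[3], **cfg["model"])
    fit = summarize_chain(fit_mcmc(sample, spec))
    _write_csv(fit.scalars, outdir / "fit_scalars.csv")
    _write_csv(
        fit.resid_cluster.rename_axis("cluster_id").reset_index(),
        outdir / "resid_clusters.csv",
    )
    _write_csv(
        fit.resid_district.rename_axis("district_id").reset_index(),
        outdir / "resid_districts.csv",
    )
    _write_csv(
        fit.resid_state.rename_axis("state_id").reset_index(), outdir / "resid_states.csv"
    )

    # --- variance partition
    vpc_table = vpc.vpc_from_fit(fit)
    _write_csv(vpc_table, outdir / "vpc.csv")
    state_table = None
    if cfg["state_fits"]:
        fits = fit_state_specific(sample, spec)
        state_table = vpc.state_vpc_table(fits)
        _write_csv(state_table, outdir / "vpc_states.csv")

    # --- small-area estimation
    cluster_est = estimates.precision_weighted_small_area(fit)
    district_est = estimates.precision_weighted_district(fit)
    _write_csv(cluster_est, outdir / "cluster_estimates.csv")
    _write_csv(district_est, outdir / "district_estimates.csv")

    districts = np.sort(sample["district_id"].unique())
    rng_flag = np.random.default_rng(sub[4])
    flag = pd.Series(
        (rng_flag.random(len(districts)) < cfg["aspirational_fraction"]).astype(int),
        index=districts,
    )
    summaries = estimates.within_district_sd(cluster_est, district_est, aspirational=flag)
    _write_csv(summaries, outdir / "district_summary.csv")

    corr = pd.concat(
        [
            estimates.prevalence_sd_correlation(summaries),
            estimates.prevalence_sd_correlation(summaries, group_by_state=True),
        ],
        ignore_index=True,
    )
    _write_csv(corr, outdir / "correlation.csv")

    # --- policy classification
    classified = summaries.dropna(subset=["sd"]).reset_index(drop=True)
    policy_table = policy.build_policy_table(classified)
    _write_csv(policy_table, outdir / "policy_table.csv")
    ct = policy.cross_tab(
        policy_table.set_index("district_id")["prev_tertile"],
        policy_table.set_index("district_id")["sd_tertile"],
    )
    _write_csv(ct, outdir / "crosstab.csv")
    comparison = policy.compare_flag_groups(policy_table)
    _write_csv(comparison, outdir / "flag_comparison.csv")

    return {
        "truth": truth,
        "exclusions": excl,
        "fit": fit,
        "vpc": vpc_table,
        "state_vpc": state_table,
        "cluster_estimates": cluster_est,
        "district_summary": summaries,
        "correlation": corr,
        "policy_table": policy_table,
        "crosstab": ct,
        "agreement": agreement,
    }
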