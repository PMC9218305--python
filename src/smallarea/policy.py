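"""Tertile/decile classification of districts and group comparisons.

Districts are ranked on a measure (prevalence or within-district SD) and cut
into balanced rank groups — three tertiles (low/medium/high) or ten deciles —
with ties broken by stable district-ID order so the split is reproducible and
group sizes never differ by more than one.  The 3x3 prevalence-by-SD
cross-tabulation identifies districts that combine a high burden with high
small-area inequality; an optional "aspirational district" flag supports the
comparison of nationally prioritised districts with the rest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "tertile_classify",
    "decile_table",
    "cross_tab",
    "build_policy_table",
    "compare_flag_groups",
]

TERTILE_LABELS = ("low", "medium", "high")


def _balanced_rank_groups(values: pd.Series, n_groups: int) -> pd.Series:
    """Partition into ``n_groups`` contiguous rank groups of near-equal size.

    Values are sorted ascending with district-ID tie-break; group sizes are
    floor(n/g) with the remainder distributed to the highest groups (640
    districts -> tertiles of 213/213/214, deciles of 64 each).
    """
    v = values.dropna()
    tmp = pd.DataFrame({"val": v.to_numpy(), "key": v.index.to_numpy()})
    tmp = tmp.sort_values(["val", "key"], kind="stable")
    n = len(tmp)
    base, extra = divmod(n, n_groups)
    sizes = [base + (1 if g >= n_groups - extra else 0) for g in range(n_groups)]
    codes = np.repeat(np.arange(n_groups), sizes)
    return pd.Series(codes, index=tmp["key"].to_numpy(), name="group").reindex(
        values.index
    )


def tertile_classify(values: pd.Series) -> pd.Series:
    """Label each district low/medium/high by balanced ascending rank."""
    v = values.dropna()
    if len(v) < 3:
        raise ValueError(f"need >= 3 districts to form tertiles, got {len(v)}")
    codes = _balanced_rank_groups(values, 3)
    return codes.map(dict(enumerate(TERTILE_LABELS)))


def decile_table(values: pd.Series) -> pd.Series:
    """Assign each district a decile 1-10 by balanced ascending rank."""
    v = values.dropna()
    if len(v) < 10:
        raise ValueError(f"need >= 10 districts to form deciles, got {len(v)}")
    return _balanced_rank_groups(values, 10) + 1


def cross_tab(
    prev_tertiles: pd.Series,
    sd_tertiles: pd.Series,
    aspirational: pd.Series | None = None,
) -> pd.DataFrame:
    """3x3 counts and percentages of districts by prevalence and SD tertile.

    Long format: one row per (prevalence tertile, SD tertile) cell with
    ``count`` and ``pct`` of all classified districts; stratified by the
    aspirational flag when given.
    """
    if set(prev_tertiles.index) != set(sd_tertiles.index):
        only_p = set(prev_tertiles.index) - set(sd_tertiles.index)
        only_s = set(sd_tertiles.index) - set(prev_tertiles.index)
        raise ValueError(
            f"district keys differ: {sorted(only_p)[:3]} only in prevalence, "
            f"{sorted(only_s)[:3]} only in SD"
        )
    df = pd.DataFrame({"prev_tertile": prev_tertiles, "sd_tertile": sd_tertiles})
    strata = [("all", df)]
    if aspirational is not None:
        df["aspirational"] = aspirational.reindex(df.index)
        strata = [(str(k), v) for k, v in df.groupby("aspirational")]

    cells = pd.MultiIndex.from_product(
        [TERTILE_LABELS, TERTILE_LABELS], names=["prev_tertile", "sd_tertile"]
    )
    rows = []
    for label, sub in strata:
        counts = (
            sub.groupby(["prev_tertile", "sd_tertile"], observed=False)
            .size()
            .reindex(cells, fill_value=0)
        )
        for (p, s), cnt in counts.items():
            rows.append(
                {
                    "stratum": label,
                    "prev_tertile": p,
                    "sd_tertile": s,
                    "count": int(cnt),
                    "pct": 100.0 * cnt / len(sub),
                }
            )
    return pd.DataFrame(rows)


def build_policy_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Attach tertile and decile labels for prevalence and SD to districts.

    Expects a district-summary frame (district_id, state_id, prevalence_pct,
    sd, optional aspirational).  Districts lacking an SD keep missing SD
    classifications.
    """
    d = summaries.set_index("district_id")
    out = summaries.copy()
    out["prev_tertile"] = tertile_classify(d["prevalence_pct"]).to_numpy()
    out["sd_tertile"] = tertile_classify(d["sd"]).to_numpy()
    out["prev_decile"] = decile_table(d["prevalence_pct"]).to_numpy()
    out["sd_decile"] = decile_table(d["sd"]).to_numpy()
    return out


def compare_flag_groups(summaries: pd.DataFrame) -> pd.DataFrame:
    """Descriptive comparison of aspirational vs other districts.

    Per group: n, mean and SD of district prevalence and of within-district
    SD, plus a Mann-Whitney rank comparison of the two groups on each
    measure (statistic and attained level, reported descriptively).  Skipped
    when either group has fewer than 2 districts.
    """
    if "aspirational" not in summaries.columns:
        raise ValueError("summaries must carry an 'aspirational' flag column")
    rows = []
    groups = {k: v for k, v in summaries.groupby("aspirational")}
    for key, sub in sorted(groups.items()):
        rows.append(
            {
                "group": "aspirational" if key else "other",
                "n_districts": len(sub),
                "prev_mean": sub["prevalence_pct"].mean(),
                "prev_sd": sub["prevalence_pct"].std(),
                "wdsd_mean": sub["sd"].mean(),
                "wdsd_sd": sub["sd"].std(),
            }
        )
    out = pd.DataFrame(rows)
    if len(groups) == 2 and all(len(v) >= 2 for v in groups.values()):
        a, b = (groups[k] for k in sorted(groups))
        for col, label in [("prevalence_pct", "prev"), ("sd", "wdsd")]:
            res = mannwhitneyu(
                a[col].dropna(), b[col].dropna(), alternative="two-sided"
            )
            out[f"{label}_rank_stat"] = res.statistic
            out[f"{label}_rank_p"] = res.pvalue
    return out
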