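"""Outcome derivation and analysis-sample construction.

Birth weight is recoded into nested binary outcomes — low (< 2500 g), very
low (< 1500 g) and extremely low (< 1000 g) birth weight — and the mother's
5-category reported size at birth into small ("very small" or "smaller than
average") and very small ("very small" only) birth size.  Records with a
missing weight, or a missing/"don't know" size, have the corresponding
outcomes undefined and are excluded from that outcome's analysis sample;
clusters left with zero valid records are dropped and counted.  Every
exclusion is logged so counts can be audited: included + excluded = total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SIZE_LABELS

__all__ = [
    "WEIGHT_OUTCOMES",
    "SIZE_OUTCOMES",
    "OUTCOMES",
    "ExclusionLog",
    "derive_weight_outcomes",
    "derive_size_outcomes",
    "add_outcomes",
    "build_analysis_sample",
]

WEIGHT_OUTCOMES = {"lbw": 2500.0, "vlbw": 1500.0, "elbw": 1000.0}
SIZE_OUTCOMES = ("sbs", "vsbs")
OUTCOMES = tuple(WEIGHT_OUTCOMES) + SIZE_OUTCOMES

_SMALL = {"very_small", "smaller_than_average"}


@dataclass
class ExclusionLog:
    """Audit trail for one outcome's analysis sample."""

    outcome: str
    total: int
    excluded: dict[str, int] = field(default_factory=dict)
    included: int = 0
    clusters_total: int = 0
    clusters_dropped: int = 0

    def check_conservation(self) -> None:
        if self.included + sum(self.excluded.values()) != self.total:
            raise AssertionError("exclusion log does not conserve record counts")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def derive_weight_outcomes(birth_weight_g: pd.Series) -> pd.DataFrame:
    """Nested binary weight outcomes; missing weight leaves all undefined.

    Thresholds are strict: exactly 2500 g is not low birth weight.
    """
    w = pd.to_numeric(birth_weight_g, errors="raise")
    observed = w.notna()
    if (w[observed] <= 0).any():
        bad = w[observed & (w <= 0)].iloc[0]
        raise ValueError(f"non-positive birth weight: {bad}")
    out = pd.DataFrame(index=w.index)
    for name, cut in WEIGHT_OUTCOMES.items():
        out[name] = pd.array(np.where(w < cut, 1, 0), dtype="Int64")
        out.loc[~observed, name] = pd.NA
    return out


def derive_size_outcomes(birth_size: pd.Series) -> pd.DataFrame:
    """Binary size outcomes from the 5-category report.

    ``sbs`` is 1 for very_small / smaller_than_average, 0 for the normal
    categories; ``vsbs`` is 1 only for very_small.  ``dont_know`` and missing
    leave both undefined; any other label is rejected.
    """
    s = birth_size.astype("object")
    observed = s.notna() & (s != "dont_know")
    bad = set(s[observed].unique()) - set(SIZE_LABELS)
    if bad:
        raise ValueError(f"unrecognised birth_size label(s): {sorted(bad)}")
    out = pd.DataFrame(index=s.index)
    out["sbs"] = pd.array(np.where(s.isin(_SMALL), 1, 0), dtype="Int64")
    out["vsbs"] = pd.array(np.where(s == "very_small", 1, 0), dtype="Int64")
    out.loc[~observed, ["sbs", "vsbs"]] = pd.NA
    return out


def add_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Attach all five derived outcome columns to a child-level table."""
    out = records.copy()
    out[list(WEIGHT_OUTCOMES)] = derive_weight_outcomes(records["birth_weight_g"])
    out[list(SIZE_OUTCOMES)] = derive_size_outcomes(records["birth_size"])
    return out


def build_analysis_sample(
    records: pd.DataFrame, outcome: str
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Restrict to records where ``outcome`` is defined; drop empty clusters.

    Returns the analysis sample (with an ``outcome`` column holding the
    chosen flag) and an :class:`ExclusionLog`.  Clusters whose records are
    all excluded are dropped and counted; clusters reduced to a single valid
    record are retained.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    df = records if outcome in records.columns else add_outcomes(records)

    log = ExclusionLog(outcome=outcome, total=len(df))
    log.clusters_total = df["cluster_id"].nunique()
    defined = df[outcome].notna()
    reason = (
        "missing_birth_weight" if outcome in WEIGHT_OUTCOMES else "missing_or_dont_know_birth_size"
    )
    log.excluded[reason] = int((~defined).sum())

    sample = df.loc[defined].copy()
    log.included = len(sample)
    log.clusters_dropped = log.clusters_total - sample["cluster_id"].nunique()
    log.check_conservation()

    if sample.empty:
        raise ValueError(f"analysis sample for {outcome!r} is empty; log: {log}")
    sample["outcome"] = sample[outcome].astype(np.int64)
    return sample.reset_index(drop=True), log
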