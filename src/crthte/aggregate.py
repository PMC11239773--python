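"""Cluster-level aggregation of individual-level data.

Builds the cluster-level analysis dataset: the mean booster outcome per
cluster and two cluster-level encodings of the individual-level race
indicator — the mean-centered within-cluster proportion, and a binary
indicator that the proportion exceeds a threshold (default 0.5).  Both
encodings are pure functions of the per-cluster proportion.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "aggregate",
    "center_proportions",
    "dichotomize_proportions",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "cluster_id",
    "region",
    "urban",
    "arm",
    "n_staff",
    "mean_outcome",
    "race_proportion",
]


def aggregate(individuals: pd.DataFrame, clusters: pd.DataFrame) -> pd.DataFrame:
    """Collapse individual records to one row per cluster.

    ``mean_outcome`` and ``race_proportion`` are within-cluster means of
    the binary outcome and race indicator.  Requires outcomes and arms
    to be filled in; every cluster must have at least one individual.
    """
    if "outcome" not in individuals or "arm" not in individuals:
        raise ValueError("individuals must carry 'arm' and 'outcome' columns")
    counts = individuals.groupby("cluster_id").size()
    missing = set(clusters["cluster_id"]) - set(counts.index)
    if missing:
        raise ValueError(f"clusters with zero individuals: {sorted(missing)}")

    grouped = individuals.groupby("cluster_id", sort=True).agg(
        mean_outcome=("outcome", "mean"),
        race_proportion=("race", "mean"),
        n_staff=("outcome", "size"),
        arm=("arm", "first"),
    )
    summary = (
        clusters[["cluster_id", "region", "urban"]]
        .merge(grouped.reset_index(), on="cluster_id", how="inner")
        .sort_values("cluster_id", ignore_index=True)
    )
    return summary[SUMMARY_COLUMNS]


def center_proportions(summaries: pd.DataFrame) -> pd.DataFrame:
    """Add the mean-centered race proportion.

    Centers each cluster's proportion at the unweighted mean over the K
    clusters (recomputed per dataset), so the centered values sum to
    zero and regression coefficients are interpreted as differences from
    the study-mean composition.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 clusters to center proportions")
    out = summaries.copy()
    out["race_proportion_centered"] = (
        out["race_proportion"] - out["race_proportion"].mean()
    )
    return out


def dichotomize_proportions(summaries: pd.DataFrame, t: float = 0.5) -> pd.DataFrame:
    """Add the high/low race-composition indicator.

    ``race_indicator`` is 1 iff the cluster's race proportion is
    strictly greater than ``t`` (a proportion exactly at the threshold
    counts as low; with 100 staff per cluster the boundary is
    attainable).
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {t}")
    out = summaries.copy()
    out["race_indicator"] = (out["race_proportion"] > t).astype(int)
    return out
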