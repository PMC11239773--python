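"""Constrained randomization of clusters to two arms.

Clusters are randomized within region strata (half of each stratum to
the intervention arm) while balancing the urban/rural composition of the
two arms: candidate allocations are drawn (or exhaustively enumerated
when feasible), scored on urban imbalance, and one allocation is drawn
uniformly from the best-balanced accepted set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["Allocation", "balance_score", "constrained_randomize"]


@dataclass(frozen=True)
class Allocation:
    """A cluster-to-arm assignment with provenance of how it was chosen."""

    arms: Mapping[int, int]
    score: int | None = None
    n_candidates: int | None = None
    n_accepted: int | None = None
    rule: str | None = None
    enumerated: bool = False

    def arm_array(self, cluster_ids) -> np.ndarray:
        return np.asarray([self.arms[int(c)] for c in cluster_ids], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.arms)
        return pd.DataFrame(
            {"cluster_id": ids, "arm": [self.arms[c] for c in ids]}
        )


def balance_score(allocation: Allocation, clusters: pd.DataFrame) -> int:
    """Urban imbalance of an allocation, summed over region strata.

    For each region, the absolute difference between the number of urban
    clusters assigned to arm 1 and to arm 0; lower is better, 0 means
    exact urban balance in both regions.
    """
    missing = [
        int(c) for c in clusters["cluster_id"] if int(c) not in allocation.arms
    ]
    if missing:
        raise ValueError(f"allocation missing clusters {missing}")
    arm = allocation.arm_array(clusters["cluster_id"])
    urban = clusters["urban"].to_numpy()
    region = clusters["region"].to_numpy()
    score = 0
    for r in np.unique(region):
        in_r = region == r
        u1 = int(np.sum(urban[in_r] & (arm[in_r] == 1)))
        u0 = int(np.sum(urban[in_r] & (arm[in_r] == 0)))
        score += abs(u1 - u0)
    return score


def _stratum_candidate_count(k: int) -> int:
    """Number of half-split arm-1 subsets of a stratum of size k."""
    if k % 2 == 0:
        return math.comb(k, k // 2)
    return math.comb(k, k // 2) + math.comb(k, k // 2 + 1)


def _enumerate_stratum(ids: np.ndarray) -> list[frozenset]:
    k = len(ids)
    sizes = [k // 2] if k % 2 == 0 else [k // 2, k // 2 + 1]
    subsets: list[frozenset] = []
    for m in sizes:
        subsets.extend(frozenset(c) for c in combinations(ids.tolist(), m))
    return subsets


def constrained_randomize(
    clusters: pd.DataFrame,
    n_candidates: int = 50_000,
    acceptance: str = "min",
    q: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> Allocation:
    """Constrained randomization stratified by region, balancing urban status.

    Candidate allocations assign half of each region stratum to arm 1
    (for odd strata, the leftover cluster's arm is chosen uniformly).
    When the total number of stratified allocations is at most
    ``n_candidates`` they are enumerated exhaustively; otherwise
    ``n_candidates`` are sampled uniformly with replacement.  The
    accepted set is either every candidate achieving the minimum
    observed balance score (``acceptance="min"``, the default) or the
    best ``q`` fraction (``acceptance="quantile"``).  Accepted
    candidates are de-duplicated and one is returned uniformly at
    random.
    """
    if acceptance not in ("min", "quantile"):
        raise ValueError(f"unknown acceptance rule {acceptance!r}")
    if acceptance == "quantile" and not 0.0 < q <= 1.0:
        raise ValueError(f"q must lie in (0, 1], got {q}")
    if n_candidates < 1:
        raise ValueError("n_candidates must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    region = clusters["region"].to_numpy()
    urban = clusters["urban"].to_numpy()
    ids = clusters["cluster_id"].to_numpy()
    region_values = np.unique(region)
    strata = []
    for r in region_values:
        idx = np.flatnonzero(region == r)
        if idx.size < 2:
            raise ValueError(
                f"region {r} has {idx.size} cluster(s); need >= 2 to half-split"
            )
        strata.append(idx)

    total = 1
    for idx in strata:
        total *= _stratum_candidate_count(len(idx))

    if total <= n_candidates:
        candidates, scores = _enumerate_candidates(strata, ids, urban)
        keep, cutoff = _acceptance_mask(scores, acceptance, q)
        accepted = _dedup_rows(candidates[keep])
        enumerated = True
        n_drawn = total
    else:
        accepted, cutoff = _sample_accepted(
            strata, ids, urban, n_candidates, acceptance, q, rng
        )
        enumerated = False
        n_drawn = n_candidates

    choice = accepted[rng.integers(len(accepted))]

    arms = {int(c): int(a) for c, a in zip(ids, choice)}
    return Allocation(
        arms=arms,
        score=cutoff,
        n_candidates=n_drawn,
        n_accepted=len(accepted),
        rule=acceptance,
        enumerated=enumerated,
    )


def _enumerate_candidates(strata, ids, urban):
    """Exhaustively enumerate stratified half-split allocations."""
    per_stratum = [_enumerate_stratum(ids[idx]) for idx in strata]
    n_total = math.prod(len(s) for s in per_stratum)
    K = len(ids)
    candidates = np.zeros((n_total, K), dtype=np.int8)
    id_to_col = {int(c): j for j, c in enumerate(ids)}
    for row, combo in enumerate(product(*per_stratum)):
        for subset in combo:
            for c in subset:
                candidates[row, id_to_col[int(c)]] = 1
    scores = _score_candidates(candidates, strata, urban)
    return candidates, scores


def _dedup_rows(mat: np.ndarray) -> np.ndarray:
    """Drop duplicate 0/1 rows (bit-packed comparison, order-insensitive)."""
    if len(mat) < 2:
        return mat
    packed = np.ascontiguousarray(np.packbits(mat, axis=1))
    view = packed.view(np.dtype((np.void, packed.shape[1]))).ravel()
    _, idx = np.unique(view, return_index=True)
    return mat[np.sort(idx)]


def _acceptance_mask(scores, acceptance, q):
    if acceptance == "min":
        cutoff = int(scores.min())
        return scores == cutoff, cutoff
    k = max(1, math.ceil(q * len(scores)))
    cutoff = int(np.partition(scores, k - 1)[k - 1])
    return scores <= cutoff, cutoff


def _uniform_subsets(k, sizes, rng):
    """Boolean matrix whose rows are uniform random subsets of 0..k-1.

    Row i contains exactly ``sizes[i]`` members; each row is an
    independent uniform permutation truncated by rank.
    """
    sizes = np.asarray(sizes)
    if k == 0:
        return np.zeros((len(sizes), 0), dtype=bool)
    perm = rng.permuted(
        np.tile(np.arange(k, dtype=np.int16), (len(sizes), 1)), axis=1
    )
    return perm < sizes[:, None]


def _sample_accepted(strata, ids, urban, n_candidates, acceptance, q, rng):
    """Sample candidates uniformly with replacement; return the accepted set.

    Sampling a uniform stratified half-split allocation is equivalent to
    drawing, per stratum, the arm-1 urban count from a hypergeometric
    distribution and then a uniform subset of urban and rural clusters
    conditional on that count — and the balance score depends on the
    candidate only through the urban counts.  So all ``n_candidates``
    scores are drawn first (cheap), and full allocations are
    materialized only for the accepted candidates, which preserves the
    distribution of the naive materialize-everything procedure exactly.
    Odd strata flip a fair coin per candidate for the leftover cluster.
    """
    K = len(ids)
    scores = np.zeros(n_candidates, dtype=np.int64)
    u1s, ms = [], []
    for idx in strata:
        k = idx.size
        U = int(urban[idx].sum())
        if k % 2 == 0:
            m = np.full(n_candidates, k // 2)
        else:
            m = k // 2 + rng.integers(0, 2, size=n_candidates)
        u1 = rng.hypergeometric(U, k - U, m)
        scores += np.abs(2 * u1 - U)
        u1s.append(u1)
        ms.append(m)

    keep, cutoff = _acceptance_mask(scores, acceptance, q)
    kept = np.flatnonzero(keep)
    accepted = np.zeros((kept.size, K), dtype=np.int8)
    for idx, u1, m in zip(strata, u1s, ms):
        is_urban = urban[idx].astype(bool)
        urb_cols = idx[is_urban]
        rur_cols = idx[~is_urban]
        accepted[:, urb_cols] = _uniform_subsets(urb_cols.size, u1[kept], rng)
        accepted[:, rur_cols] = _uniform_subsets(
            rur_cols.size, m[kept] - u1[kept], rng
        )
    accepted = _dedup_rows(accepted)
    return accepted, cutoff


def _score_candidates(candidates, strata, urban):
    scores = np.zeros(len(candidates), dtype=np.int64)
    for idx in strata:
        u = urban[idx].astype(np.int64)
        u_total = int(u.sum())
        u1 = candidates[:, idx].astype(np.int64) @ u
        scores += np.abs(2 * u1 - u_total)
    return scores
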