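"""Synthetic cluster-randomized-trial data generation.

Emulates a two-region trial of long-term care centers: ``K`` clusters
split across two regions, each cluster urban/suburban or rural, with
``n_staff`` staff members per cluster.  Each staff member carries a
binary self-reported race indicator, an optional already-boosted-at-
baseline flag, and a binary booster-vaccination outcome drawn from a
linear probability model (see :mod:`crthte.scenarios`).

RNG contract: each function consumes the supplied generator in table
order (clusters by ascending ``cluster_id``, individuals by row), so a
fixed seed reproduces a dataset bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scenarios import TrueCoefficients, validate_support

__all__ = [
    "CLUSTER_COLUMNS",
    "INDIVIDUAL_COLUMNS",
    "generate_clusters",
    "generate_individuals",
    "assign_baseline_boosted",
    "generate_outcomes",
]

CLUSTER_COLUMNS = ["cluster_id", "region", "urban", "n_staff"]
INDIVIDUAL_COLUMNS = [
    "cluster_id",
    "region",
    "urban",
    "race",
    "baseline_boosted",
    "arm",
    "outcome",
]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_clusters(
    K: int,
    region_split: float = 0.5,
    urban_scheme: str = "fixed",
    p_urban: float = 0.5,
    n_staff: int = 100,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Generate the cluster frame: region and urban/rural composition.

    Exactly ``round(K * region_split)`` clusters land in region 1, the
    rest in region 0.  Under ``urban_scheme="fixed"`` each region gets
    exactly ``round(p_urban * K_r)`` urban clusters (deterministic,
    balanced composition — the base study setting); under
    ``"heterogeneous"`` every cluster draws its urban flag independently
    as Bernoulli(``p_urban``).
    """
    if K < 4:
        raise ValueError(f"need K >= 4 to randomize within two regions, got {K}")
    if not 0.0 < region_split < 1.0:
        raise ValueError(f"region_split must lie in (0, 1), got {region_split}")
    if not 0.0 <= p_urban <= 1.0:
        raise ValueError(f"p_urban must lie in [0, 1], got {p_urban}")
    if urban_scheme not in ("fixed", "heterogeneous"):
        raise ValueError(f"unknown urban_scheme {urban_scheme!r}")
    if n_staff < 1:
        raise ValueError(f"n_staff must be positive, got {n_staff}")
    rng = _as_rng(rng)

    n_region1 = int(round(K * region_split))
    if n_region1 in (0, K):
        raise ValueError("region_split leaves one region empty")
    region = np.zeros(K, dtype=np.int64)
    region[K - n_region1:] = 1

    urban = np.zeros(K, dtype=np.int64)
    for r in (0, 1):
        idx = np.flatnonzero(region == r)
        if urban_scheme == "fixed":
            n_urban = int(round(p_urban * idx.size))
            urban[idx[:n_urban]] = 1
        else:
            urban[idx] = (rng.random(idx.size) < p_urban).astype(np.int64)

    return pd.DataFrame(
        {
            "cluster_id": np.arange(1, K + 1, dtype=np.int64),
            "region": region,
            "urban": urban,
            "n_staff": np.full(K, n_staff, dtype=np.int64),
        }
    )


def generate_individuals(
    clusters: pd.DataFrame,
    race_scheme: str = "fixed",
    p_race: float = 0.5,
    beta_concentration: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Generate one row per staff member with a binary race indicator.

    Under ``race_scheme="fixed"`` every individual draws race as
    Bernoulli(``p_race``) i.i.d.  Under ``"heterogeneous"`` each cluster
    first draws its own prevalence from a Beta distribution with mean
    ``p_race`` and concentration ``beta_concentration`` (a + b), then
    individuals draw Bernoulli at the cluster prevalence — the standard
    beta-binomial over-dispersion device.  Larger concentration
    approaches the fixed scheme.
    """
    if not 0.0 < p_race < 1.0:
        raise ValueError(f"p_race must lie in (0, 1), got {p_race}")
    if race_scheme not in ("fixed", "heterogeneous"):
        raise ValueError(f"unknown race_scheme {race_scheme!r}")
    if beta_concentration <= 0:
        raise ValueError(
            f"beta_concentration must be positive, got {beta_concentration}"
        )
    rng = _as_rng(rng)

    n_staff = clusters["n_staff"].to_numpy()
    K = len(clusters)
    if race_scheme == "fixed":
        p_c = np.full(K, p_race)
    else:
        a = p_race * beta_concentration
        b = (1.0 - p_race) * beta_concentration
        p_c = rng.beta(a, b, size=K)

    total = int(n_staff.sum())
    per_indiv_p = np.repeat(p_c, n_staff)
    race = (rng.random(total) < per_indiv_p).astype(np.int64)

    individuals = pd.DataFrame(
        {
            "cluster_id": np.repeat(clusters["cluster_id"].to_numpy(), n_staff),
            "region": np.repeat(clusters["region"].to_numpy(), n_staff),
            "urban": np.repeat(clusters["urban"].to_numpy(), n_staff),
            "race": race,
            "baseline_boosted": np.zeros(total, dtype=np.int64),
        }
    )
    return individuals


def assign_baseline_boosted(
    individuals: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Flag a random subset of staff as already boosted at baseline.

    Flags are independent Bernoulli(``fraction``) draws, independent of
    race, urban status and region.  Flagged individuals are forced to
    outcome 1 downstream.  ``fraction=0`` reproduces the base mechanism
    exactly (no RNG draws are consumed in that case).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    out = individuals.copy()
    if fraction == 0.0:
        out["baseline_boosted"] = 0
        return out
    rng = _as_rng(rng)
    out["baseline_boosted"] = (rng.random(len(out)) < fraction).astype(np.int64)
    return out


def generate_outcomes(
    individuals: pd.DataFrame,
    clusters: pd.DataFrame,
    allocation,
    coefs: TrueCoefficients,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw booster outcomes from the linear probability model.

    Attaches each cluster's arm from ``allocation``, computes the linear
    predictor per individual, and draws Y ~ Bernoulli(p); individuals
    flagged as baseline-boosted get Y = 1 regardless.  One uniform draw
    is consumed per individual in row order, including the baseline-
    boosted (keeps the stream alignment independent of the flags).
    """
    violations = validate_support(coefs)
    if violations:
        raise ValueError(
            f"generating coefficients invalid on support: {violations[0]}"
        )
    rng = _as_rng(rng)

    cluster_ids = clusters["cluster_id"].to_numpy()
    missing = [int(c) for c in cluster_ids if c not in allocation.arms]
    if missing:
        raise ValueError(f"allocation missing clusters {missing}")

    out = individuals.copy()
    arm_map = {int(c): int(a) for c, a in allocation.arms.items()}
    out["arm"] = out["cluster_id"].map(arm_map).astype(np.int64)

    a = out["arm"].to_numpy()
    urban = out["urban"].to_numpy()
    race = out["race"].to_numpy()
    region = out["region"].to_numpy()
    p = (
        coefs.beta0
        + coefs.beta_trt * a
        + coefs.beta_urban * urban
        + coefs.beta_race * race
        + coefs.beta_region * region
        + coefs.beta_trt_urban * a * urban
        + coefs.beta_trt_race * a * race
    )
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("implied outcome probability outside [0, 1]")

    y = (rng.random(len(out)) < p).astype(np.int64)
    y[out["baseline_boosted"].to_numpy() == 1] = 1
    out["outcome"] = y
    return out[INDIVIDUAL_COLUMNS]
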