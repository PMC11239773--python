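"""Model grid, least squares, cluster-robust variance and Wald tests.

The analysis models are linear (identity-link) regressions of the
binary individual-level outcome or the continuous cluster-level mean
outcome, so coefficients are risk differences (individual level) or
differences in cluster mean proportions (cluster level).  Inference
uses the cluster-robust sandwich variance with an independence working
structure — for individual-level data the meat sums residual
cross-products within clusters; for cluster-level data each cluster is
its own unit, reducing to the heteroskedasticity-robust (HC0) form.  A
small-sample multiplier K/(K-2) is applied to the covariance because
two variables (region, urban status) are used in constrained
randomization.  Wald tests compare estimate/SE to a standard normal
reference by default (a t(K-2) reference is available).

Sixteen models form the grid: individual-level models 1a-1f and
cluster-level models 2a-2j.  All include intervention, urban status and
region (the randomization factors); they differ in whether they adjust
for self-reported race (raw binary at the individual level; centered
proportion or high/low indicator at the cluster level) and which
intervention interactions they allow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateDesignError",
    "ModelSpec",
    "MODEL_GRID",
    "build_design_matrix",
    "fit_ols",
    "cluster_sandwich_variance",
    "apply_small_sample_correction",
    "wald_tests",
    "FitResult",
    "fit_model",
]


class DegenerateDesignError(ValueError):
    """Raised when a requested design is degenerate for a given dataset.

    Degeneracy (a constant requested column, or rank deficiency) is a
    property of the simulated dataset, not a bug: the caller records it
    and excludes the dataset from that model's denominators.
    """


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model grid.

    ``level`` is "individual" or "cluster"; ``race_encoding`` applies at
    the cluster level only ("proportion" = mean-centered proportion,
    "indicator" = high/low threshold indicator) — individual-level
    models use the raw binary indicator.  HTE by race requires race
    adjustment; every model includes intervention, urban and region.
    """

    model_id: str
    level: str
    adjust_race: bool = False
    race_encoding: str = "none"
    hte_urban: bool = False
    hte_race: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("individual", "cluster"):
            raise ValueError(f"level must be individual|cluster, got {self.level!r}")
        if self.hte_race and not self.adjust_race:
            raise ValueError("hte_race requires adjust_race")
        if self.level == "cluster" and self.adjust_race and self.race_encoding not in (
            "proportion",
            "indicator",
        ):
            raise ValueError(
                "cluster-level race adjustment needs race_encoding proportion|indicator"
            )
        if self.level == "individual" and self.race_encoding != "none":
            raise ValueError("individual-level models use the raw binary race variable")


def _build_grid() -> dict[str, ModelSpec]:
    grid: dict[str, ModelSpec] = {}
    # Individual level: base, +A:urban, +race, +race+A:urban, +race+A:race,
    # +race+both interactions.
    individual = {
        "1a": (False, False, False),
        "1b": (False, True, False),
        "1c": (True, False, False),
        "1d": (True, True, False),
        "1e": (True, False, True),
        "1f": (True, True, True),
    }
    for mid, (race, hu, hr) in individual.items():
        grid[mid] = ModelSpec(
            model_id=mid, level="individual", adjust_race=race,
            hte_urban=hu, hte_race=hr,
        )
    # Cluster level: same ladder, with race encoded as the centered
    # proportion (2c/2e/2g/2i) or the >0.5 indicator (2d/2f/2h/2j).
    cluster = {
        "2a": (False, "none", False, False),
        "2b": (False, "none", True, False),
        "2c": (True, "proportion", False, False),
        "2d": (True, "indicator", False, False),
        "2e": (True, "proportion", True, False),
        "2f": (True, "indicator", True, False),
        "2g": (True, "proportion", False, True),
        "2h": (True, "indicator", False, True),
        "2i": (True, "proportion", True, True),
        "2j": (True, "indicator", True, True),
    }
    for mid, (race, enc, hu, hr) in cluster.items():
        grid[mid] = ModelSpec(
            model_id=mid, level="cluster", adjust_race=race,
            race_encoding=enc, hte_urban=hu, hte_race=hr,
        )
    return grid


MODEL_GRID: dict[str, ModelSpec] = _build_grid()

_CLUSTER_RACE_COLUMN = {
    "proportion": "race_proportion_centered",
    "indicator": "race_indicator",
}


def build_design_matrix(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, cluster_ids, column_names) for one model.

    Column order: intercept, intervention, urban, region, [race
    encoding], [intervention x urban], [intervention x race].
    Interactions are elementwise products of the already-built
    main-effect columns.  Raises :class:`DegenerateDesignError` if any
    requested non-intercept column is constant in this dataset.
    """
    if spec.level == "individual":
        y = data["outcome"].to_numpy(dtype=float)
        race_col = "race"
    else:
        y = data["mean_outcome"].to_numpy(dtype=float)
        race_col = _CLUSTER_RACE_COLUMN.get(spec.race_encoding)
        if spec.adjust_race and race_col not in data:
            raise ValueError(
                f"model {spec.model_id} needs column {race_col!r}; aggregate the "
                "race encodings first"
            )
    cluster_ids = data["cluster_id"].to_numpy()

    n = len(data)
    columns = [np.ones(n)]
    names = ["intercept"]
    a = data["arm"].to_numpy(dtype=float)
    columns.append(a)
    names.append("intervention")
    columns.append(data["urban"].to_numpy(dtype=float))
    names.append("urban")
    columns.append(data["region"].to_numpy(dtype=float))
    names.append("region")
    if spec.adjust_race:
        race = data[race_col].to_numpy(dtype=float)
        columns.append(race)
        names.append("race")
    if spec.hte_urban:
        columns.append(a * data["urban"].to_numpy(dtype=float))
        names.append("trt_x_urban")
    if spec.hte_race:
        columns.append(a * race)
        names.append("trt_x_race")

    X = np.column_stack(columns)
    degenerate = [
        name
        for name, col in zip(names[1:], X.T[1:])
        if np.ptp(col) == 0.0
    ]
    if degenerate:
        raise DegenerateDesignError(
            f"model {spec.model_id}: constant column(s) {degenerate}"
        )
    return X, y, cluster_ids, names


def fit_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary least squares; returns (estimates, residuals).

    Raises :class:`DegenerateDesignError` on rank deficiency.
    """
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateDesignError(
            f"design is rank deficient ({rank} < {X.shape[1]})"
        )
    residuals = y - X @ beta
    return beta, residuals


def cluster_sandwich_variance(
    X: np.ndarray, residuals: np.ndarray, cluster_ids: np.ndarray
) -> np.ndarray:
    """Cluster-robust sandwich covariance with independence working structure.

    (X'X)^{-1} [ sum_c X_c' r_c r_c' X_c ] (X'X)^{-1}, summing over
    clusters.  With one observation per cluster this is exactly the HC0
    heteroskedasticity-robust covariance.
    """
    order = np.argsort(cluster_ids, kind="stable")
    Xs = X[order]
    rs = residuals[order]
    ids = np.asarray(cluster_ids)[order]
    starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    scores = np.add.reduceat(Xs * rs[:, None], starts, axis=0)  # (K, p)
    bread = np.linalg.inv(X.T @ X)
    meat = scores.T @ scores
    return bread @ meat @ bread


def apply_small_sample_correction(cov: np.ndarray, K: int) -> np.ndarray:
    """Scale the covariance by K/(K-2).

    Two variables (region and urban status) are used in constrained
    randomization, hence the loss of two degrees of freedom.
    """
    if K <= 2:
        raise ValueError(f"need K > 2 for the K/(K-2) correction, got {K}")
    return cov * (K / (K - 2))


def wald_tests(
    estimates: np.ndarray,
    cov: np.ndarray,
    names: Sequence[str],
    alpha: float = 0.05,
    reference: str = "normal",
    df: int | None = None,
) -> pd.DataFrame:
    """Two-sided Wald tests per coefficient from the corrected covariance.

    statistic = estimate / SE; p-values from the standard normal (or
    t(df) when ``reference="t"``); reject iff p < alpha.  A zero SE
    leaves the statistic and p-value undefined and flags the row as
    degenerate.
    """
    # clip float noise: the sandwich is PSD, so a negative diagonal entry can
    # only be rounding error (near-singular fits at small K)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        statistic = np.where(se > 0, estimates / se, np.nan)
    if reference == "normal":
        p = 2.0 * stats.norm.sf(np.abs(statistic))
    elif reference == "t":
        if df is None or df < 1:
            raise ValueError("t reference needs positive df")
        p = 2.0 * stats.t.sf(np.abs(statistic), df=df)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return pd.DataFrame(
        {
            "coefficient": list(names),
            "estimate": estimates,
            "se": se,
            "statistic": statistic,
            "p": p,
            "reject": (p < alpha) & (se > 0),
            "degenerate": se == 0.0,
        }
    )


@dataclass
class FitResult:
    """One model fit on one dataset: the Wald table or a degeneracy record."""

    model_id: str
    n_clusters: int
    table: pd.DataFrame | None = None
    degenerate: bool = False
    message: str = ""


def fit_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
    reference: str = "normal",
) -> FitResult:
    """Fit one grid model with cluster-robust, small-sample-corrected inference.

    A degenerate design for this dataset (constant requested column,
    rank deficiency) is recorded in the result rather than raised, so
    a simulation study can tally and exclude it.
    """
    K = int(pd.unique(data["cluster_id"]).size)
    try:
        X, y, cluster_ids, names = build_design_matrix(data, spec)
        beta, residuals = fit_ols(X, y)
    except DegenerateDesignError as err:
        return FitResult(
            model_id=spec.model_id, n_clusters=K, degenerate=True, message=str(err)
        )
    cov = cluster_sandwich_variance(X, residuals, cluster_ids)
    cov = apply_small_sample_correction(cov, K)
    table = wald_tests(
        beta, cov, names, alpha=alpha, reference=reference,
        df=K - 2 if reference == "t" else None,
    )
    return FitResult(model_id=spec.model_id, n_clusters=K, table=table)
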