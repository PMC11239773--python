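"""Simulation engine: scenarios x K x models x replications.

Each replication builds one dataset (clusters -> individuals ->
constrained randomization -> outcomes -> cluster aggregation), fits the
requested analysis models, and records estimates and Wald tests.  The
study summarizes, per (scenario, K, model, coefficient): the rejection
proportion (type-I error under a true null, power otherwise) with its
Monte-Carlo standard error, the mean and SD of estimates, and bias
against the generating coefficient where one exists.

Reproducibility: per-replication seeds derive deterministically from
(master_seed, scenario, K, replication index) via a seed sequence, so
every cell is independently reproducible and results do not depend on
the worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .aggregate import aggregate, center_proportions, dichotomize_proportions
from .estimation import MODEL_GRID, fit_model
from .randomize import constrained_randomize
from .scenarios import ScenarioSpec, TrueCoefficients, build_coefficients
from .simulate import (
    assign_baseline_boosted,
    generate_clusters,
    generate_individuals,
    generate_outcomes,
)

__all__ = [
    "StudyGrid",
    "scenario_key",
    "replication_seed",
    "simulate_dataset",
    "run_replication",
    "run_study",
    "summarize",
    "generating_truth",
    "compare_power",
]

RAW_COLUMNS = [
    "scenario",
    "K",
    "rep",
    "model_id",
    "coefficient",
    "estimate",
    "se",
    "statistic",
    "p",
    "reject",
    "degenerate",
]


@dataclass(frozen=True)
class StudyGrid:
    """Full factorial study configuration with the base-study defaults.

    Defaults encode the base simulated trial: two equal regions, equal
    urban/rural composition, 100 staff per cluster, race prevalence
    0.5, 50,000 candidate allocations with a minimum-imbalance
    acceptance rule, 1000 replications per cell, and all 16 models.
    """

    scenarios: tuple[ScenarioSpec, ...]
    K_values: tuple[int, ...] = (30, 40, 80)
    n_reps: int = 1000
    master_seed: int = 20230
    model_ids: tuple[str, ...] = tuple(MODEL_GRID)
    n_staff: int = 100
    region_split: float = 0.5
    p_urban: float = 0.5
    p_race: float = 0.5
    beta_concentration: float = 10.0
    n_candidates: int = 50_000
    acceptance: str = "min"
    acceptance_quantile: float = 0.1
    threshold: float = 0.5
    alpha: float = 0.05
    reference: str = "normal"
    base: TrueCoefficients | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(self, "K_values", tuple(self.K_values))
        object.__setattr__(self, "model_ids", tuple(self.model_ids))
        unknown = [m for m in self.model_ids if m not in MODEL_GRID]
        if unknown:
            raise ValueError(f"unknown model ids {unknown}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")


def scenario_key(spec: ScenarioSpec) -> int:
    """Stable small-integer key for a scenario, used in seed derivation.

    Named scenarios use their id; custom scenarios encode their flag
    pattern (offset so custom keys never collide with ids 1-9).
    """
    bits = (
        int(spec.urban_main)
        + 2 * int(spec.race_main)
        + 4 * int(spec.hte_urban)
        + 8 * int(spec.hte_race)
    )
    ext = (
        16 * int(spec.urban_heterogeneity)
        + 32 * int(spec.race_heterogeneity)
        + 64 * int(round(spec.baseline_boosted_fraction * 1000))
    )
    if spec.scenario_id != "custom":
        return int(spec.scenario_id) + 100 * ext
    return 100 + bits + 100 * ext


def replication_seed(
    master_seed: int, spec: ScenarioSpec, K: int, rep: int
) -> np.random.SeedSequence:
    """Deterministic per-replication seed from (master, scenario, K, rep)."""
    return np.random.SeedSequence(
        [int(master_seed), scenario_key(spec), int(K), int(rep)]
    )


def simulate_dataset(
    spec: ScenarioSpec,
    K: int,
    coefs: TrueCoefficients,
    seed: np.random.SeedSequence | int,
    *,
    n_staff: int = 100,
    region_split: float = 0.5,
    p_urban: float = 0.5,
    p_race: float = 0.5,
    beta_concentration: float = 10.0,
    n_candidates: int = 50_000,
    acceptance: str = "min",
    acceptance_quantile: float = 0.1,
    threshold: float = 0.5,
):
    """Generate one complete trial dataset under a scenario.

    Returns (clusters, individuals, allocation, summaries); the
    summaries carry both cluster-level race encodings.  The seed is
    split into five independent streams, one per generation stage, so
    the stages cannot perturb each other's draws.
    """
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(int(seed))
    # explicit child keys rather than spawn(): spawning mutates the parent's
    # spawn counter, which would make a reused seed object non-reproducible
    children = [
        np.random.SeedSequence(entropy=seed.entropy, spawn_key=seed.spawn_key + (i,))
        for i in range(5)
    ]
    s_clusters, s_indiv, s_boost, s_rand, s_outcome = (
        np.random.default_rng(child) for child in children
    )
    clusters = generate_clusters(
        K,
        region_split=region_split,
        urban_scheme="heterogeneous" if spec.urban_heterogeneity else "fixed",
        p_urban=p_urban,
        n_staff=n_staff,
        rng=s_clusters,
    )
    individuals = generate_individuals(
        clusters,
        race_scheme="heterogeneous" if spec.race_heterogeneity else "fixed",
        p_race=p_race,
        beta_concentration=beta_concentration,
        rng=s_indiv,
    )
    individuals = assign_baseline_boosted(
        individuals, spec.baseline_boosted_fraction, rng=s_boost
    )
    allocation = constrained_randomize(
        clusters,
        n_candidates=n_candidates,
        acceptance=acceptance,
        q=acceptance_quantile,
        rng=s_rand,
    )
    individuals = generate_outcomes(
        individuals, clusters, allocation, coefs, rng=s_outcome
    )
    summaries = aggregate(individuals, clusters)
    summaries = center_proportions(summaries)
    summaries = dichotomize_proportions(summaries, t=threshold)
    return clusters, individuals, allocation, summaries


def run_replication(
    spec: ScenarioSpec,
    K: int,
    coefs: TrueCoefficients,
    model_ids: Sequence[str],
    seed: np.random.SeedSequence | int,
    *,
    alpha: float = 0.05,
    reference: str = "normal",
    **dataset_kwargs,
) -> pd.DataFrame:
    """One dataset, every requested model; returns a long results frame.

    Degenerate fits yield a single flagged row with missing estimates
    rather than aborting the replication.
    """
    _, individuals, _, summaries = simulate_dataset(
        spec, K, coefs, seed, **dataset_kwargs
    )
    frames = []
    for model_id in model_ids:
        ms = MODEL_GRID[model_id]
        data = individuals if ms.level == "individual" else summaries
        result = fit_model(data, ms, alpha=alpha, reference=reference)
        if result.degenerate:
            frames.append(
                pd.DataFrame(
                    {
                        "model_id": [model_id],
                        "coefficient": [None],
                        "estimate": [np.nan],
                        "se": [np.nan],
                        "statistic": [np.nan],
                        "p": [np.nan],
                        "reject": [False],
                        "degenerate": [True],
                    }
                )
            )
        else:
            tab = result.table.copy()
            tab.insert(0, "model_id", model_id)
            frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def _run_cell_rep(grid: StudyGrid, scen_idx: int, K: int, rep: int) -> pd.DataFrame:
    spec = grid.scenarios[scen_idx]
    coefs = build_coefficients(spec, grid.base)
    seed = replication_seed(grid.master_seed, spec, K, rep)
    out = run_replication(
        spec,
        K,
        coefs,
        grid.model_ids,
        seed,
        alpha=grid.alpha,
        reference=grid.reference,
        n_staff=grid.n_staff,
        region_split=grid.region_split,
        p_urban=grid.p_urban,
        p_race=grid.p_race,
        beta_concentration=grid.beta_concentration,
        n_candidates=grid.n_candidates,
        acceptance=grid.acceptance,
        acceptance_quantile=grid.acceptance_quantile,
        threshold=grid.threshold,
    )
    out.insert(0, "scenario", str(spec.scenario_id))
    out.insert(1, "K", K)
    out.insert(2, "rep", rep)
    return out


def run_study(
    grid: StudyGrid, n_jobs: int = 1, return_raw: bool = False
):
    """Run the full grid and summarize operating characteristics.

    Results are invariant to ``n_jobs``: seeds are derived per
    replication and the reduction preserves task order.  Returns the
    operating-characteristics frame, or ``(oc, raw)`` when
    ``return_raw`` is set.
    """
    tasks = [
        (i, K, rep)
        for i, _ in enumerate(grid.scenarios)
        for K in grid.K_values
        for rep in range(grid.n_reps)
    ]
    if n_jobs == 1:
        frames = [_run_cell_rep(grid, i, K, rep) for i, K, rep in tasks]
    else:
        frames = Parallel(n_jobs=n_jobs)(
            delayed(_run_cell_rep)(grid, i, K, rep) for i, K, rep in tasks
        )
    raw = pd.concat(frames, ignore_index=True)[RAW_COLUMNS]
    truths = {
        str(spec.scenario_id): build_coefficients(spec, grid.base)
        for spec in grid.scenarios
    }
    oc = summarize(raw, truths, alpha=grid.alpha)
    if return_raw:
        return oc, raw
    return oc


_COMMON_TRUTH = {
    "intercept": "beta0",
    "intervention": "beta_trt",
    "urban": "beta_urban",
    "region": "beta_region",
    "trt_x_urban": "beta_trt_urban",
}


def generating_truth(
    coefficient: str, level: str, coefs: TrueCoefficients
) -> float | None:
    """Generating-model counterpart of a fitted coefficient, if any.

    Cluster-level coefficients on aggregated race encodings (``race``
    and ``trt_x_race`` at the cluster level) have no generating
    counterpart — the generating model is individual-level, and the
    mismatch between levels is exactly the ecological-bias problem — so
    they are summarized without a bias column.
    """
    table = dict(_COMMON_TRUTH)
    if level == "individual":
        table["race"] = "beta_race"
        table["trt_x_race"] = "beta_trt_race"
    name = table.get(coefficient)
    if name is None:
        return None
    return getattr(coefs, name)


def summarize(
    raw: pd.DataFrame,
    truths: dict[str, TrueCoefficients],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Collapse raw per-replication fits to operating characteristics.

    Degenerate replications are excluded from a model's denominator and
    tallied in ``n_degenerate``.  ``mc_se`` is sqrt(p(1-p)/n_eff) for
    the rejection proportion.
    """
    rows = []
    grouped = raw.groupby(["scenario", "K", "model_id"], sort=True)
    for (scenario, K, model_id), block in grouped:
        n_total = block["rep"].nunique()
        degenerate_reps = block.loc[block["degenerate"], "rep"].nunique()
        ok = block[~block["degenerate"]]
        level = MODEL_GRID[model_id].level
        coefs = truths[scenario]
        for coefficient, cblock in ok.groupby("coefficient", sort=False):
            n_eff = len(cblock)
            p_hat = float(cblock["reject"].mean()) if n_eff else np.nan
            truth = generating_truth(coefficient, level, coefs)
            mean_est = float(cblock["estimate"].mean())
            rows.append(
                {
                    "scenario": scenario,
                    "K": K,
                    "model_id": model_id,
                    "coefficient": coefficient,
                    "n_reps": n_total,
                    "n_degenerate": degenerate_reps,
                    "n_eff": n_eff,
                    "reject_prop": p_hat,
                    "mc_se": float(np.sqrt(p_hat * (1 - p_hat) / n_eff))
                    if n_eff
                    else np.nan,
                    "mean_estimate": mean_est,
                    "sd_estimate": float(cblock["estimate"].std(ddof=1)),
                    "truth": np.nan if truth is None else truth,
                    "bias": np.nan if truth is None else mean_est - truth,
                }
            )
    return pd.DataFrame(rows)


def compare_power(
    oc: pd.DataFrame,
    coefficient: str = "trt_x_race",
    individual_models: Sequence[str] = ("1e", "1f"),
    cluster_models: Sequence[str] = ("2g", "2h", "2i", "2j"),
) -> pd.DataFrame:
    """Individual- versus cluster-level rejection rates for one coefficient.

    For each (scenario, K) and each (individual, cluster) model pair:
    the two rejection proportions, their difference, and the combined
    Monte-Carlo SE of the difference.  The metric is labeled "power"
    when the generating HTE is non-zero in that cell and "type_i_error"
    otherwise.  Raises if either side of the comparison is absent.
    """
    sub = oc[oc["coefficient"] == coefficient]
    have = set(sub["model_id"])
    ind = [m for m in individual_models if m in have]
    clu = [m for m in cluster_models if m in have]
    if not ind or not clu:
        raise ValueError(
            f"need both individual and cluster models for {coefficient!r}; "
            f"found individual={ind}, cluster={clu}"
        )
    rows = []
    for (scenario, K), block in sub.groupby(["scenario", "K"], sort=True):
        by_model = block.set_index("model_id")
        for mi in ind:
            if mi not in by_model.index:
                continue
            ri = by_model.loc[mi]
            truth = ri["truth"]
            metric = (
                "power" if np.isfinite(truth) and truth != 0 else "type_i_error"
            )
            for mc in clu:
                if mc not in by_model.index:
                    continue
                rc = by_model.loc[mc]
                rows.append(
                    {
                        "scenario": scenario,
                        "K": K,
                        "metric": metric,
                        "individual_model": mi,
                        "cluster_model": mc,
                        "reject_individual": ri["reject_prop"],
                        "reject_cluster": rc["reject_prop"],
                        "difference": ri["reject_prop"] - rc["reject_prop"],
                        "se_difference": float(
                            np.sqrt(ri["mc_se"] ** 2 + rc["mc_se"] ** 2)
                        ),
                    }
                )
    if not rows:
        raise ValueError("no matched (scenario, K) cells to compare")
    return pd.DataFrame(rows)
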