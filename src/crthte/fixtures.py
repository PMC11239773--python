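"""Tiny deterministic datasets for tests and examples."""

from __future__ import annotations

from .engine import simulate_dataset
from .scenarios import ScenarioSpec, build_coefficients

__all__ = ["tiny_dataset"]


def tiny_dataset(seed: int = 20230, scenario_id: int = 6, K: int = 4, n_staff: int = 5):
    """A complete miniature trial dataset (K=4 clusters, 5 staff each).

    Fully deterministic for a given seed; the constrained randomization
    runs on the enumeration path at this size.  Returns a dict with the
    cluster table, individual table, allocation and cluster summaries.
    """
    spec = ScenarioSpec.from_id(scenario_id)
    coefs = build_coefficients(spec)
    clusters, individuals, allocation, summaries = simulate_dataset(
        spec, K, coefs, seed, n_staff=n_staff, n_candidates=1000
    )
    return {
        "spec": spec,
        "coefs": coefs,
        "clusters": clusters,
        "individuals": individuals,
        "allocation": allocation,
        "summaries": summaries,
    }
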