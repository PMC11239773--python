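"""Data-generating truth: scenario flags and linear-probability coefficients.

The simulated trial randomizes long-term care centers (clusters) to an
intervention intended to raise booster-vaccination uptake among staff.
Outcomes are generated from a linear probability model, so every
coefficient is a risk difference:

    P(Y=1) = beta0 + beta_trt*A + beta_urban*urban + beta_race*race
             + beta_region*region + beta_trt_urban*A*urban
             + beta_trt_race*A*race

Scenarios toggle four generating effects on or off: an urban/rural main
effect, a self-reported-race main effect, and treatment-effect
heterogeneity (HTE) by each of the two variables.  Three further switches
control realism extensions: heterogeneous urban composition across
clusters, heterogeneous race prevalence across clusters, and a fraction
of staff already boosted at baseline.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "TrueCoefficients",
    "ScenarioSpec",
    "SCENARIO_FLAGS",
    "build_coefficients",
    "validate_support",
    "INTERVENTION_EFFECT",
    "URBAN_MAIN_EFFECT",
    "RACE_MAIN_EFFECT",
    "URBAN_HTE_EFFECT",
    "RACE_HTE_EFFECT",
    "DEFAULT_BASELINE_PROBABILITY",
    "DEFAULT_REGION_EFFECT",
]

# Generating effect sizes, on the risk-difference (probability) scale.
INTERVENTION_EFFECT = 0.14
URBAN_MAIN_EFFECT = 0.03
RACE_MAIN_EFFECT = 0.01
URBAN_HTE_EFFECT = 0.10
RACE_HTE_EFFECT = 0.15

# Baseline booster probability and region effect are configurable; the
# defaults keep every implied probability inside [0, 1] for all nine
# scenarios while matching trial eligibility (baseline uptake well below
# 60%).
DEFAULT_BASELINE_PROBABILITY = 0.30
DEFAULT_REGION_EFFECT = 0.0

_COEF_FIELDS = (
    "beta0",
    "beta_trt",
    "beta_urban",
    "beta_race",
    "beta_region",
    "beta_trt_urban",
    "beta_trt_race",
)


def _implied_probability(
    coefs: Mapping[str, float], a: int, urban: int, race: int, region: int
) -> float:
    return (
        coefs["beta0"]
        + coefs["beta_trt"] * a
        + coefs["beta_urban"] * urban
        + coefs["beta_race"] * race
        + coefs["beta_region"] * region
        + coefs["beta_trt_urban"] * a * urban
        + coefs["beta_trt_race"] * a * race
    )


def validate_support(coefs: "TrueCoefficients | Mapping[str, float]") -> list[dict]:
    """Enumerate the binary covariate support and flag invalid probabilities.

    Walks every combination of (arm, urban, race, region) in {0,1}^4 and
    returns those whose implied probability leaves [0, 1].  An empty list
    means the coefficients generate a valid Bernoulli model everywhere.
    Accepts either a :class:`TrueCoefficients` or a plain mapping so that
    candidate values can be screened before construction.
    """
    if dataclasses.is_dataclass(coefs):
        coefs = dataclasses.asdict(coefs)
    table = {name: float(coefs.get(name, 0.0)) for name in _COEF_FIELDS}
    violations = []
    for a, urban, race, region in itertools.product((0, 1), repeat=4):
        p = _implied_probability(table, a, urban, race, region)
        if not 0.0 <= p <= 1.0:
            violations.append(
                {"arm": a, "urban": urban, "race": race, "region": region,
                 "probability": p}
            )
    return violations


@dataclass(frozen=True)
class TrueCoefficients:
    """Risk-difference coefficients of the generating linear probability model.

    Construction fails if any covariate combination on the binary support
    would imply a probability outside [0, 1], because outcomes are drawn
    as Bernoulli variables with these linear predictors as means.
    """

    beta0: float = DEFAULT_BASELINE_PROBABILITY
    beta_trt: float = INTERVENTION_EFFECT
    beta_urban: float = 0.0
    beta_race: float = 0.0
    beta_region: float = DEFAULT_REGION_EFFECT
    beta_trt_urban: float = 0.0
    beta_trt_race: float = 0.0

    def __post_init__(self) -> None:
        violations = validate_support(self)
        if violations:
            raise ValueError(
                "coefficients imply probabilities outside [0, 1] for "
                f"{len(violations)} covariate combination(s), e.g. {violations[0]}"
            )

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


# Mapping of named scenarios to generating flags, in the order
# (urban_main, race_main, hte_urban, hte_race).  Scenario 1 has no
# subgroup effects at all; scenario 6 is the simplest scenario with HTE
# by self-reported race; scenario 9 turns everything on.  Single-effect
# scenarios come first, then two-effect, then three-effect combinations.
SCENARIO_FLAGS: dict[int, tuple[bool, bool, bool, bool]] = {
    1: (False, False, False, False),
    2: (True, False, False, False),
    3: (False, True, False, False),
    4: (True, True, False, False),
    5: (True, False, True, False),
    6: (False, True, False, True),
    7: (True, True, True, False),
    8: (True, True, False, True),
    9: (True, True, True, True),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Which generating effects are active, plus realism-extension switches.

    ``scenario_id`` is one of the nine named scenarios or ``"custom"``.
    The four effect flags fully determine the generating coefficients via
    :func:`build_coefficients`; the extension switches control the
    generator (cluster composition and baseline-boosted staff) without
    touching the coefficients.
    """

    scenario_id: int | str = "custom"
    urban_main: bool = False
    race_main: bool = False
    hte_urban: bool = False
    hte_race: bool = False
    urban_heterogeneity: bool = False
    race_heterogeneity: bool = False
    baseline_boosted_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.scenario_id != "custom":
            if self.scenario_id not in SCENARIO_FLAGS:
                raise ValueError(
                    f"scenario_id must be 1-9 or 'custom', got {self.scenario_id!r}"
                )
        if not 0.0 <= self.baseline_boosted_fraction < 1.0:
            raise ValueError(
                "baseline_boosted_fraction must lie in [0, 1), got "
                f"{self.baseline_boosted_fraction}"
            )

    @classmethod
    def from_id(
        cls,
        scenario_id: int,
        *,
        urban_heterogeneity: bool = False,
        race_heterogeneity: bool = False,
        baseline_boosted_fraction: float = 0.0,
    ) -> "ScenarioSpec":
        """Build one of the nine named scenarios, optionally with extensions."""
        try:
            urban_main, race_main, hte_urban, hte_race = SCENARIO_FLAGS[scenario_id]
        except KeyError:
            raise ValueError(f"unknown scenario id {scenario_id!r}") from None
        return cls(
            scenario_id=scenario_id,
            urban_main=urban_main,
            race_main=race_main,
            hte_urban=hte_urban,
            hte_race=hte_race,
            urban_heterogeneity=urban_heterogeneity,
            race_heterogeneity=race_heterogeneity,
            baseline_boosted_fraction=baseline_boosted_fraction,
        )


def build_coefficients(
    spec: ScenarioSpec, base: TrueCoefficients | None = None
) -> TrueCoefficients:
    """Map scenario flags to concrete generating coefficients.

    The intervention main effect is always 0.14.  Each flagged effect
    takes its fixed generating value (urban main 0.03, race main 0.01,
    urban HTE 0.10, race HTE 0.15); unflagged effects are exactly zero,
    so null hypotheses tested downstream are exactly true in null
    scenarios.  The baseline probability and region effect are taken from
    ``base`` (library defaults when omitted).  Deterministic and
    idempotent; raises if the implied probabilities leave [0, 1].
    """
    if base is None:
        base = TrueCoefficients()
    return TrueCoefficients(
        beta0=base.beta0,
        beta_trt=INTERVENTION_EFFECT,
        beta_urban=URBAN_MAIN_EFFECT if spec.urban_main else 0.0,
        beta_race=RACE_MAIN_EFFECT if spec.race_main else 0.0,
        beta_region=base.beta_region,
        beta_trt_urban=URBAN_HTE_EFFECT if spec.hte_urban else 0.0,
        beta_trt_race=RACE_HTE_EFFECT if spec.hte_race else 0.0,
    )
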