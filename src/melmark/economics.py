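"""Screening-economics algebra: NNT, NNS and cost per life saved.

These are the back-of-envelope identities that turn the scenario engine's
excisions-per-death-averted ratio into money:

* ``NNT`` — benign pigmented lesions excised per melanoma excised.
* ``NNS`` — screening consultations needed to save one life, composed as
  consultations-per-excision x NNT x melanomas-excised-per-life.
* cost per excision — one excision event (consultation + excision +
  pathology) plus the extra consultations that did not lead to an excision.
* cost per life saved — cost per excision x NNT x melanomas excised per
  life, usually quoted as a range because the excisions-per-life ratio
  spans the plausible (D0, p) configurations.

All amounts are in the configured currency unit (nominally Australian
dollars); ``inflation_adjust`` compounds a flat annual rate.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Plausible range of Stage-1 melanomas excised per life saved over the
#: observed era, interpolated across the model configurations.
EXCISIONS_PER_LIFE_RANGE = (50.0, 120.0)


@dataclass(frozen=True)
class CostAssumptions:
    """Unit costs and screening yields behind the NNS arithmetic.

    ``consultations_per_excision`` is 1 for extreme-risk screening (every
    consultation yields an excision) and around 25 for population-wide
    screening.
    """

    nnt: float = 10.0
    consultations_per_excision: float = 1.0
    cost_excision_event: float = 300.0
    cost_consultation: float = 50.0

    def __post_init__(self):
        if self.nnt <= 0 or self.cost_excision_event <= 0 \
                or self.cost_consultation <= 0:
            raise ValueError("costs and NNT must be positive")
        if self.consultations_per_excision < 1:
            raise ValueError("consultations_per_excision must be >= 1 "
                             "(an excision implies a consultation)")


@dataclass(frozen=True)
class CostResult:
    """NNS and cost outputs for one assumption set and excision ratio."""

    nns: float
    cost_per_excision: float
    cost_per_life_saved: tuple[float, float]


def nns(consultations_per_excision: float, nnt: float,
        excisions_per_life: float) -> float:
    """Number needed to screen: the product of the three yield factors."""
    for name, v in (("consultations_per_excision", consultations_per_excision),
                    ("nnt", nnt), ("excisions_per_life", excisions_per_life)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return consultations_per_excision * nnt * excisions_per_life


def cost_per_excision(assumptions: CostAssumptions) -> float:
    """Cost of one excision including its share of yield-less consultations.

    One consultation is bundled in the excision event; the remaining
    (consultations_per_excision - 1) consultations are billed separately.
    """
    extra = assumptions.consultations_per_excision - 1.0
    return (assumptions.cost_excision_event
            + extra * assumptions.cost_consultation)


def cost_per_life_saved(assumptions: CostAssumptions,
                        excisions_per_life) -> tuple[float, float]:
    """Cost range to avert one melanoma death by secondary prevention.

    ``excisions_per_life`` may be a scalar (e.g. the scenario engine's
    Ratio) or a (low, high) range; the result is always a (low, high)
    tuple, elementwise cost_per_excision x NNT x excisions_per_life.
    """
    try:
        lo, hi = excisions_per_life
    except TypeError:
        lo = hi = float(excisions_per_life)
    if lo > hi:
        raise ValueError(f"range ({lo}, {hi}) is not ordered")
    cpe = cost_per_excision(assumptions)
    return (cpe * assumptions.nnt * lo, cpe * assumptions.nnt * hi)


def cost_summary(assumptions: CostAssumptions,
                 excisions_per_life=EXCISIONS_PER_LIFE_RANGE) -> CostResult:
    """NNS and cost-per-life outputs for one assumption set."""
    try:
        lo, hi = excisions_per_life
    except TypeError:
        lo = hi = float(excisions_per_life)
    return CostResult(
        nns=nns(assumptions.consultations_per_excision, assumptions.nnt, hi),
        cost_per_excision=cost_per_excision(assumptions),
        cost_per_life_saved=cost_per_life_saved(assumptions, (lo, hi)))


def primary_prevention_cost(per_capita_spend: float, population: float,
                            lives_saved: float) -> float:
    """Campaign cost of saving one life by primary prevention.

    Total campaign spend (per-capita spend times population covered)
    divided by the melanoma deaths it averted.
    """
    if per_capita_spend <= 0 or population <= 0:
        raise ValueError("spend and population must be positive")
    if lives_saved <= 0:
        raise ValueError("lives_saved must be positive")
    return per_capita_spend * population / lives_saved


def inflation_adjust(amount: float, annual_rate: float, years: int) -> float:
    """Compound ``amount`` forward by a flat annual inflation rate."""
    if annual_rate < 0:
        raise ValueError("inflation rate must be non-negative")
    return amount * (1.0 + annual_rate) ** years
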