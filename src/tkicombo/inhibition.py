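"""Median-effect growth inhibition under one, two or three Bcr-Abl1 inhibitors.

The fractional growth rate of a cell exposed to a single inhibitor at
concentration :math:`C` follows the median-effect (Hill) relation

.. math:: f_v = \\frac{1}{1 + (C / IC_{50})^m},

with ``m`` the Hill coefficient.  When drugs are combined, two limiting
interaction modes are considered:

* *exclusive* — the drugs compete for one binding site (all ATP-pocket
  inhibitors with each other): their potency-scaled concentrations add;
* *nonexclusive* — the drugs bind entirely independently (an ATP-pocket
  inhibitor with the allosteric, myristoyl-pocket inhibitor asciminib): the
  sum gains the product cross term.

A mixed triple form covers two competing ATP-pocket drugs plus one
non-competing allosteric drug: the competing pair adds exclusively, and the
combined pair term interacts nonexclusively with the allosteric term.

Resistance data are carried as IC50 values of a mutant relative to cells
carrying native-sequence Bcr-Abl1; a relative IC50 above one marks a mutation
that is resistant to some degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError, MissingDataError, ModeMismatchError

__all__ = [
    "InteractionMode",
    "DrugPotency",
    "MutantProfile",
    "EffectSummary",
    "fractional_growth_single",
    "fractional_growth_pair",
    "fractional_growth_triple",
    "growth_from_terms",
    "relative_ic50",
    "aggregate_relative_ic50",
    "effect_integral",
]

DEFAULT_HILL = 2.0
"""Scenario-wide Hill coefficient used by default throughout the package."""


class InteractionMode(str, Enum):
    EXCLUSIVE = "exclusive"
    NONEXCLUSIVE = "nonexclusive"
    MIXED_TRIPLE = "mixed_triple"


@dataclass(frozen=True)
class DrugPotency:
    """IC50 (against native-sequence Bcr-Abl1) and Hill coefficient of one drug.

    In normalised-dose work the IC50 is expressed in normalised units where
    the wildtype value is 1 and a mutant's value equals its relative IC50.
    """

    drug_name: str
    ic50: float = 1.0
    hill_m: float = DEFAULT_HILL

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise InputError(f"{self.drug_name}: ic50 must be positive")
        if self.hill_m <= 0:
            raise InputError(f"{self.drug_name}: hill coefficient must be positive")


@dataclass(frozen=True)
class MutantProfile:
    """Per-drug relative IC50 values for one Bcr-Abl1 variant.

    Drugs without a measured value are simply absent from the mapping; they
    are never imputed.
    """

    mutant_name: str
    relative_ic50: Mapping[str, float]
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for drug, value in self.relative_ic50.items():
            if not (value > 0):
                raise InputError(
                    f"{self.mutant_name}/{drug}: relative IC50 must be positive"
                )

    def has(self, drug_name: str) -> bool:
        return drug_name in self.relative_ic50

    def get(self, drug_name: str) -> float:
        try:
            return self.relative_ic50[drug_name]
        except KeyError:
            raise MissingDataError(
                f"no relative IC50 for mutant {self.mutant_name!r} and drug {drug_name!r}"
            ) from None


@dataclass(frozen=True)
class EffectSummary:
    """Daily-mean fractional growth, the scalar effectiveness measure of a treatment."""

    mean_fractional_growth: float
    period: float

    def __post_init__(self) -> None:
        if not (0 < self.mean_fractional_growth <= 1):
            raise InputError("mean fractional growth must lie in (0, 1]")


def _hill(base, m: float):
    return 1.0 / (1.0 + np.asarray(base, dtype=float) ** m)


def fractional_growth_single(conc, potency: DrugPotency, m: float | None = None):
    """Fractional growth rate under a single inhibitor.  Vectorised over ``conc``."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise InputError("concentration must be non-negative")
    out = _hill(c / potency.ic50, potency.hill_m if m is None else m)
    return out if out.ndim else float(out)


def fractional_growth_pair(
    c1,
    c2,
    p1: DrugPotency,
    p2: DrugPotency,
    mode: InteractionMode,
    m: float = DEFAULT_HILL,
):
    """Fractional growth under two inhibitors in exclusive or nonexclusive mode."""
    mode = InteractionMode(mode)
    if mode is InteractionMode.MIXED_TRIPLE:
        raise ModeMismatchError("mixed_triple mode requires exactly three drugs")
    t1 = np.asarray(c1, dtype=float) / p1.ic50
    t2 = np.asarray(c2, dtype=float) / p2.ic50
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise InputError("concentrations must be non-negative")
    base = t1 + t2
    if mode is InteractionMode.NONEXCLUSIVE:
        base = base + t1 * t2
    out = _hill(base, m)
    return out if out.ndim else float(out)


def fractional_growth_triple(
    concs: Sequence,
    potencies: Sequence[DrugPotency],
    noncompeting_index: int,
    m: float = DEFAULT_HILL,
):
    """Fractional growth under two competing ATP-pocket drugs plus one allosteric drug.

    The two competing terms add (exclusive); their sum interacts nonexclusively
    with the term of the drug at ``noncompeting_index``.  Setting any one
    concentration to zero reduces the form to the corresponding pair equation.
    """
    if len(concs) != 3 or len(potencies) != 3:
        raise ModeMismatchError("triple form requires exactly three drugs")
    if noncompeting_index not in (0, 1, 2):
        raise InputError("noncompeting_index must identify one of the three drugs")
    terms = [np.asarray(c, dtype=float) / p.ic50 for c, p in zip(concs, potencies)]
    if any(np.any(t < 0) for t in terms):
        raise InputError("concentrations must be non-negative")
    allo = terms[noncompeting_index]
    atp = sum(t for i, t in enumerate(terms) if i != noncompeting_index)
    out = _hill(atp + allo + atp * allo, m)
    return out if out.ndim else float(out)


def growth_from_terms(atp_term, allosteric_term=0.0, m: float = DEFAULT_HILL):
    """Fractional growth from pre-computed potency-scaled concentration terms.

    ``atp_term`` is the sum over competing ATP-pocket drugs of ``C/IC50``;
    ``allosteric_term`` the same for the non-competing allosteric drug.  This
    single form realises the monodrug, exclusive-pair and mixed-triple
    equations, and the nonexclusive pair when only one ATP-pocket drug is
    active.
    """
    atp = np.asarray(atp_term, dtype=float)
    allo = np.asarray(allosteric_term, dtype=float)
    out = _hill(atp + allo + atp * allo, m)
    return out if out.ndim else float(out)


def relative_ic50(mutant_ic50: float, wildtype_ic50: float) -> float:
    """Mutant IC50 divided by the wildtype IC50; values above 1 flag resistance."""
    if mutant_ic50 <= 0 or wildtype_ic50 <= 0:
        raise InputError("IC50 values must be positive")
    return mutant_ic50 / wildtype_ic50


def aggregate_relative_ic50(values: Iterable[float]) -> float:
    """Geometric mean of per-source relative IC50 values.

    Callers filter out entries that are approximations or bounds before
    aggregation; an empty list therefore means the datum is unavailable.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise MissingDataError("no precise relative IC50 values to aggregate")
    if any(v <= 0 for v in vals):
        raise InputError("relative IC50 values must be positive")
    return float(math.exp(np.mean(np.log(vals))))


def effect_integral(fv_profile, period: float = 1.0, times=None) -> EffectSummary:
    """Mean fractional growth over one period of a periodic profile.

    The profile must sample exactly one period on a uniform grid with the
    right endpoint excluded (it wraps onto the left one), for which the
    arithmetic mean equals the periodic trapezoid integral divided by the
    period.
    """
    values = np.asarray(fv_profile, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise InputError("fv profile must be a non-empty 1-d array")
    if times is not None:
        t = np.asarray(times, dtype=float)
        steps = np.diff(t)
        if t.shape != values.shape or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise InputError("fv profile grid must be uniform")
    if np.any(values <= 0) or np.any(values > 1):
        raise InputError("fractional growth values must lie in (0, 1]")
    return EffectSummary(mean_fractional_growth=float(np.mean(values)), period=period)
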