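"""Selection ratio of resistant clones under axitinib-supplemented treatment.

A resistance mutation is evolutionarily favoured under a treatment whenever
the mutant grows faster than cells carrying native-sequence Bcr-Abl1.  The
per-time-point selection ratio

.. math:: \\chi(t) = f_v^{(\\text{mutant})}(t) / f_v^{(\\text{wildtype})}(t)

quantifies this (mutant and wildtype are assumed to grow at the same rate
without inhibitors, so :math:`\\chi = 1` untreated; :math:`\\chi > 1` means
the mutant — by default the gatekeeper T315I — is being selected for).

Axitinib inhibits T315I more strongly than native Bcr-Abl1 (relative IC50
below one), so supplementing a standard TKI with axitinib pushes
:math:`\\chi` down, most effectively at particular administration times.
Scenarios come in two dosing flavours: *plasma* doses derived from the
steady-state PK profiles and absolute Ba/F3 IC50 values, and *normalised*
doses where each drug (or backbone combination) is scaled to a stated daily
mean growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigError, InputError, MissingDataError
from .inhibition import DEFAULT_HILL, DrugPotency, MutantProfile, growth_from_terms
from .doseopt import dose_reduction_factor, scale_to_effect
from .pk import PkParameters, profile_on_grid

__all__ = [
    "ALLOSTERIC_DRUGS",
    "SupplementScenario",
    "ChiTimeCourse",
    "chi_at_time",
    "chi_time_course",
    "optimize_supplement_offset",
    "optimize_axitinib_offset",
]

ALLOSTERIC_DRUGS = frozenset({"asciminib"})
"""Drugs binding the myristoyl pocket; all others compete for the ATP pocket."""


@dataclass(frozen=True)
class SupplementScenario:
    """Configuration of one supplementation time course.

    ``backbone`` drugs are dosed at t = 0 (a half-day dosing interval tiles
    the second daily dose automatically); only the supplement's
    administration offset is scanned.
    """

    backbone: tuple[str, ...]
    supplement: str = "axitinib"
    dosing: str = "plasma"  # "plasma" | "normalised"
    mutant_name: str = "T315I"
    effect_target: float = 0.1  # backbone daily mean growth under normalised dosing
    supplement_growth_reduction: float = 0.05  # supplement normalised to this reduction
    m: float = DEFAULT_HILL
    n_points: int = 240
    n_offsets: int = 48
    criterion: str = "min_instantaneous"  # or "min_average"

    def __post_init__(self) -> None:
        if self.dosing not in ("plasma", "normalised"):
            raise ConfigError(f"unknown dosing kind {self.dosing!r}")
        if self.criterion not in ("min_instantaneous", "min_average"):
            raise ConfigError(f"unknown optimisation criterion {self.criterion!r}")
        if not self.backbone:
            raise ConfigError("scenario needs at least one backbone drug")


@dataclass(frozen=True)
class ChiTimeCourse:
    """Daily selection-ratio curve with its summary statistics."""

    time_grid: np.ndarray
    chi: np.ndarray
    supplement_offset: float  # days

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.chi) <= 0):
            raise InputError("chi must be positive everywhere")

    @property
    def minimum(self) -> float:
        return float(np.min(self.chi))

    @property
    def mean(self) -> float:
        return float(np.mean(self.chi))

    @property
    def fraction_below_one(self) -> float:
        return float(np.mean(np.asarray(self.chi) < 1.0))


def chi_at_time(
    concentrations: Mapping[str, float],
    potencies: Mapping[str, DrugPotency],
    mutant: MutantProfile,
    m: float = DEFAULT_HILL,
) -> float:
    """Selection ratio for one set of instantaneous concentrations.

    Every drug with a non-zero concentration must have a relative IC50 entry
    in the mutant profile; with no active drug the ratio is exactly one.
    """
    atp_wt = atp_mut = 0.0
    allo_wt = allo_mut = 0.0
    for drug, conc in concentrations.items():
        if conc == 0:
            continue
        if conc < 0:
            raise InputError(f"{drug}: concentration must be non-negative")
        term = conc / potencies[drug].ic50
        rel = mutant.get(drug)  # raises MissingDataError when absent
        if drug in ALLOSTERIC_DRUGS:
            allo_wt += term
            allo_mut += term / rel
        else:
            atp_wt += term
            atp_mut += term / rel
    f_wt = growth_from_terms(atp_wt, allo_wt, m)
    f_mut = growth_from_terms(atp_mut, allo_mut, m)
    return float(f_mut) / float(f_wt)


def _plasma_term_profile(drug: str, pk: PkParameters, potency: DrugPotency,
                         n_points: int, offset: float) -> np.ndarray:
    prof = profile_on_grid(pk, n_points=n_points, administration_offset=offset)
    return prof.values / potency.ic50


def _scenario_term_profiles(
    scenario: SupplementScenario,
    pk_table: Mapping[str, PkParameters],
    potencies: Mapping[str, DrugPotency],
    supplement_offset: float,
) -> dict[str, np.ndarray]:
    """Per-drug potency-scaled concentration profiles on the daily grid."""
    for drug in (*scenario.backbone, scenario.supplement):
        if drug not in pk_table or drug not in potencies:
            raise ConfigError(f"drug {drug!r} missing from the PK or potency tables")
    n = scenario.n_points
    terms: dict[str, np.ndarray] = {}
    for drug in scenario.backbone:
        terms[drug] = _plasma_term_profile(drug, pk_table[drug], potencies[drug], n, 0.0)
    terms[scenario.supplement] = _plasma_term_profile(
        scenario.supplement, pk_table[scenario.supplement],
        potencies[scenario.supplement], n, supplement_offset,
    )

    if scenario.dosing == "normalised":
        m = scenario.m
        allo = [d for d in scenario.backbone if d in ALLOSTERIC_DRUGS]
        atp = [d for d in scenario.backbone if d not in ALLOSTERIC_DRUGS]
        if len(scenario.backbone) == 1:
            drug = scenario.backbone[0]
            terms[drug] = terms[drug] * scale_to_effect(terms[drug], scenario.effect_target, m)
        elif len(scenario.backbone) == 2 and len(allo) == 1:
            # backbone pair normalised jointly: even effect-wise split, given
            # simultaneously, shrunk by the pair's dose-reduction factor so the
            # combination meets the effect target
            a, b = atp[0], allo[0]
            r_a = terms[a] * scale_to_effect(terms[a], scenario.effect_target, m)
            r_b = terms[b] * scale_to_effect(terms[b], scenario.effect_target, m)
            zeta = dose_reduction_factor(0.5, r_a, r_b, "nonexclusive", m,
                                         scenario.effect_target)
            terms[a] = 0.5 * zeta * r_a
            terms[b] = 0.5 * zeta * r_b
        else:
            raise ConfigError(
                "normalised dosing supports a single backbone drug or an "
                "ATP-pocket + allosteric backbone pair"
            )
        supp = scenario.supplement
        if np.any(terms[supp]):  # a zero-dose supplement stays at zero
            target = 1.0 - scenario.supplement_growth_reduction
            terms[supp] = terms[supp] * scale_to_effect(terms[supp], target, m)
    return terms


def chi_time_course(
    scenario: SupplementScenario,
    pk_table: Mapping[str, PkParameters],
    potencies: Mapping[str, DrugPotency],
    mutant: MutantProfile,
    supplement_offset: float = 0.0,
) -> ChiTimeCourse:
    """Daily chi curve for a given supplement administration offset (days).

    ATP-pocket drugs combine exclusively; asciminib, when present, interacts
    nonexclusively with the summed ATP-pocket term (mixed triple form).
    """
    terms = _scenario_term_profiles(scenario, pk_table, potencies, supplement_offset)
    n = scenario.n_points
    atp_wt = np.zeros(n)
    atp_mut = np.zeros(n)
    allo_wt = np.zeros(n)
    allo_mut = np.zeros(n)
    for drug, term in terms.items():
        if not np.any(term):
            continue
        if not mutant.has(drug):
            raise MissingDataError(
                f"no relative IC50 for mutant {mutant.mutant_name!r} and drug {drug!r}"
            )
        rel = mutant.get(drug)
        if drug in ALLOSTERIC_DRUGS:
            allo_wt += term
            allo_mut += term / rel
        else:
            atp_wt += term
            atp_mut += term / rel
    chi = growth_from_terms(atp_mut, allo_mut, scenario.m) / growth_from_terms(
        atp_wt, allo_wt, scenario.m
    )
    t = np.arange(n) / n
    return ChiTimeCourse(time_grid=t, chi=np.asarray(chi), supplement_offset=supplement_offset)


def optimize_supplement_offset(
    scenario: SupplementScenario,
    pk_table: Mapping[str, PkParameters],
    potencies: Mapping[str, DrugPotency],
    mutant: MutantProfile,
) -> tuple[float, ChiTimeCourse]:
    """Best supplement administration offset on the scenario's offset grid.

    Scans ``n_offsets`` equidistant offsets over one day (48 means every
    30 min) and minimises either the instantaneous daily minimum of chi or
    its daily mean.  Ties break toward the smallest offset.  Returns the
    offset in days together with the corresponding time course.
    """
    offsets = np.arange(scenario.n_offsets) / scenario.n_offsets
    best_offset = None
    best_score = np.inf
    best_course = None
    for off in offsets:
        course = chi_time_course(scenario, pk_table, potencies, mutant, float(off))
        score = course.minimum if scenario.criterion == "min_instantaneous" else course.mean
        if score < best_score - 1e-15:
            best_score = score
            best_offset = float(off)
            best_course = course
    assert best_course is not None
    return best_offset, best_course


# the supplement is axitinib in every scenario shipped with the package
optimize_axitinib_offset = optimize_supplement_offset
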