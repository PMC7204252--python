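"""Effect normalisation, dose-reduction optimisation and combination sensitivity.

The work horse quantities:

* *effect normalisation* — each drug's dose is rescaled so that its daily
  mean fractional growth equals a common effect target (default 0.1, i.e.
  90 % growth inhibition).  This stands in for all the factors (transport,
  plasma-protein binding, ...) separating plasma concentration from realised
  inhibition.
* *dose-reduction factor* :math:`\\zeta` — the single scalar by which a
  mixture of ``x`` effect-wise parts of drug A and ``1 - x`` parts of drug B
  (both individually normalised) can be shrunk while still meeting the effect
  target.  For a nonexclusive mixture the potency term of the combination is

  .. math:: x\\zeta r_A(t) + (1-x)\\zeta r_B(t) + x(1-x)\\zeta^2 r_A(t) r_B(t),

  where :math:`r(t)` denotes the normalised potency-scaled concentration
  profile ``C(t)/IC50``; the cross term carries :math:`\\zeta^2` because it is
  the product of the two administered concentrations.
* *effective IC50* of a fixed-ratio combination, and its value for a mutant
  relative to the wildtype value, which summarises how sensitive an optimised
  combination remains to resistance mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import FitFailureError, InputError, ModeMismatchError
from .inhibition import DEFAULT_HILL, DrugPotency, InteractionMode
from .pk import PkParameters, profile_on_grid

__all__ = [
    "CombinationDesign",
    "ScanResult",
    "scale_to_effect",
    "normalize_dose",
    "normalized_ratio_profile",
    "combination_mean_growth",
    "dose_reduction_factor",
    "scan_combination",
    "effective_ic50",
    "mutant_sensitivity_profile",
]

N_INTEGRATION_POINTS = 1000
"""Default number of daily grid points for effect integrals during optimisation."""


@dataclass(frozen=True)
class CombinationDesign:
    """One point of the dose-ratio/offset design space of a two-drug combination."""

    drug_a: str
    drug_b: str
    dose_ratio: float  # x, effect-wise share of drug A in [0, 1]
    administration_offset: float  # drug-B dosing time minus drug-A dosing time, days
    mode: InteractionMode
    dose_reduction: float = 1.0  # zeta
    effect_target: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.dose_ratio <= 1.0:
            raise InputError("dose ratio x must lie in [0, 1]")
        if self.dose_reduction <= 0:
            raise InputError("dose reduction factor must be positive")
        if not 0.0 < self.effect_target < 1.0:
            raise InputError("effect target must lie in (0, 1)")

    @property
    def per_drug_doses(self) -> tuple[float, float]:
        """Fraction of each drug's normalised standard dose actually administered.

        With an even split (x = 0.5) and zeta = 0.5, each drug is given at
        exactly 25 % of its monodrug amount.
        """
        return (
            self.dose_ratio * self.dose_reduction,
            (1.0 - self.dose_ratio) * self.dose_reduction,
        )


@dataclass(frozen=True)
class ScanResult:
    """Full zeta surface of a ratio/offset scan plus the optimal design."""

    table: pd.DataFrame  # columns: dose_ratio, offset_h, zeta, dose_a, dose_b
    best: CombinationDesign


def scale_to_effect(ratio_profile, effect_target: float, m: float = DEFAULT_HILL) -> float:
    """Scalar ``s`` such that the mean of ``1 / (1 + (s r(t))^m)`` equals the target."""
    if not 0.0 < effect_target < 1.0:
        raise InputError("effect target must lie in (0, 1)")
    r = np.asarray(ratio_profile, dtype=float)
    if np.all(r == 0):
        raise InputError("cannot normalise an all-zero concentration profile")

    def residual(s: float) -> float:
        return float(np.mean(1.0 / (1.0 + (s * r) ** m))) - effect_target

    lo, hi = 1e-12, 1e12
    if not (residual(lo) > 0 > residual(hi)):
        raise FitFailureError(
            "effect target unreachable by scaling the dose",
            residuals={"at_lower": residual(lo), "at_upper": residual(hi)},
        )
    return brentq(residual, lo, hi, xtol=1e-30, rtol=8.9e-16)


def normalized_ratio_profile(
    params: PkParameters,
    potency: DrugPotency,
    effect_target: float = 0.1,
    m: float = DEFAULT_HILL,
    n_points: int = N_INTEGRATION_POINTS,
    administration_offset: float = 0.0,
) -> np.ndarray:
    """Potency-scaled daily profile ``s * C(t) / IC50`` after effect normalisation."""
    profile = profile_on_grid(params, n_points=n_points, administration_offset=administration_offset)
    r = profile.values / potency.ic50
    return scale_to_effect(r, effect_target, m) * r


def normalize_dose(
    params: PkParameters,
    potency: DrugPotency,
    effect_target: float = 0.1,
    m: float = DEFAULT_HILL,
    n_points: int = N_INTEGRATION_POINTS,
) -> float:
    """Dose scale factor that brings the daily mean fractional growth to the target."""
    profile = profile_on_grid(params, n_points=n_points)
    return scale_to_effect(profile.values / potency.ic50, effect_target, m)


def _combination_base(x: float, zeta, r_a, r_b, mode: InteractionMode):
    base = x * zeta * r_a + (1.0 - x) * zeta * r_b
    if mode is InteractionMode.NONEXCLUSIVE:
        base = base + x * (1.0 - x) * zeta * zeta * r_a * r_b
    return base


def combination_mean_growth(
    x: float,
    zeta: float,
    r_a,
    r_b,
    mode: InteractionMode,
    m: float = DEFAULT_HILL,
) -> float:
    """Daily mean fractional growth of the scaled two-drug mixture."""
    mode = InteractionMode(mode)
    if mode is InteractionMode.MIXED_TRIPLE:
        raise ModeMismatchError("pairwise combination cannot use mixed_triple mode")
    base = _combination_base(x, zeta, np.asarray(r_a, float), np.asarray(r_b, float), mode)
    return float(np.mean(1.0 / (1.0 + base ** m)))


def dose_reduction_factor(
    x: float,
    r_a,
    r_b,
    mode: InteractionMode,
    m: float = DEFAULT_HILL,
    effect_target: float = 0.1,
) -> float:
    """Solve for zeta such that the mixture meets the effect target.

    Both profiles must already be individually normalised to the same target,
    which guarantees zeta = 1 exactly at x = 0 and x = 1.
    """
    if not 0.0 <= x <= 1.0:
        raise InputError("dose ratio x must lie in [0, 1]")
    mode = InteractionMode(mode)
    if x == 0.0 or x == 1.0:
        return 1.0
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)

    def residual(zeta: float) -> float:
        return combination_mean_growth(x, zeta, r_a, r_b, mode, m) - effect_target

    lo, hi = 1e-9, 8.0
    if not (residual(lo) > 0 > residual(hi)):
        raise FitFailureError(
            "could not bracket the dose reduction factor",
            residuals={"at_lower": residual(lo), "at_upper": residual(hi)},
        )
    return brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)


def scan_combination(
    pk_a: PkParameters,
    potency_a: DrugPotency,
    pk_b: PkParameters,
    potency_b: DrugPotency,
    mode: InteractionMode = InteractionMode.NONEXCLUSIVE,
    effect_target: float = 0.1,
    m: float = DEFAULT_HILL,
    n_ratios: int = 21,
    n_offsets: int = 24,
    n_points: int = N_INTEGRATION_POINTS,
) -> ScanResult:
    """Zeta surface over equidistant dose ratios and administration offsets.

    Offsets are drug-B administration times relative to drug A, equidistant
    over one day (24 offsets means hourly).  The reported optimum is the grid
    argmin of zeta, with ties broken toward the smallest offset and then the
    smallest ``|x - 0.5|``.
    """
    mode = InteractionMode(mode)
    r_a = normalized_ratio_profile(pk_a, potency_a, effect_target, m, n_points)
    r_b0 = normalized_ratio_profile(pk_b, potency_b, effect_target, m, n_points)
    ratios = np.linspace(0.0, 1.0, n_ratios)
    offsets_h = np.arange(n_offsets) * (24.0 / n_offsets)

    records = []
    for off_h in offsets_h:
        shift = int(round(off_h / 24.0 * n_points)) % n_points
        r_b = np.roll(r_b0, shift)
        for x in ratios:
            zeta = dose_reduction_factor(x, r_a, r_b, mode, m, effect_target)
            records.append((float(x), float(off_h), zeta, x * zeta, (1.0 - x) * zeta))
    table = pd.DataFrame.from_records(
        records, columns=["dose_ratio", "offset_h", "zeta", "dose_a", "dose_b"]
    )

    order = np.lexsort(
        (np.abs(table["dose_ratio"].to_numpy() - 0.5),
         table["offset_h"].to_numpy(),
         table["zeta"].to_numpy())
    )
    opt = table.iloc[order[0]]
    best = CombinationDesign(
        drug_a=pk_a.drug_name,
        drug_b=pk_b.drug_name,
        dose_ratio=float(opt["dose_ratio"]),
        administration_offset=float(opt["offset_h"]) / 24.0,
        mode=mode,
        dose_reduction=float(opt["zeta"]),
        effect_target=effect_target,
    )
    return ScanResult(table=table, best=best)


def effective_ic50(x: float, ic50_a: float, ic50_b: float, mode: InteractionMode) -> float:
    """Single-drug-equivalent IC50 of a fixed-ratio combination.

    Exclusive mixtures combine harmonically,
    ``1 / (x / A + (1 - x) / B)``; nonexclusive mixtures gain the product
    cross term and the effective IC50 is the positive root of the resulting
    quadratic in the combined pseudo-concentration.
    """
    if not 0.0 <= x <= 1.0:
        raise InputError("dose ratio x must lie in [0, 1]")
    if ic50_a <= 0 or ic50_b <= 0:
        raise InputError("IC50 values must be positive")
    mode = InteractionMode(mode)
    beta = x / ic50_a + (1.0 - x) / ic50_b
    if mode is InteractionMode.EXCLUSIVE:
        return 1.0 / beta
    if mode is InteractionMode.NONEXCLUSIVE:
        alpha = x * (1.0 - x) / (ic50_a * ic50_b)
        # positive quadratic root written without cancellation for small alpha
        return 2.0 / (beta + np.sqrt(beta * beta + 4.0 * alpha))
    raise ModeMismatchError("effective IC50 is defined for two-drug modes only")


def mutant_sensitivity_profile(
    design: CombinationDesign,
    r_a,
    r_b,
    mutant_table: pd.DataFrame | Mapping[str, Mapping[str, float]],
    m: float = DEFAULT_HILL,
) -> pd.DataFrame:
    """Per-mutant effective relative IC50 and curve-shape flag for one design.

    ``r_a`` and ``r_b`` are the normalised potency-scaled profiles of the two
    drugs (drug B already shifted to the design's offset).  For each mutant
    with data for both drugs the effective IC50 of the combination under the
    mutant's potencies is divided by the wildtype effective value.  The
    ``shape_enhanced`` flag marks mutants for which the combination, at its
    optimised reduced doses, inhibits the mutant less than either monodrug
    alone would at its normalised dose — the dose-effect curve-shape effect
    that can make a nonexclusive combination extra sensitive to a mutation.

    Mutants lacking data for either drug are retained with ``available``
    False rather than dropped.
    """
    table = pd.DataFrame(mutant_table)
    x, zeta = design.dose_ratio, design.dose_reduction
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    wildtype_eff = effective_ic50(x, 1.0, 1.0, design.mode)

    rows = []
    for mutant, row in table.iterrows():
        rel_a = row.get(design.drug_a, np.nan)
        rel_b = row.get(design.drug_b, np.nan)
        if np.isnan(rel_a) or np.isnan(rel_b):
            rows.append((mutant, np.nan, False, False))
            continue
        eff = effective_ic50(x, rel_a, rel_b, design.mode) / wildtype_eff
        base = _combination_base(x, zeta, r_a / rel_a, r_b / rel_b, design.mode)
        fv_combo = float(np.mean(1.0 / (1.0 + base ** m)))
        fv_mono_a = float(np.mean(1.0 / (1.0 + (r_a / rel_a) ** m)))
        fv_mono_b = float(np.mean(1.0 / (1.0 + (r_b / rel_b) ** m)))
        shape_enhanced = fv_combo > max(fv_mono_a, fv_mono_b)
        rows.append((mutant, eff, shape_enhanced, True))
    return pd.DataFrame.from_records(
        rows, columns=["mutant", "effective_relative_ic50", "shape_enhanced", "available"]
    ).set_index("mutant")
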