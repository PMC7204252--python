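"""Synthetic MTS dose-response plates and ideal combination curves.

Emulates the wet-lab assay geometry used for KCL-22 cells: 96-well plates,
twofold dilution series, each curve in triplicate, with fixed-ratio drug
mixtures at the assay's stated top-concentration ratios
(imatinib:dasatinib 6.31:0.0130, imatinib:asciminib 6.31:0.0524 and
dasatinib:asciminib 0.0130:0.0524, in uM).  Signals follow the median-effect
truth model with multiplicative Gaussian noise (MTS absorbance noise is
roughly proportional to signal); the generator is deterministic per seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .inhibition import DEFAULT_HILL, DrugPotency, InteractionMode
from .synergy import DoseResponseDataset, PLATE_COLUMNS

__all__ = [
    "PlateDesign",
    "NoiseModel",
    "ASSAY_RATIOS",
    "default_truth",
    "simulate_plate",
    "simulate_ideal_combination",
]

ASSAY_RATIOS: dict[tuple[str, str], tuple[float, float]] = {
    ("imatinib", "dasatinib"): (6.31, 0.0130),
    ("imatinib", "asciminib"): (6.31, 0.0524),
    ("dasatinib", "asciminib"): (0.0130, 0.0524),
}
"""Top concentrations (uM) of the fixed-ratio mixtures measured in the assay."""


def default_truth(m: float = DEFAULT_HILL) -> dict[str, DrugPotency]:
    """Ground-truth potencies for the simulated KCL-22-like cell response.

    Synthetic stand-ins (no cell-line IC50 values are published alongside the
    assay design): chosen so each drug's dilution series, starting at the
    assay's top concentration, spans fractional inhibition of roughly
    0.05-0.95.
    """
    return {
        "imatinib": DrugPotency("imatinib", ic50=1.26, hill_m=m),
        "dasatinib": DrugPotency("dasatinib", ic50=0.0026, hill_m=m),
        "asciminib": DrugPotency("asciminib", ic50=0.0105, hill_m=m),
    }


@dataclass(frozen=True)
class PlateDesign:
    """Geometry of one simulated plate."""

    top_concentrations: dict[str, float] = field(
        default_factory=lambda: {"imatinib": 6.31, "dasatinib": 0.0130, "asciminib": 0.0524}
    )
    combination_ratios: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(ASSAY_RATIOS)
    )
    dilution_steps: int = 8  # twofold steps per curve
    replicates: int = 3
    n_controls: int = 6
    n_blanks: int = 3
    seeding_density: str = "1e4 cells/well"

    def __post_init__(self) -> None:
        if self.dilution_steps < 4:
            raise InputError("a dilution series needs at least 4 steps")
        if any(v <= 0 for v in self.top_concentrations.values()):
            raise InputError("top concentrations must be positive")
        for pair, tops in self.combination_ratios.items():
            if any(v <= 0 for v in tops):
                raise InputError(f"ratio for {pair} must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise on the viability signal."""

    signal_scale: float = 1.0
    relative_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise InputError("noise sd must be non-negative")
        if self.signal_scale <= 0:
            raise InputError("signal scale must be positive")


def _mixture_growth(
    conc_a: float,
    conc_b: float,
    pot_a: DrugPotency,
    pot_b: DrugPotency,
    mode: InteractionMode,
    m: float,
) -> float:
    t1 = conc_a / pot_a.ic50
    t2 = conc_b / pot_b.ic50
    base = t1 + t2
    if InteractionMode(mode) is InteractionMode.NONEXCLUSIVE:
        base += t1 * t2
    return 1.0 / (1.0 + base ** m)


def _wells(plate_id: str):
    """Endless stream of (plate, well) labels, 96 wells per physical plate."""
    for plate_index in itertools.count(1):
        for row, col in itertools.product("ABCDEFGH", range(1, 13)):
            yield f"{plate_id}-{plate_index}", f"{row}{col}"


def simulate_plate(
    truth: dict[str, DrugPotency] | None = None,
    mode: InteractionMode = InteractionMode.NONEXCLUSIVE,
    design: PlateDesign | None = None,
    noise: NoiseModel | None = None,
    m: float = DEFAULT_HILL,
    plate_id: str = "sim",
) -> DoseResponseDataset:
    """Simulate one plate: monodrug series, fixed-ratio mixtures, controls, blanks.

    Sample signals are ``scale * f_v * (1 + noise)`` truncated at zero;
    control wells are drug-free (``f_v = 1``) and blank wells carry no cells
    (zero signal).
    """
    truth = default_truth(m) if truth is None else truth
    design = PlateDesign() if design is None else design
    noise = NoiseModel() if noise is None else noise
    rng = np.random.default_rng(noise.seed)
    wells = _wells(plate_id)

    def signal_of(fv: float) -> float:
        s = noise.signal_scale * fv * (1.0 + rng.normal(0.0, noise.relative_sd))
        return max(s, 0.0)

    rows = []
    dilutions = 2.0 ** -np.arange(design.dilution_steps)
    for drug, top in design.top_concentrations.items():
        pot = truth[drug]
        for frac in dilutions:
            conc = top * frac
            fv = 1.0 / (1.0 + (conc / pot.ic50) ** m)
            for rep in range(1, design.replicates + 1):
                rows.append((*next(wells), drug, conc, "", 0.0, rep,
                             signal_of(fv), "sample"))
    for (drug_a, drug_b), (top_a, top_b) in design.combination_ratios.items():
        pot_a, pot_b = truth[drug_a], truth[drug_b]
        for frac in dilutions:
            ca, cb = top_a * frac, top_b * frac
            fv = _mixture_growth(ca, cb, pot_a, pot_b, mode, m)
            for rep in range(1, design.replicates + 1):
                rows.append((*next(wells), drug_a, ca, drug_b, cb, rep,
                             signal_of(fv), "sample"))
    for rep in range(1, design.n_controls + 1):
        rows.append((*next(wells), "", 0.0, "", 0.0, rep, signal_of(1.0), "control"))
    for rep in range(1, design.n_blanks + 1):
        rows.append((*next(wells), "", 0.0, "", 0.0, rep, 0.0, "blank"))

    return DoseResponseDataset(pd.DataFrame(rows, columns=PLATE_COLUMNS))


def simulate_ideal_combination(
    pot_a: DrugPotency,
    pot_b: DrugPotency,
    mode: InteractionMode,
    ratio: float,
    total_conc,
    m: float = DEFAULT_HILL,
) -> np.ndarray:
    """Noiseless fractional growth of a fixed-ratio mixture at given total doses.

    ``ratio`` is the fraction of the total concentration that is drug A; a
    ratio of 1 reproduces the drug-A monodrug curve exactly.
    """
    if not 0.0 <= ratio <= 1.0:
        raise InputError("ratio must lie in [0, 1]")
    total = np.asarray(total_conc, dtype=float)
    if np.any(total < 0):
        raise InputError("concentrations must be non-negative")
    out = np.array([
        _mixture_growth(ratio * c, (1.0 - ratio) * c, pot_a, pot_b, mode, m)
        for c in np.atleast_1d(total)
    ])
    return out if np.ndim(total_conc) else float(out[0])
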