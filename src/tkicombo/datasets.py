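"""Packaged reference tables: mutant relative IC50s, PK constants, potencies."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .inhibition import DEFAULT_HILL, DrugPotency, MutantProfile
from .pk import PkObservables, PkParameters, fit_pk_parameters

__all__ = [
    "load_mutant_table",
    "mutant_profile",
    "load_pk_table",
    "load_wildtype_potencies",
    "normalised_potencies",
]

_OBSERVABLE_COLUMNS = ("c_max", "t_max", "half_life")


def _data_path(name: str):
    return resources.files("tkicombo.data").joinpath(name)


def load_mutant_table(path: str | Path | None = None) -> pd.DataFrame:
    """Relative-IC50 matrix, one row per Bcr-Abl1 mutant, one column per drug.

    Blank cells mean the datum is unavailable (kept as NaN, never imputed).
    """
    source = _data_path("mutant_relative_ic50.csv") if path is None else path
    with resources.as_file(source) if path is None else _nullcontext(source) as p:
        table = pd.read_csv(p, comment="#", index_col="mutant")
    return table


class _nullcontext:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def mutant_profile(name: str, table: pd.DataFrame | None = None) -> MutantProfile:
    """One mutant's per-drug relative IC50 values as a :class:`MutantProfile`."""
    if table is None:
        table = load_mutant_table()
    if name not in table.index:
        raise ConfigError(f"unknown mutant {name!r}")
    row = table.loc[name].dropna()
    return MutantProfile(mutant_name=name, relative_ic50=row.to_dict())


def load_pk_table(path: str | Path | None = None, refit: bool = True) -> dict[str, PkParameters]:
    """PK parameters per drug from the packaged (or a user-supplied) config.

    When the observable columns (c_max, t_max, half_life) are present and
    ``refit`` is on, parameters are fitted from them; otherwise the explicit
    parameter columns are used directly.
    """
    source = _data_path("pk_parameters.csv") if path is None else path
    with resources.as_file(source) if path is None else _nullcontext(source) as p:
        table = pd.read_csv(p, comment="#")
    out: dict[str, PkParameters] = {}
    for _, row in table.iterrows():
        name = row["drug"]
        has_obs = refit and all(
            c in table.columns and np.isfinite(row[c]) for c in _OBSERVABLE_COLUMNS
        )
        if has_obs:
            obs = PkObservables(
                drug_name=name,
                c_max=float(row["c_max"]),
                t_max=float(row["t_max"]),
                half_life=float(row["half_life"]),
                reference_dose=float(row["dose"]),
                reference_interval=float(row["tau"]),
            )
            out[name] = fit_pk_parameters(obs)
        else:
            out[name] = PkParameters(
                drug_name=name,
                absorption_rate=float(row["k_a"]),
                elimination_rate=float(row["k_e"]),
                dose=float(row["dose"]),
                dosing_interval=float(row["tau"]),
                scaled_volume=float(row["scaled_volume"]),
            )
    return out


def load_wildtype_potencies(
    m: float = DEFAULT_HILL, path: str | Path | None = None
) -> dict[str, DrugPotency]:
    """Absolute wildtype IC50 per drug (ug/L), for plasma-scale concentrations."""
    source = _data_path("wildtype_ic50.csv") if path is None else path
    with resources.as_file(source) if path is None else _nullcontext(source) as p:
        table = pd.read_csv(p, comment="#")
    return {
        row["drug"]: DrugPotency(row["drug"], ic50=float(row["ic50_ug_per_l"]), hill_m=m)
        for _, row in table.iterrows()
    }


def normalised_potencies(drugs, m: float = DEFAULT_HILL) -> dict[str, DrugPotency]:
    """Potencies in normalised-dose units: wildtype IC50 = 1 for every drug."""
    return {d: DrugPotency(d, ic50=1.0, hill_m=m) for d in drugs}
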