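"""Orchestration of the three headline analyses into reproducible text outputs.

Every scenario is a pure function of (configuration, seed, packaged
fixtures): rerunning with the same inputs yields byte-identical tables.
Outputs are tab-separated files with a header comment recording the package
version and seed so that any figure built from them is auditable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .datasets import (
    load_mutant_table,
    load_pk_table,
    load_wildtype_potencies,
    mutant_profile,
    normalised_potencies,
)
from .doseopt import mutant_sensitivity_profile, normalized_ratio_profile, scan_combination
from .errors import ConfigError
from .inhibition import DEFAULT_HILL, InteractionMode
from .selection import SupplementScenario, optimize_supplement_offset
from .simulate import NoiseModel, simulate_plate
from .synergy import ci_curve_with_uncertainty

import numpy as np

__all__ = ["run_scenario", "DEFAULT_SCENARIOS"]

DEFAULT_SCENARIOS = ("dose-reduction", "axitinib-supplement", "synergy-ci")


def _write_table(df: pd.DataFrame, path: Path, seed, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tkicombo {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def _check_drugs(drugs, pk_table, mutant_table=None) -> None:
    for drug in drugs:
        if drug not in pk_table:
            raise ConfigError(f"drug {drug!r} is not in the PK table")
        if mutant_table is not None and drug not in mutant_table.columns:
            raise ConfigError(f"drug {drug!r} is not in the mutant table")


def run_scenario(config: Mapping, outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Run one named scenario and write its result tables under ``outdir``.

    Returns a mapping from logical output name to the written path.
    """
    name = config.get("scenario")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "dose-reduction":
        return _run_dose_reduction(config, outdir, seed)
    if name == "axitinib-supplement":
        return _run_supplement(config, outdir, seed)
    if name == "synergy-ci":
        return _run_synergy(config, outdir, seed)
    raise ConfigError(f"unknown scenario {name!r}; expected one of {DEFAULT_SCENARIOS}")


def _run_dose_reduction(config: Mapping, outdir: Path, seed) -> dict[str, Path]:
    pk_table = load_pk_table()
    mutants = load_mutant_table()
    pairs = config.get(
        "pairs",
        [[d, "asciminib"] for d in ("imatinib", "nilotinib", "dasatinib", "bosutinib", "ponatinib")],
    )
    m = float(config.get("m", DEFAULT_HILL))
    target = float(config.get("effect_target", 0.1))
    mode = InteractionMode(config.get("mode", "nonexclusive"))
    n_ratios = int(config.get("n_ratios", 21))
    n_offsets = int(config.get("n_offsets", 24))
    potencies = normalised_potencies(pk_table, m)

    outputs: dict[str, Path] = {}
    optima = []
    for drug_a, drug_b in pairs:
        _check_drugs((drug_a, drug_b), pk_table, mutants)
        scan = scan_combination(
            pk_table[drug_a], potencies[drug_a], pk_table[drug_b], potencies[drug_b],
            mode=mode, effect_target=target, m=m, n_ratios=n_ratios, n_offsets=n_offsets,
        )
        stem = f"zeta_{drug_a}_{drug_b}"
        path = outdir / f"{stem}.tsv"
        _write_table(scan.table, path, seed, index=False)
        outputs[stem] = path

        best = scan.best
        r_a = normalized_ratio_profile(pk_table[drug_a], potencies[drug_a], target, m)
        r_b = np.roll(
            normalized_ratio_profile(pk_table[drug_b], potencies[drug_b], target, m),
            int(round(best.administration_offset * r_a.size)) % r_a.size,
        )
        sens = mutant_sensitivity_profile(best, r_a, r_b, mutants, m)
        spath = outdir / f"sensitivity_{drug_a}_{drug_b}.tsv"
        _write_table(sens, spath, seed, index=True)
        outputs[f"sensitivity_{drug_a}_{drug_b}"] = spath
        optima.append(
            (drug_a, drug_b, best.dose_ratio, best.administration_offset * 24.0,
             best.dose_reduction, *best.per_drug_doses)
        )
    summary = pd.DataFrame(
        optima,
        columns=["drug_a", "drug_b", "dose_ratio", "offset_h", "zeta", "dose_a", "dose_b"],
    )
    path = outdir / "dose_reduction_optima.tsv"
    _write_table(summary, path, seed, index=False)
    outputs["optima"] = path
    return outputs


def _run_supplement(config: Mapping, outdir: Path, seed) -> dict[str, Path]:
    pk_table = load_pk_table()
    mutant_tab = load_mutant_table()
    dosing = config.get("dosing", "plasma")
    backbones = config.get("backbones", [["imatinib"], ["nilotinib"], ["dasatinib"], ["bosutinib"]])
    criterion = config.get("criterion", "min_instantaneous")
    m = float(config.get("m", DEFAULT_HILL))
    mutant_name = config.get("mutant", "T315I")
    mutant = mutant_profile(mutant_name, mutant_tab)
    potencies = load_wildtype_potencies(m)

    outputs: dict[str, Path] = {}
    summary_rows = []
    for backbone in backbones:
        _check_drugs((*backbone, "axitinib"), pk_table, mutant_tab)
        scenario = SupplementScenario(
            backbone=tuple(backbone), dosing=dosing, mutant_name=mutant_name,
            m=m, criterion=criterion,
        )
        offset, course = optimize_supplement_offset(scenario, pk_table, potencies, mutant)
        label = "_".join(backbone)
        df = pd.DataFrame({"time_d": course.time_grid, "chi": course.chi})
        path = outdir / f"chi_{label}.tsv"
        _write_table(df, path, seed, index=False)
        outputs[f"chi_{label}"] = path
        summary_rows.append(
            (label, offset * 24.0, course.minimum, course.mean, course.fraction_below_one)
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=["backbone", "axitinib_offset_h", "chi_min", "chi_mean", "fraction_chi_below_1"],
    )
    path = outdir / "supplement_summary.tsv"
    _write_table(summary, path, seed, index=False)
    outputs["summary"] = path
    return outputs


def _run_synergy(config: Mapping, outdir: Path, seed) -> dict[str, Path]:
    mode = InteractionMode(config.get("mode", "nonexclusive"))
    n_resamples = int(config.get("n_resamples", 1000))
    noise = NoiseModel(relative_sd=float(config.get("noise_sd", 0.05)), seed=seed)
    plate = simulate_plate(mode=mode, noise=noise)

    outputs: dict[str, Path] = {}
    path = outdir / "plate.csv"
    plate.to_csv(path)
    outputs["plate"] = path
    for label in plate.curve_labels():
        if "+" not in label:
            continue
        curve = ci_curve_with_uncertainty(
            plate, label, n_resamples=n_resamples, seed=seed,
        )
        df = pd.DataFrame({
            "fa": curve.fa, "ci": curve.ci, "ci_mean": curve.ci_mean,
            "lower89": curve.lower, "upper89": curve.upper,
        })
        stem = f"ci_{label.replace('+', '_')}"
        cpath = outdir / f"{stem}.tsv"
        _write_table(df, cpath, seed, index=False)
        outputs[stem] = cpath
    return outputs
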