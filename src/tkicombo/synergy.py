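"""Dose-response fitting and Chou-Talalay combination-index analysis.

Plate measurements (MTS viability signals from twofold dilution series in
triplicate) are reduced to fractional inhibition
``fa = 1 - signal / mean(control)`` after blank subtraction.  Each curve —
two single drugs and their fixed-ratio mixture — is fitted with the
median-effect equation ``fa / (1 - fa) = (D / Dm)^m`` by least squares on the
log-linearised form, and optionally with a four-parameter logistic curve.

The combination index at fractional inhibition ``fa`` is

.. math:: CI = \\frac{D_1}{D_{x,1}} + \\frac{D_2}{D_{x,2}},

where ``(D_1, D_2)`` are the components of the mixture dose achieving ``fa``
under the combination fit and ``D_{x,i}`` the monodrug dose achieving the
same ``fa``.  CI below one indicates synergy, above one antagonism.  A
three-term variant (adding ``D_1 D_2 / (D_{x,1} D_{x,2})``) is available for
mutually nonexclusive reporting.

Uncertainty is quantified with a nonparametric bootstrap over replicate
wells, reporting pointwise 89 % percentile compatibility intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import InputError, UnfittableCurveError

__all__ = [
    "PLATE_COLUMNS",
    "DoseResponseDataset",
    "MedianEffectFit",
    "FourPLFit",
    "CICurve",
    "fractional_inhibition",
    "fit_median_effect",
    "fit_four_pl",
    "combination_index",
    "ci_curve_with_uncertainty",
    "default_fa_grid",
]

PLATE_COLUMNS = [
    "plate", "well", "drug_a", "conc_a", "drug_b", "conc_b", "replicate", "signal", "role",
]

FA_CLIP = 1e-3  # wells outside (FA_CLIP, 1 - FA_CLIP) are excluded from log-linear fits


@dataclass(frozen=True)
class DoseResponseDataset:
    """Plate records: sample wells plus zero-drug control wells and blank wells."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in PLATE_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"plate table lacks columns {missing}")
        df["drug_a"] = df["drug_a"].fillna("")
        df["drug_b"] = df["drug_b"].fillna("")
        object.__setattr__(self, "data", df)

    @classmethod
    def from_csv(cls, path) -> "DoseResponseDataset":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def curve_labels(self) -> list[str]:
        samples = self.data[self.data["role"] == "sample"]
        return list(dict.fromkeys(_curve_labels(samples)))


def _curve_labels(samples: pd.DataFrame) -> np.ndarray:
    a = samples["drug_a"].to_numpy(dtype=object)
    b = samples["drug_b"].to_numpy(dtype=object)
    both = (a != "") & (b != "")
    return np.where(both, a.astype(str) + "+" + b.astype(str), np.where(a != "", a, b))


def fractional_inhibition(dataset: DoseResponseDataset) -> pd.DataFrame:
    """Per-sample-well fractional inhibition with blank subtraction.

    Blank wells set the background; control (zero-drug) wells set full
    growth.  Blank-only wells carry no fa and are excluded.  Returned frame
    adds columns ``fa``, ``total_conc`` and ``curve``.
    """
    df = dataset.data
    controls = df[df["role"] == "control"]
    if controls.empty:
        raise InputError("dataset has no control wells")
    blanks = df[df["role"] == "blank"]
    background = float(blanks["signal"].mean()) if not blanks.empty else 0.0
    control_level = float(controls["signal"].mean()) - background
    if control_level <= 0:
        raise InputError("control signal does not exceed blank background")

    samples = df[df["role"] == "sample"].copy()
    samples["fa"] = 1.0 - (samples["signal"] - background) / control_level
    samples["total_conc"] = samples["conc_a"] + samples["conc_b"]
    samples["curve"] = _curve_labels(samples)
    return samples


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters: median-effect dose Dm and slope m."""

    dm: float
    m: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.dm <= 0 or self.m <= 0:
            raise UnfittableCurveError(
                f"median-effect fit degenerate (Dm={self.dm}, m={self.m})"
            )

    def dose_for(self, fa) -> np.ndarray:
        """Dose achieving fractional inhibition ``fa`` under this fit."""
        fa = np.asarray(fa, dtype=float)
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)

    def fa_at(self, dose) -> np.ndarray:
        r = (np.asarray(dose, dtype=float) / self.dm) ** self.m
        return r / (1.0 + r)


def _median_effect_xy(conc, fa, eps: float = FA_CLIP):
    conc = np.asarray(conc, dtype=float)
    fa = np.asarray(fa, dtype=float)
    keep = (conc > 0) & (fa > eps) & (fa < 1.0 - eps)
    return np.log10(conc[keep]), np.log10(fa[keep] / (1.0 - fa[keep]))


def _median_effect_fa(conc, dm, m):
    r = (conc / dm) ** m
    return r / (1.0 + r)


def fit_median_effect(conc, fa, eps: float = FA_CLIP, method: str = "nls") -> MedianEffectFit:
    """Fit the median-effect equation ``fa / (1 - fa) = (D / Dm)^m``.

    The classic log-linearised regression of ``log(fa/fu)`` on ``log D``
    (wells clipped outside ``(eps, 1 - eps)`` excluded) always provides the
    starting point and is available as ``method="loglinear"``.  The default
    refines it by least squares on the fa scale itself, using every dosed
    well: the logit transform blows up measurement noise near fa = 0 and 1
    and its one-sided exclusion of out-of-range wells biases the slope
    downward, whereas the fa-scale fit stays unbiased at the plate's noise
    level.  Both are exact (zero residual) on noiseless median-effect data
    for any (Dm, m), and deterministic.
    """
    if method not in ("nls", "loglinear"):
        raise InputError(f"unknown fit method {method!r}")
    x, y = _median_effect_xy(conc, fa, eps)
    if x.size < 2 or np.ptp(x) == 0:
        raise UnfittableCurveError(
            "need at least two informative wells at distinct concentrations"
        )
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise UnfittableCurveError("median-effect slope is non-positive")
    dm = float(10.0 ** (-intercept / slope))
    m = float(slope)

    conc_all = np.asarray(conc, dtype=float)
    fa_all = np.asarray(fa, dtype=float)
    keep = conc_all > 0
    conc_all, fa_all = conc_all[keep], fa_all[keep]
    if method == "nls":
        try:
            with warnings.catch_warnings():
                # an interpolating fit has no residual degrees of freedom
                warnings.simplefilter("ignore", OptimizeWarning)
                (dm, m), _ = curve_fit(
                    _median_effect_fa, conc_all, fa_all, p0=(dm, m), maxfev=10000
                )
        except RuntimeError as err:
            raise UnfittableCurveError(f"median-effect fit did not converge: {err}") from err
        if dm <= 0 or m <= 0:
            raise UnfittableCurveError("median-effect fit degenerate")
        n_points = int(conc_all.size)
    else:
        n_points = int(x.size)
    resid = fa_all - _median_effect_fa(conc_all, dm, m)
    total = fa_all - np.mean(fa_all)
    ss_tot = float(total @ total)
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return MedianEffectFit(dm=float(dm), m=float(m), r_squared=r2, n_points=n_points)


@dataclass(frozen=True)
class FourPLFit:
    """Four-parameter logistic fit of raw signal against concentration."""

    bottom: float
    top: float
    midpoint: float
    slope: float
    stderr: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.top > self.bottom:
            raise UnfittableCurveError("4PL fit requires top > bottom")
        if self.midpoint <= 0:
            raise UnfittableCurveError("4PL midpoint must be positive")


def _four_pl(conc, bottom, top, midpoint, slope):
    return bottom + (top - bottom) / (1.0 + (conc / midpoint) ** slope)


def fit_four_pl(conc, signal) -> FourPLFit:
    """Fit signal = bottom + (top - bottom) / (1 + (C / mid)^slope)."""
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    keep = conc > 0
    conc, signal = conc[keep], signal[keep]
    if conc.size < 4:
        raise UnfittableCurveError("need at least four wells for a 4PL fit")
    p0 = (float(signal.min()), float(signal.max()), float(np.median(conc)), 1.0)
    try:
        popt, pcov = curve_fit(_four_pl, conc, signal, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise UnfittableCurveError(f"4PL fit did not converge: {err}") from err
    stderr = tuple(np.sqrt(np.clip(np.diag(pcov), 0, None)))
    return FourPLFit(*map(float, popt), stderr=stderr)


def combination_index(
    fa,
    combo_fit: MedianEffectFit,
    mono_fits: Sequence[MedianEffectFit],
    ratio: float,
    form: str = "exclusive",
):
    """Chou-Talalay combination index at fractional inhibition ``fa``.

    ``ratio`` is the fraction of the mixture's total concentration that is
    drug 1 (fixed-ratio design).  ``form`` selects the two-term (mutually
    exclusive, the reporting default) or three-term (nonexclusive) formula.
    """
    fa_arr = np.asarray(fa, dtype=float)
    if np.any(fa_arr <= 0) or np.any(fa_arr >= 1):
        raise InputError("fa must lie strictly inside (0, 1)")
    if not 0.0 <= ratio <= 1.0:
        raise InputError("ratio must lie in [0, 1]")
    if form not in ("exclusive", "nonexclusive"):
        raise InputError(f"unknown CI form {form!r}")
    fit1, fit2 = mono_fits
    d_total = combo_fit.dose_for(fa_arr)
    d1 = ratio * d_total
    d2 = (1.0 - ratio) * d_total
    dx1 = fit1.dose_for(fa_arr)
    dx2 = fit2.dose_for(fa_arr)
    ci = d1 / dx1 + d2 / dx2
    if form == "nonexclusive":
        ci = ci + (d1 * d2) / (dx1 * dx2)
    return ci if ci.ndim else float(ci)


@dataclass(frozen=True)
class CICurve:
    """Combination-index curve on an fa grid with 89 % compatibility intervals."""

    fa: np.ndarray
    ci: np.ndarray  # point estimate from the full-data fits
    ci_mean: np.ndarray  # bootstrap mean
    lower: np.ndarray
    upper: np.ndarray
    n_resamples: int

    def __post_init__(self) -> None:
        fa = np.asarray(self.fa, dtype=float)
        if np.any(fa <= 0) or np.any(fa >= 1):
            raise InputError("fa grid must lie strictly inside (0, 1)")


def default_fa_grid(n: int = 50) -> np.ndarray:
    return np.linspace(0.05, 0.95, n)


def _fits_for_dataset(samples: pd.DataFrame, combo_label: str):
    """Median-effect fits for the combination curve and its two monodrugs."""
    combo = samples[samples["curve"] == combo_label]
    if combo.empty:
        raise InputError(f"no wells for combination curve {combo_label!r}")
    drug_a = combo["drug_a"].iloc[0]
    drug_b = combo["drug_b"].iloc[0]
    ratio = float(
        (combo["conc_a"] / (combo["conc_a"] + combo["conc_b"])).mean()
    )
    fits = {}
    for label in (combo_label, drug_a, drug_b):
        sub = samples[samples["curve"] == label]
        if sub.empty:
            raise InputError(f"no wells for curve {label!r}")
        fits[label] = fit_median_effect(sub["total_conc"], sub["fa"])
    return fits[combo_label], (fits[drug_a], fits[drug_b]), ratio


def ci_curve_with_uncertainty(
    dataset: DoseResponseDataset,
    combo_label: str,
    fa_grid: np.ndarray | None = None,
    n_resamples: int = 1000,
    seed: int | None = 0,
    form: str = "exclusive",
) -> CICurve:
    """CI curve with bootstrap 89 % compatibility intervals.

    Resamples wells with replacement within every group of nominally
    identical wells (same curve and concentration, and the control and blank
    groups), refits all three median-effect curves jointly and recomputes CI
    on the fa grid.  Deterministic for a fixed seed.
    """
    if fa_grid is None:
        fa_grid = default_fa_grid()
    df = dataset.data
    group_keys = ["role", "drug_a", "conc_a", "drug_b", "conc_b"]
    sizes = df.groupby(group_keys).size()
    if (sizes.min() < 2) or df[df["role"] == "sample"].empty:
        raise InputError("bootstrap needs at least two replicate wells per group")

    samples = fractional_inhibition(dataset)
    combo_fit, mono_fits, ratio = _fits_for_dataset(samples, combo_label)
    point = combination_index(fa_grid, combo_fit, mono_fits, ratio, form)

    rng = np.random.default_rng(seed)
    groups = [idx.to_numpy() for _, idx in df.groupby(group_keys).groups.items()]
    curves = np.empty((n_resamples, fa_grid.size))
    kept = 0
    for _ in range(n_resamples):
        take = np.concatenate([g[rng.integers(0, g.size, g.size)] for g in groups])
        boot = DoseResponseDataset(df.loc[take].reset_index(drop=True))
        try:
            s = fractional_inhibition(boot)
            cf, mf, r = _fits_for_dataset(s, combo_label)
        except (UnfittableCurveError, InputError):
            continue  # a degenerate resample carries no CI information
        curves[kept] = combination_index(fa_grid, cf, mf, r, form)
        kept += 1
    if kept < max(10, n_resamples // 10):
        raise UnfittableCurveError("too many degenerate bootstrap resamples")
    curves = curves[:kept]
    lower, upper = np.percentile(curves, [5.5, 94.5], axis=0)
    return CICurve(
        fa=np.asarray(fa_grid, dtype=float),
        ci=np.asarray(point, dtype=float),
        ci_mean=curves.mean(axis=0),
        lower=lower,
        upper=upper,
        n_resamples=kept,
    )
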