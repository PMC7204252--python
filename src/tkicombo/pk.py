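"""One-compartment oral steady-state pharmacokinetics.

All orally dosed Bcr-Abl1 inhibitors considered here are modelled with the
classic one-compartment first-order absorption model at steady state.  Over
one dosing interval :math:`\\tau` the plasma concentration is

.. math::

    C(t) = \\frac{S F D k_a}{V_d (k_a - k_e)}
           \\left[\\frac{e^{-k_e t}}{1 - e^{-k_e \\tau}}
                - \\frac{e^{-k_a t}}{1 - e^{-k_a \\tau}}\\right],

which is periodic with the dosing interval.  The salt factor ``S``,
bioavailability ``F`` and distribution volume ``V_d`` only ever appear as the
single combination :math:`V_d S^{-1} F^{-1}` ("scaled volume") and are fitted
as one parameter.

Units used throughout the package: time in days, rates in day^-1, doses in
mg, scaled volumes in m^3, so that concentrations come out in mg/m^3, i.e.
ug/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .errors import DegenerateParameterError, FitFailureError, InputError

__all__ = [
    "PkParameters",
    "PkObservables",
    "ConcentrationProfile",
    "steady_state_concentration",
    "steady_state_auc",
    "peak_time",
    "fit_pk_parameters",
    "profile_on_grid",
]


@dataclass(frozen=True)
class PkParameters:
    """Constants of the steady-state oral one-compartment model for one drug."""

    drug_name: str
    absorption_rate: float  # k_a, day^-1
    elimination_rate: float  # k_e, day^-1
    dose: float  # D, mg
    dosing_interval: float  # tau, days
    scaled_volume: float  # V_d / (S F), m^3

    def __post_init__(self) -> None:
        if self.absorption_rate == self.elimination_rate:
            raise DegenerateParameterError(
                f"{self.drug_name}: k_a == k_e makes the two-exponential profile singular"
            )
        if not (self.absorption_rate > self.elimination_rate > 0):
            raise InputError(
                f"{self.drug_name}: require k_a > k_e > 0, "
                f"got k_a={self.absorption_rate}, k_e={self.elimination_rate}"
            )
        if self.dosing_interval <= 0:
            raise InputError(f"{self.drug_name}: dosing interval must be positive")
        if self.dose < 0:
            raise InputError(f"{self.drug_name}: dose must be non-negative")
        if self.scaled_volume <= 0:
            raise InputError(f"{self.drug_name}: scaled volume must be positive")


@dataclass(frozen=True)
class PkObservables:
    """Clinically reported steady-state observables used to fit :class:`PkParameters`."""

    drug_name: str
    c_max: float  # ug/L
    t_max: float  # days after administration
    half_life: float  # terminal half-life, days
    reference_dose: float  # mg
    reference_interval: float  # days

    def __post_init__(self) -> None:
        for field in ("c_max", "t_max", "half_life", "reference_dose", "reference_interval"):
            if getattr(self, field) <= 0:
                raise InputError(f"{self.drug_name}: {field} must be positive")
        if not self.t_max < self.reference_interval:
            raise InputError(
                f"{self.drug_name}: t_max must fall strictly inside the dosing interval"
            )


@dataclass(frozen=True)
class ConcentrationProfile:
    """A concentration time course sampled on a uniform grid covering one period.

    The grid point ``time_grid[j] = j * period / n`` covers ``[0, period)``;
    the right endpoint is the wrap-around of the left one.
    """

    time_grid: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or t.size < 2:
            raise InputError("time grid and values must be matching 1-d arrays (n >= 2)")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise InputError("concentration profile grid must be equidistant")
        if np.any(v < 0):
            raise InputError("concentrations must be non-negative")
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "values", v)

    @property
    def n_points(self) -> int:
        return int(self.time_grid.size)

    def mean(self) -> float:
        """Time-average over the period (exact trapezoid for the periodic grid)."""
        return float(np.mean(self.values))


def steady_state_concentration(params: PkParameters, t):
    """Plasma concentration at time ``t`` (days), interpreted modulo the dosing interval.

    Vectorised over ``t``.  Returns ug/L given the package's canonical units.
    """
    ka, ke, tau = params.absorption_rate, params.elimination_rate, params.dosing_interval
    tt = np.mod(np.asarray(t, dtype=float), tau)
    prefactor = params.dose * ka / (params.scaled_volume * (ka - ke))
    out = prefactor * (
        np.exp(-ke * tt) / -math.expm1(-ke * tau)
        - np.exp(-ka * tt) / -math.expm1(-ka * tau)
    )
    return out if out.ndim else float(out)


def steady_state_auc(params: PkParameters) -> float:
    """Closed-form area under the curve over one dosing interval: ``D / (V_scaled * k_e)``."""
    return params.dose / (params.scaled_volume * params.elimination_rate)


def peak_time(params: PkParameters) -> float:
    """Time of the steady-state concentration maximum within one interval."""
    ka, ke, tau = params.absorption_rate, params.elimination_rate, params.dosing_interval
    return math.log(
        (ka * -math.expm1(-ke * tau)) / (ke * -math.expm1(-ka * tau))
    ) / (ka - ke)


def _peak_time_kakt(ka: float, ke: float, tau: float) -> float:
    return math.log((ka * -math.expm1(-ke * tau)) / (ke * -math.expm1(-ka * tau))) / (ka - ke)


def fit_pk_parameters(obs: PkObservables) -> PkParameters:
    """Recover ``(k_a, k_e, scaled_volume)`` from steady-state observables.

    The terminal log-slope ties ``k_e = ln 2 / half_life`` directly; ``k_a``
    is then the root of the stationarity condition of the steady-state profile
    at ``t_max``; the scaled volume follows from linearity of the profile in
    ``D / V``.  Deterministic for fixed inputs.
    """
    ke = math.log(2.0) / obs.half_life
    tau = obs.reference_interval

    def residual(ka: float) -> float:
        return _peak_time_kakt(ka, ke, tau) - obs.t_max

    lo = ke * (1.0 + 1e-9)
    hi = max(1e4, 1e3 * ke)
    r_lo, r_hi = residual(lo), residual(hi)
    if not (r_lo > 0 > r_hi):
        raise FitFailureError(
            f"{obs.drug_name}: cannot bracket k_a for t_max={obs.t_max}; "
            "observables are inconsistent with k_a > k_e",
            residuals={"at_ka_lower": r_lo, "at_ka_upper": r_hi},
        )
    ka = brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16)

    unit = PkParameters(obs.drug_name, ka, ke, obs.reference_dose, tau, 1.0)
    scaled_volume = steady_state_concentration(unit, obs.t_max) / obs.c_max
    return replace(unit, scaled_volume=scaled_volume)


def profile_on_grid(
    params: PkParameters,
    n_points: int = 240,
    administration_offset: float = 0.0,
    day: float = 1.0,
) -> ConcentrationProfile:
    """Steady-state concentration sampled at ``n_points`` equidistant times over one day.

    ``administration_offset`` shifts the dosing time and is interpreted modulo
    the drug's dosing interval, so drugs dosed more than once per day (e.g. a
    half-day interval) tile their periodic profile across the daily grid.
    """
    if n_points < 2:
        raise InputError("n_points must be at least 2")
    t = np.arange(n_points) * (day / n_points)
    values = steady_state_concentration(params, t - administration_offset)
    return ConcentrationProfile(time_grid=t, values=np.asarray(values), period=day)
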