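"""Thermal response functions for ectotherm life-history traits.

Three functional families cover the empirically conserved shapes of
thermal reaction norms:

* Boltzmann-Arrhenius (monotonic) for mortality rates and for the
  monotonic hypothesis of competition strength,
* Gaussian (symmetric unimodal) for the birth rate and for the unimodal
  hypothesis of competition strength,
* Sharpe-Schoolfield (left-skewed) for the maturation rate, with reduced
  forms when one or both enzyme-inactivation terms cannot be estimated.

All temperatures are Kelvin, all rates per day.  Parameter containers
are frozen dataclasses validated on construction; every other module
consumes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

__all__ = [
    "ArrheniusParams",
    "GaussianParams",
    "SchoolfieldParams",
    "CompetitionSpec",
    "arrhenius_rate",
    "gaussian_rate",
    "maturation_rate",
    "competition_strength",
    "stage_duration",
]


def _check_positive_temperature(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("temperature must be positive (Kelvin)")
    return t


@dataclass(frozen=True)
class ArrheniusParams:
    """Boltzmann-Arrhenius response: rate(T) = v_ref * exp(A*(1/T_ref - 1/T)).

    Parameters
    ----------
    value_at_ref : float
        Rate per day at the reference temperature ``t_ref``.
    arrhenius : float
        Arrhenius constant A in Kelvin (activation enthalpy over the gas
        constant); positive A gives a rate increasing with temperature.
    t_ref : float
        Reference temperature in Kelvin, chosen inside the range of full
        enzyme activity (typically 20-30 degC).
    """

    value_at_ref: float
    arrhenius: float
    t_ref: float = 297.0

    def __post_init__(self):
        if not (self.value_at_ref > 0):
            raise ValueError("value_at_ref must be > 0")
        if not (self.t_ref > 273):
            raise ValueError("t_ref must be > 273 K")
        if not math.isfinite(self.arrhenius):
            raise ValueError("arrhenius must be finite")


@dataclass(frozen=True)
class GaussianParams:
    """Gaussian response: rate(T) = peak * exp(-(T - t_opt)^2 / (2*breadth^2)).

    ``breadth`` is the response-breadth s in Kelvin (the temperature range
    over which the trait operates); the maximum ``peak`` occurs at ``t_opt``.
    """

    peak: float
    t_opt: float
    breadth: float

    def __post_init__(self):
        if not (self.peak > 0):
            raise ValueError("peak must be > 0")
        if not (self.breadth > 0):
            raise ValueError("breadth must be > 0")


@dataclass(frozen=True)
class SchoolfieldParams:
    """Sharpe-Schoolfield thermodynamic rate-process response for maturation.

    Full form::

        m(T) = (T/t_ref) * v_ref * exp(A*(1/t_ref - 1/T))
               / (1 + exp(a_low*(1/t_half_low - 1/T))
                    + exp(a_high*(1/t_half_high - 1/T)))

    ``t_half_low``/``t_half_high`` are the temperatures of 50% enzyme
    activity; ``a_low``/``a_high`` the associated inactivation enthalpies
    over the gas constant, in Kelvin.  Absent (``None``) low-side fields
    select the reduced high-inactivation-only form; with both sides absent
    the response degenerates to a plain exponential
    ``v_ref * exp(A*(1/t_ref - 1/T))`` without the ``T/t_ref`` prefactor,
    appropriate when only the rising portion of the curve was measured.
    """

    value_at_ref: float
    arrhenius: float
    t_ref: float = 297.0
    a_low: Optional[float] = None
    t_half_low: Optional[float] = None
    a_high: Optional[float] = None
    t_half_high: Optional[float] = None

    def __post_init__(self):
        if not (self.value_at_ref > 0):
            raise ValueError("value_at_ref must be > 0")
        if (self.a_low is None) != (self.t_half_low is None):
            raise ValueError("a_low and t_half_low must be given together")
        if (self.a_high is None) != (self.t_half_high is None):
            raise ValueError("a_high and t_half_high must be given together")
        if self.t_half_low is not None and not (self.t_half_low >= 273):
            # the freezing point itself is an admissible (and conventional) pin
            raise ValueError("t_half_low must be >= 273 K")
        if (
            self.t_half_low is not None
            and self.t_half_high is not None
            and not (self.t_half_low < self.t_half_high)
        ):
            raise ValueError("t_half_low must be < t_half_high")
        if self.a_low is not None and self.t_half_high is None:
            raise ValueError("low-side inactivation requires the high side too")

    @property
    def form(self) -> Literal["full", "high_only", "exponential"]:
        if self.a_low is not None:
            return "full"
        if self.a_high is not None:
            return "high_only"
        return "exponential"


@dataclass(frozen=True)
class CompetitionSpec:
    """Temperature dependence of per-capita self-limitation strength q(T).

    ``acts_on`` names the demographic rate bearing the density dependence.
    ``shape`` selects between the two hypotheses for q(T): ``monotonic``
    (Boltzmann-Arrhenius, activity-driven resource demand) or ``unimodal``
    (Gaussian, demand peaking at the reproductive optimum).  Exactly the
    parameter block matching ``shape`` must be populated; units of q are
    per individual.
    """

    acts_on: Literal["fecundity", "adult_mortality", "juvenile_mortality"]
    shape: Literal["monotonic", "unimodal"]
    monotonic_params: Optional[ArrheniusParams] = None
    unimodal_params: Optional[GaussianParams] = None

    def __post_init__(self):
        if self.acts_on not in ("fecundity", "adult_mortality", "juvenile_mortality"):
            raise ValueError(f"unknown acts_on: {self.acts_on!r}")
        if self.shape == "monotonic":
            if self.monotonic_params is None or self.unimodal_params is not None:
                raise ValueError("monotonic shape requires exactly monotonic_params")
        elif self.shape == "unimodal":
            if self.unimodal_params is None or self.monotonic_params is not None:
                raise ValueError("unimodal shape requires exactly unimodal_params")
        else:
            raise ValueError(f"unknown shape: {self.shape!r}")


def arrhenius_rate(p: ArrheniusParams, t):
    """Boltzmann-Arrhenius rate at temperature ``t`` (Kelvin).

    Strictly increasing in ``t`` for positive Arrhenius constant and equal
    to ``p.value_at_ref`` at ``p.t_ref``.
    """
    t = _check_positive_temperature(t)
    out = p.value_at_ref * np.exp(p.arrhenius * (1.0 / p.t_ref - 1.0 / t))
    return float(out) if out.ndim == 0 else out


def gaussian_rate(p: GaussianParams, t):
    """Gaussian rate at temperature ``t`` (Kelvin); maximal at ``p.t_opt``."""
    t = _check_positive_temperature(t)
    out = p.peak * np.exp(-((t - p.t_opt) ** 2) / (2.0 * p.breadth**2))
    return float(out) if out.ndim == 0 else out


def maturation_rate(p: SchoolfieldParams, t):
    """Maturation rate at temperature ``t`` under the form selected by ``p``.

    The full form divides the Arrhenius kinetics by both inactivation
    terms; the high-only form drops the low-temperature term; the
    exponential form drops the denominator and the ``T/t_ref`` prefactor.
    """
    t = _check_positive_temperature(t)
    if p.form == "exponential":
        out = p.value_at_ref * np.exp(p.arrhenius * (1.0 / p.t_ref - 1.0 / t))
        return float(out) if out.ndim == 0 else out
    num = (t / p.t_ref) * p.value_at_ref * np.exp(p.arrhenius * (1.0 / p.t_ref - 1.0 / t))
    den = 1.0 + np.exp(p.a_high * (1.0 / p.t_half_high - 1.0 / t))
    if p.form == "full":
        den = den + np.exp(p.a_low * (1.0 / p.t_half_low - 1.0 / t))
    out = num / den
    return float(out) if out.ndim == 0 else out


def competition_strength(c: CompetitionSpec, t):
    """Per-capita competition coefficient q(T) at temperature ``t``.

    Dispatches to the Arrhenius or Gaussian evaluator on the populated
    parameter block; the functional forms are shared with the trait
    responses.
    """
    if c.shape == "monotonic":
        return arrhenius_rate(c.monotonic_params, t)
    return gaussian_rate(c.unimodal_params, t)


def stage_duration(p: SchoolfieldParams, t):
    """Juvenile stage duration tau(T) = 1/m(T) in days at constant ``t``."""
    m = maturation_rate(p, t)
    if np.any(np.asarray(m) <= 0.0):
        raise ValueError("maturation rate is zero: stage duration is infinite")
    return 1.0 / m
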