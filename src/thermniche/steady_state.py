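"""Equilibria, stability, and recovery time of the density-dependent model.

In a constant thermal environment the delayed model admits closed-form
steady states.  Writing x(T) = b(T) S_J(T) / d_A(T) for the lifetime
replacement ratio (with S_J = exp(-d_J/m_J) and tau = 1/m_J):

* density-dependent fecundity, B = b exp(-q_b A):
      A* = ln(x) / q_b(T)            (viable when x > 1)
* density-dependent adult mortality, D_A = d_A (1 + q_d A):
      A* = (x - 1) / q_d(T)          (viable when x > 1)

and J* = B* A* (1 - S_J) / d_J from the juvenile balance.

Because S_J and tau are constants at fixed temperature and juveniles do
not feed back on the adult equation, the linearization about A* closes
on the scalar delayed characteristic equation

    lambda = -a + c exp(-lambda tau)

with (a, c) = (d_A, d_A (1 - q_b A*)) under DD fecundity and
(d_A (1 + 2 q_d A*), b S_J) under DD mortality.  All roots are
lambda_k = -a + W_k(c tau e^{a tau}) / tau over the Lambert-W branches;
the dominant (maximal real part) root comes from the principal branch
(paired with its conjugate when complex), and is cross-checked by
argument-principle root counting in a rectangle to its right.  The
recovery time after a small perturbation is

    t_recovery = -Re(lambda) / |lambda|^2 ,

positive whenever the equilibrium is stable.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import lambertw

from .responses import ArrheniusParams, CompetitionSpec, GaussianParams, competition_strength
from .species import SpeciesTraits
from .dde import ModelSpec

__all__ = [
    "EquilibriumResult",
    "StabilityResult",
    "EnvelopeCurve",
    "equilibrium",
    "dd_envelope",
    "dominant_eigenvalue",
    "recovery_curve",
    "characteristic_roots",
    "count_characteristic_roots",
    "unimodal_fecundity_competition",
    "monotonic_mortality_competition",
]


def unimodal_fecundity_competition(
    traits: SpeciesTraits, q_at_opt: float = 0.1
) -> CompetitionSpec:
    """Baseline DD-fecundity configuration: unimodal q(T) centred on the
    reproductive optimum with the birth-response breadth."""
    return CompetitionSpec(
        acts_on="fecundity",
        shape="unimodal",
        unimodal_params=GaussianParams(q_at_opt, traits.birth.t_opt, traits.birth.breadth),
    )


def monotonic_mortality_competition(
    traits: SpeciesTraits, q_at_ref: float = 0.1, t_ref: float = 297.0
) -> CompetitionSpec:
    """Baseline DD-adult-mortality configuration: Arrhenius q(T) with the
    species' adult-mortality Arrhenius constant."""
    return CompetitionSpec(
        acts_on="adult_mortality",
        shape="monotonic",
        monotonic_params=ArrheniusParams(q_at_ref, traits.adult_mortality.arrhenius, t_ref),
    )


@dataclass(frozen=True)
class EquilibriumResult:
    """Closed-form steady state of the DD model at constant temperature."""

    adults_star: float
    juveniles_star: float
    viable: bool
    dd_trait: str
    t: float


@dataclass(frozen=True)
class StabilityResult:
    """Dominant eigenvalue of the delayed linearization about A*."""

    dominant_eigenvalue: complex
    stable: bool
    recovery_time: float  # days; NaN when unstable
    residual: float  # |lambda + a - c e^(-lambda tau)|


@dataclass(frozen=True)
class EnvelopeCurve:
    """A quantity evaluated on a temperature grid plus its refined extremum."""

    temperatures: np.ndarray
    values: np.ndarray
    t_best: float
    value_best: float


def _constant_temperature(model: ModelSpec, t: Optional[float]) -> float:
    if t is not None:
        return float(t)
    if not model.forcing.is_constant:
        raise ValueError("steady-state analysis requires constant forcing")
    return model.forcing.mean


def equilibrium(model: ModelSpec, t: Optional[float] = None) -> EquilibriumResult:
    """Closed-form equilibrium abundances at constant temperature.

    Supports density dependence on fecundity or adult mortality; the
    population is non-viable (zero steady state) when lifetime
    replacement b S_J / d_A does not exceed one.
    """
    if model.competition is None:
        raise ValueError("equilibrium requires a density-dependent model")
    acts_on = model.competition.acts_on
    if acts_on == "juvenile_mortality":
        raise NotImplementedError(
            "closed-form equilibria are implemented for density dependence "
            "on fecundity or adult mortality"
        )
    tk = _constant_temperature(model, t)
    traits = model.traits
    m = traits.maturation_rate(tk)
    if m <= 0:
        raise ValueError("zero maturation rate")
    tau = 1.0 / m
    d_j = traits.juvenile_mortality_rate(tk)
    d_a = traits.adult_mortality_rate(tk)
    b = traits.birth_rate(tk)
    s_j = math.exp(-d_j * tau)
    x = b * s_j / d_a
    q = competition_strength(model.competition, tk)
    if x <= 1.0 or q <= 0.0:
        return EquilibriumResult(0.0, 0.0, False, acts_on, tk)
    if acts_on == "fecundity":
        a_star = math.log(x) / q
        b_eff = d_a / s_j  # b * exp(-q A*) at equilibrium
    else:
        a_star = (x - 1.0) / q
        b_eff = b
    j_star = b_eff * a_star * (1.0 - s_j) / d_j
    return EquilibriumResult(a_star, j_star, True, acts_on, tk)


def _linearization(model: ModelSpec, eq: EquilibriumResult) -> Tuple[float, float, float]:
    """(a, c, tau) of the scalar delayed characteristic equation."""
    tk = eq.t
    traits = model.traits
    tau = 1.0 / traits.maturation_rate(tk)
    d_a = traits.adult_mortality_rate(tk)
    s_j = math.exp(-traits.juvenile_mortality_rate(tk) * tau)
    q = competition_strength(model.competition, tk)
    if eq.dd_trait == "fecundity":
        a = d_a
        c = d_a * (1.0 - q * eq.adults_star)
    else:
        a = d_a * (1.0 + 2.0 * q * eq.adults_star)
        c = traits.birth_rate(tk) * s_j
    return a, c, tau


def _w_branch_log(log_mod: float, arg_angle: float, k: int) -> complex:
    """Branch-k Lambert W of x given Log x = log_mod + i*arg_angle.

    Falls back to scipy for representable arguments; otherwise iterates
    the asymptotic fixed point w = Log x + 2 pi i k - Log w.
    """
    if log_mod < 650.0:
        return complex(lambertw(cmath.exp(complex(log_mod, arg_angle)), k))
    target = complex(log_mod, arg_angle) + 2j * math.pi * k
    w = target
    for _ in range(300):
        wn = target - cmath.log(w)
        if abs(wn - w) < 1e-14 * abs(wn):
            w = wn
            break
        w = wn
    return w


def characteristic_roots(
    a: float, c: float, tau: float, n_branches: int = 8
) -> list:
    """Roots of lambda = -a + c exp(-lambda tau) from Lambert-W branches.

    Each candidate is polished by complex Newton iteration on the
    characteristic function and kept only if its residual is below
    1e-10 (|a| + |c|).  Returned sorted by decreasing real part.
    """
    if c == 0.0:
        return [complex(-a, 0.0)]
    log_mod = math.log(abs(c) * tau) + a * tau
    ang = math.pi if c < 0 else 0.0
    roots = []
    scale = abs(a) + abs(c)
    for k in range(-n_branches, n_branches + 1):
        w = _w_branch_log(log_mod, ang, k)
        lam = (w - a * tau) / tau
        for _ in range(50):  # Newton polish
            g = lam + a - c * cmath.exp(-lam * tau)
            if abs(g) < 1e-12 * scale:
                break
            gp = 1.0 + c * tau * cmath.exp(-lam * tau)
            if gp == 0:
                break
            lam = lam - g / gp
        res = abs(lam + a - c * cmath.exp(-lam * tau))
        if res < 1e-10 * scale and not any(abs(lam - r) < 1e-9 * (1 + abs(lam)) for r in roots):
            roots.append(lam)
    roots.sort(key=lambda z: -z.real)
    return roots


def count_characteristic_roots(
    a: float,
    c: float,
    tau: float,
    re_bounds: Tuple[float, float],
    im_bounds: Tuple[float, float],
    n: int = 4000,
) -> int:
    """Number of characteristic roots inside a rectangle, by the argument
    principle (winding number of lambda + a - c e^(-lambda tau) along the
    boundary)."""
    re0, re1 = re_bounds
    im0, im1 = im_bounds
    corners = [
        complex(re0, im0),
        complex(re1, im0),
        complex(re1, im1),
        complex(re0, im1),
        complex(re0, im0),
    ]
    pts = []
    for z0, z1 in zip(corners[:-1], corners[1:]):
        s = np.linspace(0.0, 1.0, n // 4, endpoint=False)
        pts.extend(z0 + (z1 - z0) * s)
    pts.append(corners[0])
    vals = np.array([z + a - c * cmath.exp(-z * tau) for z in pts])
    if np.any(np.abs(vals) == 0.0):
        raise RuntimeError("root on contour")
    total = np.sum(np.angle(vals[1:] / vals[:-1]))
    return int(round(total / (2.0 * math.pi)))


def dominant_eigenvalue(
    model: ModelSpec, eq: EquilibriumResult, validate: bool = True
) -> StabilityResult:
    """Dominant root of the delayed characteristic equation at ``eq``.

    With ``validate=True`` an argument-principle count confirms no root
    lies to the right of the reported one (the rectangle is widened once
    before failing).
    """
    if not eq.viable:
        raise ValueError("equilibrium is not viable")
    a, c, tau = _linearization(model, eq)
    n_branches = 8
    while True:
        roots = characteristic_roots(a, c, tau, n_branches=n_branches)
        lam = roots[0]
        if not validate:
            break
        margin = 1e-6 * (1.0 + abs(lam))
        re_hi = 5.0 * abs(a) + abs(c) + 1.0
        im_hi = abs(lam.imag) + 6.0 * math.pi / tau
        extra = count_characteristic_roots(
            a, c, tau, (lam.real + margin, re_hi), (-im_hi, im_hi)
        )
        if extra == 0:
            break
        if n_branches >= 40:
            raise RuntimeError(
                "argument-principle count disagrees with Lambert-W branch scan"
            )
        n_branches = 40
    residual = abs(lam + a - c * cmath.exp(-lam * tau))
    stable = lam.real < 0.0
    recovery = (-lam.real / abs(lam) ** 2) if stable else math.nan
    return StabilityResult(lam, stable, recovery, residual)


def _refine(fn, temps, values, minimize: bool, xatol: float = 1e-3):
    vals = np.where(np.isnan(values), math.inf if minimize else -math.inf, values)
    i = int(np.argmin(vals) if minimize else np.argmax(vals))
    lo = temps[max(i - 1, 0)]
    hi = temps[min(i + 1, len(temps) - 1)]
    if lo == hi:
        return float(temps[i]), float(values[i])
    sign = 1.0 if minimize else -1.0
    res = minimize_scalar(
        lambda t: sign * fn(t), bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    return float(res.x), float(sign * res.fun)


def dd_envelope(model: ModelSpec, temperatures: Sequence[float]) -> EnvelopeCurve:
    """Climate envelope under density dependence: A*(T) with its argmax.

    Non-viable temperatures contribute zero abundance; the argmax is
    refined by bounded maximization to 1e-3 K.
    """
    temps = np.asarray(temperatures, dtype=float)
    values = np.array([equilibrium(model, t).adults_star for t in temps])

    def a_star(t):
        return equilibrium(model, t).adults_star

    t_best, v_best = _refine(a_star, temps, values, minimize=False)
    return EnvelopeCurve(temps, values, t_best, v_best)


def recovery_curve(model: ModelSpec, temperatures: Sequence[float]) -> EnvelopeCurve:
    """Recovery time vs temperature, restricted to stable viable equilibria,
    with the argmin refined to 1e-3 K."""
    temps = np.asarray(temperatures, dtype=float)

    def trec(t):
        eq = equilibrium(model, t)
        if not eq.viable:
            return math.nan
        st = dominant_eigenvalue(model, eq, validate=False)
        return st.recovery_time if st.stable else math.nan

    values = np.array([trec(t) for t in temps])
    if np.all(np.isnan(values)):
        raise ValueError("no stable viable equilibrium on the temperature grid")
    t_best, v_best = _refine(trec, temps, values, minimize=True)
    return EnvelopeCurve(temps, values, t_best, v_best)
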