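"""Intrinsic growth rate, fundamental thermal niche, and niche overlap.

For a two-stage (juvenile/adult) ectotherm population in a constant
thermal environment, the long-term density-independent growth rate has
the closed form

    r(T) = -d_A(T) + (1/tau) * W( b(T) * tau * exp(tau * (d_A - d_J)) ),

with tau = 1/m_J(T) the juvenile stage duration and W the principal
(positive) real branch of the Lambert W function.  The fundamental
thermal niche is the interval (Tmin, Tmax) on which r(T) > 0; its
optimum Topt_r is where r is maximized.  Interspecific niche overlap is
measured on the shared temperature interval by the area under the lower
of the two growth-rate curves (the sum of the one-sided r-integrals
split at the temperature where the curves intersect), expressed as a
fraction of each species' full-niche r-integral.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar
from scipy.special import lambertw

from .species import SpeciesTraits

__all__ = [
    "intrinsic_growth_rate",
    "NicheMetrics",
    "niche_metrics",
    "OverlapResult",
    "niche_overlap",
    "DEFAULT_SEARCH_RANGE",
]

logger = logging.getLogger(__name__)

#: Default Kelvin search window; spans all biologically plausible niches
#: while avoiding the Schoolfield singularities at extreme cold.
DEFAULT_SEARCH_RANGE = (274.0, 323.0)

_LOG_SAFE = 650.0  # exp() overflows near 709; stay clear


def _lambertw_principal_log(ln_arg: float) -> float:
    """Principal-branch W(x) given ln(x), stable for arbitrarily large x.

    For moderate arguments defers to scipy; beyond the float range of
    exp() it solves w + ln w = ln x by Newton iteration (the asymptotic
    regime where W(x) ~ ln x - ln ln x).
    """
    if ln_arg < _LOG_SAFE:
        return float(lambertw(math.exp(ln_arg)).real)
    w = ln_arg - math.log(ln_arg)
    for _ in range(100):
        f = w + math.log(w) - ln_arg
        w -= f / (1.0 + 1.0 / w)
        if abs(f) < 1e-13 * max(1.0, abs(ln_arg)):
            break
    return w


def intrinsic_growth_rate(traits: SpeciesTraits, t) -> float:
    """Density-independent intrinsic growth rate r(T) per day.

    Evaluated through the Lambert-W closed form; the argument of W is
    always positive, so the principal branch is real.  Overflow-prone
    regimes (very long stage durations at thermal extremes) are handled
    in log space.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        m = traits.maturation_rate(ti)
        if m <= 0.0:
            raise ValueError("maturation rate is zero: growth rate undefined")
        tau = 1.0 / m
        b = traits.birth_rate(ti)
        d_a = traits.adult_mortality_rate(ti)
        d_j = traits.juvenile_mortality_rate(ti)
        if b <= 0.0:
            out[i] = -d_a
            continue
        ln_arg = math.log(b * tau) + tau * (d_a - d_j)
        out[i] = -d_a + _lambertw_principal_log(ln_arg) / tau
    return float(out[0]) if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class NicheMetrics:
    """Fundamental thermal niche of one species (temperatures in Kelvin).

    ``viable`` is False when r(T) <= 0 everywhere on the search range, in
    which case the remaining fields are NaN/empty.
    """

    t_min: float
    t_max: float
    t_opt_r: float
    r_max: float
    r_curve: np.ndarray = field(repr=False)  # shape (n, 2): temperature, r
    viable: bool = True


def niche_metrics(
    traits: SpeciesTraits,
    search_range: Tuple[float, float] = DEFAULT_SEARCH_RANGE,
    curve_step: float = 0.05,
) -> NicheMetrics:
    """Locate Tmin, Tmax and Topt_r for one species.

    The optimum is found by bounded scalar maximization (1e-4 K), the
    niche limits by bracketed root finding of r(T) = 0 on either side of
    the optimum (1e-6 K).  Root brackets are seeded from sign changes of
    the sampled r-curve; with multiple sign changes on one side (possible
    with reduced maturation forms at extreme tails) the bracket nearest
    the optimum is used and a warning is logged.
    """
    lo, hi = search_range
    grid = np.arange(lo, hi + curve_step / 2, curve_step)
    r_grid = intrinsic_growth_rate(traits, grid)
    curve = np.column_stack([grid, r_grid])

    if np.all(r_grid <= 0.0):
        return NicheMetrics(math.nan, math.nan, math.nan, math.nan, curve, viable=False)

    # refine the optimum in a window around the sampled argmax: r(T) can be
    # near-flat far from the peak, where a global bounded search may stall
    i_max = int(np.argmax(r_grid))
    res = minimize_scalar(
        lambda t: -intrinsic_growth_rate(traits, t),
        bounds=(grid[max(i_max - 1, 0)], grid[min(i_max + 1, len(grid) - 1)]),
        method="bounded",
        options={"xatol": 1e-4},
    )
    t_opt = float(res.x)
    r_max = intrinsic_growth_rate(traits, t_opt)

    def _root(side: str) -> float:
        if side == "low":
            mask = grid < t_opt
            sign_change = np.flatnonzero(np.diff(np.sign(r_grid[mask])) != 0)
            idx = np.flatnonzero(mask)[sign_change]
        else:
            mask = grid > t_opt
            sign_change = np.flatnonzero(np.diff(np.sign(r_grid[mask])) != 0)
            idx = np.flatnonzero(mask)[0] + sign_change
        if len(idx) == 0:
            # no sign change sampled: the limit sits at the range edge
            return lo if side == "low" else hi
        if len(idx) > 1:
            logger.warning(
                "multiple r(T)=0 sign changes on the %s side; using the one nearest Topt_r",
                side,
            )
        i = idx[-1] if side == "low" else idx[0]
        return brentq(
            lambda t: intrinsic_growth_rate(traits, t), grid[i], grid[i + 1], xtol=1e-6
        )

    t_min = _root("low")
    t_max = _root("high")
    return NicheMetrics(float(t_min), float(t_max), t_opt, float(r_max), curve)


@dataclass(frozen=True)
class OverlapResult:
    """Thermal-niche overlap between two species (Kelvin, per-day units).

    ``shared_area`` is the overlap measure: the one-sided integral of
    species a's r up to ``t_intersect`` plus species b's r beyond it,
    i.e. the area under min(r_a, r_b) on the overlap interval.
    ``fraction_a``/``fraction_b`` divide that area by each species'
    full-niche r-integral.
    """

    t_intersect: float
    overlap_interval: Tuple[float, float]
    integral_a_over_overlap: float
    integral_b_over_overlap: float
    integral_a_total: float
    integral_b_total: float
    shared_area: float
    fraction_a: float
    fraction_b: float


def _empty_overlap(int_a: float, int_b: float) -> OverlapResult:
    return OverlapResult(
        t_intersect=math.nan,
        overlap_interval=(math.nan, math.nan),
        integral_a_over_overlap=0.0,
        integral_b_over_overlap=0.0,
        integral_a_total=int_a,
        integral_b_total=int_b,
        shared_area=0.0,
        fraction_a=0.0,
        fraction_b=0.0,
    )


def niche_overlap(
    a: SpeciesTraits,
    b: SpeciesTraits,
    search_range: Tuple[float, float] = DEFAULT_SEARCH_RANGE,
    metrics_a: Optional[NicheMetrics] = None,
    metrics_b: Optional[NicheMetrics] = None,
) -> OverlapResult:
    """Quantify the thermal-niche overlap of two species.

    The intersection temperature solves r_a(T) = r_b(T) on the overlap
    interval to |r_a - r_b| <= 1e-6; integrals use adaptive quadrature
    (absolute tolerance 1e-8).  Disjoint niches give an empty interval
    and zero fractions.  When the two growth curves are numerically
    identical (species compared against itself) the intersection is
    reported at the interval midpoint and both fractions are 1.
    """
    ma = metrics_a or niche_metrics(a, search_range)
    mb = metrics_b or niche_metrics(b, search_range)
    if not (ma.viable and mb.viable):
        raise ValueError("both species must be viable to compute overlap")

    r_a = lambda t: intrinsic_growth_rate(a, t)  # noqa: E731
    r_b = lambda t: intrinsic_growth_rate(b, t)  # noqa: E731
    int_a = quad(r_a, ma.t_min, ma.t_max, epsabs=1e-8, limit=200)[0]
    int_b = quad(r_b, mb.t_min, mb.t_max, epsabs=1e-8, limit=200)[0]

    lo = max(ma.t_min, mb.t_min)
    hi = min(ma.t_max, mb.t_max)
    if lo >= hi:
        return _empty_overlap(int_a, int_b)

    diff = lambda t: r_a(t) - r_b(t)  # noqa: E731
    probe = np.linspace(lo, hi, 201)
    dvals = np.array([diff(t) for t in probe])
    if np.max(np.abs(dvals)) < 1e-9:
        # identical niches: full mutual overlap
        mid = 0.5 * (lo + hi)
        return OverlapResult(
            t_intersect=mid,
            overlap_interval=(lo, hi),
            integral_a_over_overlap=int_a,
            integral_b_over_overlap=int_b,
            integral_a_total=int_a,
            integral_b_total=int_b,
            shared_area=int_a,
            fraction_a=1.0,
            fraction_b=1.0,
        )

    crossings = np.flatnonzero(np.diff(np.sign(dvals)) != 0)
    if len(crossings) == 0:
        # one species dominates throughout the interval: the shared area
        # is the smaller curve's integral over the interval
        lower = r_a if dvals.mean() > 0 else r_b
        shared = quad(lower, lo, hi, epsabs=1e-8, limit=200)[0]
        shared = max(shared, 0.0)
        return OverlapResult(
            t_intersect=math.nan,
            overlap_interval=(lo, hi),
            integral_a_over_overlap=shared if lower is r_a else 0.0,
            integral_b_over_overlap=shared if lower is r_b else 0.0,
            integral_a_total=int_a,
            integral_b_total=int_b,
            shared_area=shared,
            fraction_a=shared / int_a,
            fraction_b=shared / int_b,
        )
    i = crossings[0]
    t_int = brentq(diff, probe[i], probe[i + 1], xtol=1e-10)
    assert abs(diff(t_int)) <= 1e-6

    # which species is the lower curve on each side of the intersection
    a_lower_left = diff(0.5 * (lo + t_int)) < 0
    left_fn, right_fn = (r_a, r_b) if a_lower_left else (r_b, r_a)
    left = quad(left_fn, lo, t_int, epsabs=1e-8, limit=200)[0]
    right = quad(right_fn, t_int, hi, epsabs=1e-8, limit=200)[0]
    shared = left + right
    int_a_ov = left if a_lower_left else right
    int_b_ov = right if a_lower_left else left
    return OverlapResult(
        t_intersect=float(t_int),
        overlap_interval=(float(lo), float(hi)),
        integral_a_over_overlap=int_a_ov,
        integral_b_over_overlap=int_b_ov,
        integral_a_total=int_a,
        integral_b_total=int_b,
        shared_area=shared,
        fraction_a=shared / int_a,
        fraction_b=shared / int_b,
    )
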