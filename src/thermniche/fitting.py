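"""Nonlinear least-squares fitting of thermal response functions.

`ThermalResponseModel` fits one response family to per-temperature mean
trait values by unweighted least squares, the convention for reaction-
norm data where each mean carries similar reliability.  Standard errors
are asymptotic: the residual-variance-scaled inverse Gauss-Newton
normal matrix, with t statistics and two-sided p-values on the residual
degrees of freedom — matching what R's ``nls`` reports.  Reference-
temperature trait values are conventionally measured, not estimated,
and can be pinned through ``fixed``.

The skewed maturation surface has local minima in (t_half_high, a_high),
so fits multi-start from a coarse grid and keep the lowest sum of
squares (ties broken by the smaller parameter norm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import t as t_dist

from .observations import TraitObservations
from .responses import ArrheniusParams, GaussianParams, SchoolfieldParams

__all__ = [
    "FAMILIES",
    "ThermalResponseModel",
    "ThermalResponseResults",
    "RankDeficiencyWarning",
    "fit_response",
]


class RankDeficiencyWarning(UserWarning):
    """The normal matrix is (near-)singular: some parameter is weakly
    identified by the data and its standard error is unreliable."""


FAMILIES = {
    "gaussian": ("peak", "t_opt", "breadth"),
    "arrhenius": ("value_at_ref", "arrhenius"),
    "exponential": ("value_at_ref", "arrhenius"),
    "schoolfield_high": ("value_at_ref", "arrhenius", "a_high", "t_half_high"),
    "schoolfield": (
        "value_at_ref",
        "arrhenius",
        "a_low",
        "t_half_low",
        "a_high",
        "t_half_high",
    ),
}


def _predict(family: str, p: Dict[str, float], t: np.ndarray, t_ref: float) -> np.ndarray:
    if family == "gaussian":
        return p["peak"] * np.exp(-((t - p["t_opt"]) ** 2) / (2.0 * p["breadth"] ** 2))
    base = p["value_at_ref"] * np.exp(p["arrhenius"] * (1.0 / t_ref - 1.0 / t))
    if family in ("arrhenius", "exponential"):
        return base
    den = 1.0 + np.exp(p["a_high"] * (1.0 / p["t_half_high"] - 1.0 / t))
    if family == "schoolfield":
        den = den + np.exp(p["a_low"] * (1.0 / p["t_half_low"] - 1.0 / t))
    return (t / t_ref) * base / den


def _bounds(family: str, names, t: np.ndarray):
    lo_t, hi_t = float(t.min()), float(t.max())
    table = {
        "peak": (1e-10, np.inf),
        "breadth": (1e-3, 200.0),
        "t_opt": (lo_t - 30.0, hi_t + 30.0),
        "value_at_ref": (1e-10, np.inf),
        "arrhenius": (-1e6, 1e6),
        "a_low": (-1e7, 1e7),
        "t_half_low": (273.0 + 1e-6, hi_t + 50.0),
        "a_high": (1.0, 1e7),
        "t_half_high": (lo_t - 10.0, hi_t + 60.0),
    }
    lo = np.array([table[n][0] for n in names])
    hi = np.array([table[n][1] for n in names])
    return lo, hi


def _starts(family: str, names, t: np.ndarray, y: np.ndarray, t_ref: float, fixed):
    """Heuristic starting points; several for multi-modal surfaces."""
    eps = max(1e-12, 1e-6 * max(y.max(), 1e-12))
    slope_x = 1.0 / t_ref - 1.0 / t
    # Arrhenius linearization for rate-like params
    pos = y > 0
    if pos.sum() >= 2:
        coef = np.polyfit(slope_x[pos], np.log(y[pos] + eps), 1)
        v0, a0 = float(np.exp(coef[1])), float(coef[0])
    else:
        v0, a0 = max(y.mean(), eps), 1e4
    a0 = float(np.clip(a0, -9e5, 9e5))
    v0 = max(v0, 1e-9)

    base = {
        "peak": max(y.max(), eps),
        "t_opt": float(t[np.argmax(y)]),
        "breadth": max((t.max() - t.min()) / 4.0, 1.0),
        "value_at_ref": v0,
        "arrhenius": a0 if a0 != 0 else 1e4,
        "a_low": -1e5,
        "t_half_low": 273.5,
        "a_high": 5e4,
        "t_half_high": float(t.max()),
    }
    base.update(fixed)
    starts = [dict(base)]
    if family == "gaussian":
        for topt in (t.min(), 0.5 * (t.min() + t.max()), t.max()):
            s = dict(base)
            s["t_opt"] = float(topt)
            starts.append(s)
    if family in ("schoolfield", "schoolfield_high"):
        for th in (t.max() - 3.0, t.max() + 5.0, t.max() + 15.0):
            for ah in (2e4, 8e4):
                s = dict(base)
                s["t_half_high"], s["a_high"] = float(th), ah
                starts.append(s)
    return [np.array([s[n] for n in names]) for s in starts]


@dataclass
class ThermalResponseResults:
    """Estimates and asymptotic inference for one response-family fit."""

    family: str
    t_ref: float
    estimates: Dict[str, float]
    standard_errors: Dict[str, float]
    t_values: Dict[str, float]
    p_values: Dict[str, float]
    dof: int
    ssr: float
    converged: bool
    fixed: Dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def params(self) -> Dict[str, float]:
        """All parameters, estimated and pinned."""
        return {**self.estimates, **self.fixed}

    def to_params(self):
        """Typed parameter object usable by the response evaluators."""
        p = self.params
        if self.family == "gaussian":
            return GaussianParams(p["peak"], p["t_opt"], p["breadth"])
        if self.family == "arrhenius":
            return ArrheniusParams(p["value_at_ref"], p["arrhenius"], self.t_ref)
        kwargs = dict(
            value_at_ref=p["value_at_ref"], arrhenius=p["arrhenius"], t_ref=self.t_ref
        )
        if self.family == "schoolfield":
            kwargs.update(a_low=p["a_low"], t_half_low=p["t_half_low"])
        if self.family in ("schoolfield", "schoolfield_high"):
            kwargs.update(a_high=p["a_high"], t_half_high=p["t_half_high"])
        return SchoolfieldParams(**kwargs)

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, est in self.estimates.items():
            rows.append(
                (
                    name,
                    est,
                    self.standard_errors[name],
                    self.t_values[name],
                    self.p_values[name],
                    self.dof,
                    False,
                )
            )
        for name, val in self.fixed.items():
            rows.append((name, val, np.nan, np.nan, np.nan, np.nan, True))
        return pd.DataFrame(
            rows, columns=["parameter", "estimate", "se", "t_value", "p_value", "df", "fixed"]
        )

    def summary(self) -> str:
        lines = [
            f"Thermal response fit: family={self.family}  t_ref={self.t_ref:.1f} K",
            f"converged={self.converged}  ssr={self.ssr:.6g}  df={self.dof}",
            f"{'parameter':>14} {'estimate':>12} {'se':>10} {'t':>8} {'p':>10}",
        ]
        for name, est in self.estimates.items():
            lines.append(
                f"{name:>14} {est:>12.5g} {self.standard_errors[name]:>10.3g} "
                f"{self.t_values[name]:>8.3g} {self.p_values[name]:>10.3g}"
            )
        for name, val in self.fixed.items():
            lines.append(f"{name:>14} {val:>12.5g} {'(fixed)':>10}")
        if self.message:
            lines.append(self.message)
        return "\n".join(lines)


class ThermalResponseModel:
    """Least-squares model for one trait's thermal response.

    Parameters
    ----------
    observations : TraitObservations
        Per-temperature mean trait values.
    family : str
        One of ``gaussian``, ``arrhenius``, ``exponential``,
        ``schoolfield_high`` (no low-temperature inactivation) or
        ``schoolfield`` (full).
    t_ref : float
        Reference temperature (Kelvin), held constant.
    fixed : dict, optional
        Parameters pinned at assigned values (e.g. the measured
        reference trait value, or unidentifiable inactivation terms).
    """

    def __init__(
        self,
        observations: TraitObservations,
        family: str,
        t_ref: float = 297.0,
        fixed: Optional[Dict[str, float]] = None,
    ):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
        self.observations = observations
        self.family = family
        self.t_ref = float(t_ref)
        self.fixed = dict(fixed or {})
        unknown = set(self.fixed) - set(FAMILIES[family])
        if unknown:
            raise ValueError(f"fixed parameters not in family: {sorted(unknown)}")
        self.free_names = [n for n in FAMILIES[family] if n not in self.fixed]
        n_points = len(observations.data)
        if n_points - len(self.free_names) < 1:
            raise ValueError(
                f"{n_points} points cannot identify {len(self.free_names)} free "
                "parameters with at least one residual degree of freedom"
            )

    def predict(self, params: Dict[str, float], t) -> np.ndarray:
        return _predict(self.family, params, np.asarray(t, dtype=float), self.t_ref)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        p = dict(zip(self.free_names, x))
        p.update(self.fixed)
        return (
            _predict(self.family, p, self.observations.temperatures, self.t_ref)
            - self.observations.means
        )

    def fit(self, multistart: bool = True) -> ThermalResponseResults:
        t = self.observations.temperatures
        y = self.observations.means
        lo, hi = _bounds(self.family, self.free_names, t)
        starts = _starts(self.family, self.free_names, t, y, self.t_ref, self.fixed)
        if not multistart:
            starts = starts[:1]

        best = None
        for x0 in starts:
            x0 = np.clip(x0, lo + 1e-12, hi - 1e-12 if np.all(np.isfinite(hi)) else hi)
            try:
                res = least_squares(
                    self._residuals,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=5000,
                )
            except Exception:  # pragma: no cover - defensive
                continue
            ssr = float(2.0 * res.cost)
            norm = float(np.linalg.norm(res.x))
            key = (round(ssr, 12), norm)
            if best is None or key < (round(best[0], 12), best[1]):
                best = (ssr, norm, res)
        if best is None:
            return ThermalResponseResults(
                self.family,
                self.t_ref,
                {},
                {},
                {},
                {},
                dof=0,
                ssr=np.inf,
                converged=False,
                fixed=dict(self.fixed),
                message="optimizer failed from every start",
            )
        ssr, _, res = best
        dof = len(y) - len(self.free_names)
        s2 = ssr / dof

        jac = res.jac
        u, sv, vt = np.linalg.svd(jac, full_matrices=False)
        if sv[0] == 0 or sv[-1] / sv[0] < 1e-10:
            weakest = self.free_names[int(np.argmax(np.abs(vt[-1])))]
            warnings.warn(
                f"normal matrix is rank deficient: parameter '{weakest}' is not "
                "identified by these data; standard errors use a pseudoinverse",
                RankDeficiencyWarning,
                stacklevel=2,
            )
            cov = s2 * np.linalg.pinv(jac.T @ jac, rcond=1e-10)
        else:
            cov = s2 * (vt.T @ np.diag(1.0 / sv**2) @ vt)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))

        estimates = dict(zip(self.free_names, map(float, res.x)))
        ses = dict(zip(self.free_names, map(float, se)))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = {
                n: (estimates[n] / ses[n]) if ses[n] > 0 else np.inf for n in self.free_names
            }
        pvals = {
            n: float(2.0 * t_dist.sf(abs(tvals[n]), dof)) if np.isfinite(tvals[n]) else 0.0
            for n in self.free_names
        }
        return ThermalResponseResults(
            family=self.family,
            t_ref=self.t_ref,
            estimates=estimates,
            standard_errors=ses,
            t_values={n: float(v) for n, v in tvals.items()},
            p_values=pvals,
            dof=dof,
            ssr=ssr,
            converged=bool(res.success),
            fixed=dict(self.fixed),
            message="" if res.success else str(res.message),
        )


def fit_response(
    obs: TraitObservations,
    family: str,
    fixed: Optional[Dict[str, float]] = None,
    t_ref: float = 297.0,
    multistart: bool = True,
) -> ThermalResponseResults:
    """Fit a response family to trait observations (convenience wrapper)."""
    return ThermalResponseModel(obs, family, t_ref=t_ref, fixed=fixed).fit(
        multistart=multistart
    )
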