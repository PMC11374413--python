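"""Per-temperature trait observations and the synthetic-data generator.

Trait values are measured on individual insects reared at a handful of
constant temperatures; analyses work with the per-temperature means,
their standard errors and replicate counts.  The generator emulates
such replicate measurements around a known parameter set: each
individual value is the true rate times a multiplicative Gaussian error
(truncated at zero), matching the roughly proportional scatter of
life-history rate data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .species import EXPERIMENT_TEMPS_C, SpeciesTraits
from .units import to_kelvin

__all__ = ["TRAITS", "TraitObservations", "generate_trait_data", "reference_value"]

TRAITS = ("birth", "maturation", "juvenile_mortality", "adult_mortality")


@dataclass
class TraitObservations:
    """Aggregated trait measurements: one row per rearing temperature.

    ``data`` columns: ``temperature_k``, ``mean`` (trait units per day),
    ``se`` (same units), ``n`` (replicate count).  At least three
    distinct temperatures are required, strictly increasing after sort.
    """

    trait: str
    data: pd.DataFrame

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}; expected one of {TRAITS}")
        required = {"temperature_k", "mean", "se", "n"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = self.data.sort_values("temperature_k").reset_index(drop=True)
        t = df["temperature_k"].to_numpy(dtype=float)
        if len(t) < 3 or np.any(np.diff(t) <= 0):
            raise ValueError("need >= 3 strictly distinct temperatures")
        if np.any(df["mean"].to_numpy(dtype=float) < 0):
            raise ValueError("mean trait values must be >= 0")
        self.data = df

    @property
    def temperatures(self) -> np.ndarray:
        return self.data["temperature_k"].to_numpy(dtype=float)

    @property
    def means(self) -> np.ndarray:
        return self.data["mean"].to_numpy(dtype=float)

    @classmethod
    def from_aggregated(cls, df: pd.DataFrame, trait: str, celsius: bool = False):
        """Build from a table with columns temperature(_c|_k), mean, se, n."""
        df = df.copy()
        if "temperature_c" in df.columns:
            df["temperature_k"] = to_kelvin(df.pop("temperature_c"))
        elif celsius:
            df["temperature_k"] = to_kelvin(df["temperature_k"])
        return cls(trait, df[["temperature_k", "mean", "se", "n"]])

    @classmethod
    def from_long(cls, df: pd.DataFrame, trait: str):
        """Aggregate a long table (one row per individual) with columns
        temperature_c (or temperature_k) and value."""
        df = df.copy()
        if "temperature_c" in df.columns:
            df["temperature_k"] = to_kelvin(df.pop("temperature_c"))
        grouped = df.groupby("temperature_k")["value"]
        agg = pd.DataFrame(
            {
                "mean": grouped.mean(),
                "se": grouped.sem().fillna(0.0),
                "n": grouped.size(),
            }
        ).reset_index()
        return cls(trait, agg)


def reference_value(obs: TraitObservations, t_ref: float = 297.0) -> float:
    """Observed mean at the temperature nearest ``t_ref``.

    Reference trait values are conventionally measured rather than
    estimated, so fits pin the reference parameter at this value.
    """
    i = int(np.argmin(np.abs(obs.temperatures - t_ref)))
    return float(obs.means[i])


def _true_rate(truth: SpeciesTraits, trait: str, t: float) -> float:
    return {
        "birth": truth.birth_rate,
        "maturation": truth.maturation_rate,
        "juvenile_mortality": truth.juvenile_mortality_rate,
        "adult_mortality": truth.adult_mortality_rate,
    }[trait](t)


def generate_trait_data(
    truth: SpeciesTraits,
    temperatures: Optional[Sequence[float]] = None,
    n_per_temp: int = 20,
    noise_sd_frac: float = 0.05,
    seed: int = 0,
) -> Dict[str, TraitObservations]:
    """Synthesize replicate trait measurements around a known species.

    Individual values are drawn as truth(T) * (1 + Normal(0, sd_frac)),
    truncated at zero, then aggregated to per-temperature mean/SE/n.
    ``temperatures`` (Kelvin) defaults to the species' rearing-experiment
    treatment set when the species name is recognised, otherwise to the
    eight-treatment set.  The same seed always reproduces the same
    tables.
    """
    if n_per_temp < 1:
        raise ValueError("n_per_temp must be >= 1")
    if noise_sd_frac < 0:
        raise ValueError("noise_sd_frac must be >= 0")
    if temperatures is None:
        temps_c = EXPERIMENT_TEMPS_C.get(
            truth.name.lower(), EXPERIMENT_TEMPS_C["harlequin"]
        )
        temperatures = [to_kelvin(c) for c in temps_c]
    temps = np.asarray(temperatures, dtype=float)
    rng = np.random.default_rng(seed)
    out: Dict[str, TraitObservations] = {}
    for trait in TRAITS:
        rows = []
        for t in temps:
            mu = _true_rate(truth, trait, float(t))
            values = mu * (1.0 + rng.normal(0.0, noise_sd_frac, size=n_per_temp))
            values = np.maximum(values, 0.0)
            se = (
                float(np.std(values, ddof=1) / np.sqrt(n_per_temp))
                if n_per_temp > 1 and noise_sd_frac > 0
                else 0.0
            )
            rows.append((float(t), float(values.mean()), se, n_per_temp))
        out[trait] = TraitObservations(
            trait,
            pd.DataFrame(rows, columns=["temperature_k", "mean", "se", "n"]),
        )
    return out
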