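"""Species trait containers and fixture I/O.

A :class:`SpeciesTraits` bundles the four fitted thermal responses a
species needs for the population models: Gaussian birth rate,
Sharpe-Schoolfield maturation rate, and Arrhenius juvenile/adult
mortality rates.  Shipped fixtures carry the published parameter sets
for the invasive bagrada bug (*Bagrada hilaris*), the naturalized
harlequin bug (*Murgantia histrionica*), and a generic warm-adapted
ectotherm used for qualitative model exploration.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .responses import (
    ArrheniusParams,
    GaussianParams,
    SchoolfieldParams,
    arrhenius_rate,
    gaussian_rate,
    maturation_rate,
)

__all__ = [
    "SpeciesTraits",
    "FixtureError",
    "load_species",
    "bagrada",
    "harlequin",
    "generic_warm",
    "EXPERIMENT_TEMPS_C",
]

#: Constant-temperature treatments used in the rearing experiments, degC.
EXPERIMENT_TEMPS_C = {
    "bagrada": (24.0, 27.0, 30.0, 33.0, 35.0, 36.0),
    "harlequin": (15.0, 18.0, 21.0, 24.0, 27.0, 29.0, 33.0, 35.0),
}


class FixtureError(ValueError):
    """Raised when a species fixture violates parameter invariants."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid species fixture:\n" + "\n".join(self.errors))


@dataclass(frozen=True)
class SpeciesTraits:
    """Fitted thermal-response parameter set for one species."""

    name: str
    birth: GaussianParams
    maturation: SchoolfieldParams
    juvenile_mortality: ArrheniusParams
    adult_mortality: ArrheniusParams

    # rate shorthands used throughout the dynamics modules
    def birth_rate(self, t):
        return gaussian_rate(self.birth, t)

    def maturation_rate(self, t):
        return maturation_rate(self.maturation, t)

    def juvenile_mortality_rate(self, t):
        return arrhenius_rate(self.juvenile_mortality, t)

    def adult_mortality_rate(self, t):
        return arrhenius_rate(self.adult_mortality, t)

    def stage_duration(self, t):
        """Juvenile stage duration tau(T) = 1/m(T), days."""
        return 1.0 / self.maturation_rate(t)

    def juvenile_survivorship(self, t):
        """Through-stage survivorship S_J(T) = exp(-d_J(T) * tau(T))."""
        return np.exp(-self.juvenile_mortality_rate(t) * self.stage_duration(t))


def _build(errors, label, cls, **kwargs):
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{label}: {exc}")
        return None


def _parse_species(doc: dict, origin: str) -> SpeciesTraits:
    errors = []
    name = doc.get("name")
    if not isinstance(name, str) or not name:
        errors.append("name: missing or empty")
        name = origin

    def section(key, fields):
        block = doc.get(key)
        if not isinstance(block, dict):
            errors.append(f"{key}: missing section")
            return None
        unknown = set(block) - set(fields)
        if unknown:
            errors.append(f"{key}: unknown fields {sorted(unknown)}")
        return block

    birth = None
    b = section("birth", {"peak", "t_opt", "breadth"})
    if b is not None:
        missing = {"peak", "t_opt", "breadth"} - set(b)
        if missing:
            errors.append(f"birth: missing fields {sorted(missing)}")
        else:
            for f in ("peak", "t_opt", "breadth"):
                if not isinstance(b[f], (int, float)):
                    errors.append(f"birth.{f}: not a number")
            try:
                birth = GaussianParams(b["peak"], b["t_opt"], b["breadth"])
            except (TypeError, ValueError) as exc:
                errors.append(f"birth.{_offending_gaussian(b)}: {exc}")

    m = section(
        "maturation",
        {"value_at_ref", "arrhenius", "t_ref", "a_low", "t_half_low", "a_high", "t_half_high"},
    )
    maturation = None
    if m is not None:
        maturation = _build(errors, "maturation", SchoolfieldParams, **m)

    mortality = {}
    for key in ("juvenile_mortality", "adult_mortality"):
        blk = section(key, {"value_at_ref", "arrhenius", "t_ref"})
        if blk is not None:
            mortality[key] = _build(errors, key, ArrheniusParams, **blk)
        else:
            mortality[key] = None

    if errors or birth is None or maturation is None or None in mortality.values():
        raise FixtureError(errors or ["incomplete record"])
    return SpeciesTraits(
        name=name,
        birth=birth,
        maturation=maturation,
        juvenile_mortality=mortality["juvenile_mortality"],
        adult_mortality=mortality["adult_mortality"],
    )


def _offending_gaussian(block) -> str:
    if not (block["peak"] > 0):
        return "peak"
    if not (block["breadth"] > 0):
        return "breadth"
    return "t_opt"


def load_species(path) -> SpeciesTraits:
    """Load and validate a species fixture from a TOML file.

    Partial or invalid records raise :class:`FixtureError` listing every
    violated field rather than failing on the first.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return _parse_species(doc, origin=path.stem)


def _shipped(name: str) -> SpeciesTraits:
    ref = resources.files("thermniche.data").joinpath(f"{name}.toml")
    doc = tomllib.loads(ref.read_text())
    return _parse_species(doc, origin=name)


def bagrada() -> SpeciesTraits:
    """Published parameter set for the invasive bagrada bug."""
    return _shipped("bagrada")


def harlequin() -> SpeciesTraits:
    """Published parameter set for the naturalized harlequin bug."""
    return _shipped("harlequin")


def generic_warm() -> SpeciesTraits:
    """Generic warm-adapted ectotherm used for qualitative predictions."""
    return _shipped("generic_warm")
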