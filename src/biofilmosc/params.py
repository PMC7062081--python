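"""Model parameters and state containers for the biofilm oscillator.

The model describes three well-mixed pools — peripheral glutamate ``Gp``,
ammonia ``A`` and interior glutamate ``Gi`` — in a two-compartment biofilm.
All concentrations are in mmol/l and time is in hours throughout the package.
The global variable ordering is ``(Gp, A, Gi[, B])`` and every array, matrix
row/column and CSV column in the package follows it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = ["ParameterSet", "State", "VARIABLES", "RATE_CONSTANTS"]

#: Canonical ordering of the dynamic variables.
VARIABLES = ("Gp", "A", "Gi")

#: Rate constants that enter the kinetic equations (b only enters growth).
RATE_CONSTANTS = ("k1", "k2", "k3", "k4", "k5")

_VARIANTS = ("baseline", "self_amplified")


@dataclass(frozen=True)
class ParameterSet:
    """The seven constants of the biofilm oscillator.

    Parameters
    ----------
    k1 : float
        Rate constant of glutamate uptake from the environment by the
        biofilm periphery, (mmol/l h)^-1.  The uptake term ``k1*G_E*Gp``
        is self-amplifying in ``Gp``.
    k2 : float
        Biomass formation coefficient for the bilinear consumption of
        ammonia and peripheral glutamate, (mmol/l h)^-1.
    k3 : float
        First-order rate constant of ammonia diffusion out of the
        biofilm, 1/h.
    k4 : float
        First-order rate constant of glutamate transfer from the
        periphery into the interior, 1/h.
    k5 : float
        First-order rate constant of ammonia production from interior
        glutamate (glutamate dehydrogenase activity), 1/h.
    G_E : float
        External glutamate concentration, mmol/l.  Held constant
        (supplied in large excess) and used as the main bifurcation
        parameter.
    b : float
        Conversion factor for biomass production, ((mmol/l)^2 h)^-1.
    variant : str
        ``"baseline"`` uses the linear transfer term ``k4*Gp``;
        ``"self_amplified"`` replaces it by ``k4*Gi*Gp`` wherever it
        appears, modelling self-amplified import into the interior.
    """

    k1: float = 0.3426
    k2: float = 5.3
    k3: float = 4.0
    k4: float = 2.0
    k5: float = 2.3
    G_E: float = 30.0
    b: float = 0.1
    variant: str = "baseline"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "variant":
                continue
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"parameter {f.name} must be a finite number, got {v!r}")
            if v <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {v}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")

    # ------------------------------------------------------------------
    # Derived quantities
    # ------------------------------------------------------------------
    @property
    def k(self) -> float:
        """Aggregate net peripheral growth constant ``k1*G_E - k4`` (1/h)."""
        return self.k1 * self.G_E - self.k4

    # ------------------------------------------------------------------
    # Construction / modification
    # ------------------------------------------------------------------
    @classmethod
    def default(cls) -> "ParameterSet":
        """Return the reference parameterization of the biofilm model."""
        return cls()

    def replace(self, **kwargs: object) -> "ParameterSet":
        """Return a copy with the given fields overridden."""
        return replace(self, **kwargs)  # type: ignore[arg-type]

    def values(self, names: Iterable[str]) -> np.ndarray:
        """Numeric values for the given parameter names, in order."""
        return np.array([float(getattr(self, n)) for n in names])

    # ------------------------------------------------------------------
    # Flat key-value serialization (YAML-subset)
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), default_flow_style=False, sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class State:
    """One point of the model: concentrations, optionally with biomass.

    ``Gp``, ``A``, ``Gi`` are concentrations in mmol/l; ``B`` (cells/l)
    is present only in growth-augmented states.
    """

    Gp: float
    A: float
    Gi: float
    B: float | None = None

    def __post_init__(self) -> None:
        for name in ("Gp", "A", "Gi"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"state component {name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"state component {name} must be >= 0, got {v}")
        if self.B is not None and (not math.isfinite(self.B) or self.B < 0):
            raise ValueError(f"biomass B must be finite and >= 0, got {self.B}")

    @property
    def has_biomass(self) -> bool:
        return self.B is not None

    def concentrations(self) -> np.ndarray:
        """The (Gp, A, Gi) triple as an array."""
        return np.array([self.Gp, self.A, self.Gi])

    def as_array(self) -> np.ndarray:
        """Full state vector, including B when present."""
        if self.B is None:
            return self.concentrations()
        return np.array([self.Gp, self.A, self.Gi, self.B])

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "State":
        y = list(map(float, y))
        if len(y) == 3:
            return cls(*y)
        if len(y) == 4:
            return cls(y[0], y[1], y[2], y[3])
        raise ValueError(f"state vector must have 3 or 4 components, got {len(y)}")


def as_state(state: "State | Iterable[float]") -> State:
    """Coerce an array-like or State into a validated State."""
    if isinstance(state, State):
        return state
    return State.from_array(np.asarray(state, dtype=float))
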