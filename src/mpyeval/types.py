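"""Domain containers shared across the package.

Quantities follow the conventions of protein-nutrition modelling for
lactating dairy cows: supplies and expenditures are daily flows in g/d,
energy in Mcal/d (converted to MJ/d where an equation requires it), body
weight in kg, days in milk (DIM) in d, and the rolling herd average (RHA)
in kg milk true protein per 305-d lactation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Scenario",
    "CowRecord",
    "SupplyProfile",
    "ExpenditureProfile",
    "PredictionResult",
    "InvalidInputError",
]


class InvalidInputError(ValueError):
    """Raised when a physical quantity violates its domain contract."""


class Scenario(str, enum.Enum):
    """Dry matter intake prediction scenario.

    ``DMI_Ao`` is predicted from animal traits only; ``DMI_AR`` from animal
    plus ration fibre traits. Every cow can carry one nutrient-supply
    profile per scenario.
    """

    DMI_Ao = "DMI_Ao"
    DMI_AR = "DMI_AR"

    @classmethod
    def parse(cls, label: str) -> "Scenario":
        try:
            return cls(label)
        except ValueError:
            aliases = {"ao": cls.DMI_Ao, "ar": cls.DMI_AR, "a&r": cls.DMI_AR,
                       "dmi_a&r": cls.DMI_AR}
            key = str(label).strip().lower()
            if key in aliases:
                return aliases[key]
            raise InvalidInputError(f"unknown scenario label: {label!r}")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidInputError(msg)


@dataclass(frozen=True)
class CowRecord:
    """One cow: identity, body/lactation state, herd production level, and
    the observed milk protein yield it is evaluated against."""

    cow_id: str
    herd_id: str
    parity: int
    bw: float          # body weight, kg
    dim: float         # days in milk, d
    mpy_obs: float     # observed milk protein yield, g/d
    rha: Optional[float] = None  # rolling herd average, kg true protein/305 d

    def __post_init__(self) -> None:
        _require(self.bw > 0, f"bw must be > 0, got {self.bw}")
        _require(self.dim >= 1, f"dim must be >= 1, got {self.dim}")
        _require(self.mpy_obs >= 0, f"mpy_obs must be >= 0, got {self.mpy_obs}")
        _require(self.parity >= 1, f"parity must be >= 1, got {self.parity}")
        if self.rha is not None:
            _require(self.rha > 0, f"rha, when present, must be > 0, got {self.rha}")


@dataclass(frozen=True)
class SupplyProfile:
    """Predicted nutrient supplies for one cow under one DMI scenario.

    The five essential amino acids (His, Ile, Leu, Lys, Met) are digested
    flows, ``oaa`` groups the remaining amino acids
    (NEAA + Arg + Phe + Thr + Trp + Val), and ``eaa_sq`` is the sum of the
    five squared EAA supplies (g²/d²). ``de_np`` is the non-protein fraction
    of digestible energy intake.
    """

    scenario: Scenario
    dmi: float          # kg DM/d
    mp_supply: float    # g MP/d
    his: float          # g/d
    ile: float
    leu: float
    lys: float
    met: float
    oaa: float          # g/d
    de_intake: float    # Mcal/d
    de_np: float        # Mcal/d, non-protein DE
    dndf_kg: float      # digestible NDF, kg/d
    eaa_sq: float = field(default=math.nan)  # g²/d²; computed when nan

    def __post_init__(self) -> None:
        for name in ("dmi", "mp_supply", "his", "ile", "leu", "lys", "met",
                     "oaa", "de_intake", "de_np", "dndf_kg"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"{name} must be finite and >= 0, got {v}")
        _require(self.de_np <= self.de_intake + 1e-9 * max(1.0, self.de_intake),
                 f"de_np ({self.de_np}) must not exceed de_intake ({self.de_intake})")
        computed = self.his**2 + self.ile**2 + self.leu**2 + self.lys**2 + self.met**2
        if math.isnan(self.eaa_sq):
            object.__setattr__(self, "eaa_sq", computed)
        else:
            scale = max(computed, 1.0)
            _require(abs(self.eaa_sq - computed) <= 1e-9 * scale,
                     f"eaa_sq ({self.eaa_sq}) inconsistent with sum of squared EAA ({computed})")


@dataclass(frozen=True)
class ExpenditureProfile:
    """Protein expenditures for one cow, on a metabolizable-protein basis.

    Export expenditures (metabolic fecal, scurf, growth) convert to a
    true-protein basis through ``target_eff`` (the fixed target efficiency
    of MP utilization, default 69%). Urinary endogenous loss is already a
    protein flow and is used unconverted.
    """

    tpuri: float         # urinary endogenous loss, g protein/d
    tpfecal_mp: float    # metabolic fecal, g MP-basis/d
    tpscurf_mp: float    # scurf, g MP-basis/d
    tpgrowth_mp: float   # growth deposition, g MP-basis/d
    target_eff: float = 0.69  # dimensionless fraction

    def __post_init__(self) -> None:
        for name in ("tpuri", "tpfecal_mp", "tpscurf_mp", "tpgrowth_mp"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"{name} must be finite and >= 0, got {v}")
        _require(0 < self.target_eff <= 1,
                 f"target_eff must be in (0, 1], got {self.target_eff}")


@dataclass(frozen=True)
class PredictionResult:
    """Predicted milk protein yields for one cow under one scenario.

    ``mpy_multi`` comes from the multivariate supply/BW equation, ``eff``
    is the predicted variable efficiency of MP utilization (%), ``ratio``
    its energy-normalized MP driver (g MP net of urinary endogenous loss
    per MJ DE), and ``mpy_eff`` the yield predicted through that
    efficiency. Predictions are reported unclamped and may be negative.
    """

    cow_id: str
    scenario: Scenario
    mpy_multi: float   # g/d
    eff: float         # %
    ratio: float       # g/MJ
    mpy_eff: float     # g/d

    def __post_init__(self) -> None:
        _require(math.isfinite(self.eff), f"eff must be finite, got {self.eff}")
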