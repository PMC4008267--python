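"""Closed-form bench calculations: growth accounting and UVB dosimetry.

Two small formulas used when running a repeated-sublethal-UVB senescence
experiment on diploid fibroblasts:

* cumulative population doublings (cPDL) over one passage, from the cell
  count at the end of the passage (A) and the count seeded at its start (B):
  ``cPDL = (log10(A) - log10(B)) / 0.301``.  The divisor is the printed
  laboratory constant 0.301, not ``log10(2) = 0.30103...``; the two differ
  by about 0.01%, and the printed constant is kept so results match the
  lab convention.

* irradiation time in seconds for a target UVB dose: energy per area
  (J/m^2) divided by the lamp's measured power per area (W/m^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DoseSpec",
    "GrowthObservation",
    "cumulative_pdl",
    "irradiation_time",
    "irradiation_time_seconds",
]

#: printed lab constant standing in for log10(2)
PDL_DIVISOR = 0.301


@dataclass(frozen=True)
class GrowthObservation:
    """Cell counts bracketing one passage: ``cells_end`` (A), ``cells_seeded`` (B)."""

    cells_end: float
    cells_seeded: float

    def __post_init__(self) -> None:
        if self.cells_end <= 0 or self.cells_seeded <= 0:
            raise ValueError(
                f"cell counts must be positive, got A={self.cells_end}, B={self.cells_seeded}"
            )


@dataclass(frozen=True)
class DoseSpec:
    """A UVB dose: ``energy_per_area`` in J/m^2 and lamp ``power_per_area`` in W/m^2."""

    energy_per_area: float
    power_per_area: float

    def __post_init__(self) -> None:
        if self.energy_per_area < 0:
            raise ValueError(f"energy per area must be >= 0, got {self.energy_per_area}")
        if self.power_per_area <= 0:
            raise ValueError(f"power per area must be > 0, got {self.power_per_area}")


def cumulative_pdl(obs: GrowthObservation) -> float:
    """Population doublings over one passage; negative if the culture shrank."""
    return (math.log10(obs.cells_end) - math.log10(obs.cells_seeded)) / PDL_DIVISOR


def irradiation_time(spec: DoseSpec) -> float:
    """Exposure time in seconds delivering ``energy_per_area`` at ``power_per_area``."""
    return spec.energy_per_area / spec.power_per_area


def irradiation_time_seconds(spec: DoseSpec) -> int:
    """`irradiation_time` rounded to whole seconds, half away from zero.

    Python's built-in ``round`` is banker's rounding; timers are set with
    conventional half-up rounding, so .5 always rounds away from zero here.
    """
    t = irradiation_time(spec)
    return int(math.floor(t + 0.5))
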