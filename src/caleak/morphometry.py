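"""ER size arithmetic from segmented cross-section areas.

Inputs are pre-measured areas (µm²) from confocal cross-sections; the ER
volume fraction is estimated stereologically from the area fraction as
``volume_fraction = area_fraction ** (3/2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError

__all__ = ["AreaMeasurements", "FractionResult", "er_volume_fraction", "append_fractions", "round_half_up"]


@dataclass(frozen=True)
class AreaMeasurements:
    """Cross-section areas of one cell, µm²; nucleus area optional."""

    cell_area: float
    er_area: float
    nucleus_area: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.er_area <= self.cell_area):
            raise DomainError(
                f"need 0 < er_area <= cell_area, got er={self.er_area}, cell={self.cell_area}"
            )


@dataclass(frozen=True)
class FractionResult:
    area_fraction: float
    volume_fraction: float


def er_volume_fraction(m: AreaMeasurements) -> FractionResult:
    """Area fraction ER/cell and its 3/2-power volume-fraction estimate."""
    af = m.er_area / m.cell_area
    return FractionResult(area_fraction=af, volume_fraction=af**1.5)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves up (report convention)."""
    return int(math.floor(x + 0.5))


def append_fractions(df: pd.DataFrame) -> pd.DataFrame:
    """Append fraction columns to a per-cell area table.

    Expects columns ``cell_area_um2`` and ``er_area_um2`` (and optionally
    ``nucleus_area_um2``); returns a copy with ``area_fraction`` and
    ``volume_fraction`` added.
    """
    out = df.copy()
    fractions = [
        er_volume_fraction(
            AreaMeasurements(cell_area=row.cell_area_um2, er_area=row.er_area_um2)
        )
        for row in out.itertuples()
    ]
    out["area_fraction"] = [f.area_fraction for f in fractions]
    out["volume_fraction"] = [f.volume_fraction for f in fractions]
    return out
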