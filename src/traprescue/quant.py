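"""Small quantification formulas for the wet-lab readouts.

Two readouts are covered:

* laser micro-irradiation tracks — relative accumulation of a protein (GFP
  channel) or of the damage marker γH2AX at the irradiated area, relative to
  the nucleoplasm, both background-subtracted;
* Traffic Light Reporter (TLR) assay — homologous-recombination (HR) and
  mutagenic end-joining (mutEJ) percentages normalized to a
  transfection-reagent-only mock, with HR further normalized to the S/G2
  cell-cycle fraction.

The γH2AX formula is a background-subtracted *difference*, not a ratio; it is
implemented exactly as published despite its asymmetry with the GFP form
(``ratio_gh2ax=True`` switches to the ratio variant if the difference form is
suspected to be a typographical slip).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = ["TrackIntensities", "TlrCounts", "laser_accumulation", "tlr_normalize"]


@dataclass(frozen=True)
class TrackIntensities:
    """Mean pixel intensities: irradiated track, nucleoplasm, cell-free area."""

    i_damage: float
    i_nucleoplasm: float
    i_background: float

    def __post_init__(self) -> None:
        if min(self.i_damage, self.i_nucleoplasm, self.i_background) < 0:
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class TlrCounts:
    """Raw and mock-control reporter percentages plus the S/G2 fraction."""

    hr_raw: float
    mutej_raw: float
    hr_mock: float
    mutej_mock: float
    f_sg2: float = 1.0

    def __post_init__(self) -> None:
        if self.hr_mock <= 0 or self.mutej_mock <= 0:
            raise ValueError("mock percentages must be positive")
        if not 0 < self.f_sg2 <= 1:
            raise ValueError("f_sg2 must lie in (0, 1]")


def laser_accumulation(
    t: TrackIntensities,
    channel: Literal["gfp", "gH2AX"],
    ratio_gh2ax: bool = False,
) -> float:
    """Relative accumulation at a laser track.

    gfp:   (I_damage - I_background) / (I_nucleoplasm - I_background) - 1
    gH2AX: (I_damage - I_background) - (I_nucleoplasm - I_background) - 1

    For the GFP ratio the nucleoplasm must exceed the background.
    """
    dmg = t.i_damage - t.i_background
    nuc = t.i_nucleoplasm - t.i_background
    if channel == "gfp" or (channel == "gH2AX" and ratio_gh2ax):
        if nuc <= 0:
            raise ValueError(
                "nucleoplasm intensity must exceed background for the ratio form"
            )
        return dmg / nuc - 1.0
    if channel == "gH2AX":
        return dmg - nuc - 1.0
    raise ValueError(f"unknown channel {channel!r}")


def tlr_normalize(c: TlrCounts) -> tuple[float, float]:
    """Mock-normalized (relative HR, relative mutEJ).

    rel_HR = (hr_raw / hr_mock) / f_SG2;  rel_mutEJ = mutej_raw / mutej_mock.
    Only HR is cell-cycle corrected: HR requires a sister chromatid and is
    restricted to S/G2.
    """
    rel_hr = (c.hr_raw / c.hr_mock) / c.f_sg2
    rel_mutej = c.mutej_raw / c.mutej_mock
    return rel_hr, rel_mutej
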