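"""Nucleosome coordinate arithmetic.

Positions on the nucleosomal DNA core are 1-based base pairs from the 5'
end of the top strand.  Superhelical locations (SHL) count helical turns
from the dyad (SHL 0) at half-turn resolution; positive toward the 3' end
of the top strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

DEFAULT_CORE_LENGTH = 147
DEFAULT_PERIODICITY = 10.4  # bp per superhelical turn


@dataclass(frozen=True)
class NucleosomeFrame:
    """Coordinate frame of a nucleosome core particle."""

    core_length: int = DEFAULT_CORE_LENGTH
    dyad_position: int = 74  # 1-based central bp of a 147-bp core
    periodicity: float = DEFAULT_PERIODICITY

    def __post_init__(self) -> None:
        if not (1 <= self.dyad_position <= self.core_length):
            raise ValidationError(
                f"dyad {self.dyad_position} outside core 1..{self.core_length}"
            )
        if self.periodicity <= 0:
            raise ValidationError("periodicity must be positive")


@dataclass(frozen=True)
class MotifPlacement:
    """A motif on the core, by its 1-based start position."""

    motif_start: int
    motif_length: int = 9

    @property
    def center(self) -> int:
        # Central bp of the motif; start + 4 for a 9-bp motif.
        return self.motif_start + self.motif_length // 2


def round_half(x: float) -> float:
    """Round to the nearest half-integer; exact ties round away from zero."""
    doubled = 2.0 * x
    if doubled >= 0:
        return math.floor(doubled + 0.5) / 2.0
    return math.ceil(doubled - 0.5) / 2.0


def distance_from_dyad(position: int, frame: NucleosomeFrame = NucleosomeFrame()) -> int:
    """Signed bp distance of ``position`` from the dyad (positive 3' of top strand)."""
    if not (1 <= position <= frame.core_length):
        raise ValidationError(
            f"position {position} outside core 1..{frame.core_length}"
        )
    return position - frame.dyad_position


def shl_of_position(position: int, frame: NucleosomeFrame = NucleosomeFrame()) -> float:
    """SHL label of a single bp position."""
    return round_half(distance_from_dyad(position, frame) / frame.periodicity)


def shl_of_motif(placement: MotifPlacement, frame: NucleosomeFrame = NucleosomeFrame()) -> float:
    """SHL label of a motif, referenced to its central base pair."""
    if placement.motif_start < 1 or placement.motif_start + placement.motif_length - 1 > frame.core_length:
        raise ValidationError("motif not fully inside core")
    return round_half(distance_from_dyad(placement.center, frame) / frame.periodicity)


def relocate_shl(shl_old: float, dyad_old: int, dyad_new: int,
                 frame: NucleosomeFrame = NucleosomeFrame()) -> float:
    """SHL label of the same DNA site after the dyad moves on the same DNA.

    The site keeps its absolute position; the label is re-derived from its
    distance to the new dyad.
    """
    if abs(shl_old) > 7:
        raise ValidationError(f"SHL {shl_old} outside the nucleosome (|SHL| <= 7)")
    distance = shl_old * frame.periodicity
    return round_half((distance - (dyad_new - dyad_old)) / frame.periodicity)
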