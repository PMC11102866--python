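"""In vitro MNase dyad-density mapping.

Fragments are filtered to mono-nucleosome lengths, the midpoint of each
kept fragment is taken as a dyad, per-bp dyad counts are expressed as a
percentage of all kept dyads, and positions are called by greedy peak
picking.  Coordinates are 0-based half-open internally; reported dyads are
1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_formats import FragmentRecord

DEFAULT_MIN_LEN = 145
DEFAULT_MAX_LEN = 147


@dataclass
class DyadProfile:
    """Per-bp dyad density (percent of kept dyads) on one reference."""

    ref_id: str
    density: np.ndarray  # percent per bp; sums to 100
    n_fragments_total: int
    n_fragments_kept: int

    def __post_init__(self) -> None:
        if (self.density < 0).any():
            raise ValidationError("negative density")
        if abs(float(self.density.sum()) - 100.0) > 1e-9:
            raise ValidationError("density does not sum to 100")
        if self.n_fragments_kept > self.n_fragments_total:
            raise ValidationError("kept > total")


@dataclass(frozen=True)
class NucleosomePosition:
    dyad: int  # 1-based bp on the reference
    weight: float  # fraction of kept dyads within +/- window


@dataclass
class DyadChange:
    """Per-bp log2 fold change of dyad density between conditions."""

    ref_id: str
    log2fc: np.ndarray  # NaN where undefined
    defined: np.ndarray  # bool mask: both densities > 0


def filter_fragments(fragments: list[FragmentRecord],
                     min_len: int = DEFAULT_MIN_LEN,
                     max_len: int = DEFAULT_MAX_LEN) -> list[FragmentRecord]:
    """Keep fragments with min_len <= length <= max_len (inclusive)."""
    if min_len > max_len:
        raise ValidationError("min_len > max_len")
    return [f for f in fragments if min_len <= f.length <= max_len]


def dyad_positions(fragments: list[FragmentRecord]) -> np.ndarray:
    """0-based midpoint of each fragment; lower central base for even lengths."""
    if not fragments:
        return np.array([], dtype=int)
    starts = np.array([f.start for f in fragments])
    ends = np.array([f.end for f in fragments])
    return (starts + ends - 1) // 2


def dyad_density(dyads: np.ndarray, ref_length: int, ref_id: str = "ref",
                 n_fragments_total: int | None = None) -> DyadProfile:
    """Percent of dyads at each bp of the reference."""
    dyads = np.asarray(dyads, dtype=int)
    if dyads.size == 0:
        raise ValidationError("no dyads: zero kept fragments")
    if (dyads < 0).any() or (dyads >= ref_length).any():
        raise ValidationError("dyad outside reference")
    counts = np.bincount(dyads, minlength=ref_length).astype(float)
    density = 100.0 * counts / counts.sum()
    # exact renormalization so the sum is 100 to machine precision
    density *= 100.0 / density.sum()
    return DyadProfile(ref_id, density, n_fragments_total or dyads.size, dyads.size)


def profile_fragments(fragments: list[FragmentRecord], ref_length: int,
                      ref_id: str = "ref",
                      min_len: int = DEFAULT_MIN_LEN,
                      max_len: int = DEFAULT_MAX_LEN) -> DyadProfile:
    """filter -> midpoint -> density in one call."""
    kept = filter_fragments(fragments, min_len, max_len)
    return dyad_density(dyad_positions(kept), ref_length, ref_id=ref_id,
                        n_fragments_total=len(fragments))


def density_log2fc(profile_plus: DyadProfile, profile_minus: DyadProfile) -> DyadChange:
    """Per-bp log2(plus / minus) dyad density; undefined where either is 0."""
    if profile_plus.ref_id != profile_minus.ref_id:
        raise ValidationError("reference mismatch")
    if profile_plus.density.shape != profile_minus.density.shape:
        raise ValidationError("reference length mismatch")
    p, m = profile_plus.density, profile_minus.density
    defined = (p > 0) & (m > 0)
    log2fc = np.full(p.shape, np.nan)
    log2fc[defined] = np.log2(p[defined] / m[defined])
    return DyadChange(profile_plus.ref_id, log2fc, defined)


def call_positions(profile: DyadProfile, window: int = 3,
                   min_separation: int = 10,
                   min_weight: float = 0.05) -> list[NucleosomePosition]:
    """Greedy peak picking on window-smoothed density.

    Repeatedly takes the maximum of the smoothed density, assigns the peak
    the fraction of kept dyads within +/- ``window`` bp, suppresses
    +/- ``min_separation`` bp around it and stops when a peak's weight
    falls below ``min_weight``.  Peaks are 1-based, in descending weight.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    frac = profile.density / 100.0
    kernel = np.ones(2 * window + 1)
    smooth = np.convolve(frac, kernel, mode="same")
    available = np.ones(frac.size, dtype=bool)
    calls = []
    while available.any():
        masked = np.where(available, smooth, -np.inf)
        peak = int(np.argmax(masked))
        # the smoothed maximum can be a plateau; refine to the raw maximum
        lo, hi = max(0, peak - window), min(frac.size, peak + window + 1)
        peak = lo + int(np.argmax(frac[lo:hi]))
        lo, hi = max(0, peak - window), min(frac.size, peak + window + 1)
        weight = float(frac[lo:hi].sum())
        if weight < min_weight:
            break
        calls.append(NucleosomePosition(dyad=peak + 1, weight=weight))
        slo, shi = max(0, peak - min_separation), min(frac.size, peak + min_separation + 1)
        available[slo:shi] = False
    calls.sort(key=lambda c: -c.weight)
    return calls
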