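"""Tiled-motif library design and spike-in-normalized enrichment scoring.

A motif is substituted (never inserted) at every start offset of a
positioning-sequence backbone; bound/unbound read counts per construct are
normalized by library size, ratioed to the spike-in construct, and the
enrichment score is the log2 fold change of normalized bound over
normalized unbound.  Zero counts propagate as missing — no pseudocounts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import SequenceRecord

CONSTRUCT_ID_PATTERN = re.compile(r"^pos(\d+)$")


@dataclass(frozen=True)
class TiledConstruct:
    """One library member: backbone with the motif substituted at an offset.

    ``motif_start`` is the 0-based offset on the backbone; the construct id
    encodes the 1-based start ("pos{N}").
    """

    construct_id: str
    motif_start: int
    sequence: str


@dataclass(frozen=True)
class EnrichmentRecord:
    construct_id: str
    replicate: int
    normalized_bound: float
    normalized_unbound: float
    enrichment: float  # log2; NaN when status == "missing"
    status: str  # "ok" | "missing"


def tile_motif(backbone: SequenceRecord, motif: str, step: int = 1) -> list[TiledConstruct]:
    """Substitute ``motif`` at every ``step``-spaced start offset of the backbone."""
    motif = motif.upper()
    if len(motif) > len(backbone.sequence):
        raise ValidationError("motif longer than backbone")
    if step < 1:
        raise ValidationError("step must be >= 1")
    seq = backbone.sequence
    out = []
    for start in range(0, len(seq) - len(motif) + 1, step):
        tiled = seq[:start] + motif + seq[start + len(motif):]
        out.append(TiledConstruct(f"pos{start + 1}", start, tiled))
    return out


def motif_start_of_id(construct_id: str) -> int | None:
    """1-based motif start encoded in a construct id, or None for other ids."""
    m = CONSTRUCT_ID_PATTERN.match(construct_id)
    return int(m.group(1)) if m else None


def normalize_counts(table: pd.DataFrame, spike_id: str) -> pd.DataFrame:
    """Spike-in-normalize a count table.

    Per (replicate, fraction) library: each count is divided by the library
    size, then by the library-size-normalized spike-in count.  Returns the
    table with ``library_size`` and ``normalized`` columns added.
    """
    out = table.copy()
    out["library_size"] = out.groupby(["replicate", "fraction"])["count"].transform("sum")
    spike = out[out["construct_id"] == spike_id]
    for (rep, frac), grp in out.groupby(["replicate", "fraction"]):
        sp = spike[(spike["replicate"] == rep) & (spike["fraction"] == frac)]
        if len(sp) == 0 or int(sp["count"].iloc[0]) == 0:
            raise ValidationError(
                f"spike-in {spike_id!r} absent or zero in replicate {rep} fraction {frac}"
            )
    spike_counts = (
        spike.set_index(["replicate", "fraction"])["count"]
    )
    keys = pd.MultiIndex.from_frame(out[["replicate", "fraction"]])
    out["normalized"] = out["count"].to_numpy(float) / spike_counts.reindex(keys).to_numpy(float)
    return out


def enrichment(normalized: pd.DataFrame, spike_id: str) -> list[EnrichmentRecord]:
    """Per-construct, per-replicate log2(normalized bound / normalized unbound).

    A zero or absent count in either fraction yields status "missing" with
    NaN enrichment (no pseudocount).  The spike-in scores exactly 0.
    """
    records = []
    wide = normalized.pivot_table(
        index=["construct_id", "replicate"], columns="fraction",
        values=["count", "normalized"], aggfunc="first",
    )
    for (cid, rep), row in wide.iterrows():
        nb = row.get(("normalized", "bound"), np.nan)
        nu = row.get(("normalized", "unbound"), np.nan)
        cb = row.get(("count", "bound"), np.nan)
        cu = row.get(("count", "unbound"), np.nan)
        ok = all(np.isfinite(v) and v > 0 for v in (cb, cu, nb, nu))
        if not ok:
            records.append(EnrichmentRecord(cid, int(rep), float(nb), float(nu), float("nan"), "missing"))
            continue
        score = 0.0 if cid == spike_id else math.log2(nb / nu)
        records.append(EnrichmentRecord(cid, int(rep), float(nb), float(nu), score, "ok"))
    return records


def score_counts(table: pd.DataFrame, spike_id: str) -> list[EnrichmentRecord]:
    """Convenience: normalize then score a raw count table."""
    return enrichment(normalize_counts(table, spike_id), spike_id)


def profile(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Per-position mean and sample s.d. of enrichment over replicates.

    Positions are taken from "pos{N}" construct ids (1-based motif start);
    other ids (e.g. the spike-in) are excluded.  Replicates with status
    "missing" are dropped from the mean; a position missing in all
    replicates is reported with status "missing" and NaN statistics.
    """
    rows = []
    by_pos: dict[int, list[float]] = {}
    n_total: dict[int, int] = {}
    for rec in records:
        pos = motif_start_of_id(rec.construct_id)
        if pos is None:
            continue
        n_total[pos] = n_total.get(pos, 0) + 1
        if rec.status == "ok":
            by_pos.setdefault(pos, []).append(rec.enrichment)
    for pos in sorted(n_total):
        vals = by_pos.get(pos, [])
        if vals:
            arr = np.array(vals)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
            rows.append((pos, float(arr.mean()), sd, len(arr), "ok"))
        else:
            rows.append((pos, float("nan"), float("nan"), 0, "missing"))
    return pd.DataFrame(
        rows, columns=["motif_start_1based", "mean_enrichment", "sd", "n", "status"]
    )


def classify_reads(reads: list[str], constructs: list[TiledConstruct]) -> dict[str, int]:
    """Exact-match read-to-construct counts, for error-free synthetic reads only.

    Real read mapping (aligner, MAPQ filtering) is upstream of this package.
    """
    index = {c.sequence: c.construct_id for c in constructs}
    counts: dict[str, int] = {c.construct_id: 0 for c in constructs}
    for read in reads:
        cid = index.get(read.upper())
        if cid is not None:
            counts[cid] += 1
    return counts
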