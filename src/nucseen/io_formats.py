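"""Readers and writers for the external formats the pipeline touches.

All sequence and fragment coordinates are 0-based, half-open internally;
1-based closed coordinates appear only at CLI boundaries.  Structure
coordinates are Angstroms.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

DNA_ALPHABET = frozenset("ACGTN")

COUNT_COLUMNS = ["construct_id", "replicate", "fraction", "count"]
FRAGMENT_COLUMNS = ["ref_id", "start", "end", "condition"]
TRACE_COLUMNS = ["molecule_id", "frame_index", "time_s", "donor", "acceptor"]

FRACTIONS = ("bound", "unbound")
CONDITIONS = ("minus_factor", "plus_factor")

# ---------------------------------------------------------------------------
# sequences


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase DNA sequence (alphabet ACGTN)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are uppercased; any character outside ACGTN is a
    :class:`FormatError` naming the offending line.
    """
    records = []
    with open(path) as handle:
        parsed = list(SeqIO.parse(handle, "fasta"))
    if not parsed:
        raise FormatError(f"{path}: empty or not FASTA")
    for rec in parsed:
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} line {_find_line(path, rec.id, bad)}: "
                f"non-DNA characters {sorted(bad)}"
            )
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, seq))
    return records


def _find_line(path: str | os.PathLike, rec_id: str, bad: set[str]) -> int:
    """Locate the first line of a record containing a bad character."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == rec_id if line[1:].split() else False
                continue
            if in_record and (set(line.strip().upper()) & bad):
                return lineno
    return -1


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tabular inputs


def read_counts(path: str | os.PathLike, spike_id: str | None = None) -> pd.DataFrame:
    """Read a TSV count table (construct_id, replicate, fraction, count).

    Rows are typed and validated: counts are non-negative integers,
    fraction is 'bound'/'unbound', keys are unique.  If ``spike_id`` is
    given, it must appear in every (replicate, fraction) library.
    """
    df = pd.read_csv(path, sep="\t", dtype={"construct_id": str})
    _require_columns(df, COUNT_COLUMNS, path)
    df = df[COUNT_COLUMNS].copy()
    if df["count"].isna().any() or (df["count"] < 0).any():
        raise FormatError(f"{path}: negative or missing counts")
    df["replicate"] = df["replicate"].astype(int)
    df["count"] = df["count"].astype(int)
    if (df["replicate"] < 1).any():
        raise FormatError(f"{path}: replicate numbers must be >= 1")
    bad_frac = set(df["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise FormatError(f"{path}: unknown fraction labels {sorted(bad_frac)}")
    dup = df.duplicated(subset=["construct_id", "replicate", "fraction"])
    if dup.any():
        first = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate key ({first.construct_id}, {first.replicate}, {first.fraction})"
        )
    if spike_id is not None:
        for (rep, frac), grp in df.groupby(["replicate", "fraction"]):
            if spike_id not in set(grp["construct_id"]):
                raise ValidationError(
                    f"spike-in {spike_id!r} missing from replicate {rep} fraction {frac}"
                )
    return df


def write_counts(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FragmentRecord:
    """A sequenced fragment interval on a reference construct, 0-based half-open."""

    ref_id: str
    start: int
    end: int
    condition: str = "minus_factor"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"fragment on {self.ref_id!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fragments(path: str | os.PathLike, ref_length: int | None = None) -> list[FragmentRecord]:
    """Read a TSV fragment table (ref_id, start, end[, condition])."""
    df = pd.read_csv(path, sep="\t", dtype={"ref_id": str})
    required = FRAGMENT_COLUMNS[:3]
    _require_columns(df, required, path)
    if "condition" not in df.columns:
        df["condition"] = "minus_factor"
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise FormatError(f"{path}: unknown condition labels {sorted(bad_cond)}")
    out = []
    for row in df.itertuples(index=False):
        if row.start >= row.end:
            raise FormatError(
                f"{path}: fragment on {row.ref_id} has start {row.start} >= end {row.end}"
            )
        if ref_length is not None and row.end > ref_length:
            raise FormatError(
                f"{path}: fragment end {row.end} beyond reference length {ref_length}"
            )
        out.append(FragmentRecord(row.ref_id, int(row.start), int(row.end), row.condition))
    return out


def write_fragments(fragments: Sequence[FragmentRecord], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(f.ref_id, f.start, f.end, f.condition) for f in fragments],
        columns=FRAGMENT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_traces(path: str | os.PathLike, dt_tolerance: float = 1e-6) -> pd.DataFrame:
    """Read a CSV trace table (molecule_id, frame_index, time_s, donor, acceptor).

    Frames must be strictly increasing in time per molecule with a uniform
    frame interval (within ``dt_tolerance`` seconds).
    """
    df = pd.read_csv(path, dtype={"molecule_id": str})
    _require_columns(df, TRACE_COLUMNS, path)
    df = df[TRACE_COLUMNS].copy()
    df["frame_index"] = df["frame_index"].astype(int)
    for mol, grp in df.groupby("molecule_id", sort=False):
        t = grp["time_s"].to_numpy(float)
        if len(t) >= 2:
            dts = np.diff(t)
            if (dts <= 0).any():
                raise FormatError(f"{path}: molecule {mol}: time not strictly increasing")
            if np.ptp(dts) > dt_tolerance:
                raise FormatError(
                    f"{path}: molecule {mol}: non-uniform frame interval "
                    f"(spread {np.ptp(dts):.3g} s > {dt_tolerance:g} s)"
                )
    return df


def write_traces(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[TRACE_COLUMNS].to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# atomic structures


@dataclass
class StructureModel:
    """Labelled atomic coordinates, array-backed.

    Parallel arrays over atoms; ``coords`` is an (n, 3) float array in
    Angstroms.  ``entities`` optionally annotates chains (e.g. 'histone_H2A',
    'dna_I', 'factor').
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    entities: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.chain_ids)
        for name in ("res_ids", "res_names", "atom_names", "elements"):
            if len(getattr(self, name)) != n:
                raise ValidationError("atom array length mismatch")
        if self.coords.shape != (n, 3):
            raise ValidationError(f"coords must be ({n}, 3)")
        if not np.isfinite(self.coords).all():
            raise ValidationError("non-finite coordinates")

    @classmethod
    def from_atoms(cls, atoms: Iterable[tuple], entities: dict[str, str] | None = None
                   ) -> "StructureModel":
        """Build from (chain_id, res_id, res_name, atom_name, element, x, y, z) tuples."""
        rows = list(atoms)
        if not rows:
            raise ValidationError("no atoms")
        chain, rid, rname, aname, elem = (np.array(c) for c in zip(*[r[:5] for r in rows]))
        coords = np.array([r[5:8] for r in rows], dtype=float)
        return cls(chain, rid.astype(int), rname, aname, elem, coords,
                   entities=dict(entities or {}))

    def __len__(self) -> int:
        return len(self.chain_ids)

    @property
    def n_atoms(self) -> int:
        return len(self)

    def check_unique(self) -> None:
        keys = list(zip(self.chain_ids, self.res_ids, self.atom_names))
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (chain, residue, atom) key in model")

    def mask(self, chain: str | None = None, res_id: int | None = None,
             atom_name: str | Sequence[str] | None = None,
             res_name: str | Sequence[str] | None = None) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chain_ids == chain
        if res_id is not None:
            m &= self.res_ids == res_id
        if atom_name is not None:
            names = [atom_name] if isinstance(atom_name, str) else list(atom_name)
            m &= np.isin(self.atom_names, names)
        if res_name is not None:
            names = [res_name] if isinstance(res_name, str) else list(res_name)
            m &= np.isin(self.res_names, names)
        return m

    def select(self, **kwargs) -> "StructureModel":
        return self.subset(self.mask(**kwargs))

    def subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.chain_ids[mask], self.res_ids[mask], self.res_names[mask],
            self.atom_names[mask], self.elements[mask], self.coords[mask],
            entities=dict(self.entities),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        out = self.subset(np.ones(len(self), dtype=bool))
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)


_DNA_RES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U"}


def classify_chains(model: StructureModel) -> dict[str, str]:
    """Heuristically tag each chain as 'dna' or 'protein' by residue names."""
    out = {}
    for chain in model.chains():
        names = set(model.res_names[model.chain_ids == chain])
        out[chain] = "dna" if names <= _DNA_RES else "protein"
    return out


def read_structure(path: str | os.PathLike, dialect: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    Model 1 only; alternate locations resolved to the highest occupancy
    (ties keep the first listed).  ``dialect`` is inferred from the file
    extension when omitted.
    """
    if dialect is None:
        ext = os.path.splitext(str(path))[1].lower()
        dialect = "mmcif" if ext in (".cif", ".mmcif") else "pdb"
    if dialect not in ("pdb", "mmcif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        if dialect == "pdb":
            from biotite.structure.io.pdb import PDBFile

            arr = PDBFile.read(str(path)).get_structure(model=1, altloc="occupancy")
        else:
            from biotite.structure.io.pdbx import CIFFile, get_structure

            arr = get_structure(CIFFile.read(str(path)), model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"{path}: cannot parse as {dialect}: {exc}") from exc
    if arr.array_length() == 0:
        raise FormatError(f"{path}: no atoms found")
    model = StructureModel(
        chain_ids=arr.chain_id.astype(str),
        res_ids=arr.res_id.astype(int),
        res_names=arr.res_name.astype(str),
        atom_names=arr.atom_name.astype(str),
        elements=arr.element.astype(str),
        coords=np.asarray(arr.coord, dtype=float),
    )
    if not np.isfinite(model.coords).all():
        raise FormatError(f"{path}: non-finite coordinates")
    return model


def write_structure(model: StructureModel, path: str | os.PathLike) -> None:
    """Write a model as a PDB file (coordinates at standard 3-decimal precision)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arr = struc.AtomArray(len(model))
    arr.chain_id = model.chain_ids.astype("U4")
    arr.res_id = model.res_ids
    arr.res_name = model.res_names.astype("U5")
    arr.atom_name = model.atom_names.astype("U6")
    arr.element = model.elements.astype("U2")
    arr.coord = model.coords.astype(np.float32)
    arr.hetero = np.zeros(len(model), dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
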