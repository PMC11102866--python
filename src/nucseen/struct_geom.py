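"""Structural geometry: superposition, per-residue RMSD, clashes, anchors.

All operations act on :class:`~nucseen.io_formats.StructureModel` objects
or bare (n, 3) coordinate arrays in Angstroms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io_formats import StructureModel

# Bondi van der Waals radii (Angstrom)
DEFAULT_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_CLASH_TOLERANCE = 0.4
DEFAULT_CONTACT_CUTOFF = 4.0

# minor-groove floor atoms per base; sugar atoms are flank only
MINOR_GROOVE_FLOOR = {
    "DA": ("N3",), "DG": ("N3",), "A": ("N3",), "G": ("N3",),
    "DC": ("O2",), "DT": ("O2",), "C": ("O2",), "T": ("O2",),
}
MINOR_GROOVE_FLANK = ("C1'", "C4'")

ARG_SIDECHAIN_N = ("NE", "NH1", "NH2")
LYS_SIDECHAIN_N = ("NZ",)


# ---------------------------------------------------------------------------
# superposition


@dataclass
class Superposition:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # 3-vector
    rmsd: float
    pairing: list = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def apply_model(self, model: StructureModel) -> StructureModel:
        return model.transformed(self.rotation, self.translation)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     pairing: list | None = None) -> Superposition:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Classic SVD solution with the reflection corrected to a proper
    rotation.  Inputs are paired (n, 3) arrays, n >= 3, non-collinear.
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValidationError("paired (n, 3) coordinate arrays required")
    if p.shape[0] < 3:
        raise ValidationError("need at least 3 paired atoms")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    # collinear or coincident points leave the rotation underdetermined
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValidationError("degenerate pairing (collinear or coincident atoms)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = qc - rot @ pc
    moved = p @ rot.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return Superposition(rot, translation, rmsd, pairing or [])


def pair_ca_atoms(model_a: StructureModel, model_b: StructureModel,
                  chains: list[str] | None = None):
    """Match Calpha atoms present in both models by (chain, residue)."""
    coords_a, coords_b, pairing = [], [], []
    mask_a = model_a.mask(atom_name="CA")
    mask_b = model_b.mask(atom_name="CA")
    index_b = {}
    for i in np.flatnonzero(mask_b):
        index_b[(model_b.chain_ids[i], int(model_b.res_ids[i]))] = i
    for i in np.flatnonzero(mask_a):
        key = (model_a.chain_ids[i], int(model_a.res_ids[i]))
        if chains is not None and key[0] not in chains:
            continue
        j = index_b.get(key)
        if j is not None:
            coords_a.append(model_a.coords[i])
            coords_b.append(model_b.coords[j])
            pairing.append((key, key))
    if not coords_a:
        raise ValidationError("no common Calpha atoms")
    return np.array(coords_a), np.array(coords_b), pairing


def superpose_models(mobile: StructureModel, reference: StructureModel,
                     chains: list[str] | None = None) -> tuple[StructureModel, Superposition]:
    """Superpose ``mobile`` onto ``reference`` on shared Calpha atoms."""
    ca_m, ca_r, pairing = pair_ca_atoms(mobile, reference, chains=chains)
    sup = kabsch_superpose(ca_m, ca_r, pairing)
    return sup.apply_model(mobile), sup


# ---------------------------------------------------------------------------
# per-residue RMSD


def residue_rmsd(model_a: StructureModel, model_b: StructureModel,
                 chain_map: dict[str, str] | None = None,
                 anchor_chains: list[str] | None = None,
                 superpose: bool = True) -> pd.DataFrame:
    """Per-residue Calpha displacement of B relative to A.

    Models are first superposed on the Calpha atoms of ``anchor_chains``
    (all shared chains when None) unless ``superpose`` is False; chains of
    B may be renamed through ``chain_map`` (A-chain -> B-chain).  Residues
    lacking a Calpha in either model are omitted.
    """
    if chain_map is not None and not chain_map:
        raise ValidationError("empty chain_map")
    b = model_b
    if chain_map:
        inverse = {v: k for k, v in chain_map.items()}
        b = model_b.subset(np.isin(model_b.chain_ids, list(inverse)))
        b.chain_ids = np.array([inverse[c] for c in b.chain_ids])
    if superpose:
        b, _ = superpose_models(b, model_a, chains=anchor_chains)
    rows = []
    index_b = {}
    for i in np.flatnonzero(b.mask(atom_name="CA")):
        index_b[(b.chain_ids[i], int(b.res_ids[i]))] = b.coords[i]
    for i in np.flatnonzero(model_a.mask(atom_name="CA")):
        key = (model_a.chain_ids[i], int(model_a.res_ids[i]))
        other = index_b.get(key)
        if other is None:
            continue
        dist = float(np.linalg.norm(model_a.coords[i] - other))
        rows.append((key[0], key[1], dist))
    return pd.DataFrame(rows, columns=["chain", "residue_number", "rmsd_ca"])


# ---------------------------------------------------------------------------
# steric clashes


@dataclass(frozen=True)
class Clash:
    atom_i: tuple  # (chain, res_id, res_name, atom_name)
    atom_j: tuple
    distance: float
    overlap: float


def detect_clashes(factor: StructureModel, target: StructureModel,
                   radii: dict[str, float] | None = None,
                   tolerance: float = DEFAULT_CLASH_TOLERANCE,
                   default_radius: float | None = None) -> list[Clash]:
    """van der Waals overlaps between two atom sets.

    A pair clashes when distance < r_i + r_j - tolerance.  Hydrogens are
    ignored.  Results are sorted by decreasing overlap.
    """
    radii = dict(DEFAULT_VDW_RADII if radii is None else radii)

    def prep(model: StructureModel):
        mask = ~np.isin(model.elements, ["H", "D"])
        sub = model.subset(mask)
        r = np.empty(len(sub))
        for i, elem in enumerate(sub.elements):
            if elem in radii:
                r[i] = radii[elem]
            elif default_radius is not None:
                r[i] = default_radius
            else:
                raise ValidationError(f"no vdW radius for element {elem!r}")
        return sub, r

    fa, ra = prep(factor)
    ta, rt = prep(target)
    if len(fa) == 0 or len(ta) == 0:
        return []
    cutoff = ra.max() + rt.max() - tolerance
    tree = cKDTree(ta.coords)
    clashes = []
    for i, neighbours in enumerate(tree.query_ball_point(fa.coords, r=cutoff)):
        for j in neighbours:
            dist = float(np.linalg.norm(fa.coords[i] - ta.coords[j]))
            overlap = ra[i] + rt[j] - tolerance - dist
            if overlap > 0:
                clashes.append(Clash(
                    (str(fa.chain_ids[i]), int(fa.res_ids[i]), str(fa.res_names[i]), str(fa.atom_names[i])),
                    (str(ta.chain_ids[j]), int(ta.res_ids[j]), str(ta.res_names[j]), str(ta.atom_names[j])),
                    dist, float(overlap),
                ))
    clashes.sort(key=lambda c: -c.overlap)
    return clashes


# ---------------------------------------------------------------------------
# DBD docking


def dock_dbd(dbd_model: StructureModel, nucleosome_model: StructureModel,
             template_nucleotides: list[tuple[str, int]],
             target_nucleotides: list[tuple[str, int]],
             backbone_atoms: tuple[str, ...] = ("P", "C1'")) -> tuple[StructureModel, Superposition]:
    """Place a DNA-bound domain onto nucleosomal DNA by backbone alignment.

    The DBD model's own DNA duplex (``template_nucleotides`` as
    (chain, res_id) in order) is superposed onto the nucleosomal segment
    covering the motif (``target_nucleotides``, same order and length)
    using the listed backbone atoms, and the whole DBD model is
    transformed.  Returns (transformed model, superposition).
    """
    if len(template_nucleotides) != len(target_nucleotides):
        raise ValidationError("template/target nucleotide lists differ in length")

    def backbone(model: StructureModel, nucleotides):
        coords = []
        for chain, res in nucleotides:
            for name in backbone_atoms:
                mask = model.mask(chain=chain, res_id=res, atom_name=name)
                idx = np.flatnonzero(mask)
                if idx.size:
                    coords.append((name, (chain, res), model.coords[idx[0]]))
        return coords

    tmpl = backbone(dbd_model, template_nucleotides)
    targ = backbone(nucleosome_model, target_nucleotides)
    tmpl_keys = {(k, name) for name, k, _ in tmpl}
    targ_keys = {}
    for pos, (chain, res) in enumerate(target_nucleotides):
        for name in backbone_atoms:
            targ_keys[(pos, name)] = None
    # pair by position in the nucleotide list + atom name
    tmpl_by = {}
    for name, key, coord in tmpl:
        pos = template_nucleotides.index(key)
        tmpl_by[(pos, name)] = coord
    targ_by = {}
    for name, key, coord in targ:
        pos = target_nucleotides.index(key)
        targ_by[(pos, name)] = coord
    shared = sorted(set(tmpl_by) & set(targ_by))
    if len(shared) < 3:
        raise ValidationError("motif segment atoms missing in nucleosome DNA")
    mobile = np.array([tmpl_by[k] for k in shared])
    reference = np.array([targ_by[k] for k in shared])
    sup = kabsch_superpose(mobile, reference, pairing=shared)
    return sup.apply_model(dbd_model), sup


# ---------------------------------------------------------------------------
# minor-groove anchors


@dataclass(frozen=True)
class AnchorContact:
    anchor: tuple            # (chain, res_id, res_name)
    anchor_atom: str
    groove_atom: tuple       # (chain, res_id, res_name, atom_name)
    distance: float
    occupied: bool


def minor_groove_atoms(model: StructureModel, include_flank: bool = False) -> np.ndarray:
    """Mask of minor-groove atoms (base floor N3/O2; optionally sugar flank)."""
    mask = np.zeros(len(model), dtype=bool)
    for res_name, atoms in MINOR_GROOVE_FLOOR.items():
        mask |= model.mask(res_name=res_name, atom_name=list(atoms))
    if include_flank:
        dna_res = list(MINOR_GROOVE_FLOOR)
        mask |= model.mask(res_name=dna_res, atom_name=list(MINOR_GROOVE_FLANK))
    return mask


def anchor_contacts(model: StructureModel,
                    anchor_spec: list[tuple[str, int, tuple[str, ...]]],
                    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                    include_flank: bool = False) -> list[AnchorContact]:
    """Minimum anchor-nitrogen to minor-groove distances.

    ``anchor_spec`` lists (chain, residue_number, side-chain N atom names).
    An anchor is "occupied" when its minimum distance to a minor-groove
    floor atom is <= ``contact_cutoff``.
    """
    groove_mask = minor_groove_atoms(model, include_flank=include_flank)
    groove_idx = np.flatnonzero(groove_mask)
    if groove_idx.size == 0:
        raise ValidationError("no minor-groove atoms (no DNA?) in model")
    tree = cKDTree(model.coords[groove_idx])
    contacts = []
    for chain, res_id, atom_names in anchor_spec:
        idx = np.flatnonzero(model.mask(chain=chain, res_id=res_id, atom_name=list(atom_names)))
        if idx.size == 0:
            raise ValidationError(f"anchor residue {chain}/{res_id} atoms {atom_names} absent")
        best = None
        for i in idx:
            dist, j = tree.query(model.coords[i])
            if best is None or dist < best[0]:
                best = (float(dist), str(model.atom_names[i]), groove_idx[j])
        dist, anchor_atom, gi = best
        res_name = str(model.res_names[np.flatnonzero(model.mask(chain=chain, res_id=res_id))[0]])
        contacts.append(AnchorContact(
            anchor=(chain, res_id, res_name),
            anchor_atom=anchor_atom,
            groove_atom=(str(model.chain_ids[gi]), int(model.res_ids[gi]),
                         str(model.res_names[gi]), str(model.atom_names[gi])),
            distance=dist,
            occupied=dist <= contact_cutoff,
        ))
    return contacts


def min_nitrogen_distance(model: StructureModel,
                          res_a: tuple[str, int, tuple[str, ...]],
                          res_b: tuple[str, int, tuple[str, ...]]) -> float:
    """Minimum distance between two residues' listed atoms (e.g. NZ vs ND1/NE2)."""
    ca = model.coords[model.mask(chain=res_a[0], res_id=res_a[1], atom_name=list(res_a[2]))]
    cb = model.coords[model.mask(chain=res_b[0], res_id=res_b[1], atom_name=list(res_b[2]))]
    if ca.size == 0 or cb.size == 0:
        raise ValidationError("residue atoms absent")
    return float(np.min(np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)))


# ---------------------------------------------------------------------------
# DNA path / unwrap angle


def line_direction(points: np.ndarray) -> np.ndarray:
    """Unit direction of the least-squares line through points, oriented
    from the first toward the last point."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise ValidationError("need >= 4 points for a stable line fit")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    direction = vt[0]
    if direction @ (pts[-1] - pts[0]) < 0:
        direction = -direction
    return direction / np.linalg.norm(direction)


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two direction vectors, degrees in [0, 180)."""
    c = float(np.clip(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0))
    return math.degrees(math.acos(c)) % 180.0


def unwrap_angle_from_centers(centers_a: np.ndarray, centers_b: np.ndarray) -> float:
    """Angle between the fitted lines through two base-pair-center paths."""
    return angle_between(line_direction(centers_a), line_direction(centers_b))


def base_pair_centers(model: StructureModel, strand_pairs: list[tuple[tuple[str, int], tuple[str, int]]],
                      atom_name: str = "C1'") -> np.ndarray:
    """Midpoints of paired C1' atoms for a list of ((chainI, res), (chainJ, res)) pairs."""
    centers = []
    for (ci, ri), (cj, rj) in strand_pairs:
        a = model.coords[model.mask(chain=ci, res_id=ri, atom_name=atom_name)]
        b = model.coords[model.mask(chain=cj, res_id=rj, atom_name=atom_name)]
        if a.size == 0 or b.size == 0:
            raise ValidationError(f"missing {atom_name} for pair {(ci, ri)}/{(cj, rj)}")
        centers.append(0.5 * (a[0] + b[0]))
    return np.array(centers)


def unwrap_angle(model_bound: StructureModel, model_free: StructureModel,
                 strand_pairs: list, segment: slice | None = None,
                 anchor_chains: list[str] | None = None,
                 superpose: bool = True) -> float:
    """DNA terminal-segment reorientation angle between two models.

    After superposing ``model_bound`` onto ``model_free`` on histone-core
    Calpha atoms, a least-squares line is fitted through the base-pair
    centers of the terminal ``segment`` (default: last 20 pairs) in each
    model and the inter-line angle is returned in degrees.
    """
    bound = model_bound
    if superpose:
        bound, _ = superpose_models(model_bound, model_free, chains=anchor_chains)
    if segment is None:
        segment = slice(-20, None)
    pairs = strand_pairs[segment]
    if len(pairs) < 4:
        raise ValidationError("segment too short (< 4 bp)")
    centers_bound = base_pair_centers(bound, pairs)
    centers_free = base_pair_centers(model_free, pairs)
    return unwrap_angle_from_centers(centers_bound, centers_free)
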