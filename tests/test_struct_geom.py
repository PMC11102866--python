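import math

import numpy as np
import pytest
from scipy.optimize import minimize

from nucseen.errors import ValidationError
from nucseen.io_formats import StructureModel
from nucseen import struct_geom as sg
from nucseen.synthetic_data import (
    CoordSimSpec,
    ideal_duplex,
    rotation_matrix,
    simulate_dna_arc,
    simulate_point_cloud,
)


def rotation_angle_deg(r):
    return math.degrees(math.acos(np.clip((np.trace(r) - 1) / 2, -1, 1)))


# ---------------------------------------------------------------------------
# Kabsch


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        sup = sg.kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_recovers_known_rotation(self):
        pts, moved, truth = simulate_point_cloud(CoordSimSpec(rotation_angle_deg=37.0))
        sup = sg.kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert rotation_angle_deg(sup.rotation) == pytest.approx(37.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, truth["rotation"], atol=1e-9)

    def test_noisy_rmsd_scale(self):
        # noise sd 0.1 A per coordinate on one set -> rmsd ~ 0.1 * sqrt(3)
        pts, moved, _ = simulate_point_cloud(
            CoordSimSpec(n_atoms=100, noise_sd=0.1, seed=4))
        sup = sg.kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.1 * math.sqrt(3), rel=0.2)

    def test_reflection_corrected(self):
        pts = np.random.default_rng(1).normal(size=(20, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        sup = sg.kabsch_superpose(pts, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_collinear(self):
        pts = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValidationError):
            sg.kabsch_superpose(pts, pts)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(30, 3))
        b = a + rng.normal(0, 0.5, size=(30, 3))
        base = sg.kabsch_superpose(a, b).rmsd
        r = rotation_matrix((1.0, 2.0, 0.5), 63.0)
        assert sg.kabsch_superpose(a @ r.T + 7.0, b).rmsd == pytest.approx(base)
        assert sg.kabsch_superpose(a, b @ r.T - 3.0).rmsd == pytest.approx(base)

    @pytest.mark.parametrize("n_atoms,noise", [(4, 0.0), (6, 0.3), (8, 1.0)])
    def test_quaternion_grid_search_oracle(self, n_atoms, noise):
        # independent oracle: coarse random-quaternion search + local polish
        rng = np.random.default_rng(n_atoms)
        a = rng.normal(size=(n_atoms, 3))
        b = a @ rotation_matrix((0.3, -1.0, 0.7), 41.0).T + np.array([1.0, 2.0, 3.0])
        b = b + rng.normal(0, noise, size=b.shape)

        a0 = a - a.mean(axis=0)
        b0 = b - b.mean(axis=0)

        def quat_to_rot(q):
            w, x, y, z = q / np.linalg.norm(q)
            return np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])

        def cost(q):
            return float(np.mean(np.sum((a0 @ quat_to_rot(q).T - b0) ** 2, axis=1)))

        best_q, best_c = None, np.inf
        for q in rng.normal(size=(4000, 4)):
            c = cost(q)
            if c < best_c:
                best_q, best_c = q, c
        res = minimize(cost, best_q, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 20000})
        oracle_rmsd = math.sqrt(res.fun)
        assert sg.kabsch_superpose(a, b).rmsd == pytest.approx(oracle_rmsd, abs=1e-6)


# ---------------------------------------------------------------------------
# per-residue RMSD


def chain_models(offsets):
    """Two models, chain A rigid anchor, chain B with per-residue offsets in B-copy."""
    rng = np.random.default_rng(0)
    anchor = rng.normal(0, 10, size=(20, 3))
    body = rng.normal(0, 10, size=(len(offsets), 3))
    atoms_a, atoms_b = [], []
    for i, c in enumerate(anchor, start=1):
        atoms_a.append(("A", i, "ALA", "CA", "C", *c))
        atoms_b.append(("A", i, "ALA", "CA", "C", *c))
    for i, (c, off) in enumerate(zip(body, offsets), start=1):
        atoms_a.append(("B", i, "ALA", "CA", "C", *c))
        atoms_b.append(("B", i, "ALA", "CA", "C", *(c + off)))
    return StructureModel.from_atoms(atoms_a), StructureModel.from_atoms(atoms_b)


class TestResidueRmsd:
    def test_identical_models(self):
        a, b = chain_models(np.zeros((5, 3)))
        table = sg.residue_rmsd(a, b)
        assert np.allclose(table["rmsd_ca"], 0.0, atol=1e-9)

    def test_single_displaced_residue(self):
        offsets = np.zeros((5, 3))
        offsets[2] = [1.0, 0.0, 0.0]
        a, b = chain_models(offsets)
        table = sg.residue_rmsd(a, b, anchor_chains=["A"])
        moved = table[(table.chain == "B") & (table.residue_number == 3)]
        assert moved["rmsd_ca"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        others = table[~((table.chain == "B") & (table.residue_number == 3))]
        assert np.allclose(others["rmsd_ca"], 0.0, atol=1e-9)

    def test_shifted_helix_block(self):
        offsets = np.zeros((30, 3))
        offsets[10:20] = [0.8, 0.0, 0.0]
        a, b = chain_models(offsets)
        table = sg.residue_rmsd(a, b, anchor_chains=["A"])
        block = table[(table.chain == "B") & table.residue_number.between(11, 20)]
        rest = table[(table.chain == "B") & ~table.residue_number.between(11, 20)]
        assert np.allclose(block["rmsd_ca"], 0.8, atol=1e-9)
        assert np.allclose(rest["rmsd_ca"], 0.0, atol=1e-9)

    def test_rigid_copy_is_zero(self):
        a, _ = chain_models(np.zeros((8, 3)))
        moved = a.transformed(rotation_matrix((0, 0, 1), 25.0), np.array([3.0, -1.0, 2.0]))
        table = sg.residue_rmsd(a, moved)
        assert np.allclose(table["rmsd_ca"], 0.0, atol=1e-9)

    def test_empty_chain_map(self):
        a, b = chain_models(np.zeros((3, 3)))
        with pytest.raises(ValidationError):
            sg.residue_rmsd(a, b, chain_map={})


# ---------------------------------------------------------------------------
# clashes


def carbon_pair(distance):
    a = StructureModel.from_atoms([("X", 1, "LIG", "C1", "C", 0, 0, 0)])
    b = StructureModel.from_atoms([("Y", 1, "LIG", "C1", "C", distance, 0, 0)])
    return a, b


class TestClashes:
    def test_no_clash_at_3_5(self):
        assert sg.detect_clashes(*carbon_pair(3.5)) == []

    def test_clash_overlap_half_angstrom(self):
        clashes = sg.detect_clashes(*carbon_pair(2.5))
        assert len(clashes) == 1
        assert clashes[0].overlap == pytest.approx(0.5)
        assert clashes[0].distance == pytest.approx(2.5)

    def test_far_sets_empty(self):
        assert sg.detect_clashes(*carbon_pair(50.0)) == []

    def test_hydrogens_ignored(self):
        a = StructureModel.from_atoms([("X", 1, "LIG", "H1", "H", 0, 0, 0)])
        b = StructureModel.from_atoms([("Y", 1, "LIG", "C1", "C", 0.5, 0, 0)])
        assert sg.detect_clashes(a, b) == []

    def test_unknown_element(self):
        a = StructureModel.from_atoms([("X", 1, "LIG", "FE", "FE", 0, 0, 0)])
        b = StructureModel.from_atoms([("Y", 1, "LIG", "C1", "C", 1.0, 0, 0)])
        with pytest.raises(ValidationError):
            sg.detect_clashes(a, b)
        assert sg.detect_clashes(a, b, default_radius=1.5)

    def test_symmetry(self):
        a, b = carbon_pair(2.0)
        ab = sg.detect_clashes(a, b)
        ba = sg.detect_clashes(b, a)
        assert len(ab) == len(ba) == 1
        assert ab[0].distance == pytest.approx(ba[0].distance)

    @pytest.mark.parametrize("tol_small,tol_big", [(0.0, 0.4), (0.4, 1.0)])
    def test_monotone_in_tolerance(self, tol_small, tol_big):
        rng = np.random.default_rng(2)
        a = StructureModel.from_atoms(
            [("X", i, "LIG", f"C{i}", "C", *c) for i, c in
             enumerate(rng.uniform(0, 10, size=(30, 3)), 1)])
        b = StructureModel.from_atoms(
            [("Y", i, "LIG", f"C{i}", "C", *c) for i, c in
             enumerate(rng.uniform(0, 10, size=(30, 3)), 1)])
        small = {(c.atom_i, c.atom_j) for c in sg.detect_clashes(a, b, tolerance=tol_small)}
        big = {(c.atom_i, c.atom_j) for c in sg.detect_clashes(a, b, tolerance=tol_big)}
        assert big <= small


# ---------------------------------------------------------------------------
# docking


class TestDockDbd:
    def duplex_pairs(self, lo, hi):
        return ([("I", i) for i in range(lo, hi)] + [("J", i) for i in range(lo, hi)])

    def test_identical_template_identity_transform(self):
        nuc = ideal_duplex(30)
        dbd = ideal_duplex(9)
        docked, sup = sg.dock_dbd(dbd, nuc, self.duplex_pairs(1, 10), self.duplex_pairs(1, 10))
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(docked.coords, dbd.coords, atol=1e-9)

    def test_ten_bp_apart_is_one_helical_turn(self):
        nuc = ideal_duplex(40)  # 36 deg/bp: 10 bp = exactly one turn
        dbd = ideal_duplex(9)
        _, s1 = sg.dock_dbd(dbd, nuc, self.duplex_pairs(1, 10), self.duplex_pairs(5, 14))
        _, s2 = sg.dock_dbd(dbd, nuc, self.duplex_pairs(1, 10), self.duplex_pairs(15, 24))
        rel = s2.rotation @ s1.rotation.T
        assert rotation_angle_deg(rel) == pytest.approx(0.0, abs=1e-4)
        # translation along the helix axis by 10 bp of rise
        shift = (s2.apply(dbd.coords) - s1.apply(dbd.coords)).mean(axis=0)
        assert np.linalg.norm(shift) == pytest.approx(34.0, abs=1e-4)

    def test_missing_target_atoms(self):
        nuc = ideal_duplex(30).select(atom_name="P")  # no C1' at all
        nuc_empty = nuc.subset(np.zeros(len(nuc), dtype=bool) | (nuc.res_ids > 28))
        dbd = ideal_duplex(9)
        with pytest.raises(ValidationError):
            sg.dock_dbd(dbd, nuc_empty, self.duplex_pairs(1, 10), self.duplex_pairs(1, 10))


# ---------------------------------------------------------------------------
# anchors


def arginine_near_dna(distance):
    atoms = [
        ("I", 1, "DC", "O2", "O", 0.0, 0.0, 0.0),
        ("I", 1, "DC", "C1'", "C", 2.0, 0.0, 0.0),
        ("A", 77, "ARG", "NH1", "N", distance, 0.0, 0.0),
        ("A", 77, "ARG", "NH2", "N", distance + 1.0, 0.0, 0.0),
    ]
    return StructureModel.from_atoms(atoms)


class TestAnchorContacts:
    def test_occupied_at_3A(self):
        model = arginine_near_dna(3.0)
        contacts = sg.anchor_contacts(model, [("A", 77, sg.ARG_SIDECHAIN_N[1:])])
        assert contacts[0].occupied
        assert contacts[0].distance == pytest.approx(3.0)
        assert contacts[0].groove_atom[3] == "O2"

    def test_not_occupied_at_6A(self):
        model = arginine_near_dna(6.0)
        contacts = sg.anchor_contacts(model, [("A", 77, sg.ARG_SIDECHAIN_N[1:])])
        assert not contacts[0].occupied

    def test_absent_anchor(self):
        model = arginine_near_dna(3.0)
        with pytest.raises(ValidationError):
            sg.anchor_contacts(model, [("A", 99, sg.ARG_SIDECHAIN_N)])

    def test_min_nitrogen_distance(self):
        atoms = [
            ("C", 75, "LYS", "NZ", "N", 0.0, 0.0, 0.0),
            ("C", 82, "HIS", "ND1", "N", 2.97, 0.0, 0.0),
            ("C", 82, "HIS", "NE2", "N", 4.5, 0.0, 0.0),
        ]
        model = StructureModel.from_atoms(atoms)
        d = sg.min_nitrogen_distance(model, ("C", 75, ("NZ",)), ("C", 82, ("ND1", "NE2")))
        assert d == pytest.approx(2.97)


# ---------------------------------------------------------------------------
# unwrap angle


class TestUnwrapAngle:
    def test_identical_models_zero(self):
        free, bound, pairs, _ = simulate_dna_arc(CoordSimSpec(unwrap_angle_deg=0.0))
        assert sg.unwrap_angle(bound, free, pairs) == pytest.approx(0.0, abs=1e-9)
        assert sg.unwrap_angle(free, free, pairs) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_50_degrees(self):
        free, bound, pairs, _ = simulate_dna_arc(CoordSimSpec(unwrap_angle_deg=50.0))
        assert sg.unwrap_angle(bound, free, pairs) == pytest.approx(50.0, abs=0.5)

    def test_symmetric(self):
        free, bound, pairs, _ = simulate_dna_arc(CoordSimSpec(unwrap_angle_deg=33.0))
        ab = sg.unwrap_angle(bound, free, pairs)
        ba = sg.unwrap_angle(free, bound, pairs)
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_short_segment_error(self):
        free, bound, pairs, _ = simulate_dna_arc(CoordSimSpec())
        with pytest.raises(ValidationError):
            sg.unwrap_angle(bound, free, pairs, segment=slice(-3, None))

    @pytest.mark.parametrize("angle", [10.0, 90.0, 160.0])
    def test_range_of_angles(self, angle):
        free, bound, pairs, _ = simulate_dna_arc(CoordSimSpec(unwrap_angle_deg=angle))
        assert sg.unwrap_angle(bound, free, pairs) == pytest.approx(angle, abs=0.5)
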