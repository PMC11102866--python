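"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (spec, seed) and returns both the
dataset and a ground-truth sidecar for parameter-recovery tests.  No
pipeline stage reads the truth objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import FragmentRecord, StructureModel, TRACE_COLUMNS

SPIKE_ID = "widom601"

# The Widom 601 147-bp core positioning sequence (Lowary & Widom).
WIDOM_601 = (
    "CTGGAGAATCCCGGTGCCGAGGCCGCTCAATTGGTCGTAGACAGCTCTAGCACCGCTTAAACGCACGTA"
    "CGCGCTGTCCCCCGCGTTTTAACCGCCAAGGGGATTACTCCCTAGTCTCCAGGCACGTGTCAGATATAT"
    "ACATCCTGT"
)

NR5A2_MOTIF = "TCAAGGCCA"


# ---------------------------------------------------------------------------
# SeEN-seq counts


@dataclass(frozen=True)
class SeenSeqSimSpec:
    """Multinomial read-count simulation over a tiled library plus spike-in."""

    enrichment: tuple  # log2 enrichment per motif start (len = n constructs)
    reads_per_fraction: int = 100_000
    replicates: int = 3
    spike_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_fraction <= 0:
            raise ValidationError("reads_per_fraction must be positive")
        if not (0.0 < self.spike_fraction < 1.0):
            raise ValidationError("spike_fraction must be in (0, 1)")


def simulate_seen_counts(spec: SeenSeqSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate bound/unbound count tables with a known enrichment vector.

    Unbound read probabilities are uniform over constructs (plus the
    spike-in); bound probabilities are proportional to 2**enrichment.  The
    spike-in weight is identical in both fractions, so the true
    spike-normalized log2 fold change of construct i is exactly
    ``enrichment[i]``.
    """
    rng = np.random.default_rng(spec.seed)
    e = np.asarray(spec.enrichment, dtype=float)
    n = e.size
    ids = [f"pos{i + 1}" for i in range(n)] + [SPIKE_ID]
    per_construct = (1.0 - spec.spike_fraction) / n
    unbound_w = np.concatenate([np.full(n, per_construct), [spec.spike_fraction]])
    bound_w = np.concatenate([per_construct * 2.0**e, [spec.spike_fraction]])
    rows = []
    for rep in range(1, spec.replicates + 1):
        for fraction, weights in (("bound", bound_w), ("unbound", unbound_w)):
            counts = rng.multinomial(spec.reads_per_fraction, weights / weights.sum())
            rows.extend(
                (cid, rep, fraction, int(c)) for cid, c in zip(ids, counts)
            )
    table = pd.DataFrame(rows, columns=["construct_id", "replicate", "fraction", "count"])
    truth = {"enrichment": e, "spike_id": SPIKE_ID,
             "bound_weights": bound_w / bound_w.sum(),
             "unbound_weights": unbound_w / unbound_w.sum()}
    return table, truth


# ---------------------------------------------------------------------------
# MNase fragments


@dataclass(frozen=True)
class FragmentSimSpec:
    """Fragment ensemble around known dyads.

    ``dyads`` are 1-based bp on the reference (matching reported dyad
    calls); fragments are centered so that the half-open midpoint rule
    recovers the dyad exactly for every generated length.
    """

    dyads: tuple = (73, 87, 108)
    weights: tuple = (0.5, 0.3, 0.2)
    length_probs: dict = field(default_factory=lambda: {145: 1 / 3, 146: 1 / 3, 147: 1 / 3})
    # wide enough that a full-length fragment can center on the last dyad
    ref_length: int = 240
    ref_id: str = "endo"
    n_fragments: int = 10_000
    condition: str = "minus_factor"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dyads) != len(self.weights):
            raise ValidationError("dyads and weights differ in length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")


def simulate_fragments(spec: FragmentSimSpec) -> tuple[list[FragmentRecord], dict]:
    """Draw fragments dyad-centered with a discrete length distribution."""
    rng = np.random.default_rng(spec.seed)
    dyads0 = np.asarray(spec.dyads, dtype=int) - 1  # 0-based
    comp = rng.choice(len(dyads0), size=spec.n_fragments, p=np.asarray(spec.weights))
    lengths_avail = np.array(sorted(spec.length_probs))
    probs = np.array([spec.length_probs[l] for l in lengths_avail], dtype=float)
    lengths = rng.choice(lengths_avail, size=spec.n_fragments, p=probs / probs.sum())
    starts = dyads0[comp] - (lengths - 1) // 2
    ends = starts + lengths
    # digestion cannot extend past the construct: truncate at the ends
    # (shifts the midpoint of a clipped fragment by at most the clip size)
    starts = np.clip(starts, 0, spec.ref_length)
    ends = np.clip(ends, 0, spec.ref_length)
    if (starts >= ends).any():
        raise ValidationError("dyads outside the reference")
    lengths = ends - starts
    fragments = [
        FragmentRecord(spec.ref_id, int(s), int(e), spec.condition)
        for s, e in zip(starts, ends)
    ]
    truth = {"component": comp, "dyads_1based": np.asarray(spec.dyads),
             "weights": np.asarray(spec.weights), "lengths": lengths}
    return fragments, truth


# ---------------------------------------------------------------------------
# smFRET traces


@dataclass(frozen=True)
class FretSimSpec:
    """Two-state FRET trace simulation with bleaching and a donor-only class.

    Dwells are sampled in continuous time and the instantaneous state is
    read out at frame midpoints, so frame quantization and missed
    sub-frame events are faithfully present in the output.
    """

    tau_low_s: float = 16.4
    tau_high_s: float = 20.27
    e_high: float = 0.75
    e_low: float = 0.25
    intensity_total: float = 1000.0
    noise_sd: float = 50.0
    alpha: float = 0.05
    gamma: float = 1.0
    frame_interval_s: float = 10.0
    n_frames: int = 180
    acceptor_bleach_mean_s: float = 600.0
    donor_bleach_mean_s: float = 900.0
    donor_only_fraction: float = 0.1
    multistep_fraction: float = 0.0
    n_molecules: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.e_low < self.e_high <= 1.0):
            raise ValidationError("need 0 <= e_low < e_high <= 1")
        for name in ("tau_low_s", "tau_high_s", "frame_interval_s",
                     "acceptor_bleach_mean_s", "donor_bleach_mean_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def wt_preset(n_molecules: int = 300, seed: int = 0, **overrides) -> FretSimSpec:
    """Wild-type-like preset: lifetimes (16.4, 20.27) s at 10 s frames."""
    return replace(FretSimSpec(tau_low_s=16.4, tau_high_s=20.27,
                               frame_interval_s=10.0, n_frames=180,
                               n_molecules=n_molecules, seed=seed), **overrides)


def d159a_preset(n_molecules: int = 300, seed: int = 0, **overrides) -> FretSimSpec:
    """CTE-mutant-like preset: lifetimes (9.19, 16.44) s at 6 s frames."""
    return replace(FretSimSpec(tau_low_s=9.19, tau_high_s=16.44,
                               frame_interval_s=6.0, n_frames=300,
                               n_molecules=n_molecules, seed=seed), **overrides)


def _sample_state_path(rng, spec: FretSimSpec, t_end: float):
    """Continuous-time alternating state path up to t_end.

    Returns (switch_times, first_state_is_high).  The initial state is
    drawn from the stationary occupancy.
    """
    pi_high = spec.tau_high_s / (spec.tau_low_s + spec.tau_high_s)
    high = bool(rng.random() < pi_high)
    first_high = high
    t = 0.0
    switches = []
    while t < t_end:
        tau = spec.tau_high_s if high else spec.tau_low_s
        t += rng.exponential(tau)
        if t < t_end:
            switches.append(t)
        high = not high
    return np.array(switches), first_high


def _states_at(times: np.ndarray, switches: np.ndarray, first_high: bool) -> np.ndarray:
    n_before = np.searchsorted(switches, times)
    if first_high:
        return (n_before % 2) == 0
    return (n_before % 2) == 1


def simulate_fret_traces(spec: FretSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-molecule donor/acceptor traces.

    Returns (trace table, per-molecule truth table with columns
    molecule_id, label, acceptor_bleach_frame, donor_bleach_frame,
    n_true_switches).
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval_s
    frame_times = (np.arange(spec.n_frames) + 0.5) * dt
    t_end = spec.n_frames * dt
    total = spec.intensity_total
    rows = []
    truth_rows = []
    for m in range(spec.n_molecules):
        mol = f"mol{m:04d}"
        u = rng.random()
        if u < spec.donor_only_fraction:
            label = "donor_only"
        elif u < spec.donor_only_fraction + spec.multistep_fraction:
            label = "multistep"
        else:
            label = "fret"
        t_donor = rng.exponential(spec.donor_bleach_mean_s)
        t_acceptor = rng.exponential(spec.acceptor_bleach_mean_s)
        donor = np.zeros(spec.n_frames)
        acceptor = np.zeros(spec.n_frames)
        n_switch = 0

        if label == "donor_only":
            alive = frame_times < t_donor
            donor[alive] = total
            t_acceptor = math.inf
        elif label == "multistep":
            # static high-FRET molecule whose acceptor goes dark and
            # recovers before its final bleach (blinking / second event)
            t_gap0 = 0.3 * t_end + rng.exponential(0.05 * t_end)
            gap = 5 * dt
            t_gap1 = t_gap0 + gap
            t_acceptor = max(t_gap1 + 10 * dt, t_acceptor)
            t_donor = max(t_acceptor + 10 * dt, t_donor)
            for i, t in enumerate(frame_times):
                if t >= t_donor:
                    continue
                acceptor_dark = (t_gap0 <= t < t_gap1) or t >= t_acceptor
                if acceptor_dark:
                    donor[i] = total
                    acceptor[i] = spec.alpha * total
                else:
                    d_em = total * (1 - spec.e_high)
                    donor[i] = d_em
                    acceptor[i] = total * spec.e_high + spec.alpha * d_em
        else:
            switches, first_high = _sample_state_path(rng, spec, t_end)
            high = _states_at(frame_times, switches, first_high)
            e_state = np.where(high, spec.e_high, spec.e_low)
            pre = frame_times < min(t_acceptor, t_donor)
            recovered = (frame_times >= t_acceptor) & (frame_times < t_donor)
            d_em = total * (1 - e_state)
            donor[pre] = d_em[pre]
            acceptor[pre] = total * e_state[pre] + spec.alpha * d_em[pre]
            donor[recovered] = total
            acceptor[recovered] = spec.alpha * total
            n_switch = int(np.sum((switches < min(t_acceptor, t_donor, t_end))))

        donor = donor + rng.normal(0.0, spec.noise_sd, spec.n_frames)
        acceptor = acceptor + rng.normal(0.0, spec.noise_sd, spec.n_frames)
        for i in range(spec.n_frames):
            rows.append((mol, i, i * dt, donor[i], acceptor[i]))
        truth_rows.append((
            mol, label,
            int(t_acceptor / dt) if t_acceptor < t_end else -1,
            int(t_donor / dt) if t_donor < t_end else -1,
            n_switch,
        ))
    traces = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=[
        "molecule_id", "label", "acceptor_bleach_frame", "donor_bleach_frame",
        "n_true_switches"])
    return traces, truth


# ---------------------------------------------------------------------------
# coordinates


@dataclass(frozen=True)
class CoordSimSpec:
    n_atoms: int = 100
    rotation_axis: tuple = (0.0, 0.0, 1.0)
    rotation_angle_deg: float = 37.0
    translation: tuple = (5.0, -3.0, 2.0)
    noise_sd: float = 0.0
    arc_radius: float = 42.0
    arc_n_bp: int = 60
    arc_step_deg: float = 4.0
    hinge_index: int = 40
    unwrap_angle_deg: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.unwrap_angle_deg <= 180.0):
            raise ValidationError("unwrap angle must be in [0, 180] degrees")


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(theta) * k + (1 - math.cos(theta)) * (k @ k)


def simulate_point_cloud(spec: CoordSimSpec):
    """Random point cloud and its image under a known rigid transform."""
    rng = np.random.default_rng(spec.seed)
    points = rng.normal(0.0, 10.0, size=(spec.n_atoms, 3))
    rot = rotation_matrix(spec.rotation_axis, spec.rotation_angle_deg)
    t = np.asarray(spec.translation, dtype=float)
    moved = points @ rot.T + t
    if spec.noise_sd > 0:
        moved = moved + rng.normal(0.0, spec.noise_sd, size=moved.shape)
    truth = {"rotation": rot, "translation": t,
             "angle_deg": spec.rotation_angle_deg}
    return points, moved, truth


def _arc_centers(spec: CoordSimSpec) -> np.ndarray:
    angles = np.radians(np.arange(spec.arc_n_bp) * spec.arc_step_deg)
    return np.column_stack([
        spec.arc_radius * np.cos(angles),
        spec.arc_radius * np.sin(angles),
        np.zeros_like(angles),
    ])


def _arc_model(centers: np.ndarray, core: np.ndarray) -> StructureModel:
    """Model with pseudo C1' strand atoms straddling each bp center (chains
    I/J) plus a rigid Calpha 'core' chain A for superposition."""
    atoms = []
    z = np.array([0.0, 0.0, 1.0])
    for i, c in enumerate(centers, start=1):
        for chain, sign in (("I", 1.0), ("J", -1.0)):
            x, y, zz = c + sign * z
            res = "DA" if chain == "I" else "DT"
            atoms.append((chain, i, res, "C1'", "C", x, y, zz))
    for i, c in enumerate(core, start=1):
        atoms.append(("A", i, "ALA", "CA", "C", c[0], c[1], c[2]))
    return StructureModel.from_atoms(atoms)


def ideal_duplex(n_bp: int, twist_deg: float = 36.0, rise: float = 3.4,
                 radius: float = 9.0, strand_offset_deg: float = 120.0,
                 extra_chain: StructureModel | None = None) -> StructureModel:
    """Idealized straight double helix with P and C1' pseudo-atoms.

    Chains I and J, residues 1..n_bp; useful as a docking template/target.
    """
    atoms = []
    for i in range(n_bp):
        theta = math.radians(twist_deg * i)
        z = rise * i
        for chain, sign in (("I", 0.0), ("J", 1.0)):
            phi = theta + sign * math.radians(strand_offset_deg)
            res = "DA" if chain == "I" else "DT"
            x, y = radius * math.cos(phi), radius * math.sin(phi)
            atoms.append((chain, i + 1, res, "C1'", "C", x, y, z))
            xp, yp = 1.1 * radius * math.cos(phi + 0.2), 1.1 * radius * math.sin(phi + 0.2)
            atoms.append((chain, i + 1, res, "P", "P", xp, yp, z + 1.0))
    return StructureModel.from_atoms(atoms)


def simulate_dna_arc(spec: CoordSimSpec):
    """Wrapped-DNA path pair: full arc vs arc with a rotated terminal segment.

    The terminal segment (bp index >= hinge_index) of the "bound" model is
    rotated by ``unwrap_angle_deg`` about the axis normal to the arc plane
    through the hinge base pair, so line fits through the terminal
    base-pair centers differ by exactly that angle.
    Returns (model_free, model_bound, strand_pairs, truth).
    """
    rng = np.random.default_rng(spec.seed)
    centers = _arc_centers(spec)
    core = rng.normal(0.0, 15.0, size=(24, 3))
    hinge = spec.hinge_index
    if not (4 <= hinge <= spec.arc_n_bp - 4):
        raise ValidationError("hinge too close to the arc ends")
    rot = rotation_matrix((0.0, 0.0, 1.0), spec.unwrap_angle_deg)
    pivot = centers[hinge]
    moved = centers.copy()
    moved[hinge:] = (centers[hinge:] - pivot) @ rot.T + pivot
    if spec.noise_sd > 0:
        moved = moved + rng.normal(0.0, spec.noise_sd, size=moved.shape)
    model_free = _arc_model(centers, core)
    model_bound = _arc_model(moved, core)
    strand_pairs = [(("I", i), ("J", i)) for i in range(1, spec.arc_n_bp + 1)]
    truth = {"unwrap_angle_deg": spec.unwrap_angle_deg, "hinge_index": hinge}
    return model_free, model_bound, strand_pairs, truth
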