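"""Synthetic systems with known ground truth for every analysis stage.

Four generators are provided:

* :func:`build_bilayer` — a planar two-leaflet patch of headgroup-only
  pseudo-lipids (single atoms named ``N``), a 70/30 neutral/anionic species
  mix by default, and the counterion count implied by the total anionic
  charge (1000 lipids at 30% monovalent anionic → 300 counterions).
* :func:`simulate_docking_trajectory` — a rigid pseudo-protein translated
  and rotated above the patch so its centre-of-mass height and
  helix-segment angle follow a prescribed piecewise-linear schedule exactly,
  before optional i.i.d. Gaussian positional noise; the noiseless heights,
  angles and per-residue contact indicators are returned as ground truth.
* :func:`simulate_transport_trace` — a fluorescence transport trace with
  single-exponential transfer kinetics after an injection time, plus
  additive Gaussian noise.
* :func:`generate_sequences` — random amino-acid sequences with a signature
  motif planted into a known fraction at recorded positions.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from .io_formats import (
    LEAFLET_LOWER,
    LEAFLET_NONE,
    LEAFLET_UPPER,
    MEMBRANE_CHAIN,
    PROTEIN_CHAIN,
    ParamTable,
    Trajectory,
)
from .geometry import SegmentSpec, membrane_plane_z, segment_axis
from .kinetics import KineticTrace
from .motifs import AMINO_ACIDS, SequenceRecord

__all__ = [
    "BilayerSpec",
    "DockingSchedule",
    "GroundTruth",
    "TraceGroundTruth",
    "build_bilayer",
    "make_pseudo_protein",
    "simulate_docking_trajectory",
    "simulate_transport_trace",
    "generate_sequences",
    "default_params",
    "approach_dock_schedule",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class BilayerSpec:
    """Planar bilayer patch description.

    ``anionic_fraction`` of the lipids carry ``lipid_charge`` (PS-like, -1 by
    default); the remainder are neutral (PC-like).  ``leaflet_separation`` is
    the headgroup-plane to headgroup-plane distance.
    """

    n_lipids: int = 1000
    anionic_fraction: float = 0.30
    lipid_charge: float = -1.0
    leaflet_separation: float = 38.0  # Å, typical fluid PC bilayer P-P distance
    patch_side: float = 180.0         # Å
    z_jitter_sd: float = 1.0          # Å
    min_spacing: float = 6.0          # Å, densest packing allowed

    def __post_init__(self) -> None:
        if self.n_lipids <= 0 or self.n_lipids % 2:
            raise ValueError("n_lipids must be positive and even")
        if not 0.0 <= self.anionic_fraction <= 1.0:
            raise ValueError("anionic_fraction must lie in [0, 1]")


def _anionic_counts(spec: BilayerSpec) -> tuple[int, int]:
    """Anionic lipids per (upper, lower) leaflet, largest-remainder rounded.

    The bilayer total is fixed first (half-up rounding of n_lipids x
    fraction, the tie broken toward the anionic species), then split across
    leaflets with any odd lipid going to the upper one.
    """
    total = _round_half_up(spec.n_lipids * spec.anionic_fraction)
    upper = _round_half_up(total / 2.0)
    return upper, total - upper


def build_bilayer(
    spec: BilayerSpec, seed: int = 0
) -> tuple[struc.AtomArray, int]:
    """Build headgroup pseudo-atoms for both leaflets.

    Returns the atoms (chain ``M``, residue names ``PS``/``PC``, one ``N``
    atom per lipid, ``leaflet`` annotation set) and the counterion count,
    i.e. the magnitude of the total anionic charge.
    """
    rng = np.random.default_rng(seed)
    n_half = spec.n_lipids // 2
    side = math.ceil(math.sqrt(n_half))
    spacing = spec.patch_side / side
    if spacing < spec.min_spacing:
        raise ValueError(
            f"patch of {spec.patch_side} Å cannot hold {n_half} lipids per "
            f"leaflet at >= {spec.min_spacing} Å spacing (got {spacing:.2f} Å)"
        )
    grid = (np.arange(side) - (side - 1) / 2.0) * spacing
    xy = np.array([(x, y) for x in grid for y in grid])[:n_half]

    n_up, n_lo = _anionic_counts(spec)
    atoms = struc.AtomArray(spec.n_lipids)
    coords = np.zeros((spec.n_lipids, 3))
    res_names = np.full(spec.n_lipids, "PC", dtype="U5")
    leaflet = np.zeros(spec.n_lipids, dtype=int)
    half_sep = spec.leaflet_separation / 2.0
    for offset, z_sign, code, n_anionic in (
        (0, +1.0, LEAFLET_UPPER, n_up),
        (n_half, -1.0, LEAFLET_LOWER, n_lo),
    ):
        sl = slice(offset, offset + n_half)
        coords[sl, :2] = xy
        coords[sl, 2] = z_sign * half_sep + rng.normal(
            0.0, spec.z_jitter_sd, n_half
        )
        leaflet[sl] = code
        anionic_sites = rng.choice(n_half, size=n_anionic, replace=False)
        res_names[offset + anionic_sites] = "PS"
    atoms.coord = coords
    atoms.atom_name = np.full(spec.n_lipids, "N")
    atoms.res_name = res_names
    atoms.res_id = np.arange(1, spec.n_lipids + 1)
    atoms.chain_id = np.full(spec.n_lipids, MEMBRANE_CHAIN)
    atoms.element = np.full(spec.n_lipids, "N")
    atoms.set_annotation("leaflet", leaflet)
    counterions = _round_half_up((n_up + n_lo) * abs(spec.lipid_charge))
    return atoms, counterions


def make_pseudo_protein(
    seed: int = 0,
    first_res: int = 36,
    last_res: int = 434,
    atoms_per_residue: int = 1,
    radius: float = 18.0,
    segment: tuple[int, int] = (346, 356),
    rise_per_res: float = 1.5,
) -> struc.AtomArray:
    """A rigid pseudo-protein: one compact Cα cloud per residue.

    Residue numbering defaults to 36-434, mirroring a lid-less ORD-sized
    construct.  The orientation-segment residues are laid along a straight
    line (helix-axis surrogate, 1.5 Å rise per residue) so the segment axis
    is exact; everything else is an isotropic random cloud.  With
    ``atoms_per_residue > 1`` each residue is a small rigid cluster around
    its centre, the first atom (``CA``) exactly at the centre.
    """
    rng = np.random.default_rng(seed)
    res_ids = np.arange(first_res, last_res + 1)
    n_res = res_ids.size
    # uniform in a ball: radius ∝ cube root of uniform
    directions = rng.normal(size=(n_res, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    centers = directions * radius * rng.uniform(size=(n_res, 1)) ** (1 / 3)
    lo, hi = segment
    seg_mask = (res_ids >= lo) & (res_ids <= hi)
    n_seg = int(seg_mask.sum())
    if n_seg:
        t = np.arange(n_seg) - (n_seg - 1) / 2.0
        direction = np.array([1.0, 0.0, 1.0]) / math.sqrt(2.0)
        centers[seg_mask] = t[:, None] * rise_per_res * direction

    n_atoms = n_res * atoms_per_residue
    coords = np.zeros((n_atoms, 3))
    atom_names = np.empty(n_atoms, dtype="U5")
    out_res = np.repeat(res_ids, atoms_per_residue)
    for i in range(n_res):
        base = i * atoms_per_residue
        coords[base] = centers[i]
        atom_names[base] = "CA"
        if atoms_per_residue > 1:
            offsets = rng.normal(0.0, 1.0, (atoms_per_residue - 1, 3))
            coords[base + 1 : base + atoms_per_residue] = centers[i] + offsets
            atom_names[base + 1 : base + atoms_per_residue] = [
                f"C{j}" for j in range(1, atoms_per_residue)
            ]
    atoms = struc.AtomArray(n_atoms)
    atoms.coord = coords
    atoms.atom_name = atom_names
    atoms.res_id = out_res
    atoms.res_name = np.full(n_atoms, "ALA")
    atoms.chain_id = np.full(n_atoms, PROTEIN_CHAIN)
    atoms.element = np.full(n_atoms, "C")
    atoms.set_annotation("leaflet", np.full(n_atoms, LEAFLET_NONE))
    return atoms


@dataclass
class DockingSchedule:
    """Piecewise-linear targets for the docking motion.

    ``breakpoints`` is a sequence of (time ns, height Å, angle °) rows with
    strictly increasing times; targets between breakpoints are linearly
    interpolated.  ``noise_sd`` is the per-coordinate Gaussian jitter added
    to every atom of every frame.
    """

    breakpoints: list = field(
        default_factory=lambda: [(0.0, 54.0, 60.0), (500.0, 54.0, 60.0)]
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        times = [b[0] for b in self.breakpoints]
        if len(times) < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        for _, _, ang in self.breakpoints:
            if not 0.0 <= ang <= 90.0:
                raise ValueError("schedule angles must lie in [0°, 90°]")

    @property
    def t_start(self) -> float:
        return self.breakpoints[0][0]

    @property
    def t_end(self) -> float:
        return self.breakpoints[-1][0]

    def interpolate(self, t_ns) -> tuple[np.ndarray, np.ndarray]:
        t_ns = np.asarray(t_ns, dtype=float)
        times = np.array([b[0] for b in self.breakpoints])
        h = np.interp(t_ns, times, [b[1] for b in self.breakpoints])
        ang = np.interp(t_ns, times, [b[2] for b in self.breakpoints])
        return h, ang


def approach_dock_schedule(
    duration_ns: float = 500.0,
    h_start: float = 54.0,
    h_dock: float = 16.0,
    theta_start: float = 60.0,
    theta_dock: float = 20.0,
    dock_fraction: float = 0.6,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DockingSchedule:
    """Approach-then-dock preset: start ~54 Å above the plane, descend and
    reorient over the first part of the run, then hold the docked pose."""
    t_dock = dock_fraction * duration_ns
    return DockingSchedule(
        breakpoints=[
            (0.0, h_start, theta_start),
            (t_dock, h_dock, theta_dock),
            (duration_ns, h_dock, theta_dock),
        ],
        noise_sd=noise_sd,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Noiseless per-frame values behind a synthetic docking trajectory."""

    time_ns: np.ndarray
    height: np.ndarray
    angle: np.ndarray
    residue_ids: np.ndarray
    contact: np.ndarray  # (n_frames, n_residues) bool
    contact_threshold: float

    def contact_fraction(self) -> pd.Series:
        """Schedule-implied per-residue contact percentage."""
        f = 100.0 * self.contact.mean(axis=0)
        return pd.Series(f, index=pd.Index(self.residue_ids, name="residue_id"))


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v (Rodrigues)."""
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180° about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return -np.eye(3) + 2.0 * np.outer(perp, perp)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def simulate_docking_trajectory(
    protein: struc.AtomArray,
    bilayer: struc.AtomArray,
    schedule: DockingSchedule,
    frame_interval_ps: float = 100.0,
    duration_ns: float = 500.0,
    segment_spec: SegmentSpec | None = None,
    contact_threshold: float = 5.0,
) -> tuple[Trajectory, GroundTruth]:
    """Scripted rigid-body docking motion above a static bilayer.

    Every frame the protein is rigidly rotated so its orientation-segment
    axis makes the scheduled angle with the membrane plane, and translated so
    its (unit-mass) centre of mass sits the scheduled height above the
    realized reference plane; only then is Gaussian noise added.  500 ns at
    100 ps per frame yields 5000 frames.
    """
    segment_spec = segment_spec or SegmentSpec()
    if schedule.t_start > 0.0 or schedule.t_end < duration_ns:
        raise ValueError(
            f"schedule [{schedule.t_start}, {schedule.t_end}] ns does not "
            f"cover the run [0, {duration_ns}] ns"
        )
    dt_ns = frame_interval_ps / 1000.0
    n_frames = int(round(duration_ns / dt_ns))
    if n_frames < 1:
        raise ValueError("duration shorter than one frame interval")
    times = np.arange(n_frames) * dt_ns
    h_t, ang_t = schedule.interpolate(times)

    template = protein + bilayer
    plane_z = membrane_plane_z(bilayer)
    u0 = segment_axis(protein, segment_spec)
    prot_coords0 = np.asarray(protein.coord, dtype=float)
    com0 = prot_coords0.mean(axis=0)
    memb_coords = np.asarray(bilayer.coord, dtype=float)
    n_prot = prot_coords0.shape[0]
    prot_res = protein.res_id
    res_order = np.argsort(prot_res, kind="stable")
    res_ids, res_start = np.unique(prot_res[res_order], return_index=True)
    res_counts = np.diff(np.append(res_start, n_prot))

    rng = np.random.default_rng(schedule.seed)
    coords = np.empty((n_frames, len(template), 3))
    contact = np.zeros((n_frames, res_ids.size), dtype=bool)
    for i in range(n_frames):
        theta = math.radians(ang_t[i])
        d = np.array([math.cos(theta), 0.0, math.sin(theta)])
        R = _rotation_between(u0, d)
        prot = (prot_coords0 - com0) @ R.T
        prot[:, 2] += plane_z + h_t[i]
        coords[i, :n_prot] = prot
        coords[i, n_prot:] = memb_coords
        res_z = np.add.reduceat(prot[res_order, 2], res_start) / res_counts
        contact[i] = (res_z - plane_z) < contact_threshold
        if schedule.noise_sd > 0:
            coords[i] += rng.normal(0.0, schedule.noise_sd, coords[i].shape)
    stack = struc.AtomArrayStack(n_frames, len(template))
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    # the public coord setter downcasts to float32, which would cap noiseless
    # schedule recovery near 1e-6; keep the simulated frames at float64
    stack._coord = coords
    traj = Trajectory(stack, frame_interval_ps=frame_interval_ps)
    truth = GroundTruth(
        time_ns=times,
        height=h_t,
        angle=ang_t,
        residue_ids=res_ids,
        contact=contact,
        contact_threshold=contact_threshold,
    )
    return traj, truth


@dataclass
class TraceGroundTruth:
    """True parameters behind a synthetic transport trace."""

    k: float                       # s⁻¹
    true_initial_rate: float | None = None  # µM/s, requires an AssayConfig


def simulate_transport_trace(
    k: float = 0.05,
    F0: float = 100.0,
    Fmax: float = 600.0,
    t_inject: float = 10.0,
    noise_sd: float = 0.0,
    dt: float = 0.5,
    duration: float = 120.0,
    seed: int = 0,
    config=None,
) -> tuple[KineticTrace, TraceGroundTruth]:
    """Exponential transfer trace: flat at F0, then saturating rise after
    injection, ``F = F0 + (Fmax − F0)(1 − exp(−k(t − t_inject)))``, plus
    additive Gaussian noise.

    If an :class:`~lipswitch.kinetics.AssayConfig` is supplied, the ground
    truth also carries the true initial transport rate, accessible ligand
    concentration × k (µM/s).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if Fmax <= F0:
        raise ValueError("need Fmax > F0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, duration + dt / 2.0, dt)
    F = np.full_like(time, float(F0))
    post = time >= t_inject
    F[post] = F0 + (Fmax - F0) * (1.0 - np.exp(-k * (time[post] - t_inject)))
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, F.shape)
    trace = KineticTrace(
        time=time,
        F=F,
        F0=float(F0),
        Fmax=float(Fmax),
        t_inject=float(t_inject),
        t_protein=float(t_inject),
    )
    rate = None
    if config is not None:
        from .kinetics import accessible_concentration

        rate = accessible_concentration(config) * k
    return trace, TraceGroundTruth(k=k, true_initial_rate=rate)


def _find_all(seq: str, motif: str) -> list[int]:
    hits, start = [], 0
    while True:
        pos = seq.find(motif, start)
        if pos == -1:
            return hits
        hits.append(pos + 1)
        start = pos + 1


def generate_sequences(
    n: int,
    motif: str = "LPTFILE",
    plant_fraction: float = 0.5,
    length: int = 120,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Random sequences with the motif planted into a known fraction.

    Exactly ``round(plant_fraction × n)`` sequences carry the motif at a
    recorded 1-based position (and nowhere else); the remainder are
    rejection-checked to be motif-free.  Returns the records and a mapping
    of record id to planted position.
    """
    if len(motif) >= length:
        raise ValueError("motif must be shorter than the sequence length")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    n_plant = _round_half_up(plant_fraction * n)
    records: list[SequenceRecord] = []
    planted: dict[str, int] = {}
    for i in range(n):
        while True:
            seq = "".join(rng.choice(alphabet, size=length))
            if not _find_all(seq, motif):
                break
        rec_id = f"seq{i + 1:04d}"
        if i < n_plant:
            while True:
                pos = int(rng.integers(0, length - len(motif) + 1))
                candidate = seq[:pos] + motif + seq[pos + len(motif):]
                if _find_all(candidate, motif) == [pos + 1]:
                    seq = candidate
                    planted[rec_id] = pos + 1
                    break
        records.append(SequenceRecord(id=rec_id, sequence=seq))
    return records, planted


def default_params(frame, lipid_charge: float = -1.0) -> ParamTable:
    """Generic nonbonded parameters for pseudo-atom systems.

    Anionic headgroups (residue name ``PS``) carry ``lipid_charge``; all
    other atoms are neutral.  A single soft sphere (σ = 4 Å, ε = 0.1
    kcal/mol) stands in for every atom type.
    """
    n = len(frame)
    charge = np.where(frame.res_name == "PS", lipid_charge, 0.0)
    table = pd.DataFrame(
        {
            "charge": charge,
            "sigma": np.full(n, 4.0),
            "epsilon": np.full(n, 0.1),
        },
        index=pd.Index(np.arange(1, n + 1), name="atom_id"),
    )
    return ParamTable(table)
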