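"""Membrane docking-geometry metrics for protein/bilayer trajectories.

All vertical metrics are measured against the membrane reference plane: the
mean z of the upper-leaflet headgroup nitrogens (atoms named ``N``).  Three
per-frame observables are produced:

* ``h`` — signed z-distance between the protein centre of mass and the plane,
* ``h_entry`` — signed z-distance between the centroid of the three
  pocket-entry residues (defaults N129/F185/S190) and the plane,
* ``theta`` — angle in degrees between the orientation segment of the α7
  helix (default residues 346-356) and the membrane plane, folded into
  [0°, 90°].

Per-residue contact fractions count, over a trajectory window, the frames in
which a residue's centre of mass lies at a signed z-distance below a cutoff
(default 5 Å) from the plane; residues buried below the plane count as
contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

import biotite.structure as struc

from .io_formats import LEAFLET_UPPER, LEAFLET_LOWER, PROTEIN_CHAIN, Trajectory

__all__ = [
    "SegmentSpec",
    "ATOMIC_MASSES",
    "masses_from_atom_names",
    "membrane_plane_z",
    "com",
    "protein_height",
    "entry_height",
    "segment_angle",
    "contact_fractions",
    "sample_series",
    "rmsd",
    "rmsf",
]

#: Standard atomic masses (u) keyed by element symbol.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
}


@dataclass
class SegmentSpec:
    """Residue selections for the orientation axis and the pocket entry."""

    segment: tuple[int, int] = (346, 356)
    entry_residues: tuple[int, ...] = (129, 185, 190)

    def __post_init__(self) -> None:
        lo, hi = self.segment
        if hi < lo:
            raise ValueError("segment range must be non-decreasing")
        if not self.entry_residues:
            raise ValueError("entry_residues must be non-empty")


def masses_from_atom_names(atom_names) -> np.ndarray:
    """Infer atomic masses from the first alphabetic character of each name.

    PDB-style names may carry leading digits (e.g. ``1HB``); digits are
    skipped.  Unknown elements fall back to carbon.
    """
    masses = np.empty(len(atom_names))
    for i, name in enumerate(atom_names):
        element = next((c for c in name if c.isalpha()), "C").upper()
        masses[i] = ATOMIC_MASSES.get(element, ATOMIC_MASSES["C"])
    return masses


def _coords(frame) -> np.ndarray:
    return np.asarray(frame.coord, dtype=float)


def membrane_plane_z(frame: struc.AtomArray, leaflet: int = LEAFLET_UPPER) -> float:
    """Mean z of the headgroup nitrogens of one leaflet (the reference plane)."""
    mask = (frame.atom_name == "N") & (frame.leaflet == leaflet)
    if not mask.any():
        name = "upper" if leaflet == LEAFLET_UPPER else "lower"
        raise ValueError(f"no 'N' atoms in the {name} leaflet")
    return float(frame.coord[mask, 2].mean(dtype=np.float64))


def com(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted mean position; unit masses if none supplied."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("need a non-empty (n, 3) coordinate array")
    if masses is None:
        return coords.mean(axis=0)
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def protein_height(
    frame: struc.AtomArray, masses: np.ndarray | None = None
) -> float:
    """Signed height of the protein COM above the membrane plane, in Å."""
    mask = frame.chain_id == PROTEIN_CHAIN
    if not mask.any():
        raise ValueError("frame contains no protein atoms (chain 'P')")
    m = masses[mask] if masses is not None else None
    return float(com(_coords(frame)[mask], m)[2] - membrane_plane_z(frame))


def entry_height(
    frame: struc.AtomArray,
    spec: SegmentSpec | None = None,
    masses: np.ndarray | None = None,
) -> float:
    """Signed height of the pocket-entry centroid above the membrane plane.

    The centroid is the mass centre of all atoms of the entry residues.
    """
    spec = spec or SegmentSpec()
    prot = frame.chain_id == PROTEIN_CHAIN
    mask = prot & np.isin(frame.res_id, spec.entry_residues)
    for res in spec.entry_residues:
        if not np.any(prot & (frame.res_id == res)):
            raise ValueError(f"entry residue {res} not present in the protein")
    m = masses[mask] if masses is not None else None
    return float(com(_coords(frame)[mask], m)[2] - membrane_plane_z(frame))


def segment_axis(
    frame: struc.AtomArray,
    spec: SegmentSpec | None = None,
    method: str = "pca",
) -> np.ndarray:
    """Unit direction of the orientation segment.

    ``pca`` uses the first principal component of the segment's Cα positions
    (all atoms if no Cα naming is present), robust to coordinate jitter.
    ``endpoints`` uses the vector from the first to the last residue centroid
    and serves as an independent cross-check.  The sign points toward
    increasing residue number.
    """
    spec = spec or SegmentSpec()
    lo, hi = spec.segment
    prot = frame.chain_id == PROTEIN_CHAIN
    in_seg = prot & (frame.res_id >= lo) & (frame.res_id <= hi)
    ca = in_seg & (frame.atom_name == "CA")
    mask = ca if ca.any() else in_seg
    coords = _coords(frame)[mask]
    res_ids = frame.res_id[mask]
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 reference atoms in the segment")
    if np.allclose(coords, coords[0]):
        raise ValueError("degenerate segment: all reference points coincide")
    if method == "pca":
        centred = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        axis = vt[0]
    elif method == "endpoints":
        first = coords[res_ids == res_ids.min()].mean(axis=0)
        last = coords[res_ids == res_ids.max()].mean(axis=0)
        axis = last - first
        if np.allclose(axis, 0):
            raise ValueError("degenerate segment: coincident endpoints")
    else:
        raise ValueError(f"unknown axis method {method!r}")
    axis = axis / np.linalg.norm(axis)
    # orient toward increasing residue number
    order = np.argsort(res_ids, kind="stable")
    span = coords[order[-1]] - coords[order[0]]
    if np.dot(axis, span) < 0:
        axis = -axis
    return axis


def segment_angle(
    frame: struc.AtomArray,
    spec: SegmentSpec | None = None,
    angle_ref: str = "plane",
    method: str = "pca",
) -> float:
    """Angle of the orientation segment, in degrees, folded into [0°, 90°].

    ``angle_ref='plane'`` (default) reports the angle between the segment and
    the membrane plane; ``'normal'`` reports it against the membrane normal
    (the z axis).  The two conventions are complementary to 90°.
    """
    axis = segment_axis(frame, spec, method=method)
    cos_to_normal = abs(float(np.clip(axis[2], -1.0, 1.0)))
    angle_to_normal = np.degrees(np.arccos(cos_to_normal))
    if angle_ref == "plane":
        return 90.0 - angle_to_normal
    if angle_ref == "normal":
        return angle_to_normal
    raise ValueError("angle_ref must be 'plane' or 'normal'")


def _residue_com_z(frame: struc.AtomArray, masses: np.ndarray | None):
    """z of each protein residue's COM, returned with the residue ids."""
    prot = frame.chain_id == PROTEIN_CHAIN
    res_ids = frame.res_id[prot]
    z = _coords(frame)[prot, 2]
    w = masses[prot] if masses is not None else np.ones(prot.sum())
    order = np.argsort(res_ids, kind="stable")
    res_sorted = res_ids[order]
    uniq, start = np.unique(res_sorted, return_index=True)
    zw = (z * w)[order]
    wsum = np.add.reduceat(w[order], start)
    zsum = np.add.reduceat(zw, start)
    return uniq, zsum / wsum


def contact_fractions(
    traj: Trajectory,
    threshold: float = 5.0,
    window: tuple[int, int] | None = None,
    masses: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-residue percentage of frames in membrane contact.

    A residue is in contact in a frame iff the *signed* z-distance between
    its centre of mass and the membrane plane is strictly below ``threshold``
    (residues below the plane therefore always count).  ``window`` selects a
    0-based, half-open frame range; default is the whole trajectory.

    Returns a DataFrame indexed by ``residue_id`` with column ``f_percent``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    start, end = window if window is not None else (0, traj.n_frames)
    if not (0 <= start < end <= traj.n_frames):
        raise ValueError(f"empty or out-of-range window {(start, end)}")
    counts = None
    res_index = None
    for i in range(start, end):
        frame = traj.frame(i)
        plane = membrane_plane_z(frame)
        res_ids, z = _residue_com_z(frame, masses)
        contact = (z - plane) < threshold
        if counts is None:
            counts = contact.astype(int)
            res_index = res_ids
        else:
            counts += contact
    f = 100.0 * counts / (end - start)
    return pd.DataFrame({"f_percent": f}, index=pd.Index(res_index, name="residue_id"))


def sample_series(
    traj: Trajectory,
    every_ps: float | None = None,
    spec: SegmentSpec | None = None,
    angle_ref: str = "plane",
    masses: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame (h, h_entry, theta) sampled every ``every_ps`` picoseconds.

    ``every_ps`` must be a multiple of the trajectory frame interval; the
    default samples every frame.  A 500 ns trajectory stored every 100 ps
    yields 5000 samples.
    """
    spec = spec or SegmentSpec()
    dt = traj.frame_interval_ps
    if every_ps is None:
        every_ps = dt
    stride_f = every_ps / dt
    stride = int(round(stride_f))
    if stride < 1 or abs(stride_f - stride) > 1e-9:
        raise ValueError(
            f"stride {every_ps} ps is not a multiple of the frame interval {dt} ps"
        )
    rows = []
    for i in range(0, traj.n_frames, stride):
        frame = traj.frame(i)
        rows.append(
            (
                i * dt / 1000.0,
                protein_height(frame, masses),
                entry_height(frame, spec, masses),
                segment_angle(frame, spec, angle_ref=angle_ref),
            )
        )
    return pd.DataFrame(rows, columns=["time_ns", "h", "h_entry", "theta_deg"])


def _kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``target``."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


def rmsd(frame_a, frame_b, superpose: bool = True) -> float:
    """Root-mean-square deviation between two matched coordinate sets, in Å.

    With ``superpose`` the optimal least-squares rigid-body fit (Kabsch) is
    applied first.  Accepts ``AtomArray`` objects or plain (n, 3) arrays.
    """
    a = np.asarray(getattr(frame_a, "coord", frame_a), dtype=float)
    b = np.asarray(getattr(frame_b, "coord", frame_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if superpose:
        a = _kabsch_superpose(a, b)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def rmsf(traj: Trajectory, mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-residue root-mean-square fluctuation about the time-average.

    Each frame is first superposed onto the mean structure (computed after an
    initial superposition onto frame 0), then per-atom mean-square deviations
    from the refined average are averaged within each residue.

    Returns a DataFrame indexed by ``residue_id`` with column ``rmsf``.
    """
    if mask is None:
        mask = traj.protein_mask()
    coords = np.asarray(traj.stack.coord, dtype=float)[:, mask, :]
    res_ids = traj.stack.res_id[mask]
    aligned = np.array([_kabsch_superpose(c, coords[0]) for c in coords])
    mean = aligned.mean(axis=0)
    aligned = np.array([_kabsch_superpose(c, mean) for c in aligned])
    mean = aligned.mean(axis=0)
    msd = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)
    order = np.argsort(res_ids, kind="stable")
    uniq, start = np.unique(res_ids[order], return_index=True)
    per_res = np.sqrt(
        np.add.reduceat(msd[order], start)
        / np.diff(np.append(start, len(order)))
    )
    return pd.DataFrame({"rmsf": per_res}, index=pd.Index(uniq, name="residue_id"))
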