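"""Numerical accessible-surface-area (ASA) computation and ΔASA comparison.

ASA follows the Shrake-Rupley construction: each atom sphere is expanded by
the solvent probe radius (default 1.5 Å), sampled with a deterministic
golden-spiral point set (default 960 points), and a sample point counts as
accessible when it lies outside every other expanded sphere.  Per-atom ASA is
the accessible fraction of 4π(rᵢ + probe)².

ΔASA between a full structure and a truncated one (atoms only removed)
quantifies how much surface of the retained residues the deleted part was
occluding — e.g. how much of a lipid-binding pocket's rim a molecular lid
covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["RadiusSet", "sphere_points", "shrake_rupley_asa", "delta_asa"]

#: Van der Waals radii (Å) by element, a standard generic set.
DEFAULT_VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
}


@dataclass
class RadiusSet:
    """Atomic radii, probe radius and sampling density for ASA runs."""

    radii: dict = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    probe_radius: float = 1.5
    n_sphere_points: int = 960
    default_radius: float = 1.70

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("radii must be positive")
        if self.n_sphere_points < 8:
            raise ValueError("n_sphere_points too small for a meaningful surface")

    def radius_of(self, atom_name: str) -> float:
        element = next((c for c in atom_name if c.isalpha()), "").upper()
        if element in self.radii:
            return self.radii[element]
        return self.default_radius


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _atom_radii(frame, radii: RadiusSet, explicit=None) -> np.ndarray:
    if explicit is not None:
        return np.asarray(explicit, dtype=float)
    return np.array([radii.radius_of(name) for name in frame.atom_name])


def shrake_rupley_asa(
    frame,
    radii: RadiusSet | None = None,
    mask: np.ndarray | None = None,
    atom_radii: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-atom accessible surface area of the selected atoms, in Ų.

    ``mask`` restricts which atoms are reported; *all* atoms of the frame
    still occlude.  ``atom_radii`` overrides name-based radius lookup.
    Returns a DataFrame with columns ``residue_id`` and ``asa``; the total is
    its ``asa`` sum.
    """
    radii = radii or RadiusSet()
    coords = np.asarray(frame.coord, dtype=float)
    n = coords.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    expanded = _atom_radii(frame, radii, atom_radii) + radii.probe_radius
    points = sphere_points(radii.n_sphere_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    asa = np.zeros(n)
    for i in np.flatnonzero(mask):
        shell = coords[i] + expanded[i] * points
        neighbors = [
            j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
            if j != i
        ]
        accessible = np.ones(len(shell), dtype=bool)
        for j in neighbors:
            d2 = ((shell - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= expanded[j] ** 2
        asa[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return pd.DataFrame(
        {"residue_id": frame.res_id[mask], "asa": asa[mask]},
        index=pd.Index(np.flatnonzero(mask) + 1, name="atom_id"),
    )


def residue_asa(per_atom: pd.DataFrame) -> pd.Series:
    """Aggregate a per-atom ASA table to per-residue totals."""
    return per_atom.groupby("residue_id")["asa"].sum()


def delta_asa(
    frame_full,
    frame_truncated,
    radii: RadiusSet | None = None,
) -> pd.DataFrame:
    """Per-residue ASA gained by a deletion: ASA(truncated) - ASA(full).

    ``frame_truncated`` must contain a subset (by residue_id) of the full
    structure's residues.  Positive values mark surface that the deleted
    atoms were covering.
    """
    radii = radii or RadiusSet()
    full_res = set(np.unique(frame_full.res_id))
    trunc_res = set(np.unique(frame_truncated.res_id))
    extra = trunc_res - full_res
    if extra:
        raise ValueError(
            f"truncated structure has residues absent from the full one: {sorted(extra)[:10]}"
        )
    asa_full = residue_asa(shrake_rupley_asa(frame_full, radii))
    asa_trunc = residue_asa(shrake_rupley_asa(frame_truncated, radii))
    shared = asa_trunc.index
    out = (asa_trunc - asa_full.loc[shared]).rename("delta_asa").to_frame()
    out.index.name = "residue_id"
    return out
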