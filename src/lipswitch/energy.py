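"""Switched pairwise Coulomb and Lennard-Jones protein-membrane energies.

Both terms use the same C¹-continuous potential switch taking the
interaction smoothly to zero between ``r_on`` (default 10 Å) and ``r_off``
(default 12 Å):

    S(x) = 1 - 3x² + 2x³,   x = (r - r_on) / (r_off - r_on)

Coulomb uses the CHARMM constant k = 332.0636 kcal·Å·mol⁻¹·e⁻²; Lennard-Jones
uses 4ε[(σ/r)¹² - (σ/r)⁶] with Lorentz-Berthelot combining rules (arithmetic
σ, geometric ε).  This is a desk-scale, non-periodic approximation of a
force-field energy rerun: absolute magnitudes are not comparable to energies
computed with mesh Ewald electrostatics on a periodic solvated system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ParamTable, Trajectory
import pandas as pd

__all__ = [
    "COULOMB_K",
    "SwitchSpec",
    "switch_factor",
    "pair_energy",
    "frame_interaction_energy",
    "energy_series",
]

#: Coulomb constant in kcal·Å·mol⁻¹·e⁻² (CHARMM convention).
COULOMB_K = 332.0636


@dataclass(frozen=True)
class SwitchSpec:
    """Switching window: full strength below r_on, zero beyond r_off (Å)."""

    r_on: float = 10.0
    r_off: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.r_on < self.r_off:
            raise ValueError("need 0 < r_on < r_off")


def switch_factor(r, spec: SwitchSpec = SwitchSpec()):
    """Dimensionless switching multiplier in [0, 1]; vectorised over r."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    x = np.clip((r - spec.r_on) / (spec.r_off - spec.r_on), 0.0, 1.0)
    s = 1.0 - 3.0 * x**2 + 2.0 * x**3
    return s if s.ndim else float(s)


def pair_energy(
    r: float,
    q_i: float,
    q_j: float,
    sigma_i: float,
    sigma_j: float,
    eps_i: float,
    eps_j: float,
    spec: SwitchSpec = SwitchSpec(),
) -> tuple[float, float]:
    """Switched (coulomb, vdw) energy of one atom pair, in kcal/mol."""
    if r <= 0:
        raise ValueError("overlapping atoms (r = 0)")
    if r >= spec.r_off:
        return 0.0, 0.0
    s = switch_factor(r, spec)
    coul = COULOMB_K * q_i * q_j / r * s
    sigma = 0.5 * (sigma_i + sigma_j)
    eps = np.sqrt(eps_i * eps_j)
    sr6 = (sigma / r) ** 6
    vdw = 4.0 * eps * (sr6**2 - sr6) * s
    return float(coul), float(vdw)


def frame_interaction_energy(
    frame,
    params: ParamTable,
    group_a: np.ndarray | None = None,
    group_b: np.ndarray | None = None,
    spec: SwitchSpec = SwitchSpec(),
) -> tuple[float, float]:
    """Total switched (E_coul, E_vdw) over all cross pairs of two selections.

    Defaults to the protein (chain ``P``) against the membrane (chain ``M``).
    The sum is computed with full pair enumeration inside the cutoff, so the
    result is identical to the brute-force double loop.
    """
    if group_a is None:
        group_a = frame.chain_id == "P"
    if group_b is None:
        group_b = frame.chain_id == "M"
    if np.any(group_a & group_b):
        raise ValueError("selections must be disjoint")
    atom_ids = np.arange(1, len(frame) + 1)
    pa = params.lookup(atom_ids[group_a])
    pb = params.lookup(atom_ids[group_b])
    ca = np.asarray(frame.coord, dtype=float)[group_a]
    cb = np.asarray(frame.coord, dtype=float)[group_b]
    diff = ca[:, None, :] - cb[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    if np.any(r == 0):
        raise ValueError("overlapping atoms between the two selections")
    s = switch_factor(r, spec)
    inside = r < spec.r_off
    qq = np.outer(pa["charge"].to_numpy(), pb["charge"].to_numpy())
    coul = np.where(inside, COULOMB_K * qq / r * s, 0.0).sum()
    sigma = 0.5 * (
        pa["sigma"].to_numpy()[:, None] + pb["sigma"].to_numpy()[None, :]
    )
    eps = np.sqrt(
        pa["epsilon"].to_numpy()[:, None] * pb["epsilon"].to_numpy()[None, :]
    )
    sr6 = (sigma / r) ** 6
    vdw = np.where(inside, 4.0 * eps * (sr6**2 - sr6) * s, 0.0).sum()
    return float(coul), float(vdw)


def energy_series(
    traj: Trajectory,
    params: ParamTable,
    spec: SwitchSpec = SwitchSpec(),
) -> pd.DataFrame:
    """Per-frame protein-membrane interaction energies.

    Returns a DataFrame with columns ``time_ns``, ``e_coul_kcal``,
    ``e_vdw_kcal``.
    """
    rows = []
    pmask, mmask = traj.protein_mask(), traj.membrane_mask()
    for i in range(traj.n_frames):
        coul, vdw = frame_interaction_energy(
            traj.frame(i), params, pmask, mmask, spec
        )
        rows.append((traj.times_ns[i], coul, vdw))
    return pd.DataFrame(rows, columns=["time_ns", "e_coul_kcal", "e_vdw_kcal"])
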