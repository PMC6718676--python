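import numpy as np
import pytest
import biotite.structure as struc

import lipswitch as lw


def make_atoms(coords, atom_names=None, res_ids=None, chain="P", leaflet=None):
    """Build a minimal AtomArray for toy fixtures."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.atom_name = np.asarray(atom_names if atom_names is not None else ["CA"] * n)
    atoms.res_id = np.asarray(res_ids if res_ids is not None else np.arange(1, n + 1))
    atoms.res_name = np.full(n, "ALA")
    atoms.chain_id = np.full(n, chain)
    atoms.element = np.full(n, "C")
    atoms.set_annotation(
        "leaflet",
        np.asarray(leaflet if leaflet is not None else np.zeros(n, dtype=int)),
    )
    return atoms


@pytest.fixture(scope="session")
def small_bilayer():
    spec = lw.BilayerSpec(n_lipids=100, patch_side=80.0, z_jitter_sd=1.0)
    atoms, counterions = lw.build_bilayer(spec, seed=11)
    return atoms, counterions


@pytest.fixture(scope="session")
def pseudo_protein():
    return lw.make_pseudo_protein(seed=7)


@pytest.fixture(scope="session")
def noiseless_traj(pseudo_protein, small_bilayer):
    schedule = lw.DockingSchedule(
        breakpoints=[(0.0, 40.0, 70.0), (1.0, 12.0, 20.0), (2.0, 12.0, 20.0)]
    )
    traj, truth = lw.simulate_docking_trajectory(
        pseudo_protein, small_bilayer[0], schedule,
        frame_interval_ps=100.0, duration_ns=2.0,
    )
    return traj, truth, schedule
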