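"""Shared fixtures: toy topologies and small synthetic bundles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tncoupling.io import Atom, Topology, Trajectory

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_topology(n_residues: int = 5, atoms_per_residue: int = 3,
                  ligand_atoms: int = 2, chain: str = "C") -> Topology:
    """Toy topology: one protein chain plus an optional HETATM ligand."""
    atoms: list[Atom] = []
    names = ["CA", "CB", "CG", "CD", "CE"]
    for resid in range(1, n_residues + 1):
        for j in range(atoms_per_residue):
            atoms.append(Atom(len(atoms), names[j], "C", resid, "ALA", chain))
    for j in range(ligand_atoms):
        atoms.append(Atom(len(atoms), f"L{j + 1}", "C", 1, "LIG", "L", is_hetero=True))
    return Topology(atoms)


def random_trajectory(topology: Topology, n_frames: int, rng: np.random.Generator,
                      box: float = 12.0) -> Trajectory:
    coords = rng.uniform(0, box, size=(n_frames, topology.n_atoms, 3))
    return Trajectory(coords, run_id="rand")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def brute_force_contacts(topology: Topology, coords: np.ndarray, cutoff: float):
    """Independent oracle: naive all-pairs ligand-protein distance scan.

    Returns (per-residue contact probabilities, per-frame bound flags).
    """
    lig = [a for a in topology.atoms if a.chain_id == "L"]
    prot = [a for a in topology.atoms if a.chain_id == "C"]
    residues = sorted({(a.chain_id, a.residue_number) for a in prot})
    n_frames = coords.shape[0]
    probs = {}
    for key in residues:
        hits = 0
        for f in range(n_frames):
            dmin = min(
                np.linalg.norm(coords[f, la.index] - coords[f, pa.index])
                for la in lig
                for pa in prot
                if (pa.chain_id, pa.residue_number) == key
            )
            if dmin < cutoff:
                hits += 1
        probs[key] = hits / n_frames
    bound = []
    for f in range(n_frames):
        dmin = min(
            np.linalg.norm(coords[f, la.index] - coords[f, pa.index])
            for la in lig
            for pa in prot
        )
        bound.append(dmin < cutoff)
    return probs, bound


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def wt_bundle():
    """Session-scoped wild-type apo synthetic bundle (small, ligand-free)."""
    from tncoupling.synthetic import TrajectorySpec, gen_trajectory

    return gen_trajectory(TrajectorySpec(n_frames=300, n_runs=2, seed=7))


@pytest.fixture(scope="session")
def g159d_bundle():
    """Session-scoped mutant bundle with salt bridge and bound ligand."""
    from tncoupling.synthetic import LigandSpec, TrajectorySpec, gen_trajectory

    spec = TrajectorySpec(
        n_frames=400,
        n_runs=2,
        variant="G159D",
        saltbridge_occupancy=0.801,
        ligand=LigandSpec.for_bound_fraction(0.93, mean_episode_frames=40),
        seed=11,
    )
    return gen_trajectory(spec)
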