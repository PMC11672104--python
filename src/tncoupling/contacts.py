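"""Ligand-protein contact occupancy, hotspots and binding episodes.

A ligand is in contact with a residue in a frame when the minimal
distance between any ligand atom and any atom of the residue is
strictly below the cutoff (default 2.5 Angstrom).  Residue-level
contact probabilities over a trajectory give the contact profile;
residues contacted strictly more than 10% of the time are hotspots.
Attachment treats the whole protein as one selection and segments the
per-frame bound state into maximal bound/unbound episodes, whose
bound-frame fraction is the "fraction of time attached".

No periodic-boundary imaging is applied: coordinates are assumed
pre-imaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .io import RegionSpec, StructureError, Topology, Trajectory, resolve

__all__ = [
    "ContactProfile",
    "AttachmentSummary",
    "Episode",
    "residue_contact_series",
    "contact_profile",
    "hotspots",
    "attachment",
]

DEFAULT_CONTACT_CUTOFF_A = 2.5
DEFAULT_HOTSPOT_THRESHOLD = 0.10


@dataclass(frozen=True)
class Episode:
    start_frame: int      # inclusive
    end_frame: int        # exclusive
    bound: bool

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class ContactProfile:
    """Per-residue contact probability over a trajectory."""

    probabilities: dict[tuple[str, int], float]   # (chain, resid) -> p
    residue_names: dict[tuple[str, int], str]
    cutoff: float
    n_frames: int

    def __post_init__(self) -> None:
        for key, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"contact probability for {key} outside [0, 1]: {p}")


@dataclass
class AttachmentSummary:
    fraction_attached: float
    episodes: list[Episode]
    n_frames: int

    @property
    def mean_bound_episode_length(self) -> float:
        lens = [e.length for e in self.episodes if e.bound]
        return float(np.mean(lens)) if lens else 0.0


def _check_cutoff(cutoff: float) -> None:
    if cutoff <= 0:
        raise ValueError(f"contact cutoff must be positive, got {cutoff}")


def _heavy_filter(topology: Topology, indices: np.ndarray, heavy_only: bool) -> np.ndarray:
    if not heavy_only:
        return indices
    keep = [i for i in indices if topology.atoms[i].element.upper() != "H"]
    if not keep:
        raise StructureError("selection is empty after removing hydrogens")
    return np.array(keep, dtype=int)


def _min_distance_series(
    trajectory: Trajectory, idx_a: np.ndarray, idx_b: np.ndarray
) -> np.ndarray:
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        out[f] = cdist(trajectory.coordinates[f, idx_a], trajectory.coordinates[f, idx_b]).min()
    return out


def residue_contact_series(
    trajectory: Trajectory,
    topology: Topology,
    ligand: RegionSpec,
    residue: tuple[str, int],
    cutoff: float = DEFAULT_CONTACT_CUTOFF_A,
    heavy_only: bool = False,
) -> np.ndarray:
    """Boolean per-frame series: ligand-residue min distance < cutoff (strict)."""
    _check_cutoff(cutoff)
    lig = _heavy_filter(topology, resolve(ligand, topology), heavy_only)
    chain, resid = residue
    res_idx = np.array(
        [a.index for a in topology.atoms if a.chain_id == chain and a.residue_number == resid],
        dtype=int,
    )
    if res_idx.size == 0:
        raise StructureError(f"residue {chain}:{resid} not found in topology")
    res_idx = _heavy_filter(topology, res_idx, heavy_only)
    return _min_distance_series(trajectory, lig, res_idx) < cutoff


def contact_profile(
    trajectory: Trajectory,
    topology: Topology,
    ligand: RegionSpec,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_A,
    heavy_only: bool = False,
) -> ContactProfile:
    """Contact probability for every protein (non-hetero) residue.

    The probability is the mean of the residue's per-frame contact
    series; the profile covers all protein residues, zeros included.
    """
    _check_cutoff(cutoff)
    lig = _heavy_filter(topology, resolve(ligand, topology), heavy_only)
    lig_set = set(int(i) for i in lig)

    # group protein atoms by residue, preserving file order
    res_atoms: dict[tuple[str, int], list[int]] = {}
    res_names: dict[tuple[str, int], str] = {}
    for a in topology.atoms:
        if a.is_hetero or a.index in lig_set:
            continue
        if heavy_only and a.element.upper() == "H":
            continue
        key = (a.chain_id, a.residue_number)
        res_atoms.setdefault(key, []).append(a.index)
        res_names.setdefault(key, a.residue_name)
    if not res_atoms:
        raise StructureError("topology has no protein residues outside the ligand selection")

    # flatten residue atom lists so per-residue minima reduce in one pass
    keys = list(res_atoms)
    flat = np.concatenate([res_atoms[k] for k in keys])
    bounds = np.cumsum([0] + [len(res_atoms[k]) for k in keys])[:-1]
    counts = np.zeros(len(keys), dtype=int)
    for f in range(trajectory.n_frames):
        d = cdist(trajectory.coordinates[f, lig], trajectory.coordinates[f, flat]).min(axis=0)
        counts += np.minimum.reduceat(d, bounds) < cutoff
    probs = {k: counts[i] / trajectory.n_frames for i, k in enumerate(keys)}
    return ContactProfile(probs, res_names, cutoff=cutoff, n_frames=trajectory.n_frames)


def hotspots(
    profile: ContactProfile, threshold: float = DEFAULT_HOTSPOT_THRESHOLD
) -> list[tuple[str, int]]:
    """Residues contacted strictly more than ``threshold`` of the time.

    Sorted by probability descending, ties broken by (chain, residue)
    ascending.  A residue at exactly the threshold is excluded.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"hotspot threshold must be in [0, 1), got {threshold}")
    picked = [(key, p) for key, p in profile.probabilities.items() if p > threshold]
    picked.sort(key=lambda kp: (-kp[1], kp[0]))
    return [key for key, _ in picked]


def _episodes_from_bound(bound: np.ndarray) -> list[Episode]:
    episodes: list[Episode] = []
    start = 0
    for f in range(1, len(bound) + 1):
        if f == len(bound) or bound[f] != bound[start]:
            episodes.append(Episode(start, f, bool(bound[start])))
            start = f
    return episodes


def attachment(
    trajectory: Trajectory,
    topology: Topology,
    ligand: RegionSpec,
    protein: RegionSpec,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_A,
    heavy_only: bool = False,
    debounce_frames: int = 0,
) -> AttachmentSummary:
    """Fraction of time the ligand is attached to the protein, with episodes.

    Bound in a frame iff the min ligand-protein atom distance < cutoff.
    ``debounce_frames`` > 0 flips bound/unbound runs shorter than the
    window to their surrounding state before segmentation (default off:
    raw per-frame state).
    """
    _check_cutoff(cutoff)
    lig = _heavy_filter(topology, resolve(ligand, topology), heavy_only)
    prot = _heavy_filter(topology, resolve(protein, topology), heavy_only)
    if set(map(int, lig)) & set(map(int, prot)):
        raise StructureError("ligand and protein selections overlap")
    bound = _min_distance_series(trajectory, lig, prot) < cutoff

    if debounce_frames > 0:
        for ep in _episodes_from_bound(bound):
            if ep.length < debounce_frames and ep.start_frame > 0:
                bound[ep.start_frame : ep.end_frame] = bound[ep.start_frame - 1]

    episodes = _episodes_from_bound(bound)
    fraction = float(bound.sum()) / trajectory.n_frames
    return AttachmentSummary(fraction, episodes, trajectory.n_frames)
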