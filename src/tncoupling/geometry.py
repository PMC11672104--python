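"""Per-frame geometric observables of troponin dynamics.

The metrics here are the molecular-dynamics readouts of the
phosphorylation response: the angle between cTnC helices A and B
(a proxy for opening of the N-lobe hydrophobic patch, with >110 deg
conventionally the open state), the hinge angle between the NcTnC and
ITC quasi-rigid domains, the distance between the two domains, and the
occupancy of the interdomain D159-R83 salt bridge that rigidifies the
G159D mutant.

Helix axes are the first principal component of the helix C-alpha
coordinates, sign-oriented from the N- to the C-terminal residue.  All
metrics are invariant under global rigid transforms of a frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .io import RegionSpec, StructureError, Topology, Trajectory, resolve

__all__ = [
    "AngleSeries",
    "DistanceSeries",
    "OccupancySeries",
    "GeometryError",
    "helix_axis",
    "interhelix_angle",
    "hinge_angle",
    "interdomain_distance",
    "pair_bond_occupancy",
    "ab_angle_series",
    "hinge_angle_series",
    "interdomain_distance_series",
]

#: conventional ionic-contact threshold between charged side-chain atoms
DEFAULT_SALTBRIDGE_CUTOFF_A = 4.0


class GeometryError(ValueError):
    """Raised for degenerate geometry (too few atoms, zero vectors...)."""


@dataclass
class AngleSeries:
    """Per-frame angle values in degrees for one run and condition."""

    metric_name: str          # "AB_helix" or "hinge"
    values: np.ndarray        # degrees, one per frame
    run_id: str = "run"
    condition: str = ""       # e.g. "G159D/SEP/EGCG"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0.0 or self.values.max() > 180.0):
            raise GeometryError(f"{self.metric_name}: angle outside [0, 180] degrees")


@dataclass
class DistanceSeries:
    values: np.ndarray        # Angstrom per frame
    endpoints: tuple[str, str] = ("domain1", "domain2")
    run_id: str = "run"
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (not np.all(np.isfinite(self.values)) or self.values.min() < 0):
            raise GeometryError("distances must be finite and non-negative")


@dataclass
class OccupancySeries:
    """Per-frame bound/unbound state of an atom-pair contact."""

    bound: np.ndarray         # bool per frame
    cutoff: float             # Angstrom
    run_id: str = "run"
    condition: str = ""

    def __post_init__(self) -> None:
        self.bound = np.asarray(self.bound, dtype=bool)

    @property
    def occupancy(self) -> float:
        return float(self.bound.mean()) if self.bound.size else 0.0


def helix_axis(coords: np.ndarray) -> np.ndarray:
    """First principal axis of a helix's C-alpha coordinates.

    ``coords`` must be ordered N- to C-terminal; the returned unit
    vector points from the N- toward the C-terminal end.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise GeometryError(f"expected (n, 3) coordinates, got {coords.shape}")
    if coords.shape[0] < 4:
        raise GeometryError(f"helix axis needs >= 4 C-alpha atoms, got {coords.shape[0]}")
    centred = coords - coords.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 1e-12:
        raise GeometryError("degenerate helix: all atoms coincide")
    axis = vt[0]
    nc = coords[-1] - coords[0]
    sign = np.dot(axis, nc)
    if abs(sign) <= 1e-12:
        raise GeometryError("cannot orient helix axis: endpoints are symmetric about the axis")
    if sign < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 <= 1e-12 or n2 <= 1e-12:
        raise GeometryError("zero-length vector in angle computation")
    c = np.dot(v1, v2) / (n1 * n2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def interhelix_angle(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Angle (deg) between the oriented axes of two helices."""
    return _angle_deg(helix_axis(coords_a), helix_axis(coords_b))


def hinge_angle(
    pivot_coords: np.ndarray,
    domain1_coords: np.ndarray,
    domain2_coords: np.ndarray,
) -> float:
    """Angle at the pivot centroid between the two domain centroids (deg)."""
    pivot = np.atleast_2d(np.asarray(pivot_coords, dtype=float)).mean(axis=0)
    c1 = np.asarray(domain1_coords, dtype=float).mean(axis=0)
    c2 = np.asarray(domain2_coords, dtype=float).mean(axis=0)
    return _angle_deg(c1 - pivot, c2 - pivot)


def interdomain_distance(domain1_coords: np.ndarray, domain2_coords: np.ndarray) -> float:
    """Euclidean distance (Angstrom) between two domain C-alpha centroids."""
    c1 = np.asarray(domain1_coords, dtype=float).mean(axis=0)
    c2 = np.asarray(domain2_coords, dtype=float).mean(axis=0)
    return float(np.linalg.norm(c1 - c2))


def pair_bond_occupancy(
    trajectory: Trajectory,
    topology: Topology,
    selection_a: RegionSpec,
    selection_b: RegionSpec,
    cutoff: float = DEFAULT_SALTBRIDGE_CUTOFF_A,
) -> tuple[float, OccupancySeries]:
    """Fraction of frames with min inter-selection distance < cutoff.

    An empty selection (the wild-type case: Gly159 carries no
    carboxylate atoms, so the D159 selection resolves to nothing) gives
    occupancy 0 by definition rather than an error.
    """
    if cutoff <= 0:
        raise GeometryError(f"cutoff must be positive, got {cutoff}")
    try:
        idx_a = resolve(selection_a, topology)
        idx_b = resolve(selection_b, topology)
    except StructureError:
        bound = np.zeros(trajectory.n_frames, dtype=bool)
        series = OccupancySeries(bound, cutoff, run_id=trajectory.run_id)
        return 0.0, series
    bound = np.empty(trajectory.n_frames, dtype=bool)
    for f in range(trajectory.n_frames):
        d = cdist(trajectory.coordinates[f, idx_a], trajectory.coordinates[f, idx_b])
        bound[f] = d.min() < cutoff
    series = OccupancySeries(bound, cutoff, run_id=trajectory.run_id)
    return series.occupancy, series


# ---------------------------------------------------------------------------
# trajectory-level series

def ab_angle_series(
    trajectory: Trajectory,
    topology: Topology,
    helix_a: RegionSpec,
    helix_b: RegionSpec,
    condition: str = "",
) -> AngleSeries:
    """Per-frame helix A/B interhelix angle over a trajectory."""
    ia = resolve(helix_a, topology)
    ib = resolve(helix_b, topology)
    vals = np.array(
        [
            interhelix_angle(trajectory.coordinates[f, ia], trajectory.coordinates[f, ib])
            for f in range(trajectory.n_frames)
        ]
    )
    return AngleSeries("AB_helix", vals, run_id=trajectory.run_id, condition=condition)


def hinge_angle_series(
    trajectory: Trajectory,
    topology: Topology,
    domain1: RegionSpec,
    domain2: RegionSpec,
    pivot: RegionSpec,
    condition: str = "",
) -> AngleSeries:
    """Per-frame NcTnC-ITC hinge angle over a trajectory."""
    i1 = resolve(domain1, topology)
    i2 = resolve(domain2, topology)
    ip = resolve(pivot, topology)
    if set(ip) & (set(i1) | set(i2)):
        raise GeometryError("hinge pivot atoms must be disjoint from the domains")
    vals = np.array(
        [
            hinge_angle(
                trajectory.coordinates[f, ip],
                trajectory.coordinates[f, i1],
                trajectory.coordinates[f, i2],
            )
            for f in range(trajectory.n_frames)
        ]
    )
    return AngleSeries("hinge", vals, run_id=trajectory.run_id, condition=condition)


def interdomain_distance_series(
    trajectory: Trajectory,
    topology: Topology,
    domain1: RegionSpec,
    domain2: RegionSpec,
    condition: str = "",
) -> DistanceSeries:
    """Per-frame centroid-centroid domain distance over a trajectory."""
    i1 = resolve(domain1, topology)
    i2 = resolve(domain2, topology)
    vals = np.array(
        [
            interdomain_distance(trajectory.coordinates[f, i1], trajectory.coordinates[f, i2])
            for f in range(trajectory.n_frames)
        ]
    )
    return DistanceSeries(vals, endpoints=(domain1.label, domain2.label),
                          run_id=trajectory.run_id, condition=condition)
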