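"""Synthetic inputs with known ground truth for every pipeline stage.

The trajectory generator stands in for long atomistic MD runs of the
troponin core.  It builds an abstract C-alpha-level scaffold on a
single chain "C" numbered 1-161 (so the default troponin region
definitions - helices A and B, the N-lobe, the ITC-like second domain,
the linker pivot, Arg83 and residue 159 - apply unchanged) plus a
3-atom pseudo-ligand on chain "L".  Per frame it *exactly* realizes

* a sampled helix A/B angle, by rotating the helix-B arm about a fixed
  axis,
* a sampled hinge angle and interdomain centroid distance, by placing
  the N-lobe centroid at the solved polar position about the pivot,
* a salt-bridge state (Bernoulli draw at the target occupancy), by
  placing the Asp159 carboxylate oxygens at 3.0 or 8.0 Angstrom from
  the Arg83 guanidinium nitrogens,
* a two-state Markov ligand with stationary bound fraction
  p_on / (p_on + p_off), bound frames pinning a ligand atom 2.0
  Angstrom from a target residue and unbound frames placing it far
  (>= 15 Angstrom) outside the protein,

and it records all per-frame ground truth in a manifest, so that a
downstream metric disagreeing with the manifest indicates an error in
the metric code, not in the generator.

Default distribution parameters are the wild-type apo unphosphorylated
study condition (A/B angle N(101.81, 9.15) deg, hinge N(121.61, 7.24)
deg, interdomain distance N(30.18, 1.34) Angstrom, 5 runs of 3750
frames at 0.4 ns/frame).

The activation-curve and transient generators emulate the in vitro
motility CSVs and 10 s / 1 Hz cell-shortening records respectively,
again with manifests of the planted parameters.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .io import Atom, RegionSpec, Topology, Trajectory, write_pdb, write_trajectory
from .motility import ActivationCurve, hill
from .transients import TransientTrace

__all__ = [
    "GaussianMixture1D",
    "LigandSpec",
    "TrajectorySpec",
    "CurveSpec",
    "TransientSpec",
    "SyntheticTrajectory",
    "default_regions",
    "gen_trajectory",
    "gen_activation_curves",
    "gen_transients",
    "gen_paired_transients",
    "solve_beat_template",
]

# ---------------------------------------------------------------------------
# scaffold layout (local coordinates, Angstrom)

_CHAIN = "C"
_N_RESIDUES = 161
_HELIX_A = (14, 28)        # 15 pseudo-C-alpha arm
_HELIX_B = (38, 48)        # 11 pseudo-C-alpha arm
_NLOBE = (1, 85)
_LINKER = (86, 92)
_PIVOT_RESID = 89
_ITC = (93, 161)
_ARG_RESID = 83
_ASP_RESID = 159
_CA_RISE = 2.0             # pseudo C-alpha spacing along an arm (keeps the
                           # scaffold compact so domains never interpenetrate)
_D2 = 15.0                 # pivot -> ITC centroid distance
_SB_BOUND_A = 3.0          # carboxylate-guanidinium distance when bonded
_SB_UNBOUND_A = 8.0
_LIGAND_CONTACT_A = 2.0    # bound ligand atom -> target residue distance
_LIGAND_DIRECTIONS = [
    np.array(v, dtype=float) / np.linalg.norm(v)
    for v in (
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
        (1, 0, 1), (-1, 0, 1), (0, 1, 1), (0, -1, 1),
    )
]


@dataclass(frozen=True)
class GaussianMixture1D:
    """Weights/means/stds of a 1-D Gaussian mixture (weights sum to 1)."""

    means: tuple[float, ...]
    stds: tuple[float, ...]
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        w = self.weights or tuple([1.0 / len(self.means)] * len(self.means))
        object.__setattr__(self, "weights", w)
        if not (len(self.means) == len(self.stds) == len(self.weights)):
            raise ValueError("means, stds and weights must have equal length")
        if any(s <= 0 for s in self.stds):
            raise ValueError("mixture stds must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @staticmethod
    def normal(mean: float, std: float) -> "GaussianMixture1D":
        return GaussianMixture1D((mean,), (std,), (1.0,))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        return rng.normal(np.asarray(self.means)[comp], np.asarray(self.stds)[comp])


@dataclass(frozen=True)
class LigandSpec:
    """Two-state Markov binding of a pseudo-ligand.

    ``sites`` are (chain, resid, weight) target residues; each bound
    episode picks one site with the given weights.  The stationary
    bound fraction is p_on / (p_on + p_off).
    """

    p_on: float = 0.19
    p_off: float = 0.01
    # default site: tip of the helix-A arm, which faces away from the
    # interdomain interface at every realizable hinge geometry
    sites: tuple = ((_CHAIN, _HELIX_A[1], 1.0),)
    resname: str = "LIG"

    def __post_init__(self) -> None:
        if not (0 < self.p_on <= 1 and 0 < self.p_off <= 1):
            raise ValueError("p_on and p_off must be in (0, 1]")
        if not self.sites:
            raise ValueError("ligand needs at least one target site")

    @property
    def bound_fraction(self) -> float:
        return self.p_on / (self.p_on + self.p_off)

    @staticmethod
    def for_bound_fraction(fraction: float, mean_episode_frames: float = 100.0) -> "LigandSpec":
        """Choose (p_on, p_off) with the requested stationary bound fraction."""
        if not 0 < fraction < 1:
            raise ValueError("bound fraction must be in (0, 1)")
        p_off = min(1.0, 1.0 / mean_episode_frames)
        p_on = min(1.0, p_off * fraction / (1.0 - fraction))
        return LigandSpec(p_on=p_on, p_off=p_off)


@dataclass(frozen=True)
class TrajectorySpec:
    """Planted statistics of a synthetic trajectory bundle."""

    n_frames: int = 3750
    n_runs: int = 5
    frame_interval_ns: float = 0.4
    ab_angle: GaussianMixture1D = field(
        default_factory=lambda: GaussianMixture1D.normal(101.81, 9.15)
    )
    hinge_angle: GaussianMixture1D = field(
        default_factory=lambda: GaussianMixture1D.normal(121.61, 7.24)
    )
    interdomain_distance: tuple[float, float] = (30.18, 1.34)   # mean, std (Angstrom)
    saltbridge_occupancy: float = 0.0        # wild-type: Gly159, no bond
    variant: str = "WT"                      # "WT" or "G159D"
    ligand: Optional[LigandSpec] = None      # None = apo
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_runs < 1:
            raise ValueError("n_frames and n_runs must be >= 1")
        if not 0.0 <= self.saltbridge_occupancy <= 1.0:
            raise ValueError("saltbridge occupancy must be in [0, 1]")
        if self.interdomain_distance[1] <= 0:
            raise ValueError("interdomain distance std must be positive")
        if self.variant not in ("WT", "G159D"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class SyntheticTrajectory:
    topology: Topology
    runs: list[Trajectory]
    manifest: dict
    regions: dict[str, RegionSpec]

    def write(self, out_dir: str, trajectory_format: str = "pdb") -> dict[str, str]:
        """Write topology, per-run trajectories and the manifest to disk."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {"topology": os.path.join(out_dir, "topology.pdb")}
        write_pdb(paths["topology"], self.topology, self.runs[0].coordinates[0])
        ext = {"pdb": ".pdb", "dcd": ".dcd"}[trajectory_format]
        for traj in self.runs:
            p = os.path.join(out_dir, f"{traj.run_id}{ext}")
            write_trajectory(p, self.topology, traj)
            paths[traj.run_id] = p
        paths["manifest"] = os.path.join(out_dir, "manifest.json")
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh)
        return paths


def default_regions(ligand: bool = False) -> dict[str, RegionSpec]:
    """Region definitions matching the synthetic scaffold numbering.

    These are also the shipped defaults for real topologies that follow
    canonical cNTnC assignments; they are plain data and fully
    user-overridable through configuration.
    """
    regions = {
        "helix_a": RegionSpec.chain_range("helix_a", _CHAIN, *_HELIX_A, ca_only=True),
        "helix_b": RegionSpec.chain_range("helix_b", _CHAIN, *_HELIX_B, ca_only=True),
        "nc_lobe": RegionSpec.chain_range("nc_lobe", _CHAIN, *_NLOBE, ca_only=True),
        "itc_domain": RegionSpec.chain_range("itc_domain", _CHAIN, *_ITC, ca_only=True),
        "pivot": RegionSpec.chain_range("pivot", _CHAIN, _PIVOT_RESID, _PIVOT_RESID, ca_only=True),
        "arg83_guanidinium": RegionSpec.chain_range(
            "arg83_guanidinium", _CHAIN, _ARG_RESID, _ARG_RESID, atom_names=("NH1", "NH2")
        ),
        "asp159_carboxylate": RegionSpec.chain_range(
            "asp159_carboxylate", _CHAIN, _ASP_RESID, _ASP_RESID, atom_names=("OD1", "OD2")
        ),
        "protein": RegionSpec.chain_range("protein", _CHAIN, 1, _N_RESIDUES),
    }
    if ligand:
        regions["ligand"] = RegionSpec.chain_range("ligand", "L", 1, 1)
    return regions


# ---------------------------------------------------------------------------
# scaffold construction

def _build_topology(spec: TrajectorySpec) -> Topology:
    atoms: list[Atom] = []

    def add(name: str, element: str, resid: int, resname: str, chain: str, het: bool = False) -> None:
        atoms.append(Atom(len(atoms), name, element, resid, resname, chain, het))

    for resid in range(1, _N_RESIDUES + 1):
        if resid == _ARG_RESID:
            add("CA", "C", resid, "ARG", _CHAIN)
            add("NH1", "N", resid, "ARG", _CHAIN)
            add("NH2", "N", resid, "ARG", _CHAIN)
        elif resid == _ASP_RESID:
            if spec.variant == "G159D":
                add("CA", "C", resid, "ASP", _CHAIN)
                add("OD1", "O", resid, "ASP", _CHAIN)
                add("OD2", "O", resid, "ASP", _CHAIN)
            else:
                add("CA", "C", resid, "GLY", _CHAIN)
        else:
            add("CA", "C", resid, "ALA", _CHAIN)
    if spec.ligand is not None:
        for name in ("C1", "C2", "C3"):
            add(name, "C", 1, spec.ligand.resname, "L", het=True)
    return Topology(atoms)


def _arm_points(base: np.ndarray, direction: np.ndarray, n: int) -> np.ndarray:
    return base[None, :] + _CA_RISE * np.arange(n)[:, None] * direction[None, :]


def _blob(center: np.ndarray, n: int, rng: np.random.Generator,
          radius: float = 9.0, min_sep: float = 3.0) -> np.ndarray:
    pts: list[np.ndarray] = []
    while len(pts) < n:
        v = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(v) > radius:
            continue
        p = center + v
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_sep:
            continue
        pts.append(p)
    return np.array(pts)


def _nlobe_local(theta_ab_deg: float, blob_pts: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    """Local N-lobe C-alpha positions realizing the A/B angle exactly."""
    a = np.array([0.0, 0.0, 1.0])
    th = np.radians(theta_ab_deg)
    b = np.array([0.0, -np.sin(th), np.cos(th)])    # rotation of a about x by theta
    pos: dict[int, np.ndarray] = {}
    arm_a = _arm_points(np.array([10.0, 0.0, -14.0]), a, _HELIX_A[1] - _HELIX_A[0] + 1)
    for k, resid in enumerate(range(_HELIX_A[0], _HELIX_A[1] + 1)):
        pos[resid] = arm_a[k]
    arm_b = _arm_points(np.array([-10.0, 0.0, -10.0]), b, _HELIX_B[1] - _HELIX_B[0] + 1)
    for k, resid in enumerate(range(_HELIX_B[0], _HELIX_B[1] + 1)):
        pos[resid] = arm_b[k]
    pos.update(blob_pts)
    return pos


def _generate_run(
    spec: TrajectorySpec,
    topology: Topology,
    rng: np.random.Generator,
    run_id: str,
) -> tuple[Trajectory, dict]:
    nf = spec.n_frames
    # static scaffold pieces (fixed across frames within a run)
    nlobe_extra = [r for r in range(_NLOBE[0], _NLOBE[1] + 1)
                   if not (_HELIX_A[0] <= r <= _HELIX_A[1] or _HELIX_B[0] <= r <= _HELIX_B[1])]
    scaffold_rng = np.random.default_rng(12345)  # geometry layout, not statistics
    blob1 = _blob(np.array([0.0, 16.0, 0.0]), len(nlobe_extra), scaffold_rng, radius=8.0)
    blob1_pts = dict(zip(nlobe_extra, blob1))
    itc_resids = list(range(_ITC[0], _ITC[1] + 1))
    itc_pts = _blob(np.array([_D2, 0.0, 0.0]), len(itc_resids), scaffold_rng)
    itc_pts = itc_pts - itc_pts.mean(axis=0) + np.array([_D2, 0.0, 0.0])  # centroid exact
    linker_resids = [r for r in range(_LINKER[0], _LINKER[1] + 1) if r != _PIVOT_RESID]
    linker_pts = {r: np.array([(-2.0 + 0.8 * i), 3.0, 0.5 * i]) for i, r in enumerate(linker_resids)}

    # per-frame planted values
    ab = np.clip(spec.ab_angle.sample(rng, nf), 5.0, 175.0)
    hinge = np.clip(spec.hinge_angle.sample(rng, nf), 5.0, 175.0)
    dmean, dstd = spec.interdomain_distance
    dist = np.clip(rng.normal(dmean, dstd, nf), _D2 + 1.0, None)
    sb_bound = rng.random(nf) < spec.saltbridge_occupancy

    lig_bound = np.zeros(nf, dtype=bool)
    lig_site = np.full(nf, -1, dtype=int)
    if spec.ligand is not None:
        ls = spec.ligand
        state = rng.random() < ls.bound_fraction
        weights = np.array([s[2] for s in ls.sites], dtype=float)
        weights /= weights.sum()
        site = int(rng.choice(len(ls.sites), p=weights))
        for f in range(nf):
            if state:
                lig_bound[f] = True
                lig_site[f] = site
                if rng.random() < ls.p_off:
                    state = False
            else:
                if rng.random() < ls.p_on:
                    state = True
                    site = int(rng.choice(len(ls.sites), p=weights))

    # index lookups
    by_key = {(a.chain_id, a.residue_number, a.name): a.index for a in topology.atoms}
    ca = {r: by_key[(_CHAIN, r, "CA")] for r in range(1, _N_RESIDUES + 1)}
    nh1, nh2 = by_key[(_CHAIN, _ARG_RESID, "NH1")], by_key[(_CHAIN, _ARG_RESID, "NH2")]
    od = None
    if spec.variant == "G159D":
        od = (by_key[(_CHAIN, _ASP_RESID, "OD1")], by_key[(_CHAIN, _ASP_RESID, "OD2")])
    lig_idx = None
    if spec.ligand is not None:
        lig_idx = tuple(by_key[("L", 1, n)] for n in ("C1", "C2", "C3"))

    protein_idx = [a.index for a in topology.atoms if a.chain_id == _CHAIN]
    nlobe_ca = [ca[r] for r in range(_NLOBE[0], _NLOBE[1] + 1)]

    coords = np.zeros((nf, topology.n_atoms, 3))
    for f in range(nf):
        frame = coords[f]
        # pivot at origin; ITC domain static
        frame[ca[_PIVOT_RESID]] = 0.0
        for k, r in enumerate(itc_resids):
            frame[ca[r]] = itc_pts[k]
        for r, p in linker_pts.items():
            frame[ca[r]] = p

        # N-lobe: realize A/B angle locally, then place its centroid so the
        # hinge angle and interdomain distance both hold exactly
        local = _nlobe_local(ab[f], blob1_pts)
        local_arr = np.array([local[r] for r in range(_NLOBE[0], _NLOBE[1] + 1)])
        c_local = local_arr.mean(axis=0)
        th = np.radians(hinge[f])
        # |c1 - c2| = dist[f] with c2 = (d2, 0, 0):  solve the triangle for d1
        rad = dist[f] ** 2 - (_D2 * np.sin(th)) ** 2
        d1 = _D2 * np.cos(th) + np.sqrt(max(rad, 0.0))
        target_centroid = d1 * np.array([np.cos(th), np.sin(th), 0.0])
        shift = target_centroid - c_local
        for r in range(_NLOBE[0], _NLOBE[1] + 1):
            frame[ca[r]] = local[r] + shift

        # Arg83 guanidinium rides on its C-alpha; Asp159 carboxylate placed
        # at the drawn salt-bridge distance from NH1
        frame[nh1] = frame[ca[_ARG_RESID]] + np.array([1.5, 0.0, 0.0])
        frame[nh2] = frame[nh1] + np.array([0.0, 1.2, 0.0])
        if od is not None:
            dsb = _SB_BOUND_A if sb_bound[f] else _SB_UNBOUND_A
            frame[od[0]] = frame[nh1] + np.array([0.0, 0.0, dsb])
            frame[od[1]] = frame[nh1] + np.array([0.0, 0.0, dsb + 0.5])

        if lig_idx is not None:
            if lig_bound[f]:
                chain, resid, _w = spec.ligand.sites[lig_site[f]]
                anchor = frame[by_key[(chain, resid, "CA")]]
                target_idx = by_key[(chain, resid, "CA")]
                others = [i for i in protein_idx if topology.atoms[i].residue_number != resid
                          or topology.atoms[i].chain_id != chain]
                base = direction = None
                for cand in _LIGAND_DIRECTIONS:
                    trial = anchor + _LIGAND_CONTACT_A * cand
                    pts = trial[None, :] + np.arange(3)[:, None] * cand[None, :]
                    from scipy.spatial.distance import cdist as _cdist
                    if _cdist(pts, frame[others]).min() > _LIGAND_CONTACT_A + 0.6:
                        base, direction = trial, cand
                        break
                if base is None:
                    raise RuntimeError(
                        "internal error: no collision-free bound ligand placement "
                        f"at residue {chain}:{resid} in frame {f}"
                    )
            else:
                prot = frame[protein_idx]
                centre = prot.mean(axis=0)
                radius = np.linalg.norm(prot - centre, axis=1).max()
                direction = np.array([0.0, -1.0, 0.0])
                base = centre + (radius + 20.0) * direction
            for k, idx in enumerate(lig_idx):
                frame[idx] = base + k * 1.0 * direction

    traj = Trajectory(coords, frame_interval_ns=spec.frame_interval_ns, run_id=run_id)
    truth = {
        "ab_angle_deg": ab.tolist(),
        "hinge_angle_deg": hinge.tolist(),
        "interdomain_distance_a": dist.tolist(),
        "saltbridge_bound": sb_bound.astype(int).tolist(),
        "ligand_bound": lig_bound.astype(int).tolist(),
        "ligand_site": lig_site.tolist(),
    }
    return traj, truth


def gen_trajectory(spec: TrajectorySpec) -> SyntheticTrajectory:
    """Generate a synthetic multi-run trajectory bundle with ground truth."""
    topology = _build_topology(spec)
    ss = np.random.SeedSequence(spec.seed)
    runs: list[Trajectory] = []
    per_run: dict[str, dict] = {}
    for i, child in enumerate(ss.spawn(spec.n_runs), start=1):
        run_id = f"run{i}"
        traj, truth = _generate_run(spec, topology, np.random.default_rng(child), run_id)
        runs.append(traj)
        per_run[run_id] = truth
    manifest = {
        "kind": "trajectory",
        "spec": {
            "n_frames": spec.n_frames,
            "n_runs": spec.n_runs,
            "frame_interval_ns": spec.frame_interval_ns,
            "ab_angle": asdict(spec.ab_angle),
            "hinge_angle": asdict(spec.hinge_angle),
            "interdomain_distance": list(spec.interdomain_distance),
            "saltbridge_occupancy": spec.saltbridge_occupancy,
            "variant": spec.variant,
            "ligand": None if spec.ligand is None else {
                "p_on": spec.ligand.p_on,
                "p_off": spec.ligand.p_off,
                "bound_fraction": spec.ligand.bound_fraction,
                "sites": [list(s) for s in spec.ligand.sites],
            },
            "seed": spec.seed,
        },
        "runs": per_run,
    }
    regions = default_regions(ligand=spec.ligand is not None)
    return SyntheticTrajectory(topology, runs, manifest, regions)


# ---------------------------------------------------------------------------
# activation curves

@dataclass(frozen=True)
class CurveSpec:
    """Planted parameters of paired P/unP Ca2+-activation curves.

    Defaults mirror the native thin-filament condition: unphosphorylated
    EC50 0.059 uM with a 2.24-fold desensitisation on phosphorylation.
    """

    ec50_unp_um: float = 0.059
    ratio: float = 2.24            # EC50(P) / EC50(unP)
    n_h: float = 2.0
    f_max: float = 0.80
    f_min: float = 0.05
    noise_sd: float = 0.0
    n_points: int = 8
    n_replicates: int = 1
    span_factor: float = 20.0      # concentrations span EC50/span .. EC50*ratio*span
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ec50_unp_um <= 0 or self.ratio <= 0:
            raise ValueError("EC50 and ratio must be positive")
        if self.n_points < 5:
            raise ValueError("need >= 5 concentrations")


def gen_activation_curves(spec: CurveSpec) -> tuple[list[tuple[ActivationCurve, ActivationCurve]], dict]:
    """Paired (P, unP) activation curves per replicate, plus manifest."""
    rng = np.random.default_rng(spec.seed)
    ca = np.geomspace(
        spec.ec50_unp_um / spec.span_factor,
        spec.ec50_unp_um * spec.ratio * spec.span_factor,
        spec.n_points,
    )
    ec50_p = spec.ec50_unp_um * spec.ratio
    pairs = []
    for r in range(1, spec.n_replicates + 1):
        f_unp = hill(ca, spec.ec50_unp_um, spec.n_h, spec.f_min, spec.f_max)
        f_p = hill(ca, ec50_p, spec.n_h, spec.f_min, spec.f_max)
        if spec.noise_sd > 0:
            f_unp = f_unp + rng.normal(0, spec.noise_sd, ca.size)
            f_p = f_p + rng.normal(0, spec.noise_sd, ca.size)
        rid = f"r{r}"
        pairs.append(
            (
                ActivationCurve(ca, f_p, phospho_state="P", replicate_id=rid),
                ActivationCurve(ca, f_unp, phospho_state="unP", replicate_id=rid),
            )
        )
    manifest = {
        "kind": "activation_curves",
        "ec50_unp_um": spec.ec50_unp_um,
        "ec50_p_um": ec50_p,
        "ratio": spec.ratio,
        "n_h": spec.n_h,
        "f_min": spec.f_min,
        "f_max": spec.f_max,
        "noise_sd": spec.noise_sd,
        "ca_um": ca.tolist(),
        "n_replicates": spec.n_replicates,
        "seed": spec.seed,
    }
    return pairs, manifest


def curves_to_dataframe(pairs, condition: str = "", ligand: str = ""):
    """Long-form table (condition, ligand, phospho_state, replicate_id, ca_um, fraction_motile)."""
    import pandas as pd

    rows = []
    for p_curve, u_curve in pairs:
        for curve in (p_curve, u_curve):
            for c, f in zip(curve.ca_um, curve.fraction_motile):
                rows.append(
                    {
                        "condition": condition,
                        "ligand": ligand,
                        "phospho_state": curve.phospho_state,
                        "replicate_id": curve.replicate_id,
                        "ca_um": c,
                        "fraction_motile": f,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contraction transients

def _raised_cosine_rise(s: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(s, 0.0, 1.0)))


def solve_beat_template(ttp90_s: float, ttb90_s: float, period_s: float = 1.0) -> tuple[float, float]:
    """Rise/decay durations of a raised-cosine beat with the given timings.

    The analyser measures ttp90 from the 10%-amplitude onset crossing to
    the 90% crossing on the rise, and ttb90 from the peak to the 90%
    recovery crossing; the crossing times of the unit template are
    solved numerically and scaled so the measured intervals equal the
    requested values.
    """
    from scipy.optimize import brentq

    s10 = brentq(lambda s: _raised_cosine_rise(np.array([s]))[0] - 0.1, 0.0, 1.0)
    s90 = brentq(lambda s: _raised_cosine_rise(np.array([s]))[0] - 0.9, 0.0, 1.0)
    t_rise = ttp90_s / (s90 - s10)
    # decay mirrors the rise: 90% recovery at the same fractional time
    t_decay = ttb90_s / s90
    if t_rise + t_decay >= period_s:
        raise ValueError(
            f"infeasible beat: rise {t_rise:.3f} s + decay {t_decay:.3f} s "
            f">= stimulus period {period_s} s"
        )
    return t_rise, t_decay


@dataclass(frozen=True)
class TransientSpec:
    """Planted parameters of 10 s / 1 Hz cell-shortening records."""

    l0_um: float = 120.0
    amplitude_pct: float = 8.0
    ttp90_s: float = 0.15
    ttb90_s: float = 0.45
    n_cells: int = 40
    duration_s: float = 10.0
    stimulus_rate_hz: float = 1.0
    sampling_hz: float = 250.0
    noise_sd_um: float = 0.10      # ~1% of the shortening depth at the defaults
    drift_um: float = 0.05         # slow sinusoidal baseline drift amplitude
    cell_cv: float = 0.05          # cell-to-cell lognormal-ish spread of parameters
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("l0_um", "amplitude_pct", "ttp90_s", "ttb90_s", "duration_s",
                     "stimulus_rate_hz", "sampling_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        solve_beat_template(self.ttp90_s, self.ttb90_s, 1.0 / self.stimulus_rate_hz)


def _jitter(rng: np.random.Generator, cv: float) -> float:
    # truncated at 2 sigma so timing jitter cannot make a beat infeasible
    return 1.0 + float(np.clip(rng.normal(0, cv), -2 * cv, 2 * cv))


def _make_trace(
    spec: TransientSpec,
    rng: np.random.Generator,
    cell_id: str,
    treatment: str,
    l0: float,
    amp_pct: float,
    ttp90: float,
    ttb90: float,
) -> TransientTrace:
    period = 1.0 / spec.stimulus_rate_hz
    t_rise, t_decay = solve_beat_template(ttp90, ttb90, period)
    dt = 1.0 / spec.sampling_hz
    t = np.arange(0.0, spec.duration_s, dt)
    depth = l0 * amp_pct / 100.0
    onset_offset = 0.1 * period            # baseline before each beat
    phase = (t + period - onset_offset) % period   # 0 at each beat onset
    deficit = np.zeros_like(t)
    rise = phase < t_rise
    deficit[rise] = _raised_cosine_rise(phase[rise] / t_rise)
    fall = (phase >= t_rise) & (phase < t_rise + t_decay)
    deficit[fall] = 0.5 * (1.0 + np.cos(np.pi * (phase[fall] - t_rise) / t_decay))
    length = l0 - depth * deficit
    length = length + spec.drift_um * np.sin(2 * np.pi * t / spec.duration_s)
    if spec.noise_sd_um > 0:
        length = length + rng.normal(0.0, spec.noise_sd_um, t.size)
    return TransientTrace(t, length, spec.stimulus_rate_hz, cell_id=cell_id, treatment=treatment)


def gen_transients(spec: TransientSpec, treatment: str = "baseline") -> tuple[list[TransientTrace], dict]:
    """Per-cell shortening traces with cell-to-cell parameter spread."""
    rng = np.random.default_rng(spec.seed)
    traces, cells = [], {}
    for i in range(1, spec.n_cells + 1):
        cid = f"cell{i:03d}"
        l0 = spec.l0_um * _jitter(rng, spec.cell_cv)
        amp = spec.amplitude_pct * _jitter(rng, spec.cell_cv)
        ttp = spec.ttp90_s * _jitter(rng, spec.cell_cv)
        ttb = spec.ttb90_s * _jitter(rng, spec.cell_cv)
        traces.append(_make_trace(spec, rng, cid, treatment, l0, amp, ttp, ttb))
        cells[cid] = {"l0_um": l0, "amplitude_pct": amp, "ttp90_s": ttp, "ttb90_s": ttb}
    manifest = {"kind": "transients", "treatment": treatment,
                "spec": asdict(spec), "cells": cells}
    return traces, manifest


def gen_paired_transients(
    spec: TransientSpec,
    lusitropy: float = 0.21,
    lusitropy_sd: float = 0.02,
    inotropy: float = 0.0,
) -> tuple[list[TransientTrace], list[TransientTrace], dict]:
    """Paired baseline/dobutamine records for the same cells.

    Each cell's dobutamine ttb90 is its baseline ttb90 scaled by
    (1 - lusitropy_i) with per-cell lusitropy ~ N(lusitropy,
    lusitropy_sd); ``inotropy`` is the fractional amplitude increase.
    """
    rng = np.random.default_rng(spec.seed)
    pre_traces, post_traces = [], []
    cells = {}
    for i in range(1, spec.n_cells + 1):
        cid = f"cell{i:03d}"
        l0 = spec.l0_um * _jitter(rng, spec.cell_cv)
        amp = spec.amplitude_pct * _jitter(rng, spec.cell_cv)
        ttp = spec.ttp90_s * _jitter(rng, spec.cell_cv)
        ttb = spec.ttb90_s * _jitter(rng, spec.cell_cv)
        lus_i = rng.normal(lusitropy, lusitropy_sd)
        ttb_post = ttb * (1.0 - lus_i)
        amp_post = amp * (1.0 + inotropy)
        pre_traces.append(_make_trace(spec, rng, cid, "baseline", l0, amp, ttp, ttb))
        post_traces.append(_make_trace(spec, rng, cid, "dobutamine", l0, amp_post, ttp, ttb_post))
        cells[cid] = {
            "l0_um": l0, "amplitude_pct": amp, "ttp90_s": ttp,
            "ttb90_s_pre": ttb, "ttb90_s_dob": ttb_post, "lusitropy": lus_i,
        }
    manifest = {
        "kind": "paired_transients",
        "spec": asdict(spec),
        "lusitropy": lusitropy,
        "lusitropy_sd": lusitropy_sd,
        "inotropy": inotropy,
        "cells": cells,
    }
    return pre_traces, post_traces, manifest


def transients_to_dataframe(traces: Sequence[TransientTrace]):
    """Long-form table (cell_id, treatment, time_s, length_um)."""
    import pandas as pd

    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "treatment": tr.treatment,
                    "time_s": tr.time_s,
                    "length_um": tr.cell_length,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
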