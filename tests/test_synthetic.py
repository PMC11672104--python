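"""Ground-truth guarantees of the synthetic generators."""

import json

import numpy as np
import pytest

from tncoupling.contacts import attachment, contact_profile
from tncoupling.geometry import (
    ab_angle_series,
    hinge_angle_series,
    interdomain_distance_series,
    pair_bond_occupancy,
)
from tncoupling.io import load_topology, load_trajectory, resolve
from tncoupling.synthetic import (
    GaussianMixture1D,
    LigandSpec,
    TrajectorySpec,
    gen_trajectory,
    solve_beat_template,
)


class TestScaffold:
    def test_region_specs_resolve_on_scaffold(self, wt_bundle):
        topo, regions = wt_bundle.topology, wt_bundle.regions
        assert len(resolve(regions["helix_a"], topo)) == 15
        assert len(resolve(regions["helix_b"], topo)) == 11
        assert len(resolve(regions["nc_lobe"], topo)) == 85
        assert len(resolve(regions["itc_domain"], topo)) == 69
        assert len(resolve(regions["pivot"], topo)) == 1

    def test_wild_type_has_no_carboxylate(self, wt_bundle):
        names = {a.name for a in wt_bundle.topology.atoms if a.residue_number == 159}
        assert names == {"CA"}

    def test_mutant_carries_carboxylate_and_ligand(self, g159d_bundle):
        topo = g159d_bundle.topology
        names = {a.name for a in topo.atoms if a.residue_number == 159 and a.chain_id == "C"}
        assert {"OD1", "OD2"} <= names
        assert any(a.chain_id == "L" and a.is_hetero for a in topo.atoms)


class TestPlantedAngles:
    def test_per_frame_angles_exact(self, wt_bundle):
        """Re-measured angles equal the manifest ground truth to 1e-6 degrees."""
        topo, regions = wt_bundle.topology, wt_bundle.regions
        for traj in wt_bundle.runs:
            truth = wt_bundle.manifest["runs"][traj.run_id]
            ab = ab_angle_series(traj, topo, regions["helix_a"], regions["helix_b"]).values
            hinge = hinge_angle_series(
                traj, topo, regions["nc_lobe"], regions["itc_domain"], regions["pivot"]
            ).values
            dist = interdomain_distance_series(
                traj, topo, regions["nc_lobe"], regions["itc_domain"]
            ).values
            np.testing.assert_allclose(ab, truth["ab_angle_deg"], atol=1e-6)
            np.testing.assert_allclose(hinge, truth["hinge_angle_deg"], atol=1e-6)
            np.testing.assert_allclose(dist, truth["interdomain_distance_a"], atol=1e-6)

    def test_sample_mean_within_sampling_error(self):
        """Mean of recovered A/B angles is within 3*sigma/sqrt(n) of the target."""
        spec = TrajectorySpec(n_frames=3750, n_runs=1, seed=1)
        bundle = gen_trajectory(spec)
        traj = bundle.runs[0]
        ab = ab_angle_series(traj, bundle.topology, bundle.regions["helix_a"],
                             bundle.regions["helix_b"]).values
        assert abs(ab.mean() - 101.81) < 3 * 9.15 / np.sqrt(3750)

    def test_mixture_distribution_supported(self):
        mix = GaussianMixture1D(means=(95.0, 120.0), stds=(4.0, 4.0), weights=(0.5, 0.5))
        spec = TrajectorySpec(n_frames=2000, n_runs=1, ab_angle=mix, seed=3)
        bundle = gen_trajectory(spec)
        ab = ab_angle_series(bundle.runs[0], bundle.topology, bundle.regions["helix_a"],
                             bundle.regions["helix_b"]).values
        assert abs(ab.mean() - 107.5) < 1.0
        # bimodal: both component neighbourhoods populated
        assert (np.abs(ab - 95) < 8).mean() > 0.3 and (np.abs(ab - 120) < 8).mean() > 0.3


class TestPlantedOccupancies:
    def test_saltbridge_occupancy_recovered(self, g159d_bundle):
        topo, regions = g159d_bundle.topology, g159d_bundle.regions
        for traj in g159d_bundle.runs:
            truth = g159d_bundle.manifest["runs"][traj.run_id]
            occ, series = pair_bond_occupancy(
                traj, topo, regions["asp159_carboxylate"], regions["arg83_guanidinium"]
            )
            assert occ == pytest.approx(np.mean(truth["saltbridge_bound"]), abs=0)
            np.testing.assert_array_equal(series.bound, np.array(truth["saltbridge_bound"], bool))

    def test_ligand_bound_state_recovered_exactly(self, g159d_bundle):
        topo, regions = g159d_bundle.topology, g159d_bundle.regions
        for traj in g159d_bundle.runs:
            truth = g159d_bundle.manifest["runs"][traj.run_id]
            summ = attachment(traj, topo, regions["ligand"], regions["protein"])
            assert summ.fraction_attached == pytest.approx(np.mean(truth["ligand_bound"]), abs=0)

    def test_contact_profile_matches_bound_fraction(self, g159d_bundle):
        """The single-site ligand contacts exactly its target residue when bound."""
        topo, regions = g159d_bundle.topology, g159d_bundle.regions
        traj = g159d_bundle.runs[0]
        truth = g159d_bundle.manifest["runs"][traj.run_id]
        prof = contact_profile(traj, topo, regions["ligand"])
        target = ("C", 28)
        assert prof.probabilities[target] == pytest.approx(np.mean(truth["ligand_bound"]), abs=0)
        others = {k: v for k, v in prof.probabilities.items() if k != target}
        assert max(others.values()) == 0.0

    def test_markov_bound_fraction_converges(self):
        """Stationary bound fraction approaches p_on/(p_on+p_off) as frames grow."""
        lig = LigandSpec.for_bound_fraction(0.95, mean_episode_frames=50)
        errs = {}
        for nf in (3750, 37500):
            spec = TrajectorySpec(n_frames=nf, n_runs=1, variant="G159D", ligand=lig, seed=21)
            bundle = gen_trajectory(spec)
            frac = np.mean(bundle.manifest["runs"]["run1"]["ligand_bound"])
            errs[nf] = abs(frac - 0.95)
        assert errs[3750] < 0.03
        assert errs[37500] < 0.01


class TestDeterminismAndRoundTrip:
    def test_same_seed_identical_coordinates(self):
        a = gen_trajectory(TrajectorySpec(n_frames=40, n_runs=2, seed=9))
        b = gen_trajectory(TrajectorySpec(n_frames=40, n_runs=2, seed=9))
        for ta, tb in zip(a.runs, b.runs):
            np.testing.assert_array_equal(ta.coordinates, tb.coordinates)

    def test_bundle_reloads_losslessly(self, tmp_path, g159d_bundle):
        paths = g159d_bundle.write(str(tmp_path), trajectory_format="pdb")
        topo = load_topology(paths["topology"])
        assert topo.n_atoms == g159d_bundle.topology.n_atoms
        with open(paths["manifest"]) as fh:
            manifest = json.load(fh)
        assert manifest["spec"]["variant"] == "G159D"
        traj = load_trajectory(paths["run1"], topo)
        np.testing.assert_allclose(
            traj.coordinates, g159d_bundle.runs[0].coordinates, atol=5.1e-4
        )


class TestBeatTemplate:
    def test_solved_crossings_match_requested_times(self):
        t_rise, t_decay = solve_beat_template(0.15, 0.45, 1.0)
        # on the raised-cosine rise, 10% and 90% crossings sit at acos-solved fractions
        s10 = np.arccos(1 - 0.2) / np.pi
        s90 = np.arccos(1 - 1.8) / np.pi
        assert t_rise * (s90 - s10) == pytest.approx(0.15, abs=1e-9)
        assert t_decay * s90 == pytest.approx(0.45, abs=1e-9)

    def test_infeasible_combination_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            solve_beat_template(0.4, 0.55, 1.0)


class TestSpecValidation:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TrajectorySpec(n_frames=0)
        with pytest.raises(ValueError):
            TrajectorySpec(saltbridge_occupancy=1.2)
        with pytest.raises(ValueError):
            GaussianMixture1D(means=(1.0, 2.0), stds=(1.0,))
        with pytest.raises(ValueError):
            GaussianMixture1D(means=(1.0,), stds=(0.0,))
        with pytest.raises(ValueError):
            LigandSpec(p_on=0.0)
        with pytest.raises(ValueError):
            LigandSpec.for_bound_fraction(1.5)
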