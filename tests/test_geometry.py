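import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from aptadyn import (
    FixtureSpec,
    Trajectory,
    detect_contacts,
    kabsch,
    make_hairpin_system,
    pair_rmsd,
    rmsd_profile,
    rmsf,
    simulate_trajectory,
    superpose,
)
from aptadyn.geometry import align_on_rigid_core, distance_fluctuation_score
from aptadyn.errors import DegenerateInputError, GeometryError


def brute_force_rmsd(mobile, ref, n_starts=80, rng=None):
    """Rotation-search oracle: coarse random starts + local refinement."""
    rng = rng or np.random.default_rng(0)
    P = mobile - mobile.mean(axis=0)
    Q = ref - ref.mean(axis=0)

    def objective(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((P @ R.T - Q) ** 2).sum() / len(P))

    starts = Rotation.random(n_starts, random_state=rng).as_rotvec()
    starts = np.vstack([starts, np.zeros(3)])
    best = min(objective(s) for s in starts)
    best_starts = sorted(starts, key=objective)[:5]
    for s in best_starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestSuperposition:
    def test_identical_frames_rmsd_zero(self, rng):
        x = rng.normal(size=(10, 3))
        assert kabsch(x, x).rmsd <= 1e-10

    def test_rigid_motion_invariance(self, rng):
        x = rng.normal(size=(12, 3)) * 5
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        moved = x @ R.T + np.array([1.0, -2.0, 3.0])
        assert kabsch(moved, x).rmsd <= 1e-9

    def test_rotation_is_proper(self, rng):
        a, b = rng.normal(size=(2, 8, 3))
        res = kabsch(a, b)
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-9

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=(10, 3)) * 3
            b = a + rng.normal(size=(10, 3)) * 0.5
            assert abs(pair_rmsd(a, b) - brute_force_rmsd(a, b, rng=rng)) < 1e-6

    def test_symmetry_in_arguments(self, rng):
        a, b = rng.normal(size=(2, 9, 3))
        assert pair_rmsd(a, b) == pytest.approx(pair_rmsd(b, a), abs=1e-9)

    def test_collinear_atoms_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            kabsch(line, line)

    def test_too_few_atoms_rejected(self, rng):
        x = rng.normal(size=(2, 3))
        with pytest.raises(GeometryError):
            kabsch(x, x)

    def test_transform_applied_to_all_atoms(self, default_system, default_traj):
        topo = default_system.topology
        aligned, series = superpose(default_traj, 0, "backbone", topo)
        assert aligned.n_atoms == default_traj.n_atoms
        assert series[0] <= 1e-10
        assert np.all(series >= 0)


class TestRmsdProfile:
    def test_all_mask_consistent_with_superpose(self, default_system, default_traj):
        topo = default_system.topology
        _, series = superpose(default_traj, 0, "all", topo)
        prof = rmsd_profile(default_traj, 0, ["all"], topo)
        assert np.allclose(prof["all"], series)

    def test_segment_local_fit_separates_rigid_from_floppy(self, default_system, default_traj):
        topo = default_system.topology
        gt = default_system.ground_truth
        stem_lo, stem_hi = min(gt["stem_residues"]), max(gt["stem_residues"])
        tail_lo, tail_hi = min(gt["tail_residues"]), max(gt["tail_residues"])
        prof = rmsd_profile(
            default_traj, 0,
            [f"res {stem_lo}-{stem_hi} backbone", f"res {tail_lo}-{tail_hi} backbone"],
            topo,
        )
        core = prof[f"res {stem_lo}-{stem_hi} backbone"]
        tail = prof[f"res {tail_lo}-{tail_hi} backbone"]
        # segment-local fit: the core keeps its internal conformation while
        # the tail's internal jitter is an order of magnitude larger
        assert np.median(core[1:]) < np.median(tail[1:])
        assert np.median(core[1:]) < 1.0

    def test_empty_mask_list(self, default_system, default_traj):
        assert rmsd_profile(default_traj, 0, [], default_system.topology) == {}


class TestRmsf:
    def test_constant_trajectory_all_zero(self, default_system):
        traj = Trajectory(np.repeat(default_system.reference[None], 4, axis=0))
        vals = rmsf(traj, default_system.topology, "heavy")
        assert max(vals.values()) <= 1e-12

    def test_isotropic_jitter_gives_sigma_root3(self, default_system, rng):
        sigma = 0.5
        base = default_system.reference
        coords = np.repeat(base[None], 5000, axis=0)
        coords += rng.normal(0, sigma, coords.shape)
        vals = rmsf(Trajectory(coords), default_system.topology, "heavy")
        mean_rmsf = np.mean(list(vals.values()))
        assert mean_rmsf == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_single_frame_is_degenerate(self, default_system):
        traj = Trajectory(default_system.reference[None])
        with pytest.raises(DegenerateInputError):
            rmsf(traj, default_system.topology, "heavy")

    @pytest.mark.parametrize("seed", [0, 7, 23])
    def test_planted_floppy_tail_exceeds_stem_every_seed(self, default_system, seed):
        spec = FixtureSpec(n_frames=80, seed=seed)
        traj = simulate_trajectory(default_system, spec)
        _, _, rmsf_map = align_on_rigid_core(traj, default_system.topology)
        gt = default_system.ground_truth
        stem = max(rmsf_map[r] for r in gt["stem_residues"])
        tail = max(rmsf_map[r] for r in gt["tail_residues"])
        assert tail > stem

    def test_distance_fluctuation_ranks_core_below_tail(self, default_system, default_traj):
        score = distance_fluctuation_score(default_traj, default_system.topology)
        gt = default_system.ground_truth
        assert max(score[r] for r in gt["stem_residues"]) < min(
            score[r] for r in gt["tail_residues"]
        )


class TestContacts:
    def test_ideal_gc_pair_gives_three_canonical_hbonds(self, quiet_system_traj):
        system, traj = quiet_system_traj
        recs = detect_contacts(traj, system.topology, "hbond")
        pair = [r for r in recs if (r.i, r.j) == (1, 12)]
        assert len(pair) == 3
        for r in pair:
            assert 2.8 <= r.mean_distance <= 3.0
            assert r.abundance == 100.0
            assert r.canonical

    def test_planted_pairs_recovered_as_canonical_basepairs(self, quiet_system_traj):
        system, traj = quiet_system_traj
        recs = detect_contacts(traj, system.topology, "basepair")
        found = {(r.i, r.j) for r in recs if r.canonical}
        assert found >= {tuple(p) for p in system.ground_truth["pairs"]}

    def test_distant_residues_make_no_records(self, quiet_system_traj):
        system, traj = quiet_system_traj
        recs = detect_contacts(traj, system.topology, "hbond")
        tail = set(system.ground_truth["tail_residues"])
        stem = set(system.ground_truth["stem_residues"])
        assert not any(
            (r.i in tail and r.j in stem) or (r.i in stem and r.j in tail)
            for r in recs
        )

    def test_abundance_is_exact_frame_count(self):
        spec = FixtureSpec(
            n_frames=1000, sigma_stem=0.01, sigma_tail=0.01, tail_reorient_deg=0.2,
            planted_contact_fraction=0.9, seed=4,
        )
        system = make_hairpin_system(spec)
        traj = simulate_trajectory(system, spec)
        recs = detect_contacts(traj, system.topology, "basepair")
        broken = [r for r in recs if (r.i, r.j) == (1, 12)]
        assert len(broken) == 1
        assert broken[0].abundance == pytest.approx(90.0, abs=1e-12)

    def test_duplicating_frames_preserves_abundance(self, quiet_system_traj):
        system, traj = quiet_system_traj
        doubled = Trajectory(np.repeat(traj.coordinates, 2, axis=0))
        a = {(r.i, r.j, r.atoms): r.abundance
             for r in detect_contacts(traj, system.topology, "hbond")}
        b = {(r.i, r.j, r.atoms): r.abundance
             for r in detect_contacts(doubled, system.topology, "hbond")}
        assert a == b

    def test_stem_stacking_detected_consecutively(self, quiet_system_traj):
        system, traj = quiet_system_traj
        recs = detect_contacts(traj, system.topology, "stack")
        got = {(r.i, r.j) for r in recs}
        # consecutive bases in both stem strands stack; loop/tail do not
        stem = sorted(system.ground_truth["stem_residues"])
        expected = {(1, 2), (2, 3), (3, 4), (9, 10), (10, 11), (11, 12)}
        assert expected <= got
        loop = set(system.ground_truth["loop_residues"])
        assert not any(r.i in loop or r.j in loop for r in recs)
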