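import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from aptadyn import (
    FixtureSpec,
    endpoint_average,
    gb_polar,
    make_hairpin_system,
    mm_pair_energy,
    sasa,
    sasa_nonpolar,
)
from aptadyn.energy import COULOMB_CONSTANT
from aptadyn.io import Atom, Topology


def ion(atom_id, q=1.0, radius=2.0, residue=1, sigma=0.0, eps=0.0):
    return Atom(atom_id, f"X{atom_id}", "C", residue, q, sigma, eps, radius, 0.8)


def born_energy(q, radius, eps_in=1.0, eps_out=78.5):
    return -0.5 * (1 / eps_in - 1 / eps_out) * COULOMB_CONSTANT * q**2 / radius


class TestPairEnergies:
    def test_unit_charges_at_reference_distance(self):
        topo = Topology(atoms=[ion(1), ion(2, residue=2)], bonds=[])
        _, e_elec = mm_pair_energy(topo, np.array([[0, 0, 0], [3.320637, 0, 0.0]]))
        assert e_elec == pytest.approx(100.0, abs=1e-9)

    def test_lj_minimum_is_minus_epsilon(self):
        sigma, eps = 3.0, 0.35
        topo = Topology(
            atoms=[ion(1, q=0.0, sigma=sigma, eps=eps),
                   ion(2, q=0.0, sigma=sigma, eps=eps, residue=2)],
            bonds=[],
        )
        r = 2 ** (1 / 6) * sigma
        e_vdw, _ = mm_pair_energy(topo, np.array([[0, 0, 0], [r, 0, 0.0]]))
        assert e_vdw == pytest.approx(-eps, abs=1e-12)

    def test_single_atom_is_zero(self):
        topo = Topology(atoms=[ion(1)], bonds=[])
        assert mm_pair_energy(topo, np.zeros((1, 3))) == (0.0, 0.0)

    def test_bonded_and_one_three_pairs_excluded(self):
        atoms = [ion(i, q=1.0, sigma=3.0, eps=0.2, residue=1) for i in (1, 2, 3)]
        topo = Topology(atoms=atoms, bonds=[(1, 2), (2, 3)])
        x = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0.0]])
        e_vdw, e_elec = mm_pair_energy(topo, x)
        assert e_vdw == 0.0 and e_elec == 0.0

    def test_one_four_scaling(self):
        atoms = [ion(i, q=1.0, sigma=0.0, eps=0.0) for i in (1, 2, 3, 4)]
        topo = Topology(atoms=atoms, bonds=[(1, 2), (2, 3), (3, 4)])
        x = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        _, e_elec = mm_pair_energy(topo, x)
        # only the 1-4 pair (atoms 1,4 at 3 Å) survives, scaled by 1/1.2
        assert e_elec == pytest.approx(COULOMB_CONSTANT / 3.0 / 1.2, abs=1e-9)


class TestGeneralizedBorn:
    def test_single_ion_matches_born_closed_form(self):
        topo = Topology(atoms=[ion(1)], bonds=[])
        got = gb_polar(topo, np.zeros((1, 3)))
        assert got == pytest.approx(born_energy(1.0, 2.0), rel=1e-9)

    def test_uncharged_system_is_zero(self):
        topo = Topology(
            atoms=[ion(1, q=0.0), ion(2, q=0.0, residue=2)], bonds=[]
        )
        assert gb_polar(topo, np.array([[0, 0, 0], [4.0, 0, 0]])) == 0.0

    def test_far_separated_ions_approach_born_sum(self):
        topo = Topology(atoms=[ion(1), ion(2, residue=2)], bonds=[])
        # the screened cross term decays like 1/r: at 5000 Å it is below
        # 0.1% of the Born self-energy sum
        got = gb_polar(topo, np.array([[0, 0, 0], [5000.0, 0, 0]]))
        expected = 2 * born_energy(1.0, 2.0)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_descreening_deepens_solvation_of_buried_charge(self):
        # a neighbor displaces dielectric: effective radius grows, |G| shrinks
        topo = Topology(atoms=[ion(1), ion(2, q=0.0, residue=2)], bonds=[])
        close = gb_polar(topo, np.array([[0, 0, 0], [3.0, 0, 0]]))
        assert close > born_energy(1.0, 2.0)  # less negative


class TestSasa:
    def test_isolated_sphere_analytic(self):
        topo = Topology(atoms=[ion(1, radius=2.0)], bonds=[])
        got = sasa(topo, np.zeros((1, 3)), probe=1.4, n_points=960)[0]
        assert got == pytest.approx(4 * np.pi * 3.4**2, rel=0.01)

    def test_buried_atom_contributes_nothing(self):
        topo = Topology(
            atoms=[ion(1, radius=1.0), ion(2, radius=8.0, residue=2)], bonds=[]
        )
        areas = sasa(topo, np.zeros((2, 3)), probe=1.4)
        assert areas[0] == 0.0

    def test_two_overlapping_spheres_match_lens_formula(self):
        r = 2.0
        d = 2.5
        topo = Topology(atoms=[ion(1, radius=r), ion(2, radius=r, residue=2)], bonds=[])
        got = sasa(topo, np.array([[0, 0, 0], [d, 0, 0.0]]), probe=1.4, n_points=2000)
        R = r + 1.4
        # each sphere loses a cap of height h = R - d/2
        cap = 2 * np.pi * R * (R - d / 2)
        expected = 4 * np.pi * R**2 - cap
        assert got[0] == pytest.approx(expected, rel=0.01)
        assert got[1] == pytest.approx(expected, rel=0.01)

    def test_nonpolar_term_is_gamma_sasa_plus_b(self):
        topo = Topology(atoms=[ion(1, radius=2.0)], bonds=[])
        area = sasa(topo, np.zeros((1, 3)))[0]
        val = sasa_nonpolar(topo, np.zeros((1, 3)), gamma=0.005, b=0.9)
        assert val == pytest.approx(0.005 * area + 0.9, abs=1e-12)


class TestRigidMotionInvariance:
    def test_all_components_invariant(self, hairpin_only_system):
        topo = hairpin_only_system.topology
        x = hairpin_only_system.reference
        R = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = x @ R.T + np.array([10.0, -3.0, 7.0])
        for func in (
            lambda f: mm_pair_energy(topo, f)[0],
            lambda f: mm_pair_energy(topo, f)[1],
            lambda f: gb_polar(topo, f),
        ):
            assert func(moved) == pytest.approx(func(x), abs=1e-9)
        # quadrature SASA is grid-orientation dependent at finite n_points,
        # so allow the quadrature error instead of 1e-9
        a0 = sasa_nonpolar(topo, x, n_points=960)
        a1 = sasa_nonpolar(topo, moved, n_points=960)
        assert a1 == pytest.approx(a0, rel=0.01)


class TestEndpointAverage:
    def test_constant_series(self):
        mean, sem = endpoint_average(np.full(100, 3.5), 0.5)
        assert (mean, sem) == (3.5, 0.0)

    def test_alternating_series_block_formula(self):
        series = np.tile([1.0, -1.0], 500)
        mean, sem = endpoint_average(series, 1.0, n_blocks=5)
        assert mean == 0.0
        # every block of 200 frames averages exactly 0
        assert sem == 0.0

    def test_full_window_equals_plain_mean(self, rng):
        series = rng.normal(size=400)
        mean, _ = endpoint_average(series, 1.0)
        assert mean == pytest.approx(series.mean())

    def test_time_range_window(self, rng):
        series = np.arange(10.0)
        times = np.arange(10.0) * 0.1
        mean, _ = endpoint_average(series, (0.5, 0.9), times=times)
        assert mean == pytest.approx(np.mean([5, 6, 7, 8, 9]))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            endpoint_average(np.arange(10.0), (100.0, 200.0), times=np.arange(10.0))


class TestModelRankingContract:
    def test_planted_contacts_win_sign_test(self, hairpin_only_system):
        """A conformer keeping its planted base pairs scores below the same
        topology with the 3' half swung away, in at least 9 of 10 seeds."""
        system = hairpin_only_system
        topo, ref = system.topology, system.reference
        loop = set(system.ground_truth["loop_residues"])
        half = loop | {
            r for r in system.ground_truth["stem_residues"] if r > max(loop)
        }
        ha = np.array([k for k, a in enumerate(topo.atoms) if a.residue_index in half])
        unfolded = ref.copy()
        pivot = ref[ha].mean(axis=0)
        unfolded[ha] = (
            Rotation.from_rotvec([1.2, 0, 0]).apply(unfolded[ha] - pivot)
            + pivot + np.array([0.0, 18.0, 6.0])
        )
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            totals = []
            for conf in (ref, unfolded):
                vals = []
                for _ in range(3):
                    x = conf + rng.normal(0, 0.05, conf.shape)
                    e_vdw, e_elec = mm_pair_energy(topo, x)
                    vals.append(
                        e_vdw + e_elec + gb_polar(topo, x)
                        + sasa_nonpolar(topo, x, n_points=240)
                    )
                totals.append(np.mean(vals))
            wins += totals[0] < totals[1]
        assert wins >= 9
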