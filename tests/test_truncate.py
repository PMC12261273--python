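import numpy as np
import pytest

from aptadyn import (
    FixtureSpec,
    compare_variants,
    detect_contacts,
    essentiality_map,
    make_hairpin_system,
    mobility_profile,
    propose_truncations,
    simulate_trajectory,
)
from aptadyn.geometry import ContactRecord
from aptadyn.errors import AlignmentError
from aptadyn.truncate import TruncationReport


def contact(i, j, abundance, kind="basepair"):
    return ContactRecord(
        kind=kind, i=i, j=j, atoms="x-y", mean_distance=2.9,
        mean_angle=0.0, abundance=abundance,
    )


def report_for(n, mobility=None, essential=None, variant="v"):
    return TruncationReport(
        variant=variant, n_residues=n,
        mobility=np.asarray(mobility if mobility is not None else np.zeros(n), float),
        essential=np.asarray(essential if essential is not None else np.zeros(n, bool)),
        kept=[(1, n)], removed=[],
    )


class TestMobilityProfile:
    def test_constant_profile_maps_to_half(self):
        scores = mobility_profile(np.full(10, 1.7))
        assert np.allclose(scores, 0.5)

    def test_small_spread_stays_near_zero(self):
        # an all-rigid profile (sub-floor range) must not be stretched
        rmsf = np.array([0.30, 0.35, 0.32, 0.34, 0.31])
        assert mobility_profile(rmsf).max() <= 0.1

    def test_rigid_stem_floppy_tail_ordering(self):
        rmsf = np.array([0.3, 0.3, 0.3, 4.0, 8.0])
        inter = np.array([0.2, 0.2, 0.3, 3.0, 9.0])
        scores = mobility_profile(rmsf, inter)
        assert scores[:3].max() < scores[3:].min()
        assert scores.max() <= 1.0 and scores.min() >= 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mobility_profile(np.zeros(5), np.zeros(6))


class TestEssentialityMap:
    def test_empty_contacts_flag_nothing(self):
        assert not essentiality_map([], 12).any()

    def test_planted_stem_pairs_flag_both_partners(self):
        contacts = [contact(2, 11, 100.0), contact(3, 10, 100.0), contact(4, 9, 100.0)]
        flags = essentiality_map(contacts, 12)
        assert set(np.where(flags)[0] + 1) == {2, 3, 4, 9, 10, 11}

    def test_low_abundance_ignored(self):
        assert not essentiality_map([contact(2, 11, 40.0)], 12, 50.0).any()

    def test_stacking_excluded_by_default_but_optional(self):
        stacks = [contact(5, 6, 95.0, kind="stack")]
        assert not essentiality_map(stacks, 8).any()
        assert essentiality_map(stacks, 8, include_stacking=True).any()

    def test_raising_threshold_grows_removable_set(self):
        contacts = [contact(1, 8, 60.0), contact(2, 7, 90.0)]
        low = essentiality_map(contacts, 8, abundance_threshold=50.0)
        high = essentiality_map(contacts, 8, abundance_threshold=80.0)
        assert set(np.where(high)[0]) <= set(np.where(low)[0])


class TestProposeTruncations:
    def test_floppy_3prime_tail_removed(self):
        essential = np.array([True] * 12 + [False] * 10)
        mobility = np.concatenate([np.full(12, 0.05), np.full(10, 0.9)])
        rep = propose_truncations(mobility, essential, min_length=8)
        assert rep.removed_residues() == set(range(13, 23))
        assert rep.kept == [(1, 12)]

    def test_floppy_5prime_tail_removed(self):
        essential = np.array([False] * 6 + [True] * 14)
        mobility = np.concatenate([np.full(6, 0.8), np.full(14, 0.1)])
        rep = propose_truncations(mobility, essential, min_length=8)
        assert rep.removed_residues() == set(range(1, 7))
        assert rep.removed[0]["end_label"] == "5p"

    def test_fully_essential_molecule_yields_empty_report(self):
        essential = np.ones(15, bool)
        rep = propose_truncations(np.full(15, 0.9), essential)
        assert rep.removed == []
        assert rep.reason == "no non-essential terminal segment"

    def test_low_mobility_terminus_not_removed(self):
        essential = np.zeros(20, bool)
        essential[5:15] = True
        mobility = np.full(20, 0.1)
        rep = propose_truncations(mobility, essential)
        assert rep.removed == []
        assert "mobility" in rep.reason

    def test_never_removes_essential_residue(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(16, 40))
            essential = rng.random(n) < 0.4
            mobility = rng.random(n)
            rep = propose_truncations(mobility, essential, min_length=10)
            assert not any(essential[r - 1] for r in rep.removed_residues())

    def test_min_length_respected(self):
        essential = np.zeros(20, bool)
        mobility = np.ones(20)
        rep = propose_truncations(mobility, essential, min_length=15)
        kept = rep.kept[0][1] - rep.kept[0][0] + 1
        assert kept >= 15

    def test_report_is_byte_deterministic(self):
        essential = np.array([True] * 10 + [False] * 8)
        mobility = np.concatenate([np.full(10, 0.1), np.full(8, 0.8)])
        a = propose_truncations(mobility, essential, min_length=5).to_json()
        b = propose_truncations(mobility, essential, min_length=5).to_json()
        assert a == b

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fixture_evidence_end_to_end(self, default_system, seed):
        spec = FixtureSpec(n_frames=120, seed=seed)
        traj = simulate_trajectory(default_system, spec)
        from aptadyn.cli import _truncation_report

        rep = _truncation_report(default_system.topology, traj, 8, 0.5, 50.0,
                                 epsilon=5.5)
        removed = rep.removed_residues()
        tail = set(default_system.ground_truth["tail_residues"])
        stem = set(default_system.ground_truth["stem_residues"])
        assert len(removed & tail) >= 8
        assert not removed & stem


class TestCompareVariants:
    def _spacer_pair_systems(self, seed=0):
        # variant A: 4-bp stem + T4 loop + 3-nt A tail at the 3' end
        spec_a = FixtureSpec(n_stem=4, n_loop=4, n_tail=3, tail_end="3p",
                            tail_base="A", n_frames=60, seed=seed)
        sys_a = make_hairpin_system(spec_a)
        # variant B: A plus a 5-T spacer at the 5' end whose last 3 Ts pair
        # with those As, enlarging the stem to 7 bp
        spec_b = FixtureSpec(n_stem=7, n_loop=4, n_tail=2, tail_end="5p",
                            tail_base="T", stem_seq="TTTGCGC", n_frames=60, seed=seed)
        sys_b = make_hairpin_system(spec_b)
        return (spec_a, sys_a), (spec_b, sys_b)

    def test_structure_altering_spacer_lists_exactly_planted_pairs(self):
        (spec_a, sys_a), (spec_b, sys_b) = self._spacer_pair_systems()
        assert sys_b.sequence.residues[:5] == "TTTTT"
        assert sys_b.sequence.residues[5:] == sys_a.sequence.residues
        contacts_a = detect_contacts(
            simulate_trajectory(sys_a, spec_a), sys_a.topology, "basepair"
        )
        contacts_b = detect_contacts(
            simulate_trajectory(sys_b, spec_b), sys_b.topology, "basepair"
        )
        cmp = compare_variants(
            report_for(15, variant="A"), contacts_a,
            report_for(20, variant="B"), contacts_b,
            spacer_end="5p",
        )
        assert cmp.classification == "structure-altering"
        assert cmp.spacer_core_pairs == [(3, 20), (4, 19), (5, 18)]

    def test_inert_spacer(self):
        spec_a = FixtureSpec(n_stem=4, n_loop=4, n_tail=0, n_frames=40, seed=1)
        sys_a = make_hairpin_system(spec_a)
        spec_b = FixtureSpec(n_stem=4, n_loop=4, n_tail=5, tail_end="5p",
                            tail_base="T", n_frames=40, seed=1)
        sys_b = make_hairpin_system(spec_b)
        ca = detect_contacts(simulate_trajectory(sys_a, spec_a), sys_a.topology, "basepair")
        cb = detect_contacts(simulate_trajectory(sys_b, spec_b), sys_b.topology, "basepair")
        cmp = compare_variants(report_for(12), ca, report_for(17), cb, "5p")
        assert cmp.classification == "inert spacer"
        assert cmp.spacer_core_pairs == []
        assert cmp.gained == [] and cmp.lost == []

    def test_identical_variants_empty_diff(self):
        contacts = [contact(2, 11, 100.0)]
        cmp = compare_variants(report_for(12), contacts, report_for(12), contacts)
        assert cmp.gained == [] and cmp.lost == [] and cmp.spacer_core_pairs == []

    def test_unmappable_variants_rejected(self):
        with pytest.raises(AlignmentError):
            compare_variants(report_for(12), [], report_for(10), [])
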