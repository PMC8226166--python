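"""Ideal chain geometry and scheduled-contact trajectory generation."""

from fractions import Fraction

import numpy as np
import pytest

from ptmdimer.contacts import (
    compute_contact_series,
    make_pair_key,
    mean_ncc,
    min_residue_distances,
)
from ptmdimer.persistence import build_interaction_map, count_intermolecular
from ptmdimer.ptm import parse_annotation
from ptmdimer.synthetic import (
    AssociationSchedule,
    Episode,
    InfeasibleScheduleError,
    build_ideal_chain,
    generate_dimer_trajectory,
    make_fixture_suite,
)


def ca_coords(frame):
    return np.array([a.xyz for a in frame.atoms if a.atom_name == "CA"])


class TestIdealChain:
    def test_virtual_ca_ca_bond(self, p0m0_spec):
        for conformation in ("helical", "extended"):
            ca = ca_coords(build_ideal_chain(p0m0_spec, conformation))
            steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            assert np.allclose(steps, 3.8, atol=0.1)

    def test_helix_pitch_geometry(self, p0m0_spec):
        ca = ca_coords(build_ideal_chain(p0m0_spec, "helical"))
        d4 = [np.linalg.norm(ca[i + 4] - ca[i]) for i in range(len(ca) - 4)]
        assert all(abs(d - 6.2) < 0.5 for d in d4)

    def test_helix_more_compact_than_extended(self, p0m0_spec):
        helical = ca_coords(build_ideal_chain(p0m0_spec, "helical"))
        extended = ca_coords(build_ideal_chain(p0m0_spec, "extended"))
        assert np.linalg.norm(helical[-1] - helical[0]) < np.linalg.norm(
            extended[-1] - extended[0]
        )

    def test_reduced_side_chain_atoms(self, p1m2_spec):
        frame = build_ideal_chain(p1m2_spec, "extended")
        by_res = {}
        for atom in frame.atoms:
            by_res.setdefault(atom.residue_index, []).append(atom)
        # Ala1: backbone + CB; Gly12: backbone only; others: + tip
        assert [a.atom_name for a in by_res[1]] == ["N", "CA", "C", "O", "CB"]
        assert [a.atom_name for a in by_res[12]] == ["N", "CA", "C", "O"]
        # phospho-Thr3 tip is a phosphorus, Arg8 tip a nitrogen
        assert by_res[3][-1].element == "P"
        assert by_res[8][-1].element == "N"
        # modified residues carry their conventional PDB names
        assert by_res[3][0].residue_name == "TPO"
        assert by_res[4][0].residue_name == "M3L"
        assert by_res[8][0].residue_name == "DA2"

    def test_unknown_conformation(self, p0m0_spec):
        with pytest.raises(ValueError, match="conformation"):
            build_ideal_chain(p0m0_spec, "coil")


class TestScheduleValidation:
    def test_non_integer_frame_count_rejected(self):
        with pytest.raises(ValueError, match="not an integer"):
            AssociationSchedule(
                episodes=(Episode(3, 8, Fraction(1, 3)),), n_frames=100
            )

    def test_separation_margin_enforced(self):
        with pytest.raises(ValueError, match="margin"):
            AssociationSchedule(
                episodes=(Episode(3, 8, Fraction(1, 2)),),
                n_frames=10,
                apart_distance=6.0,
                noise_sigma=0.5,
            )

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            AssociationSchedule(
                episodes=(
                    Episode(3, 8, Fraction(1, 4)),
                    Episode(3, 8, Fraction(1, 2)),
                ),
                n_frames=8,
            )

    def test_contact_distance_bound(self):
        with pytest.raises(ValueError, match="3.2"):
            Episode(1, 1, Fraction(1, 2), contact_distance=3.5)


class TestGenerator:
    def test_determinism_same_seed(self, p1m2_spec, p0m0_spec):
        schedule = AssociationSchedule(
            episodes=(Episode(3, 8, Fraction(1, 4)),), n_frames=8, seed=99
        )
        t1, _ = generate_dimer_trajectory(p1m2_spec, p0m0_spec, "helical", schedule)
        t2, _ = generate_dimer_trajectory(p1m2_spec, p0m0_spec, "helical", schedule)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.coords, f2.coords)

    def test_different_seed_differs(self, p1m2_spec, p0m0_spec):
        base = dict(episodes=(Episode(3, 8, Fraction(1, 4)),), n_frames=8)
        t1, _ = generate_dimer_trajectory(
            p1m2_spec, p0m0_spec, "helical", AssociationSchedule(**base, seed=1)
        )
        t2, _ = generate_dimer_trajectory(
            p1m2_spec, p0m0_spec, "helical", AssociationSchedule(**base, seed=2)
        )
        assert any(
            not np.array_equal(f1.coords, f2.coords)
            for f1, f2 in zip(t1.frames, t2.frames)
        )

    def test_chain_integrity_rigid_body_only(self, p1m2_spec, p0m0_spec):
        schedule = AssociationSchedule(
            episodes=(Episode(3, 8, Fraction(1, 2)),),
            n_frames=6,
            noise_sigma=0.0,
            seed=3,
        )
        traj, _ = generate_dimer_trajectory(p1m2_spec, p0m0_spec, "extended", schedule)
        idx_b = [i for i, a in enumerate(traj.frames[0].atoms) if a.chain_id == "B"]

        def internal_distances(frame):
            c = frame.coords[idx_b]
            return np.linalg.norm(c[:, None] - c[None, :], axis=2)

        ref = internal_distances(traj.frames[0])
        for frame in traj.frames[1:]:
            assert np.allclose(internal_distances(frame), ref, atol=1e-9)

    @pytest.mark.parametrize("conformation", ["helical", "extended"])
    def test_exact_schedule_recovery(self, p1m2_spec, p0m0_spec, conformation):
        schedule = AssociationSchedule(
            episodes=(
                Episode(3, 8, Fraction(64, 100)),
                Episode(2, 3, Fraction(19, 100)),
            ),
            n_frames=100,
            seed=21,
        )
        traj, truth = generate_dimer_trajectory(
            p1m2_spec, p0m0_spec, conformation, schedule
        )
        series = compute_contact_series(traj)
        for pair, expected in truth.scheduled_fractions.items():
            assert Fraction(series.frames_in_contact(pair), 100) == expected
        pmap = build_interaction_map(series, traj.topology)
        assert count_intermolecular(pmap) == truth.expected_intermolecular()

    def test_ground_truth_labels_match_series(self, small_dimer):
        traj, truth = small_dimer
        series = compute_contact_series(traj)
        for pair, labels in truth.frame_labels.items():
            assert np.array_equal(series.pair_incidence[pair], labels)

    def test_empty_schedule_keeps_chains_apart(self, apart_dimer):
        traj, truth = apart_dimer
        series = compute_contact_series(traj)
        assert mean_ncc(series) == 0.0
        assert truth.expected_intermolecular() == 0
        for frame in traj.frames[:3]:
            assert min(min_residue_distances(frame).values()) >= 18.0

    def test_single_contact_ncc_bounds(self, small_dimer):
        # one scheduled tip-tip contact: at least one atom pair close in
        # contact frames, none otherwise
        traj, truth = small_dimer
        series = compute_contact_series(traj)
        labels = next(iter(truth.frame_labels.values()))
        assert np.all(series.per_frame_ncc[labels] >= 1)
        assert np.all(series.per_frame_ncc[~labels] == 0)
        assert mean_ncc(series) >= float(
            sum(truth.scheduled_fractions.values())
        )

    def test_infeasible_simultaneous_docking_reported(self, p0m0_spec):
        # two overlapping episodes pinning opposite chain ends parallel:
        # every intermediate side chain would also touch
        schedule = AssociationSchedule(
            episodes=(
                Episode(2, 2, Fraction(9, 10)),
                Episode(11, 11, Fraction(9, 10)),
            ),
            n_frames=10,
            seed=5,
        )
        with pytest.raises(InfeasibleScheduleError) as err:
            generate_dimer_trajectory(p0m0_spec, p0m0_spec, "extended", schedule)
        assert err.value.episodes == (0, 1)

    def test_disjoint_assignment_requires_capacity(self, p0m0_spec):
        schedule = AssociationSchedule(
            episodes=(
                Episode(2, 2, Fraction(3, 4)),
                Episode(5, 9, Fraction(1, 2)),
            ),
            n_frames=8,
            assignment="disjoint",
        )
        with pytest.raises(InfeasibleScheduleError, match="sum"):
            generate_dimer_trajectory(p0m0_spec, p0m0_spec, "helical", schedule)


class TestFixtureSuite:
    def test_regeneration_is_deterministic(self, tmp_path):
        a = make_fixture_suite(tmp_path / "a", seed=77, n_frames=100)
        b = make_fixture_suite(tmp_path / "b", seed=77, n_frames=100)
        for name in a:
            assert (tmp_path / "a" / f"{name}.pdb").read_bytes() == (
                tmp_path / "b" / f"{name}.pdb"
            ).read_bytes()
        # at least the ladder, the two high-persistence dimers and a null run
        assert len(a) == 4
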