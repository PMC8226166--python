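"""Multi-model PDB reading/writing and trajectory views."""

import numpy as np
import pytest

from conftest import make_atom, two_chain_frame
from ptmdimer.trajectory import (
    ChainCountError,
    Frame,
    PDBFormatError,
    RosterMismatchError,
    Trajectory,
    chain_view,
    heavy_atom_view,
    infer_element,
    read_multimodel_pdb,
    read_topology,
    write_multimodel_pdb,
    write_topology,
)


def _small_traj(n_frames=3, n_per_chain=10, jitter=0.0):
    rng = np.random.default_rng(0)
    frames = []
    for f in range(n_frames):
        base_a = np.arange(n_per_chain)[:, None] * [1.5, 0, 0]
        base_b = base_a + [0, 8, 0]
        if jitter:
            base_a = base_a + rng.normal(0, jitter, base_a.shape)
            base_b = base_b + rng.normal(0, jitter, base_b.shape)
        frame = two_chain_frame(base_a, base_b)
        frames.append(Frame(atoms=frame.atoms, frame_index=f))
    return Trajectory(frames=tuple(frames), chain_ids=("A", "B"))


class TestReadWrite:
    def test_roundtrip_preserves_roster_and_coords(self, tmp_path):
        traj = _small_traj(n_frames=3, jitter=2.0)
        path = tmp_path / "t.pdb"
        write_multimodel_pdb(traj, path)
        again = read_multimodel_pdb(path)
        assert len(again) == 3
        assert again.n_atoms == traj.n_atoms
        for f1, f2 in zip(traj.frames, again.frames):
            assert [a.atom_name for a in f1.atoms] == [a.atom_name for a in f2.atoms]
            assert [a.chain_id for a in f1.atoms] == [a.chain_id for a in f2.atoms]
            assert [a.residue_index for a in f1.atoms] == [
                a.residue_index for a in f2.atoms
            ]
            # PDB stores %8.3f -> half-ULP 5e-4 per coordinate
            assert np.abs(f1.coords - f2.coords).max() < 1e-3

    def test_model_count_matches_frames(self, tmp_path):
        traj = _small_traj(n_frames=80)
        path = tmp_path / "t80.pdb"
        write_multimodel_pdb(traj, path)
        text = path.read_text()
        assert text.count("MODEL ") == 80
        assert text.count("ENDMDL") == 80
        assert len(read_multimodel_pdb(path)) == 80

    def test_single_atom_file_layout(self, tmp_path):
        frame = Frame(atoms=(make_atom("CA", "C", (1, 2, 3)),))
        # bypass the two-chain Trajectory invariant: write manually
        path = tmp_path / "one.pdb"
        from ptmdimer.trajectory import _atom_line, _ter_line

        with open(path, "w") as fh:
            fh.write("MODEL        1\n")
            fh.write(_atom_line(1, frame.atoms[0]))
            fh.write(_ter_line(2, frame.atoms[0]))
            fh.write("ENDMDL\n")
        lines = path.read_text().splitlines()
        assert [l[:3] for l in lines] == ["MOD", "ATO", "TER", "END"]
        assert "   1.000   2.000   3.000" in lines[1]

    def test_roster_mismatch_names_missing_atom(self, tmp_path):
        traj = _small_traj(n_frames=2)
        path = tmp_path / "bad.pdb"
        write_multimodel_pdb(traj, path)
        lines = path.read_text().splitlines(keepends=True)
        # drop one ATOM line from MODEL 2
        second_model = [i for i, l in enumerate(lines) if l.startswith("MODEL")][1]
        atom_idx = next(
            i for i, l in enumerate(lines[second_model:], second_model)
            if l.startswith("ATOM") and " C3 " in l
        )
        del lines[atom_idx]
        path.write_text("".join(lines))
        with pytest.raises(RosterMismatchError, match="C3"):
            read_multimodel_pdb(path)

    def test_wrong_chain_count_rejected(self, tmp_path):
        frame = two_chain_frame([(0, 0, 0)], [(5, 0, 0)])
        only_a = Frame(atoms=tuple(a for a in frame.atoms if a.chain_id == "A"))
        path = tmp_path / "one_chain.pdb"
        from ptmdimer.trajectory import _atom_line

        with open(path, "w") as fh:
            fh.write("MODEL        1\n")
            for i, a in enumerate(only_a.atoms, 1):
                fh.write(_atom_line(i, a))
            fh.write("ENDMDL\n")
        with pytest.raises(ChainCountError, match="found 1"):
            read_multimodel_pdb(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(PDBFormatError, match="no models"):
            read_multimodel_pdb(path)

    def test_solvent_and_ions_dropped(self, tmp_path):
        traj = _small_traj(n_frames=1)
        path = tmp_path / "solv.pdb"
        write_multimodel_pdb(traj, path)
        lines = path.read_text().splitlines(keepends=True)
        water = (
            "HETATM  999  O   HOH W 501      10.000  10.000  10.000"
            "  1.00  0.00           O\n"
        )
        lines.insert(1, water)
        path.write_text("".join(lines))
        again = read_multimodel_pdb(path)
        assert again.n_atoms == traj.n_atoms

    def test_element_inference_fallback(self):
        assert infer_element(" CA ") == "C"
        assert infer_element("NT") == "N"
        assert infer_element("PT") == "P"
        assert infer_element("1HB") == "H"
        assert infer_element("OXT") == "O"


class TestViews:
    def test_heavy_atom_view_removes_hydrogens(self):
        atoms = tuple(
            [make_atom(f"C{i}", "C", (i, 0, 0), chain="A") for i in range(5)]
            + [make_atom(f"H{i}", "H", (i, 1, 0), chain="A") for i in range(3)]
            + [make_atom("CB", "C", (0, 9, 0), chain="B")]
        )
        traj = Trajectory(
            frames=(Frame(atoms=atoms),), chain_ids=("A", "B")
        )
        heavy = heavy_atom_view(traj)
        assert heavy.n_atoms == 6
        assert len(heavy.frames) == len(traj.frames)

    def test_heavy_atom_view_idempotent(self):
        traj = _small_traj(n_frames=2)
        once = heavy_atom_view(traj)
        twice = heavy_atom_view(once)
        assert once == twice

    def test_chain_view_partitions_frame(self):
        frame = two_chain_frame(np.zeros((10, 3)), np.ones((10, 3)))
        a = chain_view(frame, "A")
        b = chain_view(frame, "B")
        assert len(a) == 10 and len(b) == 10
        assert len(a) + len(b) == len(frame)
        assert all(at.chain_id == "A" for at in a.atoms)

    def test_chain_view_unknown_chain(self):
        frame = two_chain_frame([(0, 0, 0)], [(5, 0, 0)])
        with pytest.raises(KeyError, match="'C'"):
            chain_view(frame, "C")

    def test_heavy_view_commutes_with_chain_view(self):
        atoms = tuple(
            [
                make_atom("CA", "C", (0, 0, 0), chain="A"),
                make_atom("HA", "H", (0, 1, 0), chain="A"),
                make_atom("CB", "C", (9, 0, 0), chain="B"),
                make_atom("HB", "H", (9, 1, 0), chain="B"),
            ]
        )
        traj = Trajectory(frames=(Frame(atoms=atoms),), chain_ids=("A", "B"))
        heavy_then_chain = chain_view(heavy_atom_view(traj).frames[0], "A")
        chain_then_heavy = tuple(
            a for a in chain_view(traj.frames[0], "A").atoms if a.element != "H"
        )
        assert heavy_then_chain.atoms == chain_then_heavy


class TestTopologySidecar:
    def test_roundtrip(self, tmp_path, p1m2_spec, p0m0_spec):
        path = tmp_path / "topo.yaml"
        write_topology({"A": p1m2_spec, "B": p0m0_spec}, path)
        topo = read_topology(path)
        assert topo == {"A": p1m2_spec, "B": p0m0_spec}

    def test_malformed_sidecar(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("not_chains: {}\n")
        with pytest.raises(PDBFormatError, match="chains"):
            read_topology(path)
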