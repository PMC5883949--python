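import math

import numpy as np
import pytest

from mdcontacts.trajectory_io import (AtomClass, Frame, TopologyParseError,
                                      TrajectoryError, Topology, iter_frames,
                                      load_restriction, load_topology,
                                      select_atoms, write_multi_model_pdb,
                                      write_pdb, write_plain_trajectory)
from mdcontacts.synthetic_fixtures import topology_from_centers

ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       3.000   0.000   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       4.000   0.000   0.000  1.00  0.00           C
ATOM      6  HB1 ALA A   1       5.000   0.000   0.000  1.00  0.00           H
ATOM      7  N   GLY A   2       6.000   0.000   0.000  1.00  0.00           N
ATOM      8  CA  GLY A   2       7.000   0.000   0.000  1.00  0.00           C
ATOM      9  C   GLY A   2       8.000   0.000   0.000  1.00  0.00           C
ATOM     10  O   GLY A   2       9.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def ala_gly(tmp_path):
    p = tmp_path / "ala_gly.pdb"
    p.write_text(ALA_PDB)
    return load_topology(p)


class TestLoadTopology:
    def test_toy_pdb(self, ala_gly):
        assert ala_gly.n_residues == 2
        assert ala_gly.n_atoms == 10
        assert ala_gly.residues[0] == ("A", 1, "ALA")
        assert ala_gly.elements[5] == "H"
        assert list(ala_gly.atom_residue) == [0] * 6 + [1] * 4

    def test_multi_chain_order(self, tmp_path):
        lines = []
        serial = 1
        for chain, n in (("A", 3), ("B", 2)):
            for r in range(1, n + 1):
                lines.append(f"ATOM  {serial:5d}  CA  ALA {chain}{r:4d}    "
                             f"{1.0:8.3f}{2.0:8.3f}{3.0:8.3f}  1.00  0.00           C")
                serial += 1
        p = tmp_path / "chains.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        top = load_topology(p)
        assert [r[0] for r in top.residues] == ["A", "A", "A", "B", "B"]
        assert [r[1] for r in top.residues] == [1, 2, 3, 1, 2]

    def test_hetatm_water_is_own_residue(self, tmp_path):
        text = ALA_PDB.replace(
            "END\n",
            "HETATM   11  O   HOH A 100      10.000   0.000   0.000  1.00  0.00           O\nEND\n")
        p = tmp_path / "wat.pdb"
        p.write_text(text)
        top = load_topology(p)
        assert top.n_residues == 3
        assert top.residues[2] == ("A", 100, "HOH")

    def test_insertion_code_rejected(self, tmp_path):
        bad = ALA_PDB.replace("ALA A   1 ", "ALA A   1A")
        p = tmp_path / "icode.pdb"
        p.write_text(bad)
        with pytest.raises(TopologyParseError, match="insertion"):
            load_topology(p)

    def test_malformed_record_names_line(self, tmp_path):
        bad = ALA_PDB.replace("       2.000", "       x.000")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(TopologyParseError, match=r":3:"):
            load_topology(p)

    def test_empty_input(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(TopologyParseError, match="no atoms"):
            load_topology(p)

    def test_altloc_b_dropped(self, tmp_path):
        text = ALA_PDB.replace("  CA  ALA", "  CA BALA", 1)
        p = tmp_path / "altloc.pdb"
        p.write_text(text)
        top = load_topology(p)
        assert top.n_atoms == 9  # the B-altloc CA is dropped

    def test_gro_dialect(self, tmp_path):
        gro = ("toy\n 4\n"
               "    1ALA     N    1   0.100   0.200   0.300\n"
               "    1ALA    CA    2   0.200   0.200   0.300\n"
               "    2GLY     N    3   0.900   0.200   0.300\n"
               "    2GLY    CA    4   1.000   0.200   0.300\n"
               "   2.0   2.0   2.0\n")
        p = tmp_path / "toy.gro"
        p.write_text(gro)
        top = load_topology(p)
        assert top.n_residues == 2
        assert top.atom_names[1] == "CA"
        assert top.residues[1] == ("", 2, "GLY")

    def test_angstrom_to_nm_conversion(self, tmp_path, ala_gly):
        # CA of residue 0 sits at 1 A = 0.1 nm; re-read the coordinates
        # through the multi-model reader to check the conversion
        p = tmp_path / "one.pdb"
        p.write_text(ALA_PDB)
        frame = next(iter_frames(p, ala_gly))
        assert frame.coords[1, 0] == pytest.approx(0.1, abs=1e-9)


class TestSelectAtoms:
    @pytest.mark.parametrize("mode,expected", [
        (AtomClass.HEAVY, ["N", "CA", "C", "O", "CB"]),
        (AtomClass.C_ALPHA, ["CA"]),
        (AtomClass.BACKBONE, ["N", "CA", "C", "O"]),
        (AtomClass.SIDE_CHAIN, ["CB"]),
        (AtomClass.ALL, ["N", "CA", "C", "O", "CB", "HB1"]),
    ])
    def test_alanine_classes(self, ala_gly, mode, expected):
        sel = select_atoms(ala_gly, mode)
        names = [ala_gly.atom_names[a] for a in sel.groups[0]]
        assert names == expected

    def test_glycine_side_chain_inert(self, ala_gly):
        sel = select_atoms(ala_gly, "side_chain")
        assert len(sel.groups[1]) == 0
        assert sel.inert[1]

    def test_partition_backbone_side_chain(self, ala_gly):
        """backbone ∪ side_chain == heavy and the two are disjoint."""
        for r in range(ala_gly.n_residues):
            bb = set(select_atoms(ala_gly, "backbone").groups[r])
            sc = set(select_atoms(ala_gly, "side_chain").groups[r])
            heavy = set(select_atoms(ala_gly, "heavy").groups[r])
            assert bb | sc == heavy
            assert bb & sc == set()

    def test_restriction(self, ala_gly, tmp_path):
        p = tmp_path / "restrict.txt"
        p.write_text("2\n")
        sel = select_atoms(ala_gly, "heavy", restrict=load_restriction(p))
        assert len(sel.groups[0]) == 0 and len(sel.groups[1]) == 4


class TestIterFrames:
    @pytest.fixture
    def plain_traj(self, tmp_path):
        top = topology_from_centers(2, 2)
        rng = np.random.default_rng(0)
        frames = [rng.normal(size=(top.n_atoms, 3)) for _ in range(10)]
        p = tmp_path / "traj.dat"
        write_plain_trajectory(p, [2.0 * i for i in range(10)], frames)
        return top, p, frames

    def test_all_frames(self, plain_traj):
        top, p, _ = plain_traj
        out = list(iter_frames(p, top))
        assert len(out) == 10
        assert [f.time for f in out] == [2.0 * i for i in range(10)]

    def test_stride(self, plain_traj):
        top, p, _ = plain_traj
        out = list(iter_frames(p, top, stride=3))
        assert [f.index for f in out] == [0, 3, 6, 9]

    def test_begin_at_fifth_frame_time(self, plain_traj):
        top, p, _ = plain_traj
        out = list(iter_frames(p, top, begin=8.0))  # 5th stored frame's time
        assert len(out) == 6

    @pytest.mark.parametrize("stride", [1, 2, 3, 4, 7])
    def test_count_under_stride(self, plain_traj, stride):
        top, p, _ = plain_traj
        n = len(list(iter_frames(p, top, stride=stride)))
        assert n == math.ceil(10 / stride)

    def test_roundtrip_precision(self, plain_traj):
        top, p, frames = plain_traj
        for f, orig in zip(iter_frames(p, top), frames):
            assert np.abs(f.coords - orig).max() < 5e-7  # 6 printed decimals

    def test_atom_count_mismatch(self, plain_traj, tmp_path):
        _, p, _ = plain_traj
        big = topology_from_centers(3, 2)
        with pytest.raises(TrajectoryError):
            list(iter_frames(p, big))

    def test_atom_count_mismatch_pdb(self, tmp_path):
        top = topology_from_centers(2, 2)
        frames = [np.zeros((4, 3))]
        p = tmp_path / "multi.pdb"
        write_multi_model_pdb(p, top, frames)
        big = topology_from_centers(3, 2)
        with pytest.raises(TrajectoryError, match="topology has 6"):
            list(iter_frames(p, big))

    def test_multi_model_pdb_times_from_dt(self, tmp_path):
        top = topology_from_centers(2, 2)
        frames = [np.full((4, 3), 0.1 * i) for i in range(3)]
        p = tmp_path / "traj.pdb"
        write_multi_model_pdb(p, top, frames)
        out = list(iter_frames(p, top, dt=5.0))
        assert [f.time for f in out] == [0.0, 5.0, 10.0]
        assert np.abs(out[2].coords - 0.2).max() < 1e-3  # 3 printed decimals (A)

    def test_non_increasing_times_rejected(self, tmp_path):
        top = topology_from_centers(1, 1)
        p = tmp_path / "bad.dat"
        p.write_text("t 1.0\n0 0 0\nt 1.0\n0 0 0\n")
        with pytest.raises(TrajectoryError, match="strictly increasing"):
            list(iter_frames(p, top))

    def test_truncated_frame_names_index(self, tmp_path):
        top = topology_from_centers(1, 2)
        p = tmp_path / "trunc.dat"
        p.write_text("t 0.0\n0 0 0\n0 0 1\nt 1.0\n0 0 0\n")
        with pytest.raises(TrajectoryError, match="frame 1"):
            list(iter_frames(p, top))


def test_mdanalysis_agrees_on_multimodel_pdb(tmp_path):
    """Independent reader check: MDAnalysis sees the same coordinates."""
    mda = pytest.importorskip("MDAnalysis")
    top = topology_from_centers(3, 2)
    rng = np.random.default_rng(5)
    frames = [np.abs(rng.normal(1.0, 0.3, size=(top.n_atoms, 3))) for _ in range(4)]
    p = tmp_path / "multi.pdb"
    write_multi_model_pdb(p, top, frames)
    ours = [f.coords for f in iter_frames(p, top)]
    u = mda.Universe(str(p))
    theirs = [u.atoms.positions / 10.0 for _ in u.trajectory]
    assert len(ours) == len(theirs) == 4
    for a, b in zip(ours, theirs):
        assert np.abs(a - b).max() < 1e-3
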