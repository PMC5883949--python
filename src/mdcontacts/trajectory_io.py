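"""Topology and trajectory input.

Reads PDB and GRO topologies, streams multi-frame coordinates from
multi-model PDB files, a plain whitespace frame format, or (optionally,
via MDAnalysis) binary XTC/TRR/DCD trajectories, and resolves atom-class
selections into per-residue atom groups.

Units: coordinates are nanometres internally.  PDB files (Angstrom) are
converted on read; GRO files are already in nm.

Distances computed downstream are plain Euclidean distances: trajectories
are expected to be pre-processed so that molecules are whole (no
minimum-image handling is applied).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyParseError",
    "TrajectoryError",
    "ResidueKey",
    "Topology",
    "AtomClass",
    "SelectionMap",
    "Frame",
    "load_topology",
    "select_atoms",
    "load_restriction",
    "iter_frames",
    "write_pdb",
    "write_multi_model_pdb",
    "write_plain_trajectory",
]

#: names of protein backbone heavy atoms
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class TopologyParseError(ValueError):
    """Raised when a topology file cannot be parsed."""


class TrajectoryError(ValueError):
    """Raised for trajectory-level problems (atom-count mismatch, bad frame)."""


#: (chain_id, residue_seq, residue_name)
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class Topology:
    """Atoms grouped into residues, in file order.

    Attributes
    ----------
    atom_names, elements : per-atom name and element symbol.
    atom_residue : per-atom 0-based residue index.
    residues : ordered list of (chain_id, residue_seq, residue_name).
    """

    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    atom_residue: np.ndarray
    residues: tuple[ResidueKey, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_atoms(self, res_index: int) -> np.ndarray:
        """Indices of the atoms belonging to residue ``res_index``."""
        return np.flatnonzero(self.atom_residue == res_index)


class AtomClass(str, Enum):
    """Which atoms of each residue enter the distance search."""

    C_ALPHA = "c_alpha"
    BACKBONE = "backbone"
    SIDE_CHAIN = "side_chain"
    HEAVY = "heavy"
    ALL = "all"


@dataclass(frozen=True)
class SelectionMap:
    """Per-residue ordered atom-index groups for a given atom class.

    Residues with zero selected atoms are *inert*: they participate in no
    residue pair (e.g. glycine under ``side_chain``).
    """

    groups: tuple[np.ndarray, ...]

    @property
    def n_residues(self) -> int:
        return len(self.groups)

    @property
    def inert(self) -> np.ndarray:
        return np.array([len(g) == 0 for g in self.groups], dtype=bool)

    @property
    def flat_indices(self) -> np.ndarray:
        """All selected atom indices, concatenated in residue order."""
        if not self.groups:
            return np.empty(0, dtype=np.intp)
        return np.concatenate([g for g in self.groups]).astype(np.intp) \
            if any(len(g) for g in self.groups) else np.empty(0, dtype=np.intp)

    @property
    def flat_residue_labels(self) -> np.ndarray:
        """Residue index for each entry of :attr:`flat_indices`."""
        labels = [np.full(len(g), i, dtype=np.intp) for i, g in enumerate(self.groups)]
        if not labels:
            return np.empty(0, dtype=np.intp)
        return np.concatenate(labels) if sum(len(v) for v in labels) else np.empty(0, dtype=np.intp)


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: 0-based storage index, time in ps, (n_atoms, 3) nm."""

    index: int
    time: float
    coords: np.ndarray


def _infer_element(atom_name: str) -> str:
    """Guess the element from a PDB/GRO atom name.

    Leading digits are stripped (``1HB`` is a hydrogen); the first remaining
    alphabetic character is taken.  Two-letter elements (Cl, Na, ...) are not
    resolved by this heuristic; provide explicit element columns for those.
    """
    s = atom_name.strip().lstrip("0123456789")
    return s[0].upper() if s else ""


def _finish_topology(names, elements, res_of_atom, residues, path):
    if not names:
        raise TopologyParseError(f"{path}: no atoms found (empty input)")
    return Topology(
        atom_names=tuple(names),
        elements=tuple(elements),
        atom_residue=np.asarray(res_of_atom, dtype=np.intp),
        residues=tuple(residues),
    )


def _parse_pdb_atoms(lines: Iterable[tuple[int, str]], path, collect_coords=False):
    """Shared fixed-column ATOM/HETATM parser.

    Yields per-atom records (name, element, residue key, xyz in nm) while
    applying the altloc policy (keep ' ' and 'A', drop others with a warning)
    and rejecting insertion codes.
    """
    warned_altloc = False
    for lineno, line in lines:
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise TopologyParseError(f"{path}:{lineno}: truncated {rec.strip()} record")
        altloc = line[16]
        if altloc not in (" ", "A"):
            if not warned_altloc:
                logger.warning("%s:%d: dropping alternate-location atoms (altloc %r)",
                               path, lineno, altloc)
                warned_altloc = True
            continue
        icode = line[26]
        if icode != " ":
            raise TopologyParseError(
                f"{path}:{lineno}: insertion codes are unsupported (found {icode!r})")
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        try:
            resseq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise TopologyParseError(f"{path}:{lineno}: malformed numeric field: {exc}") from None
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(name)
        yield name, element.upper(), (chain, resseq, resname), (x / 10.0, y / 10.0, z / 10.0)


def _load_topology_pdb(path: Path) -> Topology:
    names: list[str] = []
    elements: list[str] = []
    res_of_atom: list[int] = []
    residues: list[ResidueKey] = []
    with open(path) as fh:
        numbered = []
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec in ("ENDMDL",):
                break  # topology is the first model
            numbered.append((lineno, line))
    for name, element, key, _xyz in _parse_pdb_atoms(numbered, path):
        if not residues or residues[-1] != key:
            if key in residues[:-1]:
                raise TopologyParseError(
                    f"{path}: residue {key} appears in two non-contiguous blocks")
            residues.append(key)
        names.append(name)
        elements.append(element)
        res_of_atom.append(len(residues) - 1)
    return _finish_topology(names, elements, res_of_atom, residues, path)


def _load_topology_gro(path: Path) -> Topology:
    names: list[str] = []
    elements: list[str] = []
    res_of_atom: list[int] = []
    residues: list[ResidueKey] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 2:
        raise TopologyParseError(f"{path}: truncated GRO file")
    try:
        n_atoms = int(lines[1].split()[0])
    except (ValueError, IndexError):
        raise TopologyParseError(f"{path}:2: expected atom count") from None
    if n_atoms == 0:
        raise TopologyParseError(f"{path}: no atoms found (empty input)")
    for k in range(n_atoms):
        lineno = 3 + k
        if lineno - 1 >= len(lines):
            raise TopologyParseError(f"{path}:{lineno}: missing atom record")
        line = lines[lineno - 1]
        try:
            resseq = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
        except ValueError as exc:
            raise TopologyParseError(f"{path}:{lineno}: malformed GRO record: {exc}") from None
        key: ResidueKey = ("", resseq, resname)
        if not residues or residues[-1] != key:
            residues.append(key)
        names.append(name)
        elements.append(_infer_element(name))
        res_of_atom.append(len(residues) - 1)
    return _finish_topology(names, elements, res_of_atom, residues, path)


def load_topology(path: str | Path, dialect: str | None = None) -> Topology:
    """Read a topology from a PDB or GRO file.

    Parameters
    ----------
    path : file path.
    dialect : ``"pdb"`` or ``"gro"``; inferred from the suffix when omitted.

    Multi-chain files yield one global residue list, chains concatenated in
    file order.  HETATM records (e.g. waters) become their own residues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "gro" if path.suffix.lower() == ".gro" else "pdb"
    if dialect == "pdb":
        return _load_topology_pdb(path)
    if dialect == "gro":
        return _load_topology_gro(path)
    raise ValueError(f"unknown topology dialect {dialect!r}")


def select_atoms(
    topology: Topology,
    atom_class: AtomClass | str,
    restrict: Sequence[int] | None = None,
) -> SelectionMap:
    """Resolve an atom class into per-residue atom-index groups.

    ``restrict`` optionally limits the analysis to the given 0-based residue
    indices; all other residues become inert.  Residues with no matching atom
    (glycine under ``side_chain``) are inert and logged.
    """
    atom_class = AtomClass(atom_class)
    names = np.array(topology.atom_names)
    elements = np.array(topology.elements)
    heavy = elements != "H"
    if atom_class is AtomClass.ALL:
        mask = np.ones(topology.n_atoms, dtype=bool)
    elif atom_class is AtomClass.HEAVY:
        mask = heavy
    elif atom_class is AtomClass.C_ALPHA:
        mask = names == "CA"
    elif atom_class is AtomClass.BACKBONE:
        mask = np.isin(names, list(BACKBONE_NAMES)) & heavy
    elif atom_class is AtomClass.SIDE_CHAIN:
        mask = heavy & ~np.isin(names, list(BACKBONE_NAMES))
    else:  # pragma: no cover
        raise ValueError(atom_class)
    allowed = None if restrict is None else set(int(r) for r in restrict)
    groups = []
    for r in range(topology.n_residues):
        if allowed is not None and r not in allowed:
            groups.append(np.empty(0, dtype=np.intp))
            continue
        idx = np.flatnonzero((topology.atom_residue == r) & mask)
        if len(idx) == 0:
            logger.info("residue %d %s is inert under atom class %s",
                        r, topology.residues[r], atom_class.value)
        groups.append(idx.astype(np.intp))
    return SelectionMap(groups=tuple(groups))


def load_restriction(path: str | Path) -> list[int]:
    """Read a residue restriction file: one 1-based residue index per line."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            try:
                v = int(line)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected a residue index") from None
            if v < 1:
                raise ValueError(f"{path}:{lineno}: residue indices are 1-based")
            out.append(v - 1)
    return out


# ---------------------------------------------------------------------------
# frame streaming
# ---------------------------------------------------------------------------

def _iter_plain(path: Path, n_atoms: int) -> Iterator[tuple[float | None, np.ndarray]]:
    """Plain frame format: ``t <time_ps>`` then one ``x y z`` (nm) line per atom."""
    with open(path) as fh:
        frame_idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            if not header.strip():
                continue
            parts = header.split()
            if len(parts) != 2 or parts[0] != "t":
                raise TrajectoryError(
                    f"{path}: frame {frame_idx}: expected 't <time_ps>' header, got {header!r}")
            try:
                t = float(parts[1])
            except ValueError:
                raise TrajectoryError(f"{path}: frame {frame_idx}: bad time {parts[1]!r}") from None
            coords = np.empty((n_atoms, 3), dtype=np.float64)
            for a in range(n_atoms):
                line = fh.readline()
                if not line:
                    raise TrajectoryError(
                        f"{path}: frame {frame_idx}: truncated after {a} of {n_atoms} atoms")
                vals = line.split()
                if len(vals) != 3:
                    raise TrajectoryError(
                        f"{path}: frame {frame_idx}: expected 3 coordinates, got {line!r}")
                coords[a] = [float(v) for v in vals]
            yield t, coords
            frame_idx += 1


def _iter_pdb_models(path: Path, n_atoms: int) -> Iterator[tuple[float | None, np.ndarray]]:
    """Multi-model PDB (MODEL/ENDMDL blocks); times are synthesized by the caller."""
    block: list[tuple[int, str]] = []
    saw_model = False
    frame_idx = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                block = []
            elif rec.startswith("ENDMDL") or line.strip() == "END":
                if block:
                    yield None, _coords_from_pdb_block(block, path, n_atoms, frame_idx)
                    frame_idx += 1
                block = []
            elif rec in ("ATOM  ", "HETATM"):
                block.append((lineno, line))
    if block:
        # file without trailing ENDMDL/END, or a single-model file
        yield None, _coords_from_pdb_block(block, path, n_atoms, frame_idx)
    elif not saw_model and frame_idx == 0:
        raise TrajectoryError(f"{path}: no coordinate frames found")


def _coords_from_pdb_block(block, path, n_atoms, frame_idx):
    xyz = [c for *_n, c in _parse_pdb_atoms(block, path)]
    if len(xyz) != n_atoms:
        raise TrajectoryError(
            f"{path}: frame {frame_idx}: {len(xyz)} atoms, topology has {n_atoms}")
    return np.asarray(xyz, dtype=np.float64)


def _iter_mdanalysis(path: Path, topology: Topology):
    """Binary trajectory adapter (XTC/TRR/DCD) behind the same frame contract."""
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise TrajectoryError(
            f"reading {path.suffix} trajectories requires MDAnalysis") from exc
    n = topology.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.load_new(str(path))
    for ts in u.trajectory:
        yield float(ts.time), np.asarray(ts.positions, dtype=np.float64) / 10.0


def iter_frames(
    traj_path: str | Path,
    topology: Topology,
    begin: float = 0.0,
    end: float = math.inf,
    stride: int = 1,
    dt: float = 1.0,
) -> Iterator[Frame]:
    """Stream frames with times in ``[begin, end]``, taking every ``stride``-th
    selected frame.

    Times come from the trajectory when present (plain format, binary
    formats); multi-model PDB frames carry no time and get
    ``frame_index * dt``.  Times must be strictly increasing.
    """
    traj_path = Path(traj_path)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if begin > end:
        raise ValueError("begin must be <= end")
    suffix = traj_path.suffix.lower()
    if suffix in (".xtc", ".trr", ".dcd"):
        raw = _iter_mdanalysis(traj_path, topology)
    elif suffix == ".pdb":
        raw = _iter_pdb_models(traj_path, topology.n_atoms)
    else:
        raw = _iter_plain(traj_path, topology.n_atoms)
    prev_time = -math.inf
    n_selected = 0
    for index, (t, coords) in enumerate(raw):
        if t is None:
            t = index * dt
        if coords.shape != (topology.n_atoms, 3):
            raise TrajectoryError(
                f"{traj_path}: frame {index}: coordinate count {coords.shape[0]} "
                f"!= topology atom count {topology.n_atoms}")
        if t <= prev_time:
            raise TrajectoryError(
                f"{traj_path}: frame {index}: times not strictly increasing "
                f"({t} after {prev_time})")
        prev_time = t
        if t < begin or t > end:
            continue
        if n_selected % stride == 0:
            yield Frame(index=index, time=t, coords=coords)
        n_selected += 1


# ---------------------------------------------------------------------------
# writers (used by the synthetic-fixture generator and tests)
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial, name, resname, chain, resseq, xyz_nm, element):
    x, y, z = (10.0 * v for v in xyz_nm)  # nm -> Angstrom
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"ATOM  {serial:5d} {name_field}{'':1s}{resname:<3s} {chain:1s}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}\n")


def write_pdb(path: str | Path, topology: Topology, coords: np.ndarray) -> None:
    """Write a single-model PDB for ``topology`` with ``coords`` in nm."""
    with open(path, "w") as fh:
        for a in range(topology.n_atoms):
            r = int(topology.atom_residue[a])
            chain, resseq, resname = topology.residues[r]
            fh.write(_pdb_atom_line(a + 1, topology.atom_names[a], resname,
                                    chain or "A", resseq, coords[a],
                                    topology.elements[a]))
        fh.write("END\n")


def write_multi_model_pdb(path: str | Path, topology: Topology,
                          frames: Iterable[np.ndarray]) -> None:
    """Write a multi-model PDB trajectory (coordinates in nm)."""
    with open(path, "w") as fh:
        for m, coords in enumerate(frames, 1):
            fh.write(f"MODEL     {m:4d}\n")
            for a in range(topology.n_atoms):
                r = int(topology.atom_residue[a])
                chain, resseq, resname = topology.residues[r]
                fh.write(_pdb_atom_line(a + 1, topology.atom_names[a], resname,
                                        chain or "A", resseq, coords[a],
                                        topology.elements[a]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_plain_trajectory(path: str | Path, times: Sequence[float],
                           frames: Sequence[np.ndarray], decimals: int = 6) -> None:
    """Write the plain frame format: ``t <time>`` header + ``x y z`` per atom (nm)."""
    fmt = f"%.{decimals}f"
    with open(path, "w") as fh:
        for t, coords in zip(times, frames):
            fh.write(f"t {t:.6f}\n")
            for row in np.asarray(coords):
                fh.write(" ".join(fmt % v for v in row) + "\n")
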