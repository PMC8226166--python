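"""Two-chain peptide trajectories as multi-model PDB files.

The native trajectory format is multi-model PDB: one ``MODEL``/``ENDMDL``
block per frame, two peptide chains per model, fixed-column ``ATOM``
records with coordinates in Å (``%8.3f``).  At the scale analysed here
(~80-200 frames of 12-residue peptides) a human-inspectable text format
is preferable to binary MD formats.

The reader enforces a consistent atom roster across models (same names,
residues, chains and order in every frame), drops solvent and counter-ion
records (HOH/WAT/TIP3/NA/CL) with a logged count, and infers the element
from columns 77-78 when present, else from the atom name.

Residue naming for modified residues follows the common PDB conventions
TPO (phospho-Thr), SEP (phospho-Ser), M3L (trimethyl-Lys) and
DA2 (asymmetric dimethyl-Arg); standard names with the PTM declared in a
topology sidecar are accepted equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .ptm import PeptideSpec, parse_annotation

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "PDBFormatError",
    "RosterMismatchError",
    "ChainCountError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "heavy_atom_view",
    "chain_view",
    "read_topology",
    "write_topology",
    "MODIFIED_RESNAMES",
]

log = logging.getLogger(__name__)


class PDBFormatError(ValueError):
    """Malformed or unsupported multi-model PDB content."""


class RosterMismatchError(PDBFormatError):
    """Models disagree on the atom roster; message names the atom."""


class ChainCountError(PDBFormatError):
    """A model does not contain exactly two peptide chains."""


_SOLVENT_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "NA", "CL", "NA+", "CL-"}

#: (one-letter base, ptm) -> PDB residue name for modified residues.
MODIFIED_RESNAMES = {
    ("T", "ph"): "TPO",
    ("S", "ph"): "SEP",
    ("Y", "ph"): "PTR",
    ("K", "me3"): "M3L",
    ("K", "me1"): "MLZ",
    ("K", "me2"): "MLY",
    ("K", "ac"): "ALY",
    ("R", "me2"): "DA2",
    ("R", "me1"): "AGM",
}

_THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# Two-character elements that can occur in (modified) peptides; metals and
# halogens are out of scope, so anything else falls back to one character.
_TWO_CHAR_ELEMENTS = {"SE"}


def residue_name(base: str, ptm: str) -> str:
    """PDB 3-letter residue name for a (base, ptm) state."""
    if ptm != "none" and (base, ptm) in MODIFIED_RESNAMES:
        return MODIFIED_RESNAMES[(base, ptm)]
    return _THREE_LETTER[base]


def infer_element(atom_name: str) -> str:
    """Element from an atom name: first alphabetic character, with the
    two-character elements restricted to those present in peptides."""
    stripped = atom_name.strip()
    alpha = "".join(ch for ch in stripped if ch.isalpha()).upper()
    if not alpha:
        raise PDBFormatError(f"cannot infer element from atom name {atom_name!r}")
    if alpha[:2] in _TWO_CHAR_ELEMENTS:
        return alpha[0] + alpha[1].lower()
    return alpha[0]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame; coordinates in Å."""

    atom_name: str
    element: str
    residue_index: int  # 1-based within chain
    residue_name: str
    chain_id: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name!r}")


@dataclass(frozen=True)
class Frame:
    """Ordered atoms of one trajectory frame."""

    atoms: tuple[AtomRecord, ...]
    frame_index: int = 0
    time: float | None = None  # ps

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Frame":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = tuple(
            replace(a, xyz=(float(x), float(y), float(z)))
            for a, (x, y, z) in zip(self.atoms, coords)
        )
        return replace(self, atoms=atoms)

    def chain_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return tuple(seen)


def _roster_key(atom: AtomRecord) -> tuple:
    return (atom.chain_id, atom.residue_index, atom.residue_name, atom.atom_name)


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames of a two-chain system with an identical atom roster."""

    frames: tuple[Frame, ...]
    chain_ids: tuple[str, str]
    topology: Mapping[str, PeptideSpec] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise PDBFormatError("trajectory has no frames")
        if len(set(self.chain_ids)) != 2:
            raise ChainCountError(
                f"expected exactly two distinct chain ids, got {self.chain_ids!r}"
            )
        roster = [_roster_key(a) for a in self.frames[0].atoms]
        for frame in self.frames[1:]:
            other = [_roster_key(a) for a in frame.atoms]
            if other != roster:
                _raise_roster_mismatch(roster, other, frame.frame_index)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0].atoms)


def _raise_roster_mismatch(ref: list, other: list, frame_index: int) -> None:
    ref_set, other_set = set(ref), set(other)
    missing = ref_set - other_set
    extra = other_set - ref_set
    if missing:
        chain, resi, resn, name = sorted(missing)[0]
        raise RosterMismatchError(
            f"frame {frame_index}: atom {name.strip()!r} of residue "
            f"{resn} {resi} (chain {chain}) missing from model"
        )
    if extra:
        chain, resi, resn, name = sorted(extra)[0]
        raise RosterMismatchError(
            f"frame {frame_index}: unexpected atom {name.strip()!r} of residue "
            f"{resn} {resi} (chain {chain})"
        )
    raise RosterMismatchError(f"frame {frame_index}: atom order differs from frame 0")


def _parse_atom_line(line: str) -> AtomRecord:
    atom_name = line[12:16]
    resn = line[17:20].strip()
    chain = line[21].strip() or "A"
    try:
        resi = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBFormatError(f"malformed ATOM record: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(atom_name)
    element = element.capitalize() if len(element) > 1 else element.upper()
    return AtomRecord(
        atom_name=atom_name.strip(),
        element=element,
        residue_index=resi,
        residue_name=resn,
        chain_id=chain,
        xyz=(x, y, z),
    )


def read_multimodel_pdb(path, topology: Mapping[str, PeptideSpec] | None = None) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Files without MODEL records are treated as a single frame.  Solvent and
    counter-ion records are dropped (count logged).  Raises
    :class:`ChainCountError` unless exactly two chains are present and
    :class:`RosterMismatchError` if models disagree on the atom roster.
    """
    frames: list[Frame] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model = False
    n_solvent = 0

    def flush() -> None:
        nonlocal current
        if current:
            frames.append(Frame(atoms=tuple(current), frame_index=len(frames)))
            current = []

    with open(path) as fh:
        for line in fh:
            record = line[:6]
            if record == "MODEL ":
                saw_model = True
                in_model = True
                flush()
            elif record == "ENDMDL":
                in_model = False
                flush()
            elif record in ("ATOM  ", "HETATM"):
                resn = line[17:20].strip()
                if resn in _SOLVENT_RESNAMES:
                    n_solvent += 1
                    continue
                current.append(_parse_atom_line(line))
    flush()

    if n_solvent:
        log.info("dropped %d solvent/ion atom records", n_solvent)
    if not frames:
        raise PDBFormatError(f"{path}: no models / no atoms found")
    if saw_model and in_model:
        log.warning("%s: final MODEL block not closed by ENDMDL", path)

    chains = frames[0].chain_ids()
    if len(chains) != 2:
        raise ChainCountError(
            f"{path}: expected exactly 2 chains per model, found "
            f"{len(chains)} ({', '.join(chains) or 'none'})"
        )
    chain_ids = tuple(sorted(chains))
    return Trajectory(frames=tuple(frames), chain_ids=chain_ids, topology=topology)


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame,
    TER after each chain, coordinates %8.3f)."""
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            serial = 1
            prev_chain = frame.atoms[0].chain_id if frame.atoms else None
            last_atom = None
            for atom in frame.atoms:
                if atom.chain_id != prev_chain:
                    fh.write(_ter_line(serial, last_atom))
                    serial += 1
                    prev_chain = atom.chain_id
                fh.write(_atom_line(serial, atom))
                serial += 1
                last_atom = atom
            if last_atom is not None:
                fh.write(_ter_line(serial, last_atom))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: one-letter elements start in column 14.
    name = name.strip()
    if len(name) >= 4 or len(element) == 2:
        return f"{name:<4.4s}"
    return f" {name:<3.3s}"


def _atom_line(serial: int, atom: AtomRecord) -> str:
    x, y, z = atom.xyz
    return (
        f"ATOM  {serial:5d} {_format_atom_name(atom.atom_name, atom.element)}"
        f"{'':1s}{atom.residue_name:>3.3s} {atom.chain_id:1.1s}"
        f"{atom.residue_index:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2.2s}\n"
    )


def _ter_line(serial: int, atom: AtomRecord | None) -> str:
    if atom is None:
        return "TER\n"
    return (
        f"TER   {serial:5d}      {atom.residue_name:>3.3s} "
        f"{atom.chain_id:1.1s}{atom.residue_index:4d}\n"
    )


def heavy_atom_view(traj: Trajectory) -> Trajectory:
    """Trajectory with all hydrogen atoms removed (idempotent)."""
    new_frames = []
    for frame in traj.frames:
        atoms = tuple(a for a in frame.atoms if a.element != "H")
        new_frames.append(replace(frame, atoms=atoms))
    return replace(traj, frames=tuple(new_frames))


def chain_view(frame: Frame, chain_id: str) -> Frame:
    """Atoms of one chain only, order preserved."""
    if chain_id not in frame.chain_ids():
        raise KeyError(f"chain {chain_id!r} not present in frame {frame.frame_index}")
    atoms = tuple(a for a in frame.atoms if a.chain_id == chain_id)
    return replace(frame, atoms=atoms)


def read_topology(path) -> dict[str, PeptideSpec]:
    """Read a YAML topology sidecar mapping chain id -> annotation string."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "chains" not in raw:
        raise PDBFormatError(f"{path}: topology sidecar must map 'chains'")
    topo = {}
    for chain_id, entry in raw["chains"].items():
        if isinstance(entry, str):
            annotation, label = entry, str(chain_id)
        else:
            annotation = entry["annotation"]
            label = entry.get("label", str(chain_id))
        topo[str(chain_id)] = parse_annotation(annotation, label=label)
    return topo


def write_topology(topology: Mapping[str, PeptideSpec], path) -> None:
    from .ptm import format_annotation

    doc = {
        "chains": {
            cid: {"annotation": format_annotation(spec), "label": spec.label}
            for cid, spec in topology.items()
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
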