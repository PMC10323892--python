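"""Protein structure and alignment I/O and the shared coordinate data model.

The package works on a deliberately small hierarchy — chains, residues,
atoms — carrying Cartesian coordinates in Angstrom and a per-atom van der
Waals radius. Structures are read from PDB ``ATOM`` records (wwPDB v3.3
fixed columns); hydrogens, HETATM records and waters are skipped and only
the first MODEL of a multi-model file is kept, because every downstream
step (SASA burial, contact maps, Calpha sampling) operates on heavy atoms
of a single conformation.

Residue numbering follows the author numbering of the input file. An
optional offset table converts to UniProt numbering, which is the
convention used for distance restraints in cyclin-CDK work.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "AtomRecord",
    "ResidueKey",
    "Structure",
    "AlignmentMap",
    "PDBParseError",
    "AlignmentFormatError",
    "read_pdb",
    "write_pdb",
    "read_alignment",
    "read_offset_table",
    "apply_numbering_offsets",
]

#: Pinned element -> van der Waals radius table (Angstrom). Kept inside the
#: package so SASA and contact results are reproducible across installs.
VDW_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS: float = 1.70

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted as a structure."""


class AlignmentFormatError(ValueError):
    """Raised for malformed aligned-FASTA input."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue: chain, author sequence number, insertion code.

    Insertion codes sort after the same ``residue_seq`` without a code
    (the empty string sorts first).
    """

    chain_id: str
    residue_seq: int
    insertion_code: str = ""

    def __str__(self) -> str:  # e.g. "A:97" or "A:97A"
        return f"{self.chain_id}:{self.residue_seq}{self.insertion_code}"


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    coords: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.residue_seq, self.insertion_code)


class Structure:
    """An ordered chains -> residues -> atoms hierarchy.

    Atoms are stored in input order; residue and chain order is the order of
    first appearance. ``(chain, residue_seq, insertion_code, atom_name)``
    must be unique and every residue has at least one atom.
    """

    def __init__(self, id: str, atoms: Sequence[AtomRecord]):
        if not atoms:
            raise ValueError(f"structure {id!r} has no atoms")
        self.id = id
        self.atoms: list[AtomRecord] = list(atoms)
        self._by_residue: dict[ResidueKey, list[AtomRecord]] = {}
        seen: set[tuple[str, int, str, str]] = set()
        for a in self.atoms:
            k = (a.chain_id, a.residue_seq, a.insertion_code, a.atom_name)
            if k in seen:
                raise ValueError(f"duplicate atom {k} in structure {id!r}")
            seen.add(k)
            self._by_residue.setdefault(a.residue_key, []).append(a)
        self.chains: list[str] = []
        for a in self.atoms:
            if a.chain_id not in self.chains:
                self.chains.append(a.chain_id)

    # ---- residue / atom access -------------------------------------------
    def residues(self, chain_id: str | None = None) -> list[ResidueKey]:
        keys = list(self._by_residue)
        if chain_id is None:
            return keys
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not in structure {self.id!r}")
        return [k for k in keys if k.chain_id == chain_id]

    def residue_atoms(self, key: ResidueKey) -> list[AtomRecord]:
        return self._by_residue[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._by_residue

    @property
    def n_residues(self) -> int:
        return len(self._by_residue)

    def coords(self) -> np.ndarray:
        """All atom coordinates, shape (n_atoms, 3)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    # ---- derived structures ----------------------------------------------
    def select_chains(self, chain_ids: Iterable[str]) -> "Structure":
        wanted = list(chain_ids)
        for c in wanted:
            if c not in self.chains:
                raise KeyError(f"chain {c!r} not in structure {self.id!r}")
        atoms = [a for a in self.atoms if a.chain_id in wanted]
        return Structure(f"{self.id}|{''.join(wanted)}", atoms)

    def ca_atoms(self, chain_id: str | None = None) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.atom_name == "CA" and (chain_id is None or a.chain_id == chain_id)
        ]

    def ca_coords(self, chain_id: str | None = None) -> np.ndarray:
        return np.array([a.coords for a in self.ca_atoms(chain_id)], dtype=float)

    def with_coords(self, new_coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of the structure with all atom coordinates replaced."""
        new_coords = np.asarray(new_coords, dtype=float)
        if new_coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"expected coordinates of shape {(len(self.atoms), 3)}, "
                f"got {new_coords.shape}"
            )
        atoms = [
            replace(a, coords=(float(x), float(y), float(z)))
            for a, (x, y, z) in zip(self.atoms, new_coords)
        ]
        return Structure(id or self.id, atoms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        if len(self.atoms) != len(other.atoms):
            return False
        for a, b in zip(self.atoms, other.atoms):
            if (
                a.atom_name != b.atom_name
                or a.element != b.element
                or a.residue_name != b.residue_name
                or a.chain_id != b.chain_id
                or a.residue_seq != b.residue_seq
                or a.insertion_code != b.insertion_code
                or a.coords != b.coords
            ):
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"<Structure {self.id!r}: {len(self.chains)} chains, "
            f"{self.n_residues} residues, {len(self.atoms)} atoms>"
        )


def _element_of(line: str, atom_name: str) -> str:
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the atom-name convention: first alphabetic character
        stripped = atom_name.lstrip("0123456789")
        element = stripped[:1]
    return element.upper()


def read_pdb(path: str | Path, id: str | None = None) -> Structure:
    """Parse ATOM records of a PDB file into a :class:`Structure`.

    HETATM records, waters and hydrogens are skipped; for alternate
    locations only the first-listed altloc of each atom is kept; only the
    first MODEL of a multi-model file is read. Radii come from the pinned
    element table (:data:`VDW_RADII`).
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    seen_atoms: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "ENDMDL":
                break
            if not rec.startswith("ATOM"):
                continue
            atom_name = line[12:16].strip()
            altloc = line[16:17].strip()
            residue_name = line[17:20].strip()
            chain_id = line[21:22].strip() or " "
            icode = line[26:27].strip()
            if residue_name in _WATER_NAMES:
                continue
            element = _element_of(line, atom_name)
            if element in ("H", "D"):
                continue
            try:
                serial = int(line[6:11])
                residue_seq = int(line[22:26])
                coords = (
                    float(line[30:38]),
                    float(line[38:46]),
                    float(line[46:54]),
                )
            except ValueError as exc:
                raise PDBParseError(
                    f"{path.name}, line {lineno}: malformed ATOM record ({exc})"
                ) from exc
            key = (chain_id, residue_seq, icode, atom_name)
            if key in seen_atoms:
                continue  # later altloc of an atom already read
            seen_atoms.add(key)
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=atom_name,
                    element=element,
                    residue_name=residue_name,
                    chain_id=chain_id,
                    residue_seq=residue_seq,
                    insertion_code=icode,
                    coords=coords,
                    vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
                    # altloc column is intentionally dropped: only the first
                    # listed conformer of each atom survives the read
                )
            )
    if not atoms:
        raise PDBParseError(f"{path.name}: no ATOM records found")
    return Structure(id or path.stem, atoms)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as PDB ATOM records (8.3-format coordinates).

    Serials are renumbered from 1; chains are terminated with TER records.
    Re-parsing the file reproduces the structure on all fields except the
    serial numbers.
    """
    path = Path(path)
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        x, y, z = a.coords
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_seq:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


@dataclass
class AlignmentMap:
    """Per-sequence maps from 1-based ungapped residue index to 1-based
    alignment column, derived from an aligned FASTA file."""

    length: int
    maps: dict[str, dict[int, int]] = field(default_factory=dict)

    @property
    def sequence_ids(self) -> list[str]:
        return list(self.maps)

    def index_to_column(self, seq_id: str, index: int) -> int:
        if seq_id not in self.maps:
            raise KeyError(f"sequence {seq_id!r} not in alignment")
        m = self.maps[seq_id]
        if index not in m:
            raise KeyError(f"residue index {index} out of range for {seq_id!r}")
        return m[index]

    def column_to_index(self, seq_id: str, column: int) -> int | None:
        """Inverse map; ``None`` when the sequence has a gap at the column."""
        if seq_id not in self.maps:
            raise KeyError(f"sequence {seq_id!r} not in alignment")
        for idx, col in self.maps[seq_id].items():
            if col == column:
                return idx
        return None


def read_alignment(path: str | Path) -> AlignmentMap:
    """Read an aligned FASTA file into an :class:`AlignmentMap`.

    All sequences must have equal length; ``-`` is the gap character.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path.name}: no sequences found")
    length = len(records[0].seq)
    amap = AlignmentMap(length=length)
    for rec in records:
        if len(rec.seq) != length:
            raise AlignmentFormatError(
                f"{path.name}: sequence {rec.id!r} has length {len(rec.seq)}, "
                f"expected {length} (ragged alignment)"
            )
        if rec.id in amap.maps:
            raise AlignmentFormatError(f"{path.name}: duplicate id {rec.id!r}")
        mapping: dict[int, int] = {}
        idx = 0
        for col, ch in enumerate(str(rec.seq), start=1):
            if ch != "-":
                idx += 1
                mapping[idx] = col
        amap.maps[rec.id] = mapping
    return amap


def read_offset_table(path: str | Path) -> dict[str, int]:
    """Read a chain -> numbering-offset table.

    Three tab-separated columns: chain_id, pdb_seq_start, uniprot_seq_start.
    Returns per-chain offsets such that uniprot = pdb + offset.
    """
    offsets: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"offset table line {lineno}: expected 3 columns")
        chain, pdb_start, up_start = parts[0], int(parts[1]), int(parts[2])
        offsets[chain] = up_start - pdb_start
    return offsets


def apply_numbering_offsets(structure: Structure, offsets: Mapping[str, int]) -> Structure:
    """Renumber residues per chain by the given offsets (PDB -> UniProt)."""
    atoms = [
        replace(a, residue_seq=a.residue_seq + offsets.get(a.chain_id, 0))
        for a in structure.atoms
    ]
    return Structure(structure.id, atoms)
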