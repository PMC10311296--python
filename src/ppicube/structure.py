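"""PDB structure handling and the atom-type channel encoding.

A protein--protein complex is held as a flat list of heavy atoms split
into two partner chain groups.  Every voxel cube built downstream encodes
each atom as a one-hot channel, either over the 167 distinct
(residue type, heavy-atom name) pairs of the 20 standard amino acids
("full167") or over the four chemical elements C, N, O, S ("element4").
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Structure",
    "ChannelScheme",
    "STANDARD_RESIDUES",
    "HEAVY_ATOMS",
    "parse_pdb",
    "write_pdb",
    "build_channel_scheme",
    "channel_index",
]

# Heavy-atom topology of the 20 standard amino acids, PDB atom names.
# Backbone first (N, CA, C, O), then side chain; terminal OXT and all
# hydrogens are excluded.  The pair count over all residues is exactly 167.
HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("N", "CA", "C", "O", "CB"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "GLY": ("N", "CA", "C", "O"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
}

STANDARD_RESIDUES: tuple[str, ...] = tuple(sorted(HEAVY_ATOMS))

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S")

# Nonstandard residues mapped onto a standard parent before encoding.
_RESIDUE_ALIASES: dict[str, str] = {"MSE": "MET"}
_ATOM_ALIASES: dict[tuple[str, str], str] = {("MSE", "SE"): "SD"}


@dataclass(frozen=True)
class Atom:
    """One heavy atom with its PDB identity and coordinates (Å)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """Heavy atoms of a two-partner complex.

    ``partner1``/``partner2`` are disjoint chain-id sets naming the two
    sides of the interface.  Hydrogens, waters and unrecognised hetero
    groups are absent by construction.
    """

    atoms: list[Atom]
    partner1: frozenset[str]
    partner2: frozenset[str]

    def __post_init__(self) -> None:
        self.partner1 = frozenset(self.partner1)
        self.partner2 = frozenset(self.partner2)
        if self.partner1 & self.partner2:
            raise ValueError(
                f"partner chain sets overlap: {sorted(self.partner1 & self.partner2)}"
            )

    def partner_of(self, chain_id: str) -> int:
        if chain_id in self.partner1:
            return 1
        if chain_id in self.partner2:
            return 2
        raise KeyError(f"chain {chain_id!r} belongs to neither partner")

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Atoms grouped by residue, in file order."""
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def coords(self) -> np.ndarray:
        return np.asarray([a.position for a in self.atoms], dtype=float)

    def subset(self, chain_ids: Iterable[str]) -> "Structure":
        """Atoms of the given chains only (used for the unbound state)."""
        keep = set(chain_ids)
        atoms = [a for a in self.atoms if a.chain_id in keep]
        return Structure(atoms, self.partner1 & keep, self.partner2 & keep)


@dataclass(frozen=True)
class ChannelScheme:
    """Mapping from atom identity to a one-hot channel index.

    ``full167`` enumerates the 167 (residue, heavy atom) pairs in a fixed
    order: residues alphabetically by 3-letter code, atoms in backbone-
    then-side-chain topology order.  ``element4`` uses C, N, O, S.
    """

    mode: str
    index_of: dict = field(hash=False)
    n_channels: int

    def labels(self) -> list[str]:
        """Channel labels in index order, for audit export."""
        inv = sorted(self.index_of.items(), key=lambda kv: kv[1])
        return ["/".join(k) if isinstance(k, tuple) else k for k, _ in inv]

    def export_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, lab in enumerate(self.labels()):
                fh.write(f"{i}\t{lab}\n")


def build_channel_scheme(mode: str = "full167") -> ChannelScheme:
    """Construct the atom->channel encoding.

    Parameters
    ----------
    mode : {"full167", "element4"}
    """
    if mode == "full167":
        index: dict[tuple[str, str], int] = {}
        for res in STANDARD_RESIDUES:
            for name in HEAVY_ATOMS[res]:
                index[(res, name)] = len(index)
        return ChannelScheme("full167", index, len(index))
    if mode == "element4":
        return ChannelScheme("element4", {e: i for i, e in enumerate(ELEMENTS)}, 4)
    raise ValueError(f"unknown channel scheme mode {mode!r}")


def channel_index(scheme: ChannelScheme, atom: Atom) -> int:
    """Channel of one atom under a scheme.

    Raises ``KeyError`` with a descriptive message for a (residue, atom)
    pair outside the standard heavy-atom topology (full167) or an element
    outside {C,N,O,S} (element4).
    """
    if scheme.mode == "full167":
        res = _RESIDUE_ALIASES.get(atom.residue_name, atom.residue_name)
        name = _ATOM_ALIASES.get((atom.residue_name, atom.atom_name), atom.atom_name)
        try:
            return scheme.index_of[(res, name)]
        except KeyError:
            raise KeyError(
                f"atom {atom.atom_name!r} of residue {atom.residue_name!r} is not "
                "a standard heavy atom (nonstandard residue or malformed name?)"
            ) from None
    try:
        return scheme.index_of[atom.element]
    except KeyError:
        raise KeyError(
            f"element {atom.element!r} outside the C/N/O/S channel set"
        ) from None


def _element_of(atom_name: str, biotite_element: str) -> str:
    el = biotite_element.strip().upper()
    if el in ("C", "N", "O", "S"):
        return el
    if el == "SE":
        return "S"  # selenomethionine handled as its sulfur parent
    # fall back to the leading element letter of the atom name
    lead = atom_name.strip().lstrip("0123456789")[:1].upper()
    return lead


def parse_pdb(
    path: str | Path | io.StringIO,
    partner1: Iterable[str],
    partner2: Iterable[str],
) -> Structure:
    """Read a two-partner complex from a PDB file.

    Keeps heavy atoms of standard residues (selenomethionine is mapped to
    methionine); drops hydrogens, waters and other hetero groups.  For
    multi-model files only model 1 is used; alternate locations resolve to
    the highest-occupancy conformer.  Chains outside the two partner sets
    are dropped.

    Raises
    ------
    ValueError
        If a requested partner chain is absent from the file, or a partner
        set is empty.
    """
    p1, p2 = frozenset(partner1), frozenset(partner2)
    if not p1 or not p2:
        raise ValueError("both partner chain sets must be non-empty")

    pdb = PDBFile.read(path)
    arr = pdb.get_structure(model=1, altloc="occupancy")

    present = set(np.unique(arr.chain_id).tolist())
    missing = (p1 | p2) - present
    if missing:
        raise ValueError(
            f"partner chain(s) {sorted(missing)} not found in PDB file "
            f"(chains present: {sorted(present)})"
        )

    known = set(STANDARD_RESIDUES) | set(_RESIDUE_ALIASES)
    mask = (
        np.isin(arr.chain_id, list(p1 | p2))
        & np.isin(arr.res_name, list(known))
        & (arr.element != "H")
        & (arr.element != "D")
    )
    arr = arr[mask]

    atoms: list[Atom] = []
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i])
        atom_name = str(arr.atom_name[i])
        mapped_res = _RESIDUE_ALIASES.get(res_name, res_name)
        mapped_name = _ATOM_ALIASES.get((res_name, atom_name), atom_name)
        pos = np.array(arr.coord[i], dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite coordinates for atom record {i}")
        atoms.append(
            Atom(
                chain_id=str(arr.chain_id[i]),
                residue_number=int(arr.res_id[i]),
                insertion_code=str(arr.ins_code[i]).strip(),
                residue_name=mapped_res,
                atom_name=mapped_name,
                element=_element_of(mapped_name, str(arr.element[i])),
                position=pos,
            )
        )
    return Structure(atoms, p1, p2)


def to_atom_array(structure: Structure) -> bts.AtomArray:
    """Convert to a biotite ``AtomArray`` (used for SASA and PDB output)."""
    n = len(structure.atoms)
    arr = bts.AtomArray(n)
    for i, a in enumerate(structure.atoms):
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.residue_number
        arr.ins_code[i] = a.insertion_code
        arr.res_name[i] = a.residue_name
        arr.atom_name[i] = a.atom_name
        arr.element[i] = a.element
        arr.coord[i] = a.position
    arr.hetero[:] = False
    return arr


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as a standard PDB file (ATOM records)."""
    pdb = PDBFile()
    pdb.set_structure(to_atom_array(structure))
    pdb.write(path)
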