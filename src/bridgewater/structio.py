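"""PDB structure I/O and atom-role partitioning.

Reads a protein-ligand complex from PDB text, splits its atoms into
protein / ligand / water / other roles, classifies hydrogen-bond-capable
(polar) heavy atoms, and writes structures back out with predicted waters
appended as HETATM oxygen records.

Parsing is delegated to :mod:`gemmi`; this module only adds role
assignment, altloc resolution and the fixed-width writer needed for a
lossless round trip at PDB coordinate precision (3 decimals).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import AmbiguousLigandError, LigandNotFoundError, MalformedPDBError

__all__ = [
    "Atom",
    "InterfaceComplex",
    "PolarAtomSet",
    "LigandSelector",
    "load_complex",
    "classify_polar_atoms",
    "write_waters",
    "coords",
    "strip_waters",
    "DEFAULT_WATER_NAMES",
    "DEFAULT_POLAR_ELEMENTS",
]

DEFAULT_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})
DEFAULT_POLAR_ELEMENTS = frozenset({"N", "O"})

#: roles an atom can take inside an :class:`InterfaceComplex`
ROLES = ("protein", "ligand", "water", "other")


@dataclass
class Atom:
    """One heavy atom with its PDB identity preserved as-is."""

    serial: int
    name: str
    element: str
    coord: np.ndarray  # (3,) float64, Angstrom
    residue_name: str
    residue_number: int
    chain: str
    role: str
    icode: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial}: coord must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"atom {self.serial}: unknown role {self.role!r}")

    @property
    def residue_id(self) -> str:
        return f"{self.residue_name} {self.residue_number}{self.icode} {self.chain}".strip()


@dataclass
class InterfaceComplex:
    """Atoms of one protein + one designated ligand, partitioned by role.

    ``water_oxygens`` holds crystallographic water oxygens only (water
    hydrogens are dropped on load); ``other_atoms`` collects everything
    that is neither protein, selected ligand nor water (ions, cofactors,
    nucleic acids, unselected ligand copies).
    """

    protein_atoms: list[Atom]
    ligand_atoms: list[Atom]
    water_oxygens: list[Atom]
    other_atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError("ligand_atoms must be non-empty")
        keys = {(a.residue_name, a.residue_number, a.chain, a.icode) for a in self.ligand_atoms}
        if len(keys) != 1:
            raise ValueError(f"ligand atoms span multiple residues: {sorted(keys)}")
        bad = [a for a in self.water_oxygens if a.element != "O"]
        if bad:
            raise ValueError("water_oxygens may contain only oxygen atoms")
        overlap = {a.serial for a in self.protein_atoms} & {a.serial for a in self.ligand_atoms}
        if overlap:
            raise ValueError(f"protein and ligand share serials {sorted(overlap)}")

    @property
    def all_atoms(self) -> list[Atom]:
        return self.protein_atoms + self.ligand_atoms + self.water_oxygens + self.other_atoms


@dataclass
class PolarAtomSet:
    """Hydrogen-bond donor/acceptor-capable heavy atoms on each side."""

    ligand_polar: list[Atom]
    protein_polar: list[Atom]


@dataclass(frozen=True)
class LigandSelector:
    """Selects the ligand residue by name, optionally narrowed by chain/number.

    The string forms ``"4CD"``, ``"4CD:A"`` and ``"4CD:A:401"`` are accepted
    by :meth:`parse`.
    """

    residue_name: str
    chain: str | None = None
    residue_number: int | None = None

    @classmethod
    def parse(cls, text: str) -> "LigandSelector":
        parts = text.split(":")
        if len(parts) == 1:
            return cls(parts[0])
        if len(parts) == 2:
            return cls(parts[0], parts[1] or None)
        if len(parts) == 3:
            return cls(parts[0], parts[1] or None,
                       int(parts[2]) if parts[2] else None)
        raise ValueError(f"cannot parse ligand selector {text!r}")

    def matches(self, residue_name: str, chain: str, residue_number: int) -> bool:
        if residue_name != self.residue_name:
            return False
        if self.chain is not None and chain != self.chain:
            return False
        if self.residue_number is not None and residue_number != self.residue_number:
            return False
        return True


def coords(atoms: Sequence[Atom]) -> np.ndarray:
    """Stack atom coordinates into an (n, 3) float array (0, 3) if empty."""
    if not atoms:
        return np.empty((0, 3), dtype=float)
    return np.array([a.coord for a in atoms], dtype=float)


def _validate_coordinate_lines(pdb_text: str) -> None:
    for i, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise MalformedPDBError("record shorter than coordinate columns", i)
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise MalformedPDBError(
                    f"unparseable {what} coordinate {line[lo:hi]!r}", i
                ) from None


def _infer_element(atom_name: str) -> str:
    letters = [c for c in atom_name if c.isalpha()]
    if not letters:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    return letters[0].upper()


def _element_of(atom: gemmi.Atom) -> str:
    name = atom.element.name.strip()
    if not name or name.upper() == "X":
        return _infer_element(atom.name)
    # normalize: one- or two-letter symbol, first letter upper-case
    return name[0].upper() + name[1:].lower()


def _select_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken toward altloc 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    for at in res:
        prev = by_name.get(at.name)
        if prev is None:
            by_name[at.name] = at
            continue
        key_new = (-at.occ, at.altloc or "A")
        key_old = (-prev.occ, prev.altloc or "A")
        if key_new < key_old:
            by_name[at.name] = at
    return list(by_name.values())


def load_complex(
    pdb_text: str,
    ligand_selector: LigandSelector | str,
    *,
    source_id: str = "",
    water_names: frozenset[str] | set[str] = DEFAULT_WATER_NAMES,
    keep_hydrogens: bool = False,
) -> InterfaceComplex:
    """Parse PDB text and partition its atoms around one ligand residue.

    Heavy atoms only by default; waters are reduced to their oxygen; the
    highest-occupancy altloc is kept (ties go to 'A').

    Raises
    ------
    LigandNotFoundError
        if no residue matches the selector.
    AmbiguousLigandError
        if the selector matches more than one distinct residue.
    MalformedPDBError
        if a coordinate field cannot be parsed (reports the line number).
    """
    if isinstance(ligand_selector, str):
        ligand_selector = LigandSelector.parse(ligand_selector)
    _validate_coordinate_lines(pdb_text)
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise LigandNotFoundError("structure contains no models")
    model = structure[0]

    # first pass: which residues match the selector?
    matches: list[tuple[str, int, str]] = []
    for ch in model:        # (chain, seqid, icode) triples of matching residues
        for res in ch:
            key = (ch.name, res.seqid.num, res.seqid.icode.strip())
            if ligand_selector.matches(res.name, ch.name, res.seqid.num) and key not in matches:
                matches.append(key)
    if not matches:
        raise LigandNotFoundError(
            f"ligand not found: no residue matches {ligand_selector}"
        )
    if len(matches) > 1:
        raise AmbiguousLigandError(
            f"ambiguous ligand selector {ligand_selector}: matches {matches}"
        )
    ligand_key = matches[0]

    protein: list[Atom] = []
    ligand: list[Atom] = []
    waters: list[Atom] = []
    other: list[Atom] = []
    for ch in model:
        for res in ch:
            is_ligand = (ch.name, res.seqid.num, res.seqid.icode.strip()) == ligand_key
            is_water = res.name in water_names
            info = gemmi.find_tabulated_residue(res.name)
            is_protein = (not is_ligand and not is_water
                          and info is not None and info.is_amino_acid())
            for at in _select_altlocs(res):
                element = _element_of(at)
                if element == "H" and not keep_hydrogens:
                    continue
                if element == "D" and not keep_hydrogens:
                    continue
                if is_water and element != "O":
                    continue
                role = ("ligand" if is_ligand else
                        "water" if is_water else
                        "protein" if is_protein else "other")
                atom = Atom(
                    serial=at.serial,
                    name=at.name,
                    element=element,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain=ch.name,
                    role=role,
                    icode=res.seqid.icode.strip(),
                    occupancy=at.occ,
                )
                {"protein": protein, "ligand": ligand,
                 "water": waters, "other": other}[role].append(atom)

    return InterfaceComplex(
        protein_atoms=protein,
        ligand_atoms=ligand,
        water_oxygens=waters,
        other_atoms=other,
        source_id=source_id or structure.name or "",
    )


def classify_polar_atoms(
    complex_: InterfaceComplex,
    polar_elements: frozenset[str] | set[str] = DEFAULT_POLAR_ELEMENTS,
) -> PolarAtomSet:
    """Return the hydrogen-bond donor/acceptor-capable heavy atoms.

    A heavy atom counts as polar when its element is in ``polar_elements``
    (N and O by default; add "S" to include thiols/thioethers). With no
    explicit hydrogens there is no donor/acceptor distinction: element
    membership approximates "can take part in a hydrogen bond".
    """
    return PolarAtomSet(
        ligand_polar=[a for a in complex_.ligand_atoms if a.element in polar_elements],
        protein_polar=[a for a in complex_.protein_atoms if a.element in polar_elements],
    )


def strip_waters(complex_: InterfaceComplex) -> InterfaceComplex:
    """Copy of the complex without its crystallographic waters."""
    return dataclasses.replace(complex_, water_oxygens=[])


def _format_record(record: str, serial: int, atom: "Atom" = None, *,
                   name: str = "", resname: str = "", chain: str = "",
                   resnum: int = 0, icode: str = "", xyz=None,
                   occ: float = 1.0, b: float = 0.0, element: str = "") -> str:
    if atom is not None:
        name, resname, chain = atom.name, atom.residue_name, atom.chain
        resnum, icode, xyz = atom.residue_number, atom.icode, atom.coord
        occ, element = atom.occupancy, atom.element
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3}"
    else:
        name_field = f"{name:<4}"
    elem_field = element.upper().rjust(2)
    return (
        f"{record:<6}{serial:>5} {name_field} {resname:<3} {chain:>1}"
        f"{resnum:>4}{icode or ' ':>1}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {elem_field}"
    )


def write_waters(complex_: InterfaceComplex, placed: Iterable) -> str:
    """Serialize the complex plus predicted waters to PDB text.

    Placed waters become HETATM oxygen records (residue HOH, chain W,
    residue numbers 1..n, occupancy 1.00, B 0.00). Formatting is
    normalized; reloading the output reproduces every coordinate to the
    3-decimal PDB precision and the same role partition.
    """
    lines: list[str] = []
    serial = 0
    for atom in complex_.protein_atoms:
        serial += 1
        lines.append(_format_record("ATOM", serial, atom))
    for atom in complex_.ligand_atoms + complex_.other_atoms + complex_.water_oxygens:
        serial += 1
        lines.append(_format_record("HETATM", serial, atom))
    for i, pw in enumerate(placed, start=1):
        serial += 1
        coord = np.asarray(getattr(pw, "coord", pw), dtype=float)
        lines.append(_format_record(
            "HETATM", serial, name="O", resname="HOH", chain="W",
            resnum=i, xyz=coord, occ=1.0, b=0.0, element="O",
        ))
    lines.append("END")
    return "\n".join(lines) + "\n"
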