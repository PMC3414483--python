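"""Structure data model, PDB I/O, groove selection and curation filters.

The in-memory model is deliberately small: a :class:`Structure` is a map of
chain id to an ordered list of :class:`Residue`, each holding ordered
:class:`Atom` records with coordinates in Angstrom.  Reading goes through
Bio.PDB (first model only, highest-occupancy altloc, waters/heteroatoms
skipped); writing emits fixed-width ATOM records directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from . import data as _data
from .topology import (BACKBONE_ATOMS, CANONICAL_HEAVY_ATOMS,
                       STANDARD_RESIDUES, THREE_TO_ONE, element_of)

__all__ = [
    "Atom", "Residue", "Structure", "GrooveDefinition", "PDBError",
    "read_pdb", "write_pdb", "extract_peptide", "select_groove",
    "validate_complex", "default_groove",
]

PEPTIDE_LENGTH_RANGE = (8, 12)


class PDBError(ValueError):
    """Raised for unreadable or unserializable PDB content."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.coords)) or self.coords.shape != (3,):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")


@dataclass
class Residue:
    name: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.coords for a in self.atoms])
        return np.array([self.atom(n).coords for n in names])

    def copy(self) -> "Residue":
        return Residue(self.name, self.number, self.icode,
                       [replace(a, coords=a.coords.copy()) for a in self.atoms])


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]]
    resolution: float | None = None

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.chains[chain_id])

    def all_atoms(self) -> list[tuple[str, Residue, Atom]]:
        out = []
        for cid, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    out.append((cid, res, atom))
        return out

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for _, _, a in self.all_atoms()])

    def set_coords(self, coords: np.ndarray) -> None:
        flat = [a for _, _, a in self.all_atoms()]
        if len(flat) != len(coords):
            raise ValueError("coordinate count mismatch")
        for atom, xyz in zip(flat, coords):
            atom.coords = np.asarray(xyz, dtype=float)

    def copy(self) -> "Structure":
        return Structure(self.id,
                         {cid: [r.copy() for r in residues]
                          for cid, residues in self.chains.items()},
                         self.resolution)


@dataclass(frozen=True)
class GrooveDefinition:
    """Ordered residue numbers delineating the binding groove."""
    residue_numbers: tuple[int, ...]

    def __len__(self):
        return len(self.residue_numbers)


def default_groove() -> GrooveDefinition:
    """The 37 solvent-accessible groove residues of HLA-A*02:01."""
    return GrooveDefinition(tuple(_data.load_groove_residues()))


# ---------------------------------------------------------------------------
# I/O

def read_pdb(path: str | Path) -> Structure:
    """Read the first model of a PDB file into a :class:`Structure`.

    HETATM records and waters are skipped; for disordered atoms the
    highest-occupancy conformer is kept (ties by altloc label order).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBError(f"{path}: cannot parse PDB file: {exc}") from exc
    models = list(bio.get_models())
    if not models:
        raise PDBError(f"{path}: no ATOM records found")
    chains: dict[str, list[Residue]] = {}
    for chain in models[0]:
        residues = []
        for res in chain:
            hetflag = res.id[0]
            if hetflag != " ":  # HETATM / water
                continue
            atoms = []
            for atom in res:
                if atom.is_disordered():
                    children = sorted(atom.child_dict.items())
                    best = max(children,
                               key=lambda kv: (kv[1].get_occupancy() or 0.0,
                                               [-ord(c) for c in kv[0]]))[1]
                else:
                    best = atom
                if best.element == "H" or atom.get_id().startswith("H"):
                    continue
                atoms.append(Atom(atom.get_id(),
                                  best.element or element_of(atom.get_id()),
                                  np.asarray(best.get_coord(), dtype=float),
                                  best.get_occupancy() or 1.0,
                                  best.get_bfactor() or 0.0))
            if atoms:
                residues.append(Residue(res.get_resname().strip(), res.id[1],
                                        res.id[2].strip(), atoms))
        if residues:
            chains[chain.id.strip() or "A"] = residues
    if not chains:
        raise PDBError(f"{path}: no ATOM records found")
    resolution = getattr(bio.header, "get", lambda *_: None)("resolution") \
        if hasattr(bio, "header") else None
    if isinstance(bio.header, dict):
        resolution = bio.header.get("resolution")
    return Structure(path.stem, chains, resolution)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Serialize as standards-conformant fixed-width ATOM records."""
    lines = []
    serial = 1
    if structure.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS.")
    for cid, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms:
                x, y, z = atom.coords
                if max(abs(x), abs(y), abs(z)) >= 10000.0:
                    raise PDBError(
                        f"coordinate overflow ({x:.1f},{y:.1f},{z:.1f}) for "
                        f"atom {atom.name} in {res.name}{res.number}")
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.name:<3s} {cid:1s}"
                    f"{res.number:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{atom.bfactor:6.2f}          {atom.element:>2s}")
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selection / curation

def _peptide_candidates(complex_: Structure) -> list[str]:
    lo, hi = PEPTIDE_LENGTH_RANGE
    return [cid for cid, residues in complex_.chains.items()
            if lo <= len(residues) <= hi]


def heavy_chain_id(complex_: Structure) -> str:
    """The HLA heavy chain: the longest non-peptide-length chain."""
    candidates = set(_peptide_candidates(complex_))
    others = [cid for cid in complex_.chains if cid not in candidates]
    if not others:
        raise ValueError(f"{complex_.id}: no receptor-sized chain found")
    return max(others, key=lambda cid: len(complex_.chains[cid]))


def extract_peptide(complex_: Structure) -> Structure:
    """Pull out the single bound peptide chain, relabeled P1..Pn.

    Raises an ambiguity error unless exactly one chain has peptide length
    (8-12 residues).
    """
    candidates = _peptide_candidates(complex_)
    if len(candidates) != 1:
        raise ValueError(
            f"{complex_.id}: expected exactly one peptide-length chain, "
            f"found {len(candidates)} ({candidates})")
    cid = candidates[0]
    residues = [r.copy() for r in complex_.chains[cid]]
    for i, res in enumerate(residues, start=1):
        res.number = i
        res.icode = ""
    return Structure(f"{complex_.id}_peptide", {cid: residues},
                     complex_.resolution)


def select_groove(structure: Structure, groove_def: GrooveDefinition,
                  chain_id: str | None = None) -> list[Residue]:
    """Residues at the groove numbers, in definition order."""
    cid = chain_id or heavy_chain_id(structure)
    by_number = {r.number: r for r in structure.chains[cid]}
    out = []
    for num in groove_def.residue_numbers:
        if num not in by_number:
            raise ValueError(
                f"{structure.id}: groove residue {num} missing from chain {cid}")
        out.append(by_number[num])
    return out


def validate_complex(complex_: Structure,
                     strict_nonamer: bool = True) -> tuple[bool, list[str]]:
    """Apply the benchmark-set curation filters to a p-HLA complex.

    Rejects gapped peptides, non-standard residue names, residues missing
    heavy atoms relative to the canonical set, and (in strict mode, the
    default) any peptide length other than 9.  Returns (accepted, reasons).
    """
    reasons: list[str] = []
    candidates = _peptide_candidates(complex_)
    if len(candidates) != 1:
        return False, [f"expected one peptide-length chain, found {len(candidates)}"]
    peptide = complex_.chains[candidates[0]]
    if strict_nonamer and len(peptide) != 9:
        reasons.append(f"peptide length {len(peptide)} != 9 (strict nonamer mode)")
    numbers = [r.number for r in peptide]
    if any(b - a != 1 for a, b in zip(numbers, numbers[1:])):
        reasons.append("gapped: peptide residue numbering is not consecutive")
    for res in peptide:
        if res.name not in STANDARD_RESIDUES:
            reasons.append(f"non-standard residue {res.name} at {res.number}")
            continue
        missing = [n for n in CANONICAL_HEAVY_ATOMS[res.name]
                   if not res.has_atom(n)]
        if missing:
            reasons.append(
                f"incomplete residue {res.name}{res.number}: missing {missing}")
    return (not reasons), reasons
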