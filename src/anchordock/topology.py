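"""Amino-acid heavy-atom topology and idealized side-chain construction.

Each side-chain heavy atom is defined in internal coordinates relative to
three previously placed atoms: ``(atom, a, b, c, bond, angle, torsion)``
where ``torsion`` is either a fixed value (float), ``("chi", k)`` for the
k-th rotatable angle, or ``("chi", k, offset)`` for branch atoms placed at
a fixed offset from chi_k.  Bond lengths in Angstrom, angles in degrees;
values are idealized textbook geometry, adequate for template threading
and rotamer packing (crystallographic accuracy is not the goal here).
"""

from __future__ import annotations

import numpy as np

from .geometry import nerf_place

BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

# CB placement shared by all non-glycine residues: dihedral(C, N, CA, CB)
# chosen to give L-chirality at CA.
_CB = ("CB", "C", "N", "CA", 1.530, 110.5, -122.5)

Chi = tuple  # alias for readability in the table below

SIDE_CHAIN_TOPOLOGY: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", "N", "CA", "CB", 1.417, 110.8, ("chi", 1))],
    "CYS": [_CB, ("SG", "N", "CA", "CB", 1.808, 113.8, ("chi", 1))],
    "THR": [_CB,
            ("OG1", "N", "CA", "CB", 1.433, 109.6, ("chi", 1)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0))],
    "VAL": [_CB,
            ("CG1", "N", "CA", "CB", 1.527, 110.5, ("chi", 1)),
            ("CG2", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 122.0))],
    "LEU": [_CB,
            ("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1)),
            ("CD1", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2)),
            ("CD2", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 122.0))],
    "ILE": [_CB,
            ("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -122.0)),
            ("CD1", "CA", "CB", "CG1", 1.513, 113.9, ("chi", 2))],
    "PRO": [_CB,
            ("CG", "N", "CA", "CB", 1.492, 104.5, ("chi", 1)),
            ("CD", "CA", "CB", "CG", 1.503, 106.1, ("chi", 2))],
    "MET": [_CB,
            ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1)),
            ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2)),
            ("CE", "CB", "CG", "SD", 1.791, 100.8, ("chi", 3))],
    "PHE": [_CB,
            ("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1)),
            ("CD1", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2)),
            ("CD2", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.382, 120.8, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.382, 120.8, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0)],
    "TYR": [_CB,
            ("CG", "N", "CA", "CB", 1.512, 113.9, ("chi", 1)),
            ("CD1", "CA", "CB", "CG", 1.389, 120.8, ("chi", 2)),
            ("CD2", "CA", "CB", "CG", 1.389, 120.8, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.382, 121.1, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.382, 121.1, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.378, 119.5, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.376, 119.8, 180.0)],
    "TRP": [_CB,
            ("CG", "N", "CA", "CB", 1.498, 113.6, ("chi", 1)),
            ("CD1", "CA", "CB", "CG", 1.365, 126.9, ("chi", 2)),
            ("CD2", "CA", "CB", "CG", 1.433, 126.7, ("chi", 2, 180.0)),
            ("NE1", "CB", "CG", "CD1", 1.375, 110.2, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.409, 107.3, 180.0),
            ("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
            ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
            ("CZ3", "CG", "CD2", "CE3", 1.382, 118.6, 180.0),
            ("CH2", "CD2", "CE2", "CZ2", 1.368, 117.5, 0.0)],
    "ASP": [_CB,
            ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1)),
            ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2)),
            ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 180.0))],
    "ASN": [_CB,
            ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1)),
            ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2)),
            ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi", 2, 180.0))],
    "GLU": [_CB,
            ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2)),
            ("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3)),
            ("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 180.0))],
    "GLN": [_CB,
            ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2)),
            ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3)),
            ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi", 3, 180.0))],
    "LYS": [_CB,
            ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2)),
            ("CE", "CB", "CG", "CD", 1.520, 111.7, ("chi", 3)),
            ("NZ", "CG", "CD", "CE", 1.489, 111.9, ("chi", 4))],
    "ARG": [_CB,
            ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2)),
            ("NE", "CB", "CG", "CD", 1.460, 111.5, ("chi", 3)),
            ("CZ", "CG", "CD", "NE", 1.330, 124.2, ("chi", 4)),
            ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0)],
    "HIS": [_CB,
            ("CG", "N", "CA", "CB", 1.492, 113.8, ("chi", 1)),
            ("ND1", "CA", "CB", "CG", 1.378, 122.7, ("chi", 2)),
            ("CD2", "CA", "CB", "CG", 1.356, 131.0, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "ND1", 1.321, 109.3, 180.0),
            ("NE2", "CB", "CG", "CD2", 1.374, 107.2, 180.0)],
}

#: number of rotatable chi angles per residue type
N_CHI = {name: max([t[6][1] for t in atoms if isinstance(t[6], tuple)],
                   default=0)
         for name, atoms in SIDE_CHAIN_TOPOLOGY.items()}

#: full canonical heavy-atom complement per residue type
CANONICAL_HEAVY_ATOMS = {
    name: tuple(BACKBONE_ATOMS) + tuple(t[0] for t in atoms)
    for name, atoms in SIDE_CHAIN_TOPOLOGY.items()
}


def element_of(atom_name: str) -> str:
    """Element symbol from a PDB heavy-atom name (first non-digit char)."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def build_side_chain(res_name: str, backbone: dict[str, np.ndarray],
                     chis: tuple[float, ...]) -> dict[str, np.ndarray]:
    """Construct idealized side-chain heavy atoms onto a backbone.

    ``backbone`` must contain N, CA, C coordinates.  Returns the new atoms
    (CB onward) as a name -> coordinate dict; GLY yields an empty dict.
    """
    if res_name not in SIDE_CHAIN_TOPOLOGY:
        raise ValueError(f"non-standard residue {res_name!r}")
    needed = N_CHI[res_name]
    if len(chis) < needed:
        raise ValueError(
            f"{res_name} needs {needed} chi angles, got {len(chis)}")
    placed: dict[str, np.ndarray] = dict(backbone)
    out: dict[str, np.ndarray] = {}
    for atom, a, b, c, bond, angle, tor in SIDE_CHAIN_TOPOLOGY[res_name]:
        if isinstance(tor, tuple):
            torsion = chis[tor[1] - 1] + (tor[2] if len(tor) > 2 else 0.0)
        else:
            torsion = tor
        xyz = nerf_place(placed[a], placed[b], placed[c], bond, angle, torsion)
        placed[atom] = xyz
        out[atom] = xyz
    return out
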