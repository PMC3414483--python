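"""Deterministic synthetic fixtures: a mini-groove and bound peptides.

The generated receptor is an idealized stand-in for the class I binding
groove — two parallel poly-alanine helical walls flanking a strand floor,
enclosing a cavity about 32 A long with backbone hydrogen-bond partners
near both ends — not a physically realistic HLA fold.  Residues carry the
real A*02:01 groove numbering so every selection code path runs
unchanged.  All generators are pure functions of their spec: the same
seed reproduces bit-identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import (ALPHA_HELIX, BETA_STRAND, build_backbone,
                       principal_axis_frame)
from .pepmodel import RotamerLibrary, place_side_chains
from .structio import Atom, Residue, Structure
from .topology import ONE_TO_THREE, build_side_chain

__all__ = ["FixtureSpec", "generate_groove", "generate_bound_peptide",
           "generate_complex", "generate_ensemble", "generate_score_dataset",
           "end_pocket_centroids"]

DEFAULT_SEQUENCE = "ILKEPVHGV"

# segment layout: (residue numbers, secondary structure, y, z)
_HELIX1_NUMBERS = tuple(range(55, 85))       # covers alpha1 groove residues
_HELIX2_NUMBERS = tuple(range(142, 172))     # covers alpha2 groove residues
_STRAND1_NUMBERS = (4, 5, 6, 7, 8, 9, 26, 45, 97, 98)
_STRAND2_NUMBERS = (99, 100, 114, 115, 116, 123, 124, 133, 134, 135)
_POCKET_N_NUMBERS = (1, 2)       # raised ledge past the N-terminal end
_POCKET_C_NUMBERS = (179, 180)   # raised ledge past the C-terminal end

POCKET_N_RESIDUES = _POCKET_N_NUMBERS
POCKET_C_RESIDUES = _POCKET_C_NUMBERS

_CAVITY_CENTER_X = 14.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions."""
    seed: int = 0
    n_structures: int = 10
    coordinate_noise_sigma: float = 0.3   # A
    peptide_sequences: tuple[str, ...] = (DEFAULT_SEQUENCE,)
    groove_variant: str = "default"


def _segment(numbers, phi_psi, y, z, res_name="ALA",
             center_x=_CAVITY_CENTER_X):
    n = len(numbers)
    bb = build_backbone([phi_psi] * n)
    ca = np.array([r["CA"] for r in bb])
    rot, centroid = principal_axis_frame(ca)
    offset = np.array([center_x, y, z])
    residues = []
    for num, r in zip(numbers, bb):
        atoms = []
        placed = {}
        for name in ("N", "CA", "C", "O"):
            xyz = (r[name] - centroid) @ rot.T + offset
            placed[name] = xyz
            atoms.append(Atom(name, name[0], xyz))
        if res_name != "GLY":
            cb = build_side_chain(res_name, placed, ())["CB"]
            atoms.append(Atom("CB", "C", cb))
        residues.append(Residue(res_name, num, "", atoms))
    return residues


_LEDGE_LOCAL = {
    "N": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([1.458, 0.0, 0.0]),
    "C": np.array([2.009, 1.422, 0.0]),
    "O": np.array([3.223, 1.628, 0.0]),
}
_LEDGE_Z = -2.3


def _pocket_ledge(numbers, x0: float) -> list[Residue]:
    """Two isolated glycines forming a hydrogen-bond ledge at a cavity end.

    The local residue frame runs along +x with the carbonyl O at the +x
    end and the amide N at the -x end, so a single placement offers an
    acceptor toward one cavity end and a donor toward the other.  The
    pair straddles the cavity axis at y = +/-1.75 (the second residue is
    mirrored in y so both polar faces converge on the axis).
    """
    out = []
    for k, (num, y0) in enumerate(zip(numbers, (-1.75, 1.75))):
        atoms = []
        for name in ("N", "CA", "C", "O"):
            local = _LEDGE_LOCAL[name].copy()
            if k == 1:
                local[1] *= -1.0
            atoms.append(Atom(name, name[0],
                              local + np.array([x0, y0, _LEDGE_Z])))
        out.append(Residue("GLY", num, "", atoms))
    return out


def generate_groove(spec: FixtureSpec = FixtureSpec()) -> Structure:
    """Idealized rigid receptor groove with A*02:01 residue numbering.

    Two 30-residue helical walls at y = +/-7 flank a two-strand floor at
    z = -3.6; all 37 default groove residue numbers resolve.  The
    construction is deterministic (the spec seed only matters for the
    noise/ensemble generators).
    """
    if spec.groove_variant != "default":
        raise ValueError(f"unknown groove variant {spec.groove_variant!r}")
    residues = []
    # glycine floor: flat, backbone-only, no side chains poking into the cavity
    residues += _segment(_STRAND1_NUMBERS, BETA_STRAND, -1.8, -4.3, "GLY")
    residues += _segment(_STRAND2_NUMBERS, BETA_STRAND, +1.8, -4.3, "GLY")
    residues += _segment(_HELIX1_NUMBERS, ALPHA_HELIX, -10.0, 0.8)
    residues += _segment(_HELIX2_NUMBERS, ALPHA_HELIX, +10.0, 0.8)
    # raised ledges just past the cavity ends: the designated hydrogen-bond
    # partners (backbone N/O) for the peptide termini / anchor residues
    residues += _pocket_ledge(_POCKET_N_NUMBERS, x0=-5.55)  # O faces cavity
    residues += _pocket_ledge(_POCKET_C_NUMBERS, x0=30.65)  # N faces cavity
    # residues stay in segment build order: chain adjacency == spatial
    # connectivity (author numbers jump within a segment by design)
    return Structure("fixture_groove", {"A": residues})


def end_pocket_centroids(groove: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Centroids of the pockets' hydrogen-bond partner atoms.

    The N-end pocket offers carbonyl O acceptors; the C-end pocket amide
    N donors.  Their centroids measure the usable cavity length.
    """
    by_num = {r.number: r for r in groove.chains["A"]}
    def _centroid(nums, atom):
        return np.mean([by_num[n].atom(atom).coords for n in nums], axis=0)
    return (_centroid(POCKET_N_RESIDUES, "O"),
            _centroid(POCKET_C_RESIDUES, "N"))


def canonical_peptide_backbone() -> list[dict[str, np.ndarray]]:
    """The fixed 9-mer arc backbone shared by every fixture peptide."""
    bb = build_backbone([BETA_STRAND] * 9)
    ca = np.array([r["CA"] for r in bb])
    rot, centroid = principal_axis_frame(ca)
    offset = np.array([_CAVITY_CENTER_X, 0.0, -0.4])
    out = []
    for r in bb:
        out.append({name: (xyz - centroid) @ rot.T + offset
                    for name, xyz in r.items()})
    return out


def generate_bound_peptide(spec: FixtureSpec, groove: Structure,
                           sequence: str | None = None,
                           rotamer_lib: RotamerLibrary | None = None
                           ) -> Structure:
    """A 9-mer on the canonical arc backbone, side chains packed in situ.

    Different sequences share the identical backbone (the template
    property the docking pipeline relies on).
    """
    sequence = sequence or spec.peptide_sequences[0]
    if len(sequence) != 9:
        raise ValueError(f"sequence length {len(sequence)} != 9")
    backbone = canonical_peptide_backbone()
    residues = []
    for i, (ch, bb) in enumerate(zip(sequence, backbone), start=1):
        name = ONE_TO_THREE[ch]
        atoms = [Atom(n, n[0], bb[n]) for n in ("N", "CA", "C", "O")]
        residues.append(Residue(name, i, "", atoms))
    pep = Structure(f"fixture_pep_{sequence}", {"C": residues})
    return place_side_chains(pep, sequence, rotamer_lib, environment=groove)


def generate_complex(spec: FixtureSpec = FixtureSpec(),
                     sequence: str | None = None,
                     resolution: float | None = 2.0) -> Structure:
    """Groove plus bound peptide as a two-chain p-HLA style complex."""
    groove = generate_groove(spec)
    pep = generate_bound_peptide(spec, groove, sequence)
    sequence = sequence or spec.peptide_sequences[0]
    (pc,) = pep.chains
    return Structure(f"fixture_{sequence}",
                     {"A": [r.copy() for r in groove.chains["A"]],
                      "C": [r.copy() for r in pep.chains[pc]]},
                     resolution)


def generate_ensemble(spec: FixtureSpec) -> list[Structure]:
    """Noisy, rigidly displaced copies of the fixture complex.

    Each copy receives i.i.d. Gaussian coordinate noise of width
    ``coordinate_noise_sigma`` plus a random rigid motion (which the
    superposition stage removes).
    """
    if spec.n_structures < 2:
        raise ValueError("n_structures must be >= 2")
    rng = np.random.default_rng(spec.seed)
    base = generate_complex(spec)
    out = []
    for k in range(spec.n_structures):
        copy = base.copy()
        copy.id = f"{base.id}_{k:03d}"
        coords = copy.coords_array()
        coords = coords + rng.normal(0.0, spec.coordinate_noise_sigma,
                                     coords.shape)
        rot = Rotation.from_rotvec(rng.normal(0.0, 1.0, 3)).as_matrix()
        shift = rng.uniform(-20.0, 20.0, 3)
        copy.set_coords(coords @ rot.T + shift)
        out.append(copy)
    return out


def generate_score_dataset(n_bind: int = 500, n_non: int = 500,
                           mu_bind: float = -50.0, mu_non: float = -20.0,
                           sd: float = 4.0, seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Labeled Gaussian score draws emulating binder/non-binder dG pools.

    Returns (scores, is_binder).  Lower scores mean stronger predicted
    binding, matching the free-energy convention.
    """
    if n_bind < 1 or n_non < 1:
        raise ValueError("need at least one draw per class")
    rng = np.random.default_rng(seed)
    scores = np.concatenate([rng.normal(mu_bind, sd, n_bind),
                             rng.normal(mu_non, sd, n_non)])
    labels = np.concatenate([np.ones(n_bind, dtype=bool),
                             np.zeros(n_non, dtype=bool)])
    return scores, labels
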