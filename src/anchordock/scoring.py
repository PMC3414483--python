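"""Geometric interaction scoring: soft van der Waals and hydrogen bonds.

These fast, parameter-light scores drive side-chain packing and the
rigid-body pose refinement.  Hydrogen bonds are detected at the heavy-atom
level: donor-acceptor distance 2.6-3.4 A with an antecedent-donor-acceptor
angle above 120 degrees (polar hydrogens are implicit).  The van der Waals
part is a shifted 12-6 Lennard-Jones capped at +10 kcal/mol per pair, so a
clash is penalized but never infinite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import data as _data
from .structio import Residue, Structure
from .topology import element_of

__all__ = ["AtomView", "atom_view", "soft_vdw", "hbond_energy",
           "count_hbonds", "HBOND_DMIN", "HBOND_DMAX", "HBOND_MIN_ANGLE",
           "HBOND_WELL", "VDW_CAP"]

HBOND_DMIN = 2.6
HBOND_DMAX = 3.4
HBOND_MIN_ANGLE = 120.0   # degrees
HBOND_WELL = -1.0         # kcal/mol per satisfied pair
VDW_CAP = 10.0            # kcal/mol per pair

_DONOR_NAMES = {"OG", "OG1", "OH"}          # hydroxyl donors
_NON_DONOR_N = set()                         # PRO N handled via residue name


def _lj_tables():
    df = _data.load_lj_types()
    return ({r.element: r.eps for r in df.itertuples()},
            {r.element: r.rmin_half for r in df.itertuples()})

_EPS_BY_EL, _RMH_BY_EL = _lj_tables()


@dataclass
class AtomView:
    """Flat arrays over a set of residues, with H-bond role masks."""
    coords: np.ndarray
    eps: np.ndarray
    rmin_half: np.ndarray
    donor_mask: np.ndarray
    acceptor_mask: np.ndarray
    antecedent: np.ndarray   # coords of the donor's bonded heavy neighbour

    def __len__(self):
        return len(self.coords)


def atom_view(source: Structure | list[Residue]) -> AtomView:
    """Build an :class:`AtomView` from a structure or residue list."""
    residues: list[Residue]
    if isinstance(source, Structure):
        residues = [r for ch in source.chains.values() for r in ch]
    else:
        residues = list(source)
    coords, eps, rmh, donor, acceptor, antecedent = [], [], [], [], [], []
    for res in residues:
        res_coords = {a.name: a.coords for a in res.atoms}
        for atom in res.atoms:
            el = atom.element or element_of(atom.name)
            coords.append(atom.coords)
            eps.append(_EPS_BY_EL.get(el, 0.1))
            rmh.append(_RMH_BY_EL.get(el, 1.8))
            is_donor = ((el == "N" and res.name != "PRO")
                        or atom.name in _DONOR_NAMES)
            is_acceptor = el == "O"
            donor.append(is_donor)
            acceptor.append(is_acceptor)
            if is_donor:
                # nearest covalent heavy neighbour within the residue
                best, best_d = atom.coords, np.inf
                for nm, xyz in res_coords.items():
                    if nm == atom.name:
                        continue
                    d = np.linalg.norm(xyz - atom.coords)
                    if d < 1.7 and d < best_d:
                        best, best_d = xyz, d
                antecedent.append(best)
            else:
                antecedent.append(atom.coords)
    return AtomView(np.asarray(coords, dtype=float).reshape(-1, 3),
                    np.asarray(eps), np.asarray(rmh),
                    np.asarray(donor, dtype=bool),
                    np.asarray(acceptor, dtype=bool),
                    np.asarray(antecedent, dtype=float).reshape(-1, 3))


def soft_vdw(a: AtomView, b: AtomView,
             coords_a: np.ndarray | None = None,
             coords_b: np.ndarray | None = None) -> float:
    """Capped shifted-LJ interaction energy between two atom sets."""
    xa = a.coords if coords_a is None else coords_a
    xb = b.coords if coords_b is None else coords_b
    if len(xa) == 0 or len(xb) == 0:
        return 0.0
    d = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=-1))
    d = np.maximum(d, 0.4)
    rmin = a.rmin_half[:, None] + b.rmin_half[None, :]
    epsij = np.sqrt(a.eps[:, None] * b.eps[None, :])
    sr6 = (rmin / d) ** 6
    e = epsij * (sr6 ** 2 - 2.0 * sr6)
    return float(np.minimum(e, VDW_CAP).sum())


def _hbond_matrix(donor_view: AtomView, acceptor_view: AtomView,
                  donor_coords: np.ndarray | None = None,
                  acceptor_coords: np.ndarray | None = None) -> np.ndarray:
    xd_all = donor_view.coords if donor_coords is None else donor_coords
    xa_all = acceptor_view.coords if acceptor_coords is None else acceptor_coords
    dm = donor_view.donor_mask
    am = acceptor_view.acceptor_mask
    if not dm.any() or not am.any():
        return np.zeros((0, 0), dtype=bool)
    xd = xd_all[dm]
    ante = donor_view.antecedent[dm]
    if donor_coords is not None:
        # antecedents move rigidly with the donors only for rigid motions;
        # recompute offset assuming the same displacement per atom
        ante = ante + (xd - donor_view.coords[dm])
    xa = xa_all[am]
    diff = xa[None, :, :] - xd[:, None, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    ok_dist = (dist >= HBOND_DMIN) & (dist <= HBOND_DMAX)
    u = ante - xd
    nu = np.linalg.norm(u, axis=1, keepdims=True)
    nu[nu == 0] = 1.0
    u = u / nu
    cosang = (diff * u[:, None, :]).sum(axis=-1) / np.maximum(dist, 1e-9)
    # angle(antecedent, donor, acceptor) > 120 deg  <=>  cos < cos(120)
    ok_ang = cosang < np.cos(np.deg2rad(HBOND_MIN_ANGLE))
    return ok_dist & ok_ang


def count_hbonds(a: AtomView, b: AtomView,
                 coords_a: np.ndarray | None = None,
                 coords_b: np.ndarray | None = None) -> int:
    """Satisfied donor-acceptor pairs between two sets (both directions)."""
    m1 = _hbond_matrix(a, b, coords_a, coords_b)
    m2 = _hbond_matrix(b, a, coords_b, coords_a)
    return int(m1.sum()) + int(m2.sum())


def hbond_energy(a: AtomView, b: AtomView,
                 coords_a: np.ndarray | None = None,
                 coords_b: np.ndarray | None = None) -> float:
    return HBOND_WELL * count_hbonds(a, b, coords_a, coords_b)
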