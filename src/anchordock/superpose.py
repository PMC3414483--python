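"""Peptide-excluded superposition and per-position RMSD analytics.

The conservation analysis mirrors the standard workflow for p-HLA
ensembles: all complexes are rigidly superposed on the HLA heavy chain
(the bound peptide is excluded from the fit), then pairwise per-residue
RMSDs are summarized position by position — for the groove residues, and,
after mapping peptides through their complex's transform, for peptide
positions P1..P9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structio import Structure, Residue, extract_peptide, heavy_chain_id
from .topology import BACKBONE_ATOMS

__all__ = ["RigidTransform", "ConservationTable", "kabsch",
           "superpose_complexes", "per_position_rmsd", "peptide_variability"]


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation (Angstrom)."""
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det} != +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class ConservationTable:
    """Per-position summary of pairwise RMSDs across an ensemble.

    ``table`` is indexed by position with columns n_pairs, mean, median,
    q1, q3, min, max; ``pairwise`` retains the raw per-pair values;
    ``outliers`` lists (i, j, rmsd) pairs outside 1.5 x IQR.
    """
    table: pd.DataFrame
    pairwise: dict[int, np.ndarray]
    outliers: dict[int, list[tuple[int, int, float]]]


def kabsch(ref_coords: np.ndarray,
           mob_coords: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid transform mapping mobile onto reference.

    Returns the transform and the minimized RMSD.  Requires two
    equal-length sets of >= 3 non-collinear points.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mob = np.asarray(mob_coords, dtype=float)
    if ref.shape != mob.shape:
        raise ValueError(f"point count mismatch: {ref.shape} vs {mob.shape}")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 points")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    a = ref - ref_c
    b = mob - mob_c
    if (np.linalg.matrix_rank(a, tol=1e-8) < 2
            or np.linalg.matrix_rank(b, tol=1e-8) < 2):
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(a, b)
    rmat = rot.as_matrix()
    transform = RigidTransform(rmat, ref_c - rmat @ mob_c)
    return transform, float(rssd / np.sqrt(ref.shape[0]))


def _selection_atoms(res: Residue, selection: str) -> list[str]:
    if selection == "backbone":
        return [n for n in BACKBONE_ATOMS if res.has_atom(n)]
    if selection == "allatom":
        return [a.name for a in res.atoms]
    raise ValueError(f"unknown selection {selection!r}")


def _matched_coords(ref: Structure, mob: Structure, selection: str,
                    exclude_peptide: bool) -> tuple[np.ndarray, np.ndarray]:
    ref_cid = heavy_chain_id(ref) if exclude_peptide else None
    mob_cid = heavy_chain_id(mob) if exclude_peptide else None
    ref_chains = [ref_cid] if exclude_peptide else list(ref.chains)
    ref_pts, mob_pts = [], []
    for i, rcid in enumerate(ref_chains):
        mcid = mob_cid if exclude_peptide else list(mob.chains)[i]
        mob_by_num = {r.number: r for r in mob.chains[mcid]}
        for rres in ref.chains[rcid]:
            mres = mob_by_num.get(rres.number)
            if mres is None:
                continue
            for name in _selection_atoms(rres, selection):
                if mres.has_atom(name):
                    ref_pts.append(rres.atom(name).coords)
                    mob_pts.append(mres.atom(name).coords)
    return np.array(ref_pts), np.array(mob_pts)


def superpose_complexes(ref: Structure, mobile: Structure,
                        selection: str = "backbone",
                        exclude_peptide: bool = True
                        ) -> tuple[Structure, RigidTransform, float]:
    """Superpose ``mobile`` onto ``ref`` using HLA heavy-chain atoms only.

    Residues are matched by author residue number on the heavy chain.
    Returns the transformed copy, the transform and the fit RMSD.
    """
    ref_pts, mob_pts = _matched_coords(ref, mobile, selection, exclude_peptide)
    if len(ref_pts) < 3:
        raise ValueError(
            f"{mobile.id} vs {ref.id}: fewer than 3 matched atoms")
    transform, rmsd = kabsch(ref_pts, mob_pts)
    moved = mobile.copy()
    moved.set_coords(transform.apply(moved.coords_array()))
    return moved, transform, rmsd


def _summarize(values_per_pos: dict[int, np.ndarray]) -> ConservationTable:
    rows, outliers = [], {}
    for pos, vals in values_per_pos.items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        out_idx = np.nonzero((vals < lo) | (vals > hi))[0]
        outliers[pos] = [(-1, int(k), float(vals[k])) for k in out_idx]
        rows.append({"position": pos, "n_pairs": len(vals),
                     "mean": vals.mean(), "median": med, "q1": q1, "q3": q3,
                     "min": vals.min(), "max": vals.max()})
    table = pd.DataFrame(rows).set_index("position")
    return ConservationTable(table, values_per_pos, outliers)


def _pairwise_table(residue_sets: list[dict[int, Residue]],
                    positions: list[int], selection: str) -> ConservationTable:
    n = len(residue_sets)
    values: dict[int, list[float]] = {p: [] for p in positions}
    pair_ids: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            pair_ids.append((i, j))
            for pos in positions:
                ri, rj = residue_sets[i][pos], residue_sets[j][pos]
                names = [nm for nm in _selection_atoms(ri, selection)
                         if rj.has_atom(nm)]
                if not names:
                    raise ValueError(f"no matched atoms at position {pos}")
                d = ri.coords(tuple(names)) - rj.coords(tuple(names))
                values[pos].append(float(np.sqrt((d ** 2).sum(axis=1).mean())))
    result = _summarize({p: np.asarray(v) for p, v in values.items()})
    # record true pair indices for the outliers
    for pos, lst in result.outliers.items():
        result.outliers[pos] = [(pair_ids[k][0], pair_ids[k][1], v)
                                for (_, k, v) in lst]
    return result


def per_position_rmsd(structures: list[Structure], positions: list[int],
                      selection: str = "backbone",
                      chain_ids: list[str] | None = None) -> ConservationTable:
    """Pairwise per-position RMSD across superposed structures.

    No fitting happens here: coordinates are compared as given, so the
    caller superposes first.  Every listed position must resolve in every
    structure (matched by author residue number on the heavy chain).
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    residue_sets = []
    for k, s in enumerate(structures):
        cid = chain_ids[k] if chain_ids else heavy_chain_id(s)
        by_num = {r.number: r for r in s.chains[cid]}
        for p in positions:
            if p not in by_num:
                raise ValueError(f"{s.id}: position {p} absent")
        residue_sets.append(by_num)
    return _pairwise_table(residue_sets, list(positions), selection)


def peptide_variability(structures: list[Structure],
                        transforms: list[RigidTransform],
                        selection: str = "backbone") -> ConservationTable:
    """Per-position variability of bound peptides in a common frame.

    Each complex's peptide is mapped through the transform obtained from
    its peptide-excluded superposition, then pairwise backbone RMSDs are
    summarized over P1..Pn.
    """
    if len(structures) != len(transforms):
        raise ValueError("one transform per structure required")
    peptides = []
    lengths = set()
    for s, t in zip(structures, transforms):
        pep = extract_peptide(s)
        pep.set_coords(t.apply(pep.coords_array()))
        (cid,) = pep.chains
        peptides.append({r.number: r for r in pep.chains[cid]})
        lengths.add(len(pep.chains[cid]))
    if len(lengths) != 1:
        raise ValueError(f"peptide length mismatch across set: {sorted(lengths)}")
    positions = sorted(peptides[0])
    return _pairwise_table(peptides, positions, selection)
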