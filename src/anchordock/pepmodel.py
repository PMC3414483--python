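"""Template-based construction of nonameric peptides from sequence.

Bound nonamers superpose onto an essentially shared backbone whose P1
residue dominates N-terminal packing, so modeling a peptide reduces to:
pick the template whose P1 matches (or is structurally closest to) the
target's first residue, relabel its backbone with the target sequence,
and pack side chains from a rotamer library against the peptide itself
and an optional receptor reference frame.  A short conjugate-gradient
minimization regularizes the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import data as _data
from .energy import ForceFieldParams, minimize_cartesian
from .scoring import atom_view, hbond_energy, soft_vdw
from .structio import Residue, Structure, extract_peptide, validate_complex
from .superpose import superpose_complexes
from .topology import (BACKBONE_ATOMS, CANONICAL_HEAVY_ATOMS, N_CHI,
                       ONE_TO_THREE, THREE_TO_ONE, build_side_chain)

__all__ = ["RotamerLibrary", "TemplateLibrary", "PlacementError",
           "DEFAULT_UNSEEN_MAP", "build_template_library", "map_p1",
           "thread_sequence", "place_side_chains", "build_peptide",
           "anchor_coords", "ANCHOR_POSITIONS"]

ANCHOR_POSITIONS = (1, 2, 9)

#: unseen P1 residues mapped to the closest observed template by heavy-atom
#: count / volume similarity (user-overridable)
DEFAULT_UNSEEN_MAP = {"H": "F", "W": "Y", "D": "N", "E": "M",
                      "Q": "M", "P": "A", "C": "S"}

CLASH_HARD = 1.5   # A; no rotamer may approach context closer than this
CLASH_REPAIR = 2.4  # A; side chains closer than this trigger the repair sweep


class PlacementError(RuntimeError):
    """No clash-free rotamer exists at some position."""


@dataclass(frozen=True)
class RotamerLibrary:
    """Backbone-independent rotamer library: chi tuples with priors."""
    rotamers: dict  # res_name(3-letter) -> list[(chis tuple, prior)]

    @staticmethod
    def default() -> "RotamerLibrary":
        df = _data.load_rotamer_rows()
        lib: dict[str, list[tuple[tuple[float, ...], float]]] = {}
        for row in df.itertuples():
            chis = tuple(float(getattr(row, f"chi{k}"))
                         for k in range(1, 5)
                         if not np.isnan(getattr(row, f"chi{k}", np.nan)))
            lib.setdefault(row.residue, []).append((chis, float(row.prior)))
        for name, rots in lib.items():
            total = sum(p for _, p in rots)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name}: rotamer priors sum to {total}")
            for chis, _ in rots:
                if any(not (-180.0 < c <= 180.0) for c in chis):
                    raise ValueError(f"{name}: chi out of (-180, 180]")
            rots.sort(key=lambda t: -t[1])
        return RotamerLibrary(lib)

    def for_residue(self, res_name: str):
        if res_name not in self.rotamers:
            raise KeyError(f"no rotamers for {res_name!r}")
        return self.rotamers[res_name]


@dataclass
class P1Template:
    peptide: Structure       # backbone + P1 side chain, stubs stripped
    source_id: str
    resolution: float | None


@dataclass
class TemplateLibrary:
    p1_templates: dict[str, P1Template]
    consensus_anchor: np.ndarray             # (12, 3): N,CA,C,O at P1,P2,P9
    unseen_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_UNSEEN_MAP))


def anchor_coords(peptide: Structure) -> np.ndarray:
    """Backbone coordinates at P1, P2, P9 in fixed atom order (12 x 3)."""
    (cid,) = peptide.chains
    by_num = {r.number: r for r in peptide.chains[cid]}
    rows = []
    for pos in ANCHOR_POSITIONS:
        if pos not in by_num:
            raise ValueError(f"anchor position P{pos} missing")
        res = by_num[pos]
        for name in BACKBONE_ATOMS:
            rows.append(res.atom(name).coords)
    return np.array(rows)


def _strip_to_backbone(res: Residue, keep_cb: bool = False) -> None:
    keep = set(BACKBONE_ATOMS) | ({"CB"} if keep_cb else set())
    res.atoms = [a for a in res.atoms if a.name in keep]


def build_template_library(complexes: list[Structure],
                           align: bool = True) -> TemplateLibrary:
    """Derive P1-keyed templates and the consensus anchor backbone.

    For each P1 residue present, the highest-resolution example's peptide
    is kept (resolution ties broken by structure id order) with positions
    2-9 stripped to backbone.  The consensus anchor is the arithmetic
    mean of the P1/P2/P9 backbone coordinates over all complexes, taken
    in the common peptide-excluded superposed frame.
    """
    if not complexes:
        raise ValueError("empty complex set")
    ordered = sorted(complexes, key=lambda s: s.id)
    for c in ordered:
        ok, reasons = validate_complex(c)
        if not ok:
            raise ValueError(f"{c.id}: invalid complex: {reasons}")
    ref = ordered[0]
    peptides: list[tuple[Structure, str, float | None]] = []
    for c in ordered:
        if align and c is not ref:
            moved, _, _ = superpose_complexes(ref, c)
        else:
            moved = c.copy()
        peptides.append((extract_peptide(moved), c.id, c.resolution))
    consensus = np.mean([anchor_coords(p) for p, _, _ in peptides], axis=0)

    best: dict[str, tuple[Structure, str, float | None]] = {}
    for pep, cid, resol in peptides:
        (chain,) = pep.chains
        p1 = THREE_TO_ONE[pep.chains[chain][0].name]
        eff = resol if resol is not None else np.inf
        if p1 not in best:
            best[p1] = (pep, cid, resol)
        else:
            cur_eff = best[p1][2] if best[p1][2] is not None else np.inf
            if eff < cur_eff:  # id-order tie-break via stable iteration
                best[p1] = (pep, cid, resol)
    templates = {}
    for p1, (pep, cid, resol) in best.items():
        stripped = pep.copy()
        (chain,) = stripped.chains
        for res in stripped.chains[chain][1:]:
            _strip_to_backbone(res)
        templates[p1] = P1Template(stripped, cid, resol)
    return TemplateLibrary(templates, consensus)


def map_p1(residue: str, library: TemplateLibrary) -> str:
    """Template key for a P1 residue (one-letter code)."""
    if residue not in ONE_TO_THREE:
        raise ValueError(f"non-standard residue {residue!r}")
    if residue in library.p1_templates:
        return residue
    mapped = library.unseen_map.get(residue)
    if mapped is None or mapped not in library.p1_templates:
        raise KeyError(f"no template reachable for P1 residue {residue!r}")
    return mapped


def thread_sequence(sequence: str, library: TemplateLibrary) -> Structure:
    """Relabel the matching P1 template with the target sequence.

    Output has the full template backbone, the template's P1 side chain
    when P1 matches the template key (otherwise a CB stub), and CB stubs
    at positions 2-9.
    """
    if len(sequence) != 9:
        raise ValueError(f"sequence length {len(sequence)} != 9")
    for ch in sequence:
        if ch not in ONE_TO_THREE:
            raise ValueError(f"non-standard residue {ch!r} in sequence")
    key = map_p1(sequence[0], library)
    template = library.p1_templates[key]
    pep = template.peptide.copy()
    (cid,) = pep.chains
    residues = pep.chains[cid]
    for i, res in enumerate(residues):
        target = ONE_TO_THREE[sequence[i]]
        keep_p1_side_chain = (i == 0 and sequence[0] == key)
        if not keep_p1_side_chain:
            _strip_to_backbone(res)
            res.name = target
            if target != "GLY":
                bb = {n: res.atom(n).coords for n in ("N", "CA", "C")}
                cb = build_side_chain(target, bb, (0.0,) * 4)["CB"]
                from .structio import Atom
                res.atoms.append(Atom("CB", "C", cb))
        else:
            res.name = target
    pep.id = f"model_{sequence}"
    return pep


def _residue_complete(res: Residue) -> bool:
    return all(res.has_atom(n) for n in CANONICAL_HEAVY_ATOMS[res.name])


def _context_view(residues, environment, skip_index):
    ctx = [r for k, r in enumerate(residues) if k != skip_index]
    if environment is not None:
        ctx = ctx + [r for ch in environment.chains.values() for r in ch]
    return atom_view(ctx)


def _trial_residue(res: Residue, sc: dict) -> Residue:
    from .structio import Atom
    return Residue(res.name, res.number, res.icode,
                   [a for a in res.atoms if a.name in BACKBONE_ATOMS]
                   + [Atom(n, n[0], sc[n]) for n in sc])


def _rotamer_interaction(trial: Residue, ctx_view, mobile_names: set) -> tuple[float, bool]:
    """vdW + H-bond energy of the chi-dependent atoms (beyond CB) vs context.

    CB is chi-independent, so its interactions are a constant offset and
    are deliberately left out of the score and the clash test.
    """
    tview = atom_view([trial])
    mask = np.array([a.name in mobile_names for a in trial.atoms])
    if not mask.any() or len(ctx_view) == 0:
        return 0.0, False
    sub = AtomSubset(tview, mask)
    dmin = np.sqrt(((sub.coords[:, None, :]
                     - ctx_view.coords[None, :, :]) ** 2).sum(-1)).min()
    e = soft_vdw(sub, ctx_view) + hbond_energy(sub, ctx_view)
    return e, bool(dmin < CLASH_HARD)


def _best_rotamer(res: Residue, rotamers, ctx_view, w_rot: float):
    """Score every rotamer against the context; lowest wins."""
    bb = {n: res.atom(n).coords for n in ("N", "CA", "C", "O")}
    best = None
    for chis, prior in rotamers:
        sc = build_side_chain(res.name, bb, chis)
        trial = _trial_residue(res, sc) if sc else res
        mobile = set(sc) - {"CB"}
        e_int, clash = _rotamer_interaction(trial, ctx_view, mobile)
        e = -w_rot * np.log(prior) + e_int
        if not clash and (best is None or e < best[0]):
            best = (e, chis, trial)
    return best


class AtomSubset:
    """View restricted to a boolean mask (duck-types AtomView for vdW)."""

    def __init__(self, view, mask):
        self.coords = view.coords[mask]
        self.eps = view.eps[mask]
        self.rmin_half = view.rmin_half[mask]
        self.donor_mask = view.donor_mask[mask]
        self.acceptor_mask = view.acceptor_mask[mask]
        self.antecedent = view.antecedent[mask]

    def __len__(self):
        return len(self.coords)


def place_side_chains(peptide: Structure, sequence: str,
                      rotamer_lib: RotamerLibrary | None = None,
                      environment: Structure | None = None,
                      w_rot: float = 3.0) -> Structure:
    """Greedy N-to-C rotamer assignment with one clash-repair sweep.

    Each side chain minimizes  E = -w_rot ln(p) + E_vdw_soft + E_hbond
    against the peptide backbone, already-placed neighbours and the
    (optional) receptor reference frame.  Raises :class:`PlacementError`
    naming the position if no clash-free rotamer exists anywhere.
    """
    rotamer_lib = rotamer_lib or RotamerLibrary.default()
    out = peptide.copy()
    (cid,) = out.chains
    residues = out.chains[cid]
    if len(residues) != len(sequence):
        raise ValueError("sequence length does not match peptide")

    def _assign(i: int) -> None:
        res = residues[i]
        target = ONE_TO_THREE[sequence[i]]
        if res.name == target and _residue_complete(res):
            return
        res.name = target
        _strip_to_backbone(res)
        rotamers = rotamer_lib.for_residue(target)
        ctx = _context_view(residues, environment, i)
        best = _best_rotamer(res, rotamers, ctx, w_rot)
        if best is None:
            raise PlacementError(
                f"no clash-free rotamer at position P{i + 1} ({target})")
        residues[i] = best[2]

    for i in range(len(residues)):
        _assign(i)
    # repair sweep: re-optimize residues left in residual contacts
    for i in range(len(residues)):
        others = [r for k, r in enumerate(residues) if k != i]
        ov = atom_view(others)
        if len(ov) == 0:
            continue
        mine = atom_view([residues[i]])
        d = np.sqrt(((mine.coords[:, None, :] - ov.coords[None, :, :]) ** 2
                     ).sum(-1))
        if d.min() < CLASH_REPAIR and _residue_complete(residues[i]):
            res = residues[i].copy()
            _strip_to_backbone(res)
            rotamers = rotamer_lib.for_residue(res.name)
            ctx = _context_view(residues, environment, i)
            best = _best_rotamer(res, rotamers, ctx, w_rot)
            if best is not None:
                residues[i] = best[2]
    return out


def assignment_energy(peptide: Structure, rotamer_assignment: dict,
                      rotamer_lib: RotamerLibrary | None = None,
                      environment: Structure | None = None,
                      w_rot: float = 3.0) -> float:
    """Total packing score of an explicit rotamer assignment.

    ``rotamer_assignment`` maps 0-based position -> rotamer index into
    the library list for that residue type.  Uses the same decomposition
    the greedy packer accumulates: per-rotamer prior terms, each side
    chain's chi-dependent atoms against the static frame (backbones, CB
    stubs, environment) and each side-chain pair counted once.  Serves
    as the exhaustive-search reference on small cases.
    """
    rotamer_lib = rotamer_lib or RotamerLibrary.default()
    work = peptide.copy()
    (cid,) = work.chains
    residues = work.chains[cid]
    from .structio import Atom
    total = 0.0
    mobile_sets: dict[int, set] = {}
    for i in sorted(rotamer_assignment):
        res = residues[i]
        chis, prior = rotamer_lib.for_residue(res.name)[rotamer_assignment[i]]
        _strip_to_backbone(res)
        bb = {n: res.atom(n).coords for n in ("N", "CA", "C", "O")}
        sc = build_side_chain(res.name, bb, chis)
        for nm, xyz in sc.items():
            res.atoms.append(Atom(nm, nm[0], xyz))
        if "CB" not in sc and res.name != "GLY":
            pass
        mobile_sets[i] = set(sc) - {"CB"}
        total += -w_rot * np.log(prior)
    placed = sorted(rotamer_assignment)
    for idx, i in enumerate(placed):
        ctx_res = []
        for k, r in enumerate(residues):
            if k == i:
                continue
            if k in mobile_sets and k in placed[idx + 1:]:
                # later side chains enter as static backbone + CB only
                r = r.copy()
                _strip_to_backbone(r, keep_cb=True)
            ctx_res.append(r)
        if environment is not None:
            ctx_res += [r for ch in environment.chains.values() for r in ch]
        e, _ = _rotamer_interaction(residues[i], atom_view(ctx_res),
                                    mobile_sets[i])
        total += e
    return total


def build_peptide(sequence: str, library: TemplateLibrary,
                  rotamer_lib: RotamerLibrary | None = None,
                  receptor_frame: Structure | None = None,
                  params: ForceFieldParams | None = None,
                  minimize: bool = True,
                  min_maxiter: int = 30) -> Structure:
    """Full ab initio construction: thread, pack, minimize.

    Deterministic: identical sequence and library give identical
    coordinates.
    """
    pep = thread_sequence(sequence, library)
    pep = place_side_chains(pep, sequence, rotamer_lib,
                            environment=receptor_frame)
    if minimize:
        params = params or ForceFieldParams.default()
        pep, _, _ = minimize_cartesian(pep, params=params,
                                       maxiter=min_maxiter)
    pep.id = f"model_{sequence}"
    return pep
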