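"""Implicit-solvent binding free-energy estimator (MM + GB + SASA).

The estimator follows the single-geometry decomposition

    dG_bind = G(complex) - G(receptor) - G(peptide)

with every G evaluated at the complex geometry and

    G = E_mm(vacuum) + dG_GB(polar solvation) + gamma * SASA + b.

The molecular-mechanics part is a minimal united-hydrogen heavy-atom
model: harmonic bonds/angles referenced to idealized geometry, 12-6
Lennard-Jones (linearly continued at short range for robustness) and
Coulomb electrostatics with 1-2/1-3 exclusions and scaled 1-4 pairs.
Effective Born radii come from Hawkins-Cramer-Truhlar pairwise
descreening; the nonpolar term is a Shrake-Rupley solvent-accessible
surface area with a deterministic sphere point set.  The entropy term is
omitted.  All parameters are packaged, overridable tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import data as _data
from .structio import Structure
from .topology import (BACKBONE_ATOMS, SIDE_CHAIN_TOPOLOGY, element_of)

__all__ = ["ForceFieldParams", "EnergyBreakdown", "DGResult", "mm_energy",
           "born_radii", "gb_polar", "sasa", "binding_dg", "ddg",
           "total_free_energy", "minimize_cartesian", "parameterize"]

COULOMB_CONSTANT = 332.06  # kcal * Angstrom / (mol * e^2)
K_BOND = 300.0   # kcal/mol/A^2
K_ANGLE = 50.0   # kcal/mol/rad^2
SCALE_14 = 0.5
LJ_SOFT_FRACTION = 0.8  # linear continuation below this fraction of rmin

# idealized backbone bond/angle reference values (shared with geometry)
_BB_BONDS = {("N", "CA"): 1.458, ("CA", "C"): 1.525, ("C", "O"): 1.231}
_PEPTIDE_BOND = 1.329
_BB_ANGLES = {("N", "CA", "C"): 111.2, ("CA", "C", "O"): 120.8,
              ("CA", "C", "+N"): 116.2, ("O", "C", "+N"): 123.0,
              ("C", "+N", "+CA"): 121.7, ("CB", "CA", "C"): 110.1}


class ParameterizationError(ValueError):
    """An atom could not be assigned force-field parameters."""


@dataclass(frozen=True)
class ForceFieldParams:
    """Packaged nonbonded / solvation parameter set."""
    lj: dict            # element -> (eps, rmin_half, gb_radius, gb_screen)
    charges: dict       # (resname, atom) -> q; '*' rows as backbone default
    eps_in: float = 1.0
    eps_out: float = 78.5
    gamma: float = 0.00542   # kcal/mol/A^2
    # constant nonpolar offset per state; 0 keeps dG -> 0 for
    # non-interacting partners under single-geometry decomposition
    offset_b: float = 0.0    # kcal/mol

    _cache: dict = field(default_factory=dict, hash=False, compare=False)

    @staticmethod
    def default() -> "ForceFieldParams":
        lj_df = _data.load_lj_types()
        lj = {row.element: (row.eps, row.rmin_half, row.gb_radius,
                            row.gb_screen)
              for row in lj_df.itertuples()}
        qdf = _data.load_charges()
        charges = {(row.residue, row.atom): float(row.charge)
                   for row in qdf.itertuples()}
        return ForceFieldParams(lj=lj, charges=charges)

    def charge_of(self, res_name: str, atom_name: str) -> float:
        if (res_name, atom_name) in self.charges:
            return self.charges[(res_name, atom_name)]
        if ("*", atom_name) in self.charges:
            return self.charges[("*", atom_name)]
        return 0.0


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0
    gb_polar: float = 0.0
    sasa_nonpolar: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.torsion + self.lj
                + self.coulomb + self.gb_polar + self.sasa_nonpolar)


# ---------------------------------------------------------------------------
# System construction


def _ideal_sidechain_tables(res_name: str):
    """(bond, angle) ideal-value dicts for one residue type, from topology.

    Bond keys are sorted name pairs so iteration order (and therefore
    floating-point accumulation order downstream) is reproducible across
    interpreter runs.
    """
    bonds = {}
    angles = {}
    for atom, a, b, c, bond, angle, _tor in SIDE_CHAIN_TOPOLOGY[res_name]:
        bonds[tuple(sorted((c, atom)))] = bond
        angles[(b, c, atom)] = angle
    return bonds, angles


@dataclass
class System:
    """Flattened, typed atom arrays plus bonded topology."""
    coords: np.ndarray
    charge: np.ndarray
    eps: np.ndarray
    rmin_half: np.ndarray
    gb_radius: np.ndarray
    gb_screen: np.ndarray
    bonds: np.ndarray          # (nb, 2) indices
    bond_r0: np.ndarray
    angles: np.ndarray         # (na, 3) indices, vertex in the middle
    angle_t0: np.ndarray       # radians
    scale: np.ndarray          # (n, n) nonbonded scale factors
    labels: list               # (chain, resname, resnumber, atomname)


def parameterize(structure: Structure, params: ForceFieldParams) -> System:
    """Assign charges/LJ/GB parameters and build the bonded topology.

    Bonds come from the residue topology tables plus the inter-residue
    peptide bond (consecutive residue numbers in a chain, C-N distance
    < 2.5 A); raises :class:`ParameterizationError` naming any atom that
    cannot be typed.
    """
    labels, coords, q, eps, rmh, gbr, gbs = [], [], [], [], [], [], []
    index: dict[tuple, int] = {}
    for cid, residues in structure.chains.items():
        for res in residues:
            if res.name not in SIDE_CHAIN_TOPOLOGY:
                raise ParameterizationError(
                    f"non-standard residue {res.name}{res.number}")
            for atom in res.atoms:
                el = atom.element or element_of(atom.name)
                if el not in params.lj:
                    raise ParameterizationError(
                        f"untyped atom {atom.name} ({el}) in "
                        f"{res.name}{res.number} chain {cid}")
                key = (cid, res.number, res.icode, atom.name)
                index[key] = len(coords)
                labels.append((cid, res.name, res.number, atom.name))
                coords.append(atom.coords)
                q.append(params.charge_of(res.name, atom.name))
                e, r, gr, gsc = params.lj[el]
                eps.append(e); rmh.append(r); gbr.append(gr); gbs.append(gsc)
    n = len(coords)
    coords = np.asarray(coords, dtype=float)

    bonds, bond_r0 = [], []
    angles, angle_t0 = [], []

    def _bond(i, j, r0):
        bonds.append((i, j))
        bond_r0.append(r0)

    for cid, residues in structure.chains.items():
        for ri, res in enumerate(residues):
            sc_bonds, sc_angles = _ideal_sidechain_tables(res.name)
            here = {a.name: index[(cid, res.number, res.icode, a.name)]
                    for a in res.atoms}
            # intra-residue bonds
            for (a, b), r0 in _BB_BONDS.items():
                if a in here and b in here:
                    _bond(here[a], here[b], r0)
            for (a, b), r0 in sc_bonds.items():
                if a in here and b in here:
                    _bond(here[a], here[b], r0)
            if res.name == "ALA" and "CB" in here:
                pass  # CB bond already covered by sc_bonds (via _CB entry)
            # intra-residue angles
            for (a, b, c), t0 in list(_BB_ANGLES.items()):
                if "+" in a + b + c:
                    continue
                if a in here and b in here and c in here:
                    angles.append((here[a], here[b], here[c]))
                    angle_t0.append(np.deg2rad(t0))
            for (a, b, c), t0 in sc_angles.items():
                if a in here and b in here and c in here:
                    angles.append((here[a], here[b], here[c]))
                    angle_t0.append(np.deg2rad(t0))
            # peptide bond to the next residue in the chain (author
            # numbering may jump; geometry decides whether they connect)
            if ri + 1 < len(residues):
                nxt = residues[ri + 1]
                if True:
                    there = {a.name: index[(cid, nxt.number, nxt.icode, a.name)]
                             for a in nxt.atoms}
                    if "C" in here and "N" in there:
                        d = np.linalg.norm(coords[here["C"]]
                                           - coords[there["N"]])
                        if d < 1.8:
                            _bond(here["C"], there["N"], _PEPTIDE_BOND)
                            for (a, b, c), t0 in _BB_ANGLES.items():
                                names = (a, b, c)
                                if "+" not in a + b + c:
                                    continue
                                idxs = []
                                ok = True
                                for nm in names:
                                    src = there if nm.startswith("+") else here
                                    nm2 = nm.lstrip("+")
                                    if nm2 not in src:
                                        ok = False
                                        break
                                    idxs.append(src[nm2])
                                if ok:
                                    angles.append(tuple(idxs))
                                    angle_t0.append(np.deg2rad(t0))

    bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
    angles = np.asarray(angles, dtype=int).reshape(-1, 3)

    # nonbonded scale matrix from the bond graph
    scale = np.ones((n, n))
    np.fill_diagonal(scale, 0.0)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    for i in range(n):
        for j in adj[i]:
            scale[i, j] = 0.0
            for k in adj[j]:
                if k != i:
                    scale[i, k] = scale[k, i] = 0.0
    # 1-4: paths of length 3 not already excluded
    for i, j in bonds:
        for k in adj[j]:
            if k == i:
                continue
            for m in adj[k]:
                if m in (i, j):
                    continue
                if scale[i, m] == 1.0:
                    scale[i, m] = scale[m, i] = SCALE_14
    return System(coords, np.asarray(q), np.asarray(eps), np.asarray(rmh),
                  np.asarray(gbr), np.asarray(gbs), bonds,
                  np.asarray(bond_r0), angles, np.asarray(angle_t0),
                  scale, labels)


# ---------------------------------------------------------------------------
# Vacuum molecular mechanics


def _pair_matrices(system: System, coords: np.ndarray):
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(r, 1.0)
    return diff, r


def _lj_coulomb(system: System, coords: np.ndarray, eps_in: float):
    _, r = _pair_matrices(system, coords)
    rmin = system.rmin_half[:, None] + system.rmin_half[None, :]
    epsij = np.sqrt(system.eps[:, None] * system.eps[None, :])
    r_soft = LJ_SOFT_FRACTION * rmin
    rr = np.maximum(r, r_soft)
    sr6 = (rmin / rr) ** 6
    e_lj = epsij * (sr6 ** 2 - 2.0 * sr6)
    # linear continuation below r_soft keeps energies finite on clashes
    dldr = epsij * 12.0 * (sr6 - sr6 ** 2) / rr
    e_lj = e_lj + np.where(r < r_soft, dldr * (r - r_soft), 0.0)
    qq = system.charge[:, None] * system.charge[None, :]
    e_coul = COULOMB_CONSTANT * qq / (eps_in * np.maximum(r, 0.5))
    w = system.scale
    return 0.5 * float((e_lj * w).sum()), 0.5 * float((e_coul * w).sum())


def _bonded_energy(system: System, coords: np.ndarray):
    e_bond = 0.0
    if len(system.bonds):
        d = coords[system.bonds[:, 0]] - coords[system.bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        e_bond = float((K_BOND * (r - system.bond_r0) ** 2).sum())
    e_angle = 0.0
    if len(system.angles):
        a = coords[system.angles[:, 0]]
        b = coords[system.angles[:, 1]]
        c = coords[system.angles[:, 2]]
        u, v = a - b, c - b
        cosang = (u * v).sum(axis=1) / (np.linalg.norm(u, axis=1)
                                        * np.linalg.norm(v, axis=1))
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        e_angle = float((K_ANGLE * (theta - system.angle_t0) ** 2).sum())
    return e_bond, e_angle


def mm_energy(structure: Structure, params: ForceFieldParams | None = None,
              system: System | None = None) -> EnergyBreakdown:
    """Vacuum molecular-mechanics terms of a structure."""
    params = params or ForceFieldParams.default()
    system = system or parameterize(structure, params)
    e_bond, e_angle = _bonded_energy(system, system.coords)
    e_lj, e_coul = _lj_coulomb(system, system.coords, params.eps_in)
    return EnergyBreakdown(bond=e_bond, angle=e_angle, torsion=0.0,
                           lj=e_lj, coulomb=e_coul)


# ---------------------------------------------------------------------------
# Generalized Born


def hct_integral(r: np.ndarray, rho_i: np.ndarray, s: np.ndarray) -> np.ndarray:
    """HCT pairwise descreening term H(r, rho_i, s) (1/Angstrom).

    Analytic integral of (4 pi)^-1 * x^-4 over the scaled sphere of the
    descreening atom, restricted to the region outside rho_i.
    """
    r = np.asarray(r, dtype=float)
    u = r + s
    l = np.maximum(rho_i, np.abs(r - s))
    h = 0.5 * (1.0 / l - 1.0 / u
               + 0.25 * (r - s ** 2 / r) * (1.0 / u ** 2 - 1.0 / l ** 2)
               + 0.5 / r * np.log(l / u))
    return np.where(u <= rho_i, 0.0, h)


def born_radii(structure: Structure, params: ForceFieldParams | None = None,
               system: System | None = None) -> np.ndarray:
    """Effective Born radii by pairwise descreening (HCT-style).

    An isolated atom's effective radius equals its intrinsic radius, and
    radii grow monotonically as neighbours approach.
    """
    params = params or ForceFieldParams.default()
    system = system or parameterize(structure, params)
    coords = system.coords
    n = len(coords)
    if n == 1:
        return system.gb_radius.copy()
    _, r = _pair_matrices(system, coords)
    rho = system.gb_radius
    s = (system.gb_screen * rho)[None, :] * np.ones((n, 1))
    h = hct_integral(r, rho[:, None], s)
    np.fill_diagonal(h, 0.0)
    inv_eff = 1.0 / rho - h.sum(axis=1)
    inv_eff = np.maximum(inv_eff, 1.0 / 50.0)  # guard against overlap blow-up
    return 1.0 / inv_eff


def gb_polar(structure: Structure, params: ForceFieldParams | None = None,
             system: System | None = None) -> float:
    """Polar solvation free energy (kcal/mol).

    dG = -1/2 C (1/eps_in - 1/eps_out) sum_ij q_i q_j / f_GB with
    f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))).
    """
    params = params or ForceFieldParams.default()
    system = system or parameterize(structure, params)
    q = system.charge
    if not np.any(q):
        return 0.0
    reff = born_radii(structure, params, system)
    coords = system.coords
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = (diff ** 2).sum(axis=-1)
    rr = reff[:, None] * reff[None, :]
    f_gb = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    pref = -0.5 * COULOMB_CONSTANT * (1.0 / params.eps_in
                                      - 1.0 / params.eps_out)
    return float(pref * ((q[:, None] * q[None, :]) / f_gb).sum())


# ---------------------------------------------------------------------------
# Solvent-accessible surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sasa(structure: Structure, probe: float = 1.4, n_points: int = 960,
         params: ForceFieldParams | None = None,
         system: System | None = None) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Returns (per-atom areas, total) in Angstrom^2 using the packaged GB
    radii as atomic radii and a deterministic golden-spiral point set.
    """
    params = params or ForceFieldParams.default()
    system = system or parameterize(structure, params)
    coords = system.coords
    radii = system.gb_radius + probe
    n = len(coords)
    pts = _sphere_points(n_points)
    areas = np.zeros(n)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    for i in range(n):
        neigh = np.nonzero((d2[i] < (radii[i] + radii) ** 2)
                           & (np.arange(n) != i))[0]
        surf = coords[i] + radii[i] * pts
        if len(neigh):
            dist2 = ((surf[:, None, :] - coords[neigh][None, :, :]) ** 2
                     ).sum(axis=-1)
            buried = (dist2 < (radii[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return areas, float(areas.sum())


# ---------------------------------------------------------------------------
# Free energies


def total_free_energy(structure: Structure,
                      params: ForceFieldParams | None = None,
                      system: System | None = None) -> EnergyBreakdown:
    """G = MM + GB + gamma * SASA + b for one structure/geometry."""
    params = params or ForceFieldParams.default()
    system = system or parameterize(structure, params)
    out = mm_energy(structure, params, system)
    out.gb_polar = gb_polar(structure, params, system)
    _, total_area = sasa(structure, params=params, system=system)
    out.sasa_nonpolar = params.gamma * total_area + params.offset_b
    return out


@dataclass
class DGResult:
    """Binding free energy with per-state breakdowns."""
    dg: float
    complex: EnergyBreakdown
    receptor: EnergyBreakdown
    peptide: EnergyBreakdown
    params: ForceFieldParams


def binding_dg(complex_: Structure, receptor_chains: list[str],
               peptide_chains: list[str],
               params: ForceFieldParams | None = None) -> DGResult:
    """Single-geometry MM-GBSA binding free energy.

    Receptor and peptide sub-systems are scored at the complex geometry
    (no separate relaxation).  Chain selections must partition the
    complex without overlap.
    """
    params = params or ForceFieldParams.default()
    overlap = set(receptor_chains) & set(peptide_chains)
    if overlap:
        raise ValueError(f"selection overlap on chains {sorted(overlap)}")
    def _sub(chains):
        return Structure(complex_.id,
                         {c: [r.copy() for r in complex_.chains[c]]
                          for c in chains}, complex_.resolution)
    g_c = total_free_energy(complex_, params)
    g_r = total_free_energy(_sub(receptor_chains), params)
    g_p = total_free_energy(_sub(peptide_chains), params)
    return DGResult(g_c.total - g_r.total - g_p.total, g_c, g_r, g_p, params)


def ddg(dg_variant: DGResult | float, dg_reference: DGResult | float) -> float:
    """ddG = dG(variant) - dG(reference); negative favours the variant."""
    if isinstance(dg_variant, DGResult) and isinstance(dg_reference, DGResult):
        if dg_variant.params is not dg_reference.params and \
                dg_variant.params != dg_reference.params:
            raise ValueError("dG values computed with different parameter sets")
        return dg_variant.dg - dg_reference.dg
    return float(dg_variant) - float(dg_reference)


# ---------------------------------------------------------------------------
# Minimization


def _mm_value_and_grad(system: System, coords: np.ndarray, eps_in: float):
    n = len(coords)
    grad = np.zeros_like(coords)
    # bonds
    e_bond = 0.0
    if len(system.bonds):
        i, j = system.bonds[:, 0], system.bonds[:, 1]
        d = coords[i] - coords[j]
        r = np.linalg.norm(d, axis=1)
        dr = r - system.bond_r0
        e_bond = float((K_BOND * dr ** 2).sum())
        g = (2.0 * K_BOND * dr / r)[:, None] * d
        np.add.at(grad, i, g)
        np.add.at(grad, j, -g)
    # angles
    e_angle = 0.0
    if len(system.angles):
        ia, ib, ic = (system.angles[:, 0], system.angles[:, 1],
                      system.angles[:, 2])
        u = coords[ia] - coords[ib]
        v = coords[ic] - coords[ib]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosang = np.clip((u * v).sum(axis=1) / (nu * nv), -1.0 + 1e-10,
                         1.0 - 1e-10)
        theta = np.arccos(cosang)
        dtheta = theta - system.angle_t0
        e_angle = float((K_ANGLE * dtheta ** 2).sum())
        sin_t = np.sqrt(1.0 - cosang ** 2)
        pref = (2.0 * K_ANGLE * dtheta / (-sin_t))
        dcos_da = (v / (nu * nv)[:, None]
                   - (cosang / nu ** 2)[:, None] * u)
        dcos_dc = (u / (nu * nv)[:, None]
                   - (cosang / nv ** 2)[:, None] * v)
        ga = pref[:, None] * dcos_da
        gc = pref[:, None] * dcos_dc
        np.add.at(grad, ia, ga)
        np.add.at(grad, ic, gc)
        np.add.at(grad, ib, -(ga + gc))
    # nonbonded
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(r, 1.0)
    rmin = system.rmin_half[:, None] + system.rmin_half[None, :]
    epsij = np.sqrt(system.eps[:, None] * system.eps[None, :])
    w = system.scale
    r_soft = LJ_SOFT_FRACTION * rmin
    rr = np.maximum(r, r_soft)
    sr6 = (rmin / rr) ** 6
    e_lj_mat = epsij * (sr6 ** 2 - 2.0 * sr6)
    dldr_soft = epsij * 12.0 * (sr6 - sr6 ** 2) / rr
    e_lj_mat = e_lj_mat + np.where(r < r_soft, dldr_soft * (r - r_soft), 0.0)
    dlj_dr = np.where(r < r_soft, dldr_soft, dldr_soft)  # continuation slope
    qq = system.charge[:, None] * system.charge[None, :]
    rc = np.maximum(r, 0.5)
    e_coul_mat = COULOMB_CONSTANT * qq / (eps_in * rc)
    dcoul_dr = np.where(r > 0.5, -COULOMB_CONSTANT * qq / (eps_in * rc ** 2),
                        0.0)
    e_lj = 0.5 * float((e_lj_mat * w).sum())
    e_coul = 0.5 * float((e_coul_mat * w).sum())
    dEdr = (dlj_dr + dcoul_dr) * w
    np.fill_diagonal(dEdr, 0.0)
    with np.errstate(invalid="ignore"):
        unit = diff / r[..., None]
    g_nb = (dEdr[..., None] * unit).sum(axis=1)
    grad += g_nb
    return e_bond + e_angle + e_lj + e_coul, grad


def minimize_cartesian(structure: Structure, mobile: np.ndarray | None = None,
                       params: ForceFieldParams | None = None,
                       maxiter: int = 40,
                       system: System | None = None) -> tuple[Structure, float, float]:
    """Short conjugate-gradient minimization of the vacuum MM energy.

    ``mobile`` is a boolean mask over the flattened atom order (None =
    all mobile).  Returns (minimized copy, initial energy, final energy);
    the energy never increases.
    """
    params = params or ForceFieldParams.default()
    system = system or parameterize(structure, params)
    x0 = system.coords.copy()
    n = len(x0)
    if mobile is None:
        mobile = np.ones(n, dtype=bool)
    mob_idx = np.nonzero(mobile)[0]

    def fun(flat):
        coords = x0.copy()
        coords[mob_idx] = flat.reshape(-1, 3)
        e, g = _mm_value_and_grad(system, coords, params.eps_in)
        return e, g[mob_idx].ravel()

    e0, _ = fun(x0[mob_idx].ravel())
    res = _scipy_minimize(fun, x0[mob_idx].ravel(), jac=True, method="CG",
                          options={"maxiter": maxiter, "gtol": 1e-3})
    e1 = float(res.fun)
    if e1 > e0:  # CG can overstep on rough landscapes; keep the start
        e1 = e0
        final = x0
    else:
        final = x0.copy()
        final[mob_idx] = res.x.reshape(-1, 3)
    out = structure.copy()
    out.set_coords(final)
    return out, float(e0), e1
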