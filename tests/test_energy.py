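"""MM terms, generalized-Born solvation, SASA and binding free energies."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy.spatial.transform import Rotation

import anchordock as ad
from anchordock.energy import (COULOMB_CONSTANT, ForceFieldParams,
                               ParameterizationError, binding_dg, born_radii,
                               ddg, gb_polar, hct_integral, mm_energy,
                               minimize_cartesian, parameterize, sasa)
from anchordock.structio import Atom, Residue, Structure


def _toy(atom_specs, resnames=None):
    """Structure of isolated single-atom residues on separate chains."""
    chains = {}
    for k, (name, el, xyz) in enumerate(atom_specs):
        rn = (resnames or ["GLY"] * len(atom_specs))[k]
        chains[chr(ord("A") + k)] = [Residue(rn, 1, "",
                                             [Atom(name, el, xyz)])]
    return Structure("toy", chains)


@pytest.fixture(scope="module")
def neutral_params(params):
    return ForceFieldParams(lj=params.lj, charges={})


def test_lj_well_depth_at_rmin(params, neutral_params):
    rmin = 2 * params.lj["C"][1]
    s = _toy([("CA", "C", [0, 0, 0]), ("CA", "C", [rmin, 0, 0])])
    e = mm_energy(s, neutral_params)
    assert e.lj == pytest.approx(-params.lj["C"][0], abs=1e-12)
    assert e.coulomb == 0.0


def test_coulomb_of_unit_charges_at_3p32_angstrom(params):
    pq = ForceFieldParams(lj=params.lj,
                          charges={("GLY", "CA"): 1.0, ("ALA", "CA"): -1.0})
    s = _toy([("CA", "C", [0, 0, 0]), ("CA", "C", [3.32, 0, 0])],
             ["GLY", "ALA"])
    e = mm_energy(s, pq)
    assert e.coulomb == pytest.approx(-332.06 / 3.32, abs=1e-9)


def test_single_atom_has_no_pair_terms(params):
    s = _toy([("CA", "C", [0, 0, 0])])
    e = mm_energy(s, params)
    assert e.lj == 0.0 and e.coulomb == 0.0 and e.bond == 0.0


def test_untyped_atom_is_named_in_error(params):
    s = _toy([("XX", "Q", [0, 0, 0])])
    with pytest.raises(ParameterizationError, match="XX"):
        parameterize(s, params)


def test_breakdown_total_is_sum_of_terms(complex_default, params):
    e = ad.total_free_energy(complex_default, params)
    parts = (e.bond + e.angle + e.torsion + e.lj + e.coulomb
             + e.gb_polar + e.sasa_nonpolar)
    assert e.total == pytest.approx(parts, abs=1e-9)


# ---------------------------------------------------------------------------
# Born radii


def test_isolated_atom_effective_radius_is_intrinsic(params):
    s = _toy([("CA", "C", [0, 0, 0])])
    assert born_radii(s, params)[0] == pytest.approx(params.lj["C"][2])


def test_effective_radii_grow_as_atoms_approach(params):
    prev = None
    for d in (8.0, 6.0, 4.0, 3.0):
        s = _toy([("CA", "C", [0, 0, 0]), ("CA", "C", [d, 0, 0])])
        r = born_radii(s, params)[0]
        if prev is not None:
            assert r > prev
        prev = r


def _hct_quadrature(r, rho_i, s, order=400):
    nodes, w = leggauss(order)
    mu0 = np.sqrt(max(0.0, 1 - (s / r) ** 2))
    mu = 0.5 * (nodes + 1) * (1 - mu0) + mu0
    jac = 0.5 * (1 - mu0)
    disc = np.maximum(s ** 2 - r ** 2 * (1 - mu ** 2), 0.0)
    tin = np.maximum(r * mu - np.sqrt(disc), rho_i)
    tout = np.maximum(r * mu + np.sqrt(disc), rho_i)
    return 0.5 * (w * jac * (1 / tin - 1 / tout)).sum()


def test_descreening_term_matches_quadrature(params):
    # three-atom toy: every pairwise descreening integral agrees with a
    # direct numerical evaluation to 1e-6
    coords = np.array([[0.0, 0, 0], [3.4, 0, 0], [1.5, 2.8, 0]])
    rho = params.lj["C"][2]
    scale = params.lj["C"][3]
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            r = np.linalg.norm(coords[i] - coords[j])
            analytic = float(hct_integral(np.array([r]), np.array([rho]),
                                          np.array([scale * rho]))[0])
            assert analytic == pytest.approx(
                _hct_quadrature(r, rho, scale * rho), abs=1e-6)


# ---------------------------------------------------------------------------
# GB polar


def test_gb_reduces_to_born_formula_for_single_ion(params):
    pion = ForceFieldParams(lj=params.lj, charges={("GLY", "CA"): 1.0})
    s = _toy([("CA", "C", [0, 0, 0])])
    radius = params.lj["C"][2]
    expected = -0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5) / radius
    assert gb_polar(s, pion) == pytest.approx(expected, abs=1e-6)


def test_gb_zero_for_uncharged_system(complex_default, params):
    p0 = ForceFieldParams(lj=params.lj, charges={})
    assert gb_polar(complex_default, p0) == 0.0


def test_gb_approaches_screened_coulomb_at_large_separation(params):
    pq = ForceFieldParams(lj=params.lj,
                          charges={("GLY", "CA"): 1.0, ("ALA", "CA"): -1.0})
    s = _toy([("CA", "C", [0, 0, 0]), ("CA", "C", [100.0, 0, 0])],
             ["GLY", "ALA"])
    radii = born_radii(s, pq)
    self_terms = sum(-0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5) / r
                     for r in radii)
    cross = -COULOMB_CONSTANT * (1 - 1 / 78.5) * (-1.0) / 100.0
    assert gb_polar(s, pq) == pytest.approx(self_terms + cross, abs=1e-3)


# ---------------------------------------------------------------------------
# SASA


def test_sasa_of_single_sphere_matches_closed_form(params):
    s = _toy([("CA", "C", [0, 0, 0])])
    _, total = sasa(s, params=params)
    r = params.lj["C"][2] + 1.4
    assert total == pytest.approx(4 * np.pi * r ** 2, rel=1e-6)


def test_two_overlapping_spheres_match_spherical_cap_formula(params):
    d = 2.0
    s = _toy([("CA", "C", [0, 0, 0]), ("CA", "C", [d, 0, 0])])
    per_atom, total = sasa(s, params=params)
    r = params.lj["C"][2] + 1.4  # equal radii
    # each sphere loses a cap of height h = r - d/2
    h = r - d / 2
    expected_each = 4 * np.pi * r ** 2 - 2 * np.pi * r * h
    assert per_atom[0] == pytest.approx(expected_each, rel=0.02)
    assert total == pytest.approx(2 * expected_each, rel=0.02)


def test_buried_atom_has_near_zero_area(params):
    # central atom caged by 14 neighbours
    shell = []
    for v in ([1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
              [0, 0, -1], [1, 1, 1], [1, 1, -1], [1, -1, 1], [-1, 1, 1],
              [-1, -1, 1], [-1, 1, -1], [1, -1, -1], [-1, -1, -1]):
        shell.append(2.2 * np.array(v, float) / np.linalg.norm(v))
    specs = [("CA", "C", [0.0, 0, 0])] + [("CA", "C", x) for x in shell]
    s = Structure("cage", {"A": [Residue("GLY", k + 1, "",
                                         [Atom(n, e, x)])
                                 for k, (n, e, x) in enumerate(specs)]})
    per_atom, _ = sasa(s, params=params)
    assert per_atom[0] < 1.0


# ---------------------------------------------------------------------------
# Binding dG / ddG


def test_dg_vanishes_for_non_interacting_partners(complex_default, params):
    far = complex_default.copy()
    for r in far.chains["C"]:
        for a in r.atoms:
            a.coords = a.coords + np.array([500.0, 0.0, 0.0])
    assert abs(binding_dg(far, ["A"], ["C"], params).dg) < 0.05


def test_dg_negative_for_favorable_nonpolar_contact(params):
    p0 = ForceFieldParams(lj=params.lj, charges={})
    rmin = 2 * params.lj["C"][1]
    s = _toy([("CA", "C", [0, 0, 0]), ("CA", "C", [rmin, 0, 0])])
    res = binding_dg(s, ["A"], ["B"], p0)
    assert res.dg < 0.0


def test_dg_invariant_under_rigid_motion(complex_default, params):
    base = binding_dg(complex_default, ["A"], ["C"], params).dg
    moved = complex_default.copy()
    rot = Rotation.from_rotvec([0.4, -0.9, 0.2]).as_matrix()
    moved.set_coords(moved.coords_array() @ rot.T + np.array([8.0, 1.0, -5.0]))
    assert binding_dg(moved, ["A"], ["C"], params).dg == \
        pytest.approx(base, abs=0.05)


def test_selection_overlap_is_an_error(complex_default, params):
    with pytest.raises(ValueError, match="overlap"):
        binding_dg(complex_default, ["A", "C"], ["C"], params)


def test_ddg_antisymmetry_and_zero_for_identical():
    assert ddg(-12.0, -12.0) == 0.0
    assert ddg(-10.0, -14.0) == pytest.approx(-ddg(-14.0, -10.0))


def test_ddg_positive_when_a_contact_is_removed(params):
    p0 = ForceFieldParams(lj=params.lj, charges={})
    rmin = 2 * params.lj["C"][1]
    bound = _toy([("CA", "C", [0, 0, 0]), ("CA", "C", [rmin, 0, 0])])
    apart = _toy([("CA", "C", [0, 0, 0]), ("CA", "C", [rmin + 30, 0, 0])])
    dg_ref = binding_dg(bound, ["A"], ["B"], p0)
    dg_var = binding_dg(apart, ["A"], ["B"], p0)
    assert ddg(dg_var, dg_ref) > 0.0


def test_ddg_rejects_mismatched_parameter_sets(params, complex_default):
    other = ForceFieldParams(lj=params.lj, charges={}, gamma=0.01)
    a = binding_dg(complex_default, ["A"], ["C"], params)
    b = binding_dg(complex_default, ["A"], ["C"], other)
    with pytest.raises(ValueError):
        ddg(a, b)


# ---------------------------------------------------------------------------
# Minimization


def test_minimization_never_increases_energy(complex_default, params):
    _, e0, e1 = minimize_cartesian(complex_default, params=params,
                                   maxiter=15)
    assert e1 <= e0


def test_minimizing_a_minimum_leaves_coordinates_in_place(params):
    rmin = 2 * params.lj["C"][1]
    p0 = ForceFieldParams(lj=params.lj, charges={})
    s = _toy([("CA", "C", [0, 0, 0]), ("CA", "C", [rmin, 0, 0])])
    out, e0, e1 = minimize_cartesian(s, params=p0, maxiter=50)
    assert e0 - e1 < 1e-6
    np.testing.assert_allclose(out.coords_array(), s.coords_array(),
                               atol=0.02)
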