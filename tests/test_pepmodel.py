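"""Template library construction, threading and rotamer packing."""

import itertools

import numpy as np
import pytest

import anchordock as ad
from anchordock import fixtures as fx
from anchordock.pepmodel import (DEFAULT_UNSEEN_MAP, PlacementError,
                                 anchor_coords, assignment_energy,
                                 build_peptide, build_template_library,
                                 map_p1, place_side_chains, thread_sequence)
from anchordock.structio import Atom, Residue, Structure
from anchordock.topology import BACKBONE_ATOMS, CANONICAL_HEAVY_ATOMS
from anchordock.geometry import build_backbone, BETA_STRAND


def test_rotamer_priors_sum_to_one(rotamer_library):
    for name, rots in rotamer_library.rotamers.items():
        assert sum(p for _, p in rots) == pytest.approx(1.0, abs=1e-9)
        assert all(-180.0 < c <= 180.0 for chis, _ in rots for c in chis)


def test_library_keys_follow_p1_of_input_set(spec):
    complexes = [fx.generate_complex(spec, s, r) for s, r in
                 [("ALAKEVHGV", 2.5), ("LLFGYPVYV", 2.0),
                  ("SLYNTVATL", 1.8), ("AAGIGILTV", 2.2)]]
    lib = build_template_library(complexes)
    assert sorted(lib.p1_templates) == ["A", "L", "S"]
    # resolution selects the template: A at 2.2 beats A at 2.5
    assert lib.p1_templates["A"].resolution == pytest.approx(2.2)


def test_resolution_ties_break_by_id_order(spec):
    complexes = [fx.generate_complex(spec, s, 2.0)
                 for s in ["ALAKEVHGV", "AAGIGILTV"]]
    lib = build_template_library(complexes)
    ids = sorted(c.id for c in complexes)
    assert lib.p1_templates["A"].source_id == ids[0]


def test_single_complex_consensus_equals_own_anchors(complex_default):
    lib = build_template_library([complex_default])
    pep = ad.extract_peptide(complex_default)
    np.testing.assert_allclose(lib.consensus_anchor, anchor_coords(pep),
                               atol=1e-12)
    assert len(lib.p1_templates) == 1


def test_template_stripping_preserves_backbone_bit_exactly(template_library,
                                                           library_complexes):
    for key, tpl in template_library.p1_templates.items():
        source = next(c for c in library_complexes
                      if c.id == tpl.source_id)
        pep = ad.extract_peptide(source)  # same frame: source is reference
        (cid,) = tpl.peptide.chains
        for res_t, res_s in zip(tpl.peptide.chains[cid],
                                pep.chains[list(pep.chains)[0]]):
            if res_t.number == 1:
                continue
            assert [a.name for a in res_t.atoms] == list(BACKBONE_ATOMS)
        if tpl.source_id == sorted(c.id for c in library_complexes)[0]:
            np.testing.assert_array_equal(
                tpl.peptide.chains[cid][2].atom("CA").coords,
                pep.chains[list(pep.chains)[0]][2].atom("CA").coords)


def test_empty_library_input_is_an_error():
    with pytest.raises(ValueError):
        build_template_library([])


def test_map_p1_identity_and_unseen_table(template_library):
    assert map_p1("L", template_library) == "L"
    assert map_p1("S", template_library) == "S"
    assert map_p1("C", template_library) == DEFAULT_UNSEEN_MAP["C"]
    with pytest.raises(ValueError):
        map_p1("X", template_library)


def test_thread_keeps_matching_p1_side_chain(template_library):
    pep = thread_sequence("ILKEPVHGV", template_library)
    (cid,) = pep.chains
    p1 = pep.chains[cid][0]
    assert p1.name == "ILE"
    assert set(CANONICAL_HEAVY_ATOMS["ILE"]) <= {a.name for a in p1.atoms}


def test_thread_poly_alanine_gives_backbone_plus_stubs(template_library):
    pep = thread_sequence("AAAAAAAAA", template_library)
    (cid,) = pep.chains
    for res in pep.chains[cid]:
        assert sorted(a.name for a in res.atoms) == \
            sorted(("N", "CA", "C", "O", "CB"))


def test_thread_rejects_wrong_length_and_letters(template_library):
    with pytest.raises(ValueError):
        thread_sequence("ALAKEVHG", template_library)
    with pytest.raises(ValueError):
        thread_sequence("ALAKEVHGX", template_library)


def _lone_residue(name, number=1):
    bb = build_backbone([BETA_STRAND])[0]
    return Residue(name, number, "",
                   [Atom(n, n[0], bb[n]) for n in ("N", "CA", "C", "O")])


def test_vacuum_placement_selects_max_prior_rotamer(rotamer_library):
    pep = Structure("leu", {"C": [_lone_residue("LEU")]})
    packed = place_side_chains(pep, "L", rotamer_library)
    # exhaustive oracle over every rotamer of the single residue
    energies = [assignment_energy(pep, {0: k}, rotamer_library)
                for k in range(len(rotamer_library.for_residue("LEU")))]
    best_k = int(npeptide_argmin(energies))
    chis_best = rotamer_library.for_residue("LEU")[best_k][0]
    assert best_k == 0  # in vacuum the max-prior rotamer wins
    placed = packed.chains["C"][0]
    from anchordock.geometry import dihedral
    chi1 = dihedral(placed.atom("N").coords, placed.atom("CA").coords,
                    placed.atom("CB").coords, placed.atom("CG").coords)
    assert chi1 == pytest.approx(chis_best[0], abs=1e-6)


def npeptide_argmin(values):
    return int(np.argmin(values))


def test_blocked_top_rotamer_falls_back_to_next_clash_free(rotamer_library):
    from anchordock.topology import build_side_chain
    res = _lone_residue("LEU")
    bb = {n: res.atom(n).coords for n in ("N", "CA", "C", "O")}
    top_chis = rotamer_library.for_residue("LEU")[0][0]
    cd1 = build_side_chain("LEU", bb, top_chis)["CD1"]
    blocker = Structure("env", {"E": [Residue("GLY", 1, "",
                                              [Atom("CA", "C", cd1)])]})
    pep = Structure("leu", {"C": [res]})
    packed = place_side_chains(pep, "L", rotamer_library,
                               environment=blocker)
    from anchordock.geometry import dihedral
    placed = packed.chains["C"][0]
    chi1 = dihedral(placed.atom("N").coords, placed.atom("CA").coords,
                    placed.atom("CB").coords, placed.atom("CG").coords)
    assert chi1 != pytest.approx(top_chis[0], abs=1.0)
    # oracle: among clash-free rotamers the packer found the cheapest
    rots = rotamer_library.for_residue("LEU")
    packed_e = None
    for k in range(len(rots)):
        sc = build_side_chain("LEU", bb, rots[k][0])
        dmin = min(np.linalg.norm(sc[nm] - cd1) for nm in sc if nm != "CB")
        e = assignment_energy(pep, {0: k}, rotamer_library,
                              environment=blocker)
        if abs(rots[k][0][0] - chi1) < 1.0:
            packed_e = e
        if dmin >= 1.5:
            assert packed_e is None or packed_e <= e + 1e-9
    assert packed_e is not None


def test_poly_alanine_packs_without_search(template_library, rotamer_library):
    pep = thread_sequence("AAAAAAAAA", template_library)
    packed = place_side_chains(pep, "AAAAAAAAA", rotamer_library)
    (cid,) = packed.chains
    for res in packed.chains[cid]:
        assert sorted(a.name for a in res.atoms) == \
            sorted(CANONICAL_HEAVY_ATOMS["ALA"])


def test_greedy_energy_not_worse_than_exhaustive_on_separated_pair(
        rotamer_library):
    # two serines too far apart to interact: greedy must hit the global
    # optimum of the shared scoring function
    r1 = _lone_residue("SER", 1)
    r2 = _lone_residue("SER", 2)
    for a in r2.atoms:
        a.coords = a.coords + np.array([20.0, 0.0, 0.0])
    pep = Structure("ss", {"C": [r1, r2]})
    packed = place_side_chains(pep, "SS", rotamer_lib=rotamer_library)
    n_rot = len(rotamer_library.for_residue("SER"))
    best = min(assignment_energy(pep, {0: i, 1: j}, rotamer_library)
               for i, j in itertools.product(range(n_rot), repeat=2))
    chosen = {k: _chi_index(packed, k, rotamer_library) for k in range(2)}
    greedy = assignment_energy(pep, chosen, rotamer_library)
    assert greedy <= best + 1e-9


def _chi_index(packed, pos, rotamer_library):
    from anchordock.geometry import dihedral
    res = packed.chains["C"][pos]
    chi1 = dihedral(res.atom("N").coords, res.atom("CA").coords,
                    res.atom("CB").coords, res.atom("OG").coords)
    rots = rotamer_library.for_residue("SER")
    return int(np.argmin([abs(c[0] - chi1) for c, _ in rots]))


def test_placement_failure_names_the_position(rotamer_library):
    from anchordock.topology import build_side_chain
    res = _lone_residue("SER")
    bb = {n: res.atom(n).coords for n in ("N", "CA", "C", "O")}
    blockers = []
    for k, (chis, _) in enumerate(rotamer_library.for_residue("SER")):
        og = build_side_chain("SER", bb, chis)["OG"]
        blockers.append(Residue("GLY", k + 1, "", [Atom("CA", "C", og)]))
    env = Structure("env", {"E": blockers})
    pep = Structure("ser", {"C": [res]})
    with pytest.raises(PlacementError, match="P1"):
        place_side_chains(pep, "S", rotamer_library, environment=env)


def test_build_peptide_is_deterministic(template_library):
    a = build_peptide("SLYNTVATL", template_library)
    b = build_peptide("SLYNTVATL", template_library)
    np.testing.assert_array_equal(a.coords_array(), b.coords_array())


def test_rebuild_recovers_fixture_backbone(spec, groove, template_library):
    from anchordock.dock import peptide_rmsd
    target = fx.generate_bound_peptide(spec, groove, "SLYNTVATL")
    model = build_peptide("SLYNTVATL", template_library,
                          receptor_frame=groove)
    assert peptide_rmsd(target, model, "backbone") < 0.5
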