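"""Affinity curation, density-peak thresholding, ROC and the ddG screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import anchordock as ad
from anchordock import fixtures as fx
from anchordock.screen import (HIGH_RISK_POSITIONS, ThresholdModel,
                               build_substitution_models, classify,
                               fit_threshold, load_affinity_table, roc_auc,
                               substitution_screen, SubstitutionModelSet)


# ---------------------------------------------------------------------------
# Affinity tables


def _write_table(tmp_path, rows, name="aff.tsv"):
    path = tmp_path / name
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return path


def test_ic50_boundary_500_is_a_binder(tmp_path):
    path = _write_table(tmp_path, [
        {"peptide": "SLYNTVATL", "ic50_nM": 500.0},
        {"peptide": "GILGFVFTL", "ic50_nM": 500.1}])
    recs = load_affinity_table(path)
    assert recs[0].binder and not recs[1].binder


def test_duplicates_keep_first_and_bad_sequences_dropped(tmp_path):
    path = _write_table(tmp_path, [
        {"peptide": "SLYNTVATL", "ic50_nM": 10.0},
        {"peptide": "SLYNTVATL", "ic50_nM": 9999.0},
        {"peptide": "SLYNTVAXL", "ic50_nM": 5.0},
        {"peptide": "SLYNTVAT", "ic50_nM": 5.0}])
    recs = load_affinity_table(path)
    assert len(recs) == 1
    assert recs[0].binder  # first occurrence won


def test_conflicting_quantitative_and_qualitative_dropped(tmp_path):
    path = _write_table(tmp_path, [
        {"peptide": "SLYNTVATL", "ic50_nM": 10.0, "qualitative": "Negative"},
        {"peptide": "GILGFVFTL", "ic50_nM": 10.0, "qualitative": "Positive"},
        {"peptide": "ILKEPVHGV", "ic50_nM": np.nan,
         "qualitative": "Negative"}])
    recs = load_affinity_table(path)
    assert [r.peptide for r in recs] == ["GILGFVFTL", "ILKEPVHGV"]
    assert recs[0].binder and not recs[1].binder


def test_missing_columns_raise(tmp_path):
    path = _write_table(tmp_path, [{"sequence": "SLYNTVATL"}])
    with pytest.raises(ValueError, match="peptide"):
        load_affinity_table(path)


# ---------------------------------------------------------------------------
# Threshold model


@pytest.mark.parametrize("seed", range(5))
def test_cutoff_recovers_midpoint_of_synthetic_modes(seed):
    scores, labels = fx.generate_score_dataset(seed=seed)
    model = fit_threshold(scores[labels], scores[~labels])
    assert model.cutoff == pytest.approx(-35.0, abs=1.0)
    assert model.usable
    assert model.p_value < 1e-10


def test_identical_distributions_classify_at_chance():
    rng = np.random.default_rng(0)
    pool = rng.normal(-30, 5, 1000)
    model = fit_threshold(pool[:500], pool[500:])
    preds = np.array([classify(s, model) == "binder" for s in pool])
    truth = np.arange(1000) < 500
    accuracy = (preds == truth).mean()
    assert 0.4 < accuracy < 0.6


def test_separated_classes_classify_perfectly():
    scores, labels = fx.generate_score_dataset(100, 100, -80, -10, 1.0, 3)
    model = fit_threshold(scores[labels], scores[~labels])
    preds = np.array([classify(s, model) == "binder" for s in scores])
    assert (preds == labels).all()


def test_threshold_input_validation():
    with pytest.raises(ValueError, match="at least 20"):
        fit_threshold(np.zeros(5), np.ones(50))
    with pytest.raises(ValueError, match="degenerate"):
        fit_threshold(np.zeros(50), np.ones(50))


def test_mean_midpoint_rule_is_available():
    scores, labels = fx.generate_score_dataset(seed=1)
    model = fit_threshold(scores[labels], scores[~labels],
                          rule="midpoint_means")
    b, n = scores[labels].mean(), scores[~labels].mean()
    assert model.cutoff == pytest.approx(0.5 * (b + n))


def test_classification_boundary_is_strict():
    model = ThresholdModel(-35.0, -50.0, -20.0, 0.0, 0.0, 0.1)
    assert classify(-35.0, model) == "nonbinder"
    assert classify(-45.0, model) == "binder"
    assert classify(np.inf, model) == "nonbinder"


# ---------------------------------------------------------------------------
# ROC / AUC


def test_auc_extremes():
    scores = np.array([-50.0] * 5 + [-10.0] * 5)
    labels = np.array([True] * 5 + [False] * 5)
    assert roc_auc(scores, labels).auc == 1.0
    assert roc_auc(np.zeros(10), labels).auc == 0.5


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_pair_counting_oracle_exactly(seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(size=10), 1)  # ties likely
    labels = rng.random(10) < 0.5
    if labels.all() or (~labels).all():
        labels[0] = ~labels[0]
    result = roc_auc(scores, labels)
    b, n = scores[labels], scores[~labels]
    oracle = sum((x < y) + 0.5 * (x == y) for x in b for y in n) \
        / (len(b) * len(n))
    assert result.auc == pytest.approx(oracle, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.integers(-5, 5), st.booleans()),
                min_size=2, max_size=12))
def test_auc_matches_pair_counting_on_arbitrary_small_sets(items):
    scores = np.array([s for s, _ in items], dtype=float)
    labels = np.array([l for _, l in items])
    if labels.all() or (~labels).all():
        return
    auc = roc_auc(scores, labels).auc
    b, n = scores[labels], scores[~labels]
    oracle = sum((x < y) + 0.5 * (x == y) for x in b for y in n) \
        / (len(b) * len(n))
    assert auc == pytest.approx(oracle, abs=1e-12)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc(np.zeros(4), np.ones(4, dtype=bool))


def test_synthetic_dataset_auc_matches_gaussian_closed_form():
    from scipy.stats import norm
    scores, labels = fx.generate_score_dataset(2000, 2000, -50, -20, 4.0, 9)
    auc = roc_auc(scores, labels).auc
    expected = norm.cdf(30.0 / (4.0 * np.sqrt(2)))
    assert auc == pytest.approx(expected, abs=0.01)


# ---------------------------------------------------------------------------
# Substitution models


def test_full_observed_set_yields_35_models(groove):
    models = build_substitution_models(groove, minimize=False)
    assert len(models) == 35
    positions = sorted({pos for pos, _ in models.models})
    assert positions == list(HIGH_RISK_POSITIONS)
    per_pos = {p: sum(1 for q, _ in models.models if q == p)
               for p in positions}
    assert [per_pos[p] for p in positions] == [5, 9, 8, 6, 7]


def test_self_substitution_reproduces_reference_coordinates(groove):
    # fixture floor position 9 is glycine; re-substituting G is a no-op
    table = pd.DataFrame([{"position": 9, "observed_residues": "G"}])
    models = build_substitution_models(groove, table, minimize=False)
    variant = models.models[(9, "G")]
    np.testing.assert_allclose(variant.coords_array(),
                               groove.coords_array(), atol=1e-12)


def test_position_restriction_to_single_residue(groove):
    table = pd.DataFrame([{"position": 9, "observed_residues": "T"}])
    models = build_substitution_models(groove, table, minimize=False)
    assert len(models) == 1
    res = next(r for r in models.models[(9, "T")].chains["A"]
               if r.number == 9)
    assert res.name == "THR"
    assert {a.name for a in res.atoms} >= {"OG1", "CG2"}


def test_missing_position_is_an_error(groove):
    table = pd.DataFrame([{"position": 500, "observed_residues": "T"}])
    with pytest.raises(ValueError, match="500"):
        build_substitution_models(groove, table, minimize=False)


# ---------------------------------------------------------------------------
# The screen


@pytest.fixture(scope="module")
def screen_setup(groove, template_library):
    """Reference dG for one peptide plus a manually blocked variant."""
    ref_dg = {}
    from anchordock.screen import _dock_and_score
    from anchordock.dock import DockConfig
    cfg = DockConfig()
    params = ad.ForceFieldParams.default()
    seqs = ["SLYNTVATL", "GILGFVFTL"]
    for s in seqs:
        ref_dg[s] = _dock_and_score(s, groove, template_library, cfg,
                                    None, params)
    return seqs, ref_dg


def _blocked_groove(groove):
    """A variant whose C-end pocket is sterically obstructed."""
    from anchordock.structio import Atom, Residue
    blocked = groove.copy()
    plugs = [Residue("GLY", 400 + k, "",
                     [Atom("CA", "C", [26.0 + 0.8 * k, 0.0, -1.0])])
             for k in range(4)]
    blocked.chains["A"] = blocked.chains["A"] + plugs
    blocked.id = groove.id + "_blocked"
    return blocked


def test_blocking_variant_loses_more_peptides_than_self(
        groove, template_library, screen_setup):
    seqs, ref_dg = screen_setup
    cutoff = max(ref_dg.values()) + 2.0  # reference binders sit below it
    threshold = ThresholdModel(cutoff, cutoff - 10, cutoff + 10, 0, 0, 0.1)
    model_set = SubstitutionModelSet(
        {(9, "G"): groove.copy(), (116, "W"): _blocked_groove(groove)},
        groove.id, pd.DataFrame())
    result = substitution_screen(seqs, groove, model_set,
                                 template_library, threshold)
    assert result.n_entries == len(seqs) * 2
    self_frac = result.fraction_lost.get("9G", np.nan)
    blocked_frac = result.fraction_lost.get("116W", np.nan)
    self_rows = result.table[result.table["model"] == "9G"]
    assert np.allclose(self_rows["ddg"].dropna(), 0.0, atol=1e-9)
    assert self_frac == 0.0
    # blocked pocket: higher dG, peptides lost or failed outright
    blocked_rows = result.table[result.table["model"] == "116W"]
    lost_or_failed = (blocked_rows["lost"] | blocked_rows["failed"]).mean()
    assert lost_or_failed > self_frac


def test_screen_bookkeeping_conserves_entries(groove, template_library):
    threshold = ThresholdModel(0.0, -10, 10, 0, 0, 0.1)
    model_set = SubstitutionModelSet({(9, "G"): groove.copy()},
                                     groove.id, pd.DataFrame())
    result = substitution_screen(["SLYNTVATL"], groove, model_set,
                                 template_library, threshold)
    assert result.n_entries == 1
    scored = (~result.table["failed"]).sum()
    assert scored + result.n_failed == result.n_entries
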