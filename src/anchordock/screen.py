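"""Binder classification and the non-permissive substitution screen.

Calculated binding free energies are only qualitatively comparable to
experimental affinities, so binding is decided by a threshold fitted on
score distributions: a Gaussian KDE per class, the two density peaks
(modes), and the midpoint between them as the cutoff.  A peptide binds
iff its dG is strictly below the cutoff.  The substitution screen builds
one receptor variant per observed residue at the five high-risk heavy
chain positions (9, 114, 116, 152, 156), re-docks a peptide pool against
the reference and every variant, and reports per-model ddG distributions
and the fraction of reference binders predicted to lose binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from . import data as _data
from .dock import DockConfig, PoseFailure, dock_peptide
from .energy import ForceFieldParams, binding_dg, minimize_cartesian, parameterize
from .pepmodel import (RotamerLibrary, TemplateLibrary, _best_rotamer,
                       _strip_to_backbone, build_peptide)
from .structio import GrooveDefinition, Structure, heavy_chain_id
from .topology import ONE_TO_THREE, STANDARD_RESIDUES, THREE_TO_ONE

__all__ = ["AffinityRecord", "ThresholdModel", "SubstitutionModelSet",
           "ScreenResult", "load_affinity_table", "fit_threshold",
           "classify", "roc_auc", "build_substitution_models",
           "substitution_screen", "HIGH_RISK_POSITIONS"]

IC50_BINDER_NM = 500.0   # inclusive binder boundary
HIGH_RISK_POSITIONS = (9, 114, 116, 152, 156)
SUBSTITUTION_CLASH = 2.4  # A


@dataclass(frozen=True)
class AffinityRecord:
    peptide: str
    ic50: float | None
    qualitative: str | None
    binder: bool


@dataclass
class ThresholdModel:
    cutoff: float
    binder_mode: float
    nonbinder_mode: float
    t_statistic: float
    p_value: float
    kde_bandwidth: float
    rule: str = "midpoint_modes"

    @property
    def usable(self) -> bool:
        return self.binder_mode < self.nonbinder_mode


@dataclass
class SubstitutionModelSet:
    models: dict            # (position, one-letter residue) -> Structure
    reference_id: str
    provenance: pd.DataFrame
    flagged: list = field(default_factory=list)

    def __len__(self):
        return len(self.models)


@dataclass
class ScreenResult:
    table: pd.DataFrame        # long: model, peptide, dg_ref, dg_var, ddg, lost, failed
    fraction_lost: pd.Series   # per model
    n_failed: int

    @property
    def n_entries(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Affinity data


def _is_positive(label: str) -> bool:
    return str(label).strip().lower().startswith("pos")


def load_affinity_table(path: str | Path) -> list[AffinityRecord]:
    """Read and curate a peptide affinity table (TSV/CSV).

    Expected columns: ``peptide`` plus ``ic50_nM`` and/or ``qualitative``.
    Curation: drop non-9-mers and sequences with non-standard letters,
    drop duplicate sequences (first occurrence kept), drop records whose
    quantitative and qualitative labels disagree.  Binder = IC50 <= 500
    nM (boundary inclusive) or a positive qualitative label.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "peptide" not in df.columns:
        raise ValueError(f"{path}: missing required column 'peptide'")
    has_ic50 = "ic50_nM" in df.columns
    has_qual = "qualitative" in df.columns
    if not has_ic50 and not has_qual:
        raise ValueError(f"{path}: need an 'ic50_nM' or 'qualitative' column")
    records: list[AffinityRecord] = []
    seen: set[str] = set()
    for row in df.itertuples():
        seq = str(row.peptide).strip().upper()
        if len(seq) != 9 or any(c not in ONE_TO_THREE for c in seq):
            continue  # dropped: wrong length or non-standard letter
        if seq in seen:
            continue  # duplicate: keep first by file order
        ic50 = getattr(row, "ic50_nM", None) if has_ic50 else None
        if ic50 is not None and (pd.isna(ic50)):
            ic50 = None
        qual = getattr(row, "qualitative", None) if has_qual else None
        if qual is not None and (pd.isna(qual) or not str(qual).strip()):
            qual = None
        if ic50 is None and qual is None:
            continue
        if ic50 is not None and qual is not None:
            if (float(ic50) <= IC50_BINDER_NM) != _is_positive(qual):
                continue  # conflicting labels: dropped
        binder = (float(ic50) <= IC50_BINDER_NM) if ic50 is not None \
            else _is_positive(qual)
        seen.add(seq)
        records.append(AffinityRecord(seq,
                                      float(ic50) if ic50 is not None else None,
                                      str(qual) if qual is not None else None,
                                      binder))
    return records


# ---------------------------------------------------------------------------
# Threshold classifier


def fit_threshold(binder_scores, nonbinder_scores,
                  rule: str = "midpoint_modes",
                  bandwidth: str | float = "silverman") -> ThresholdModel:
    """Density-peak threshold between binder and non-binder score pools.

    Fits a Gaussian KDE per class, locates each density's mode, and puts
    the cutoff at the midpoint between the two modes (``rule=
    'midpoint_means'`` uses the class means instead).  Also reports the
    two-sample t-test on the class means.
    """
    b = np.asarray(binder_scores, dtype=float)
    n = np.asarray(nonbinder_scores, dtype=float)
    if len(b) < 20 or len(n) < 20:
        raise ValueError("need at least 20 scores per class")
    if b.std() == 0 or n.std() == 0:
        raise ValueError("degenerate (zero-variance) score distribution")
    kde_b = stats.gaussian_kde(b, bw_method=bandwidth)
    kde_n = stats.gaussian_kde(n, bw_method=bandwidth)
    lo = min(b.min(), n.min()) - 3 * max(b.std(), n.std())
    hi = max(b.max(), n.max()) + 3 * max(b.std(), n.std())
    grid = np.linspace(lo, hi, 4001)
    mode_b = float(grid[np.argmax(kde_b(grid))])
    mode_n = float(grid[np.argmax(kde_n(grid))])
    if rule == "midpoint_modes":
        cutoff = 0.5 * (mode_b + mode_n)
    elif rule == "midpoint_means":
        cutoff = 0.5 * (b.mean() + n.mean())
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    t_stat, p_val = stats.ttest_ind(b, n, equal_var=False)
    return ThresholdModel(float(cutoff), mode_b, mode_n, float(t_stat),
                          float(p_val), float(kde_b.factor), rule)


def classify(score: float, model: ThresholdModel) -> str:
    """'binder' iff the score is strictly below the cutoff."""
    return "binder" if score < model.cutoff else "nonbinder"


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC for free-energy-like scores (lower = binder).

    Equals the probability that a random binder outscores a random
    non-binder, with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, -scores))
    fpr, tpr, thr = roc_curve(labels, -scores)
    return ROCResult(auc, fpr, tpr, -thr)


# ---------------------------------------------------------------------------
# Substitution models


def build_substitution_models(reference_hla: Structure,
                              table: pd.DataFrame | None = None,
                              rotamer_lib: RotamerLibrary | None = None,
                              params: ForceFieldParams | None = None,
                              positions: list[int] | None = None,
                              minimize: bool = True) -> SubstitutionModelSet:
    """One receptor variant per observed residue at each high-risk position.

    The side chain is replaced by its highest-prior rotamer, falling back
    to the next rotamer when a pair distance below 2.4 A against the
    surroundings occurs; a model with no clash-free rotamer is flagged
    and retained best-effort.  ``minimize=False`` (enumeration mode)
    skips the local minimization of the substituted residue.
    """
    table = table if table is not None else _data.load_highrisk_table()
    rotamer_lib = rotamer_lib or RotamerLibrary.default()
    hca = heavy_chain_id(reference_hla)
    by_num = {r.number: r for r in reference_hla.chains[hca]}
    models: dict[tuple[int, str], Structure] = {}
    flagged = []
    for trow in table.itertuples():
        pos = int(trow.position)
        if positions is not None and pos not in positions:
            continue
        if pos not in by_num:
            raise ValueError(f"position {pos} absent from chain {hca}")
        for letter in str(trow.observed_residues):
            res_name = ONE_TO_THREE[letter]
            variant = reference_hla.copy()
            residues = variant.chains[hca]
            idx = next(i for i, r in enumerate(residues) if r.number == pos)
            res = residues[idx]
            res.name = res_name
            _strip_to_backbone(res)
            if res_name != "GLY":
                from .topology import build_side_chain
                from .structio import Atom
                bb = {n: res.atom(n).coords for n in ("N", "CA", "C")}
                res.atoms.append(Atom("CB", "C",
                                      build_side_chain(res_name, bb,
                                                       (0.0,) * 4)["CB"]))
            from .scoring import atom_view
            ctx = atom_view([r for k, r in enumerate(residues) if k != idx]
                            + [r for cid, ch in variant.chains.items()
                               if cid != hca for r in ch])
            chosen = None
            for rot_i, (chis, prior) in enumerate(
                    rotamer_lib.for_residue(res_name)):
                from .pepmodel import _trial_residue, _rotamer_interaction
                from .topology import build_side_chain as _bsc
                bb4 = {n: res.atom(n).coords for n in ("N", "CA", "C", "O")}
                sc = _bsc(res_name, bb4, chis)
                trial = _trial_residue(res, sc) if sc else res
                mobile = set(sc) - {"CB"}
                if mobile and len(ctx):
                    tv = np.array([a.coords for a in trial.atoms
                                   if a.name in mobile])
                    dmin = np.sqrt(((tv[:, None] - ctx.coords[None]) ** 2
                                    ).sum(-1)).min()
                else:
                    dmin = np.inf
                if dmin >= SUBSTITUTION_CLASH:
                    chosen = trial
                    break
                if chosen is None:
                    chosen = trial   # best-effort: top-prior rotamer
            else:
                if (pos, letter) not in flagged:
                    flagged.append((pos, letter))
            residues[idx] = chosen
            if minimize and res_name != "GLY":
                params = params or ForceFieldParams.default()
                system = parameterize(variant, params)
                mobile_mask = np.array(
                    [(cid == hca and num == pos and an not in
                      ("N", "CA", "C", "O"))
                     for cid, _rn, num, an in system.labels])
                variant, _, _ = minimize_cartesian(variant, mobile_mask,
                                                   params, maxiter=15,
                                                   system=system)
            variant.id = f"{reference_hla.id}_{pos}{letter}"
            models[(pos, letter)] = variant
    return SubstitutionModelSet(models, reference_hla.id, table, flagged)


# ---------------------------------------------------------------------------
# The screen


def _dock_and_score(peptide_seq: str, receptor: Structure,
                    library: TemplateLibrary, config: DockConfig,
                    groove_def: GrooveDefinition | None,
                    params: ForceFieldParams,
                    rotamer_lib: RotamerLibrary | None = None) -> float:
    pep = build_peptide(peptide_seq, library, rotamer_lib,
                        receptor_frame=receptor, params=params)
    pose, complex_ = dock_peptide(pep, receptor, library, config,
                                  groove_def, params)
    (pep_cid,) = pose.peptide.chains
    receptor_chains = [c for c in complex_.chains if c != pep_cid]
    return binding_dg(complex_, receptor_chains, [pep_cid], params).dg


def substitution_screen(peptides: list[str], reference_hla: Structure,
                        model_set: SubstitutionModelSet,
                        library: TemplateLibrary,
                        threshold: ThresholdModel,
                        config: DockConfig | None = None,
                        groove_def: GrooveDefinition | None = None,
                        params: ForceFieldParams | None = None,
                        rotamer_lib: RotamerLibrary | None = None
                        ) -> ScreenResult:
    """Dock each peptide against the reference and every variant.

    A peptide is lost for a model iff its variant dG is at or above the
    fitted cutoff.  Per-item failures are recorded, never fatal, and the
    bookkeeping invariant scored + failed = peptides x models holds.
    """
    config = config or DockConfig()
    params = params or ForceFieldParams.default()
    ref_dg: dict[str, float] = {}
    rows = []
    for seq in peptides:
        try:
            ref_dg[seq] = _dock_and_score(seq, reference_hla, library,
                                          config, groove_def, params,
                                          rotamer_lib)
        except (PoseFailure, ValueError, RuntimeError) as exc:
            ref_dg[seq] = np.nan
    for key, variant in model_set.models.items():
        model_name = f"{key[0]}{key[1]}"
        for seq in peptides:
            row = {"model": model_name, "peptide": seq,
                   "dg_ref": ref_dg[seq], "dg_var": np.nan,
                   "ddg": np.nan, "lost": False, "failed": False}
            try:
                if np.isnan(ref_dg[seq]):
                    raise PoseFailure("reference docking failed")
                dg_var = _dock_and_score(seq, variant, library, config,
                                         groove_def, params, rotamer_lib)
                row["dg_var"] = dg_var
                row["ddg"] = dg_var - ref_dg[seq]
                row["lost"] = bool(dg_var >= threshold.cutoff)
            except (PoseFailure, ValueError, RuntimeError):
                row["failed"] = True
            rows.append(row)
    table = pd.DataFrame(rows)
    scored = table[~table["failed"]]
    frac = scored.groupby("model")["lost"].mean()
    return ScreenResult(table, frac, int(table["failed"].sum()))
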