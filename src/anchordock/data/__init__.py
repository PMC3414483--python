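"""Packaged reference data and loaders.

Contents
--------
groove_residues.json
    The 37 solvent-accessible residue numbers delineating the HLA-A*02:01
    peptide-binding groove.
benchmark_set.tsv
    The 50-complex HLA-A*02:01 nonamer benchmark: PDB id, resolution (A)
    and peptide sequence.
highrisk_positions.tsv
    The five high-risk non-permissive heavy-chain positions (9, 114, 116,
    152, 156) with groove location, peptide contacts and the amino acids
    observed across HLA-A alleles at each.
rotamers.tsv
    Backbone-independent side-chain rotamer library: modal chi-angle sets
    with prior probabilities (sum to 1 per residue type).
lj_types.tsv / charges.tsv
    Minimal united-hydrogen heavy-atom force-field tables: per-type
    Lennard-Jones and generalized-Born parameters, and per-residue
    partial charges.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

_PKG = resources.files(__name__)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_PKG / name) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_groove_residues() -> list[int]:
    return json.loads((_PKG / "groove_residues.json").read_text())


def load_benchmark_table() -> pd.DataFrame:
    """50-row table: pdb_id, resolution, sequence (all nonamers)."""
    return _read_tsv("benchmark_set.tsv")


def load_highrisk_table() -> pd.DataFrame:
    """Observed residues at the five high-risk positions."""
    return _read_tsv("highrisk_positions.tsv")


def load_rotamer_rows() -> pd.DataFrame:
    return _read_tsv("rotamers.tsv")


def load_lj_types() -> pd.DataFrame:
    return _read_tsv("lj_types.tsv")


def load_charges() -> pd.DataFrame:
    return _read_tsv("charges.tsv")
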