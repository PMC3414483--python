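"""The non-permissive substitution screen at the five high-risk positions.

Enumerates the observed residues at heavy-chain positions 9, 114, 116,
152 and 156 into 35 receptor variants, then runs a small ddG screen of
peptides against the reference and a subset of variants.
"""

import pandas as pd

from anchordock import build_substitution_models, build_template_library
from anchordock.data import load_highrisk_table
from anchordock.fixtures import FixtureSpec, generate_complex, \
    generate_groove
from anchordock.screen import ThresholdModel, substitution_screen

spec = FixtureSpec()
groove = generate_groove(spec)

models = build_substitution_models(groove, minimize=False)
print(f"{len(models)} substitution models from the observed residues:")
print(load_highrisk_table()[["position", "observed_residues"]]
      .to_string(index=False))

library = build_template_library(
    [generate_complex(spec, s, 2.0)
     for s in ("ILKEPVHGV", "SLYNTVATL")])
# screen against two variants plus an explicit self-substitution of the
# reference glycine at position 9 (a built-in ddG = 0 control)
control = build_substitution_models(
    groove, pd.DataFrame([{"position": 9, "observed_residues": "G"}]),
    minimize=False)
subset = {k: v for k, v in models.models.items()
          if k in [(9, "T"), (116, "T")]}
subset.update(control.models)
small = type(models)(subset, models.reference_id, models.provenance)

# an illustrative cutoff: in production this comes from fit_threshold on
# docked score pools
threshold = ThresholdModel(cutoff=5.0, binder_mode=-5.0,
                           nonbinder_mode=15.0, t_statistic=0.0,
                           p_value=0.0, kde_bandwidth=0.1)
result = substitution_screen(["SLYNTVATL"], groove, small, library,
                             threshold)
print("\nscreen results (ddG in kcal/mol, lost = predicted non-binder):")
print(result.table[["model", "peptide", "ddg", "lost", "failed"]]
      .to_string(index=False))
print(f"failed dockings: {result.n_failed}")

# The 9 G self-substitution control gives ddG = 0 exactly; real
# substitutions shift the docked dG and may push peptides past the
# binding cutoff -- the fraction lost per model is the screen's output.
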