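"""Peptide-excluded superposition and per-position RMSD conservation.

Generates a noisy ensemble of complexes (Gaussian coordinate noise plus
random rigid displacement), superposes every copy onto the first using
only HLA-chain atoms, and summarizes pairwise backbone RMSDs per groove
position and per peptide position P1-P9.
"""

import numpy as np

from anchordock import default_groove, per_position_rmsd, \
    peptide_variability, superpose_complexes
from anchordock.fixtures import FixtureSpec, generate_ensemble

spec = FixtureSpec(seed=3, n_structures=12, coordinate_noise_sigma=0.3)
ensemble = generate_ensemble(spec)

ref = ensemble[0]
aligned, transforms = [ref], [None]
from anchordock.superpose import RigidTransform
transforms = [RigidTransform.identity()]
for s in ensemble[1:]:
    moved, t, rmsd = superpose_complexes(ref, s)
    aligned.append(moved)
    transforms.append(t)

groove_table = per_position_rmsd(aligned,
                                 list(default_groove().residue_numbers))
print("groove conservation (mean pairwise backbone RMSD per position):")
print(groove_table.table["mean"].describe().round(3).to_string())

pep_table = peptide_variability(ensemble, transforms)
print("\npeptide variability P1..P9 (A):")
print(pep_table.table["mean"].round(3).to_string())

# With sigma = 0.3 A of injected noise, pairwise RMSDs concentrate near
# sigma * Gamma(6.5)/Gamma(6) ~ 0.72 A; flat values across positions show
# the noise is homogeneous, unlike real complexes where anchors are
# stiffer than the peptide middle.
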