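# Methods

## Scope and model

`anchordock` models nonameric peptide binding to the HLA-A\*02:01 class I
groove under three structural assumptions that the package both exploits
and lets you test:

1. the HLA heavy chain is rigid to a good approximation across bound
   complexes (sub-Ångström per-position backbone deviations);
2. bound nonamers share a common backbone scaffold whose P1, P2 and P9
   anchors occupy nearly fixed positions; and
3. given the scaffold, binding differences are dominated by side-chain
   packing and can be ranked by an implicit-solvent interaction energy.

The pipeline is therefore template-based end to end: peptide backbones
come from P1-keyed templates, placement comes from anchor superposition,
and only side chains plus a bounded rigid/flexible refinement search any
conformational space.

## Structure handling

PDB input goes through Bio.PDB: first model only, highest-occupancy
altloc (ties by label order), waters and heteroatoms skipped, hydrogens
dropped (the energy model is united-hydrogen). Author residue numbering
is authoritative for the heavy chain; peptide positions P1..P9 are
1-based chain order. Curation mirrors the benchmark-set filters: a
complex is accepted when its single peptide-length chain (8–12 residues)
is an ungapped run of standard residues with complete canonical heavy
atoms, and — in the default strict mode — exactly nine residues long.

Receptor bonded topology is derived from the residue templates plus the
inter-residue peptide bond; connection follows chain order and geometry
(C–N < 1.8 Å), not numbering, so chains whose author numbers jump (as in
the synthetic groove) stay correctly bonded. Bond keys are kept in
sorted order so floating-point accumulation order — and with it every
minimization trajectory — is reproducible across interpreter runs.

## Superposition and conservation analytics

Rigid superposition is a standard least-squares (Kabsch) fit, solved via
`scipy.spatial.transform.Rotation.align_vectors`; complexes are matched
residue-by-residue on heavy-chain author numbers and the bound peptide is
always excluded from the fit. "Backbone" means N, CA, C, O. Conservation
tables report, per position, the n·(n−1)/2 pairwise RMSDs summarized by
mean/median/quartiles/extremes with 1.5×IQR outliers. Multi-structure
sets are aligned onto the first structure in id order; pairwise RMSDs are
frame-independent, so the reference choice only fixes the output frame.

## Peptide modeling

The template library keeps, for each P1 residue observed in the input
set, the highest-resolution peptide (ties by structure id) with positions
2–9 stripped to backbone; the consensus anchor is the arithmetic mean of
the P1/P2/P9 backbone coordinates over all complexes in the common frame.
P1 residues without a template map to the key closest in heavy-atom count
and volume: H→F, W→Y, D→N, E→M, Q→M, P→A, C→S (user-overridable).

Side chains are built in internal coordinates (idealized bond lengths and
angles; a packaged backbone-independent rotamer table of modal χ sets
with priors that sum to one per residue type) and packed greedily N→C
with one clash-repair sweep. Each side chain minimizes
`E = −w_rot·ln p + E_vdW + E_hb` against the peptide frame, previously
placed side chains and an optional receptor reference frame, where
`w_rot = 3 kcal/mol`, `E_vdW` is a shifted 12-6 Lennard-Jones capped at
+10 kcal/mol per pair and `E_hb` a −1 kcal/mol geometric well
(donor–acceptor 2.6–3.4 Å, antecedent angle > 120°). CB is
χ-independent and excluded from rotamer-dependent scoring, which keeps
the greedy accumulation identical to the total of a complete assignment
— the property the exhaustive-search tests check on small cases. A
position with no rotamer farther than 1.5 Å from the context is a
placement failure. Model building ends with a short conjugate-gradient
minimization; the whole path is deterministic.

## Docking

The initial pose superposes the peptide's twelve anchor backbone atoms
onto the consensus anchor. Rigid refinement is greedy coordinate descent
over the six rigid degrees of freedom (0.1 Å translation, 1° rotation
about the peptide centroid, 50 sweeps), accepting only strict score
improvements — score = H-bond count − 0.2·E_vdW — and rejecting any move
that takes an atom more than 0.5 Å (cumulative) from its post-initial
position. The cap is enforced from the initial pose; the per-step
alternative reading would allow unbounded drift and is not offered.
Flexible refinement minimizes the vacuum MM energy with the peptide and
the 37 groove residues mobile and every other receptor atom fixed
(conjugate gradient, default 40 iterations); a result whose tightest
peptide–receptor contact is still under 1.5 Å counts as a pose failure,
reported per item rather than raised. `md_steps > 0` adds a seeded
random-shake-plus-reminimize stage; the default 0 keeps the pipeline
bitwise deterministic.

## Energy model

Minimal united-hydrogen heavy-atom force field, packaged as TSV tables:
per-element Lennard-Jones and GB parameters, per-residue partial charges
(neutral backbone unit; ±1 on Asp/Glu/Lys/Arg). Vacuum MM = harmonic
bonds/angles referenced to the idealized construction geometry + LJ
(linearly continued below 0.8·r_min so clashes stay finite and smooth) +
Coulomb, with 1-2/1-3 exclusions and 1-4 pairs scaled by 0.5; no
torsional term (backbone torsions are template-inherited and side-chain
torsions are rotamer-prior-governed, so a generic barrier term would add
parameters without information). No nonbonded cutoffs at this system
size.

Solvation: effective Born radii by Hawkins–Cramer–Truhlar pairwise
descreening (scaled intrinsic radii, no offset; effective radii capped at
50 Å in deep overlap), the standard GB cross-term
f_GB = sqrt(r² + R_iR_j·exp(−r²/4R_iR_j)), ε_in = 1, ε_out = 78.5, and a
nonpolar term γ·SASA with γ = 0.00542 kcal/mol/Å² over a deterministic
golden-spiral Shrake–Rupley surface (960 points, probe 1.4 Å, GB radii as
atomic radii). The per-state constant offset is 0 by default: under
single-geometry decomposition a nonzero constant would contribute
−b to every ΔG and break the exact non-interacting limit ΔG → 0; it
remains available as a configuration field for parameterizations that
want it. ΔG = G(complex) − G(receptor) − G(peptide) at the complex
geometry, no separate relaxation, entropy omitted — the single-trajectory
compromise. ΔG values are treated as qualitative throughout;
classification always goes through the fitted threshold.

## Classification and the substitution screen

Experimental records are labeled by IC50 ≤ 500 nM (boundary inclusive) or
a qualitative positive; duplicates keep the first occurrence and records
with conflicting quantitative/qualitative labels are dropped. The
threshold model fits a Gaussian KDE (Silverman bandwidth) per class,
takes each density's mode, and puts the cutoff midway between the modes
("mean difference between the density peaks"); the alternative reading —
midpoint of the class means — is available as `rule="midpoint_means"`.
A score classifies as binder iff strictly below the cutoff. ROC/AUC use
scikit-learn with ties counted one half; an independent pair-counting
oracle in the tests pins the equivalence.

Substitution models replace the side chain at one of the five high-risk
positions (9, 114, 116, 152, 156) with each residue observed across
HLA-A alleles there (5+9+8+6+7 = 35 models): highest-prior rotamer
first, next rotamer when any pair distance falls below 2.4 Å, flagged
best-effort when none is clash-free, then a short local minimization of
the substituted side chain (skipped in enumeration mode). The screen
docks every peptide against the reference and each variant; a peptide is
lost for a variant iff its variant ΔG is at or above the cutoff (the
absolute rule; a ΔΔG-margin rule would additionally need a margin
parameter the threshold already encodes). Failures are counted per item
and `scored + failed = peptides × models` always holds. Because the
pipeline is deterministic at `md_steps = 0`, re-substituting the
reference residue reproduces the reference structure exactly and its
ΔΔG is exactly zero — the screen's built-in control.

## Synthetic study conditions

The fixture generator emulates the geometry the method relies on, not HLA
physics: two 30-residue poly-alanine helical walls flank a poly-glycine
strand floor, enclosing a cavity ≈ 32 Å long (pocket-centroid distance
31–33 Å); two glycine ledges past the cavity ends present a carbonyl
acceptor toward the peptide N terminus and an amide donor toward the
C-terminal carbonyl, within 4 Å of the anchors. Residues carry the real
A\*02:01 groove numbering so selection, substitution and flexibility
code paths run unchanged. Peptides share one canonical extended-arc
backbone; side chains are packed per sequence in situ. Ensembles add
i.i.d. Gaussian coordinate noise plus a random rigid motion per copy;
with noise σ the per-position pairwise backbone RMSD concentrates at
σ·Γ(6.5)/Γ(6) ≈ 2.40σ, the closed form the recovery tests use. Score
pools draw two Gaussians at −50 and −20 kcal/mol (500 per class),
sd = 4 kcal/mol — a spread small enough against the 30 kcal/mol class
separation that the KDE density peaks are individually resolvable, as in
the clearly bimodal calculated-ΔG densities the threshold rule is
designed for.

What passing these tests shows — and does not show: the geometric
machinery (superposition, threading, anchored placement, capped
refinement, bookkeeping, determinism) behaves correctly, and the
statistical machinery recovers planted structure. The fixtures contain
no real pocket chemistry, so they say nothing about predictive accuracy
on experimental affinity data; reproducing benchmark statistics on real
crystal structures requires downloading the 50 PDB entries and is out of
desk scale.

## Problem sizes and numerics

Default sizes keep every stage interactive on one CPU: 50-complex
template builds in ~0.2 s, a full dock-and-score in ~4 s, the whole test
suite in under two minutes. Nonbonded sums are exact dense O(n²)
(n ≈ 500 atoms). Conjugate-gradient minimization stops at 40 iterations
or gradient norm 1e−3 and never returns a higher energy than its start.
Rotamer and refinement searches are fully enumerated/greedy with fixed
tie-breaks (first-listed wins), so no stage consumes randomness unless
`md_steps > 0` or a generator seed is involved.

## Known limitations

- United-hydrogen electrostatics cannot represent directional hydrogen
  bonding in the energy module; H-bonds enter only through the geometric
  scoring term used in packing and rigid refinement.
- The greedy packer with one repair sweep is not globally optimal for
  densely coupled side chains; exhaustive optimality is only guaranteed
  (and only asserted) for weakly coupled small cases.
- Absolute ΔG values are trajectory-sensitive on rough landscapes; only
  threshold-relative and variant-relative (ΔΔG) uses are supported
  claims.
- Peptide lengths other than nine, modified residues, explicit water and
  receptor backbone flexibility are out of scope.
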