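# Methods

## Model and assumptions

The package treats enzyme-variant activity prediction as a grid-based
QSAR problem in which the receptor, not the ligand, varies. Each assay
contributes an ensemble of conformations of a fixed atom topology
(enzyme active site + substrate). After rigid-body alignment, a cubic
lattice is evaluated with single-site probes; the two per-node quantities
are the ensemble means of a plain two-term pairwise potential
(Lennard-Jones 12-6 with geometric-mean combination of C6/C12, and
vacuum Coulomb with k_e = 332.0636 kcal·Å/(mol·e²), ε = 1). There are no
cutoffs, switching functions, periodic boundaries, polarization or
desolvation terms. Solvent atoms are excluded from the summation by
default (a role filter exposes the choice).

Assumptions this encodes:

- a *common frame* per code is sufficient — descriptors compare the same
  node across codes, so all codes are additionally superposed onto a
  reference code (first frame, conserved-atom selection);
- the ensemble mean is the right summary of the conformational
  distribution (the "fourth dimension");
- activity is (after descriptor selection) approximately linear in a
  modest number of local field values, which PLS can extract from a
  p ≫ n matrix.

## Numerical choices

- **Grid**: boundary-inclusive nodes; 24 Å at 1 Å spacing gives 25 nodes
  per axis, matching the 31,250-descriptors-per-probe bookkeeping of the
  production protocol. Node order is x-fastest and deterministic; labels
  store integer node indices so they are exact.
- **Distance clamp**: r ← max(r, 0.05 Å) before energy evaluation; nodes
  can coincide with atom positions and r = 0 is a true singularity.
- **Energy cap**: values < 30 kcal/mol pass unchanged; values in
  [30, 31] are pinned to 30; values > 31 become 30 + log10(E − 30). The
  pinning resolves the divergence of the residual-log formula as E → 30⁺
  while keeping the transform monotone. The log base is decimal by
  default and configurable. A `symmetric` option mirrors the compression
  onto E ≤ −30 for systems with strong attractive singularities; the
  default remains one-sided. Capping is applied to the per-code mean
  values (post-averaging), and is *not* idempotent on capped outputs —
  re-capping contracts values in (30, 40] toward 30 — so it is applied
  exactly once in the pipeline.
- **Superposition**: Kabsch via SVD with a determinant correction;
  degenerate (< 3 or collinear points) inputs are rejected. Fitting is
  unweighted. The fit selection must exclude atoms that differ across
  codes: fitting on a drifting site tilts the whole frame by a
  code-indexed amount and smears the mutation signal over every
  descriptor (verified empirically during development).
- **Correlation filter**: plain Pearson r, computed over the ten
  non-external codes only, so the external pair can never inform
  selection. Zero-variance columns have undefined r and are eliminated.
  Thresholds nest monotonically (0.5 ⊂ 0.45 ⊂ 0.4).
- **PLS**: scikit-learn's NIPALS `PLSRegression`, centering only by
  default (`autoscale` flag adds unit-variance scaling). The number of
  latent variables defaults to 2 (training sets have 7 samples); an
  `'auto'` option picks 1–5 by maximizing training LOO q². Models are
  stored as flat affine predictors (coefficients on the original scale,
  intercept = ȳ − x̄·β), which reproduces the library's predictions to
  machine precision and makes external prediction a single dot product.
- **Scores**: q² = 1 − PRESS/TSS with TSS about the evaluation set's own
  mean (the self-contained reading for test sets; a reference-mean
  argument exposes the train-mean alternative). RMSE in kcat units.
  Ranking filters by q²_test > q2_min and RMSE_test < rmse_max, sorts by
  ascending RMSE_test, ties broken by descending q²_test then split id
  (the id is the concatenated sorted test-code letters).
- **Confusion coding**: at the 85/sec limit "positive" is high activity;
  at 52/sec the coding inverts so low-activity enzymes are positives.
  Values exactly at a limit count as "below". Sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP); zero denominators raise rather than return 0.
- **Activity bands**: low ≤ 40.8 < moderate ≤ 71.2 < high ≤ 117 <
  very_high, the unique banding consistent with the bundled
  twelve-assay table (whose mean is 69.3/sec).

## The synthetic study generator

`gridqsar.synth` emulates the statistical structure the pipeline assumes
while remaining fully desk-scale and seeded. One scaffold (identical
across codes) contains: a 20-atom active-site ring, a 10-atom substrate
cluster, a 24-atom peripheral "protein bulk" shell at 6.5–8.5 Å, and a
two-atom *mutated site* at the pocket rim with a cleared solid angle in
front of it. A code's "mutation" gives that pair equal-and-opposite
charges growing linearly with the code index — a code-indexed dipole.
Conformations are i.i.d. Gaussian-jittered copies of the base structure
(frame 0 is the unjittered base, playing the minimized t = 0 structure),
then scattered by random rigid motions that the alignment stage must
undo. Planted activity is

    kcat_i = intercept + slope · (m_i − mean(m)) + N(0, noise_sd),

where m_i is the mean capped Coulomb energy, evaluated on the reference
frame, over grid nodes within `effect_radius` of a point `effect_offset`
in front of the mutated site. Defaults: 12 codes × 1000 conformations ×
54 atoms, 12 Å grid at 1 Å, jitter 0.10 Å, charge step 0.05 e/code,
effect ball offset 3.2 Å radius 2.4 Å, slope −25 (/sec)/(kcal/mol),
intercept 90/sec — producing kcat values spanning roughly 50–130/sec
with an exactly affine structure–activity relation.

Design rationale (each point was reached by falsifying the obvious
alternative):

- **Dipole, not monopole or steric latent.** A single-atom charge latent
  has a 1/r footprint that stays clean across the entire grid, so every
  Coulomb descriptor tracks activity and spatial enrichment of the
  planted region becomes statistically impossible. A C12 (steric) latent
  is local but lives on r⁻¹², whose ensemble mean under Gaussian jitter
  is dominated by rare close approaches and is therefore extremely
  noisy. The ±q pair decays as 1/r², strong enough locally and weak
  enough far away.
- **Reference-frame planting.** A laboratory kcat knows nothing about
  the sampling noise of a later simulation. Planting on the realized
  ensemble mean would build irreducible simulation noise into the
  dependent variable and bound external-prediction accuracy away from
  the few-tenths-of-a-percent regime the noiseless recovery test
  demands. The relation is still planted on *capped* energies, so the
  capping transform is exercised in-loop.
- **Centred relation.** The region's static-field offset is
  seed-dependent (long-range Coulomb of the random scaffold charges);
  centring m makes `intercept` the activity of the average code and
  keeps planted kcat positive for any seed.
- **Peripheral shell.** Without it the far field is so quiet that even
  tiny latent footprints survive the |r| filter everywhere; with a weak
  shell, far columns become half-noisy *survivors* that inject fresh
  noise into external predictions. The shell is strong enough
  (charges ±0.6 e at 6.5–8.5 Å) that far columns fail selection
  outright — they then can neither dilute enrichment nor perturb
  predictions. This mirrors a real active site embedded in protein bulk.

What the generator does **not** emulate: force-field physics (no bonds,
no excluded volume, no correlated dynamics), docking geometry, real
protease structure, solvent, or any relationship between the mutation
and realistic amino-acid chemistry. Passing the recovery tests therefore
shows that the *pipeline* is correct and sensitive under its own
assumptions — not that the method would succeed on any particular real
enzyme.

## Problem sizes

The desk-scale defaults (12 codes × 1000 conformations × 54 atoms on a
13³-node grid, one probe) run a full protocol — alignment, grids,
capping, three selection thresholds, 3 × 120 PLS fits with LOO, ranking,
external validation, metrics and mapping — in about a minute on one CPU.
The `production` preset widens the box to 24 Å (15,625 nodes; 156,250
descriptors per code with the five bundled probes) and runs in tens of
minutes. The acceptance script performs two full desk-scale runs
(noiseless and 5%-noise) plus the combinatorial anchors.

## Known limitations

- Probe parameters are effective single-site values bundled as an
  editable table; the production literature does not publish per-probe
  C6/C12, so absolute energies are not comparable to any published
  field, only their statistical use is.
- With ten codes, a |r| ≥ 0.45 univariate filter passes ~19% of pure
  noise columns; the PLS stage tolerates this but external predictions
  carry a corresponding noise floor. This is intrinsic to the protocol's
  sample size, not an implementation artifact.
- Cross-code alignment requires a shared fit selection; topologically
  different variants (insertions/deletions) are out of scope.
- The mapping stage reports residues near influential nodes; it does not
  claim mechanism, and region labels (LJ1…, C1…) of the original
  analysis are manual annotations we replace with neutral connected
  components.
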