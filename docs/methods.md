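# Methods

This note records the modelling conventions, defaults and design
decisions behind `qsar3d`, and what the synthetic test bed does and does
not demonstrate.

## Data model and alignment

A series is a list of rigid molecules with Cartesian coordinates (Å),
partial charges (e) and van der Waals radii. Radii default to the Bondi
table (C 1.70, N 1.55, O 1.52, S 1.80, Cl 1.75, H 1.20 Å); user radii
override. No charge model is computed — charges come from the input
files (MOL2 charge column, or a `PARTIAL_CHARGES` SDF property), because
charge assignment belongs to the structure-preparation stage, which is
out of scope along with conformer generation and energy minimisation.

Alignment is least-squares rigid superposition (Kabsch, SVD-based) of a
user-declared core-atom mapping onto a template, by default the most
active molecule in the input. It requires ≥ 3 non-collinear core atoms,
returns a proper rotation (det +1), and is idempotent to < 1e−9 Å.

## Lattice and fields

The grid has 2 Å spacing by default and extends at least 4 Å beyond
every atom's vdW sphere; node coordinates snap to integer multiples of
the spacing in the global frame, so the grid is a pure function of the
occupied region (a hull bound that lands exactly on a lattice plane is
treated as inside, tolerance 1e−9).

**Probe energies.** Steric: Lennard-Jones in the Rmin/ε form
`ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶]` with R_ij = r_i + r_probe and
ε_ij = √(ε_i ε_probe); probe ε = 0.107 kcal/mol, R = 1.70 Å (sp³
carbon). Per-element well depths ship in a small table (Tripos-era
magnitudes). Electrostatic: Coulomb with constant
332.0636 kcal·Å·mol⁻¹·e⁻² and distance-dependent dielectric ε(r) = r,
i.e. energy ∝ 1/r². Both energies truncate at ±30 kcal/mol (the steric
term only needs the +30 cap; the electrostatic cap is applied
symmetrically since a sign is conventionally not distinguished there).
At lattice nodes where a molecule hits the steric cap, its electrostatic
entry is replaced during matrix assembly by that column's mean over the
non-clashing molecules, so clash information is not double-encoded.
Distances are floored at 1e−6 Å purely to avoid division blow-ups; any
such node is capped anyway.

**Similarity indices.** `A_k(q) = Σᵢ w_probe,k · w_ik · e^(−α r²)` with
unit probe weights and α = 0.3 (the conventional default; sensible range
0.2–0.4). No cutoff — the Gaussian decays smoothly. Atom property
weights are rule-based on a unit scale consistent with the +1 probe:
steric = (r_vdw/1.70)³ (volume proxy, carbon ≡ 1); electrostatic = the
partial charge; hydrophobic = 1 for carbon and halogens, 0 for polar
atoms; donor = 1 for N/O bearing a hydrogen; acceptor = 1 for N/O. The
similarity index is used exactly as the formula above gives it (no sign
negation); commercial implementations differ in this convention, which
affects coefficient signs but not model statistics.

Columns are ordered field-major, x-fastest node order within a field.
Field selections cover the eight standard similarity-field combinations
plus the steric+electrostatic energy pair.

## PLS, preprocessing and model selection

Column filtering drops lattice columns whose *sample standard deviation*
falls below the minimum-sigma threshold ("energy variation" is read as
column sd). The default threshold is 2.0 kcal/mol for energy fields; for
similarity indices — dimensionless and mostly < 2 — the pipeline default
is 0 (no filter). Surviving columns are mean-centred and block-scaled so
each field's retained columns sum to unit total variance
(equal-field-weight convention); the response is centred only.

The PLS core is NIPALS with deflation of both X and y (tolerance 1e−12,
max 500 iterations per component, convergence error otherwise; extraction
stops early if the response is exhausted). Coefficients are
back-transformed to original descriptor units, so predictions,
contributions and contour maps need no stored latent structure.

Cross-validation refits the *entire* preprocessing inside every fold.
q² = 1 − PRESS/Σ(y−ȳ)² with ȳ the full-sample mean;
SEP = √(PRESS/(n−c−1)). SEE uses the same n−c−1 denominator and
F = (r²/c)/((1−r²)/(n−c−1)); these conventions were validated against
the published triple r² = 0.973 / SEE = 0.106 / F = 250.674 at n = 41,
c = 5, which they reproduce to < 1%. Leave-group-out draws one seeded
shuffle into 10 near-equal groups per run (not re-randomised per
component count).

The component count is chosen by a parsimony rule: starting at one
component, the next is adopted only while its q² gain over the current
choice exceeds 10% *relative* (an absolute reading changes selections;
the relative reading is documented prominently for that reason). Field
contributions are Σ_j |b_j|·s_j per field, normalised to 100%.

## Validation

*Bootstrap* (default 10 runs): rows resampled with replacement to the
original n, full refit, in-sample r²/SEE recorded; mean ± sd reported;
degenerate (constant-response) resamples are redrawn and logged.

*Progressive scrambling*: the response is partially scrambled — a
fraction λ of entries permuted among themselves — at
λ ∈ {0.05, 0.10, …, 0.50}, 3 draws per level (the mechanism and levels
are this package's choice; pairwise-within-subset permutation gives
smooth control of the original-vs-perturbed correlation). For each draw,
r²_yy′ is the squared Pearson correlation between original and perturbed
responses, and LOO q² and SDEP = √(PRESS/n) are computed on the
perturbed response. Cubic least-squares curves of q² and SDEP versus
r²_yy′ are read off at the critical point r²_yy′ = 0.85 (legacy default,
configurable): Q² (predictivity after redundancy removal), cSDEP, and
the stability slope b₁ + 2b₂x + 3b₃x². Slopes near 1 indicate a stable
model; > 1.2 an unstable one; Q² as low as 0.35 still signifies a robust
unperturbed model, so a pure-noise response must fall below 0.35. If
every draw keeps r²_yy′ > 0.95 the perturbation is too weak and an error
asks for stronger levels.

*External predictivity*: r²_pred = 1 − PRESS/SD, SD referenced to the
**training-set** mean activity. Negative values are reported as-is (the
model predicts worse than the training mean).

## Reference activity table

The packaged 61-compound table stores the published values verbatim:
substituent descriptions R1–R5, experimental pEC50, the two models'
predicted pEC50 and residuals, and the 20-compound test-set marks. The
loader checks res = exp − pred at 0.0015 (printed rounding) on every
row. Two published CoMSIA cells fail that identity and are kept verbatim
as documented errata: compound 14 (res 0.010 printed vs 0.055 implied)
and compound 40 (pred 6.928 printed where the residual implies 7.928 —
an apparent digit typo).

Two further internal inconsistencies of the published summary statistics
follow from the printed columns and are worth knowing when comparing
numbers:

* The printed CoMSIA training pairs give r² = 0.929 / SEE = 0.171
  (n = 41, c = 5), not the published 0.923 / 0.178; the printed CoMSIA
  prediction column evidently does not regenerate the published CoMSIA
  summary cells exactly (the CoMFA column does).
* Applying the published r²_pred formula (test-set PRESS over SD about
  the training mean) to the printed columns gives 0.806 (CoMFA) and
  0.804 (CoMSIA), not the published 0.904 / 0.730. Computing
  1 − PRESS/SD over *all 61* compounds instead reproduces the CoMFA
  value (0.906 ≈ 0.904), which strongly suggests the published CoMFA
  number included the training compounds; no convention we tried
  reproduces the published CoMSIA 0.730. The package computes the
  statistic as defined — test compounds only.

## Synthetic test bed

The generator emulates a congeneric series: a rigid 8-atom core and five
fixed substituent sites, each independently occupied (p = 0.75) by an
atom from {H, C, N, O, Cl} with a random small charge. Defaults mirror
the reference study's conditions: 40 molecules, activities spanning 3
log units around pEC50 6.5, noise sd 0.1 pEC50 units, and a sparse
ground truth of 3 active lattice nodes (picked among high-variance,
mutually distant columns; weights scaled once so the noiseless signal
spans exactly the 3 log units). The same seed reproduces the identical
series, and with zero noise the stored molecules and weights reproduce
the activities to 1e−10.

What passing on this bed shows: the field computations, preprocessing,
PLS, cross-validation, scrambling machinery and contour mapping are
internally correct and can recover a planted sparse linear field →
activity relationship (q² ≥ 0.99 noiseless; contour maps rank the
planted nodes with Spearman ≥ 0.8). What it does not show: performance
on real conformational ensembles, alignment uncertainty, charge-model
error, or activity cliffs — the synthetic molecules are points at fixed
sites, chemically unconstrained, and their "activities" follow the
package's own field model by construction. Published q² values that
depend on the authors' minimized structures and a commercial engine's
exact fields are therefore checked qualitatively (signal recovered,
negative controls fail), not numerically.

## Numerical details and degenerate inputs

* All randomness (group CV, bootstrap, scrambling, synthesis) descends
  from one master seed via spawned child sequences recorded in the
  report; identical seed ⇒ byte-identical report JSON and map exports.
* Percentile contour levels use linear-interpolation percentiles of the
  nonzero node values (defaults 80/20); an all-zero map is an error.
* A 0-component model predicts the training mean everywhere.
* Ties in component selection favour fewer components.
* Problem sizes used in the shipped tests (40 × ~5400 descriptor blocks,
  LOO over 30–40 compounds, 30 scrambling draws) keep the full suite
  around half a minute while exercising every stage end to end.
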