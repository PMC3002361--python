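# Methods

## Scope and representation

`zfdyn` analyses conformational ensembles of protein–DNA complexes at one
site per residue: the Cα atom of each amino acid and the C1′ atom of each
deoxyribose (the older PDB spelling `C1*` is accepted). All internal lengths
are nanometres; PDB Ångström values are converted on read and reconverted on
write. Generating the ensembles themselves (force fields, thermostats,
solvation) is outside the package's scope: it consumes coordinates, from
multi-model PDB files or a plain per-frame TSV, and descriptor tables.

Ensembles from independent simulation runs are concatenated after dropping a
leading equilibration span from each run — either a frame fraction or a time
span. The pipeline default trims the leading 25% of each run, matching the
common protocol of discarding the first 5 ns of 20 ns replicas.

## Superposition

Covariance and RMSF must reflect internal motion only, so frames are
superposed by optimal least-squares rotation + translation (Kabsch, via
SVD with a determinant correction to exclude reflections). The default
reference is the evolving mean structure: fit all frames to the current
mean, recompute the mean, and iterate until the mean moves by less than
1e-6 nm RMS (at most 10 rounds). The iteration is seeded with the current
ensemble mean, which makes the operation idempotent at its fixed point.
Fewer than three non-collinear fit sites leaves the rotation
underdetermined and is an error. Our Kabsch implementation is cross-checked
against MDAnalysis' rotation matrix in the test suite.

## Covariance analysis and essential dynamics

The positional covariance is the population moment
C = ⟨(x − ⟨x⟩)(x − ⟨x⟩)ᵀ⟩ over frames of the flattened 3N coordinate
vector; all averages in the package divide by n, not n−1, because the
quantities of interest are ensemble averages rather than unbiased
estimators. The eigendecomposition (numpy `eigh`) is stored with
eigenvalues descending and each eigenvector's sign canonicalized so its
largest-magnitude component is positive.

The essential subspace at variance fraction f (default 0.9) is the smallest
m with Σ_{k≤m} λ_k ≥ f Σ_k λ_k. Per-site RMSF is computed by projecting
each frame's displacement from the mean onto the top-m eigenvectors,
reconstructing, and taking √⟨|Δx_i|²⟩ per site; at m = 3N this is the
ordinary RMSF and Σ_i RMSF_i² = tr C exactly (Parseval), which the tests
assert. The scalar flexibility descriptor is the RMSF sum over a site
subset: protein sites only ("protein flexibility") or all sites ("complex
flexibility"). Both molecule classes are analysed in one joint covariance
and one joint essential subspace; computing the DNA contribution in a
separate subspace would be an alternative convention, and the site-subset
interface makes that easy, but the joint form is the default.

The covariance is unweighted (no masses) for ED/RMSF — fluctuations are
reported in nm — and mass-weighted only inside the entropy estimate, where
the formula requires it.

## Schlitter entropy

S = (k_B/2) ln det[ 1 + (k_B T e²/ħ²) M^{1/2} C M^{1/2} ], with M the
diagonal mass matrix (one mass per site, repeated over x, y, z; amu
converted to kg) and C in m². The value is reported per mole in J/(mol K)
with a kcal/(mol K) convenience property. S is zero for zero covariance and
strictly increasing in C (Löwner order), and for a single harmonic degree
of freedom with C = k_B T/(mω²) it reduces to
(k_B/2) ln(1 + (e k_B T/(ħω))²) — the closed form used as the oracle in the
tests. When a topology carries no masses the pipeline substitutes 110 amu
per amino-acid residue and 308 amu per nucleotide (average residue masses).

## Internal coordination and rigidity matrix

For sites i, j with |i − j| > 1,
R_ij = 1 / Σ_{k=1..3} [⟨(Δx_ij^k)²⟩ − ⟨Δx_ij^k⟩²] where Δx_ij^k is the k-th
Cartesian component of the inter-site vector; R_ij = 0 on the diagonal and
for nearest neighbours, whose bonded proximity would otherwise dominate the
matrix. Pairs rigid to numerical precision are capped at a finite
cap_value (default 1e6 nm⁻²) rather than excluded, and the cap is recorded.
The band rule is applied to site indices without special-casing chain
boundaries; restricting the computation to one molecule (e.g. protein-only
matrices) is done through the site-selection argument.

Superposition is *not* required: inter-site difference vectors are invariant
under rigid translation of a frame, and the implementation uses the
variance identity Var(x_i − x_j) = Var(x_i) + Var(x_j) − 2 Cov(x_i, x_j)
per component, which is O(N² + FN) instead of O(FN²) for the naive loop.
The naive per-pair loop is kept in the tests as the independent oracle.

Because the matrix is symmetric and entrywise non-negative, its largest
eigenvalue is the Perron root; it is reported as the overall
dynamic-coordination parameter ("main eigenvalue" read as the largest,
since high values mean high coordination). The rigidity profile is the
matching eigenvector, sign-fixed to a non-negative sum, with each absolute
component multiplied by the eigenvalue (components weighted by the
eigenvalue, not squared). An all-zero matrix has no defined profile (error);
the coordination summary of a zero matrix is 0.

## Energy decomposition

The N×N matrix M of trajectory-mean nonbonded residue-pair energies
(kcal/mol, zero diagonal: self-interaction excluded) is eigendecomposed,
M_ij = Σ_k λ_k w_ik w_jk with λ_1 the most negative ("lowest") eigenvalue.
The identities E_nb = ½ Σ_ij M_ij = ½ Σ_k λ_k W_k with W_k = (Σ_i w_ik)²
hold exactly and are asserted to 1e-8 on random matrices. When λ_1 W_1
dominates, E_nb ≈ E_nb^app = ½ λ_1 W_1; the dominance ratio
|λ_1 W_1| / Σ_k |λ_k W_k| is attached to every decomposition so the
approximation's applicability can be checked. The first eigenvector is
sign-fixed to a non-negative component sum; W_1 and the squared-component
weights are sign-invariant, so no result depends on the convention.

Hot spots are residues with w_i1² strictly above the flat-vector threshold
1/N (with a 1e-9 relative tolerance so that an exactly flat eigenvector
yields no hot spots under round-off).

E_nb^app partitions exactly by molecule class: with s_P = Σ_{i∈protein} w_i1
and s_D = Σ_{i∈DNA} w_i1, the protein–protein, protein–DNA and DNA–DNA
blocks are ½λ₁s_P², λ₁s_P s_D and ½λ₁s_D², summing to ½λ₁(s_P+s_D)² =
E_nb^app. This rank-1 partition is the default reported quantity; raw block
sums of ½ΣM_ij are exposed separately for comparison. The *intra-protein*
energy is a different quantity: the protein-only submatrix is extracted and
decomposed on its own, and its E_nb^app reported.

Energy matrices come from two routes. The primary route for
force-field-grade energetics ingests a TSV of precomputed pair means (site_i, site_j, mean_kcal_mol, sd_kcal_mol;
pairs may be listed once and are symmetrized; conflicting duplicates and
nonzero self-pairs are rejected). Alternatively, a simple screened-Coulomb
model computes matrices from coordinates: E_ij = k_e q_i q_j/(ε(r) r) with
ε constant or distance-dependent (ε(r) = ε₀·r[Å], a standard
implicit-solvent surrogate), optional Lennard-Jones 12-6 with
Lorentz-Berthelot-style combining on (ε, r_min/2), optional shifted
truncation at a cutoff, and a configurable frame stride (default 1; the
pipeline samples one frame per saved interval). This model produces
structurally sensible matrices for testing and exploration; it is not a
substitute force field, and absolute energies from it should not be
compared against published per-complex values.

## Affinity statistics

Descriptors are correlated against log₁₀(K_d/nM) with the Pearson
product-moment coefficient plus the least-squares line (scipy
`linregress`). K_d must be supplied in nM; the log base only rescales the
slope, never r. Correlations over the seven packaged complexes are
descriptive statistics at n = 7 — no significance testing or
multiple-testing correction is attached, and none should be inferred. An
untransformed-K_d variant is exposed (`transform="linear"`) and gives
comparable coefficients on the packaged data.

The packaged tables (`zfdyn/data/*.tsv`) carry the published experimental
dissociation constants and published per-complex descriptors of the seven
Zif268 zinc-finger variants; they let the correlation stage run without the
original trajectories, which were never deposited.

## Synthetic generators

The generators exist so that every operator has a ground-truth test:

- `gaussian_ensemble` draws frames from N(mean, C) with C given explicitly,
  as planted orthonormal modes, or from an elastic network: the isotropic
  Gaussian-network form, C = k_B T/k · L⁺ ⊗ I₃ with L the contact Laplacian
  at a cutoff (default 1.0 nm) and k a uniform spring constant. Frames are
  generated already superposed; a rigid-body-noise option un-superposes
  them for exercising the fitting stage.
- `planted_energy_matrix` builds λ₁ w wᵀ + symmetric zero-mean Gaussian
  noise with a designated hot-spot set carrying a component ratio (default
  3) over background sites. By default the diagonal is forced to zero, as
  in real pair-energy matrices; note this perturbs the rank-1
  eigenstructure (for a single strong hot spot at N = 4 the squared weight
  drops from 0.75 to ≈0.41), so exact-recovery tests use
  `zero_diagonal=False` while hot-spot-recovery tests use the default.
  At a per-entry noise s.d. of 5% of |λ₁| the noise bulk grows as ≈2σ√N,
  so reliable exact recovery of the planted set is a small-N property; the
  Monte-Carlo benchmark uses N = 5 with two hot spots, where recovery
  exceeds 95% of seeds.
- `synthetic_affinity_set` samples a descriptor uniformly and sets
  log₁₀ K_d = intercept + slope·descriptor + noise, for correlation- and
  slope-recovery tests.

All generators are pure functions of their arguments including the seed
(numpy `default_rng`; no global state). What the generators do *not*
emulate: anharmonicity, fat-tailed fluctuations, force-field-accurate
energetics, sequence-specific DNA structure. Tests passing on them
validate the estimators' algebra and statistical recovery, not the
biophysical accuracy of any particular simulation.

## Pipeline

`run_pipeline` takes a YAML/dict configuration (per complex: ensemble PDBs,
a synthetic spec, or precomputed descriptors, plus K_d in nM; global
settings: variance fraction 0.9, trim fraction 0.25, ICRM cap 1e6 nm⁻²,
stride 1, 300 K, seed). Stages per complex: superpose → covariance/ED →
subspace RMSF and flexibility sums → Schlitter entropy → ICRM and rigidity
profile → energy matrix (read, computed, or planted) → decomposition, hot
spots, partition, intraprotein energy. A failing complex is isolated and
logged; the cross-complex correlation stage runs when at least three
complexes survive. Per-complex synthetic seeds are derived from the global
seed and a stable digest of the complex id, so reports are byte-identical
for identical configuration + seed; the manifest records the package
version, settings and a configuration digest, and deliberately contains no
wall-clock information.

## Problem sizes and numerical choices

The test and acceptance benchmarks use sizes chosen to make the checked
properties sharp and the suite fast: 5-site/20-frame ensembles against the
ICRM brute-force oracle (agreement to 1e-10 relative), 10 000-frame
Gaussian ensembles for covariance-mode recovery (leading-eigenvector
overlap > 0.95), 100 seeds for hot-spot recovery and 200 seeds × 50
complexes for slope recovery (mean within 5% of the planted value).
Eigen-solves use symmetric routines (`eigh`) throughout; eigenvalue ties
are broken by the solver's stable ordering plus the documented sign
conventions; degenerate inputs (zero covariance, all-zero ICRM, constant
descriptor sequences) raise explicit errors rather than returning NaN.

## Known limitations

- The screened-Coulomb energy model is a surrogate; per-complex absolute
  energies comparable to published force-field/implicit-solvent values
  require ingesting externally computed pair-energy tables.
- Descriptor–affinity correlations at n = 7 carry wide sampling
  uncertainty; the package intentionally reports them without inferential
  statistics.
- The Schlitter estimate is an upper bound and, like all quasi-harmonic
  entropies, degrades for strongly anharmonic or multi-basin dynamics.
- Binary trajectory formats (XTC/DCD) are not handled; convert to
  multi-model PDB or the TSV dialect first.
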