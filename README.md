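# zfdyn

Dynamics and energetics analysis of zinc-finger–DNA complexes: how a
protein's internal flexibility, coordination and interaction-energy networks
relate to its binding affinity for DNA.

`zfdyn` is aimed at structural bioinformaticians analysing conformational
ensembles of protein–nucleic-acid complexes (from molecular-dynamics
simulation or any other source of multi-model coordinates). It works at one
representative site per residue — the Cα atom of each amino acid and the C1′
deoxyribose atom of each nucleotide — and provides:

- **Ensemble handling** — multi-model PDB (and plain TSV) reading/writing,
  iterative least-squares (Kabsch) superposition, per-run equilibration
  trimming and concatenation of independent runs, RMSD monitoring.
- **Essential dynamics** — PCA of the 3N×3N positional covariance
  C = ⟨Δx Δxᵀ⟩, the essential subspace capturing a chosen variance fraction
  (default 90%), per-residue RMSF within that subspace, and the per-molecule
  RMSF sum as a scalar flexibility descriptor.
- **Schlitter entropy** — the configurational-entropy upper bound
  S = (k_B/2) ln det[1 + (k_B T e²/ħ²) M^{1/2} C M^{1/2}].
- **ICRM** — the internal coordination and rigidity matrix
  R_ij = 1/Σ_k Var(Δx_ij^k) for |i−j| > 1 (zero on the diagonal band),
  whose principal eigenvalue is an overall dynamic-connectivity parameter
  and whose eigenvalue-weighted principal eigenvector profiles per-residue
  rigidity.
- **Energy decomposition (EDM)** — eigen-decomposition of the N×N mean
  residue-pair nonbonded energy matrix M_ij = Σ_k λ_k w_ik w_jk, the rank-1
  stabilization energy E_nb^app = ½ λ₁ (Σ_i w_i1)², hot spots (residues with
  w_i1² > 1/N), and the exact partition of E_nb^app into protein–protein,
  protein–DNA and DNA–DNA blocks.
- **Affinity statistics** — Pearson correlation of any descriptor with
  log₁₀(K_d), with packaged reference tables for the seven Zif268
  zinc-finger complexes (1A1F, 1A1G, 1A1I, 1A1J, 1A1K, 1A1L, 1AAY).
- **Synthetic benchmarks** — Gaussian ensembles from planted or
  elastic-network covariances, rank-1-plus-noise energy matrices with
  planted hot spots, and affinity sets with a planted descriptor/log K_d
  slope, so every operator is testable against known ground truth.

## Worked example

```sh
python examples/01_affinity_correlations.py
```

prints the packaged per-complex table and

```
r(log10 Kd, protein_flexibility) = -0.92   (n = 7)
r(log10 Kd, complex_flexibility) = -0.88   (n = 7)
r(log10 Kd, intraprotein_energy) = +0.85   (n = 7)
```

The negative flexibility correlations say that, across the seven complexes,
the more flexible proteins (larger essential-subspace RMSF sums) bind their
DNA targets more tightly (lower K_d). The positive intraprotein-energy
correlation says tight binders carry more negative (more stabilizing)
internal residue–residue interaction energy. The other examples
(`examples/02...05`) demonstrate essential dynamics, ICRM, energy
decomposition and the full pipeline on synthetic ensembles.

There is also a CLI:

```sh
zfdyn simulate --n-sites 30 --n-frames 200 --seed 1 --out ens.pdb
zfdyn ed ens.pdb --out rmsf.tsv
zfdyn run --config config.yaml --out results/
```

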