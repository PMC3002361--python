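"""Energy Decomposition Method (EDM) for residue-pair interaction matrices.

The N×N matrix M of trajectory-averaged nonbonded pair energies (diagonal
excluded — no self-interaction) is diagonalized,

    M_ij = Σ_k λ_k w_ik w_jk,   λ_1 ≤ λ_2 ≤ … ≤ λ_N,

and the total nonbonded energy E_nb = ½ Σ_ij M_ij = ½ Σ_k λ_k W_k with
W_k = (Σ_i w_ik)².  When the lowest (most negative) eigenvalue dominates,
E_nb is well approximated by the rank-1 term E_nb^app = ½ λ_1 W_1, and the
squared components of the first eigenvector weigh each residue's share of the
stabilization.  *Hot spots* are the residues whose squared component exceeds
the flat-vector threshold 1/N.

The approximate stabilization energy partitions exactly into
protein-protein, protein-DNA and DNA-DNA blocks, since it is a square of the
component sums.

Matrices can be ingested from a pair-energy table (the route for
force-field-grade energies computed elsewhere)
or computed from an ensemble with a simple screened-Coulomb + Lennard-Jones
model; the latter is a surrogate for force-field/GBSA energetics and is only
meant to produce structurally sensible matrices, not publication-grade
absolute energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import (
    CoordinateEnsemble,
    SiteTopology,
    nucleic_sites,
    protein_sites,
)

#: Coulomb constant in kcal·nm/(mol·e²)  (332.0636 kcal·Å/(mol·e²) / 10)
COULOMB_KCAL_NM = 33.20636


@dataclass
class EnergyMatrix:
    """Symmetric N×N mean pair energies in kcal/mol, zero diagonal."""

    values: np.ndarray
    stderr: np.ndarray | None = None
    labels: list[str] | None = None
    allow_diagonal: bool = False

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("energy matrix must be square")
        if not np.all(np.isfinite(V)):
            raise ValueError("energy matrix entries must be finite")
        if not np.allclose(V, V.T, atol=1e-8):
            raise ValueError("energy matrix must be symmetric")
        if not self.allow_diagonal and np.any(np.abs(np.diag(V)) > 1e-12):
            raise ValueError("self-interaction (diagonal) entries must be zero")
        self.values = V

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DecompositionResult:
    """Eigen-decomposition of an energy matrix (eigenvalues ascending)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    component_sums_squared: np.ndarray  # W_k = (Σ_i w_ik)²
    total_energy: float  # E_nb = ½ Σ_ij M_ij
    approx_energy: float  # E_nb^app = ½ λ_1 W_1
    dominance_ratio: float  # |λ_1 W_1| / Σ_k |λ_k W_k|

    @property
    def first_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def n_sites(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass(frozen=True)
class StabilizationPartition:
    """Molecule-class blocks of the rank-1 stabilization energy, kcal/mol."""

    protein_protein: float
    protein_dna: float
    dna_dna: float

    @property
    def total(self) -> float:
        return self.protein_protein + self.protein_dna + self.dna_dna


@dataclass(frozen=True)
class HotspotSet:
    """Residues whose squared first-eigenvector component exceeds 1/N."""

    indices: tuple[int, ...]
    weights: np.ndarray  # squared components, all sites
    threshold: float


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyModelParams:
    """Screened-Coulomb (+ optional Lennard-Jones 12-6) pair energy model.

    ``dielectric_mode``: "constant" uses ε(r)=ε0; "distance" uses the
    distance-dependent screening ε(r)=ε0·(r/Å), a common implicit-solvent
    surrogate.  ``cutoff_nm`` applies shifted truncation (the potential is
    shifted to zero at the cutoff and vanishes beyond it); None disables it.
    """

    dielectric_mode: str = "distance"
    epsilon0: float = 4.0
    use_lj: bool = False
    cutoff_nm: float | None = None


def pair_energy_matrix(
    ensemble: CoordinateEnsemble,
    topology: Sequence[SiteTopology],
    model: EnergyModelParams = EnergyModelParams(),
    stride: int = 1,
) -> EnergyMatrix:
    """Trajectory-mean pair energies between representative sites.

    Frames are sampled every ``stride`` frames; the standard error of each
    pair mean over the sampled frames is attached.  Charges (and LJ
    parameters when enabled) must be present on every site.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = ensemble.n_sites
    if len(topology) != n:
        raise ValueError("topology length must match ensemble n_sites")
    charges = np.array(
        [np.nan if s.partial_charge is None else s.partial_charge for s in topology]
    )
    if np.any(np.isnan(charges)):
        missing = [s.label for s in topology if s.partial_charge is None]
        raise ValueError(f"missing partial charges for sites: {missing[:5]}")
    if model.use_lj:
        eps = np.array([s.lj_epsilon for s in topology], dtype=float)
        rmin_half = np.array([s.lj_rmin_half for s in topology], dtype=float)
        if np.any(np.isnan(eps)) or np.any(np.isnan(rmin_half)):
            raise ValueError("LJ enabled but lj_epsilon/lj_rmin_half missing")
        eps_ij = np.sqrt(np.outer(eps, eps))
        rmin_ij = rmin_half[:, None] + rmin_half[None, :]

    qq = COULOMB_KCAL_NM * np.outer(charges, charges)
    off = ~np.eye(n, dtype=bool)

    def pair_energy(r: np.ndarray) -> np.ndarray:
        if model.dielectric_mode == "constant":
            e = qq / (model.epsilon0 * r)
        elif model.dielectric_mode == "distance":
            e = qq / (model.epsilon0 * (r * 10.0) * r)  # ε(r) = ε0 · r[Å]
        else:
            raise ValueError(f"unknown dielectric_mode {model.dielectric_mode!r}")
        if model.use_lj:
            ratio6 = (rmin_ij / r) ** 6
            e = e + eps_ij * (ratio6**2 - 2.0 * ratio6)
        return e

    frames = ensemble.coordinates[::stride]
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    for frame in frames:
        d = frame[:, None, :] - frame[None, :, :]
        r = np.sqrt(np.sum(d * d, axis=2))
        if np.any(r[off] <= 0):
            i, j = np.argwhere((r <= 0) & off)[0]
            raise ValueError(
                f"zero distance between sites {topology[i].label} and "
                f"{topology[j].label}"
            )
        r_safe = np.where(off, r, 1.0)
        e = pair_energy(r_safe)
        if model.cutoff_nm is not None:
            shift = pair_energy(np.full_like(r_safe, model.cutoff_nm))
            e = np.where(r_safe < model.cutoff_nm, e - shift, 0.0)
        e[~off] = 0.0
        acc += e
        acc2 += e * e
    nf = len(frames)
    mean = acc / nf
    var = np.clip(acc2 / nf - mean**2, 0.0, None)
    stderr = np.sqrt(var / nf)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 0.0)
    return EnergyMatrix(mean, stderr=stderr, labels=[s.label for s in topology])


# ---------------------------------------------------------------------------
# Pair-energy table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["site_i", "site_j", "mean_kcal_mol", "sd_kcal_mol"]


def read_pair_energy_table(path: str | Path) -> EnergyMatrix:
    """Read the TSV dialect (site_i, site_j, mean_kcal_mol, sd_kcal_mol).

    Pairs may be listed once (i<j); the matrix is symmetrized and unlisted
    pairs are zero.  Conflicting duplicates and nonzero self-pairs are
    rejected.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_TABLE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    n = int(max(df["site_i"].max(), df["site_j"].max())) + 1
    M = np.zeros((n, n))
    S = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    has_sd = "sd_kcal_mol" in df.columns
    for row in df.itertuples(index=False):
        i, j = int(row.site_i), int(row.site_j)
        e = float(row.mean_kcal_mol)
        if i == j:
            if abs(e) > 1e-12:
                raise ValueError(f"{path}: nonzero self-pair energy at site {i}")
            continue
        key = (min(i, j), max(i, j))
        if key in seen and abs(seen[key] - e) > 1e-6:
            raise ValueError(f"{path}: conflicting duplicate entry for pair {key}")
        seen[key] = e
        M[i, j] = M[j, i] = e
        if has_sd:
            S[i, j] = S[j, i] = float(row.sd_kcal_mol)
    return EnergyMatrix(M, stderr=S if has_sd else None)


def write_pair_energy_table(path: str | Path, matrix: EnergyMatrix) -> None:
    """Write the upper triangle (i<j) of an energy matrix in the TSV dialect."""
    iu, ju = np.triu_indices(matrix.n_sites, k=1)
    sd = matrix.stderr if matrix.stderr is not None else np.zeros_like(matrix.values)
    pd.DataFrame(
        {
            "site_i": iu,
            "site_j": ju,
            "mean_kcal_mol": matrix.values[iu, ju],
            "sd_kcal_mol": sd[iu, ju],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------


def decompose(matrix: EnergyMatrix | np.ndarray) -> DecompositionResult:
    """Full eigen-decomposition of the pair-energy matrix.

    Eigenvalues ascend, so index 0 is the most negative (most stabilizing)
    mode; the first eigenvector is sign-fixed to a non-negative component
    sum, which leaves W_1 and the squared-component weights unchanged.
    """
    V = matrix.values if isinstance(matrix, EnergyMatrix) else np.asarray(matrix, float)
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("energy matrix must be symmetric")
    evals, evecs = np.linalg.eigh(V)
    if evecs[:, 0].sum() < 0:
        evecs = evecs.copy()
        evecs[:, 0] = -evecs[:, 0]
    sums = evecs.sum(axis=0)
    W = sums**2
    e_total = 0.5 * float(V.sum())
    e_app = 0.5 * float(evals[0] * W[0])
    denom = float(np.abs(evals * W).sum())
    dominance = float(abs(evals[0] * W[0]) / denom) if denom > 0 else 0.0
    return DecompositionResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        component_sums_squared=W,
        total_energy=e_total,
        approx_energy=e_app,
        dominance_ratio=dominance,
    )


def approx_stabilization_energy(result: DecompositionResult) -> float:
    """Rank-1 approximation E_nb^app = ½ λ_1 (Σ_i w_i1)², kcal/mol.

    Check ``result.dominance_ratio`` before trusting the approximation: it
    is only valid when |λ_1 W_1| dominates the spectrum-weighted sums.
    """
    return result.approx_energy


def hot_spots(result: DecompositionResult) -> HotspotSet:
    """Sites with squared first-eigenvector component strictly above 1/N.

    The comparison is strict, so a perfectly flat eigenvector yields no hot
    spots; a relative tolerance of 1e-9 keeps round-off at the threshold from
    flipping that case.
    """
    weights = result.first_eigenvector**2
    threshold = 1.0 / result.n_sites
    indices = tuple(int(i) for i in np.flatnonzero(weights > threshold * (1 + 1e-9)))
    return HotspotSet(indices=indices, weights=weights, threshold=threshold)


def partition_stabilization(
    result: DecompositionResult, topology: Sequence[SiteTopology]
) -> StabilizationPartition:
    """Split E_nb^app into protein-protein, protein-DNA and DNA-DNA blocks.

    Because E_nb^app = ½λ₁(Σᵢwᵢ₁)², the blocks are ½λ₁s_P², λ₁s_P·s_D and
    ½λ₁s_D² with s_P, s_D the component sums over each molecule class;
    additivity to the total is exact.
    """
    if len(topology) != result.n_sites:
        raise ValueError("topology length must match decomposition size")
    w = result.first_eigenvector
    lam = float(result.eigenvalues[0])
    sp = float(w[protein_sites(topology)].sum()) if len(protein_sites(topology)) else 0.0
    sd = float(w[nucleic_sites(topology)].sum()) if len(nucleic_sites(topology)) else 0.0
    return StabilizationPartition(
        protein_protein=0.5 * lam * sp * sp,
        protein_dna=lam * sp * sd,
        dna_dna=0.5 * lam * sd * sd,
    )


def raw_block_sums(
    matrix: EnergyMatrix, topology: Sequence[SiteTopology]
) -> StabilizationPartition:
    """Direct block sums of ½ΣM_ij by molecule class (no rank-1 approximation).

    Exposed for comparison with :func:`partition_stabilization`.
    """
    P = protein_sites(topology)
    D = nucleic_sites(topology)
    V = matrix.values
    return StabilizationPartition(
        protein_protein=0.5 * float(V[np.ix_(P, P)].sum()) if len(P) else 0.0,
        protein_dna=float(V[np.ix_(P, D)].sum()) if len(P) and len(D) else 0.0,
        dna_dna=0.5 * float(V[np.ix_(D, D)].sum()) if len(D) else 0.0,
    )


def intraprotein_energy(
    matrix: EnergyMatrix, topology: Sequence[SiteTopology]
) -> float:
    """E_nb^app of the protein-only submatrix, kcal/mol.

    This decomposes the intraprotein interaction matrix on its own, which is
    not the same quantity as the protein-protein block of the whole-complex
    decomposition.
    """
    P = protein_sites(topology)
    if len(P) < 2:
        raise ValueError("need at least 2 protein sites")
    sub = matrix.values[np.ix_(P, P)]
    return decompose(EnergyMatrix(sub)).approx_energy
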