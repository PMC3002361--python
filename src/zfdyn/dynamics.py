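"""Essential dynamics: covariance analysis, subspace RMSF, Schlitter entropy.

The positional covariance matrix C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩ over a superposed
ensemble is diagonalized (principal component analysis); the top eigenvectors
capturing a stated fraction of the total variance span the *essential
subspace* of dominant collective motions.  Residue fluctuations (RMSF) are
evaluated after projecting the trajectory onto that subspace, and summed into
a scalar flexibility descriptor per molecule.  The same covariance yields the
Schlitter upper bound on configurational entropy.

All averages are population moments (divide by the number of frames): the
quantities of interest are ensemble averages, not unbiased estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import constants

from .ensemble import CoordinateEnsemble


@dataclass
class CovarianceModel:
    """Mean structure, 3N×3N covariance (nm²) and its eigen-decomposition.

    Eigenvalues are stored in descending order; eigenvector columns match.
    The sign of each eigenvector is canonicalized so its largest-magnitude
    component is positive.
    """

    mean_structure: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.mean_structure.shape[0]

    @property
    def total_variance(self) -> float:
        return float(np.trace(self.covariance))


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-site RMSF (nm) within an essential subspace."""

    rmsf: np.ndarray
    subspace_dim: int
    variance_fraction_captured: float


@dataclass(frozen=True)
class EntropyEstimate:
    """Configurational entropy upper bound, J/(mol K)."""

    value: float
    temperature: float

    @property
    def value_kcal(self) -> float:
        """Convenience conversion to kcal/(mol K)."""
        return self.value / (constants.calorie * 1000.0)


def _canonical_signs(vectors: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def covariance_matrix(ensemble: CoordinateEnsemble) -> CovarianceModel:
    """Population covariance of the flattened 3N coordinates, with PCA attached.

    Requires a superposed ensemble: without removal of rigid-body motion the
    covariance conflates overall tumbling with internal fluctuation.
    """
    if not ensemble.superposed:
        raise ValueError(
            "ensemble is not superposed; call zfdyn.ensemble.superpose first"
        )
    if ensemble.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    X = ensemble.coordinates.reshape(ensemble.n_frames, -1)
    mean = X.mean(axis=0)
    dX = X - mean
    C = dX.T @ dX / ensemble.n_frames
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _canonical_signs(evecs[:, order])
    return CovarianceModel(
        mean_structure=mean.reshape(-1, 3),
        covariance=C,
        eigenvalues=evals,
        eigenvectors=evecs,
    )


def essential_subspace(model: CovarianceModel, variance_fraction: float = 0.9) -> int:
    """Smallest m with the top-m eigenvalues covering the variance fraction."""
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must be in (0, 1]")
    total = model.eigenvalues.sum()
    if total <= 0:
        raise ValueError("covariance has zero total variance")
    cumulative = np.cumsum(model.eigenvalues) / total
    return int(np.searchsorted(cumulative, variance_fraction - 1e-12) + 1)


def subspace_rmsf(
    ensemble: CoordinateEnsemble, model: CovarianceModel, m: int
) -> FlexibilityProfile:
    """Per-site RMSF of the trajectory projected onto the first m modes.

    With m equal to the full dimension this reduces to the ordinary RMSF, and
    Σᵢ RMSFᵢ² equals the covariance trace (Parseval).
    """
    n3 = 3 * ensemble.n_sites
    if not 1 <= m <= n3:
        raise ValueError(f"subspace dimension must be in 1..{n3}")
    X = ensemble.coordinates.reshape(ensemble.n_frames, -1)
    dX = X - model.mean_structure.reshape(-1)
    V = model.eigenvectors[:, :m]
    projected = dX @ V @ V.T
    per_site = projected.reshape(ensemble.n_frames, ensemble.n_sites, 3)
    rmsf = np.sqrt(np.mean(np.sum(per_site**2, axis=2), axis=0))
    total = model.eigenvalues.sum()
    captured = float(model.eigenvalues[:m].sum() / total) if total > 0 else 1.0
    return FlexibilityProfile(
        rmsf=rmsf, subspace_dim=m, variance_fraction_captured=captured
    )


def flexibility_sum(
    profile: FlexibilityProfile, sites: Sequence[int] | None = None
) -> float:
    """Sum of per-site RMSF over a site subset (all sites by default), nm.

    Protein flexibility sums over protein sites only; complex flexibility
    over protein plus nucleic sites.
    """
    if sites is None:
        return float(profile.rmsf.sum())
    idx = np.asarray(sites, dtype=int)
    if idx.size == 0:
        raise ValueError("site subset is empty")
    return float(profile.rmsf[idx].sum())


def schlitter_entropy(
    model: CovarianceModel,
    masses_amu: Sequence[float],
    temperature: float,
) -> EntropyEstimate:
    """Schlitter entropy bound S = (k_B/2) ln det[1 + (k_B T e²/ħ²) M^½ C M^½].

    ``masses_amu`` gives one mass per site, expanded over the three Cartesian
    components; the result is per mole, J/(mol K).  The bound is zero for a
    zero covariance and grows monotonically with the fluctuations.
    """
    masses_amu = np.asarray(masses_amu, dtype=float)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if np.any(masses_amu <= 0):
        raise ValueError("masses must be positive")
    if masses_amu.shape != (model.n_sites,):
        raise ValueError(
            f"need one mass per site ({model.n_sites}), got {masses_amu.shape}"
        )
    kB = constants.k
    hbar = constants.hbar
    masses_kg = np.repeat(masses_amu * constants.atomic_mass, 3)
    C_m2 = model.covariance * 1e-18  # nm² → m²
    prefactor = kB * temperature * np.e**2 / hbar**2
    sqrt_m = np.sqrt(masses_kg)
    A = np.eye(len(masses_kg)) + prefactor * (sqrt_m[:, None] * C_m2 * sqrt_m[None, :])
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise ValueError("entropy argument matrix is not positive definite")
    s_per_molecule = 0.5 * kB * logdet
    return EntropyEstimate(
        value=float(s_per_molecule * constants.Avogadro), temperature=temperature
    )
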