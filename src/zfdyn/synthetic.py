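"""Synthetic benchmark generators with planted ground truth.

The original simulation trajectories behind this kind of analysis are rarely
deposited, so every downstream stage is validated on synthetic inputs whose
answer is known by construction:

* Gaussian conformational ensembles drawn from a prescribed 3N×3N covariance
  (explicit, planted-mode, or elastic-network derived),
* residue-pair energy matrices with a dominant negative rank-1 component and
  a designated hot-spot set,
* affinity sets in which log10(Kd) is an exact (optionally noisy) linear
  function of a descriptor.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .affinity import AffinityRecord
from .ensemble import CoordinateEnsemble

BOLTZMANN_KCAL = 0.001987204259  # kcal/(mol K)


@dataclass
class CovarianceSpec:
    """A 3N×3N positional covariance, given one of three ways.

    ``matrix``: explicit PSD matrix in nm².  ``modes``: list of
    (eigenvalue nm², unit 3N-eigenvector) pairs, remaining directions zero.
    ``elastic_network``: (cutoff_nm, spring_constant kcal/(mol nm²),
    temperature K); the covariance is k_B T times the pseudo-inverse of the
    contact Laplacian (Gaussian-network form), replicated isotropically over
    x, y, z.
    """

    matrix: np.ndarray | None = None
    modes: Sequence[tuple[float, np.ndarray]] | None = None
    elastic_network: tuple[float, float, float] | None = None

    def build(self, mean_structure: np.ndarray) -> np.ndarray:
        n3 = 3 * mean_structure.shape[0]
        given = [self.matrix is not None, self.modes is not None,
                 self.elastic_network is not None]
        if sum(given) != 1:
            raise ValueError("specify exactly one of matrix, modes, elastic_network")
        if self.matrix is not None:
            C = np.asarray(self.matrix, dtype=float)
            if C.shape != (n3, n3):
                raise ValueError(f"covariance shape {C.shape}, expected {(n3, n3)}")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("explicit covariance must be symmetric")
            evals = np.linalg.eigvalsh(C)
            if evals.min() < -1e-10 * max(np.trace(C), 1e-30):
                raise ValueError("explicit covariance is not positive semi-definite")
            return C
        if self.modes is not None:
            C = np.zeros((n3, n3))
            vecs = [np.asarray(v, dtype=float) for _, v in self.modes]
            G = np.array([[u @ v for v in vecs] for u in vecs])
            if not np.allclose(G, np.eye(len(vecs)), atol=1e-8):
                raise ValueError("mode eigenvectors must be mutually orthonormal")
            for (lam, _), v in zip(self.modes, vecs):
                if lam < 0:
                    raise ValueError("mode eigenvalues must be non-negative")
                C += lam * np.outer(v, v)
            return C
        cutoff, k_spring, temperature = self.elastic_network
        return _gnm_covariance(mean_structure, cutoff, k_spring, temperature)


def _gnm_covariance(
    mean_structure: np.ndarray, cutoff_nm: float, k_spring: float, temperature: float
) -> np.ndarray:
    """Isotropic Gaussian-network covariance, kron(kBT/k · L⁺, I₃)."""
    d = np.linalg.norm(
        mean_structure[:, None, :] - mean_structure[None, :, :], axis=2
    )
    contact = (d <= cutoff_nm) & ~np.eye(len(d), dtype=bool)
    laplacian = np.diag(contact.sum(axis=1)) - contact.astype(float)
    pinv = np.linalg.pinv(laplacian, hermitian=True)
    per_axis = (BOLTZMANN_KCAL * temperature / k_spring) * pinv
    return np.kron(per_axis, np.eye(3))


def gaussian_ensemble(
    mean_structure: np.ndarray,
    spec: CovarianceSpec,
    n_frames: int,
    seed: int,
    rigid_body_sd_nm: float = 0.0,
) -> CoordinateEnsemble:
    """Draw frames from N(mean, C).

    Frames are generated already superposed (no rigid-body component) unless
    ``rigid_body_sd_nm`` > 0, in which case each frame additionally receives a
    random rigid translation (for exercising the superposition stage) and the
    returned ensemble is flagged unsuperposed.
    """
    mean_structure = np.asarray(mean_structure, dtype=float)
    n_sites = mean_structure.shape[0]
    C = spec.build(mean_structure)
    rng = np.random.default_rng(seed)
    evals, evecs = np.linalg.eigh(C)
    evals = np.clip(evals, 0.0, None)
    z = rng.standard_normal((n_frames, 3 * n_sites))
    disp = z @ (evecs * np.sqrt(evals)).T
    coords = mean_structure[None, :, :] + disp.reshape(n_frames, n_sites, 3)
    superposed = True
    if rigid_body_sd_nm > 0.0:
        coords = coords + rng.normal(
            scale=rigid_body_sd_nm, size=(n_frames, 1, 3)
        )
        superposed = False
    return CoordinateEnsemble(coords, superposed=superposed)


@dataclass
class PlantedEnergySpec:
    """Rank-1-plus-noise residue-pair energy matrix with designated hot spots.

    The leading eigenvalue is negative (stabilizing); hot-spot sites carry a
    first-eigenvector component ``hotspot_weight_ratio`` times larger than the
    remaining sites.
    """

    n_sites: int
    hotspot_indices: frozenset[int] | set[int] = field(default_factory=frozenset)
    hotspot_weight_ratio: float = 3.0
    leading_eigenvalue: float = -100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.hotspot_indices = frozenset(int(i) for i in self.hotspot_indices)
        if any(i < 0 or i >= self.n_sites for i in self.hotspot_indices):
            raise ValueError("hotspot_indices must lie in 0..n_sites-1")
        if self.leading_eigenvalue >= 0:
            raise ValueError("leading_eigenvalue must be negative (stabilizing)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def planted_vector(self) -> np.ndarray:
        """Unit vector with the hot-spot weight ratio planted in."""
        if not self.hotspot_indices and self.hotspot_weight_ratio != 1.0:
            raise ValueError("empty hotspot set requires hotspot_weight_ratio == 1")
        w = np.ones(self.n_sites)
        w[list(self.hotspot_indices)] = self.hotspot_weight_ratio
        return w / np.linalg.norm(w)


def planted_energy_matrix(spec: PlantedEnergySpec, zero_diagonal: bool = True):
    """Build M = λ₁ w wᵀ + symmetric zero-mean noise.

    With ``zero_diagonal`` (the default, matching real residue-pair matrices
    that exclude self-interaction) the diagonal is forced to zero, which
    perturbs the rank-1 eigenstructure; pass ``zero_diagonal=False`` for an
    exact rank-1 construction.
    """
    from .energy import EnergyMatrix

    w = spec.planted_vector()
    M = spec.leading_eigenvalue * np.outer(w, w)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(scale=spec.noise_sd, size=(spec.n_sites, spec.n_sites))
        M = M + (noise + noise.T) / np.sqrt(2.0)
    if zero_diagonal:
        np.fill_diagonal(M, 0.0)
    return EnergyMatrix(M, allow_diagonal=not zero_diagonal)


def synthetic_affinity_set(
    n_complexes: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    descriptor_range: tuple[float, float],
    seed: int,
    descriptor_name: str = "synthetic_descriptor",
) -> list[AffinityRecord]:
    """Affinity records whose log10(Kd/nM) is linear in a planted descriptor.

    The descriptor is uniform on ``descriptor_range``; log10 Kd equals
    ``intercept + slope·descriptor`` plus Gaussian noise of ``noise_sd`` log10
    units.  Kd is stored in nM.
    """
    if n_complexes < 3:
        raise ValueError("need at least 3 complexes for a defined correlation")
    lo, hi = descriptor_range
    rng = np.random.default_rng(seed)
    descriptors = rng.uniform(lo, hi, size=n_complexes)
    log_kd = intercept + slope * descriptors
    if noise_sd > 0:
        log_kd = log_kd + rng.normal(scale=noise_sd, size=n_complexes)
    return [
        AffinityRecord(
            complex_id=f"SYN{i:03d}",
            kd_nm=float(10.0 ** log_kd[i]),
            descriptors={descriptor_name: float(descriptors[i])},
        )
        for i in range(n_complexes)
    ]
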