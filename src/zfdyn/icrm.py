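"""Internal Coordination and Rigidity Matrix (ICRM).

For every residue pair (i, j) with |i−j| > 1 the ICRM entry is the inverse of
the summed per-Cartesian-component population variance of the inter-site
vector:

    R_ij = 1 / Σ_{k=1..3} Var(Δx_ij^k),        R_ij = 0 for |i−j| ≤ 1.

Low distance fluctuation → high R_ij → the pair moves as part of one rigid,
dynamically coordinated unit.  Diagonal and nearest-neighbour entries are
zeroed to avoid the trivial divergence of bonded pairs; pairs that are rigid
to numerical precision are capped at a large finite value rather than
excluded.

The principal (largest) eigenvalue of this symmetric non-negative matrix is a
scalar measure of overall dynamic connectivity, and the matching eigenvector,
weighted by the eigenvalue, profiles each residue's contribution to global
rigidity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import CoordinateEnsemble

DEFAULT_CAP = 1e6  # nm^-2; stands in for "infinitely rigid"


@dataclass
class ICRMatrix:
    """N×N inverse distance-fluctuation matrix, nm⁻²."""

    values: np.ndarray
    cap_value: float = DEFAULT_CAP

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("ICRM must be square")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("ICRM must be symmetric")
        if not np.all(np.isfinite(V)):
            raise ValueError("ICRM entries must be finite")
        if V.min() < 0 or V.max() > self.cap_value * (1 + 1e-12):
            raise ValueError("ICRM entries must lie in [0, cap_value]")
        self.values = V

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RigidityProfile:
    """Principal eigenpair of the ICRM.

    ``raw_components`` is the unit principal eigenvector (sign-fixed to a
    non-negative sum); ``weighted_components`` multiplies the absolute
    components by the principal eigenvalue, giving the per-residue rigidity
    profile in nm⁻².
    """

    principal_eigenvalue: float
    raw_components: np.ndarray
    weighted_components: np.ndarray


def icrm_matrix(
    ensemble: CoordinateEnsemble,
    sites: Sequence[int] | None = None,
    cap_value: float = DEFAULT_CAP,
) -> ICRMatrix:
    """Compute the ICRM over frames for the selected sites.

    Superposition is not required: the inter-site difference vector removes
    any common rigid translation.  ``sites`` restricts the computation (e.g.
    protein residues only); indices within the returned matrix follow the
    order of the selection.
    """
    if ensemble.n_frames < 2:
        raise ValueError("ICRM needs at least 2 frames")
    coords = ensemble.coordinates
    if sites is not None:
        coords = coords[:, np.asarray(sites, dtype=int), :]
    n = coords.shape[1]
    # Var(x_i - x_j) per component = Var(x_i) + Var(x_j) - 2 Cov(x_i, x_j)
    total = np.zeros((n, n))
    for k in range(3):
        comp = coords[:, :, k]
        d = comp - comp.mean(axis=0)
        cov = d.T @ d / coords.shape[0]
        var = np.diag(cov)
        total += var[:, None] + var[None, :] - 2.0 * cov
    idx = np.arange(n)
    band = np.abs(idx[:, None] - idx[None, :]) <= 1
    with np.errstate(divide="ignore"):
        R = np.where(total > 1.0 / cap_value, 1.0 / total, cap_value)
    R[band] = 0.0
    R = (R + R.T) / 2.0  # symmetrize away roundoff
    return ICRMatrix(R, cap_value=cap_value)


def rigidity_profile(matrix: ICRMatrix) -> RigidityProfile:
    """Principal eigenpair of the ICRM (Perron root of the non-negative matrix)."""
    if not np.any(matrix.values):
        raise ValueError("rigidity profile undefined for an all-zero ICRM")
    evals, evecs = np.linalg.eigh(matrix.values)
    lam = float(evals[-1])
    vec = evecs[:, -1]
    if vec.sum() < 0:
        vec = -vec
    return RigidityProfile(
        principal_eigenvalue=lam,
        raw_components=vec,
        weighted_components=lam * np.abs(vec),
    )


def coordination_summary(matrix: ICRMatrix) -> float:
    """Overall dynamic-connectivity parameter: the principal eigenvalue, nm⁻²."""
    if not np.any(matrix.values):
        return 0.0
    return rigidity_profile(matrix).principal_eigenvalue


def write_icrm(path: str | Path, matrix: ICRMatrix, labels: Sequence[str] | None = None) -> None:
    """Square TSV with a header row of site labels."""
    if labels is None:
        labels = [f"site{i}" for i in range(matrix.n_sites)]
    pd.DataFrame(matrix.values, index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t"
    )


def write_rigidity_profile(
    path: str | Path, profile: RigidityProfile, labels: Sequence[str] | None = None
) -> None:
    n = len(profile.weighted_components)
    if labels is None:
        labels = [f"site{i}" for i in range(n)]
    pd.DataFrame(
        {"site": list(labels), "weighted_component": profile.weighted_components}
    ).to_csv(path, sep="\t", index=False)
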