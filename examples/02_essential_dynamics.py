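"""Essential dynamics of a synthetic elastic-network ensemble.

Draws 500 frames of a 30-residue chain from a Gaussian-network covariance,
superposes them, and computes the covariance PCA, the 90%-variance essential
subspace, the per-residue RMSF within it, and the Schlitter entropy bound.
"""

import numpy as np

from zfdyn.dynamics import (
    covariance_matrix,
    essential_subspace,
    flexibility_sum,
    schlitter_entropy,
    subspace_rmsf,
)
from zfdyn.synthetic import CovarianceSpec, gaussian_ensemble

rng = np.random.default_rng(42)
steps = rng.normal(size=(30, 3))
steps /= np.linalg.norm(steps, axis=1, keepdims=True)
mean = np.cumsum(0.38 * steps, axis=0)  # a compact random-walk chain, nm

spec = CovarianceSpec(elastic_network=(1.0, 100.0, 300.0))
ensemble = gaussian_ensemble(mean, spec, n_frames=500, seed=42)

model = covariance_matrix(ensemble)
m = essential_subspace(model, variance_fraction=0.9)
profile = subspace_rmsf(ensemble, model, m)

print(f"3N = {3 * ensemble.n_sites} degrees of freedom")
print(f"essential subspace dimension at 90% variance: {m}")
print(f"variance captured: {profile.variance_fraction_captured:.3f}")
print(f"flexibility sum (all residues): {flexibility_sum(profile):.3f} nm")

entropy = schlitter_entropy(model, [110.0] * 30, temperature=300.0)
print(f"Schlitter entropy bound: {entropy.value:.1f} J/(mol K)")
print()
print("The top eigenvectors of the positional covariance capture 90% of the")
print("motion; the RMSF sum over residues is the scalar flexibility descriptor")
print("that is correlated with binding affinity.")
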