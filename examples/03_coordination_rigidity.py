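"""Internal coordination and rigidity of two ensembles of different stiffness.

Computes the ICRM (inverse distance-fluctuation matrix) for a stiff and a
soft ensemble of the same chain, and compares their overall coordination
parameter (the principal eigenvalue) and per-residue rigidity profiles.
"""

import numpy as np

from zfdyn.icrm import coordination_summary, icrm_matrix, rigidity_profile
from zfdyn.synthetic import CovarianceSpec, gaussian_ensemble

rng = np.random.default_rng(7)
steps = rng.normal(size=(25, 3))
steps /= np.linalg.norm(steps, axis=1, keepdims=True)
mean = np.cumsum(0.38 * steps, axis=0)

for label, spring in [("stiff", 400.0), ("soft", 50.0)]:
    spec = CovarianceSpec(elastic_network=(1.0, spring, 300.0))
    ens = gaussian_ensemble(mean, spec, n_frames=400, seed=7)
    matrix = icrm_matrix(ens)
    profile = rigidity_profile(matrix)
    top = np.argsort(profile.weighted_components)[-3:][::-1]
    print(f"{label:5s}: coordination = {coordination_summary(matrix):9.1f} nm^-2, "
          f"most rigid residues: {list(top)}")

print()
print("Lower distance fluctuations give larger ICRM entries, hence a larger")
print("principal eigenvalue: the stiff ensemble is more dynamically coordinated.")
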