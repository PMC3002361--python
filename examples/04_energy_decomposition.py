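"""Energy decomposition of a planted residue-pair interaction matrix.

Builds a pair-energy matrix with two planted stabilizing hot spots, then
recovers them from the lowest-eigenvalue eigenvector, and partitions the
rank-1 stabilization energy into protein-protein / protein-DNA / DNA-DNA
blocks.
"""

from zfdyn.energy import decompose, hot_spots, partition_stabilization
from zfdyn.ensemble import MoleculeClass, SiteTopology
from zfdyn.synthetic import PlantedEnergySpec, planted_energy_matrix

n_protein, n_dna = 18, 6
spec = PlantedEnergySpec(
    n_sites=n_protein + n_dna,
    hotspot_indices={4, 11},
    hotspot_weight_ratio=3.0,
    leading_eigenvalue=-800.0,
    noise_sd=2.0,
    seed=0,
)
matrix = planted_energy_matrix(spec)
result = decompose(matrix)
spots = hot_spots(result)

topology = [
    SiteTopology(
        i, "A" if i < n_protein else "B", i + 1,
        "ALA" if i < n_protein else "DA",
        MoleculeClass.PROTEIN if i < n_protein else MoleculeClass.NUCLEIC,
    )
    for i in range(n_protein + n_dna)
]
part = partition_stabilization(result, topology)

print(f"lowest eigenvalue λ1 = {result.eigenvalues[0]:.1f} kcal/mol")
print(f"E_nb = {result.total_energy:.1f}, E_nb^app = {result.approx_energy:.1f} "
      f"(dominance ratio {result.dominance_ratio:.2f})")
print(f"hot spots (weight > 1/N = {spots.threshold:.3f}): {list(spots.indices)}")
print(f"partition: PP = {part.protein_protein:.1f}, "
      f"P-DNA = {part.protein_dna:.1f}, DNA-DNA = {part.dna_dna:.1f}, "
      f"total = {part.total:.1f} kcal/mol")
print()
print("The planted hot spots {4, 11} carry outsized first-eigenvector weight;")
print("the three blocks sum exactly to the rank-1 stabilization energy.")
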