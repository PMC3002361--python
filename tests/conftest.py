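import numpy as np
import pytest

from zfdyn.ensemble import CoordinateEnsemble, MoleculeClass, SiteTopology


def make_topology(n_protein: int, n_dna: int = 0) -> list[SiteTopology]:
    """Linear topology: protein chain A then DNA chain B."""
    sites = []
    for i in range(n_protein + n_dna):
        is_protein = i < n_protein
        sites.append(
            SiteTopology(
                site_index=i,
                chain_id="A" if is_protein else "B",
                residue_number=(i + 1) if is_protein else (i - n_protein + 1),
                residue_name="ALA" if is_protein else "DA",
                molecule_class=(
                    MoleculeClass.PROTEIN if is_protein else MoleculeClass.NUCLEIC
                ),
                representative_atom="CA" if is_protein else "C1'",
            )
        )
    return sites


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_ensemble(rng):
    """20 frames of 5 sites with non-trivial fluctuations, superposed flag set."""
    mean = rng.normal(scale=1.0, size=(5, 3))
    frames = mean[None] + rng.normal(scale=0.05, size=(20, 5, 3))
    return CoordinateEnsemble(frames, superposed=True)


@pytest.fixture
def helix_mean(rng):
    """A 12-site helical mean structure (nm), convenient for PDB fixtures."""
    t = np.arange(12) * 0.6
    return np.stack([0.23 * np.cos(t), 0.23 * np.sin(t), 0.15 * t], axis=1)
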