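"""Energy matrices, the eigen-decomposition and its rank-1 stabilization terms."""

import numpy as np
import pytest

from zfdyn.energy import (
    EnergyMatrix,
    EnergyModelParams,
    decompose,
    hot_spots,
    intraprotein_energy,
    pair_energy_matrix,
    partition_stabilization,
    raw_block_sums,
    read_pair_energy_table,
    write_pair_energy_table,
)
from zfdyn.ensemble import CoordinateEnsemble

from conftest import make_topology


def _charged_topology(charges, **lj):
    import dataclasses

    topo = make_topology(len(charges))
    return [
        dataclasses.replace(t, partial_charge=q, **lj) for t, q in zip(topo, charges)
    ]


def _all_minus_one(n):
    M = -np.ones((n, n))
    np.fill_diagonal(M, 0.0)
    return EnergyMatrix(M)


class TestPairEnergyMatrix:
    def test_coulomb_fixed_pair(self):
        """±1e at 1.0 nm with ε=1: 332.0636/10 Å → −33.206 kcal/mol."""
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 1.0
        topo = _charged_topology([+1.0, -1.0])
        M = pair_energy_matrix(
            CoordinateEnsemble(coords),
            topo,
            EnergyModelParams(dielectric_mode="constant", epsilon0=1.0),
        )
        assert M.values[0, 1] == pytest.approx(-33.20636, abs=1e-3)

    def test_lj_minimum(self):
        """Neutral pair at r = r_min contributes exactly −ε_LJ."""
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 0.5
        topo = _charged_topology(
            [0.0, 0.0], lj_epsilon=0.2, lj_rmin_half=0.25
        )
        M = pair_energy_matrix(
            CoordinateEnsemble(coords),
            topo,
            EnergyModelParams(dielectric_mode="constant", epsilon0=1.0, use_lj=True),
        )
        assert M.values[0, 1] == pytest.approx(-0.2, rel=1e-10)

    def test_beyond_cutoff_is_zero(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 3.0
        topo = _charged_topology([+1.0, -1.0])
        M = pair_energy_matrix(
            CoordinateEnsemble(coords),
            topo,
            EnergyModelParams(dielectric_mode="constant", epsilon0=1.0, cutoff_nm=1.5),
        )
        assert M.values[0, 1] == 0.0

    def test_missing_charge_rejected(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 1.0
        with pytest.raises(ValueError, match="charges"):
            pair_energy_matrix(CoordinateEnsemble(coords), make_topology(2))

    def test_stride_subsamples_frames(self, rng):
        coords = rng.normal(size=(10, 3, 3)) + 5 * np.arange(3)[None, :, None]
        topo = _charged_topology([1.0, -1.0, 0.5])
        full = pair_energy_matrix(CoordinateEnsemble(coords), topo)
        strided = pair_energy_matrix(CoordinateEnsemble(coords), topo, stride=5)
        assert not np.allclose(full.values, strided.values)


class TestPairEnergyTable:
    def test_round_trip(self, tmp_path, rng):
        M = rng.normal(size=(6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        matrix = EnergyMatrix(M)
        path = tmp_path / "pairs.tsv"
        write_pair_energy_table(path, matrix)
        back = read_pair_energy_table(path)
        np.testing.assert_allclose(back.values, matrix.values, atol=1e-12)

    def test_half_listed_pairs_symmetrized(self, tmp_path):
        path = tmp_path / "half.tsv"
        path.write_text(
            "site_i\tsite_j\tmean_kcal_mol\tsd_kcal_mol\n0\t2\t-1.5\t0.1\n1\t2\t0.3\t0.1\n"
        )
        M = read_pair_energy_table(path).values
        assert M[2, 0] == -1.5 and M[0, 2] == -1.5 and M[2, 1] == 0.3

    def test_nonzero_self_pair_rejected(self, tmp_path):
        path = tmp_path / "self.tsv"
        path.write_text("site_i\tsite_j\tmean_kcal_mol\tsd_kcal_mol\n3\t3\t-1.0\t0.0\n")
        with pytest.raises(ValueError, match="self-pair"):
            read_pair_energy_table(path)

    def test_conflicting_duplicates_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "site_i\tsite_j\tmean_kcal_mol\tsd_kcal_mol\n0\t1\t-1.0\t0.0\n1\t0\t-2.0\t0.0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_pair_energy_table(path)


class TestDecompose:
    def test_all_minus_one_closed_form(self):
        """Off-diagonal −1 3×3: λ₁=−2, w₁=(1,1,1)/√3, E_nb = E_nb^app = −3."""
        result = decompose(_all_minus_one(3))
        assert result.eigenvalues[0] == pytest.approx(-2.0, abs=1e-12)
        np.testing.assert_allclose(
            result.first_eigenvector, np.ones(3) / np.sqrt(3), atol=1e-12
        )
        assert result.total_energy == pytest.approx(-3.0)
        assert result.approx_energy == pytest.approx(-3.0, abs=1e-12)

    def test_rank_one_matrix_is_exact(self, rng):
        """Without the zero-diagonal correction, E_nb^app = E_nb exactly."""
        w = rng.normal(size=5)
        w /= np.linalg.norm(w)
        M = -7.5 * np.outer(w, w)
        result = decompose(M)
        assert result.approx_energy == pytest.approx(result.total_energy, rel=1e-10)
        assert result.dominance_ratio == pytest.approx(1.0)

    def test_spectral_reconstruction_identity(self, rng):
        """Σ_k λ_k W_k / 2 equals the brute-force double sum ½ΣΣ M_ij."""
        for _ in range(10):
            M = rng.normal(size=(6, 6))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            result = decompose(EnergyMatrix(M))
            lhs = 0.5 * np.sum(result.eigenvalues * result.component_sums_squared)
            rhs = 0.5 * sum(M[i, j] for i in range(6) for j in range(6))
            assert lhs == pytest.approx(rhs, abs=1e-10)
            assert result.total_energy == pytest.approx(rhs, abs=1e-10)

    def test_approximation_triangle_bound(self, rng):
        """|E_nb − E_nb^app| ≤ ½ Σ_{k≥2} |λ_k| W_k."""
        for _ in range(20):
            M = rng.normal(size=(8, 8))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            r = decompose(EnergyMatrix(M))
            bound = 0.5 * np.sum(
                np.abs(r.eigenvalues[1:]) * r.component_sums_squared[1:]
            )
            assert abs(r.total_energy - r.approx_energy) <= bound + 1e-10

    def test_eigenvectors_orthonormal(self, rng):
        M = rng.normal(size=(7, 7))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        r = decompose(EnergyMatrix(M))
        np.testing.assert_allclose(
            r.eigenvectors.T @ r.eigenvectors, np.eye(7), atol=1e-10
        )

    def test_asymmetric_input_rejected(self):
        M = np.zeros((3, 3))
        M[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            decompose(M)


class TestHotSpots:
    def test_flat_eigenvector_gives_empty_set(self):
        """Weights exactly at the 1/N threshold are excluded (strict >)."""
        result = decompose(_all_minus_one(4))
        spots = hot_spots(result)
        np.testing.assert_allclose(spots.weights, 0.25)
        assert spots.indices == ()

    def test_planted_single_hotspot(self):
        w = np.array([3.0, 1.0, 1.0, 1.0]) / np.sqrt(12.0)
        result = decompose(-10.0 * np.outer(w, w))
        spots = hot_spots(result)
        assert spots.indices == (0,)
        assert spots.weights[0] == pytest.approx(0.75)
        assert spots.threshold == pytest.approx(0.25)

    def test_planted_pair_recovered_at_zero_noise(self):
        from zfdyn.synthetic import PlantedEnergySpec, planted_energy_matrix

        spec = PlantedEnergySpec(
            n_sites=12, hotspot_indices={3, 9}, hotspot_weight_ratio=3.0,
            leading_eigenvalue=-50.0, noise_sd=0.0,
        )
        spots = hot_spots(decompose(planted_energy_matrix(spec)))
        assert set(spots.indices) == {3, 9}


class TestPartition:
    def test_four_site_closed_form(self):
        """λ=−10, w=(½,½,½,½), 2 protein + 2 DNA → −5/−10/−5, total −20."""
        w = np.full(4, 0.5)
        result = decompose(-10.0 * np.outer(w, w))
        part = partition_stabilization(result, make_topology(2, 2))
        assert part.protein_protein == pytest.approx(-5.0)
        assert part.protein_dna == pytest.approx(-10.0)
        assert part.dna_dna == pytest.approx(-5.0)
        assert part.total == pytest.approx(-20.0)

    def test_all_protein_system(self, rng):
        M = rng.normal(size=(5, 5))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        part = partition_stabilization(decompose(EnergyMatrix(M)), make_topology(5))
        assert part.protein_dna == 0.0 and part.dna_dna == 0.0
        assert part.protein_protein == pytest.approx(part.total)

    def test_additivity_on_random_matrices(self, rng):
        """PP + PD + DD equals E_nb^app exactly, over 100 random cases."""
        for _ in range(100):
            n_prot = rng.integers(2, 6)
            n_dna = rng.integers(1, 5)
            n = int(n_prot + n_dna)
            M = rng.normal(size=(n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            result = decompose(EnergyMatrix(M))
            part = partition_stabilization(result, make_topology(int(n_prot), int(n_dna)))
            assert part.total == pytest.approx(result.approx_energy, abs=1e-10)

    def test_raw_block_sums_partition_whole_matrix(self, rng):
        M = rng.normal(size=(6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        matrix = EnergyMatrix(M)
        part = raw_block_sums(matrix, make_topology(4, 2))
        assert part.total == pytest.approx(0.5 * M.sum(), abs=1e-10)


class TestIntraproteinEnergy:
    def test_embedded_protein_submatrix(self):
        """3 protein sites with −1 couplings inside a larger complex → −3."""
        M = np.zeros((5, 5))
        prot = np.ix_([0, 1, 2], [0, 1, 2])
        M[prot] = -1.0
        M[3, 4] = M[4, 3] = -20.0
        M[0, 3] = M[3, 0] = -8.0
        np.fill_diagonal(M, 0.0)
        e = intraprotein_energy(EnergyMatrix(M), make_topology(3, 2))
        assert e == pytest.approx(-3.0, abs=1e-10)

    def test_zero_protein_block_gives_zero(self):
        M = np.zeros((4, 4))
        M[2, 3] = M[3, 2] = -5.0
        assert intraprotein_energy(EnergyMatrix(M), make_topology(2, 2)) == pytest.approx(0.0)

    def test_invariant_to_dna_entries(self, rng):
        M = rng.normal(size=(6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        topo = make_topology(4, 2)
        e1 = intraprotein_energy(EnergyMatrix(M), topo)
        M2 = M.copy()
        M2[4, 5] = M2[5, 4] = 99.0
        M2[0, 4] = M2[4, 0] = -99.0
        e2 = intraprotein_energy(EnergyMatrix(M2), topo)
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_too_few_protein_sites_rejected(self):
        M = np.zeros((3, 3))
        with pytest.raises(ValueError, match="protein sites"):
            intraprotein_energy(EnergyMatrix(M), make_topology(1, 2))
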