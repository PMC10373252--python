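"""Relationship structures against independent oracles: recursive-kinship A,
elementwise G, block-arithmetic APY, dense H^-1 assembly."""

import numpy as np
import pytest

from sspig import relmat, simdata

from conftest import kinship_oracle, make_pedigree


@pytest.fixture(scope="module")
def random_pedigree():
    cfg = simdata.SimulationConfig(
        n_founders=30, n_generations=3, n_matings_per_gen=12, litter_size=4, seed=21
    )
    return simdata.simulate_pedigree(cfg)


class TestAInverse:
    def test_single_founder(self):
        ped = make_pedigree([(1, 0, 0, 0, 0)])
        f = relmat.build_A_inverse(ped)
        assert np.allclose(f.a_inverse.toarray(), [[1.0]])

    def test_trio_closed_form(self, trio):
        f = relmat.build_A_inverse(trio)
        expect = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        assert np.allclose(f.a_inverse.toarray(), expect)

    def test_inverse_of_kinship_oracle(self, random_pedigree):
        A = kinship_oracle(random_pedigree)
        f = relmat.build_A_inverse(random_pedigree)
        assert np.abs(f.a_inverse.toarray() @ A - np.eye(len(A))).max() < 1e-8

    def test_inbreeding_matches_oracle_diagonal(self, random_pedigree):
        A = kinship_oracle(random_pedigree)
        f = relmat.build_A_inverse(random_pedigree)
        assert np.allclose(f.inbreeding, A.diagonal() - 1.0, atol=1e-12)

    def test_founder_diagonal_is_one(self, random_pedigree):
        f = relmat.build_A_inverse(random_pedigree)
        # a founder with no descendants would have diagonal exactly 1;
        # all founders have F = 0
        assert np.allclose(f.inbreeding[random_pedigree.generation == 0], 0.0)


class TestA22:
    def test_unrelated_founders(self):
        ped = make_pedigree([(1, 0, 0, 0, 0), (2, 0, 0, 0, 0)])
        assert np.allclose(relmat.build_A22(ped, [1, 2]), np.eye(2))

    def test_full_sibs(self):
        ped = make_pedigree(
            [(1, 0, 0, 0, 0), (2, 0, 0, 0, 0), (3, 1, 2, 1, 1), (4, 1, 2, 1, 1)]
        )
        A22 = relmat.build_A22(ped, [3, 4])
        assert A22[0, 1] == pytest.approx(0.5)

    def test_offspring_of_half_sibs_inbred(self):
        # 1-2 -> 4; 1-3 -> 5 (half sibs); 4-5 -> 6 with F = 0.125
        ped = make_pedigree(
            [
                (1, 0, 0, 0, 0),
                (2, 0, 0, 0, 0),
                (3, 0, 0, 0, 0),
                (4, 1, 2, 1, 1),
                (5, 1, 3, 1, 2),
                (6, 4, 5, 2, 3),
            ]
        )
        A22 = relmat.build_A22(ped, [6])
        assert A22[0, 0] == pytest.approx(1.125)

    def test_matches_kinship_oracle_subset(self, random_pedigree):
        take = random_pedigree.animal[::7]
        A22 = relmat.build_A22(random_pedigree, take)
        idx = random_pedigree.index_of(take)
        oracle = kinship_oracle(random_pedigree)[np.ix_(idx, idx)]
        assert np.abs(A22 - oracle).max() < 1e-8

    def test_unknown_ids_error(self, trio):
        with pytest.raises(KeyError):
            relmat.build_A22(trio, [99])


class TestG:
    def test_two_by_two_worked_example(self):
        g = simdata.GenotypeMatrix(
            np.array([1, 2]), np.array(["a", "b"]), np.array([[0.0, 2.0], [2.0, 0.0]])
        )
        G = relmat.build_G(g)
        assert np.allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_calls_at_2p_give_zero(self):
        calls = np.tile([1.0, 0.6, 1.4], (4, 1))  # every column constant = 2p
        g = simdata.GenotypeMatrix(
            np.arange(4), np.array(["a", "b", "c"]), calls
        )
        G = relmat.build_G(g, allele_freqs=calls[0] / 2)
        assert np.abs(G.values).max() < 1e-12

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(50, 500)).astype(float)
        g = simdata.GenotypeMatrix(
            np.arange(50), np.array([f"m{j}" for j in range(500)]), calls
        )
        w = rng.uniform(0.5, 2.0, 500)
        G = relmat.build_G(g, weights=w)
        p = calls.mean(axis=0) / 2
        M = calls - 2 * p
        denom = 2 * np.sum(p * (1 - p))
        brute = np.zeros((50, 50))
        for i in range(50):
            for k in range(50):
                brute[i, k] = np.sum(w * M[i] * M[k]) / denom
        assert np.abs(G.values - brute).max() < 1e-10

    def test_monomorphic_only_errors(self):
        g = simdata.GenotypeMatrix(
            np.arange(3), np.array(["a", "b"]), np.zeros((3, 2))
        )
        with pytest.raises(ValueError):
            relmat.build_G(g)

    def test_diag_mean_near_one_plus_f_on_hwe_founders(self):
        cfg = simdata.SimulationConfig(
            n_founders=1000,
            n_generations=0,
            n_seq_markers=5000,
            n_chip_markers=100,
            n_qtl=0,
            ld_decay_rho=0.0,
            seed=6,
        )
        pop = simdata.simulate_population(cfg)
        G = relmat.build_G(pop.genotypes)
        assert abs(G.values.diagonal().mean() - 1.0) < 0.02


class TestTuneAndBlend:
    def test_worked_example(self):
        G = relmat.GenomicMatrix(np.array([1, 2]), np.array([[2.0, -2.0], [-2.0, 2.0]]))
        A22 = np.array([[1.0, 0.25], [0.25, 1.0]])
        out = relmat.tune_and_blend(G, A22, 0.05)
        # b = 0.75/4 = 0.1875, a = 1 - 0.1875*2 = 0.625; G_t == A22 here so
        # blending changes nothing
        assert np.allclose(out.values, A22)

    def test_identity_when_means_match(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 100))
        A22 = X @ X.T / 100
        G = relmat.GenomicMatrix(np.arange(30), A22.copy())
        out = relmat.tune_and_blend(G, A22, 0.0)
        assert np.allclose(out.values, A22, atol=1e-12)

    def test_means_match_after_tuning(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 400))
        G = relmat.GenomicMatrix(np.arange(100), X @ X.T / 400)
        Y = rng.standard_normal((100, 400))
        A22 = Y @ Y.T / 400 + np.eye(100) * 0.1
        out = relmat.tune_and_blend(G, A22, 0.0)
        off = ~np.eye(100, dtype=bool)
        assert out.values.diagonal().mean() == pytest.approx(A22.diagonal().mean(), abs=1e-10)
        assert out.values[off].mean() == pytest.approx(A22[off].mean(), abs=1e-10)

    def test_blended_is_positive_definite(self, small_population):
        pop = small_population
        geno = pop.genotypes.subset(animal_ids=pop.sequenced_ids)
        G = relmat.build_G(geno)
        A22 = relmat.build_A22(pop.pedigree, pop.sequenced_ids)
        out = relmat.tune_and_blend(G, A22, 0.05)
        np.linalg.cholesky(out.values)  # raises if not PD

    def test_singular_system_errors(self):
        G = relmat.GenomicMatrix(np.array([1, 2]), np.ones((2, 2)))
        with pytest.raises(ValueError):
            relmat.tune_and_blend(G, np.eye(2))


class TestDimensionality:
    def test_identity(self):
        assert relmat.dimensionality_98(np.eye(100)) == 98

    def test_direct_sum(self):
        assert relmat.dimensionality_98(np.diag([98.0, 1.0, 1.0])) == 1

    def test_rank_one(self):
        v = np.arange(1.0, 6.0)
        assert relmat.dimensionality_98(np.outer(v, v)) == 1


@pytest.fixture(scope="module")
def blended_g():
    rng = np.random.default_rng(9)
    calls = rng.binomial(2, rng.uniform(0.2, 0.5, 300), size=(40, 300)).astype(float)
    g = simdata.GenotypeMatrix(
        np.arange(1, 41), np.array([f"m{j}" for j in range(300)]), calls
    )
    G = relmat.build_G(g)
    return relmat.tune_and_blend(G, np.eye(40) + 0.01, 0.05)


class TestAPY:
    def test_all_core_equals_direct(self, blended_g):
        apy = relmat.apy_inverse(blended_g, blended_g.animal_ids)
        direct = relmat.direct_inverse(blended_g)
        assert np.abs(apy.to_dense() - direct.to_dense()).max() < 1e-10

    def test_matches_block_formula(self, blended_g):
        core_ids = blended_g.animal_ids[:25]
        apy = relmat.apy_inverse(blended_g, core_ids)
        Gv = blended_g.values
        c, n = np.arange(25), np.arange(25, 40)
        Gcci = np.linalg.inv(Gv[np.ix_(c, c)])
        P = Gcci @ Gv[np.ix_(c, n)]
        m = Gv.diagonal()[n] - np.einsum("ij,ij->j", Gv[np.ix_(c, n)], P)
        Mi = np.diag(1.0 / m)
        brute = np.block(
            [[Gcci + P @ Mi @ P.T, -P @ Mi], [-Mi @ P.T, Mi]]
        )
        assert np.abs(apy.to_dense() - brute).max() < 1e-10
        assert np.allclose(apy.diagonal(), brute.diagonal())

    def test_operator_matches_dense_on_vectors(self, blended_g):
        apy = relmat.apy_inverse(blended_g, blended_g.animal_ids[::2])
        rng = np.random.default_rng(10)
        v = rng.standard_normal((40, 3))
        assert np.allclose(apy.matmat(v), apy.to_dense() @ v)

    def test_good_core_gives_equivalent_gebv(self):
        """With a random core sized by the 98%-eigenvalue criterion, GEBV
        from the APY inverse correlate >= 0.99 with GEBV from the direct
        inverse — the approximation quality the core-size rule promises."""
        rng = np.random.default_rng(11)
        cfg = simdata.SimulationConfig(
            n_founders=60,
            n_generations=3,
            n_matings_per_gen=25,
            litter_size=6,
            n_seq_markers=800,
            n_chip_markers=80,
            n_qtl=40,
            seed=23,
        )
        pop = simdata.simulate_population(cfg)
        geno = pop.genotypes.subset(animal_ids=pop.sequenced_ids)
        G = relmat.build_G(geno)
        A22 = relmat.build_A22(pop.pedigree, pop.sequenced_ids)
        Gb = relmat.tune_and_blend(G, A22)
        k = relmat.dimensionality_98(Gb)
        n = Gb.n
        tbv = pop.phenotypes.tbv.loc[pop.sequenced_ids].iloc[:, 0].to_numpy()
        y = tbv + rng.standard_normal(n) * np.sqrt(0.6)
        lam = 0.6 / 0.35
        direct = relmat.direct_inverse(Gb)
        u_dir = np.linalg.solve(np.eye(n) + lam * direct.to_dense(), y - y.mean())
        core = relmat.choose_core(Gb, np.random.default_rng(5), n_core=k)
        apy = relmat.apy_inverse(Gb, core)
        u_apy = np.linalg.solve(np.eye(n) + lam * apy.to_dense(), y - y.mean())
        assert np.corrcoef(u_dir, u_apy)[0, 1] >= 0.99

    def test_fully_explained_noncore_errors(self):
        # duplicate animal rows: noncore exactly explained by core
        calls = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 1.0]])
        calls = np.vstack([calls, calls[0]])
        g = simdata.GenotypeMatrix(np.arange(3), np.array(["a", "b", "c"]), calls)
        G = relmat.build_G(g)
        with pytest.raises(ValueError):
            relmat.apy_inverse(G, G.animal_ids[:2])


class TestHInverse:
    def test_no_genotypes_reduces_to_a_inverse(self, random_pedigree):
        f = relmat.build_A_inverse(random_pedigree)
        h = relmat.build_H_inverse(random_pedigree, f, None, None, [])
        v = np.random.default_rng(12).standard_normal(random_pedigree.n)
        assert np.allclose(h.matvec(v), f.a_inverse @ v)

    def test_full_blend_recovers_a_inverse(self, random_pedigree):
        """blend_weight -> 1 makes G = A22, so the correction vanishes."""
        f = relmat.build_A_inverse(random_pedigree)
        ids = random_pedigree.animal[::3]
        A22 = relmat.build_A22(random_pedigree, ids, f)
        G = relmat.GenomicMatrix(ids, A22.copy())
        g_inv = relmat.direct_inverse(G)
        h = relmat.build_H_inverse(random_pedigree, f, g_inv, A22, ids)
        v = np.random.default_rng(13).standard_normal(random_pedigree.n)
        assert np.abs(h.matvec(v) - f.a_inverse @ v).max() < 1e-8

    def test_matches_dense_assembly_oracle(self, random_pedigree):
        rng = np.random.default_rng(14)
        ids = random_pedigree.animal[::3]
        calls = rng.binomial(2, 0.4, size=(len(ids), 400)).astype(float)
        g = simdata.GenotypeMatrix(ids, np.array([f"m{j}" for j in range(400)]), calls)
        f = relmat.build_A_inverse(random_pedigree)
        A22 = relmat.build_A22(random_pedigree, ids, f)
        Gb = relmat.tune_and_blend(relmat.build_G(g), A22)
        h = relmat.build_H_inverse(random_pedigree, f, relmat.direct_inverse(Gb), A22, ids)
        # dense oracle assembled independently
        idx = random_pedigree.index_of(ids)
        H = f.a_inverse.toarray()
        H[np.ix_(idx, idx)] += np.linalg.inv(Gb.values) - np.linalg.inv(A22)
        v = rng.standard_normal(random_pedigree.n)
        assert np.abs(h.matvec(v) - H @ v).max() < 1e-9
        assert np.allclose(h.diagonal(), H.diagonal())

    def test_genotyped_animal_missing_from_pedigree_errors(self, trio):
        f = relmat.build_A_inverse(trio)
        G = relmat.GenomicMatrix(np.array([99]), np.eye(1))
        with pytest.raises(KeyError):
            relmat.build_H_inverse(trio, f, relmat.direct_inverse(G), np.eye(1), [99])
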