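"""Generative-model checks: pedigree construction, gene drop, QTL scaling,
phenotype decomposition, determinism."""

import numpy as np
import pytest

from sspig import qc, simdata

from conftest import make_pedigree


class TestPedigree:
    def test_founders_only(self):
        cfg = simdata.SimulationConfig(n_founders=10, n_generations=0)
        ped = simdata.simulate_pedigree(cfg)
        assert ped.n == 10
        assert (ped.sire == 0).all() and (ped.dam == 0).all()

    def test_counts_by_construction(self):
        cfg = simdata.SimulationConfig(
            n_founders=10, n_generations=2, n_matings_per_gen=5, litter_size=6
        )
        ped = simdata.simulate_pedigree(cfg)
        # 10 founders + 2 generations x 5 litters x 6 sibs
        assert ped.n == 10 + 30 + 30

    def test_full_sibs_share_parents_and_litter(self):
        cfg = simdata.SimulationConfig(n_founders=20, n_generations=2)
        ped = simdata.simulate_pedigree(cfg)
        df = ped.to_frame()
        for _, grp in df[df.litter > 0].groupby("litter"):
            assert grp.sire.nunique() == 1 and grp.dam.nunique() == 1

    def test_generation_structure(self):
        cfg = simdata.SimulationConfig(n_founders=20, n_generations=3)
        ped = simdata.simulate_pedigree(cfg)
        sidx, didx = ped.parent_indices()
        off = sidx >= 0
        assert (
            ped.generation[off]
            == np.maximum(ped.generation[sidx[off]], ped.generation[didx[off]]) + 1
        ).all()

    def test_determinism(self):
        cfg = simdata.SimulationConfig(n_founders=30, n_generations=2, seed=5)
        a = simdata.simulate_pedigree(cfg).to_frame()
        b = simdata.simulate_pedigree(cfg).to_frame()
        assert a.equals(b)

    def test_overselection_errors(self):
        cfg = simdata.SimulationConfig(
            n_founders=4,
            n_generations=2,
            n_matings_per_gen=1,
            litter_size=2,
            mating_scheme="truncation_selection",
            selection_proportion=0.01,
        )
        with pytest.raises(ValueError):
            simdata.simulate_pedigree(cfg)

    def test_truncation_selection_concentrates_ancestry(self):
        base = dict(n_founders=60, n_generations=2, n_matings_per_gen=30, litter_size=4)
        rnd = simdata.simulate_pedigree(
            simdata.SimulationConfig(**base, mating_scheme="random", seed=3)
        )
        sel = simdata.simulate_pedigree(
            simdata.SimulationConfig(
                **base,
                mating_scheme="truncation_selection",
                selection_proportion=0.2,
                seed=3,
            )
        )
        n_sires = lambda p: len(np.unique(p.sire[p.generation == 2]))
        assert n_sires(sel) <= n_sires(rnd)


class TestGeneDrop:
    def test_mendelian_consistent(self, small_population):
        rep = qc.mendelian_checks(
            small_population.pedigree, small_population.genotypes
        )
        assert rep.mendelian_conflicts["n_conflicts"].sum() == 0
        assert len(rep.flagged_animals) == 0

    def test_no_missing_after_simulation(self, small_population):
        assert not np.isnan(small_population.genotypes.calls).any()

    def test_ld_zero_when_rho_zero(self):
        cfg = simdata.SimulationConfig(
            n_founders=2000,
            n_generations=0,
            n_seq_markers=50,
            n_chip_markers=5,
            n_qtl=5,
            ld_decay_rho=0.0,
            founder_maf_range=(0.3, 0.5),
            seed=9,
        )
        ped = simdata.simulate_pedigree(cfg)
        mm = simdata.build_marker_map(cfg)
        geno = simdata.drop_genotypes(ped, mm, cfg)
        r2 = []
        for c in np.unique(mm.chromosome):
            idx = np.flatnonzero(mm.chromosome == c)
            for a, b in zip(idx[:-1], idx[1:]):
                r2.append(np.corrcoef(geno.calls[:, a], geno.calls[:, b])[0, 1] ** 2)
        assert np.mean(r2) < 0.02

    def test_positive_rho_induces_adjacent_ld(self):
        cfg = simdata.SimulationConfig(
            n_founders=500,
            n_generations=0,
            n_seq_markers=100,
            n_chip_markers=10,
            n_qtl=5,
            ld_decay_rho=0.9,
            founder_maf_range=(0.3, 0.5),
            seed=9,
        )
        ped = simdata.simulate_pedigree(cfg)
        mm = simdata.build_marker_map(cfg)
        geno = simdata.drop_genotypes(ped, mm, cfg)
        idx = np.flatnonzero(mm.chromosome == 1)
        r2 = [
            np.corrcoef(geno.calls[:, a], geno.calls[:, b])[0, 1] ** 2
            for a, b in zip(idx[:-1], idx[1:])
        ]
        assert np.mean(r2) > 0.3

    def test_founder_genotype_frequencies_hwe(self):
        cfg = simdata.SimulationConfig(
            n_founders=2000,
            n_generations=0,
            n_seq_markers=10,
            n_chip_markers=2,
            n_qtl=2,
            founder_maf_range=(0.5, 0.5),
            ld_decay_rho=0.0,
            seed=1,
        )
        ped = simdata.simulate_pedigree(cfg)
        mm = simdata.build_marker_map(cfg)
        geno = simdata.drop_genotypes(ped, mm, cfg)
        counts = np.array(
            [(geno.calls[:, 0] == g).mean() for g in (0, 1, 2)]
        )
        # binomial 99% CI half-widths at n=2000 around (0.25, 0.5, 0.25)
        half = 2.58 * np.sqrt(np.array([0.25, 0.5, 0.25]) * np.array([0.75, 0.5, 0.75]) / 2000)
        assert (np.abs(counts - [0.25, 0.5, 0.25]) < half + 1e-12).all()

    def test_allele_frequency_expectation_over_drops(self):
        """Gene-drop frequencies drift, but their mean over replicates sits
        at the founder frequency (within 3 SE)."""
        cfg = simdata.SimulationConfig(
            n_founders=30,
            n_generations=2,
            n_matings_per_gen=10,
            litter_size=4,
            n_seq_markers=12,
            n_chip_markers=2,
            n_qtl=2,
            founder_maf_range=(0.3, 0.3),
            ld_decay_rho=0.0,
        )
        ped = simdata.simulate_pedigree(cfg.replace(seed=2))
        mm = simdata.build_marker_map(cfg.replace(seed=2))
        freqs = []
        for rep in range(200):
            geno = simdata.drop_genotypes(ped, mm, cfg, np.random.default_rng(rep))
            freqs.append(geno.calls.mean(axis=0) / 2)
        freqs = np.array(freqs)
        mean = freqs.mean(axis=0)
        se = freqs.std(axis=0, ddof=1) / np.sqrt(len(freqs))
        assert (np.abs(mean - 0.3) < 3 * se + 1e-12).all()


class TestQTLAndPhenotypes:
    def test_single_qtl_effect_scaling(self):
        """2 p (1-p) a^2 = h2: with p = 0.5 and target 1.0 => |a| = sqrt(2)."""
        cfg = simdata.SimulationConfig(
            n_seq_markers=100,
            n_chip_markers=10,
            n_qtl=1,
            traits=("T",),
            heritabilities={"T": 1.0},
            litter_variance_fractions={"T": 0.0},
            founder_maf_range=(0.5, 0.5),
            genetic_correlations=np.eye(1),
        )
        mm = simdata.build_marker_map(cfg)
        mm = simdata.assign_qtl_effects(mm, cfg)
        a = mm.qtl_effects.loc[mm.is_qtl, "T"].to_numpy()
        assert len(a) == 1
        assert abs(abs(a[0]) - np.sqrt(2.0)) < 1e-10

    def test_uncorrelated_traits_give_uncorrelated_tbv(self):
        cfg = simdata.SimulationConfig(
            n_founders=5000,
            n_generations=0,
            n_seq_markers=800,
            n_chip_markers=40,
            n_qtl=400,
            genetic_correlations=np.eye(2),
            ld_decay_rho=0.0,
            seed=4,
        )
        pop = simdata.simulate_population(cfg)
        r = np.corrcoef(pop.phenotypes.tbv["ADG"], pop.phenotypes.tbv["BF"])[0, 1]
        assert abs(r) < 0.05

    def test_founder_tbv_variance_matches_target(self):
        cfg = simdata.SimulationConfig(
            n_founders=4000,
            n_generations=0,
            n_seq_markers=500,
            n_chip_markers=50,
            n_qtl=50,
            ld_decay_rho=0.0,
            seed=8,
        )
        pop = simdata.simulate_population(cfg)
        for t in cfg.traits:
            v = pop.phenotypes.tbv[t].var()
            assert v == pytest.approx(cfg.heritabilities[t], abs=0.06)

    def test_no_qtl_means_no_genetic_variance(self):
        cfg = simdata.SimulationConfig(
            n_founders=100, n_generations=1, n_seq_markers=200, n_chip_markers=20, n_qtl=0
        )
        pop = simdata.simulate_population(cfg)
        assert (pop.phenotypes.tbv.to_numpy() == 0).all()

    def test_h2_one_value_equals_fixed_part_plus_tbv(self):
        cfg = simdata.SimulationConfig(
            n_founders=40,
            n_generations=1,
            traits=("T",),
            heritabilities={"T": 1.0},
            litter_variance_fractions={"T": 0.0},
            genetic_correlations=np.eye(1),
            n_seq_markers=200,
            n_chip_markers=20,
            n_qtl=20,
            covariate_effect=0.0,
        )
        pop = simdata.simulate_population(cfg)
        recs = pop.phenotypes.records
        tbv = pop.phenotypes.tbv.loc[recs["animal"], "T"].to_numpy()
        # residual and litter variance are zero, so value - CG mean == TBV
        resid = recs["value"].to_numpy() - tbv
        for _, grp in recs.assign(resid=resid).groupby("cg"):
            assert grp["resid"].std() < 1e-9 if len(grp) > 1 else True

    def test_h2_recovery_by_regression(self):
        cfg = simdata.SimulationConfig(
            n_founders=5000,
            n_generations=0,
            traits=("T",),
            heritabilities={"T": 0.4},
            litter_variance_fractions={"T": 0.0},
            genetic_correlations=np.eye(1),
            n_seq_markers=400,
            n_chip_markers=40,
            n_qtl=80,
            ld_decay_rho=0.0,
            cg_variance=0.0,
            seed=12,
        )
        pop = simdata.simulate_population(cfg)
        recs = pop.phenotypes.for_trait("T")
        tbv = pop.phenotypes.tbv.loc[recs["animal"], "T"].to_numpy()
        y = recs["value"].to_numpy()
        slope = np.cov(y, tbv)[0, 1] / np.var(tbv)
        assert slope == pytest.approx(1.0, abs=0.07)
        h2_hat = np.var(tbv) / np.var(y)
        assert h2_hat == pytest.approx(0.4, abs=0.05)

    def test_full_sib_phenotypic_covariance(self):
        """cov(full sibs) = litter variance + half the additive variance."""
        cfg = simdata.SimulationConfig(
            n_founders=400,
            n_generations=1,
            n_matings_per_gen=2000,
            litter_size=2,
            traits=("T",),
            heritabilities={"T": 0.4},
            litter_variance_fractions={"T": 0.2},
            genetic_correlations=np.eye(1),
            n_seq_markers=300,
            n_chip_markers=30,
            n_qtl=60,
            cg_variance=0.0,
            ld_decay_rho=0.0,
            seed=13,
        )
        pop = simdata.simulate_population(cfg)
        recs = pop.phenotypes.for_trait("T")
        df = recs.merge(
            pop.pedigree.to_frame()[["animal", "litter", "generation"]], on="animal"
        )
        df = df[df.generation == 1]
        pairs = df.groupby("litter_y")["value"].agg(list)
        pairs = np.array([p for p in pairs if len(p) == 2])
        cov = np.cov(pairs[:, 0], pairs[:, 1])[0, 1]
        # expected 0.2 + 0.5 * 0.4 = 0.4 (phenotypic variance 1)
        assert cov == pytest.approx(0.4, abs=0.08)


class TestCrossbred:
    def test_crossbreds_record_only_crossbred_traits(self):
        cfg = simdata.SimulationConfig(
            n_founders=60,
            n_generations=2,
            n_matings_per_gen=10,
            litter_size=4,
            crossbred_cohort=True,
            crossbred_traits=("ADGX",),
            heritabilities={"ADG": 0.35, "BF": 0.4, "ADGX": 0.3},
            litter_variance_fractions={"ADG": 0.1, "BF": 0.1, "ADGX": 0.1},
            n_crossbred_matings_per_gen=5,
            n_seq_markers=200,
            n_chip_markers=20,
            n_qtl=10,
        )
        pop = simdata.simulate_population(cfg)
        ped = pop.pedigree.to_frame()
        xb = set(ped[ped.cohort == simdata.CROSSBRED].animal)
        assert xb
        recs = pop.phenotypes.records
        xb_traits = set(recs[recs.animal.isin(xb)].trait)
        assert xb_traits == {"ADGX"}
        pure_traits = set(recs[~recs.animal.isin(xb)].trait)
        assert pure_traits == {"ADG", "BF"}
        # crossbreds are never sequenced
        assert not (set(pop.sequenced_ids) & xb)

    def test_structural_zeros_in_l0_r0(self):
        cfg = simdata.SimulationConfig(
            crossbred_cohort=True,
            crossbred_traits=("ADGX",),
            heritabilities={"ADG": 0.35, "BF": 0.4, "ADGX": 0.3},
            litter_variance_fractions={"ADG": 0.1, "BF": 0.1, "ADGX": 0.1},
        )
        _, l0, r0 = simdata.true_variance_components(cfg)
        assert l0.loc["ADG", "ADGX"] == 0 and r0.loc["BF", "ADGX"] == 0


def test_population_determinism(small_config):
    a = simdata.simulate_population(small_config)
    b = simdata.simulate_population(small_config)
    assert np.array_equal(a.genotypes.calls, b.genotypes.calls)
    assert a.phenotypes.records["value"].equals(b.phenotypes.records["value"])


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        simdata.SimulationConfig(
            heritabilities={"ADG": 0.9, "BF": 0.4},
            litter_variance_fractions={"ADG": 0.3, "BF": 0.1},
        ).validate()
    with pytest.raises(ValueError):
        simdata.SimulationConfig(n_chip_markers=100, n_seq_markers=50).validate()
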