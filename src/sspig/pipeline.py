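"""End-to-end scenarios: Chip, Top40k, ChipPlusSign, TopSign, each
optionally BayesR-weighted.

One simulated line is shared across panel scenarios (same pedigree, same
split, same GWAS), and the animal set entering the genomic matrices is the
intersection of the panels' QC survivors — so accuracy differences between
panels are paired and attributable to the marker sets, mirroring a fair
within-line comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import bayesr, gwas, mme, panels, qc, relmat, validation
from .simdata import Population, SimulationConfig, simulate_population

log = logging.getLogger("sspig")

# trait groupings used by the study design: two-trait growth/feed models,
# reproduction pairs, and single-trait models; terminal groups add
# crossbred-recorded traits
MODEL_GROUPS = {
    "ADFI": ("ADG", "ADFI"),
    "GROWTH": ("ADG", "BF"),
    "LOIN": ("ADG", "LDP"),
    "REPROD": ("TNB", "NSB"),
    "RET": ("RET",),
    "WWT": ("WWT",),
    "GROWTH_TERMINAL": ("ADG", "BF", "ADGX", "BFX"),
    "LOIN_TERMINAL": ("ADG", "LDP", "ADGX", "LDPX"),
}

PANEL_MODES = ("chip", "top40k", "chip_plus_sign", "top_sign")


@dataclass
class ScenarioConfig:
    line_label: str = "SIM"
    model_group: str | None = None  # key of MODEL_GROUPS, or None to use sim traits
    traits: tuple | None = None  # explicit trait list, overrides model_group
    panel_mode: str = "chip"
    weighted: bool = False
    apy: str = "auto"  # auto | on | off
    apy_threshold: int = 2000
    window_bp: int = panels.DEFAULT_WINDOW_BP
    p_threshold: float = panels.DEFAULT_P_THRESHOLD
    blend_weight: float = 0.05
    solver_tol: float = 1e-10
    n_boot: int = 1000
    bayesr_config: bayesr.BayesRConfig | None = None
    seed: int = 1

    def traits_for(self, sim_config: SimulationConfig) -> list:
        if self.traits is not None:
            return list(self.traits)
        if self.model_group is None:
            return list(sim_config.all_traits)
        traits = MODEL_GROUPS[self.model_group]
        missing = [t for t in traits if t not in sim_config.all_traits]
        if missing:
            raise ValueError(f"model group needs traits not simulated: {missing}")
        return list(traits)


@dataclass
class LineData:
    """Stage outputs shared by every panel scenario of one line/seed."""

    population: Population
    ped_factor: relmat.PedigreeFactor
    seq_genotypes: object  # post-QC sequence GenotypeMatrix (sequenced animals)
    split: validation.SplitDefinition
    debv: dict  # trait -> DataFrame(animal, debv, weight, ...)
    gwas_results: dict  # trait -> GWASResult
    chip: panels.SNPPanel
    core_ids: np.ndarray | None = None  # one APY core draw reused across panels
    meta: dict = field(default_factory=dict)


def prepare_line(
    sim_config: SimulationConfig,
    traits: list | None = None,
    seed: int = 1,
) -> LineData:
    """Simulate, QC, split, run the pedigree-only evaluation (for dEBV) and
    the per-trait GWAS on the genotyped training set."""
    pop = simulate_population(sim_config)
    ped = pop.pedigree
    traits = traits or list(sim_config.traits)
    purebred_traits = [t for t in traits if t in sim_config.traits]
    rng = np.random.default_rng(seed)

    factor = relmat.build_A_inverse(ped)

    # sequence-level QC on the sequenced (purebred) animals
    seq = pop.genotypes.subset(animal_ids=pop.sequenced_ids)
    seq_qc, mrep, irep = qc.apply_marker_qc(seq, imputed_panel=True)
    log.info(
        "line %s: %d/%d sequence markers retained after QC",
        sim_config.seed,
        len(mrep.retained_markers),
        seq.n_markers,
    )

    split = validation.split_train_test(ped, np.asarray(seq_qc.animal_ids), factor)

    # pedigree-only evaluation per trait -> dEBV (validation quasi-phenotypes)
    phen = pop.phenotypes
    debv = {}
    for t in traits:
        ebv, rel = validation.pedigree_blup(
            phen.records, t, ped, factor, phen.sigma0, phen.l0, phen.r0
        )
        der = validation.deregress_ebv(ebv, rel, ped)
        debv[t] = der.table.set_index("animal")

    # GWAS per purebred trait on genotyped training animals; population
    # structure via the chip-marker G of those animals
    chip_markers = np.asarray(seq_qc.marker_ids)[
        np.isin(seq_qc.marker_ids, pop.marker_map.marker_id[pop.marker_map.is_chip])
    ]
    gwas_results = {}
    for t in purebred_traits:
        recs = phen.for_trait(t)
        recs = recs[recs["animal"].isin(split.train_ids)]
        train_geno = seq_qc.subset(animal_ids=recs["animal"].to_numpy())
        G_train = relmat.build_G(train_geno.subset(marker_ids=chip_markers))
        y = recs["value"].to_numpy()
        X = gwas.design_matrix(recs)
        gwas_results[t] = gwas.run_gwas(y, X, G_train.values, train_geno)

    chip = panels.SNPPanel(
        "chip", chip_markers, {m: panels.CHIP for m in chip_markers}
    )
    return LineData(
        population=pop,
        ped_factor=factor,
        seq_genotypes=seq_qc,
        split=split,
        debv=debv,
        gwas_results=gwas_results,
        chip=chip,
        meta={"rng": rng, "traits": traits},
    )


def build_panel(line: LineData, config: ScenarioConfig, traits: list) -> panels.SNPPanel:
    """Per-trait panels combined across the model group's purebred traits
    (crossbred traits contribute no GWAS variants)."""
    mm = line.population.marker_map
    mode = config.panel_mode
    if mode == "chip":
        return line.chip
    per_trait = []
    for t in traits:
        if t not in line.gwas_results:
            continue
        g = line.gwas_results[t]
        if mode == "top40k":
            per_trait.append(panels.select_top40k(g, mm, config.window_bp))
        elif mode == "chip_plus_sign":
            per_trait.append(
                panels.select_chip_plus_sign(
                    g, line.chip, mm, config.p_threshold, config.window_bp
                )
            )
        elif mode == "top_sign":
            per_trait.append(
                panels.select_top_sign(g, mm, config.p_threshold, config.window_bp)
            )
        else:
            raise ValueError(f"unknown panel mode {mode!r}")
    return panels.combine_panels(per_trait, mode, mm)


def panel_qc_animals(line: LineData, panel: panels.SNPPanel) -> tuple[np.ndarray, np.ndarray]:
    """Per-panel QC: genotype-frequency deviation rule plus Mendelian
    conflicts.  Returns (retained marker ids, retained animal ids)."""
    geno = line.seq_genotypes.subset(marker_ids=panel.marker_ids)
    th = qc.QCThresholds(min_call_rate=0.0, min_maf=0.0)
    mrep = qc.filter_markers(geno, th)
    geno = geno.subset(marker_ids=mrep.retained_markers)
    men = qc.mendelian_checks(line.population.pedigree, geno, th)
    return mrep.retained_markers, men.retained_animals


def _g_inverse(line, config, G_blend, G_chip_common, rng):
    n_g = G_blend.n
    use_apy = config.apy == "on" or (config.apy == "auto" and n_g > config.apy_threshold)
    core_size = None
    if use_apy:
        if line.core_ids is None:
            line.core_ids = relmat.choose_core(G_chip_common, rng)
        core = line.core_ids[np.isin(line.core_ids, G_blend.animal_ids)]
        core_size = len(core)
        g_inv = relmat.apy_inverse(G_blend, core)
    else:
        g_inv = relmat.direct_inverse(G_blend)
    return g_inv, core_size


def run_scenario(
    config: ScenarioConfig,
    sim_config: SimulationConfig | None = None,
    line: LineData | None = None,
    genotyped_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Execute one panel scenario end to end; returns the validation report.

    ``line`` (from :func:`prepare_line`) lets several scenarios share one
    simulation; ``genotyped_ids`` fixes the harmonized animal set.
    """
    if line is None:
        if sim_config is None:
            raise ValueError("need sim_config or a prepared line")
        line = prepare_line(sim_config, seed=config.seed)
    sim_config = line.population.config
    traits = config.traits_for(sim_config)
    rng = line.meta["rng"]

    panel = build_panel(line, config, traits)
    if panel.n == 0:
        raise RuntimeError("empty panel: scenario skipped")
    markers, animals = panel_qc_animals(line, panel)
    if genotyped_ids is not None:
        animals = animals[np.isin(animals, genotyped_ids)]

    pop = line.population
    ped = pop.pedigree
    geno = line.seq_genotypes.subset(animal_ids=animals, marker_ids=markers)

    weights = None
    weight_meta = {}
    if config.weighted:
        weights = _bayesr_weights(line, config, geno, traits)
        weight_meta["trace"] = float(np.sum(weights))

    G = relmat.build_G(geno, weights=weights)
    A22 = relmat.build_A22(ped, animals, line.ped_factor)
    G_blend = relmat.tune_and_blend(G, A22, config.blend_weight)

    chip_common = line.seq_genotypes.subset(
        animal_ids=animals,
        marker_ids=line.chip.marker_ids[
            np.isin(line.chip.marker_ids, np.asarray(line.seq_genotypes.marker_ids))
        ],
    )
    G_chip_common = relmat.build_G(chip_common)
    g_inv, core_size = _g_inverse(line, config, G_blend, G_chip_common, rng)
    h_inv = relmat.build_H_inverse(ped, line.ped_factor, g_inv, A22, animals)

    phen = pop.phenotypes
    spec = mme.ModelSpec(
        traits=traits,
        sigma0=phen.sigma0,
        l0=phen.l0,
        r0=phen.r0,
        litter_included=any(
            phen.l0.loc[t, t] > 0 for t in traits
        ),
    )
    # prediction run: test-litter phenotypes are withheld
    recs = phen.records[~phen.records["animal"].isin(line.split.test_ids)]
    result = mme.assemble_and_solve(recs, spec, ped, h_inv, tol=config.solver_tol)

    rows = []
    scen_name = config.panel_mode + ("_weighted" if config.weighted else "")
    for t in traits:
        if t not in line.debv:
            continue
        dtab = line.debv[t]
        test = line.split.test_ids[np.isin(line.split.test_ids, dtab.index)]
        test = test[np.isin(test, animals)]
        if len(test) < 3:
            continue
        gebv_t = result.extract_gebv(test, t)
        debv_t = dtab.loc[test, "debv"].to_numpy()
        rows.append(
            validation.evaluate(
                gebv_t,
                debv_t,
                n_boot=config.n_boot,
                seed=config.seed + 17,
                scenario=scen_name,
                trait=t,
            )
        )
    report = validation.report_frame(rows)
    report.attrs.update(
        panel_size=panel.n,
        n_genotyped=len(animals),
        core_size=core_size,
        solver_iterations=result.iterations,
        **weight_meta,
    )
    return report


def _bayesr_weights(line, config, geno, traits):
    """Posterior SNP variances from BayesR on the genotyped training
    animals' dEBV, averaged over the group's purebred traits, rescaled to
    trace(D) = nSNP."""
    cfg = config.bayesr_config or bayesr.BayesRConfig(seed=config.seed)
    train = line.split.train_ids
    post = np.zeros(geno.n_markers)
    n_used = 0
    for t in traits:
        if t not in line.debv:
            continue
        dtab = line.debv[t]
        ids = train[np.isin(train, dtab.index)]
        ids = ids[np.isin(ids, geno.animal_ids)]
        if len(ids) < 50:
            continue
        sub = geno.subset(animal_ids=ids)
        w = bayesr.run_bayesr(dtab.loc[ids, "debv"].to_numpy(), sub, cfg)
        post += w.table["posterior_variance"].to_numpy()
        n_used += 1
    if n_used == 0:
        raise RuntimeError("no trait had enough training animals for BayesR")
    return bayesr.variances_to_weights(post / n_used)


def desk_config(architecture: str = "few_qtl", seed: int = 1) -> SimulationConfig:
    """Reference desk-scale line used for scenario comparisons.

    Two chromosomes of 50 Mbp with 4000 sequence markers (one per 25 kb) and
    an 1800-marker chip — one chip marker per 55-kb window, mirroring the
    commercial-chip regime where the evenly spaced chip matches the window
    count and suffices for the segregating chromosome segments; ~1100
    animals in 4 discrete generations with 8-piglet litters.  ``few_qtl``
    puts the genetic variance on 12 loci (large-effect regime),
    ``polygenic`` spreads it over 800.
    """
    if architecture not in ("few_qtl", "polygenic"):
        raise ValueError(f"unknown architecture {architecture!r}")
    return SimulationConfig(
        n_founders=120,
        n_generations=4,
        n_matings_per_gen=30,
        litter_size=8,
        n_chromosomes=2,
        chrom_length_bp=50_000_000,
        n_seq_markers=4000,
        n_chip_markers=1800,
        n_qtl=12 if architecture == "few_qtl" else 800,
        # large variants missing from the chip drive the few-QTL gains; an
        # infinitesimal trait's causal variation is not excluded from
        # chip-tagged positions
        qtl_on_chip=(architecture == "polygenic"),
        ld_decay_rho=0.7,
        seed=seed,
    )


def run_desk_comparison(
    architecture: str,
    seed: int,
    panel_modes=("chip", "top40k"),
    n_boot: int = 200,
) -> dict:
    """Paired panel comparison on the desk-scale line: one shared simulation,
    single-trait models per trait (so Top40k stays size-matched to the chip,
    as it was designed to be), animals harmonized across panels within each
    trait.  Returns {trait: {mode: report}}."""
    cfg = desk_config(architecture, seed)
    line = prepare_line(cfg, seed=seed)
    results: dict = {}
    for t in cfg.traits:
        sets, cfgs = [], {}
        for mode in panel_modes:
            sc = ScenarioConfig(panel_mode=mode, traits=(t,), n_boot=n_boot, seed=seed)
            panel = build_panel(line, sc, [t])
            if panel.n == 0:
                continue
            _, animals = panel_qc_animals(line, panel)
            sets.append(qc.QCReport(np.array([]), animals))
            cfgs[mode] = sc
        common = qc.harmonize_animal_sets(sets)
        results[t] = {
            mode: run_scenario(sc, line=line, genotyped_ids=common)
            for mode, sc in cfgs.items()
        }
    return results


def run_panel_comparison(
    sim_config: SimulationConfig,
    panel_modes=("chip", "top40k"),
    scenario: ScenarioConfig | None = None,
    seed: int = 1,
) -> dict:
    """Run several panel scenarios on one shared simulation with a
    harmonized animal set (animals passing QC for every panel)."""
    base = scenario or ScenarioConfig(seed=seed)
    line = prepare_line(sim_config, seed=seed)
    traits = base.traits_for(sim_config)

    built = {}
    reports = {}
    animal_sets = []
    for mode in panel_modes:
        cfg = replace(base, panel_mode=mode, seed=seed)
        panel = build_panel(line, cfg, traits)
        if panel.n == 0:
            log.warning("panel %s empty; skipped", mode)
            continue
        _, animals = panel_qc_animals(line, panel)
        built[mode] = cfg
        animal_sets.append(
            qc.QCReport(retained_markers=np.array([]), retained_animals=animals)
        )
    common = qc.harmonize_animal_sets(animal_sets)

    for mode, cfg in built.items():
        reports[mode] = run_scenario(cfg, line=line, genotyped_ids=common)
    return {"reports": reports, "line": line, "genotyped_ids": common}
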