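"""Synthetic pig-breeding populations for single-step genomic prediction.

Generates closed multi-generation pedigrees with large full-sib litters,
sequence-density genotypes with tunable local LD, a chip subset, configurable
QTL architectures, and multi-trait phenotypes with litter and residual
(co)variances — everything the downstream GWAS / panel-preselection /
ssGBLUP stages need, without any external data.

The founder-haplotype LD model is a first-order Markov chain along each
chromosome (parameter ``ld_decay_rho``): enough to give windows and
neighbouring markers realistic local correlation while staying fast and
fully controllable.  Gametes recombine as a Poisson crossover process at
1 cM per Mbp with no interference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PUREBRED = "purebred"
CROSSBRED = "crossbred"

# 1 cM per Mbp, no interference: expected crossovers per bp
RECOMB_RATE_PER_BP = 1e-8


@dataclass
class SimulationConfig:
    """All knobs of the population simulator.

    Per-trait parameters are keyed by trait label.  The phenotypic variance
    of every trait is 1, so ``heritabilities[t]`` is also the additive
    genetic variance and ``litter_variance_fractions[t]`` the litter
    variance of trait ``t``.
    """

    n_founders: int = 100
    n_generations: int = 4
    n_matings_per_gen: int = 25
    litter_size: int = 8
    mating_scheme: str = "random"  # or "truncation_selection"
    selection_proportion: float = 0.5
    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000_000
    n_seq_markers: int = 2000
    n_chip_markers: int = 200
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay_rho: float = 0.7
    n_qtl: int = 50
    qtl_on_chip: bool = False
    traits: tuple[str, ...] = ("ADG", "BF")
    heritabilities: dict = field(default_factory=lambda: {"ADG": 0.35, "BF": 0.4})
    litter_variance_fractions: dict = field(
        default_factory=lambda: {"ADG": 0.1, "BF": 0.1}
    )
    genetic_correlations: np.ndarray | None = None  # traits x traits
    litter_correlations: np.ndarray | None = None
    residual_correlations: np.ndarray | None = None
    crossbred_cohort: bool = False
    crossbred_traits: tuple[str, ...] = ()
    purebred_crossbred_corr: float = 0.7
    n_crossbred_matings_per_gen: int = 0
    cg_size: int = 25
    cg_variance: float = 0.25
    covariate_effect: float = 0.0
    seed: int = 1

    def __post_init__(self):
        if self.genetic_correlations is None:
            self.genetic_correlations = np.eye(len(self.traits))
        self.genetic_correlations = np.asarray(self.genetic_correlations, float)

    def validate(self) -> None:
        for t in self.traits:
            h2 = self.heritabilities[t]
            lf = self.litter_variance_fractions.get(t, 0.0)
            if not (0 <= h2 <= 1 and 0 <= lf <= 1 and h2 + lf <= 1):
                raise ValueError(f"heritability + litter fraction > 1 for {t}")
        C = self.genetic_correlations
        if C.shape != (len(self.traits),) * 2:
            raise ValueError("genetic_correlations shape mismatch")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("genetic_correlations must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("genetic_correlations not positive semi-definite")
        if self.n_chip_markers > self.n_seq_markers:
            raise ValueError("n_chip_markers > n_seq_markers")
        if self.n_qtl > self.n_seq_markers:
            raise ValueError("n_qtl > n_seq_markers")
        if not (0 <= self.ld_decay_rho < 1):
            raise ValueError("ld_decay_rho must be in [0, 1)")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @property
    def all_traits(self) -> tuple[str, ...]:
        return tuple(self.traits) + tuple(self.crossbred_traits)


@dataclass
class Pedigree:
    """Closed pedigree with discrete generations and full-sib litters.

    Arrays are aligned; animal ids are 1-based, parents-before-offspring,
    unknown parents coded 0.  ``litter`` is 0 for founders.
    """

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    litter: np.ndarray
    cohort: np.ndarray  # str array, PUREBRED / CROSSBRED
    sex: np.ndarray  # 'M' / 'F'

    def __post_init__(self):
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.animal)

    def index_of(self, ids) -> np.ndarray:
        """Map animal ids to 0-based positions (pedigree order)."""
        lookup = pd.Series(np.arange(self.n), index=self.animal)
        idx = lookup.reindex(np.asarray(ids))
        if idx.isna().any():
            missing = np.asarray(ids)[idx.isna().to_numpy()]
            raise KeyError(f"unknown animal ids: {missing[:5]}")
        return idx.to_numpy(dtype=np.int64)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based sire/dam positions, -1 for unknown."""
        lookup = pd.Series(np.arange(self.n), index=self.animal)

        def conv(p):
            out = np.full(self.n, -1, dtype=np.int64)
            known = p > 0
            out[known] = lookup.loc[p[known]].to_numpy()
            return out

        return conv(self.sire), conv(self.dam)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal,
                "sire": self.sire,
                "dam": self.dam,
                "generation": self.generation,
                "litter": self.litter,
                "cohort": self.cohort,
                "sex": self.sex,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(
            animal=df["animal"].to_numpy(np.int64),
            sire=df["sire"].to_numpy(np.int64),
            dam=df["dam"].to_numpy(np.int64),
            generation=df["generation"].to_numpy(np.int64),
            litter=df["litter"].to_numpy(np.int64),
            cohort=df["cohort"].to_numpy(str),
            sex=df["sex"].to_numpy(str) if "sex" in df else np.array(["M"] * len(df)),
        )

    def validate(self) -> None:
        seen: set[int] = set()
        for a, s, d in zip(self.animal, self.sire, self.dam):
            if s > 0 and s not in seen:
                raise ValueError(f"sire {s} appears after offspring {a}")
            if d > 0 and d not in seen:
                raise ValueError(f"dam {d} appears after offspring {a}")
            if s > 0 and s == d:
                raise ValueError(f"animal {a}: sire == dam")
            seen.add(int(a))


@dataclass
class MarkerMap:
    """Per-marker metadata: position, chip/QTL flags, founder frequencies."""

    marker_id: np.ndarray  # str
    chromosome: np.ndarray
    position_bp: np.ndarray
    is_chip: np.ndarray
    is_qtl: np.ndarray
    founder_af: np.ndarray
    qtl_effects: pd.DataFrame | None = None  # markers x traits, nonzero only at QTL

    @property
    def n(self) -> int:
        return len(self.marker_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker": self.marker_id,
                "chrom": self.chromosome,
                "pos": self.position_bp,
                "is_chip": self.is_chip.astype(int),
                "is_qtl": self.is_qtl.astype(int),
                "founder_af": self.founder_af,
            }
        )
        return df

    def validate(self) -> None:
        for c in np.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == c]
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on chrom {c}")
        if self.qtl_effects is not None:
            off_qtl = self.qtl_effects.loc[~self.is_qtl]
            if not (off_qtl.to_numpy() == 0).all():
                raise ValueError("qtl_effects nonzero at non-QTL markers")


@dataclass
class GenotypeMatrix:
    """0/1/2 calls (float, NaN for missing) for animals x markers."""

    animal_ids: np.ndarray
    marker_ids: np.ndarray
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.float64)
        if self.calls.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise ValueError("calls shape does not match id lists")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset(self, animal_ids=None, marker_ids=None) -> "GenotypeMatrix":
        calls = self.calls
        aid = np.asarray(self.animal_ids)
        mid = np.asarray(self.marker_ids)
        if animal_ids is not None:
            rows = pd.Series(np.arange(len(aid)), index=aid).loc[
                np.asarray(animal_ids)
            ].to_numpy()
            calls = calls[rows]
            aid = aid[rows]
        if marker_ids is not None:
            cols = pd.Series(np.arange(len(mid)), index=mid).loc[
                np.asarray(marker_ids)
            ].to_numpy()
            calls = calls[:, cols]
            mid = mid[cols]
        return GenotypeMatrix(aid, mid, calls)

    def corrupt(self, missing_rate: float, seed: int = 0) -> "GenotypeMatrix":
        """Inject missingness at random (for QC tests only)."""
        rng = np.random.default_rng(seed)
        calls = self.calls.copy()
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = np.nan
        return GenotypeMatrix(self.animal_ids, self.marker_ids, calls)


@dataclass
class PhenotypeTable:
    """Long-format records plus true breeding values for oracle checks."""

    records: pd.DataFrame  # animal, trait, value, cg, covariate, litter
    tbv: pd.DataFrame  # animals x traits (all simulated traits)
    sigma0: pd.DataFrame  # additive (co)variances among traits
    l0: pd.DataFrame  # litter (co)variances
    r0: pd.DataFrame  # residual (co)variances

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.records[self.records["trait"] == trait].reset_index(drop=True)


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Breed a closed pedigree with discrete generations and full-sib litters.

    Under ``truncation_selection`` the parents of generation g+1 are the top
    ``selection_proportion`` of generation g ranked on a latent infinitesimal
    breeding value, which concentrates ancestry and drives small Ne.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    animal, sire, dam, gen, litter, cohort, sex = [], [], [], [], [], [], []
    latent: list[float] = []  # infinitesimal index used only for selection

    def add(a, s, d, g, li, co, sx, bv):
        animal.append(a)
        sire.append(s)
        dam.append(d)
        gen.append(g)
        litter.append(li)
        cohort.append(co)
        sex.append(sx)
        latent.append(bv)

    next_id = 1
    next_litter = 1
    # founder pool A (purebred line); pool B only when a crossbred cohort is on
    pool_a, pool_b = [], []
    n_b = config.n_founders // 2 if config.crossbred_cohort else 0
    for i in range(config.n_founders):
        sx = "M" if i % 2 == 0 else "F"
        in_b = i >= config.n_founders - n_b
        add(next_id, 0, 0, 0, 0, PUREBRED, sx, rng.normal())
        (pool_b if in_b else pool_a).append(next_id)
        next_id += 1

    current = list(pool_a)
    id2latent = dict(zip(animal, latent))
    id2sex = dict(zip(animal, sex))

    for g in range(1, config.n_generations + 1):
        males = [a for a in current if id2sex[a] == "M"]
        females = [a for a in current if id2sex[a] == "F"]
        if config.mating_scheme == "truncation_selection":
            k_m = max(2, int(np.ceil(len(males) * config.selection_proportion)))
            k_f = max(2, int(np.ceil(len(females) * config.selection_proportion)))
            if k_m > len(males) or k_f > len(females):
                raise ValueError("selection_proportion leaves too few parents")
            males = sorted(males, key=lambda a: -id2latent[a])[:k_m]
            females = sorted(females, key=lambda a: -id2latent[a])[:k_f]
        if len(males) < 2 or len(females) < 2:
            raise ValueError("fewer than 2 sires or 2 dams available")

        new = []
        for _ in range(config.n_matings_per_gen):
            s = males[rng.integers(len(males))]
            d = females[rng.integers(len(females))]
            li = next_litter
            next_litter += 1
            for _ in range(config.litter_size):
                sx = "M" if rng.random() < 0.5 else "F"
                bv = 0.5 * (id2latent[s] + id2latent[d]) + rng.normal() * np.sqrt(0.5)
                add(next_id, s, d, g, li, PUREBRED, sx, bv)
                id2latent[next_id] = bv
                id2sex[next_id] = sx
                new.append(next_id)
                next_id += 1

        # crossbred litters: line-A sires x pool-B dams, recorded but never sequenced
        if config.crossbred_cohort and config.n_crossbred_matings_per_gen > 0:
            b_females = [a for a in pool_b if id2sex[a] == "F"]
            for _ in range(config.n_crossbred_matings_per_gen):
                s = males[rng.integers(len(males))]
                d = b_females[rng.integers(len(b_females))]
                li = next_litter
                next_litter += 1
                for _ in range(config.litter_size):
                    sx = "M" if rng.random() < 0.5 else "F"
                    bv = 0.5 * (id2latent[s] + id2latent[d]) + rng.normal() * np.sqrt(0.5)
                    add(next_id, s, d, g, li, CROSSBRED, sx, bv)
                    id2latent[next_id] = bv
                    id2sex[next_id] = sx
                    next_id += 1
        current = new

    ped = Pedigree(
        animal=np.array(animal),
        sire=np.array(sire),
        dam=np.array(dam),
        generation=np.array(gen),
        litter=np.array(litter),
        cohort=np.array(cohort),
        sex=np.array(sex),
    )
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# marker map and QTL


def build_marker_map(config: SimulationConfig, rng: np.random.Generator | None = None) -> MarkerMap:
    """Evenly spaced sequence markers; chip subset = every k-th marker."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    per_chrom = np.full(config.n_chromosomes, config.n_seq_markers // config.n_chromosomes)
    per_chrom[: config.n_seq_markers % config.n_chromosomes] += 1

    chrom, pos = [], []
    for c, m in enumerate(per_chrom, start=1):
        spacing = config.chrom_length_bp // (m + 1)
        chrom.extend([c] * m)
        pos.extend(spacing * (np.arange(m) + 1))
    chrom = np.array(chrom)
    pos = np.array(pos, dtype=np.int64)
    n = len(chrom)

    k = max(1, n // config.n_chip_markers)
    chip_idx = np.arange(0, n, k)[: config.n_chip_markers]
    is_chip = np.zeros(n, bool)
    is_chip[chip_idx] = True
    # top up if rounding left the chip short
    short = config.n_chip_markers - is_chip.sum()
    if short > 0:
        extra = rng.choice(np.flatnonzero(~is_chip), size=short, replace=False)
        is_chip[extra] = True

    lo, hi = config.founder_maf_range
    af = rng.uniform(lo, hi, size=n)

    m = MarkerMap(
        marker_id=np.array([f"M{c}_{p}" for c, p in zip(chrom, pos)]),
        chromosome=chrom,
        position_bp=pos,
        is_chip=is_chip,
        is_qtl=np.zeros(n, bool),
        founder_af=af,
    )
    m.validate()
    return m


def assign_qtl_effects(
    marker_map: MarkerMap, config: SimulationConfig, rng: np.random.Generator | None = None
) -> MarkerMap:
    """Flag ``n_qtl`` markers and draw correlated per-trait effects.

    Effects are multivariate normal across traits with correlation
    ``genetic_correlations``, then rescaled per trait so the founder additive
    variance 2*sum_j p_j(1-p_j) a_j^2 equals the target genetic variance
    (= heritability, since phenotypic variance is 1).  Crossbred-recorded
    traits reuse the purebred QTL with effects correlated at
    ``purebred_crossbred_corr``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    n = marker_map.n
    traits = list(config.all_traits)
    effects = pd.DataFrame(0.0, index=np.arange(n), columns=traits)
    is_qtl = np.zeros(n, bool)

    if config.n_qtl > 0:
        candidates = np.arange(n) if config.qtl_on_chip else np.flatnonzero(~marker_map.is_chip)
        qtl_idx = np.sort(rng.choice(candidates, size=config.n_qtl, replace=False))
        is_qtl[qtl_idx] = True

        C = config.genetic_correlations
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
        raw = rng.standard_normal((config.n_qtl, len(config.traits))) @ L.T
        p = marker_map.founder_af[qtl_idx]
        het = 2 * p * (1 - p)
        for j, t in enumerate(config.traits):
            a = raw[:, j]
            v = np.sum(het * a**2)
            target = config.heritabilities[t]
            a = a * np.sqrt(target / v) if v > 0 and target > 0 else a * 0.0
            effects.loc[qtl_idx, t] = a
        rho = config.purebred_crossbred_corr
        for tx in config.crossbred_traits:
            base = tx[:-1] if tx.endswith("X") else config.traits[0]
            a_p = effects.loc[qtl_idx, base].to_numpy()
            noise = rng.standard_normal(config.n_qtl)
            a_x = rho * a_p + np.sqrt(max(0.0, 1 - rho**2)) * noise * np.std(a_p)
            target = config.heritabilities.get(tx, config.heritabilities[base])
            v = np.sum(het * a_x**2)
            if v > 0 and target > 0:
                a_x = a_x * np.sqrt(target / v)
            effects.loc[qtl_idx, tx] = a_x

    return MarkerMap(
        marker_id=marker_map.marker_id,
        chromosome=marker_map.chromosome,
        position_bp=marker_map.position_bp,
        is_chip=marker_map.is_chip,
        is_qtl=is_qtl,
        founder_af=marker_map.founder_af,
        qtl_effects=effects,
    )


# ---------------------------------------------------------------------------
# gene drop


def _founder_haplotypes(
    n_haps: int, marker_map: MarkerMap, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """``n_haps`` haplotypes at once: Markov chain over alleles along each
    chromosome, vectorized across haplotypes (loop is over markers only)."""
    m = marker_map.n
    haps = np.empty((n_haps, m), dtype=np.uint8)
    p = marker_map.founder_af
    u = rng.random((n_haps, m))
    for c in np.unique(marker_map.chromosome):
        idx = np.flatnonzero(marker_map.chromosome == c)
        first = idx[0]
        haps[:, first] = u[:, first] < p[first]
        for k in range(1, len(idx)):
            i, prev = idx[k], idx[k - 1]
            pi, pp = p[i], p[prev]
            # conditional keeping marginal ~ pi with lag-1 correlation rho
            sd = np.sqrt(pi * (1 - pi) * pp * (1 - pp))
            cond = pi + rho * sd / (pp * (1 - pp)) * (haps[:, prev] - pp)
            haps[:, i] = u[:, i] < np.clip(cond, 0.0, 1.0)
    return haps


def _gamete(haps: np.ndarray, marker_map: MarkerMap, rng: np.random.Generator) -> np.ndarray:
    """Recombine a parent's two haplotypes: Poisson crossovers, 1 cM/Mbp."""
    out = np.empty(marker_map.n, dtype=np.uint8)
    for c in np.unique(marker_map.chromosome):
        sel = marker_map.chromosome == c
        pos = marker_map.position_bp[sel]
        length = pos[-1] + 1
        n_x = rng.poisson(length * RECOMB_RATE_PER_BP)
        cuts = np.sort(rng.integers(0, length, size=n_x))
        phase = rng.integers(2)
        parity = (np.searchsorted(cuts, pos, side="right") + phase) % 2
        rows = np.where(parity == 0, 0, 1)
        block = haps[:, sel]
        out[sel] = np.where(rows == 0, block[0], block[1])
    return out


def drop_genotypes(
    pedigree: Pedigree,
    marker_map: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_haplotypes: bool = False,
):
    """Gene-drop genotypes through the pedigree.

    Founders get Markov-chain haplotypes (LD); descendants inherit one
    recombinant gamete from each parent.  Output has no missing values.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    sire_idx, dam_idx = pedigree.parent_indices()
    n, m = pedigree.n, marker_map.n
    haps = np.empty((n, 2, m), dtype=np.uint8)
    # founder gametes first (vectorized), inherited gametes in pedigree order
    founder_slots = [
        (i, slot)
        for i in range(n)
        for par, slot in ((sire_idx[i], 0), (dam_idx[i], 1))
        if par < 0
    ]
    fh = _founder_haplotypes(len(founder_slots), marker_map, config.ld_decay_rho, rng)
    for (i, slot), hap in zip(founder_slots, fh):
        haps[i, slot] = hap
    for i in range(n):
        for par, slot in ((sire_idx[i], 0), (dam_idx[i], 1)):
            if par >= 0:
                haps[i, slot] = _gamete(haps[par], marker_map, rng)
    calls = haps.sum(axis=1).astype(np.float64)
    gm = GenotypeMatrix(pedigree.animal.copy(), marker_map.marker_id.copy(), calls)
    if return_haplotypes:
        return gm, haps
    return gm


# ---------------------------------------------------------------------------
# phenotypes


def _corr_to_cov(corr: np.ndarray | None, sds: np.ndarray, mask: np.ndarray) -> np.ndarray:
    k = len(sds)
    C = np.eye(k) if corr is None else np.asarray(corr, float)
    cov = C * np.outer(sds, sds)
    cov[~mask] = 0.0
    return cov


def true_variance_components(config: SimulationConfig):
    """(Sigma0, L0, R0) implied by the config, with purebred x crossbred
    litter/residual covariances structurally zero."""
    traits = list(config.all_traits)
    k = len(traits)
    is_x = np.array([t in config.crossbred_traits for t in traits])
    block_mask = np.equal.outer(is_x, is_x)  # True within purebred or crossbred block

    h2 = np.array([config.heritabilities[t] for t in traits])
    lf = np.array([config.litter_variance_fractions.get(t, 0.0) for t in traits])
    ve = 1.0 - h2 - lf

    g_corr = np.eye(k)
    npure = len(config.traits)
    g_corr[:npure, :npure] = config.genetic_correlations
    if k > npure:
        for i, tx in enumerate(config.crossbred_traits):
            base = tx[:-1] if tx.endswith("X") else config.traits[0]
            j = traits.index(base)
            g_corr[npure + i, j] = g_corr[j, npure + i] = config.purebred_crossbred_corr
    sigma0 = g_corr * np.outer(np.sqrt(h2), np.sqrt(h2))
    l0 = _corr_to_cov(config.litter_correlations, np.sqrt(lf), block_mask)
    r0 = _corr_to_cov(config.residual_correlations, np.sqrt(ve), block_mask)
    idx = pd.Index(traits)
    return (
        pd.DataFrame(sigma0, index=idx, columns=idx),
        pd.DataFrame(l0, index=idx, columns=idx),
        pd.DataFrame(r0, index=idx, columns=idx),
    )


def _mvn_block(cov: np.ndarray, size: int, rng) -> np.ndarray:
    """Draw from N(0, cov) allowing structural zeros (block PSD)."""
    k = cov.shape[0]
    out = np.zeros((size, k))
    active = np.flatnonzero(np.diag(cov) > 0)
    if len(active) == 0:
        return out
    sub = cov[np.ix_(active, active)]
    w, V = np.linalg.eigh(sub)
    w = np.clip(w, 0, None)
    L = V * np.sqrt(w)
    out[:, active] = rng.standard_normal((size, len(active))) @ L.T
    return out


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Phenotype = CG mean + covariate term + TBV + litter effect + residual.

    TBV_i = sum_j g_ij a_j from the QTL effects; litter effects are shared by
    full sibs; litter and residual draws respect the structural zeros between
    purebred- and crossbred-recorded traits.
    """
    if marker_map.qtl_effects is None:
        raise ValueError("QTL effects not assigned; call assign_qtl_effects first")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    traits = list(config.all_traits)
    sigma0, l0, r0 = true_variance_components(config)

    A = marker_map.qtl_effects[traits].to_numpy()
    tbv_vals = genotypes.calls @ A
    # express TBV as deviation from the founder mean so fixed effects stay interpretable
    tbv_vals = tbv_vals - tbv_vals[pedigree.generation == 0].mean(axis=0)
    tbv = pd.DataFrame(
        tbv_vals, index=pd.Index(genotypes.animal_ids, name="animal"), columns=traits
    )

    is_x_animal = pedigree.cohort == CROSSBRED
    is_x_trait = {t: t in config.crossbred_traits for t in traits}

    # contemporary groups: within generation, chunks of cg_size
    order = np.arange(pedigree.n)
    cg = np.empty(pedigree.n, dtype=np.int64)
    next_cg = 0
    for g in np.unique(pedigree.generation):
        idx = order[pedigree.generation == g]
        for start in range(0, len(idx), config.cg_size):
            cg[idx[start : start + config.cg_size]] = next_cg
            next_cg += 1
    cg_effects = rng.normal(0, np.sqrt(config.cg_variance), size=next_cg)

    litters = np.unique(pedigree.litter)
    lit_lookup = pd.Series(np.arange(len(litters)), index=litters)
    lit_effects = _mvn_block(l0.to_numpy(), len(litters), rng)
    resid = _mvn_block(r0.to_numpy(), pedigree.n, rng)
    covariate = rng.standard_normal(pedigree.n)

    rows = []
    for ti, t in enumerate(traits):
        want_x = is_x_trait[t]
        for i in range(pedigree.n):
            if bool(is_x_animal[i]) != want_x:
                continue
            li = lit_lookup[pedigree.litter[i]]
            lit_term = lit_effects[li, ti] if pedigree.litter[i] > 0 else 0.0
            value = (
                cg_effects[cg[i]]
                + config.covariate_effect * covariate[i]
                + tbv_vals[i, ti]
                + lit_term
                + resid[i, ti]
            )
            rows.append(
                (
                    pedigree.animal[i],
                    t,
                    value,
                    int(cg[i]),
                    covariate[i],
                    int(pedigree.litter[i]),
                )
            )
    records = pd.DataFrame(
        rows, columns=["animal", "trait", "value", "cg", "covariate", "litter"]
    )
    return PhenotypeTable(records=records, tbv=tbv, sigma0=sigma0, l0=l0, r0=r0)


@dataclass
class Population:
    """One simulated line: everything downstream stages consume."""

    config: SimulationConfig
    pedigree: Pedigree
    marker_map: MarkerMap
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable

    @property
    def sequenced_ids(self) -> np.ndarray:
        """Animals with sequence genotypes: purebreds only (crossbreds are
        phenotyped but never sequenced)."""
        return self.pedigree.animal[self.pedigree.cohort == PUREBRED]


def simulate_population(config: SimulationConfig) -> Population:
    """Run the full generative chain with one master seed."""
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=4)
    ped = simulate_pedigree(config, np.random.default_rng(seeds[0]))
    mm = build_marker_map(config, np.random.default_rng(seeds[1]))
    mm = assign_qtl_effects(mm, config, np.random.default_rng(seeds[1] + 1))
    geno = drop_genotypes(ped, mm, config, np.random.default_rng(seeds[2]))
    phen = simulate_phenotypes(ped, geno, mm, config, np.random.default_rng(seeds[3]))
    return Population(config, ped, mm, geno, phen)
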