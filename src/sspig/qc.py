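"""Genotype quality control and animal-set harmonization.

Marker filters (evaluated on the input matrix, not sequentially):
monomorphic, call rate < 0.90, MAF < 0.01, and a deviation between observed
and Hardy-Weinberg expected genotype-class frequencies > 0.15 (max over the
three classes).  Individuals with > 10% missing calls are removed.  An extra
MAF >= 0.023 rule is available for imputed-sequence panels.  Parent-progeny
Mendelian conflicts (opposing homozygotes) flag individuals for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix, Pedigree

RULE_ORDER = ("monomorphic", "call_rate", "maf", "genofreq_dev", "maf_imputed")


@dataclass
class QCThresholds:
    min_call_rate: float = 0.90
    min_maf: float = 0.01
    max_genofreq_dev: float = 0.15
    max_ind_missing: float = 0.10
    min_maf_imputed: float = 0.023
    drop_monomorphic: bool = True
    max_mendelian_rate: float = 0.01

    def validate(self):
        for name in (
            "min_call_rate",
            "min_maf",
            "max_genofreq_dev",
            "max_ind_missing",
            "min_maf_imputed",
            "max_mendelian_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]")


@dataclass
class QCReport:
    retained_markers: np.ndarray
    retained_animals: np.ndarray
    exclusion_counts: dict = field(default_factory=dict)
    mendelian_conflicts: pd.DataFrame | None = None  # parent, offspring, n_conflicts, n_informative
    flagged_animals: np.ndarray | None = None


def _marker_stats(calls: np.ndarray):
    with np.errstate(invalid="ignore"):
        n_obs = np.sum(~np.isnan(calls), axis=0).astype(float)
        n0 = np.nansum(calls == 0, axis=0).astype(float)
        n1 = np.nansum(calls == 1, axis=0).astype(float)
        n2 = np.nansum(calls == 2, axis=0).astype(float)
        p = np.where(n_obs > 0, (2 * n2 + n1) / (2 * np.maximum(n_obs, 1)), np.nan)
    return n_obs, n0, n1, n2, p


def filter_markers(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    imputed_panel: bool = False,
) -> QCReport:
    """Apply marker-level rules; attribution follows the first triggering rule
    in the order monomorphic -> call rate -> MAF -> genotype-frequency
    deviation (-> imputed-MAF when ``imputed_panel``)."""
    th = thresholds or QCThresholds()
    th.validate()
    calls = genotypes.calls
    if calls.size == 0:
        raise ValueError("empty genotype matrix")
    n_animals = calls.shape[0]
    n_obs, n0, n1, n2, p = _marker_stats(calls)
    maf = np.minimum(p, 1 - p)

    call_rate = n_obs / n_animals
    mono = (n_obs > 0) & (maf == 0)  # only one allele observed
    low_cr = call_rate < th.min_call_rate
    low_maf = maf < th.min_maf
    # HWE expected genotype-class frequencies at the observed allele frequency
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.stack([n0, n1, n2]) / np.maximum(n_obs, 1)
        q = 1 - p
        exp = np.stack([q**2, 2 * p * q, p**2])
        dev = np.nanmax(np.abs(obs - exp), axis=0)
    high_dev = dev > th.max_genofreq_dev
    low_maf_imp = maf < th.min_maf_imputed if imputed_panel else np.zeros_like(mono)

    rules = {
        "monomorphic": mono if th.drop_monomorphic else np.zeros_like(mono),
        "call_rate": low_cr,
        "maf": low_maf,
        "genofreq_dev": high_dev,
        "maf_imputed": low_maf_imp,
    }
    excluded = np.zeros(calls.shape[1], bool)
    counts = {}
    for rule in RULE_ORDER:
        hit = rules[rule] & ~excluded
        counts[rule] = int(hit.sum())
        excluded |= rules[rule]
    keep = ~excluded
    return QCReport(
        retained_markers=np.asarray(genotypes.marker_ids)[keep],
        retained_animals=np.asarray(genotypes.animal_ids),
        exclusion_counts=counts,
    )


def filter_individuals(
    genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> QCReport:
    """Exclude animals with more than ``max_ind_missing`` missing calls
    (strict inequality: exactly at the threshold is retained)."""
    th = thresholds or QCThresholds()
    th.validate()
    miss = np.isnan(genotypes.calls).mean(axis=1)
    keep = miss <= th.max_ind_missing
    return QCReport(
        retained_markers=np.asarray(genotypes.marker_ids),
        retained_animals=np.asarray(genotypes.animal_ids)[keep],
        exclusion_counts={"ind_missing": int((~keep).sum())},
    )


def mendelian_checks(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Count opposing-homozygote conflicts for each genotyped parent-offspring
    pair; flag offspring whose conflict rate with a genotyped parent exceeds
    ``max_mendelian_rate``."""
    th = thresholds or QCThresholds()
    aid = np.asarray(genotypes.animal_ids)
    pos = pd.Series(np.arange(len(aid)), index=aid)
    calls = genotypes.calls

    rows = []
    flagged = set()
    for a, s, d in zip(pedigree.animal, pedigree.sire, pedigree.dam):
        if a not in pos.index:
            continue
        for parent in (s, d):
            if parent <= 0 or parent not in pos.index:
                continue
            go = calls[pos[a]]
            gp = calls[pos[parent]]
            ok = ~np.isnan(go) & ~np.isnan(gp)
            conflict = ok & (((gp == 0) & (go == 2)) | ((gp == 2) & (go == 0)))
            n_inf = int(ok.sum())
            n_con = int(conflict.sum())
            rows.append((parent, a, n_con, n_inf))
            if n_inf > 0 and n_con / n_inf > th.max_mendelian_rate:
                flagged.add(int(a))
    table = pd.DataFrame(
        rows, columns=["parent", "offspring", "n_conflicts", "n_informative"]
    )
    keep = np.array([a not in flagged for a in aid])
    return QCReport(
        retained_markers=np.asarray(genotypes.marker_ids),
        retained_animals=aid[keep],
        exclusion_counts={"mendelian": len(flagged)},
        mendelian_conflicts=table,
        flagged_animals=np.array(sorted(flagged), dtype=np.int64),
    )


def harmonize_animal_sets(reports: list[QCReport]) -> np.ndarray:
    """Intersection of retained animals across panels so every scenario is
    evaluated on the same animal set (fair comparison)."""
    if not reports:
        raise ValueError("need at least one report")
    common = set(np.asarray(reports[0].retained_animals).tolist())
    for r in reports[1:]:
        common &= set(np.asarray(r.retained_animals).tolist())
    if not common:
        raise ValueError("empty intersection of retained animals")
    # preserve the first report's ordering
    first = np.asarray(reports[0].retained_animals)
    return first[np.isin(first, list(common))]


def apply_marker_qc(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    imputed_panel: bool = False,
) -> tuple[GenotypeMatrix, QCReport, QCReport]:
    """Convenience: marker filter then individual filter; returns the pruned
    matrix plus both reports."""
    mrep = filter_markers(genotypes, thresholds, imputed_panel=imputed_panel)
    pruned = genotypes.subset(marker_ids=mrep.retained_markers)
    irep = filter_individuals(pruned, thresholds)
    pruned = pruned.subset(animal_ids=irep.retained_animals)
    return pruned, mrep, irep
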