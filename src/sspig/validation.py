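"""Validation protocol: litter-based splits, EBV deregression, accuracy,
dispersion slope and bootstrap standard errors.

Test sets are whole litters from the last pedigree generation with at least
five full sibs; training candidates related to any test animal at an
additive relationship >= 0.5 are excluded, so gains cannot come from close
relatives alone.  Accuracy is the correlation of GEBV with deregressed EBV
(dEBV, VanRaden-style: parent average removed and the Mendelian-sampling
part unshrunk); dispersion is the slope b1 of the regression of dEBV on
GEBV (< 1 means inflated GEBV); standard errors come from bootstrapping
test animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import mme
from .relmat import HInverseFactor, PedigreeFactor, build_A_inverse
from .simdata import Pedigree


@dataclass
class SplitDefinition:
    test_ids: np.ndarray
    train_ids: np.ndarray
    excluded_for_relatedness: np.ndarray
    relationship_threshold: float = 0.5
    min_full_sibs: int = 5


@dataclass
class ValidationRow:
    scenario: str
    trait: str
    accuracy: float
    b1: float
    accuracy_se: float
    b1_se: float
    n_test: int
    flags: dict = field(default_factory=dict)


def _cross_relationships(
    pedigree: Pedigree, factor: PedigreeFactor, rows_ids, cols_ids
) -> np.ndarray:
    """A[rows, cols] via sparse solves of A^-1 (full ancestral paths)."""
    col_idx = pedigree.index_of(cols_ids)
    row_idx = pedigree.index_of(rows_ids)
    lu = spla.splu(sp.csc_matrix(factor.a_inverse))
    E = np.zeros((pedigree.n, len(col_idx)))
    E[col_idx, np.arange(len(col_idx))] = 1.0
    cols = lu.solve(E)
    return cols[row_idx, :]


def split_train_test(
    pedigree: Pedigree,
    sequenced_ids,
    factor: PedigreeFactor | None = None,
    relationship_threshold: float = 0.5,
    min_full_sibs: int = 5,
) -> SplitDefinition:
    """Whole last-generation litters (>= ``min_full_sibs`` full sibs) form
    the test set; remaining sequenced animals minus close relatives
    (relationship >= threshold to any test animal) form the training set.
    The same training set serves GWAS and prediction."""
    sequenced_ids = np.asarray(sequenced_ids)
    last = pedigree.generation.max()
    if last < 1:
        raise ValueError("pedigree needs at least 2 generations")
    in_last = pedigree.generation == last
    lit_sizes = pd.Series(pedigree.litter[in_last]).value_counts()
    qualifying = set(lit_sizes[lit_sizes >= min_full_sibs].index) - {0}
    test_mask = in_last & np.isin(pedigree.litter, list(qualifying))
    test_ids = pedigree.animal[test_mask]
    test_ids = test_ids[np.isin(test_ids, sequenced_ids)]
    if len(test_ids) == 0:
        raise ValueError("no qualifying last-generation litter")

    candidates = sequenced_ids[~np.isin(sequenced_ids, test_ids)]
    factor = factor or build_A_inverse(pedigree)
    rel = _cross_relationships(pedigree, factor, candidates, test_ids)
    too_close = (rel >= relationship_threshold).any(axis=1)
    return SplitDefinition(
        test_ids=test_ids,
        train_ids=candidates[~too_close],
        excluded_for_relatedness=candidates[too_close],
        relationship_threshold=relationship_threshold,
        min_full_sibs=min_full_sibs,
    )


# ---------------------------------------------------------------------------
# deregression


@dataclass
class DeregressedEBV:
    table: pd.DataFrame  # animal, debv, weight, reliability, r_star
    dropped: np.ndarray


def pedigree_blup(
    records: pd.DataFrame,
    trait: str,
    pedigree: Pedigree,
    factor: PedigreeFactor,
    sigma0: pd.DataFrame,
    l0: pd.DataFrame | None,
    r0: pd.DataFrame,
    covariate: bool = False,
) -> tuple[pd.Series, pd.Series]:
    """Single-trait pedigree-only evaluation (H = A) with reliabilities from
    prediction error variances via a direct dense solve."""
    spec = mme.ModelSpec(
        traits=[trait],
        sigma0=sigma0,
        l0=l0,
        r0=r0,
        covariate_traits=(trait,) if covariate else (),
        litter_included=l0 is not None,
    )
    h_inv = HInverseFactor(factor, None, None, np.array([], dtype=np.int64))
    res = mme.solve_dense(records, spec, pedigree, h_inv)
    ebv = res.gebv[trait]
    sigma2_a = float(sigma0.loc[trait, trait])
    pev = res.meta["pev"][:, 0]
    rel = 1.0 - pev / ((1.0 + factor.inbreeding) * sigma2_a)
    rel = np.clip(rel, 0.0, 1.0 - 1e-9)
    return ebv, pd.Series(rel, index=ebv.index)


def deregress_ebv(
    ebv: pd.Series,
    reliability: pd.Series,
    pedigree: Pedigree,
    min_r_star: float = 1e-3,
) -> DeregressedEBV:
    """VanRaden-style deregression.

    PA = mean of parent EBV (0 for unknown parents); the reliability of the
    Mendelian-sampling deviation is R* = (r2 - r2_PA) / (1 - r2_PA) with
    r2_PA = (r2_sire + r2_dam) / 4, and dEBV = PA + (EBV - PA)/R*.  Animals
    whose R* is undefined or not above ``min_r_star`` are dropped with a
    warning (no own/progeny information to unshrink).
    """
    idx = pd.Series(np.arange(pedigree.n), index=pedigree.animal)
    ebv = ebv.reindex(pedigree.animal)
    rel = reliability.reindex(pedigree.animal)

    def parent_vals(parr, series, default):
        out = np.full(pedigree.n, default, dtype=float)
        known = parr > 0
        out[known] = series.to_numpy()[idx[parr[known]].to_numpy()]
        return out

    ebv_s = parent_vals(pedigree.sire, ebv, 0.0)
    ebv_d = parent_vals(pedigree.dam, ebv, 0.0)
    r2_s = parent_vals(pedigree.sire, rel, 0.0)
    r2_d = parent_vals(pedigree.dam, rel, 0.0)
    pa = 0.5 * (ebv_s + ebv_d)
    r2_pa = 0.25 * (r2_s + r2_d)

    r2 = rel.to_numpy()
    r_star = (r2 - r2_pa) / (1.0 - r2_pa)
    ok = r_star > min_r_star
    if (~ok).any():
        warnings.warn(
            f"dropping {int((~ok).sum())} animals with reliability <= parent-average "
            "reliability (dEBV undefined)"
        )
    debv = np.where(ok, pa + (ebv.to_numpy() - pa) / np.where(ok, r_star, 1.0), np.nan)
    weight = np.where(ok, r_star / (1.0 - np.minimum(r_star, 1 - 1e-9)), 0.0)
    table = pd.DataFrame(
        {
            "animal": pedigree.animal,
            "debv": debv,
            "weight": weight,
            "reliability": r2,
            "r_star": r_star,
        }
    )[ok]
    return DeregressedEBV(table=table.reset_index(drop=True), dropped=pedigree.animal[~ok])


# ---------------------------------------------------------------------------
# accuracy / dispersion


def evaluate(
    gebv: np.ndarray,
    debv: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    scenario: str = "",
    trait: str = "",
) -> ValidationRow:
    """Accuracy = cor(GEBV, dEBV); b1 = slope of dEBV regressed on GEBV;
    SEs = SD of each statistic over ``n_boot`` resamples of test animals."""
    gebv = np.asarray(gebv, float)
    debv = np.asarray(debv, float)
    if len(gebv) != len(debv) or len(gebv) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(gebv) == 0 or np.std(debv) == 0:
        raise ValueError("zero variance in GEBV or dEBV")

    def stats(g, d):
        acc = float(np.corrcoef(g, d)[0, 1])
        b1 = float(np.cov(d, g, ddof=1)[0, 1] / np.var(g, ddof=1))
        return acc, b1

    acc, b1 = stats(gebv, debv)
    rng = np.random.default_rng(seed)
    n = len(gebv)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        g, d = gebv[take], debv[take]
        if np.std(g) == 0 or np.std(d) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats(g, d)
    se = np.nanstd(boots, axis=0, ddof=1)
    return ValidationRow(
        scenario=scenario,
        trait=trait,
        accuracy=acc,
        b1=b1,
        accuracy_se=float(se[0]),
        b1_se=float(se[1]),
        n_test=n,
        flags={"inflated": b1 < 1, "deflated": b1 > 1},
    )


def percent_change(acc_panel: float, acc_chip: float) -> float:
    """Accuracy change vs the chip scenario, in percent."""
    return 100.0 * (acc_panel - acc_chip) / acc_chip


def report_frame(rows: list[ValidationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "trait": r.trait,
                "accuracy": r.accuracy,
                "accuracy_se": r.accuracy_se,
                "b1": r.b1,
                "b1_se": r.b1_se,
                "n_test": r.n_test,
            }
            for r in rows
        ]
    )
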