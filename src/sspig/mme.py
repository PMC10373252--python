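"""Henderson mixed-model equations for (W)ssGBLUP.

Model per trait group:  y = Xb + Wc + Zu + e  with contemporary group (and
optional covariate) fixed effects, a diagonal-across-litters random litter
effect c ~ N(0, I x L0), additive genetic effects u ~ N(0, H x Sigma0) over
all pedigree animals, and residuals e ~ N(0, I x R0).  Residuals are handled
per animal: the inverse of the R0 submatrix for each animal's observed-trait
subset enters the equations, which is what lets crossbred animals record
only crossbred traits.

The additive penalty uses H^-1 x Sigma0^-1 purely as an operator (so APY
stays sparse), and the system is solved by preconditioned conjugate
gradients with a block-diagonal (trait-block) preconditioner.  A dense
assembly path is kept for prediction-error variances at small scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .relmat import HInverseFactor
from .simdata import Pedigree


@dataclass
class ModelSpec:
    """Trait list, fixed-effect layout and (co)variance components.

    ``sigma0``, ``l0``, ``r0`` are trait x trait DataFrames; structural zeros
    (purebred x crossbred litter/residual covariances) are plain zeros in
    block-diagonal position, so blockwise inversion is exact.
    """

    traits: list
    sigma0: pd.DataFrame
    l0: pd.DataFrame | None = None
    r0: pd.DataFrame = None
    covariate_traits: tuple = ()
    litter_included: bool = True
    min_cg_records: int = 2

    def __post_init__(self):
        self.traits = list(self.traits)
        self.sigma0 = self.sigma0.loc[self.traits, self.traits]
        self.r0 = self.r0.loc[self.traits, self.traits]
        if self.l0 is not None:
            self.l0 = self.l0.loc[self.traits, self.traits]

    @property
    def litter_traits(self) -> list:
        if not self.litter_included or self.l0 is None:
            return []
        d = np.diag(self.l0.to_numpy())
        return [t for t, v in zip(self.traits, d) if v > 0]


@dataclass
class EvaluationResult:
    gebv: pd.DataFrame  # animals x traits
    fixed_solutions: pd.Series
    litter_solutions: pd.DataFrame | None
    iterations: int
    residual: float
    meta: dict = field(default_factory=dict)

    def extract_gebv(self, animals, trait) -> np.ndarray:
        """GEBV of ``animals`` (in the requested order) for one trait."""
        if trait not in self.gebv.columns:
            raise KeyError(f"unknown trait {trait!r}")
        sub = self.gebv[trait].reindex(np.asarray(animals))
        if sub.isna().any():
            raise KeyError("animal not evaluated")
        return sub.to_numpy()


class _Assembly:
    """Sparse incidence matrices, residual-inverse blocks and index maps."""

    def __init__(self, records: pd.DataFrame, spec: ModelSpec, pedigree: Pedigree):
        traits = spec.traits
        recs = records[records["trait"].isin(traits)].copy()
        if recs.duplicated(["animal", "trait"]).any():
            raise ValueError("duplicate (animal, trait) records")
        if recs.empty:
            raise ValueError("no records for the requested traits")
        self.trait_pos = {t: k for k, t in enumerate(traits)}
        self.T = len(traits)
        self.N = pedigree.n
        recs["t_idx"] = recs["trait"].map(self.trait_pos)
        recs["a_idx"] = pedigree.index_of(recs["animal"].to_numpy())

        # ---- fixed effects: per-trait CG dummies (+ covariate); CG levels
        # with < min_cg_records records spill into a shared level
        fix_cols = []
        col_of = {}
        self._small_levels = {}
        for t in traits:
            sub = recs[recs["trait"] == t]
            counts = sub["cg"].value_counts()
            small = set(counts[counts < spec.min_cg_records].index)
            levels = sorted(set(counts.index) - small)
            if small:
                levels = levels + ["_spill"]
            for lv in levels:
                col_of[(t, "cg", lv)] = len(fix_cols)
                fix_cols.append(f"{t}:cg:{lv}")
            if t in spec.covariate_traits:
                col_of[(t, "cov", None)] = len(fix_cols)
                fix_cols.append(f"{t}:covariate")
            self._small_levels[t] = small
        self.fix_names = fix_cols
        n_rec = len(recs)

        xr, xc, xv = [], [], []
        for k, (t, cgv, cov) in enumerate(
            zip(recs["trait"], recs["cg"], recs["covariate"])
        ):
            lv = "_spill" if cgv in self._small_levels[t] else cgv
            xr.append(k)
            xc.append(col_of[(t, "cg", lv)])
            xv.append(1.0)
            if (t, "cov", None) in col_of:
                xr.append(k)
                xc.append(col_of[(t, "cov", None)])
                xv.append(float(cov))
        self.X = sp.csr_matrix((xv, (xr, xc)), shape=(n_rec, len(fix_cols)))

        # ---- litter incidence (only traits with positive litter variance,
        # only litters actually observed; founders have litter 0 = none)
        lit_traits = spec.litter_traits
        self.lit_traits = lit_traits
        self.Tl = len(lit_traits)
        if self.Tl > 0:
            lt_pos = {t: k for k, t in enumerate(lit_traits)}
            has_lit = recs["trait"].isin(lit_traits) & (recs["litter"] > 0)
            litters = np.sort(recs.loc[has_lit, "litter"].unique())
            self.litters = litters
            lpos = {li: k for k, li in enumerate(litters)}
            wr, wc = [], []
            for k, (t, li) in enumerate(zip(recs["trait"], recs["litter"])):
                if t in lt_pos and li > 0:
                    wr.append(k)
                    wc.append(lpos[li] * self.Tl + lt_pos[t])
            self.W = sp.csr_matrix(
                (np.ones(len(wr)), (wr, wc)), shape=(n_rec, len(litters) * self.Tl)
            )
            l0 = spec.l0.loc[lit_traits, lit_traits].to_numpy()
            self.l0_inv = np.linalg.inv(l0)
        else:
            self.litters = np.array([], dtype=np.int64)
            self.W = sp.csr_matrix((n_rec, 0))
            self.l0_inv = np.zeros((0, 0))

        # ---- additive incidence: record -> (animal, trait) slot
        zr = np.arange(n_rec)
        zc = recs["a_idx"].to_numpy() * self.T + recs["t_idx"].to_numpy()
        self.Z = sp.csr_matrix(
            (np.ones(n_rec), (zr, zc)), shape=(n_rec, self.N * self.T)
        )

        # ---- residual inverse, blocked by each animal's observed pattern
        r0 = spec.r0.to_numpy()
        rows, cols, vals = [], [], []
        self._pattern_of_animal = {}
        for a_idx, grp in recs.groupby("a_idx"):
            S = tuple(sorted(grp["t_idx"]))
            E = np.linalg.inv(r0[np.ix_(S, S)])
            order = grp.sort_values("t_idx").index.to_numpy()
            recpos = recs.index.get_indexer(order)
            for ii, ri in enumerate(recpos):
                for jj, rj in enumerate(recpos):
                    rows.append(ri)
                    cols.append(rj)
                    vals.append(E[ii, jj])
            self._pattern_of_animal[a_idx] = (S, E)
        self.Rinv = sp.csr_matrix((vals, (rows, cols)), shape=(n_rec, n_rec))

        self.records = recs.reset_index(drop=True)
        self.y = recs["value"].to_numpy(float)
        self.n_fix = len(fix_cols)
        self.n_lit_eq = self.W.shape[1]
        self.n_u_eq = self.N * self.T


def _assemble(records, spec, pedigree):
    recs = records.reset_index(drop=True)
    return _Assembly(recs, spec, pedigree)


def assemble_and_solve(
    records: pd.DataFrame,
    spec: ModelSpec,
    pedigree: Pedigree,
    h_inv: HInverseFactor,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> EvaluationResult:
    """Solve the MME by PCG with a trait-block-diagonal preconditioner."""
    asm = _assemble(records, spec, pedigree)
    T, N = asm.T, asm.N
    sigma0_inv = np.linalg.inv(spec.sigma0.to_numpy())
    X, W, Z, Rinv = asm.X, asm.W, asm.Z, asm.Rinv

    n_f, n_l, n_u = asm.n_fix, asm.n_lit_eq, asm.n_u_eq
    n_eq = n_f + n_l + n_u
    sl_f, sl_l, sl_u = slice(0, n_f), slice(n_f, n_f + n_l), slice(n_f + n_l, n_eq)

    def matvec(x):
        xf, xl, xu = x[sl_f], x[sl_l], x[sl_u]
        eta = X @ xf + W @ xl + Z @ xu
        r = Rinv @ eta
        out = np.empty(n_eq)
        out[sl_f] = X.T @ r
        out[sl_l] = W.T @ r
        out[sl_u] = Z.T @ r
        if n_l:
            C = xl.reshape(-1, asm.Tl)
            out[sl_l] += (C @ asm.l0_inv).ravel()
        U = xu.reshape(N, T)
        out[sl_u] += (h_inv.matmat(U) @ sigma0_inv).ravel()
        return out

    rhs = np.empty(n_eq)
    ry = Rinv @ asm.y
    rhs[sl_f] = X.T @ ry
    rhs[sl_l] = W.T @ ry
    rhs[sl_u] = Z.T @ ry

    # ---- block-diagonal preconditioner
    fix_diag = np.asarray(
        X.multiply(Rinv @ X).sum(axis=0)
    ).ravel()
    fix_diag[fix_diag <= 0] = 1.0

    u_blocks = np.einsum("i,jk->ijk", h_inv.diagonal(), sigma0_inv)
    if n_l:
        l_blocks = np.tile(asm.l0_inv, (len(asm.litters), 1, 1))
        lpos = {li: k for k, li in enumerate(asm.litters)}
        lt_idx = {t: k for k, t in enumerate(asm.lit_traits)}
    for a_idx, (S, E) in asm._pattern_of_animal.items():
        ix = np.ix_(list(S), list(S))
        u_blocks[a_idx][ix] += E
        if n_l:
            grp = asm.records[asm.records["a_idx"] == a_idx]
            li = grp["litter"].iloc[0]
            if li > 0:
                keep = [k for k, t_i in enumerate(S) if spec.traits[t_i] in lt_idx]
                if keep:
                    lt = [lt_idx[spec.traits[S[k]]] for k in keep]
                    l_blocks[lpos[li]][np.ix_(lt, lt)] += E[np.ix_(keep, keep)]
    u_inv = np.linalg.inv(u_blocks)
    l_inv = np.linalg.inv(l_blocks) if n_l else None

    def precond(x):
        out = np.empty(n_eq)
        out[sl_f] = x[sl_f] / fix_diag
        if n_l:
            C = x[sl_l].reshape(-1, asm.Tl)
            out[sl_l] = np.einsum("nij,nj->ni", l_inv, C).ravel()
        U = x[sl_u].reshape(N, T)
        out[sl_u] = np.einsum("nij,nj->ni", u_inv, U).ravel()
        return out

    A = spla.LinearOperator((n_eq, n_eq), matvec=matvec)
    M = spla.LinearOperator((n_eq, n_eq), matvec=precond)
    iters = 0

    def cb(_):
        nonlocal iters
        iters += 1

    x, info = spla.cg(A, rhs, rtol=tol, atol=0.0, maxiter=max_iter, M=M, callback=cb)
    res = float(np.linalg.norm(matvec(x) - rhs) / np.linalg.norm(rhs))
    if info > 0:
        raise RuntimeError(
            f"PCG did not converge in {max_iter} iterations "
            f"(relative residual {res:.3e})"
        )

    gebv = pd.DataFrame(
        x[sl_u].reshape(N, T), index=pd.Index(pedigree.animal, name="animal"),
        columns=spec.traits,
    )
    fixed = pd.Series(x[sl_f], index=asm.fix_names)
    litter = (
        pd.DataFrame(
            x[sl_l].reshape(-1, asm.Tl), index=asm.litters, columns=asm.lit_traits
        )
        if n_l
        else None
    )
    return EvaluationResult(gebv, fixed, litter, iters, res)


def assemble_dense(
    records: pd.DataFrame,
    spec: ModelSpec,
    pedigree: Pedigree,
    h_inv: HInverseFactor,
):
    """Dense MME (C, rhs, u-slice); for PEV/reliability at small scale and as
    a direct-solve path."""
    asm = _assemble(records, spec, pedigree)
    T, N = asm.T, asm.N
    sigma0_inv = np.linalg.inv(spec.sigma0.to_numpy())
    Xd = sp.hstack([asm.X, asm.W, asm.Z]).tocsr()
    C = (Xd.T @ asm.Rinv @ Xd).toarray()
    n_f, n_l = asm.n_fix, asm.n_lit_eq
    n_eq = C.shape[0]
    if n_l:
        C[n_f : n_f + n_l, n_f : n_f + n_l] += np.kron(
            np.eye(len(asm.litters)), asm.l0_inv
        )
    Hd = h_inv.to_dense()
    C[n_f + n_l :, n_f + n_l :] += np.kron(Hd, sigma0_inv)
    rhs = Xd.T @ (asm.Rinv @ asm.y)
    return C, np.asarray(rhs).ravel(), slice(n_f + n_l, n_eq), asm


def solve_dense(records, spec, pedigree, h_inv):
    """Direct dense solve; returns the result plus prediction error variances
    of the additive effects (animals x traits)."""
    C, rhs, sl_u, asm = assemble_dense(records, spec, pedigree, h_inv)
    Cinv = np.linalg.inv(C)
    x = Cinv @ rhs
    T, N = asm.T, asm.N
    pev = np.diag(Cinv)[sl_u].reshape(N, T)
    gebv = pd.DataFrame(
        x[sl_u].reshape(N, T), index=pd.Index(pedigree.animal, name="animal"),
        columns=spec.traits,
    )
    fixed = pd.Series(x[: asm.n_fix], index=asm.fix_names)
    res = EvaluationResult(gebv, fixed, None, 0, 0.0, meta={"pev": pev})
    return res


def extract_gebv(result: EvaluationResult, animals, trait) -> np.ndarray:
    return result.extract_gebv(animals, trait)
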