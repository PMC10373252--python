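"""Relationship structures for single-step evaluation.

Builds the sparse pedigree inverse A^-1 (Henderson rules with
Meuwissen-Luo inbreeding), the genotyped-subset pedigree matrix A22,
the VanRaden genomic relationship matrix G = M D M' / 2*sum p_j(1-p_j)
with optional SNP weights D, tuning/blending of G toward A22, the number
of eigenvalues explaining 98% of the variation in G (the APY core-size
criterion), the APY sparse inverse of G, and the combined H^-1 operator

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

exposed as matrix-vector products so the dense inverse is never formed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .simdata import GenotypeMatrix, Pedigree


# ---------------------------------------------------------------------------
# pedigree side


def inbreeding_coefficients(sire_idx: np.ndarray, dam_idx: np.ndarray) -> np.ndarray:
    """Meuwissen & Luo inbreeding coefficients.

    Parents are 0-based positions (-1 unknown) and must precede offspring.
    Uses the L-matrix ancestor walk: A_ii = sum_j L_ij^2 D_j.
    """
    n = len(sire_idx)
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # walk ancestors of i from the highest index down, accumulating L_ij
        coeff: dict[int, float] = {i: 1.0}
        heap = [-i]
        in_heap = {i}
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            in_heap.discard(j)
            cj = coeff.pop(j)
            aii += cj * cj * D[j]
            for par in (sire_idx[j], dam_idx[j]):
                if par >= 0:
                    coeff[par] = coeff.get(par, 0.0) + 0.5 * cj
                    if par not in in_heap:
                        heapq.heappush(heap, -par)
                        in_heap.add(par)
        F[i] = aii - 1.0
    return F


@dataclass
class PedigreeFactor:
    """Sparse A^-1 over all pedigree animals, plus inbreeding coefficients."""

    animal_ids: np.ndarray
    a_inverse: sp.csr_matrix
    inbreeding: np.ndarray

    @property
    def n(self) -> int:
        return len(self.animal_ids)


def build_A_inverse(pedigree: Pedigree) -> PedigreeFactor:
    """Henderson's rules with inbreeding."""
    pedigree.validate()
    sire_idx, dam_idx = pedigree.parent_indices()
    n = pedigree.n
    F = inbreeding_coefficients(sire_idx, dam_idx)

    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        # Mendelian-sampling variance D_i = 0.5 - 0.25 (F_s + F_d), with
        # F = -1 for an unknown parent; alpha = 1/D_i
        alpha = 1.0 / (0.5 - 0.25 * (fs + fd))
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -alpha / 2)
                add(p, i, -alpha / 2)
                add(p, p, alpha / 4)
        if s >= 0 and d >= 0:
            add(s, d, alpha / 4)
            add(d, s, alpha / 4)

    a_inv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    a_inv.sum_duplicates()
    return PedigreeFactor(pedigree.animal.copy(), a_inv, F)


def build_A22(
    pedigree: Pedigree, genotyped_ids, factor: PedigreeFactor | None = None
) -> np.ndarray:
    """Pedigree relationships among the genotyped animals including all
    ancestral paths, obtained by solving A^-1 X = E on the genotyped columns
    (so the full A is never formed)."""
    factor = factor or build_A_inverse(pedigree)
    idx = pedigree.index_of(genotyped_ids)
    lu = spla.splu(sp.csc_matrix(factor.a_inverse))
    E = np.zeros((pedigree.n, len(idx)))
    E[idx, np.arange(len(idx))] = 1.0
    cols = lu.solve(E)
    A22 = cols[idx, :]
    return 0.5 * (A22 + A22.T)


def tabular_A(sire_idx: np.ndarray, dam_idx: np.ndarray) -> np.ndarray:
    """Dense additive relationship matrix by the tabular method.

    Quadratic in pedigree size; used for splits/exclusions on small sets and
    as a reference route for the genotyped subset.
    """
    n = len(sire_idx)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            aij = 0.0
            if s >= 0:
                aij += 0.5 * A[j, s]
            if d >= 0:
                aij += 0.5 * A[j, d]
            A[i, j] = A[j, i] = aij
    return A


# ---------------------------------------------------------------------------
# genomic side


@dataclass
class GenomicMatrix:
    animal_ids: np.ndarray
    values: np.ndarray
    state: str = "raw"  # raw | tuned | blended
    allele_freqs: np.ndarray | None = None
    weights_used: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.animal_ids)


def build_G(
    genotypes: GenotypeMatrix,
    weights: np.ndarray | None = None,
    allele_freqs: np.ndarray | None = None,
) -> GenomicMatrix:
    """First method of VanRaden: G = M D M' / (2 sum_j p_j (1-p_j)).

    M is the call matrix column-centered at 2p_j; p_j are observed allele
    frequencies among the genotyped animals unless supplied; D = I for
    ssGBLUP, the SNP weights for WssGBLUP.
    """
    calls = genotypes.calls
    if np.isnan(calls).any():
        raise ValueError("missing calls; run QC first")
    if calls.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    p = calls.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, float)
    denom = 2.0 * np.sum(p * (1 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero denominator")
    M = calls - 2.0 * p
    if weights is None:
        G = (M @ M.T) / denom
        w = None
    else:
        w = np.asarray(weights, float)
        G = (M * w) @ M.T / denom
    return GenomicMatrix(
        np.asarray(genotypes.animal_ids), 0.5 * (G + G.T), "raw", p, w
    )


def tune_and_blend(
    G: GenomicMatrix, A22: np.ndarray, blend_weight: float = 0.05
) -> GenomicMatrix:
    """Match mean diagonal and mean off-diagonal of G to A22 (solve
    a + b*mean = target for the additive constant a and scale b), then blend:
    (1 - w) G_t + w A22 with w defaulting to 5%."""
    Gv = G.values
    n = Gv.shape[0]
    off = ~np.eye(n, dtype=bool)
    mdg, mog = Gv.diagonal().mean(), Gv[off].mean()
    mda, moa = A22.diagonal().mean(), A22[off].mean()
    if abs(mdg - mog) < 1e-12:
        raise ValueError("tuning system singular: mean(diag G) == mean(offdiag G)")
    b = (mda - moa) / (mdg - mog)
    a = mda - b * mdg
    Gt = a + b * Gv
    blended = (1 - blend_weight) * Gt + blend_weight * A22
    return GenomicMatrix(G.animal_ids, blended, "blended", G.allele_freqs, G.weights_used)


def dimensionality_98(G: GenomicMatrix | np.ndarray, threshold: float = 0.98) -> int:
    """Smallest k whose top-k eigenvalues explain >= ``threshold`` of the
    total variation in G (negative eigenvalues clipped to 0)."""
    Gv = G.values if isinstance(G, GenomicMatrix) else np.asarray(G)
    w = np.linalg.eigvalsh(Gv)[::-1]
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        return 0
    frac = np.cumsum(w) / total
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


# ---------------------------------------------------------------------------
# G inverses


class DenseGInverse:
    """Direct inverse of (blended) G, wrapped in the operator interface."""

    def __init__(self, G: GenomicMatrix):
        self.animal_ids = np.asarray(G.animal_ids)
        self._inv = np.linalg.inv(G.values)
        self._inv = 0.5 * (self._inv + self._inv.T)

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self._inv @ v

    matmat = matvec

    def diagonal(self) -> np.ndarray:
        return self._inv.diagonal().copy()

    def to_dense(self) -> np.ndarray:
        return self._inv.copy()


class APYGInverse:
    """Algorithm for proven and young: sparse-structured G^-1 from a core
    subset.  Stores G_cc^-1, P = G_cc^-1 G_cn and the noncore Mendelian-like
    diagonal m_i = g_ii - g_ic G_cc^-1 g_ci; never materializes the dense
    inverse."""

    def __init__(self, G: GenomicMatrix, core_ids):
        ids = np.asarray(G.animal_ids)
        core_ids = np.asarray(core_ids)
        pos = {a: k for k, a in enumerate(ids)}
        try:
            core = np.array([pos[a] for a in core_ids])
        except KeyError as e:
            raise KeyError(f"core id not genotyped: {e}")
        mask = np.zeros(len(ids), bool)
        mask[core] = True
        noncore = np.flatnonzero(~mask)

        Gv = G.values
        Gcc = Gv[np.ix_(core, core)]
        Gcn = Gv[np.ix_(core, noncore)]
        self._Gcc_inv = np.linalg.inv(Gcc)
        self._Gcc_inv = 0.5 * (self._Gcc_inv + self._Gcc_inv.T)
        self._P = self._Gcc_inv @ Gcn  # core x noncore
        m = Gv.diagonal()[noncore] - np.einsum("ij,ij->j", Gcn, self._P)
        if np.any(m <= 1e-10):
            raise ValueError(
                "APY noncore animal fully explained by core (m_i <= 1e-10); "
                "blend G before inverting"
            )
        self._m_inv = 1.0 / m
        self._core = core
        self._noncore = noncore
        self.animal_ids = ids
        self.core_ids = ids[core]

    @property
    def n(self) -> int:
        return len(self.animal_ids)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """Apply the APY inverse
        [[Gcc^-1 + P Mg^-1 P', -P Mg^-1], [-Mg^-1 P', Mg^-1]] to v (vector or
        matrix of columns), in the original animal order."""
        v = np.asarray(v)
        vc = v[self._core]
        vn = v[self._noncore]
        mi = self._m_inv if v.ndim == 1 else self._m_inv[:, None]
        t = mi * (self._P.T @ vc - vn)  # Mg^-1 (P' vc - vn)
        out = np.empty_like(v, dtype=float)
        out[self._core] = self._Gcc_inv @ vc + self._P @ t
        out[self._noncore] = -t
        return out

    matmat = matvec

    def diagonal(self) -> np.ndarray:
        d = np.empty(self.n)
        d[self._core] = self._Gcc_inv.diagonal() + np.einsum(
            "ij,j,ij->i", self._P, self._m_inv, self._P
        )
        d[self._noncore] = self._m_inv
        return d

    def to_dense(self) -> np.ndarray:
        return self.matmat(np.eye(self.n))


def apy_inverse(G: GenomicMatrix, core_ids) -> APYGInverse:
    return APYGInverse(G, core_ids)


def direct_inverse(G: GenomicMatrix) -> DenseGInverse:
    return DenseGInverse(G)


def choose_core(
    G_chip: GenomicMatrix, rng: np.random.Generator, n_core: int | None = None
) -> np.ndarray:
    """Random core of size = the 98%-eigenvalue count of the chip-based G
    (the criterion used to size the core), unless given explicitly."""
    if n_core is None:
        n_core = dimensionality_98(G_chip)
    n_core = min(n_core, G_chip.n)
    take = rng.choice(G_chip.n, size=n_core, replace=False)
    return np.asarray(G_chip.animal_ids)[np.sort(take)]


# ---------------------------------------------------------------------------
# H inverse


@dataclass
class HInverseFactor:
    """Lazily combined H^-1 = A^-1 + scatter(G^-1 - A22^-1) operator."""

    pedigree_factor: PedigreeFactor
    g_inverse: DenseGInverse | APYGInverse | None
    a22_inverse: np.ndarray | None
    genotyped_index: np.ndarray  # positions of genotyped animals in pedigree order

    @property
    def n(self) -> int:
        return self.pedigree_factor.n

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.pedigree_factor.a_inverse @ v
        if self.g_inverse is not None and len(self.genotyped_index) > 0:
            v2 = v[self.genotyped_index]
            corr = self.g_inverse.matvec(v2) - self.a22_inverse @ v2
            out[self.genotyped_index] += corr
        return out

    matmat = matvec

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.pedigree_factor.a_inverse.diagonal()).copy()
        if self.g_inverse is not None and len(self.genotyped_index) > 0:
            d[self.genotyped_index] += (
                self.g_inverse.diagonal() - self.a22_inverse.diagonal()
            )
        return d

    def to_dense(self) -> np.ndarray:
        H = self.pedigree_factor.a_inverse.toarray()
        if self.g_inverse is not None and len(self.genotyped_index) > 0:
            ix = np.ix_(self.genotyped_index, self.genotyped_index)
            H[ix] += self.g_inverse.to_dense() - self.a22_inverse
        return H


def build_H_inverse(
    pedigree: Pedigree,
    pedigree_factor: PedigreeFactor,
    g_inverse,
    a22: np.ndarray | None,
    genotyped_ids,
) -> HInverseFactor:
    """Combine the three blocks; ``g_inverse`` may be None (no genotypes)."""
    if g_inverse is None or len(np.atleast_1d(genotyped_ids)) == 0:
        return HInverseFactor(pedigree_factor, None, None, np.array([], dtype=np.int64))
    idx = pedigree.index_of(genotyped_ids)
    a22_inv = np.linalg.inv(a22)
    a22_inv = 0.5 * (a22_inv + a22_inv.T)
    return HInverseFactor(pedigree_factor, g_inverse, a22_inv, idx)
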