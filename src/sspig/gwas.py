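"""Single-SNP mixed-linear-model association scan.

The null model y = Xb + g + e with g ~ N(0, G sigma2_a), e ~ N(0, I sigma2_e)
is fitted once by REML after a single eigendecomposition of G (the spectral
transformation: rotating by the eigenvectors diagonalizes the covariance, so
the restricted likelihood is a cheap 1-D profile over the variance ratio).
Marker effects are then estimated by generalized least squares with the null
covariance held fixed — the standard EMMAX-style approximation — at O(n) per
marker after rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simdata import GenotypeMatrix


@dataclass
class NullModel:
    sigma2_a: float
    sigma2_e: float
    heritability_ratio: float  # sigma2_a / (sigma2_a + sigma2_e)
    eigvals: np.ndarray
    eigvecs: np.ndarray
    loglik: float


@dataclass
class GWASResult:
    table: pd.DataFrame  # marker, beta, se, p_value, flag
    null: NullModel

    def p_values(self, marker_ids=None) -> pd.Series:
        s = self.table.set_index("marker")["p_value"]
        return s if marker_ids is None else s.loc[np.asarray(marker_ids)]


_DELTA_BOUNDS = (1e-6, 1e6)  # bounds for delta = sigma2_e / sigma2_a


def _reml_neg_loglik(log_delta, lam, yr, Xr):
    """Restricted log-likelihood of the rotated model, profiled over the
    total scale; delta = sigma2_e/sigma2_a."""
    delta = np.exp(log_delta)
    w = lam + delta  # V / sigma2_a eigenvalues
    wi = 1.0 / w
    XtWX = Xr.T @ (Xr * wi[:, None])
    XtWy = Xr.T @ (yr * wi)
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    n, p = Xr.shape
    rss = np.sum(r * r * wi)
    sigma2_a = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    _, logdet_XtX = np.linalg.slogdet(Xr.T @ Xr)
    ll = -0.5 * (
        (n - p) * np.log(sigma2_a)
        + np.sum(np.log(w))
        + logdet_XtWX
        - logdet_XtX
        + (n - p)
    )
    return -ll, sigma2_a


def fit_null_reml(y: np.ndarray, X: np.ndarray, G: np.ndarray) -> NullModel:
    """REML variance components via the rotated 1-D profile likelihood."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    Gv = G.values if hasattr(G, "values") else np.asarray(G)
    lam, U = np.linalg.eigh(Gv)
    lam = np.clip(lam, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    def obj(ld):
        nll, _ = _reml_neg_loglik(ld, lam, yr, Xr)
        if not np.isfinite(nll):
            raise FloatingPointError("non-finite restricted likelihood")
        return nll

    res = optimize.minimize_scalar(
        obj,
        bounds=(np.log(_DELTA_BOUNDS[0]), np.log(_DELTA_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    nll, sigma2_a = _reml_neg_loglik(res.x, lam, yr, Xr)
    delta = np.exp(res.x)  # capped by the bounds in the degenerate limits
    sigma2_e = sigma2_a * delta
    return NullModel(
        sigma2_a=float(sigma2_a),
        sigma2_e=float(sigma2_e),
        heritability_ratio=float(sigma2_a / (sigma2_a + sigma2_e)),
        eigvals=lam,
        eigvecs=U,
        loglik=-float(nll),
    )


def snp_scan(
    y: np.ndarray,
    X: np.ndarray,
    null: NullModel,
    genotypes: GenotypeMatrix,
    batch_size: int = 4096,
) -> GWASResult:
    """GLS scan of every marker with V = G sigma2_a + I sigma2_e held fixed.

    Monomorphic markers get beta 0, p-value 1 and a flag.  Wald p-values from
    the standard normal.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    U, lam = null.eigvecs, null.eigvals
    w = 1.0 / (null.sigma2_a * lam + null.sigma2_e)  # V^-1 eigen-weights
    yr = U.T @ y
    Xr = U.T @ X
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    C = np.linalg.inv(XtWX)
    b0 = C @ (Xw.T @ yr)

    calls = genotypes.calls
    m = calls.shape[1]
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    pval = np.ones(m)
    flags = np.zeros(m, bool)
    mono = np.nanstd(calls, axis=0) == 0
    flags[mono] = True

    cols = np.flatnonzero(~mono)
    for start in range(0, len(cols), batch_size):
        sel = cols[start : start + batch_size]
        Gr = U.T @ calls[:, sel]  # rotated markers
        A = Xw.T @ Gr  # p x b
        gWg = np.einsum("ij,i,ij->j", Gr, w, Gr)
        gWy = Gr.T @ (w * yr)
        t = C @ A
        denom = gWg - np.einsum("ij,ij->j", A, t)
        num = gWy - A.T @ b0
        ok = denom > 1e-12
        b = np.where(ok, num / np.where(ok, denom, 1.0), 0.0)
        s = np.where(ok, np.sqrt(1.0 / np.where(ok, denom, 1.0)), np.nan)
        beta[sel] = b
        se[sel] = s
        z = np.where(ok, b / s, 0.0)
        pval[sel] = np.where(ok, 2 * stats.norm.sf(np.abs(z)), 1.0)
        flags[sel[~ok]] = True
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "marker": np.asarray(genotypes.marker_ids),
            "beta": beta,
            "se": se,
            "p_value": pval,
            "flagged": flags,
        }
    )
    return GWASResult(table=table, null=null)


def run_gwas(
    y: np.ndarray,
    X: np.ndarray,
    G,
    genotypes: GenotypeMatrix,
) -> GWASResult:
    """Fit the null once, then scan all markers."""
    null = fit_null_reml(y, X, G)
    return snp_scan(y, X, null, genotypes)


def design_matrix(records: pd.DataFrame, covariate: bool = False) -> np.ndarray:
    """Cross-classified contemporary-group dummies (no intercept), plus the
    covariate column when requested."""
    cg = pd.get_dummies(records["cg"].astype("category")).to_numpy(float)
    if covariate:
        cg = np.column_stack([cg, records["covariate"].to_numpy(float)])
    return cg
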