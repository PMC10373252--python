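"""BayesR Gibbs sampler and SNP-weight construction for WssGBLUP.

SNP effects are drawn from a four-component normal mixture with mean zero
and variances (0, 1e-4, 1e-3, 1e-2) x sigma2_a, where sigma2_a is the
current sampled additive variance (fully Bayesian).  Each kept iteration
stores every SNP's class variance; the posterior SNP variance is the
average over post-burn-in iterations.  Weights are the posterior variances
rescaled so that trace(D) equals the number of SNPs.

The per-SNP sweep is the hot loop and is JIT-compiled; hyperparameter draws
(class proportions, variances) stay in numpy for clarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .simdata import GenotypeMatrix

DEFAULT_MIXTURE = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class BayesRConfig:
    n_iter: int = 3000
    burn_in: int = 1000
    thin: int = 1
    mixture_fractions: tuple = DEFAULT_MIXTURE
    dirichlet_prior: tuple | None = None  # default: sparsity prior scaled to m
    df_prior: float = 4.0
    seed: int = 1

    def validate(self):
        mf = np.asarray(self.mixture_fractions)
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if mf[0] != 0 or np.any(np.diff(mf) < 0):
            raise ValueError("mixture_fractions must be nondecreasing with first = 0")


@dataclass
class SNPWeights:
    table: pd.DataFrame  # marker, posterior_variance, weight
    posterior: dict = field(default_factory=dict)  # sigma2_a, sigma2_e, proportions

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()


@njit(cache=True)
def _sweep(
    MT, xtx, r, beta, classes, gamma, log_pi, sigma2_a, sigma2_e, u_class, z_eff, var_cond
):
    """One Gibbs sweep over all SNPs; updates r, beta, classes in place.
    MT is markers x animals (each row contiguous).  ``var_cond`` receives the
    conditional expected class variance per SNP (Rao-Blackwellized, much less
    Monte-Carlo noise than the sampled class).  Returns (class counts,
    sum beta^2/gamma over nonzero classes)."""
    m = MT.shape[0]
    n = MT.shape[1]
    K = gamma.shape[0]
    counts = np.zeros(K, dtype=np.int64)
    ssq = 0.0
    logw = np.empty(K)
    for j in range(m):
        x = MT[j]
        old = beta[j]
        rhs = np.dot(x, r) + xtx[j] * old
        # class log-weights: marginal likelihood with beta integrated out
        logw[0] = log_pi[0]
        maxw = logw[0]
        for k in range(1, K):
            v = gamma[k] * sigma2_a
            if v <= 0.0:
                logw[k] = -1e300
                continue
            c = xtx[j] + sigma2_e / v
            logw[k] = (
                log_pi[k]
                + 0.5 * (np.log(sigma2_e) - np.log(v) - np.log(c))
                + 0.5 * rhs * rhs / (sigma2_e * c)
            )
            if logw[k] > maxw:
                maxw = logw[k]
        tot = 0.0
        for k in range(K):
            logw[k] = np.exp(logw[k] - maxw)
            tot += logw[k]
        ev = 0.0
        for k in range(1, K):
            ev += logw[k] / tot * gamma[k]
        var_cond[j] = ev * sigma2_a
        u = u_class[j] * tot
        acc = 0.0
        k_new = K - 1
        for k in range(K):
            acc += logw[k]
            if u <= acc:
                k_new = k
                break
        classes[j] = k_new
        counts[k_new] += 1
        if k_new == 0:
            new = 0.0
        else:
            v = gamma[k_new] * sigma2_a
            c = xtx[j] + sigma2_e / v
            mean = rhs / c
            sd = np.sqrt(sigma2_e / c)
            new = mean + sd * z_eff[j]
            ssq += new * new / gamma[k_new]
        if new != old:
            for i in range(n):
                r[i] += x[i] * (old - new)
        beta[j] = new
    return counts, ssq


def run_bayesr(
    responses: np.ndarray,
    genotypes: GenotypeMatrix,
    config: BayesRConfig | None = None,
) -> SNPWeights:
    """Gibbs sampler for the four-component mixture model.

    ``responses`` covers the genotyped training animals, aligned with the
    genotype matrix rows (typically deregressed EBV; adjusted phenotypes
    also work).
    """
    cfg = config or BayesRConfig()
    cfg.validate()
    y = np.asarray(responses, float)
    calls = genotypes.calls
    if np.isnan(calls).any():
        raise ValueError("missing genotypes")
    n, m = calls.shape
    if len(y) != n:
        raise ValueError("response length does not match genotype rows")
    if n < 50:
        raise ValueError("need at least 50 animals")

    rng = np.random.default_rng(cfg.seed)
    MT = np.ascontiguousarray((calls - calls.mean(axis=0)).T)
    xtx = np.einsum("ij,ij->i", MT, MT)
    xtx[xtx == 0] = 1e-12

    gamma = np.asarray(cfg.mixture_fractions, float)
    K = len(gamma)
    pi = np.full(K, 1.0 / K)
    vy = np.var(y)
    sigma2_a = max(vy * 0.5, 1e-8)
    sigma2_e = max(vy * 0.5, 1e-8)
    mu = y.mean()
    beta = np.zeros(m)
    classes = np.zeros(m, dtype=np.int64)
    r = y - mu  # residual y - mu - M beta

    nu = cfg.df_prior
    S_a = sigma2_a * (nu - 2) / nu  # scale priors centered at the start values
    S_e = sigma2_e * (nu - 2) / nu

    # sparsity Dirichlet prior: most SNPs are expected in the null class;
    # pseudo-counts scale with the panel so the prior stays informative
    if cfg.dirichlet_prior is None:
        alpha = np.array([0.96, 0.02, 0.01, 0.01]) * max(m / 10.0, 4.0)
    else:
        alpha = np.asarray(cfg.dirichlet_prior, float)

    kept = 0
    var_cond = np.zeros(m)
    post_var = np.zeros(m)
    post_pi = np.zeros(K)
    post_s2a = 0.0
    post_s2e = 0.0

    for it in range(cfg.n_iter):
        # intercept
        mu_new = rng.normal(mu + r.mean(), np.sqrt(sigma2_e / n))
        r += mu - mu_new
        mu = mu_new

        counts, ssq = _sweep(
            MT,
            xtx,
            r,
            beta,
            classes,
            gamma,
            np.log(pi + 1e-300),
            sigma2_a,
            sigma2_e,
            rng.random(m),
            rng.standard_normal(m),
            var_cond,
        )
        m_nz = int(m - counts[0])
        # additive variance: scaled inverse chi-square conditional
        df_a = nu + m_nz
        sigma2_a = (ssq + nu * S_a) / rng.chisquare(df_a)
        # residual variance
        df_e = nu + n
        sigma2_e = (float(r @ r) + nu * S_e) / rng.chisquare(df_e)
        if not (np.isfinite(sigma2_a) and np.isfinite(sigma2_e)):
            raise FloatingPointError(f"sampler diverged at iteration {it}")
        pi = rng.dirichlet(counts + alpha)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            kept += 1
            post_var += var_cond
            post_pi += pi
            post_s2a += sigma2_a
            post_s2e += sigma2_e

    post_var /= kept
    table = pd.DataFrame(
        {
            "marker": np.asarray(genotypes.marker_ids),
            "posterior_variance": post_var,
        }
    )
    weights = variances_to_weights(post_var)
    table["weight"] = weights
    return SNPWeights(
        table=table,
        posterior={
            "sigma2_a": post_s2a / kept,
            "sigma2_e": post_s2e / kept,
            "proportions": post_pi / kept,
            "kept": kept,
        },
    )


def variances_to_weights(
    variances: np.ndarray, floor_fraction: float = 0.01
) -> np.ndarray:
    """Rescale posterior variances so trace(D) = number of SNPs.

    Zero-variance markers get a floor (``floor_fraction`` of the mean weight
    before rescaling) to keep the weighted G full rank.
    """
    v = np.asarray(variances, float).copy()
    if np.all(v <= 0):
        raise ValueError("all posterior variances are zero")
    if floor_fraction > 0:
        v = np.maximum(v, floor_fraction * v.mean())
    return v * len(v) / v.sum()
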