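"""BayesR marker-effect estimation, GEBV prediction, and a GBLUP h2 utility.

BayesR is a Bayesian whole-genome regression in which each SNP effect comes
from a four-component normal mixture N(0, gamma_k * sigma_g^2) with variance
fractions gamma = (0, 1e-4, 1e-3, 1e-2): most markers fall in the null
component, a few carry moderate or large effects.  The model is fitted by
Gibbs sampling over effects, mixture-class indicators, mixture proportions
(Dirichlet), and the genetic and residual variances (scaled inverse
chi-square).  Breeding values of selection candidates are then predicted as
g_hat = X' beta with X' the 0/1/2 dosage matrix and beta the posterior-mean
effects.

Phenotypes are standardized internally for numerical stability and the
effects back-transformed to the phenotype scale.  The component variances are
fractions of the *current* genetic variance, re-scaled every iteration, per
the usual BayesR convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "BayesRConfig",
    "MarkerEffects",
    "fit_bayesr",
    "fit_marker_effects",
    "predict_gebv",
    "estimate_h2_gblup",
]

MIXTURE_FRACTIONS = (0.0, 1e-4, 1e-3, 1e-2)

try:  # jitted Gibbs chain; the pure-numpy chain below is the fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        return wrap


@dataclass
class BayesRConfig:
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    mixture_variance_fractions: tuple = MIXTURE_FRACTIONS
    # mild sparsity prior on the mixture proportions: the null and the
    # gamma = 1e-4 component are likelihood-equivalent for markers without
    # signal, and with a flat prior the chain can wander into states where
    # hundreds of spare markers absorb residual noise; ten pseudo-counts on
    # the null break that degeneracy without hindering real effects
    dirichlet_prior: tuple = (10.0, 1.0, 1.0, 1.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        fr = tuple(self.mixture_variance_fractions)
        if len(fr) != 4 or fr[0] != 0.0 or any(f < 0 for f in fr):
            raise ValueError("mixture fractions must be 4 non-negative values, first 0")
        if any(a <= 0 for a in self.dirichlet_prior):
            raise ValueError("dirichlet_prior entries must be positive")


@dataclass
class MarkerEffects:
    """Posterior summaries of a BayesR fit, one column per trait."""

    beta: pd.DataFrame  # markers x traits, posterior-mean effects
    class_probs: dict  # trait -> (m, 4) posterior class-membership
    var_components: pd.DataFrame  # traits x [sigma_g2, sigma_e2]

    def to_csv(self, path) -> None:
        out = self.beta.copy()
        for trait, probs in self.class_probs.items():
            for k in range(probs.shape[1]):
                out[f"p{k}_{trait}"] = probs[:, k]
        out.to_csv(path)


@njit(cache=True)
def _gibbs_jit(Xt, y, n_iter, burn_in, thin, gamma, alpha, seed):
    """Compiled single-trait BayesR chain; Xt is the (m, n) transposed dosage
    matrix (contiguous marker rows).  Same model as the numpy fallback; the
    two backends use different random streams."""
    np.random.seed(seed)
    m, n = Xt.shape
    beta = np.zeros(m)
    classes = np.zeros(m, np.int64)
    # parsimony start: begin in the all-null basin (standard BayesR
    # starting proportions); markers with real signal leave it immediately
    pi = np.array([0.95, 0.02, 0.02, 0.01])
    sigma_g2, sigma_e2 = 0.5, 0.5
    e = y.copy()
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xtx[j] = s
    # scaled-inv-chi2 priors: sigma_g2 anchored at half the (unit)
    # phenotypic variance so the mixture stays identified when few
    # markers carry effects; sigma_e2 prior is weak
    nu0, s0g, s0e = 4.0, 0.25, 0.01
    n_kept = 0
    beta_sum = np.zeros(m)
    probs_sum = np.zeros((m, 4))
    sg_sum = 0.0
    se_sum = 0.0
    logl = np.zeros(4)
    w = np.zeros(4)
    for it in range(n_iter):
        v0 = gamma * sigma_g2
        for j in range(m):
            bj = beta[j]
            r = 0.0
            for i in range(n):
                r += Xt[j, i] * e[i]
            c = xtx[j]
            r += c * bj  # own contribution added back without touching e
            maxl = 0.0
            for k in range(4):
                if k == 0:
                    logl[k] = 0.0
                else:
                    den = v0[k] * c + sigma_e2
                    logl[k] = 0.5 * (
                        np.log(sigma_e2 / den) + r * r * v0[k] / (sigma_e2 * den)
                    )
                if logl[k] > maxl:
                    maxl = logl[k]
            tot = 0.0
            for k in range(4):
                w[k] = pi[k] * np.exp(logl[k] - maxl)
                tot += w[k]
            u = np.random.random() * tot
            acc = 0.0
            knew = 3
            for k in range(4):
                acc += w[k]
                if u <= acc:
                    knew = k
                    break
            classes[j] = knew
            if knew == 0:
                bnew = 0.0
            else:
                lam = c + sigma_e2 / v0[knew]
                bnew = r / lam + np.sqrt(sigma_e2 / lam) * np.random.standard_normal()
            if bnew != bj:
                d = bj - bnew
                for i in range(n):
                    e[i] += Xt[j, i] * d
            beta[j] = bnew
        counts = np.zeros(4)
        for j in range(m):
            counts[classes[j]] += 1.0
        tot = 0.0
        for k in range(4):
            pi[k] = np.random.gamma(alpha[k] + counts[k], 1.0)
            tot += pi[k]
        pi /= tot
        df_g = 0.0
        ssq = 0.0
        for j in range(m):
            if classes[j] > 0:
                df_g += 1.0
                ssq += beta[j] * beta[j] / gamma[classes[j]]
        sigma_g2 = (ssq + nu0 * s0g) / np.random.chisquare(df_g + nu0)
        if sigma_g2 < 1e-8:
            sigma_g2 = 1e-8
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma_e2 = (sse + nu0 * s0e) / np.random.chisquare(n + nu0)
        if sigma_e2 < 1e-8:
            sigma_e2 = 1e-8
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_kept += 1
            gmean = 0.0
            for i in range(n):
                gmean += y[i] - e[i]
            gmean /= n
            gvar = 0.0
            for i in range(n):
                d = (y[i] - e[i]) - gmean
                gvar += d * d
            for j in range(m):
                beta_sum[j] += beta[j]
                probs_sum[j, classes[j]] += 1.0
            sg_sum += gvar / n  # realized genomic variance var(X beta)
            se_sum += sigma_e2
    return beta_sum / n_kept, probs_sum / n_kept, sg_sum / n_kept, se_sum / n_kept


def _gibbs_bayesr(X: np.ndarray, y: np.ndarray, cfg: BayesRConfig, rng):
    """Single-trait BayesR Gibbs chain on standardized y; returns posterior
    means of (beta, class probabilities, sigma_g2, sigma_e2)."""
    n, m = X.shape
    gamma = np.asarray(cfg.mixture_variance_fractions)
    alpha = np.asarray(cfg.dirichlet_prior)
    nu0, s0g, s0e = 4.0, 0.25, 0.01  # same priors as the jitted chain

    beta = np.zeros(m)
    classes = np.zeros(m, dtype=np.int64)
    pi = np.array([0.95, 0.02, 0.02, 0.01])  # parsimony start, as in the jitted chain
    sigma_g2, sigma_e2 = 0.5, 0.5
    e = y - X @ beta
    xtx = np.einsum("ij,ij->j", X, X)

    n_kept = 0
    beta_sum = np.zeros(m)
    probs_sum = np.zeros((m, 4))
    sg_sum = se_sum = 0.0

    for it in range(cfg.n_iter):
        v = gamma * sigma_g2  # component variances this iteration
        u_class = rng.random(m)  # batched draws: one uniform + one normal per marker
        z_eff = rng.standard_normal(m)
        for j in range(m):
            xj = X[:, j]
            if beta[j] != 0.0:
                e += xj * beta[j]
            r = xj @ e
            c = xtx[j]
            # log-likelihood of each component relative to the null one
            denom = v * c + sigma_e2
            logl = 0.5 * (np.log(sigma_e2 / denom) + (r * r * v) / (sigma_e2 * denom))
            logl[0] = 0.0
            w = pi * np.exp(logl - logl.max())
            cw = np.cumsum(w)
            k = int(np.searchsorted(cw, u_class[j] * cw[-1], side="right"))
            classes[j] = k
            if k == 0:
                beta[j] = 0.0
            else:
                post_var = sigma_e2 / (c + sigma_e2 / v[k])
                post_mean = r / (c + sigma_e2 / v[k])
                beta[j] = post_mean + np.sqrt(post_var) * z_eff[j]
                e -= xj * beta[j]

        counts = np.bincount(classes, minlength=4)
        pi = rng.dirichlet(alpha + counts)

        nz = classes > 0
        df_g = counts[1:].sum()
        ssq_g = np.sum(beta[nz] ** 2 / gamma[classes[nz]]) if df_g else 0.0
        sigma_g2 = (ssq_g + nu0 * s0g) / rng.chisquare(df_g + nu0)
        sigma_g2 = max(sigma_g2, 1e-8)
        sigma_e2 = (e @ e + nu0 * s0e) / rng.chisquare(n + nu0)
        sigma_e2 = max(sigma_e2, 1e-8)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            n_kept += 1
            beta_sum += beta
            probs_sum[np.arange(m), classes] += 1.0
            sg_sum += float(np.var(y - e))  # realized genomic variance var(X beta)
            se_sum += sigma_e2

    return (
        beta_sum / n_kept,
        probs_sum / n_kept,
        sg_sum / n_kept,
        se_sum / n_kept,
    )


def fit_bayesr(dosages, phenotypes, config: BayesRConfig | None = None):
    """Fit single-trait BayesR; returns (beta, class_probs, sigma_g2, sigma_e2)
    on the original phenotype scale."""
    cfg = config if config is not None else BayesRConfig()
    X = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("dosages rows must match phenotype entries")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    mu, sd = y.mean(), y.std()
    if sd <= 0:
        raise ValueError("phenotypes have zero variance")
    rng = np.random.default_rng(cfg.seed)
    ys = (y - mu) / sd
    # column-center the genotypes: the chain has no explicit intercept, so
    # uncentered dosages would leak the phenotype mean into every x_j' e
    X = X - X.mean(axis=0)
    if _HAVE_NUMBA:
        seed = cfg.seed if cfg.seed is not None else int(rng.integers(2**31))
        beta, probs, sg, se = _gibbs_jit(
            np.ascontiguousarray(X.T),
            ys,
            cfg.n_iter,
            cfg.burn_in,
            cfg.thin,
            np.asarray(cfg.mixture_variance_fractions, dtype=float),
            np.asarray(cfg.dirichlet_prior, dtype=float),
            seed % (2**31),
        )
    else:
        beta, probs, sg, se = _gibbs_bayesr(np.asfortranarray(X), ys, cfg, rng)
    return beta * sd, probs, sg * sd**2, se * sd**2


def fit_marker_effects(
    dosages, phenotypes: pd.DataFrame, config: BayesRConfig | None = None,
    marker_ids=None,
) -> MarkerEffects:
    """BayesR per trait column of ``phenotypes`` (traits are fitted
    independently, one single-trait chain each)."""
    cfg = config if config is not None else BayesRConfig()
    m = np.asarray(dosages).shape[1]
    ids = marker_ids if marker_ids is not None else [f"m{j}" for j in range(m)]
    betas, probs, vcs = {}, {}, {}
    # independent sub-seeds per trait so traits do not share a stream
    ss = np.random.SeedSequence(cfg.seed)
    for trait, child in zip(phenotypes.columns, ss.spawn(len(phenotypes.columns))):
        tcfg = BayesRConfig(
            cfg.n_iter, cfg.burn_in, cfg.thin, cfg.mixture_variance_fractions,
            cfg.dirichlet_prior, int(child.generate_state(1)[0] % (2**31)),
        )
        b, p, sg, se = fit_bayesr(dosages, phenotypes[trait].to_numpy(), tcfg)
        betas[trait], probs[trait] = b, p
        vcs[trait] = {"sigma_g2": sg, "sigma_e2": se}
    return MarkerEffects(
        pd.DataFrame(betas, index=ids),
        probs,
        pd.DataFrame(vcs).T,
    )


def predict_gebv(dosages, effects: MarkerEffects, trait: str) -> np.ndarray:
    """GEBVs g_hat = X' beta for one trait."""
    X = np.asarray(dosages, dtype=float)
    beta = effects.beta[trait].to_numpy()
    if X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"dosage matrix has {X.shape[1]} markers, effects have {beta.shape[0]}"
        )
    return X @ beta


def estimate_h2_gblup(phenotypes, grm, ridge: float = 0.0) -> float:
    """REML narrow-sense heritability under y = mu + g + e, g ~ N(0, G sg2).

    Profiles the restricted likelihood over h2 after an eigenrotation of the
    GRM; a small ridge is added automatically if the GRM is numerically
    singular.
    """
    y = np.asarray(phenotypes, dtype=float)
    G = np.asarray(grm.values if hasattr(grm, "values") else grm, dtype=float)
    n = y.shape[0]
    if G.shape != (n, n):
        raise ValueError("GRM dimension does not match phenotypes")
    w, U = np.linalg.eigh(G + ridge * np.eye(n))
    if w.min() < -1e-8 * max(abs(w.max()), 1.0):
        return estimate_h2_gblup(y, G, ridge=1e-6 if ridge == 0 else ridge * 10)
    w = np.clip(w, 0.0, None)
    ystar = U.T @ y
    xstar = U.T @ np.ones(n)

    def neg_reml(h2: float) -> float:
        lam = h2 / (1.0 - h2)
        d = lam * w + 1.0
        xtvx = np.sum(xstar**2 / d)
        bhat = np.sum(xstar * ystar / d) / xtvx
        resid = ystar - bhat * xstar
        quad = np.sum(resid**2 / d)
        se2 = quad / (n - 1)
        return 0.5 * ((n - 1) * np.log(se2) + np.sum(np.log(d)) + np.log(xtvx))

    res = minimize_scalar(neg_reml, bounds=(1e-4, 1.0 - 1e-4), method="bounded")
    return float(res.x)
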