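"""Differential expression between recombined (EGFP) and non-recombined
(Tomato) nuclei with a negative-binomial / Poisson generalized linear mixed
model.

Model, per gene:

    y_i ~ NB(mu_i, theta),   mu_i = exp(b0 + b1 * recomb_i + u_{s(i)} + o_i)
    u_s ~ Normal(0, sigma^2)

where ``o_i = ln(total counts of nucleus i)`` is a fixed offset, ``s(i)`` is
the sample of nucleus i, and the NB variance is mu + mu^2 / theta (theta is
the size parameter; theta -> infinity is the Poisson limit).  The marginal
likelihood integrates the per-sample random intercepts by the Laplace
approximation — appropriate here because each sample contributes hundreds of
nuclei.  If the dispersion estimate diverges (theta > 1e6) or the NB fit
fails, the gene is refit as a Poisson GLMM and labelled accordingly.

Wald standard errors for the fixed effects come from the numerical Hessian
of the Laplace log-likelihood at the optimum with the variance parameters
held fixed, the usual mixed-model convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
import scipy.stats
from scipy.special import gammaln

THETA_POISSON_CUTOFF = 1e6
_ETA_CLIP = 30.0


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise error threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def filter_expressed(
    cm, calls: pd.DataFrame, frac: float = 0.01
) -> np.ndarray:
    """Genes detected in >= ``frac`` of nuclei in either exclusive group.

    Detection is count > 0; the boundary is inclusive.  Returns gene indices.
    """
    egfp_mask = (calls["call"] == "EGFP_ONLY").to_numpy()
    tom_mask = (calls["call"] == "TOM_ONLY").to_numpy()
    if egfp_mask.sum() == 0 or tom_mask.sum() == 0:
        raise ValueError("both exclusive reporter groups must be nonempty")
    X = cm.counts.tocsc()
    det_g = np.asarray((X[:, egfp_mask] > 0).sum(axis=1)).ravel() / egfp_mask.sum()
    det_t = np.asarray((X[:, tom_mask] > 0).sum(axis=1)).ravel() / tom_mask.sum()
    return np.flatnonzero((det_g >= frac) | (det_t >= frac))


# ---------------------------------------------------------------------------
# Laplace-approximated marginal likelihood


def _nb_ll_terms(y, mu, theta):
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def _poisson_ll_terms(y, mu):
    return y * np.log(mu) - mu - gammaln(y + 1)


class _LaplaceGLMM:
    """Marginal log-likelihood machinery shared by the NB and Poisson fits."""

    def __init__(self, y, x, offset, groups, family: str):
        self.y = np.asarray(y, float)
        self.x = np.asarray(x, float)
        self.offset = np.asarray(offset, float)
        codes, uniq = pd.factorize(np.asarray(groups))
        self.groups = codes
        self.n_groups = len(uniq)
        self.family = family

    def _eta_fixed(self, b0, b1):
        return np.clip(b0 + b1 * self.x + self.offset, -_ETA_CLIP, _ETA_CLIP)

    def _score_hess(self, eta, theta):
        """Per-observation d ll / d eta and -d2 ll / d eta2."""
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        if self.family == "nb":
            score = self.y - mu * (self.y + theta) / (theta + mu)
            hess = (self.y + theta) * theta * mu / (theta + mu) ** 2
        else:
            score = self.y - mu
            hess = mu
        return score, hess

    def _ll_obs(self, eta, theta):
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        if self.family == "nb":
            return _nb_ll_terms(self.y, mu, theta)
        return _poisson_ll_terms(self.y, mu)

    def random_modes(self, b0, b1, theta, sigma2, n_iter: int = 50):
        """Newton solve for the per-group posterior modes u*."""
        eta0 = self._eta_fixed(b0, b1)
        u = np.zeros(self.n_groups)
        for _ in range(n_iter):
            eta = eta0 + u[self.groups]
            score, hess = self._score_hess(eta, theta)
            g = np.bincount(self.groups, weights=score, minlength=self.n_groups)
            g -= u / sigma2
            h = np.bincount(self.groups, weights=hess, minlength=self.n_groups)
            h += 1.0 / sigma2
            step = g / h
            step = np.clip(step, -2.0, 2.0)
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        return u

    def marginal_ll(self, b0, b1, theta, sigma2):
        u = self.random_modes(b0, b1, theta, sigma2)
        eta = self._eta_fixed(b0, b1) + u[self.groups]
        ll = self._ll_obs(eta, theta).sum()
        _, hess = self._score_hess(eta, theta)
        h = np.bincount(self.groups, weights=hess, minlength=self.n_groups)
        h += 1.0 / sigma2
        # log integral per group: g(u*) + 0.5 ln(2 pi / h) - 0.5 ln(2 pi s2) - u*^2/(2 s2)
        ll -= (u**2).sum() / (2.0 * sigma2)
        ll -= 0.5 * np.log(sigma2 * h).sum()
        return float(ll)


@dataclass
class DEResult:
    gene: str
    beta_recomb: float
    se: float
    wald_p: float
    model: str  # "NB" or "POISSON"
    theta: float  # inf for Poisson
    sigma2_re: float
    converged: bool
    loglik: float = np.nan


def _moment_init(y, x, offset):
    e_off = np.exp(np.asarray(offset, float))
    r0 = y[x == 0].sum() / max(e_off[x == 0].sum(), 1e-12)
    r1 = y[x == 1].sum() / max(e_off[x == 1].sum(), 1e-12)
    b0 = np.log(max(r0, 1e-12))
    b1 = np.log(max(r1, 1e-12)) - b0
    return float(b0), float(np.clip(b1, -5, 5))


def fit_nb_glmm(
    y,
    sample_ids,
    recomb,
    offset,
    gene: str = "",
    max_restarts: int = 2,
) -> DEResult:
    """Fit the NB GLMM for one gene; fall back to Poisson when needed.

    Parameters are optimised on (b0, b1, ln theta, ln sigma^2) by
    Nelder-Mead on the Laplace marginal likelihood.
    """
    y = np.asarray(y, float)
    x = np.asarray(recomb, float)
    if len(np.unique(x)) < 2:
        raise ValueError("both recombination levels must be present")
    if len(np.unique(np.asarray(sample_ids))) < 2:
        raise ValueError("need at least two samples")
    if np.all(y == 0):
        return DEResult(gene, np.nan, np.nan, np.nan, "NB", np.nan, np.nan, False)

    def optimise(family: str):
        glmm = _LaplaceGLMM(y, x, offset, sample_ids, family)
        b0_init, b1_init = _moment_init(y, x, np.asarray(offset, float))

        if family == "nb":
            def neg(p):
                b0, b1, lt, ls = p
                theta = np.exp(np.clip(lt, -8.0, 25.0))
                sigma2 = np.exp(np.clip(ls, -20.0, 6.0))
                return -glmm.marginal_ll(b0, b1, theta, sigma2)

            x0 = np.array([b0_init, b1_init, np.log(2.0), np.log(0.05)])
        else:
            def neg(p):
                b0, b1, ls = p
                sigma2 = np.exp(np.clip(ls, -20.0, 6.0))
                return -glmm.marginal_ll(b0, b1, np.inf, sigma2)

            x0 = np.array([b0_init, b1_init, np.log(0.05)])

        best = None
        for attempt in range(max_restarts):
            start = x0 if attempt == 0 else x0 + np.array(
                [0.5, -0.5, 1.0, -2.0][: len(x0)]
            )
            res = scipy.optimize.minimize(
                neg,
                start,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
        return glmm, best

    glmm, res = optimise("nb")
    b0, b1 = res.x[0], res.x[1]
    theta = float(np.exp(np.clip(res.x[2], -8.0, 25.0)))
    sigma2 = float(np.exp(np.clip(res.x[3], -20.0, 6.0)))
    model = "NB"
    converged = bool(res.success)
    if (not converged) or theta > THETA_POISSON_CUTOFF:
        glmm, res = optimise("poisson")
        b0, b1 = res.x[0], res.x[1]
        theta = np.inf
        sigma2 = float(np.exp(np.clip(res.x[2], -20.0, 6.0)))
        model = "POISSON"
        converged = bool(res.success)

    se, p = _wald_beta1(glmm, b0, b1, theta, sigma2)
    if not converged:
        p = np.nan
    return DEResult(
        gene=gene,
        beta_recomb=float(b1),
        se=se,
        wald_p=p,
        model=model,
        theta=theta,
        sigma2_re=sigma2,
        converged=converged,
        loglik=float(-res.fun),
    )


def _wald_beta1(glmm: _LaplaceGLMM, b0, b1, theta, sigma2, h: float = 1e-4):
    """Wald SE of b1 from the numerical fixed-effect Hessian at the optimum."""

    def ll(bb0, bb1):
        return glmm.marginal_ll(bb0, bb1, theta, sigma2)

    f0 = ll(b0, b1)
    d2_00 = (ll(b0 + h, b1) - 2 * f0 + ll(b0 - h, b1)) / h**2
    d2_11 = (ll(b0, b1 + h) - 2 * f0 + ll(b0, b1 - h)) / h**2
    d2_01 = (
        ll(b0 + h, b1 + h) - ll(b0 + h, b1 - h) - ll(b0 - h, b1 + h) + ll(b0 - h, b1 - h)
    ) / (4 * h**2)
    info = -np.array([[d2_00, d2_01], [d2_01, d2_11]])
    try:
        cov = np.linalg.inv(info)
        var = cov[1, 1]
        if var <= 0:
            return np.nan, np.nan
        se = float(np.sqrt(var))
        z = b1 / se
        return se, float(2 * scipy.stats.norm.sf(abs(z)))
    except np.linalg.LinAlgError:
        return np.nan, np.nan


@dataclass
class DETable:
    results: pd.DataFrame
    m_tested: int
    alpha: float

    @property
    def bonferroni_threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.m_tested)

    @property
    def nominal_set(self) -> list[str]:
        r = self.results
        return list(r.loc[r["wald_p"] <= 0.05, "gene"])

    @property
    def family_wise_set(self) -> list[str]:
        r = self.results
        return list(r.loc[r["wald_p"] <= self.bonferroni_threshold, "gene"])


def de_test_all(
    cm,
    calls: pd.DataFrame,
    alpha: float = 0.05,
    min_frac: float = 0.01,
    gene_indices: np.ndarray | None = None,
    jobs: int = 1,
) -> DETable:
    """Per-gene GLMM tests over the expressed genes; Bonferroni at alpha/m.

    ``m_tested`` counts every gene attempted; non-converged genes keep a
    missing p but still count toward m.  ``gene_indices`` overrides the
    expression filter (used by callers that pre-filtered).
    """
    if gene_indices is None:
        gene_indices = filter_expressed(cm, calls, frac=min_frac)
    excl = calls["call"].isin(["EGFP_ONLY", "TOM_ONLY"]).to_numpy()
    X = cm.counts.tocsc()[:, excl]
    offset = np.log(np.asarray(X.sum(axis=0)).ravel() + 1e-12)
    recomb = (calls.loc[excl, "call"] == "EGFP_ONLY").to_numpy().astype(float)
    samples = calls.loc[excl, "sample_id"].to_numpy()
    gene_ids = cm.genes["gene_id"].to_numpy()

    def fit_one(g):
        yg = np.asarray(X[g, :].todense()).ravel()
        try:
            return fit_nb_glmm(yg, samples, recomb, offset, gene=gene_ids[g])
        except ValueError:
            return DEResult(gene_ids[g], np.nan, np.nan, np.nan, "NB", np.nan, np.nan, False)

    if jobs > 1:
        from joblib import Parallel, delayed

        fits = Parallel(n_jobs=jobs)(delayed(fit_one)(g) for g in gene_indices)
    else:
        fits = [fit_one(g) for g in gene_indices]
    rows = pd.DataFrame(
        [
            {
                "gene": f.gene,
                "beta": f.beta_recomb,
                "se": f.se,
                "wald_p": f.wald_p,
                "model": f.model,
                "theta": f.theta,
                "sigma2_re": f.sigma2_re,
                "converged": f.converged,
            }
            for f in fits
        ]
    )
    return DETable(results=rows, m_tested=len(gene_indices), alpha=alpha)
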