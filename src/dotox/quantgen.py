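"""Heritability estimation and the additive/dominant likelihood-ratio test.

Heritability is estimated from the kinship mixed model

    y ~ N(X beta, sigma_g2 * K + sigma_e2 * I),

fit by REML after a single eigendecomposition of K: rotating into the
eigenbasis diagonalizes the covariance, so the restricted likelihood is a
smooth one-dimensional function of h2 = sigma_g2 / (sigma_g2 + sigma_e2)
with the total variance profiled out.  h2 is maximized on [0, 1] by a grid
sweep plus bounded refinement.  REML is the default (small-sample bias
correction); ML is available for likelihood-ratio comparisons.

The dominance test at a focal locus compares three fixed-effect linear
models of the focal-founder allele coding: additive only (0 / 0.5 / 1),
dominant only (0 / 1), and the general model with both terms.  Twice the
log-likelihood difference is referred to chi-square with 1 df.  A pattern of
"reject additive, retain dominant" indicates that one copy of the focal
allele confers the full effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .containers import VarianceComponents

logger = logging.getLogger(__name__)


def _reml_negloglik(h2, S, ytr, Xtr, reml=True):
    """Negative (restricted) log-likelihood with total variance profiled out.

    S: eigenvalues of K; ytr, Xtr: y and X rotated into K's eigenbasis.
    """
    n, p = Xtr.shape
    lam = h2 * S + (1.0 - h2)
    w = 1.0 / lam
    XtWX = Xtr.T @ (Xtr * w[:, None])
    XtWy = Xtr.T @ (ytr * w)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = ytr - Xtr @ beta
    rss = float(resid @ (resid * w))
    if reml:
        dof = n - p
        sigma2 = rss / dof
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        _, logdet_xx = np.linalg.slogdet(Xtr.T @ Xtr)
        ll = -0.5 * (
            dof * np.log(2 * np.pi * sigma2)
            + np.sum(np.log(lam))
            + logdet_xwx
            - logdet_xx
            + dof
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + np.sum(np.log(lam)) + n)
    return -ll, sigma2


def fit_variance_components(
    y: np.ndarray,
    K: np.ndarray,
    X: np.ndarray | None = None,
    reml: bool = True,
) -> VarianceComponents:
    """REML (or ML) fit of sigma_g2 * K + sigma_e2 * I.

    The kinship is rescaled internally to unit mean diagonal so that sigma_g2
    is the additive variance of a typical individual and h2 is the
    per-individual variance fraction (the likelihood is invariant to this
    reparameterization; only the component scale changes).

    With K = I (or any K with all-equal eigenvalues) the two components are
    unidentifiable: the total variance is still recovered but h2 is reported
    as NaN with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 30:
        warnings.warn(f"n = {n} < 30: variance components will be unstable")
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("K dimension does not match y")
    mean_diag = float(np.mean(np.diag(K)))
    if mean_diag <= 0:
        raise ValueError("kinship diagonal must be positive")
    K = K / mean_diag
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        raise ValueError("X rows must match y")

    S, U = np.linalg.eigh(K)
    if np.min(S) < -1e-6:
        raise ValueError("kinship matrix is not positive semidefinite")
    S = np.clip(S, 0.0, None)
    ytr = U.T @ y
    Xtr = U.T @ X

    if np.ptp(S) < 1e-10:
        warnings.warn(
            "kinship has no eigenvalue spread (K ~ scalar * I): "
            "h2 is unidentifiable; reporting total variance only"
        )
        nll, sigma2 = _reml_negloglik(0.0, S, ytr, Xtr, reml)
        return VarianceComponents(
            sigma_g2=np.nan,
            sigma_e2=sigma2,
            h2=np.nan,
            loglik=-nll,
            method="reml" if reml else "ml",
        )

    grid = np.linspace(0.0, 1.0 - 1e-6, 51)
    nlls = [_reml_negloglik(h, S, ytr, Xtr, reml)[0] for h in grid]
    k = int(np.argmin(nlls))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda h: _reml_negloglik(h, S, ytr, Xtr, reml)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x) if res.fun <= nlls[k] else float(grid[k])
    nll, sigma2 = _reml_negloglik(h2, S, ytr, Xtr, reml)
    return VarianceComponents(
        sigma_g2=h2 * sigma2,
        sigma_e2=(1.0 - h2) * sigma2,
        h2=h2,
        loglik=-nll,
        method="reml" if reml else "ml",
    )


def estimate_heritability(
    y: np.ndarray, K: np.ndarray, covariates: np.ndarray | None = None, reml: bool = True
) -> VarianceComponents:
    """Narrow-sense heritability: additive genetic variance over total variance."""
    X = None
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != len(y):
            covariates = covariates.T
        X = np.column_stack([np.ones(len(y)), covariates])
    return fit_variance_components(y, K, X=X, reml=reml)


@dataclass
class AlleleCoding:
    """Additive (0 / 0.5 / 1) and dominant (0 / 1) codings of the focal allele."""

    additive: np.ndarray
    dominant: np.ndarray

    def __post_init__(self) -> None:
        if not np.array_equal(self.dominant, (self.additive > 0).astype(float)):
            raise ValueError("dominant coding must be 1 exactly where additive > 0")


def coding_from_dosage(focal_founder_dosage: np.ndarray) -> AlleleCoding:
    """Round a continuous focal-founder dosage in [0, 2] to genotype codings.

    additive = nearest of {0, 0.5, 1} to dosage / 2 (absent / het / hom);
    dominant = 1 iff at least one estimated copy (additive > 0).
    """
    d = np.asarray(focal_founder_dosage, dtype=float)
    if np.any(d < -1e-8) or np.any(d > 2 + 1e-8):
        raise ValueError("dosages must lie in [0, 2]")
    additive = np.round(np.clip(d, 0, 2))/2.0
    dominant = (additive > 0).astype(float)
    return AlleleCoding(additive=additive, dominant=dominant)


def _ols_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """Maximum log-likelihood of a Gaussian linear model (sigma profiled)."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def dominance_lrt(
    y: np.ndarray,
    coding: AlleleCoding,
    covariates: np.ndarray | None = None,
) -> dict:
    """Likelihood-ratio tests of the general model against each submodel.

    Returns ``p_general_vs_additive`` and ``p_general_vs_dominant`` (chi2,
    1 df, on 2 * delta-loglik) plus the three log-likelihoods.  Small
    ``p_general_vs_additive`` together with large ``p_general_vs_dominant``
    is the signature of a dominant allele.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    add, dom = coding.additive, coding.dominant
    if np.ptp(add) == 0:
        raise ValueError("allele coding is constant across mice")
    if len(np.unique(add)) < 3:
        # dominant is a function of additive: with two genotype classes the
        # general model is not identifiable
        raise ValueError(
            "need all three genotype classes (0 / het / hom) for the general model"
        )
    base = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        base.extend(cov.T)
    X0 = np.column_stack(base)
    ll_add = _ols_loglik(y, np.column_stack([X0, add]))
    ll_dom = _ols_loglik(y, np.column_stack([X0, dom]))
    ll_gen = _ols_loglik(y, np.column_stack([X0, add, dom]))
    return {
        "p_general_vs_additive": float(stats.chi2.sf(2 * (ll_gen - ll_add), df=1)),
        "p_general_vs_dominant": float(stats.chi2.sf(2 * (ll_gen - ll_dom), df=1)),
        "loglik_additive": ll_add,
        "loglik_dominant": ll_dom,
        "loglik_general": ll_gen,
    }
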