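"""Random-intercept GLMMs for binomial and beta responses via a Laplace
approximation to the marginal likelihood.

The model is ``eta = X beta + sum_g Z_g b_g`` with independent Gaussian
random intercepts ``b_g ~ N(0, sigma_g^2 I)`` per grouping factor (factors
may be crossed), a logit link, and either a Bernoulli response or a beta
response with scalar precision phi (mean-precision parametrization:
``y ~ Beta(mu * phi, (1 - mu) * phi)``).

For fixed parameters the random-effect vector is profiled out by an inner
Fisher-scoring optimization of the penalized log-likelihood ``h(b)``, and
the marginal log-likelihood is approximated by

    l = h(b_hat) - 0.5 * [log det D + log det(Z'WZ + D^-1)]

with D the random-effect covariance and W the expected negative second
derivative of the log-likelihood in eta.  The outer optimization over
``(beta, log sigma_g, [log phi])`` uses BFGS with a Nelder-Mead polish;
standard errors come from the numerical Hessian of the marginal
log-likelihood at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.special import expit, gammaln, polygamma, psi


class ConvergenceError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# families: log-likelihood plus first/expected-second derivatives in eta

class _Bernoulli:
    n_extra = 0

    @staticmethod
    def loglik(y, eta, extra):
        # log p = y*eta - log(1 + exp(eta)), numerically stable
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    @staticmethod
    def d1(y, eta, extra):
        return y - expit(eta)

    @staticmethod
    def neg_d2(y, eta, extra):
        mu = expit(eta)
        return np.maximum(mu * (1.0 - mu), 1e-12)


class _Beta:
    """Beta response, logit mean link, scalar log-precision in ``extra``."""

    n_extra = 1

    @staticmethod
    def _moments(eta, extra):
        phi = np.exp(extra[0])
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        return mu, phi

    @classmethod
    def loglik(cls, y, eta, extra):
        mu, phi = cls._moments(eta, extra)
        p, q = mu * phi, (1.0 - mu) * phi
        ll = gammaln(phi) - gammaln(p) - gammaln(q) + (p - 1) * np.log(y) + (q - 1) * np.log1p(-y)
        return float(np.sum(ll))

    @classmethod
    def d1(cls, y, eta, extra):
        mu, phi = cls._moments(eta, extra)
        p, q = mu * phi, (1.0 - mu) * phi
        ystar = np.log(y) - np.log1p(-y)
        return phi * (ystar - psi(p) + psi(q)) * mu * (1.0 - mu)

    @classmethod
    def neg_d2(cls, y, eta, extra):
        # expected information in eta (Fisher scoring)
        mu, phi = cls._moments(eta, extra)
        p, q = mu * phi, (1.0 - mu) * phi
        w = (mu * (1.0 - mu)) ** 2
        return np.maximum(phi**2 * (polygamma(1, p) + polygamma(1, q)) * w, 1e-12)


_FAMILIES = {"binomial": _Bernoulli, "beta": _Beta}


@dataclass
class GLMMFit:
    params: pd.Series            # fixed effects
    bse: pd.Series               # Wald SEs of the fixed effects
    loglik: float                # Laplace marginal log-likelihood
    sigmas: dict                 # random-intercept SDs by grouping factor
    phi: Optional[float]         # beta precision (None for binomial)
    n: int
    family: str
    converged: bool
    grad_norm: float
    ranef: dict = dc_field(default_factory=dict)  # conditional modes by factor

    @property
    def df_model(self) -> int:
        # fixed effects + variance/dispersion parameters
        extra = 0 if self.phi is None else 1
        return len(self.params) + len(self.sigmas) + extra


def _build_z(groups: dict):
    """Indicator matrix per grouping factor; returns (Z, block slices, labels)."""
    blocks, slices, labels = [], {}, {}
    start = 0
    for name, codes in groups.items():
        codes = pd.Categorical(np.asarray(codes))
        q = len(codes.categories)
        z = sparse.csr_matrix(
            (np.ones(len(codes)), (np.arange(len(codes)), codes.codes)), shape=(len(codes), q)
        )
        blocks.append(z)
        slices[name] = slice(start, start + q)
        labels[name] = list(codes.categories)
        start += q
    return sparse.hstack(blocks).tocsr(), slices, labels


def _inner_mode(y, X, Zd, fam, beta, extra, dinv, b0, maxiter=50, tol=1e-10):
    """Fisher-scoring mode of the penalized log-likelihood over b."""
    b = b0.copy()
    xb = X @ beta

    def h(bv):
        eta = xb + Zd @ bv
        return fam.loglik(y, eta, extra) - 0.5 * float(bv @ (dinv * bv))

    h_cur = h(b)
    for _ in range(maxiter):
        eta = xb + Zd @ b
        g = Zd.T @ fam.d1(y, eta, extra) - dinv * b
        w = fam.neg_d2(y, eta, extra)
        H = (Zd * w[:, None]).T @ Zd
        H[np.diag_indices_from(H)] += dinv
        step = np.linalg.solve(H, g)
        # step-halving in case Fisher scoring overshoots
        for _ in range(30):
            b_new = b + step
            h_new = h(b_new)
            if h_new >= h_cur - 1e-12:
                break
            step *= 0.5
        if not np.isfinite(h_new):
            raise ConvergenceError("inner optimization diverged")
        moved = np.max(np.abs(b_new - b))
        b, h_cur = b_new, h_new
        if moved < tol * (1.0 + np.max(np.abs(b))):
            break
    eta = xb + Zd @ b
    w = fam.neg_d2(y, eta, extra)
    H = (Zd * w[:, None]).T @ Zd
    H[np.diag_indices_from(H)] += dinv
    return b, h_cur, H


def _marginal_nll(theta, y, X, Z, slices, fam, state):
    p = X.shape[1]
    n_sig = len(slices)
    beta = theta[:p]
    log_sig = theta[p:p + n_sig]
    extra = theta[p + n_sig:]
    dinv = np.empty(Z.shape[1])
    logdet_d = 0.0
    for (name, sl), ls in zip(slices.items(), log_sig):
        s2 = np.exp(2.0 * np.clip(ls, -8.0, 8.0))
        dinv[sl] = 1.0 / s2
        logdet_d += (sl.stop - sl.start) * np.log(s2)
    try:
        b, h_val, H = _inner_mode(y, X, Z, fam, beta, extra, dinv, state["b"])
    except (ConvergenceError, np.linalg.LinAlgError):
        return 1e10
    state["b"] = b
    sign, logdet_h = np.linalg.slogdet(H)
    if sign <= 0:
        return 1e10
    ll = h_val - 0.5 * (logdet_d + logdet_h)
    if not np.isfinite(ll):
        return 1e10
    return -ll


def fit_glmm(y, X, groups: dict, family: str = "binomial",
             feature_names=None, start=None, grad_tol=1.0, se: bool = True) -> GLMMFit:
    """Fit a logit-link random-intercept mixed model.

    Parameters
    ----------
    y : response (0/1 for ``"binomial"``, open-interval (0,1) for ``"beta"``)
    X : fixed-effect design matrix including the intercept column
    groups : mapping of factor name -> per-row group codes (crossed factors
        allowed; each contributes one random-intercept variance)
    """
    fam = _FAMILIES[family]
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if family == "beta" and ((y <= 0) | (y >= 1)).any():
        raise ValueError("beta responses must lie strictly inside (0, 1); apply a boundary squeeze first")
    if not groups:
        raise ValueError("groups must name at least one random-intercept factor")
    Z, slices, labels = _build_z(groups)
    Z = Z.toarray()  # q is small (tens of levels); dense algebra is faster
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(p)]

    if start is None:
        # moment starts: logit mean response, modest variance components,
        # method-of-moments beta precision
        ybar = min(max(np.mean(y), 1e-3), 1 - 1e-3)
        beta0 = np.zeros(p)
        beta0[0] = np.log(ybar / (1 - ybar))
        extra0 = []
        if fam.n_extra:
            v = max(float(np.var(y)), 1e-8)
            phi0 = max(ybar * (1 - ybar) / v - 1.0, 2.0)
            extra0 = [np.log(phi0)]
        start = np.concatenate([beta0, np.full(len(groups), np.log(0.3)), extra0])
    state = {"b": np.zeros(Z.shape[1])}
    args = (y, X, Z, slices, fam, state)

    res = optimize.minimize(_marginal_nll, start, args=args, method="L-BFGS-B",
                            options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-6})
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    # a flat likelihood near the optimum can leave a loose gradient; polish
    # with a simplex only when the gradient is genuinely large for the scale
    if grad_norm > 1e-2 * (1.0 + abs(res.fun)):
        res2 = optimize.minimize(_marginal_nll, res.x, args=args, method="Nelder-Mead",
                                 options={"maxiter": 150 * len(start), "xatol": 1e-7, "fatol": 1e-9})
        if res2.fun <= res.fun:
            res = res2
        grad_norm = float(np.max(np.abs(optimize.approx_fprime(res.x, _marginal_nll, 1e-6, *args))))
    if grad_norm > grad_tol * (1.0 + abs(res.fun)):
        raise ConvergenceError(f"mixed-model optimization did not converge (max |gradient| = {grad_norm:.3g})")

    theta = res.x
    loglik = -float(res.fun)
    beta = theta[:p]
    log_sig = theta[p:p + len(groups)]
    sigmas = {name: float(np.exp(ls)) for name, ls in zip(groups, log_sig)}
    phi = float(np.exp(theta[p + len(groups)])) if fam.n_extra else None

    # Wald SEs from the numerical Hessian of the marginal nll
    if se:
        from statsmodels.tools.numdiff import approx_hess1

        try:
            hess = approx_hess1(theta, _marginal_nll, args=args)
            cov = np.linalg.pinv(hess)
            bse = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
        except Exception:
            bse = np.full(p, np.nan)
    else:
        bse = np.full(p, np.nan)

    # conditional modes at the optimum
    _marginal_nll(theta, *args)
    ranef = {name: pd.Series(state["b"][sl], index=labels[name]) for name, sl in slices.items()}

    return GLMMFit(
        params=pd.Series(beta, index=feature_names),
        bse=pd.Series(bse, index=feature_names),
        loglik=loglik, sigmas=sigmas, phi=phi, n=len(y), family=family,
        converged=bool(grad_norm <= grad_tol * (1.0 + abs(res.fun))), grad_norm=grad_norm,
        ranef=ranef,
    )
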