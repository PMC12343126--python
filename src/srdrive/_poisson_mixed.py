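"""Maximum-likelihood Poisson random-intercept models via adaptive quadrature.

Two random-effect structures are supported:

* ``vial`` — a single random intercept per cluster; the marginal likelihood
  is a one-dimensional integral per cluster, evaluated with adaptive
  Gauss-Hermite quadrature (mode/curvature rescaling), fully vectorized
  across clusters, with an analytic score.
* ``individual_in_vial`` — individual intercepts nested inside vial
  intercepts; the inner (individual) integrals are adaptive Gauss-Hermite,
  vectorized across individuals, and the outer (vial) integral is adaptive
  on top.  All observations of one individual must share a design row (true
  for the fecundity assay, where covariates are genotype and dose), which
  reduces each individual to sufficient statistics (sum of counts, number
  of counts).

Both paths expose the marginal log-likelihood (up to quadrature error), so
likelihood-ratio tests between nested fits are meaningful.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

_LOG_2PI = float(np.log(2.0 * np.pi))
_SQRT2 = float(np.sqrt(2.0))


def _clip_exp(x):
    return np.exp(np.clip(x, -700.0, 700.0))


class VialOnlyPoissonMixed:
    """Poisson log-link model with one Gaussian random intercept per vial."""

    def __init__(self, y, X, vial_codes, n_quad: int = 15):
        vial_codes = np.asarray(vial_codes)
        order = np.argsort(vial_codes, kind="stable")
        self.y = np.asarray(y, float)[order]
        self.X = np.asarray(X, float)[order]
        _, codes = np.unique(vial_codes[order], return_inverse=True)
        self.starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
        self.n_vials = self.starts.size
        self.n_obs = self.y.size
        self.n_fixed = self.X.shape[1]
        self.A = np.add.reduceat(self.y, self.starts)  # sum of counts per vial
        self.Syx = np.add.reduceat(self.y[:, None] * self.X, self.starts, axis=0)
        self.const = -float(np.sum(gammaln(self.y + 1.0)))
        self.nodes, w = hermgauss(n_quad)
        self.log_w = np.log(w)

    def loglik_and_grad(self, params):
        beta, sigma = params[:-1], params[-1]
        eta = self.X @ beta
        E = _clip_exp(eta)
        T = np.add.reduceat(E, self.starts)
        C = np.add.reduceat(self.y * eta, self.starts)
        SEx = np.add.reduceat(E[:, None] * self.X, self.starts, axis=0)
        A = self.A
        # adaptive centre: Newton on h(z) = C + A s z - T e^{s z} - z^2/2
        z = np.zeros(self.n_vials)
        for _ in range(40):
            ez = _clip_exp(sigma * z)
            g1 = sigma * A - sigma * T * ez - z
            g2 = -sigma * sigma * T * ez - 1.0
            z -= np.clip(g1 / g2, -3.0, 3.0)
        ez = _clip_exp(sigma * z)
        tau = 1.0 / np.sqrt(sigma * sigma * T * ez + 1.0)
        zk = z[:, None] + _SQRT2 * tau[:, None] * self.nodes[None, :]
        ezk = _clip_exp(sigma * zk)
        h = C[:, None] + A[:, None] * sigma * zk - T[:, None] * ezk - 0.5 * zk * zk
        s = h + self.nodes[None, :] ** 2 + self.log_w[None, :]
        lse = logsumexp(s, axis=1)
        ll = float(np.sum(lse + np.log(_SQRT2 * tau) - 0.5 * _LOG_2PI) + self.const)
        # score via quadrature posterior expectations (Fisher identity)
        p = np.exp(s - lse[:, None])
        W = np.sum(p * ezk, axis=1)          # E[e^{sigma z}]
        Ez = np.sum(p * zk, axis=1)          # E[z]
        Eze = np.sum(p * zk * ezk, axis=1)   # E[z e^{sigma z}]
        grad_beta = self.Syx.sum(axis=0) - W @ SEx
        grad_sigma = float(np.sum(A * Ez - T * Eze))
        return ll, np.r_[grad_beta, grad_sigma]

    def loglik(self, params) -> float:
        return self.loglik_and_grad(np.asarray(params, float))[0]

    def _variance_score_at_zero(self, beta) -> float:
        """d loglik / d(sigma^2) at sigma = 0 (the classic score-test limit)."""
        eta = self.X @ beta
        E = _clip_exp(eta)
        T = np.add.reduceat(E, self.starts)
        return float(0.5 * np.sum((self.A - T) ** 2 - T))

    def fit(self, beta0, sigma0: float = 0.3):
        # optimize the variance, not the SD: the score in sigma vanishes
        # identically at the boundary, which strands quasi-Newton steps there
        x0 = np.r_[np.asarray(beta0, float), sigma0 ** 2]
        bounds = [(None, None)] * self.n_fixed + [(0.0, 400.0)]

        def nll(x):
            v = x[-1]
            sigma = np.sqrt(v)
            ll, g = self.loglik_and_grad(np.r_[x[:-1], sigma])
            if sigma < 1e-4:
                g_v = self._variance_score_at_zero(x[:-1])
            else:
                g_v = g[-1] / (2.0 * sigma)
            return -ll, -np.r_[g[:-1], g_v]

        res = minimize(nll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8})
        res.x = np.r_[res.x[:-1], np.sqrt(res.x[-1])]  # report the SD
        return res


class NestedPoissonMixed:
    """Poisson log-link model with individual intercepts nested in vials."""

    def __init__(self, y, X, vial_codes, individual_codes,
                 n_quad_outer: int = 9, n_quad_inner: int = 9):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        vial_codes = np.asarray(vial_codes)
        individual_codes = np.asarray(individual_codes)
        order = np.lexsort((individual_codes, vial_codes))
        y, X = y[order], X[order]
        vial_codes, individual_codes = vial_codes[order], individual_codes[order]
        _, f_codes = np.unique(individual_codes, return_inverse=True)
        f_starts = np.flatnonzero(np.r_[True, f_codes[1:] != f_codes[:-1]])
        sizes = np.diff(np.r_[f_starts, y.size])
        Xf = X[f_starts]
        if np.any(np.abs(X - np.repeat(Xf, sizes, axis=0)) > 1e-9):
            raise ValueError(
                "design rows must be constant within an individual for the "
                "nested random-effect model"
            )
        self.s = np.add.reduceat(y, f_starts)      # sum of counts per individual
        self.m = sizes.astype(float)               # observations per individual
        self.Xf = Xf
        _, self.vcodes = np.unique(vial_codes[f_starts], return_inverse=True)
        self.v_starts = np.flatnonzero(np.r_[True, self.vcodes[1:] != self.vcodes[:-1]])
        self.n_vials = self.v_starts.size
        self.n_ind = self.s.size
        self.n_obs = y.size
        self.n_fixed = X.shape[1]
        self.const = -float(np.sum(gammaln(y + 1.0)))
        self.nodes_o, w_o = hermgauss(n_quad_outer)
        self.log_w_o = np.log(w_o)
        self.nodes_i, w_i = hermgauss(n_quad_inner)
        self.log_w_i = np.log(w_i)

    def _inner(self, eta_u, sigma_id: float):
        """Per-individual log G(u), d/du log G, and curvature proxy.

        ``eta_u``: linear predictor plus vial effect, shape (n_ind,) or
        (n_ind, K); returned arrays have the same shape.
        """
        shape_tail = (1,) * (eta_u.ndim - 1)
        s = self.s.reshape((-1,) + shape_tail)
        m = self.m.reshape((-1,) + shape_tail)
        if sigma_id < 1e-8:
            me = m * _clip_exp(eta_u)
            a = s * eta_u - me
            return a, s - me, -me
        w = np.zeros_like(eta_u)
        inv_v = 1.0 / (sigma_id * sigma_id)
        for _ in range(30):
            me = m * _clip_exp(eta_u + w)
            w -= np.clip((s - me - w * inv_v) / (-me - inv_v), -3.0, 3.0)
        me = m * _clip_exp(eta_u + w)
        tau = 1.0 / np.sqrt(me + inv_v)
        wj = w[..., None] + _SQRT2 * tau[..., None] * self.nodes_i
        ew = _clip_exp(eta_u[..., None] + wj)
        val = s[..., None] * (eta_u[..., None] + wj) - m[..., None] * ew \
            - 0.5 * wj * wj * inv_v
        t = val + self.nodes_i ** 2 + self.log_w_i
        lse = logsumexp(t, axis=-1)
        a = lse + np.log(_SQRT2 * tau) - 0.5 * np.log(2.0 * np.pi / inv_v)
        q = np.exp(t - lse[..., None])
        Eme = np.sum(q * m[..., None] * ew, axis=-1)
        return a, s - Eme, -Eme

    def loglik(self, params) -> float:
        params = np.asarray(params, float)
        beta, sigma_v, sigma_id = params[:-2], params[-2], params[-1]
        eta = self.Xf @ beta
        if sigma_v < 1e-8:
            a, _, _ = self._inner(eta, sigma_id)
            return float(np.sum(a) + self.const)
        # outer adaptive centre per vial: Newton on
        # H(z) = sum_f log G_f(sigma_v z) - z^2/2
        z = np.zeros(self.n_vials)
        for _ in range(25):
            u = sigma_v * z[self.vcodes]
            _, d1, d2 = self._inner(eta + u, sigma_id)
            H1 = sigma_v * np.add.reduceat(d1, self.v_starts) - z
            H2 = sigma_v * sigma_v * np.add.reduceat(d2, self.v_starts) - 1.0
            z -= np.clip(H1 / H2, -3.0, 3.0)
        u = sigma_v * z[self.vcodes]
        _, _, d2 = self._inner(eta + u, sigma_id)
        H2 = sigma_v * sigma_v * np.add.reduceat(d2, self.v_starts) - 1.0
        tau = 1.0 / np.sqrt(-H2)
        zk = z[:, None] + _SQRT2 * tau[:, None] * self.nodes_o[None, :]  # (V,K)
        uk = sigma_v * zk[self.vcodes]                                   # (F,K)
        a, _, _ = self._inner(eta[:, None] + uk, sigma_id)
        H = np.add.reduceat(a, self.v_starts, axis=0) - 0.5 * zk * zk
        t = H + self.nodes_o[None, :] ** 2 + self.log_w_o[None, :]
        lse = logsumexp(t, axis=1)
        return float(np.sum(lse + np.log(_SQRT2 * tau) - 0.5 * _LOG_2PI) + self.const)

    def fit(self, beta0, sigma_v0: float = 0.3, sigma_id0: float = 0.1):
        # variance parametrization keeps finite-difference gradients
        # informative at the sigma = 0 boundary (see VialOnlyPoissonMixed.fit)
        x0 = np.r_[np.asarray(beta0, float), sigma_v0 ** 2, sigma_id0 ** 2]
        bounds = [(None, None)] * self.n_fixed + [(0.0, 400.0), (0.0, 400.0)]

        def nll(x):
            return -self.loglik(np.r_[x[:-2], np.sqrt(x[-2]), np.sqrt(x[-1])])

        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300, "ftol": 1e-11})
        res.x = np.r_[res.x[:-2], np.sqrt(res.x[-2]), np.sqrt(res.x[-1])]
        return res


def numerical_hessian(f, x, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar ``f`` at ``x``."""
    x = np.asarray(x, float)
    n = x.size
    h = np.maximum(step, step * np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H
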