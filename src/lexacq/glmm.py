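"""Maximum-likelihood logistic GLMM via the Laplace approximation.

The model is a binomial-logit mixed model with one grouping factor
(words) and a low-dimensional random-effect vector per group — here a
random intercept and a random age slope,

    y_i ~ Binomial(n_i, logistic(x_i' beta + z_i' b_{g(i)})),
    b_g ~ N(0, Sigma),   Sigma 2x2 (or 1x1), possibly with correlation.

Fitting is organised like lme4's nAGQ=1 path:

* **inner loop** — for fixed Sigma, a penalized IRLS finds the joint
  mode of (beta, b).  The Newton system is solved exactly by a Schur
  complement: the random-effect block is block-diagonal (one q x q
  block per group, q <= 2), so each iteration costs one p x p solve
  plus vectorized per-group 2x2 inversions.
* **outer loop** — Nelder-Mead over the variance parameters
  (log SDs, atanh correlation), maximizing the Laplace-approximate
  log-likelihood

      ll(theta) = loglik(y | beta_hat, b_hat)
                  - 1/2 sum_g b_hat_g' Sigma^-1 b_hat_g
                  - 1/2 sum_g log det(I + Sigma G_g),

  where G_g is the conditional-likelihood Hessian of group g at the
  mode.  The inner state is warm-started between outer evaluations.

Wald standard errors for beta come from the fixed-effect block of the
inverse joint Hessian at the optimum (conditional on theta_hat), as in
lme4.  Binomial rows may carry arbitrary positive trial counts, so
Bernoulli data aggregated into (successes, trials) cells fit exactly
the same likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

_LOG_SD_MIN, _LOG_SD_MAX = np.log(1e-4), np.log(20.0)


class GLMMError(RuntimeError):
    pass


class SeparationError(GLMMError):
    """Quasi-complete separation: some fixed effect diverges."""


class ConvergenceError(GLMMError):
    pass


@dataclass
class GLMMResult:
    beta: np.ndarray
    se: np.ndarray                 # small-sample corrected (see df_resid)
    vcov: np.ndarray               # uncorrected, conditional on theta_hat
    random_sd: np.ndarray          # SD per random-effect dimension
    random_corr: float             # correlation (0.0 when q == 1 or fixed)
    random_effects: np.ndarray     # posterior modes, n_groups x q
    loglik: float
    converged: bool
    n_outer_evals: int
    df_resid: int                  # groups minus between-group fixed effects
    colnames: list[str] | None = None

    @property
    def zvalues(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.zvalues), self.df_resid)


def _sigma_from_params(params: np.ndarray, q: int,
                       estimate_corr: bool) -> np.ndarray:
    sds = np.exp(params[:q])
    if q == 1:
        return np.array([[sds[0] ** 2]])
    rho = np.tanh(params[q]) if estimate_corr else 0.0
    return np.array([[sds[0] ** 2, rho * sds[0] * sds[1]],
                     [rho * sds[0] * sds[1], sds[1] ** 2]])


class _LaplaceFitter:
    def __init__(self, X, successes, trials, Z, group, n_groups):
        self.X = X
        self.y = successes
        self.n = trials
        self.Z = Z
        self.q = Z.shape[1]
        self.p = X.shape[1]
        self.n_groups = n_groups
        # rows are pre-sorted by group; reduceat boundaries
        self.starts = np.searchsorted(group, np.arange(n_groups))
        self.beta = np.zeros(self.p)
        # start the intercept-ish column at the empirical logit
        pbar = float(self.y.sum() / self.n.sum())
        pbar = min(max(pbar, 1e-6), 1 - 1e-6)
        const = np.all(X == X[0, :], axis=0) & (X[0, :] != 0)
        if const.any():
            self.beta[np.argmax(const)] = special.logit(pbar) / X[0, np.argmax(const)]
        self.b = np.zeros((n_groups, self.q))

    def _gsum(self, v: np.ndarray) -> np.ndarray:
        return np.add.reduceat(v, self.starts, axis=0)

    def _eta(self, beta, b):
        return self.X @ beta + np.einsum("ij,ij->i", self.Z,
                                         b[self.group_of_row])

    def set_group_rows(self, group):
        self.group_of_row = group

    def _penalized_nll(self, beta, b, Sinv):
        eta = self._eta(beta, b)
        # binomial log-likelihood without the constant binomial coefficient
        ll = float(self.y @ eta - self.n @ np.logaddexp(0.0, eta))
        pen = 0.5 * float(np.einsum("gi,ij,gj->", b, Sinv, b))
        return -ll + pen

    def inner(self, Sigma, max_iter=80, tol=1e-9):
        """Penalized IRLS to the joint (beta, b) mode at fixed Sigma."""
        Sinv = np.linalg.inv(Sigma)
        beta, b = self.beta.copy(), self.b.copy()
        f = self._penalized_nll(beta, b, Sinv)
        X, Z, yv, nv = self.X, self.Z, self.y, self.n
        for _ in range(max_iter):
            eta = self._eta(beta, b)
            mu = special.expit(eta)
            w = nv * mu * (1.0 - mu) + 1e-12
            r = yv - nv * mu

            E = X * w[:, None]
            XtWX = X.T @ E
            U = np.stack([self._gsum(E * Z[:, k:k + 1])
                          for k in range(self.q)], axis=2)   # G x p x q
            G = np.empty((self.n_groups, self.q, self.q))
            for k in range(self.q):
                for l in range(k, self.q):
                    G[:, k, l] = G[:, l, k] = self._gsum(w * Z[:, k] * Z[:, l])
            gb = np.stack([self._gsum(r * Z[:, k])
                           for k in range(self.q)], axis=1) - b @ Sinv
            gbeta = X.T @ r

            D = G + Sinv[None, :, :]
            Dinv = np.linalg.inv(D)
            S = XtWX - np.einsum("gpk,gkl,gql->pq", U, Dinv, U)
            rhs = gbeta - np.einsum("gpk,gkl,gl->p", U, Dinv, gb)
            try:
                dbeta = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError as exc:
                raise SeparationError(
                    "singular fixed-effect system (separation or rank "
                    "deficiency)") from exc
            db = np.einsum("gkl,gl->gk", Dinv,
                           gb - np.einsum("gpk,p->gk", U, dbeta))

            step = 1.0
            for _ in range(30):
                beta_new = beta + step * dbeta
                b_new = b + step * db
                f_new = self._penalized_nll(beta_new, b_new, Sinv)
                if f_new <= f + 1e-12:
                    break
                step *= 0.5
            grad_norm = max(np.abs(gbeta).max(initial=0.0),
                            np.abs(gb).max(initial=0.0))
            improve = f - f_new
            beta, b, f = beta_new, b_new, f_new
            if improve < tol * (abs(f) + 1.0) and grad_norm < 1e-4 * (
                    self.n.sum() / 100 + 1.0):
                break
        self.beta, self.b = beta, b
        # Laplace correction: log det(I + Sigma G_g) at the mode
        eta = self._eta(beta, b)
        mu = special.expit(eta)
        w = nv * mu * (1.0 - mu)
        G = np.empty((self.n_groups, self.q, self.q))
        for k in range(self.q):
            for l in range(k, self.q):
                G[:, k, l] = G[:, l, k] = self._gsum(w * Z[:, k] * Z[:, l])
        M = np.eye(self.q)[None, :, :] + Sigma[None, :, :] @ G
        sign, logdet = np.linalg.slogdet(M)
        if np.any(sign <= 0):
            raise ConvergenceError("non-positive Laplace determinant")
        ll = float(yv @ eta - nv @ np.logaddexp(0.0, eta))
        pen = 0.5 * float(np.einsum("gi,ij,gj->", b, Sinv, b))
        laplace_ll = ll - pen - 0.5 * float(logdet.sum())
        return laplace_ll

    def fixed_effect_vcov(self, Sigma):
        """beta block of the inverse joint Hessian at the current mode."""
        Sinv = np.linalg.inv(Sigma)
        X, Z = self.X, self.Z
        eta = self._eta(self.beta, self.b)
        mu = special.expit(eta)
        w = self.n * mu * (1.0 - mu) + 1e-12
        E = X * w[:, None]
        XtWX = X.T @ E
        U = np.stack([self._gsum(E * Z[:, k:k + 1])
                      for k in range(self.q)], axis=2)
        G = np.empty((self.n_groups, self.q, self.q))
        for k in range(self.q):
            for l in range(k, self.q):
                G[:, k, l] = G[:, l, k] = self._gsum(w * Z[:, k] * Z[:, l])
        Dinv = np.linalg.inv(G + Sinv[None, :, :])
        S = XtWX - np.einsum("gpk,gkl,gql->pq", U, Dinv, U)
        vcov = np.linalg.inv(S)
        if np.any(np.diag(vcov) <= 0):
            raise ConvergenceError(
                "fixed-effect information matrix is not positive definite "
                "(near-singular design or boundary fit)")
        return vcov


def fit_logistic_glmm(X: np.ndarray, successes: np.ndarray,
                      trials: np.ndarray, group: np.ndarray,
                      Z: np.ndarray | None = None,
                      estimate_corr: bool = True,
                      start_sd: tuple[float, ...] = (0.3, 0.1),
                      colnames: list[str] | None = None,
                      xatol: float = 2e-3, fatol: float = 1e-4,
                      max_outer: int = 400) -> GLMMResult:
    """Fit the binomial-logit mixed model; see module docstring.

    Parameters
    ----------
    X : fixed-effect design, n_rows x p.
    successes, trials : binomial cell counts per row (use trials of 1
        for Bernoulli rows).
    group : integer group (word) index per row.
    Z : random-effect covariates per row, n_rows x q (default: a
        column of ones, i.e. random intercepts only).
    estimate_corr : estimate the intercept-slope correlation (q == 2).
    """
    X = np.asarray(X, dtype=float)
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    group = np.asarray(group)
    if Z is None:
        Z = np.ones((X.shape[0], 1))
    Z = np.asarray(Z, dtype=float)
    if np.any((successes < 0) | (successes > trials)):
        raise ValueError("successes must lie in [0, trials]")
    uniq = np.unique(group)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups (words)")
    # densify group codes and sort rows by group
    codes = np.searchsorted(uniq, group)
    order = np.argsort(codes, kind="stable")
    fitter = _LaplaceFitter(X[order], successes[order], trials[order],
                            Z[order], codes[order], uniq.size)
    fitter.set_group_rows(codes[order])

    q = Z.shape[1]
    n_params = q + (1 if (q == 2 and estimate_corr) else 0)
    x0 = np.array([np.log(s) for s in start_sd[:q]] +
                  ([0.0] if n_params > q else []))
    bounds = [( _LOG_SD_MIN, _LOG_SD_MAX)] * q + \
             ([(-3.0, 3.0)] if n_params > q else [])
    n_evals = 0

    def objective(params):
        nonlocal n_evals
        n_evals += 1
        Sigma = _sigma_from_params(params, q, estimate_corr)
        return -fitter.inner(Sigma)

    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            bounds=bounds,
                            options={"xatol": xatol, "fatol": fatol,
                                     "maxfev": max_outer})
    Sigma = _sigma_from_params(res.x, q, estimate_corr)
    loglik = fitter.inner(Sigma)
    vcov = fitter.fixed_effect_vcov(Sigma)
    beta = fitter.beta
    if np.any(np.abs(beta) > 30):
        raise SeparationError(
            "fixed effect exceeds 30 on the logit scale; data are "
            "(quasi-)separated")
    if not res.success and res.status != 2:  # status 2: maxfev hit
        raise ConvergenceError(f"variance optimization failed: {res.message}")

    sds = np.exp(res.x[:q])
    corr = float(np.tanh(res.x[q])) if n_params > q else 0.0
    b = fitter.b

    # Small-sample correction for Wald inference.  The conditional
    # covariance S^-1 ignores (i) the ML downward bias of the variance
    # components (no REML exists for this model) and (ii) their
    # sampling uncertainty, so tests on group-level (word-level)
    # effects run anticonservative when the number of groups is modest.
    # Between-within remedy: count the fixed effects that carry
    # group-level information (no within-group variation), set
    # df = n_groups - n_between, scale SEs by sqrt(n_groups / df) (the
    # REML-analog degrees-of-freedom adjustment of the dominant
    # variance term) and refer Wald statistics to t_df.
    Xs, codes_s = X[order], codes[order]
    starts = np.searchsorted(codes_s, np.arange(uniq.size))
    gmeans = np.add.reduceat(Xs, starts, axis=0) / \
        np.diff(np.append(starts, len(Xs)))[:, None]
    within_var = np.add.reduceat((Xs - gmeans[codes_s]) ** 2, starts,
                                 axis=0).sum(axis=0)
    scale = np.mean(Xs ** 2, axis=0) + 1e-12
    n_between = int(np.sum(within_var / (len(Xs) * scale) < 1e-10))
    df_resid = max(uniq.size - n_between, 1)
    se = np.sqrt(np.diag(vcov)) * np.sqrt(uniq.size / df_resid)

    return GLMMResult(beta=beta, se=se, vcov=vcov,
                      random_sd=sds, random_corr=corr, random_effects=b,
                      loglik=float(loglik), converged=bool(res.success),
                      n_outer_evals=n_evals, df_resid=df_resid,
                      colnames=colnames)
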