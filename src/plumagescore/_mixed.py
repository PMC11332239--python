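"""Mixed-model engine: Laplace-approximate ML for beta and Gaussian GLMMs.

The model is

    eta = X beta + sum_k Z_k b_k,   b_k ~ N(0, sigma_k^2 I)

with either a beta response, ``y ~ Beta(mu * phi, (1 - mu) * phi)`` with
``mu = logit^{-1}(eta)`` and constant precision phi, or a Gaussian response
``y ~ N(eta, sigma_e^2)``.

Estimation follows the standard two-level scheme: for fixed variance
parameters theta = (log sigma_k^2, log dispersion), an inner penalized
Fisher-scoring loop finds the joint mode of (beta, b); the marginal
likelihood is then the Laplace approximation around that mode (exact for
the Gaussian family), and an outer quasi-Newton (L-BFGS-B) search maximizes
it over theta.  Profiling beta into the inner loop keeps the outer problem
tiny and is the same device lme4 uses for its fast GLMM deviance.

Wald covariance for beta comes from the (beta, b) block of the joint
information at the optimum, i.e. conditional on the estimated variance
parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import digamma, expit, gammaln, ndtri, polygamma
from scipy.stats import beta as beta_dist
from scipy.stats import norm as norm_dist

logger = logging.getLogger(__name__)

__all__ = ["MixedModel", "MixedFit", "BetaFamily", "GaussianFamily"]

_Z95 = 1.959963984540054


class BetaFamily:
    """Beta response with logit link and constant precision phi."""

    name = "beta"
    #: starting log-dispersion is replaced by a method-of-moments value
    default_log_dispersion = np.log(10.0)

    @staticmethod
    def check_response(y: np.ndarray) -> None:
        if np.any((y <= 0.0) | (y >= 1.0)):
            raise ValueError(
                "beta responses must lie strictly in (0, 1); "
                "apply a boundary squeeze to values touching 0 or 1"
            )

    @staticmethod
    def mean(eta: np.ndarray) -> np.ndarray:
        return expit(eta)

    @staticmethod
    def loglik(y: np.ndarray, eta: np.ndarray, phi: float) -> np.ndarray:
        mu = expit(eta)
        a, b = mu * phi, (1.0 - mu) * phi
        return (gammaln(phi) - gammaln(a) - gammaln(b)
                + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))

    @staticmethod
    def eta_score(y: np.ndarray, eta: np.ndarray, phi: float) -> np.ndarray:
        mu = expit(eta)
        ystar = np.log(y) - np.log1p(-y)
        mustar = digamma(mu * phi) - digamma((1.0 - mu) * phi)
        return phi * (ystar - mustar) * mu * (1.0 - mu)

    @staticmethod
    def eta_weight(y: np.ndarray, eta: np.ndarray, phi: float) -> np.ndarray:
        # expected information w.r.t. eta; strictly positive
        mu = expit(eta)
        return (phi ** 2) * (polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi)) * (mu * (1.0 - mu)) ** 2

    @staticmethod
    def moment_dispersion(y: np.ndarray) -> float:
        m, v = float(np.mean(y)), float(np.var(y))
        if v <= 0:
            return 50.0
        return float(np.clip(m * (1.0 - m) / v - 1.0, 2.0, 1e4))

    @staticmethod
    def quantile_residuals(y: np.ndarray, eta: np.ndarray, phi: float,
                           rng: np.random.Generator | None = None) -> np.ndarray:
        mu = expit(eta)
        u = beta_dist.cdf(y, mu * phi, (1.0 - mu) * phi)
        return ndtri(np.clip(u, 1e-12, 1 - 1e-12))


class GaussianFamily:
    """Gaussian response with identity link; dispersion is the residual variance."""

    name = "gaussian"
    default_log_dispersion = 0.0

    @staticmethod
    def check_response(y: np.ndarray) -> None:
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")

    @staticmethod
    def mean(eta: np.ndarray) -> np.ndarray:
        return eta

    @staticmethod
    def loglik(y: np.ndarray, eta: np.ndarray, s2: float) -> np.ndarray:
        return -0.5 * ((y - eta) ** 2 / s2 + np.log(2.0 * np.pi * s2))

    @staticmethod
    def eta_score(y: np.ndarray, eta: np.ndarray, s2: float) -> np.ndarray:
        return (y - eta) / s2

    @staticmethod
    def eta_weight(y: np.ndarray, eta: np.ndarray, s2: float) -> np.ndarray:
        return np.full(len(y), 1.0 / s2)

    @staticmethod
    def moment_dispersion(y: np.ndarray) -> float:
        return float(max(np.var(y), 1e-8))

    @staticmethod
    def quantile_residuals(y: np.ndarray, eta: np.ndarray, s2: float,
                           rng: np.random.Generator | None = None) -> np.ndarray:
        return (y - eta) / np.sqrt(s2)


_FAMILIES = {"beta": BetaFamily, "gaussian": GaussianFamily}


@dataclass
class MixedFit:
    """Result of a mixed-model fit."""

    terms: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    variance_components: dict[str, float]  # sigma_k^2 per grouping factor
    dispersion: float  # beta precision phi, or Gaussian residual variance
    loglik: float
    converged: bool
    n_obs: int
    family: str
    blups: dict[str, pd.Series] = field(default_factory=dict)
    fitted_eta: np.ndarray | None = None
    message: str = ""

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "estimate": self.coefficients,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_values,
        })


class MixedModel:
    """Beta or Gaussian GLMM with independent random intercepts.

    Parameters
    ----------
    X : (n, p) dense design matrix including the intercept column.
    y : (n,) response.
    groups : ordered mapping {factor name -> (n,) label array}; each factor
        contributes one random intercept per distinct label.
    family : 'beta' or 'gaussian'.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 groups: dict[str, np.ndarray] | None = None,
                 family: str = "beta",
                 terms: list[str] | None = None) -> None:
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.y = np.asarray(y, dtype=float)
        self.n, self.p = self.X.shape
        if len(self.y) != self.n:
            raise ValueError("X and y disagree on n")
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("design matrix is rank deficient")
        self.family = _FAMILIES[family]
        self.family.check_response(self.y)
        self.terms = list(terms) if terms is not None else [f"x{j}" for j in range(self.p)]

        self.factor_names: list[str] = []
        self.factor_levels: dict[str, np.ndarray] = {}
        zs = []
        for name, labels in (groups or {}).items():
            labels = np.asarray(labels)
            if len(labels) != self.n:
                raise ValueError(f"grouping factor '{name}' has wrong length")
            levels, codes = np.unique(labels, return_inverse=True)
            self.factor_names.append(name)
            self.factor_levels[name] = levels
            zs.append(sparse.csr_matrix(
                (np.ones(self.n), (np.arange(self.n), codes)),
                shape=(self.n, len(levels))))
        self.q_sizes = [z.shape[1] for z in zs]
        self.q = int(sum(self.q_sizes))
        blocks = [sparse.csr_matrix(self.X)] + zs
        self.A = sparse.hstack(blocks, format="csr")
        self._u = np.zeros(self.p + self.q)  # warm start across outer evals

    # -- inner problem -----------------------------------------------------

    def _penalty_diag(self, sig2: np.ndarray) -> np.ndarray:
        pen = np.zeros(self.p + self.q)
        off = self.p
        for size, s2 in zip(self.q_sizes, sig2):
            pen[off:off + size] = 1.0 / s2
            off += size
        return pen

    def _pen_obj(self, u: np.ndarray, pen: np.ndarray, disp: float) -> float:
        eta = self.A @ u
        return float(np.sum(self.family.loglik(self.y, eta, disp)) - 0.5 * np.sum(pen * u * u))

    def _inner(self, pen: np.ndarray, disp: float, tol: float = 1e-12,
               max_iter: int = 200):
        """Penalized Fisher scoring for u = (beta, b) at fixed theta.

        Returns (u, H_lu, logdet_H, converged) where H is the joint
        information A' W A + diag(pen) at the mode.
        """
        u = self._u.copy()
        f = self._pen_obj(u, pen, disp)
        lu = None
        for _ in range(max_iter):
            eta = self.A @ u
            g = self.A.T @ self.family.eta_score(self.y, eta, disp) - pen * u
            w = self.family.eta_weight(self.y, eta, disp)
            AW = self.A.multiply(w[:, None])
            H = (self.A.T @ AW).tocsc() + sparse.diags(pen, format="csc")
            lu = splu(H)
            step = lu.solve(g)
            t = 1.0
            for _ in range(40):
                f_new = self._pen_obj(u + t * step, pen, disp)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            u = u + t * step
            improved = f_new - f
            f = f_new
            if np.max(np.abs(g)) < tol * (1.0 + abs(f)) or improved < 1e-12 * (1.0 + abs(f)):
                break
        eta = self.A @ u
        w = self.family.eta_weight(self.y, eta, disp)
        AW = self.A.multiply(w[:, None])
        H = (self.A.T @ AW).tocsc() + sparse.diags(pen, format="csc")
        lu = splu(H)
        self._u = u
        return u, lu, H, f

    def _laplace_negloglik(self, x: np.ndarray) -> float:
        sig2 = np.exp(x[:len(self.q_sizes)])
        disp = float(np.exp(x[-1]))
        pen = self._penalty_diag(sig2)
        u, lu, H, f_pen = self._inner(pen, disp)
        if self.q == 0:
            return -f_pen
        # logdet of the random-effect block of H
        Hbb = H[self.p:, self.p:].tocsc()
        lub = splu(Hbb)
        logdet_Hbb = float(np.sum(np.log(np.abs(lub.U.diagonal()))))
        logdet_D = float(sum(size * np.log(s2) for size, s2 in zip(self.q_sizes, sig2)))
        return -(f_pen - 0.5 * (logdet_Hbb + logdet_D))

    # -- fitting -----------------------------------------------------------

    def fit(self, start_sig2: float = 0.1, maxiter: int = 200) -> MixedFit:
        k = len(self.q_sizes)
        y0 = self.y
        x0 = np.concatenate([
            np.full(k, np.log(start_sig2)),
            [np.log(self.family.moment_dispersion(y0))],
        ])
        bounds = [(-12.0, 5.0)] * k + [(-8.0, 12.0)]
        self._u = np.zeros(self.p + self.q)
        # the objective is evaluated through an iterative inner solve, so
        # the finite-difference step must sit well above the inner noise
        opts = {"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9, "eps": 1e-5}
        res = minimize(self._laplace_negloglik, x0, method="L-BFGS-B", bounds=bounds,
                       options=opts)
        # polish: restart once from the optimum with a smaller step
        res2 = minimize(self._laplace_negloglik, res.x, method="L-BFGS-B", bounds=bounds,
                        options={**opts, "eps": 1e-6})
        if res2.fun <= res.fun:
            res = res2
        x = res.x
        sig2 = np.exp(x[:k])
        disp = float(np.exp(x[-1]))
        pinned = sig2 <= np.exp(-12.0) * 1.01
        if np.any(pinned):
            for name, flag in zip(self.factor_names, pinned):
                if flag:
                    logger.warning("variance component for '%s' pinned at ~0 (singular fit)", name)
        sig2 = np.where(pinned, 0.0, sig2)
        loglik = -self._laplace_negloglik(x)
        u = self._u
        beta = u[:self.p]
        eta = self.A @ u

        cov_beta = self._beta_covariance(x)
        se = np.sqrt(np.diag(cov_beta))
        zstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
        pvals = 2.0 * norm_dist.sf(np.abs(zstat))

        blups: dict[str, pd.Series] = {}
        off = self.p
        for name, size in zip(self.factor_names, self.q_sizes):
            blups[name] = pd.Series(u[off:off + size], index=self.factor_levels[name])
            off += size

        converged = bool(res.success)
        if not converged:
            logger.warning("outer optimizer did not report convergence: %s", res.message)
        return MixedFit(
            terms=self.terms,
            coefficients=beta,
            se=se,
            ci_low=beta - _Z95 * se,
            ci_high=beta + _Z95 * se,
            p_values=pvals,
            variance_components={n: float(s) for n, s in zip(self.factor_names, sig2)},
            dispersion=disp,
            loglik=float(loglik),
            converged=converged,
            n_obs=self.n,
            family=self.family.name,
            blups=blups,
            fitted_eta=np.asarray(eta),
            message=str(res.message),
        )

    def _beta_covariance(self, x: np.ndarray) -> np.ndarray:
        sig2 = np.exp(x[:len(self.q_sizes)])
        disp = float(np.exp(x[-1]))
        pen = self._penalty_diag(sig2)
        u = self._u
        eta = self.A @ u
        w = self.family.eta_weight(self.y, eta, disp)
        AW = self.A.multiply(w[:, None])
        H = (self.A.T @ AW).tocsc() + sparse.diags(pen, format="csc")
        if self.q == 0:
            return np.linalg.inv(H.toarray())
        Hbb = H[self.p:, self.p:].tocsc()
        Hxb = H[:self.p, self.p:].toarray()
        Hxx = H[:self.p, :self.p].toarray()
        lub = splu(Hbb)
        S = Hxx - Hxb @ lub.solve(Hxb.T)
        return np.linalg.inv(S)

    def quantile_residuals(self, fit: MixedFit) -> np.ndarray:
        """Randomized quantile residuals at the fitted conditional means."""
        return self.family.quantile_residuals(self.y, fit.fitted_eta, fit.dispersion)
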