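"""Penalized Gaussian linear mixed models.

A single solver serves every additive model in the package:

    y = X beta + sum_k Z_k b_k + eps,
    b_k ~ N(0, tau_k^2 I),  eps ~ N(0, sigma^2 I),

where the ``Z_k`` blocks are either (a) the range space of a penalized
cubic P-spline basis — so spline smoothing with REML/ML smoothness
selection is the standard mixed-model representation of a penalized
regression spline — or (b) indicator/slope matrices of nested taxonomic
groups (random intercepts and random slopes).

The variance ratios ``gamma_k = tau_k^2 / sigma^2`` are estimated by
numerically maximising the profiled REML or ML likelihood; ``beta`` and
``sigma^2`` are profiled out in closed form.  Two algebraically equivalent
evaluation paths keep each objective evaluation cheap: an observation-side
path (Cholesky of the n x n marginal correlation) when n is small, and a
coefficient-side Woodbury path (q x q) when the total random dimension q is
smaller than n — the latter makes the per-iteration cost independent of n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy import optimize
from scipy.interpolate import BSpline

from .errors import DegenerateModelError

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)
_BOUNDS = (-12.0, 12.0)  # bounds on log(gamma); exp(-12) is numerically zero


# ---------------------------------------------------------------------------
# P-spline basis
# ---------------------------------------------------------------------------

@dataclass
class PSplineBasis:
    """Cubic B-spline basis with a second-order difference penalty.

    The penalty null space {1, x} is carried by the fixed effects (intercept
    plus a linear column), and the penalised range space is whitened into an
    i.i.d. random-effect block via the eigendecomposition of the penalty.
    """

    knots: np.ndarray        # full (padded) knot vector
    degree: int
    transform: np.ndarray    # k x (k - 2) map from whitened coefs to B-spline coefs
    x_lo: float
    x_hi: float

    @classmethod
    def build(cls, x: np.ndarray, k: int = 10, degree: int = 3) -> "PSplineBasis":
        if k < 4:
            raise DegenerateModelError("spline basis dimension must be >= 4")
        x_lo, x_hi = float(np.min(x)), float(np.max(x))
        if x_hi <= x_lo:
            raise DegenerateModelError("smooth covariate is constant")
        n_inner = k - degree + 1
        inner = np.linspace(x_lo, x_hi, n_inner)
        step = inner[1] - inner[0]
        knots = np.concatenate(
            [x_lo - step * np.arange(degree, 0, -1), inner,
             x_hi + step * np.arange(1, degree + 1)]
        )
        D2 = np.diff(np.eye(k), n=2, axis=0)
        S = D2.T @ D2
        d, U = np.linalg.eigh(S)
        pos = d > d[-1] * 1e-10
        transform = U[:, pos] / np.sqrt(d[pos])
        return cls(knots=knots, degree=degree, transform=transform, x_lo=x_lo, x_hi=x_hi)

    def design(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.x_lo, self.x_hi)
        B = BSpline.design_matrix(xc, self.knots, self.degree).toarray()
        return B

    def range_design(self, x: np.ndarray) -> np.ndarray:
        """Design of the whitened, penalised part (n x (k - 2))."""
        return self.design(x) @ self.transform


# ---------------------------------------------------------------------------
# Random-effect blocks
# ---------------------------------------------------------------------------

@dataclass
class RandomBlock:
    """One i.i.d. random-effect block with a single variance ratio."""

    name: str
    Z: np.ndarray
    kind: str = "random"   # "smooth" | "intercept" | "slope"
    scale: float = 1.0     # divide sqrt(tau^2) by this to report original units


@dataclass
class PLMMFit:
    method: str
    converged: bool
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list[str]
    b: np.ndarray
    block_slices: dict[str, slice]
    blocks: list[RandomBlock]
    gamma: dict[str, float]
    sigma2: float
    loglik: float
    loglik_ml: float
    aic: float
    edf_fixed: float
    edf_blocks: dict[str, float]
    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float
    n_obs: int
    y: np.ndarray
    theta_cov: np.ndarray = field(repr=False, default=None)

    @property
    def edf_total(self) -> float:
        return self.edf_fixed + sum(self.edf_blocks.values())

    def tau2(self, name: str) -> float:
        return self.gamma[name] * self.sigma2


class PLMM:
    """Profiled-likelihood fitter for the penalized Gaussian LMM."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        blocks: list[RandomBlock],
        fixed_names: list[str] | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.blocks = blocks
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise DegenerateModelError("fewer observations than fixed-effect columns")
        self.fixed_names = fixed_names or [f"x{j}" for j in range(self.p)]
        self.q_sizes = [blk.Z.shape[1] for blk in blocks]
        self.q = int(sum(self.q_sizes))
        self._col_block = np.repeat(np.arange(len(blocks)), self.q_sizes)
        self.Z = (
            np.concatenate([blk.Z for blk in blocks], axis=1)
            if blocks else np.zeros((self.n, 0))
        )
        self._use_q_path = self.q <= self.n
        if self._use_q_path:
            self._ZtZ = self.Z.T @ self.Z
            self._XtZ = self.X.T @ self.Z
            self._Zty = self.Z.T @ self.y
        else:
            self._K = [blk.Z @ blk.Z.T for blk in blocks]
        self._XtX = self.X.T @ self.X
        self._Xty = self.X.T @ self.y
        self._yty = float(self.y @ self.y)

    # -- likelihood -------------------------------------------------------

    def _core(self, gamma: np.ndarray):
        """Return (logdet V0, XtVX, XtVy, ytVy) for unit-variance V0."""
        if self.q == 0:
            return 0.0, self._XtX, self._Xty, self._yty
        if self._use_q_path:
            g = np.sqrt(gamma[self._col_block])
            M = np.eye(self.q) + (g[:, None] * self._ZtZ) * g[None, :]
            cf = sla.cho_factor(M, lower=True, check_finite=False)
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            W = np.concatenate([self._XtZ * g[None, :], (self._Zty * g)[None, :]])
            Sol = sla.cho_solve(cf, W.T, check_finite=False).T
            corr = Sol @ W.T
            XtVX = self._XtX - corr[: self.p, : self.p]
            XtVy = self._Xty - corr[: self.p, -1]
            ytVy = self._yty - corr[-1, -1]
            return logdet, XtVX, XtVy, ytVy
        V0 = np.eye(self.n)
        for gk, K in zip(gamma, self._K):
            V0 += gk * K
        cf = sla.cho_factor(V0, lower=True, check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        W = np.column_stack([self.X, self.y])
        Sol = sla.cho_solve(cf, W, check_finite=False)
        G = W.T @ Sol
        return logdet, G[: self.p, : self.p], G[: self.p, -1], float(G[-1, -1])

    def _neg2ll(self, loggamma: np.ndarray, method: str) -> float:
        gamma = np.exp(np.clip(loggamma, *_BOUNDS))
        logdet, XtVX, XtVy, ytVy = self._core(gamma)
        try:
            beta = sla.solve(XtVX, XtVy, assume_a="pos", check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf
        rss = max(float(ytVy - XtVy @ beta), 1e-300)
        if method == "ML":
            sig2 = rss / self.n
            val = self.n * (_LOG_2PI + np.log(sig2) + 1.0) + logdet
        else:
            dof = self.n - self.p
            sig2 = rss / dof
            sign, ld_xvx = np.linalg.slogdet(XtVX)
            if sign <= 0:
                return np.inf
            val = dof * (_LOG_2PI + np.log(sig2) + 1.0) + logdet + ld_xvx
        return float(val) if np.isfinite(val) else np.inf

    def _optimize(self, method: str, start: np.ndarray):
        if self.q == 0 or len(self.blocks) == 0:
            return np.zeros(0), True
        res = optimize.minimize(
            self._neg2ll, start, args=(method,), method="L-BFGS-B",
            bounds=[_BOUNDS] * len(self.blocks),
        )
        best = res
        if not res.success:
            res2 = optimize.minimize(
                self._neg2ll, res.x, args=(method,), method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
            )
            if res2.fun <= res.fun:
                best = res2
        return np.clip(best.x, *_BOUNDS), bool(best.success)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        method: str = "REML",
        start_loggamma: float | np.ndarray = -1.0,
        fixed_loggamma: np.ndarray | None = None,
    ) -> PLMMFit:
        """Estimate variance ratios by REML (default) or ML, then assemble
        coefficients, BLUPs, effective degrees of freedom and covariances.

        ``fixed_loggamma`` pins the variance ratios (used for penalty-limit
        diagnostics); optimisation is skipped in that case.
        """
        if method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")
        nb = len(self.blocks)
        start = np.broadcast_to(np.atleast_1d(np.asarray(start_loggamma, float)), (nb,)).copy()
        if fixed_loggamma is not None:
            loggamma = np.asarray(fixed_loggamma, dtype=float)
            converged = True
        else:
            loggamma, converged = self._optimize(method, start)
        if not converged:
            logger.warning("variance-parameter optimisation did not fully converge")
        gamma = np.exp(loggamma) if nb else np.zeros(0)

        logdet, XtVX, XtVy, ytVy = self._core(gamma)
        beta = sla.solve(XtVX, XtVy, assume_a="pos", check_finite=False)
        rss = max(float(ytVy - XtVy @ beta), 1e-300)
        dof = self.n - self.p
        sigma2 = rss / (self.n if method == "ML" else dof)
        neg2 = self._neg2ll(loggamma, method)
        loglik = -0.5 * neg2
        if method == "ML":
            loglik_ml = loglik
            loggamma_ml = loggamma
        else:
            loggamma_ml, _ = (
                (loggamma, True) if fixed_loggamma is not None
                else self._optimize("ML", loggamma.copy() if nb else start)
            )
            loglik_ml = -0.5 * self._neg2ll(loggamma_ml, "ML")
        # marginal AIC on the ML fit: fixed effects + variance ratios + sigma^2
        aic = -2.0 * loglik_ml + 2.0 * (self.p + nb + 1)

        # augmented (Henderson) system for BLUPs, edf and posterior covariance
        if self.q:
            lam = 1.0 / gamma[self._col_block]
            G = np.block([[self._XtX, self._XtZ if self._use_q_path else self.X.T @ self.Z],
                          [(self._XtZ if self._use_q_path else self.X.T @ self.Z).T,
                           self._ZtZ if self._use_q_path else self.Z.T @ self.Z]])
            A = G.copy()
            A[self.p:, self.p:] += np.diag(lam)
            rhs = np.concatenate([self._Xty, self._Zty if self._use_q_path else self.Z.T @ self.y])
            cf = sla.cho_factor(A, lower=True, check_finite=False)
            theta = sla.cho_solve(cf, rhs, check_finite=False)
            Ainv_G = sla.cho_solve(cf, G, check_finite=False)
            edf_vec = np.diag(Ainv_G)
            theta_cov = sigma2 * sla.cho_solve(cf, np.eye(self.p + self.q), check_finite=False)
            b = theta[self.p:]
        else:
            theta = beta
            edf_vec = np.ones(self.p)
            theta_cov = sigma2 * np.linalg.inv(self._XtX)
            b = np.zeros(0)

        block_slices: dict[str, slice] = {}
        off = self.p
        edf_blocks: dict[str, float] = {}
        for blk, qk in zip(self.blocks, self.q_sizes):
            block_slices[blk.name] = slice(off - self.p, off - self.p + qk)
            edf_blocks[blk.name] = float(np.sum(edf_vec[off : off + qk]))
            off += qk
        edf_fixed = float(np.sum(edf_vec[: self.p]))

        fitted = self.X @ theta[: self.p] + (self.Z @ b if self.q else 0.0)
        residuals = self.y - fitted
        ss_tot = float(np.sum((self.y - self.y.mean()) ** 2))
        r2 = 1.0 - float(residuals @ residuals) / ss_tot if ss_tot > 0 else np.nan
        beta_cov = sigma2 * np.linalg.inv(XtVX)

        return PLMMFit(
            method=method,
            converged=converged,
            beta=theta[: self.p],
            beta_cov=beta_cov,
            fixed_names=self.fixed_names,
            b=b,
            block_slices=block_slices,
            blocks=self.blocks,
            gamma={blk.name: float(g) for blk, g in zip(self.blocks, gamma)},
            sigma2=float(sigma2),
            loglik=float(loglik),
            loglik_ml=float(loglik_ml),
            aic=float(aic),
            edf_fixed=edf_fixed,
            edf_blocks=edf_blocks,
            fitted=fitted,
            residuals=residuals,
            r_squared=r2,
            n_obs=self.n,
            y=self.y.copy(),
            theta_cov=theta_cov,
        )
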