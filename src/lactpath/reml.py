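"""Restricted maximum likelihood for single-random-effect mixed models.

The model throughout the package is

    y = X beta + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 D)

with one record per individual, K a relationship matrix (pedigree A or
genomic G) and D = diag(1/w_i) encoding per-record residual weights.
Whitening by sqrt(w) reduces the residual covariance to the identity and
replaces K with K* = D^{-1/2} K D^{-1/2}.  After a single symmetric
eigendecomposition K* = U S U', the restricted log-likelihood is an O(n p^2)
function of the variance ratio lambda = sigma_g^2 / sigma_e^2:

    H = lambda S + I (diagonal),  sigma_e^2 profiled as RSS/(n - p),
    l_R(lambda) = -1/2 [ (n-p)(log 2 pi sigma_e^2 + 1) + sum log d_i
                         + log|X' H^-1 X| - log|X' X| ]

which is maximised by a dense grid followed by bounded scalar refinement.
The eigendecomposition does not depend on X, so per-SNP exact refits (the
SNP added as a fixed covariate) reuse it and cost only the 1-D search.

A flat profile (e.g. K proportional to the identity under equal weights,
where only sigma_g^2 + sigma_e^2 is identifiable) is detected and flagged
rather than reported as a spurious interior optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

__all__ = ["REMLError", "REMLFit", "SpectralREML"]

_LOG2PI = np.log(2.0 * np.pi)


class REMLError(ValueError):
    """Ill-posed variance-component problem."""


@dataclass
class REMLFit:
    """REML solution for one fixed-effects design."""

    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    beta_se: np.ndarray
    loglik: float
    loglambda: float
    converged: bool
    identifiable: bool
    at_boundary: bool
    n_obs: int

    @property
    def sigma_total2(self) -> float:
        return self.sigma_g2 + self.sigma_e2

    @property
    def prop_g(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / tot) if tot > 0 else np.nan


class SpectralREML:
    """Shared spectral machinery for REML fits against one kinship matrix.

    Parameters
    ----------
    y : response vector (one record per individual).
    X : fixed-effects design matrix, full column rank.
    K : symmetric PSD relationship matrix.
    weights : per-record residual weights w (Var(e_i) = sigma_e^2 / w_i);
        default all ones.
    """

    #: search bounds for log(lambda); lambda spans ~6e-6 .. 1.6e5
    LOGLAMBDA_BOUNDS = (-12.0, 12.0)
    GRID_POINTS = 25
    FLAT_TOL = 1e-6

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        K: np.ndarray,
        weights: np.ndarray | None = None,
        eig: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        y = np.asarray(y, dtype=np.float64).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[0] != y.shape[0]:
            X = X.T
        n = y.shape[0]
        if X.shape[0] != n or (eig is None and K.shape != (n, n)):
            raise REMLError(
                f"dimension mismatch: y {n}, X {X.shape}, K "
                f"{getattr(K, 'shape', None)}"
            )
        if np.var(y) == 0:
            raise REMLError("response has zero variance")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise REMLError("fixed-effects design is rank deficient")
        if weights is None:
            weights = np.ones(n)
        weights = np.asarray(weights, dtype=np.float64).ravel()
        if weights.shape != (n,) or np.any(weights <= 0):
            raise REMLError("weights must be positive and match y")

        self.n, self.p = n, X.shape[1]
        self._sqrtw = np.sqrt(weights)
        ys = self._sqrtw * y
        Xs = self._sqrtw[:, None] * X
        if eig is None:
            Ks = np.asarray(K, dtype=np.float64) * np.outer(self._sqrtw, self._sqrtw)
            s, U = eigh(Ks)
        else:  # caller-supplied decomposition of the whitened K (reused fits)
            s, U = eig
        self.s = np.clip(s, 0.0, None)
        self.U = U
        self.yr = U.T @ ys
        self.Xr = U.T @ Xs

    # -- rotation of additional covariates ---------------------------------
    def rotate(self, v: np.ndarray) -> np.ndarray:
        """Whiten-and-rotate extra covariates into the spectral basis."""
        v = np.asarray(v, dtype=np.float64)
        if v.ndim == 1:
            return self.U.T @ (self._sqrtw * v)
        return self.U.T @ (self._sqrtw[:, None] * v)

    # -- restricted likelihood ---------------------------------------------
    def _profile(self, loglam: float, Xr: np.ndarray, yr: np.ndarray):
        lam = np.exp(loglam)
        d = lam * self.s + 1.0
        Xd = Xr / d[:, None]
        XtHX = Xr.T @ Xd
        Xty = Xd.T @ yr
        try:
            beta = np.linalg.solve(XtHX, Xty)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise REMLError("singular X'H^-1X") from exc
        rss = float(yr @ (yr / d) - Xty @ beta)
        nf = self.n - Xr.shape[1]
        sigma_e2 = max(rss / nf, 1e-300)
        sign, logdet_xhx = np.linalg.slogdet(XtHX)
        _, logdet_xx = np.linalg.slogdet(Xr.T @ Xr)
        ll = -0.5 * (
            nf * (_LOG2PI + 1.0 + np.log(sigma_e2))
            + float(np.sum(np.log(d)))
            + logdet_xhx
            - logdet_xx
        )
        return ll, beta, sigma_e2, XtHX, d

    def loglik(self, loglam: float, extra: np.ndarray | None = None) -> float:
        Xr = self.Xr if extra is None else np.column_stack([self.Xr, self.rotate(extra)])
        return self._profile(loglam, Xr, self.yr)[0]

    def fit(self, extra: np.ndarray | None = None) -> REMLFit:
        """REML fit, optionally with extra fixed covariates appended to X."""
        if extra is None:
            Xr = self.Xr
        else:
            er = self.rotate(extra)
            Xr = np.column_stack([self.Xr, er if er.ndim > 1 else er[:, None]])
        if Xr.shape[1] >= self.n:
            raise REMLError("more fixed effects than observations")
        lo, hi = self.LOGLAMBDA_BOUNDS
        grid = np.linspace(lo, hi, self.GRID_POINTS)
        lls = np.array([self._profile(g, Xr, self.yr)[0] for g in grid])
        identifiable = bool(lls.max() - lls.min() > self.FLAT_TOL)
        i_best = int(np.argmax(lls))
        a = grid[max(i_best - 1, 0)]
        b = grid[min(i_best + 1, len(grid) - 1)]
        converged = True
        if identifiable and a < b:
            res = minimize_scalar(
                lambda g: -self._profile(g, Xr, self.yr)[0],
                bounds=(a, b),
                method="bounded",
                options={"xatol": 1e-7},
            )
            loglam = float(res.x)
            converged = bool(res.success)
            if self._profile(loglam, Xr, self.yr)[0] < lls[i_best]:
                loglam = float(grid[i_best])  # keep the grid optimum
        else:
            loglam = float(grid[i_best])
        ll, beta, sigma_e2, XtHX, _ = self._profile(loglam, Xr, self.yr)
        at_boundary = loglam <= lo + 0.51 * (grid[1] - grid[0]) or loglam >= hi - 0.51 * (
            grid[1] - grid[0]
        )
        lam = np.exp(loglam)
        sigma_g2 = lam * sigma_e2  # at the lower boundary this is effectively zero
        cov = sigma_e2 * np.linalg.inv(XtHX)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        if not identifiable:
            warnings.warn(
                "flat REML profile: sigma_g^2 and sigma_e^2 are not separately "
                "identifiable (reporting total variance "
                f"{sigma_g2 * float(np.mean(self.s)) + sigma_e2:.4g})",
                RuntimeWarning,
                stacklevel=2,
            )
        return REMLFit(
            sigma_g2=float(sigma_g2),
            sigma_e2=float(sigma_e2),
            beta=beta,
            beta_se=se,
            loglik=float(ll),
            loglambda=loglam,
            converged=converged,
            identifiable=identifiable,
            at_boundary=bool(at_boundary),
            n_obs=self.n,
        )
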