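"""Independent oracles the tests check the implementation against.

Everything here is deliberately naive: Monte-Carlo gene dropping for
kinship, direct multivariate-normal restricted likelihood maximised with a
generic optimiser, and brute-force interval scans.  None of it shares code
with the implementation paths it validates.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from lactpath.relatedness import Pedigree


def gene_drop_relationship(
    ped: Pedigree, n_drops: int, seed: int
) -> np.ndarray:
    """Monte-Carlo estimate of the additive relationship matrix (2x kinship).

    Each founder receives two uniquely labelled alleles; alleles are
    dropped through the pedigree; the kinship of i and j is the probability
    that one allele drawn from each is identical by descent.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    order = ped.topo_order
    alleles = np.empty((n_drops, n, 2), dtype=np.int32)
    next_label = 0
    for i in order:
        s, d = ped.parent[i]
        for k, p in enumerate((s, d)):
            if p < 0:
                alleles[:, i, k] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[:, i, k] = alleles[np.arange(n_drops), p, pick]
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = 0.0
            for a in range(2):
                for b in range(2):
                    ibd += np.mean(alleles[:, i, a] == alleles[:, j, b])
            A[i, j] = A[j, i] = ibd / 2.0  # 2 * kinship
    return A


def direct_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """REML by direct evaluation of the restricted likelihood.

    Maximises over (log sigma_g^2, log sigma_e^2) with Nelder-Mead; returns
    (sigma_g2, sigma_e2, loglik).  Suitable for n up to a few hundred.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    D = np.diag(1.0 / w)

    def negll(theta):
        sg2, se2 = np.exp(theta)
        V = sg2 * K + se2 * D
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e10
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        resid = y - X @ beta
        quad = resid @ np.linalg.solve(V, resid)
        _, logdetXtX = np.linalg.slogdet(X.T @ X)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi)
            + logdetV
            + logdetXtViX
            - logdetXtX
            + quad
        )
        return -ll

    best = None
    for start in ([np.log(0.5), np.log(0.5)], [np.log(0.05), np.log(0.95)]):
        res = optimize.minimize(
            negll, start, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10}
        )
        if best is None or res.fun < best.fun:
            best = res
    sg2, se2 = np.exp(best.x)
    return float(sg2), float(se2), float(-best.fun)


def ols_t_stats(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Last-column OLS coefficient and z statistic for [X, w] on y."""
    Xa = np.column_stack([X, w])
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    resid = y - Xa @ beta
    dof = len(y) - Xa.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(Xa.T @ Xa)
    return float(beta[-1]), float(beta[-1] / np.sqrt(cov[-1, -1]))


def random_pedigree(n_founders: int, n_total: int, seed: int) -> Pedigree:
    """Random pedigree allowing inbreeding (any two earlier animals mate)."""
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n_total)]
    sires, dams = [], []
    for i in range(n_total):
        if i < n_founders:
            sires.append("0")
            dams.append("0")
        else:
            s, d = rng.choice(i, size=2, replace=False)
            sires.append(ids[s])
            dams.append(ids[d])
    return Pedigree(ids, sires, dams)
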