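"""Factor-analysis suitability diagnostics and exploratory extraction.

Used to ask whether the 10 resource-constraint items and 6 physical
functioning items share enough correlation structure to factor, and
whether they form one dimension (they do not: the expected structure is
three factors — resource constraint, physical limitation, and a
severity/frequency doublet).

Bartlett's sphericity statistic is
``-(n - 1 - (2p + 5)/6) * ln|R|`` on ``p(p-1)/2`` chi-square df.
KMO compares squared simple correlations with squared anti-image
(partial) correlations from the inverse correlation matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

_PSD_TOL = 1e-8


def _validate_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("R must have a unit diagonal")
    if np.linalg.eigvalsh(R).min() < -_PSD_TOL:
        raise ValueError("R is not positive semidefinite")
    return R


def correlation_matrix(
    items: pd.DataFrame,
    weights: np.ndarray | None = None,
    method: str = "pearson",
) -> np.ndarray:
    """Item correlation matrix: Pearson (default) or tetrachoric.

    Complete cases only.  Pearson on 0/1 indicators is the phi
    coefficient, which attenuates under unequal item thresholds;
    ``method="tetrachoric"`` estimates the latent bivariate-normal
    correlation pairwise instead (binary items only, unweighted).
    Weighted Pearson correlations use the weighted moments (an option
    for design-aware factoring; the default analysis runs unweighted).
    """
    X = items.dropna().to_numpy(dtype=float)
    if method == "tetrachoric":
        if weights is not None:
            raise ValueError("weighted tetrachoric correlations are not supported")
        return _tetrachoric_matrix(X)
    if method != "pearson":
        raise ValueError("method must be 'pearson' or 'tetrachoric'")
    if weights is None:
        return np.corrcoef(X, rowvar=False)
    w = np.asarray(weights, dtype=float)[items.notna().all(axis=1).to_numpy()]
    mu = np.average(X, axis=0, weights=w)
    Xc = X - mu
    C = (Xc * w[:, None]).T @ Xc / w.sum()
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def _tetrachoric_pair(p1, p2, p11):
    """Latent correlation of two binary items from their 2x2 margins."""
    h = scipy.stats.norm.ppf(1 - p1)
    k = scipy.stats.norm.ppf(1 - p2)
    lo = max(p1 + p2 - 1, 0) + 1e-9
    hi = min(p1, p2) - 1e-9
    p11 = min(max(p11, lo), hi)

    def f(r):
        cov = np.array([[1.0, r], [r, 1.0]])
        both = scipy.stats.multivariate_normal(cov=cov, allow_singular=True).cdf(
            [-h, -k]
        )
        return both - p11

    try:
        return scipy.optimize.brentq(f, -0.999, 0.999, xtol=1e-6)
    except ValueError:
        return 0.999 if f(0.999) < 0 else -0.999


def _tetrachoric_matrix(X: np.ndarray) -> np.ndarray:
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("tetrachoric correlations require binary 0/1 items")
    n, p = X.shape
    marg = X.mean(axis=0)
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            p11 = float((X[:, i] * X[:, j]).mean())
            R[i, j] = R[j, i] = _tetrachoric_pair(marg[i], marg[j], p11)
    # pairwise estimates need not be jointly PSD: clip negative eigenvalues
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < 0:
        vals = np.clip(vals, 1e-6, None)
        R = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R


def bartlett_sphericity(R: np.ndarray, n: int) -> dict:
    """Bartlett's test that the correlation matrix is the identity."""
    R = _validate_corr(R)
    p = R.shape[0]
    if n <= p:
        raise ValueError("need n > p for Bartlett's test")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError(
            f"R is singular (condition number {np.linalg.cond(R):.3g}); "
            "Bartlett statistic undefined"
        )
    stat = -(n - 1 - (2 * p + 5) / 6) * logdet
    df = p * (p - 1) / 2
    return {"statistic": float(stat), "df": df, "p": float(scipy.stats.chi2.sf(stat, df))}


def kmo(R: np.ndarray) -> dict:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Overall KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j,
    where q_ij are the anti-image partial correlations obtained by
    standardizing the inverse of R.  Values near 1 indicate compact
    correlation structure suitable for factoring; near 0, none.
    """
    R = _validate_corr(R)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("R is singular; KMO undefined") from exc
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = R[off] ** 2
    q2 = Q[off] ** 2
    overall = r2.sum() / (r2.sum() + q2.sum())
    r2_item = (R**2 * off).sum(axis=1)
    q2_item = (Q**2 * off).sum(axis=1)
    return {"overall": float(overall), "per_item": r2_item / (r2_item + q2_item)}


def efa_eigenvalues(
    R: np.ndarray,
    *,
    n_factors: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-3,
) -> dict:
    """Eigenvalues of R and principal-axis loadings for retained factors.

    Eigenvalues (descending) drive the Kaiser retention rule
    (eigenvalue > 1) when ``n_factors`` is not given.  Loadings come
    from principal-axis iteration: communalities start at the squared
    multiple correlations, the reduced matrix is re-factored until the
    communalities stabilize.
    """
    R = _validate_corr(R)
    p = R.shape[0]
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]
    k = int(n_factors) if n_factors is not None else int((eig > 1).sum())
    k = max(k, 1)
    # initial communalities: squared multiple correlations
    try:
        Rinv = np.linalg.inv(R)
        h2 = 1 - 1 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        h2 = np.full(p, 0.5)
    trace = []
    for it in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        idx = np.argsort(vals)[::-1][:k]
        lam = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))
        new_h2 = np.clip((lam**2).sum(axis=1), 0, 1)
        delta = np.abs(new_h2 - h2).max()
        trace.append(delta)
        h2 = new_h2
        if delta < tol:
            break
    else:
        raise RuntimeError(
            "principal-axis communality iteration did not converge; "
            f"last deltas {trace[-5:]}"
        )
    # orient each factor so its largest loading is positive
    for j in range(k):
        if lam[np.abs(lam[:, j]).argmax(), j] < 0:
            lam[:, j] = -lam[:, j]
    return {
        "eigenvalues": eig,
        "n_retained": k,
        "loadings": lam,
        "communalities": h2,
        "n_iterations": it + 1,
    }
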