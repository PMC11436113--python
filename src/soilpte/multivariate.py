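"""Correlation, sampling-adequacy diagnostics and correlation-matrix PCA.

These are the screening statistics that typically precede receptor
modeling: a Pearson correlation matrix with two-sided p-values, Bartlett's
test of sphericity, the Kaiser-Meyer-Olkin measure of sampling adequacy
(overall and per variable), and an unrotated principal component analysis
of the correlation matrix with loadings scaled by sqrt(eigenvalue) and
components retained at eigenvalue > 1 (Kaiser criterion).

p-values are reported unadjusted; no multiple-testing correction is
applied (a documented limitation of the conventional workflow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survey_io import SurveyTable


def _conc_matrix(data) -> pd.DataFrame:
    if isinstance(data, SurveyTable):
        return data.conc
    return pd.DataFrame(data)


def pearson_matrix(data) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix R and two-sided p-values.

    p-values use the exact t transform t = r sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom. Raises for n < 3 or any zero-variance column.
    """
    X = _conc_matrix(data)
    n = len(X)
    if n < 3:
        raise ValueError("correlation requires at least 3 samples")
    sd = X.std(ddof=1)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    R = X.corr(method="pearson")
    r = R.to_numpy(copy=True)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = rr * np.sqrt((n - 2) / (1 - rr**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    np.fill_diagonal(p, 0.0)
    return R, pd.DataFrame(p, index=R.index, columns=R.columns)


def bartlett_sphericity(R: pd.DataFrame | np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that R is an identity matrix.

    chi2 = -(n - 1 - (2p + 5)/6) * ln|R|, df = p(p-1)/2.
    """
    Rm = np.asarray(R, dtype=float)
    p = Rm.shape[0]
    sign, logdet = np.linalg.slogdet(Rm)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix is singular")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(max(chi2, 0.0), df)) if df > 0 else 1.0
    return float(chi2), df, pval


def kmo(R: pd.DataFrame | np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy: overall value and per-variable MSA.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal cells, with q the
    anti-image partial correlations q_ij = -V_ij / sqrt(V_ii V_jj) from the
    inverse V of R. An exact identity R has no correlation structure to
    factor; that 0/0 case returns 0 with a warning.
    """
    Rm = np.asarray(R, dtype=float)
    p = Rm.shape[0]
    try:
        V = np.linalg.inv(Rm)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("correlation matrix is singular") from exc
    d = np.sqrt(np.outer(np.diag(V), np.diag(V)))
    Q = -V / d
    off = ~np.eye(p, dtype=bool)
    r2 = (Rm[off] ** 2)
    q2 = (Q[off] ** 2)
    denom_per = r2.reshape(p, p - 1).sum(axis=1) + q2.reshape(p, p - 1).sum(axis=1)
    total = r2.sum() + q2.sum()
    if total == 0:
        warnings.warn("identity correlation matrix: KMO undefined, returning 0")
        return 0.0, np.zeros(p)
    msa = np.where(denom_per > 0, r2.reshape(p, p - 1).sum(axis=1) / np.where(denom_per > 0, denom_per, 1.0), 0.0)
    return float(r2.sum() / total), msa


@dataclass(frozen=True)
class PCAResult:
    """Eigenstructure of the Pearson correlation matrix.

    ``loadings`` are eigenvector * sqrt(eigenvalue) (elements x components);
    each component's largest-|loading| entry is made positive. ``retained``
    counts eigenvalues above 1.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    retained: int


def varimax(loadings: np.ndarray, max_iter: int = 500,
            tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal, variance-maximizing)."""
    p, k = loadings.shape
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p))
        R = u @ vt
        new_var = s.sum()
        if new_var <= var * (1 + tol):
            break
        var = new_var
    return loadings @ R


def pca(data, rotate: bool = False) -> PCAResult:
    """PCA on the correlation matrix of a survey or frame.

    Unrotated by default; ``rotate=True`` applies a varimax rotation to
    the retained components (eigenvalue > 1), leaving the others as-is.
    """
    X = _conc_matrix(data)
    n, p = X.shape
    if n <= p:
        raise ValueError("PCA requires more samples than variables")
    R, _ = pearson_matrix(X)
    evals, evecs = np.linalg.eigh(R.to_numpy())
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-12:
        raise np.linalg.LinAlgError("rank-deficient correlation matrix")
    loadings = evecs * np.sqrt(np.clip(evals, 0, None))
    retained = int((evals > 1.0).sum())
    if rotate and retained >= 2:
        loadings[:, :retained] = varimax(loadings[:, :retained])
    # sign convention: dominant loading of each component positive
    for k in range(p):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    variance_pct = 100.0 * evals / p
    return PCAResult(
        eigenvalues=evals,
        loadings=pd.DataFrame(loadings, index=R.index,
                              columns=[f"PC{k + 1}" for k in range(p)]),
        variance_pct=variance_pct,
        cumulative_pct=np.cumsum(variance_pct),
        retained=retained,
    )
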