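"""Uncertainty-weighted positive matrix factorization (receptor model).

The receptor model decomposes a samples x elements concentration matrix as

    X[i, j] = sum_k G[i, k] * F[k, j] + E[i, j],    G, F >= 0,

by minimizing the uncertainty-scaled residual sum of squares

    Q = sum_ij ( (X[i, j] - (G F)[i, j]) / U[i, j] )^2 .

Per-cell uncertainties follow the standard receptor-modeling rules: for a
concentration at or below the method detection limit, u = 5/6 * MDL;
above it, u = sqrt((error_fraction * c)^2 + (0.5 * MDL)^2).

The optimizer is alternating weighted multiplicative updates (weights
1/u^2), which keep both matrices nonnegative and never increase Q. A
multi-start driver restarts from random initials and keeps the solution
with the lowest robust Q (cell contributions capped at cutoff^2 for
scaled residuals beyond the cutoff, the conventional outlier guard). The
factorization is only identified up to factor permutation and scaling, so
solutions are reported with each factor's mean sample contribution scaled
to 1, and :func:`align_factors` matches recovered factors to a known
truth by best-permutation cosine similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .survey_io import SurveyTable

_EPS = 1e-12


@dataclass(frozen=True)
class UncertaintyMatrix:
    """Per-cell measurement uncertainties, same shape/units as X."""

    u: np.ndarray
    below_mdl: np.ndarray

    def __post_init__(self) -> None:
        if (self.u <= 0).any():
            raise ValueError("uncertainties must be strictly positive")


def uncertainty_matrix(table: SurveyTable | pd.DataFrame | np.ndarray,
                       mdl: Mapping[str, float] | Sequence[float],
                       error_fraction: Mapping[str, float] | float = 0.1,
                       weak_sn: float = 2.0) -> UncertaintyMatrix:
    """Build the per-cell uncertainty matrix for a survey.

    ``c <= MDL`` cells use the censored branch u = 5/6 MDL; others use
    u = sqrt((ef * c)^2 + (0.5 MDL)^2). Elements whose residual-based
    signal-to-noise falls below ``weak_sn`` are flagged "weak" and have
    their uncertainties tripled (set ``weak_sn=None`` to disable).
    """
    if isinstance(table, SurveyTable):
        X = table.conc.to_numpy(dtype=float)
        elements = table.elements
    else:
        X = np.asarray(pd.DataFrame(table), dtype=float)
        elements = tuple(pd.DataFrame(table).columns)
    if isinstance(mdl, Mapping):
        mdl_arr = np.array([mdl[e] for e in elements], dtype=float)
    else:
        mdl_arr = np.asarray(mdl, dtype=float)
    if (mdl_arr <= 0).any():
        raise ValueError("MDL values must be positive")
    if isinstance(error_fraction, Mapping):
        ef = np.array([error_fraction[e] for e in elements], dtype=float)
    else:
        ef = np.full(len(mdl_arr), float(error_fraction))
    if ((ef <= 0) | (ef >= 1)).any():
        raise ValueError("error fractions must lie in (0, 1)")
    below = X <= mdl_arr
    u = np.where(below, (5.0 / 6.0) * mdl_arr,
                 np.sqrt((ef * X) ** 2 + (0.5 * mdl_arr) ** 2))
    if weak_sn is not None:
        weak = signal_to_noise(X, u) < weak_sn
        if weak.any():
            warnings.warn(f"{int(weak.sum())} element(s) flagged weak (S/N < {weak_sn}); "
                          "uncertainty tripled")
            u = np.where(weak[None, :], 3.0 * u, u)
    return UncertaintyMatrix(u=u, below_mdl=below)


def signal_to_noise(X: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Residual-based per-element S/N: mean of (x - u)/u over cells with x > u."""
    d = np.where(X > U, (X - U) / U, 0.0)
    return d.mean(axis=0)


def q_value(X: np.ndarray, U: np.ndarray, g: np.ndarray, f: np.ndarray,
            robust: bool = False, cutoff: float = 4.0) -> float:
    """Objective Q at (g, f); robust caps each cell at cutoff^2."""
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    if (U <= 0).any():
        raise ValueError("zero or negative uncertainty cell")
    scaled = (X - g @ f) / U
    contrib = scaled**2
    if robust:
        contrib = np.minimum(contrib, cutoff**2)
    return float(contrib.sum())


@dataclass(frozen=True)
class PMFSolution:
    """Best-of-starts factorization with Q diagnostics."""

    g: np.ndarray                # samples x factors, mean contribution 1
    f: np.ndarray                # factors x elements, mg/kg per unit g
    q_true: float
    q_robust: float
    q_expected: float
    n_starts: int
    best_start_seed: int
    converged: bool
    iterations: int
    q_history: np.ndarray        # per-iteration Q of the winning start
    elements: tuple[str, ...] = ()

    @property
    def n_factors(self) -> int:
        return self.g.shape[1]


def _normalize(g: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the scale indeterminacy: mean sample contribution 1 per factor."""
    scale = g.mean(axis=0)
    scale[scale <= 0] = 1.0
    return g / scale, f * scale[:, None]


def _single_start(X, U, k, rng, tol, max_iter, patience=20):
    n, m = X.shape
    W = 1.0 / U**2
    WX = W * X
    g = rng.uniform(0.5, 1.5, size=(n, k))
    # scale initial profiles to the element means so GF starts near X
    f = rng.uniform(0.5, 1.5, size=(k, m)) * (X.mean(axis=0) / k)
    q_hist = np.empty(max_iter)
    q_prev = q_value(X, U, g, f)
    still = 0
    it = 0
    for it in range(max_iter):
        GF = g @ f
        g *= (WX @ f.T) / ((W * GF) @ f.T + _EPS)
        GF = g @ f
        f *= (g.T @ WX) / (g.T @ (W * GF) + _EPS)
        q = q_value(X, U, g, f)
        q_hist[it] = q
        rel = abs(q_prev - q) / max(q_prev, _EPS)
        still = still + 1 if rel < tol else 0
        q_prev = q
        if still >= patience:
            break
    converged = still >= patience
    return g, f, q_hist[: it + 1], converged


def fit_pmf(X, U, n_factors: int, n_starts: int = 20, seed: int = 0,
            tol: float = 1e-9, max_iter: int = 5000,
            robust_cutoff: float = 4.0,
            elements: Sequence[str] = ()) -> PMFSolution:
    """Multi-start uncertainty-weighted NMF; best start by robust Q.

    ``X`` and ``U`` may be arrays or DataFrames (samples x elements), all
    entries positive. Deterministic given ``seed``. If no start converges,
    the best solution is still returned with ``converged=False`` and a
    warning.
    """
    X = np.asarray(pd.DataFrame(X), dtype=float)
    U = np.asarray(pd.DataFrame(U) if not isinstance(U, np.ndarray) else U, dtype=float)
    n, m = X.shape
    if not 1 <= n_factors <= min(n, m):
        raise ValueError(f"n_factors must be in [1, {min(n, m)}]")
    if (X <= 0).any() or (U <= 0).any():
        raise ValueError("X and U must be strictly positive")
    root = np.random.SeedSequence(int(seed))
    best = None
    for start, ss in enumerate(root.spawn(n_starts)):
        rng = np.random.default_rng(ss)
        g, f, q_hist, conv = _single_start(X, U, n_factors, rng, tol, max_iter)
        qr = q_value(X, U, g, f, robust=True, cutoff=robust_cutoff)
        if best is None or qr < best[0]:
            best = (qr, g, f, q_hist, conv, start)
    qr, g, f, q_hist, conv, start = best
    if not conv:
        warnings.warn("PMF did not meet the convergence criterion in any start")
    g, f = _normalize(g, f)
    return PMFSolution(
        g=g, f=f,
        q_true=q_value(X, U, g, f),
        q_robust=qr,
        q_expected=float(n * m - n_factors * (n + m)),
        n_starts=n_starts,
        best_start_seed=start,
        converged=conv,
        iterations=len(q_hist),
        q_history=q_hist,
        elements=tuple(elements),
    )


def scan_factors(X, U, p_min: int = 2, p_max: int = 7, n_starts: int = 20,
                 seed: int = 0, **fit_kwargs) -> pd.DataFrame:
    """Fit every factor count in [p_min, p_max]; report Q diagnostics.

    Returns one row per p with columns ``n_factors, q_true, q_robust,
    q_expected, ratio`` (ratio = Q_robust / Q_expected). Selection of the
    factor count is reported, not decided; :func:`elbow` offers a curvature
    heuristic.
    """
    Xm = np.asarray(pd.DataFrame(X), dtype=float)
    n, m = Xm.shape
    if p_max >= min(n, m):
        raise ValueError("p_max must be below min(n_samples, n_elements)")
    rows = []
    for p in range(p_min, p_max + 1):
        sol = fit_pmf(X, U, p, n_starts=n_starts, seed=seed, **fit_kwargs)
        rows.append((p, sol.q_true, sol.q_robust, sol.q_expected,
                     sol.q_robust / sol.q_expected))
    return pd.DataFrame(rows, columns=["n_factors", "q_true", "q_robust",
                                       "q_expected", "ratio"])


def elbow(scan: pd.DataFrame) -> int:
    """Factor count at the elbow of the log Q_robust/Q_expected curve.

    The elbow is the interior point with the largest positive curvature
    (second difference) of log(ratio); the curve drops steeply up to the
    true rank and flattens beyond it.
    """
    p = scan["n_factors"].to_numpy()
    y = np.log(scan["ratio"].to_numpy())
    if len(p) < 3:
        raise ValueError("scan needs at least 3 factor counts")
    curv = y[:-2] - 2 * y[1:-1] + y[2:]
    return int(p[1:-1][np.argmax(curv)])


@dataclass(frozen=True)
class ContributionTable:
    """Percent allocations derived from a PMF solution.

    ``pct``: factors x elements, each column summing to 100 — the share of
    that element's mass attributed to each factor. ``share``: percent of
    the total mass per factor, summing to 100.
    """

    pct: pd.DataFrame
    share: pd.Series

    def fractions(self) -> pd.DataFrame:
        """Column-stochastic version of ``pct`` (sums to 1 per element)."""
        return self.pct / 100.0


def contribution_table(sol: PMFSolution, force: bool = False) -> ContributionTable:
    """Element-wise and overall factor contribution percentages.

    pct[k, j] = f_kj * mean_i(g_ik) normalized over factors; the overall
    share is the same mass normalized over everything. Invariant to the
    factor scale indeterminacy. Raises on an all-zero factor, or on a
    non-converged solution unless ``force``.
    """
    if not sol.converged and not force:
        raise ValueError("solution did not converge; pass force=True to proceed")
    mass = sol.g.mean(axis=0)[:, None] * sol.f      # factors x elements
    if (mass.sum(axis=1) <= 0).any():
        raise ValueError("all-zero factor in solution")
    cols = list(sol.elements) if sol.elements else list(range(sol.f.shape[1]))
    pct = pd.DataFrame(100.0 * mass / mass.sum(axis=0, keepdims=True),
                       index=[f"factor{k + 1}" for k in range(sol.n_factors)],
                       columns=cols)
    share = pd.Series(100.0 * mass.sum(axis=1) / mass.sum(), index=pct.index,
                      name="share_pct")
    return ContributionTable(pct=pct, share=share)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def align_factors(f_est: np.ndarray, f_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-match factor permutation by total profile cosine similarity.

    Returns ``(perm, sims)`` where ``perm[k]`` is the index of the true
    factor matched to estimated factor k and ``sims[k]`` the cosine
    similarity of that pair.
    """
    f_est = np.asarray(f_est, dtype=float)
    f_true = np.asarray(f_true, dtype=float)
    if f_est.shape[0] != f_true.shape[0]:
        raise ValueError("factor count mismatch")
    k = f_est.shape[0]
    sim = np.array([[_cosine(f_est[a], f_true[b]) for b in range(k)] for a in range(k)])
    rows, cols = linear_sum_assignment(-sim)
    return cols, sim[rows, cols]
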