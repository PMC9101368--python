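"""Expectation-Maximisation core for Linear Poisson Modelling.

Observed histograms ``H`` (cells x tumors) are modelled as independent
Poisson counts with mean ``M = P @ Q`` where the columns of ``P`` are
probability mass functions (each summing to one over the full grid) and
``Q`` holds nonnegative per-tumor component weights.  The extended
Poisson log-likelihood

    L = sum_ij [ H_ij log M_ij - M_ij ]        (log H! terms dropped)

is maximised by the standard multiplicative EM updates for Poisson/KL
factorisation of count data:

    S_kj   = sum_i P_ik H_ij / M_ij
    Q'_kj  = Q_kj * S_kj
    P'_ik  ~ P_ik * sum_j Q_kj H_ij / M_ij     (renormalised per column)

Both updates use responsibilities formed from the *old* parameters, so
each iteration is one exact EM step and the likelihood is non-decreasing.
Because every column of ``P`` sums to one, the weight update implies
``sum_k Q_kj = sum_i H_ij`` exactly from the first iteration onward
(whenever the model has support wherever counts exist) — the extended-ML
normalisation property.

Frozen components (e.g. the control part during the second training
stage) keep their PMF columns bit-identical; only their weights move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EMResult", "poisson_loglik", "em_fit", "fit_weights", "weight_covariance"]

_TINY = 1e-300


def poisson_loglik(H: np.ndarray, M: np.ndarray) -> float:
    """Extended Poisson log-likelihood sum(H log M - M), log H! dropped.

    Cells with observed counts but zero model mass contribute -inf.
    """
    H = np.asarray(H, dtype=float)
    M = np.asarray(M, dtype=float)
    bad = (H > 0) & (M <= 0)
    if np.any(bad):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(H > 0, H * np.log(np.maximum(M, _TINY)), 0.0)
    return float(terms.sum() - M.sum())


@dataclass
class EMResult:
    P: np.ndarray          #: (n_cells, K) component PMFs, columns sum to 1
    Q: np.ndarray          #: (K, n_tumors) nonnegative weights
    loglik: float
    loglik_history: np.ndarray  #: per-iteration log-likelihood of best restart
    n_iter: int
    restart: int           #: index of the winning restart
    converged: bool


def _em_iterate(
    H: np.ndarray,
    P: np.ndarray,
    Q: np.ndarray,
    n_frozen: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Run EM updates in place; returns (P, Q, loglik history, converged)."""
    history = []
    ll_prev = -np.inf
    converged = False
    K = P.shape[1]
    # cells no component can ever reach (multiplicative updates preserve
    # zeros) are excluded from the likelihood: they are unfittable and
    # would pin it at -inf
    fittable = P.sum(axis=1) > 0
    Hf = H[fittable]
    for it in range(max_iter):
        M = P @ Q
        ll = poisson_loglik(Hf, M[fittable])
        history.append(ll)
        if np.isfinite(ll) and np.isfinite(ll_prev):
            if ll - ll_prev <= tol * max(abs(ll_prev), 1.0):
                converged = True
                break
        ll_prev = ll
        R = np.divide(H, M, out=np.zeros_like(H, dtype=float), where=M > 0)
        S = P.T @ R                      # (K, n_tumors)
        if K > n_frozen:
            numer = P[:, n_frozen:] * (R @ Q[n_frozen:, :].T)
            col = numer.sum(axis=0)
            nz = col > 0
            P[:, n_frozen:][:, nz] = numer[:, nz] / col[nz]
        Q *= S
    return P, Q, np.asarray(history), converged


def em_fit(
    H: np.ndarray,
    K: int,
    rng: np.random.Generator,
    restarts: int = 20,
    fixed_P: np.ndarray | None = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
    support: np.ndarray | None = None,
) -> EMResult:
    """Fit K free PMF components (plus optional frozen ones) to count data.

    Parameters
    ----------
    H : (n_cells, n_tumors) array
        Nonnegative integer counts, one column per tumor.
    K : int
        Number of *free* components to learn (>= 0; may be 0 only when
        ``fixed_P`` supplies at least one frozen component).
    rng : numpy Generator
        Drives the Dirichlet initialisation of each restart.
    restarts : int
        Random restarts; the highest-likelihood solution is returned.
    fixed_P : optional (n_cells, K0) array
        Frozen component PMFs prepended to the learned ones; their columns
        are returned unchanged bit-for-bit.
    support : optional (n_cells,) boolean array
        Restricts the free components to these cells (multiplicative
        updates keep zero-initialised cells at zero).  Used by the
        second training stage so treatment components only describe
        behaviour in cells with a demonstrated excess over the control
        model.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[1] == 0:
        raise ValueError("H must be (n_cells, n_tumors) with >= 1 tumor")
    if H.sum() <= 0:
        raise ValueError("histograms are empty")
    n_frozen = 0 if fixed_P is None else fixed_P.shape[1]
    if K < 0 or K + n_frozen < 1:
        raise ValueError("at least one component (free or frozen) is required")
    occupied = H.sum(axis=1) > 0
    if support is not None:
        occupied = occupied & np.asarray(support, dtype=bool)
    n_occ = int(occupied.sum())
    if K > n_occ:
        raise ValueError(f"K={K} exceeds the {n_occ} occupied bins")

    totals = H.sum(axis=0)
    K_tot = n_frozen + K
    best: EMResult | None = None
    for r in range(max(restarts, 1)):
        P = np.zeros((H.shape[0], K_tot))
        if n_frozen:
            P[:, :n_frozen] = fixed_P
        for k in range(n_frozen, K_tot):
            # Dirichlet(alpha=1) over occupied bins; unoccupied bins start
            # (and stay) at zero mass
            P[occupied, k] = rng.dirichlet(np.ones(n_occ))
        Q = np.tile(totals / K_tot, (K_tot, 1))
        P, Q, history, conv = _em_iterate(H, P, Q, n_frozen, max_iter, tol)
        ll = history[-1]
        if best is None or ll > best.loglik:
            best = EMResult(P, Q, ll, history, len(history), r, conv)
    assert best is not None
    return best


def fit_weights(
    P: np.ndarray,
    h: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimise component weights for one histogram with PMFs fixed.

    Cells where the observed histogram has counts but no component has any
    mass cannot be explained by the model; they are excluded from the fit
    and their total count is returned as ``excess`` for the caller to flag.

    Returns ``(q, loglik_history, excess)``; the weight update is the same
    monotone EM step as in :func:`em_fit`, so at convergence
    ``q.sum() == h[supported].sum()`` to machine precision.
    """
    P = np.asarray(P, dtype=float)
    h = np.asarray(h, dtype=float).ravel()
    support = P.sum(axis=1) > 0
    excess = float(h[~support].sum())
    hs = h.copy()
    hs[~support] = 0.0
    total = hs.sum()
    if total <= 0:
        raise ValueError("histogram has no counts on the model support")
    K = P.shape[1]
    q = np.full(K, total / K)
    history = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        m = P @ q
        ll = poisson_loglik(hs, m)
        history.append(ll)
        if np.isfinite(ll) and np.isfinite(ll_prev):
            if ll - ll_prev <= tol * max(abs(ll_prev), 1.0):
                break
        ll_prev = ll
        r = np.divide(hs, m, out=np.zeros_like(hs), where=m > 0)
        q = q * (P.T @ r)
    return q, np.asarray(history), excess


def weight_covariance(P: np.ndarray, q: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Weight covariance from the observed Fisher information.

    For the extended Poisson likelihood with PMFs fixed, the negative
    Hessian over weights is ``I_kl = sum_i h_i P_ik P_il / m_i^2`` with
    ``m = P q``.  The covariance is its (pseudo-)inverse; the pseudo-inverse
    branch covers singular information matrices (e.g. duplicate components).
    """
    P = np.asarray(P, dtype=float)
    q = np.asarray(q, dtype=float)
    h = np.asarray(h, dtype=float).ravel()
    m = P @ q
    good = m > 0
    w = np.zeros_like(m)
    w[good] = h[good] / m[good] ** 2
    info = (P * w[:, None]).T @ P
    try:
        cov = np.linalg.inv(info)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return cov
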