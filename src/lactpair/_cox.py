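"""Newton-Raphson machinery for the Cox proportional-hazards partial likelihood.

Implements the Efron tie-handling convention throughout, with a fully
vectorized fast path for tie-free data (the common case for simulated
continuous event times) and a tie-group loop otherwise.  A batched
univariate solver fits thousands of one-covariate models simultaneously,
which is what the gene- and pair-level screens need.

Monotone-likelihood (perfect separation) is detected by bounding |beta|
during iteration: the partial likelihood of a separable covariate increases
without bound as |beta| grows, so any trajectory exceeding the bound is
declared non-converged instead of being returned as a huge finite estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: |beta| beyond which the likelihood is treated as monotone (separation).
MONOTONE_BETA_BOUND = 20.0

_ETA_CLIP = 500.0  # exp() overflow guard; irrelevant within the beta bound


@dataclass(frozen=True)
class SurvOrder:
    """Samples sorted by descending time with tie-group bookkeeping."""

    order: np.ndarray        # permutation: original -> descending-time order
    time: np.ndarray         # sorted, descending
    event: np.ndarray        # float 0/1, same order
    group_starts: np.ndarray  # start index of each tie group
    group_ends: np.ndarray
    n_events: int

    @property
    def no_ties(self) -> bool:
        return bool(np.all(self.group_ends - self.group_starts == 1))


def survorder(time, event) -> SurvOrder:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-D arrays of equal length")
    order = np.argsort(-time, kind="stable")
    t = time[order]
    e = event[order]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    ends = np.r_[starts[1:], t.size]
    return SurvOrder(order, t, e, starts, ends, int(e.sum()))


def _stats_no_ties(beta: np.ndarray, Xs: np.ndarray, so: SurvOrder):
    """(loglik, gradient, information) for tie-free data; O(n p^2) in BLAS."""
    eta = np.clip(Xs @ beta, -_ETA_CLIP, _ETA_CLIP)
    w = np.exp(eta)
    dm = so.event > 0
    cw = np.cumsum(w)                      # S0 at each position (risk = prefix)
    cwx = np.cumsum(w[:, None] * Xs, axis=0)
    S0 = cw[dm]
    mu = cwx[dm] / S0[:, None]
    ll = float(eta[dm].sum() - np.log(S0).sum())
    grad = Xs[dm].sum(axis=0) - mu.sum(axis=0)
    # sum_d S2_d / S0_d  ==  X' diag(w * A) X  with A_j = sum over deaths whose
    # risk set contains j (positions >= j in descending order) of 1/S0.
    a = np.where(dm, 1.0 / cw, 0.0)
    A = np.cumsum(a[::-1])[::-1]
    info = (Xs * (w * A)[:, None]).T @ Xs - mu.T @ mu
    return ll, grad, info


def _stats_efron(beta: np.ndarray, Xs: np.ndarray, so: SurvOrder):
    """(loglik, gradient, information) with Efron handling of tied deaths."""
    eta = np.clip(Xs @ beta, -_ETA_CLIP, _ETA_CLIP)
    w = np.exp(eta)
    p = Xs.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    for s, e in zip(so.group_starts, so.group_ends):
        sl = slice(s, e)
        wg = w[sl]
        Xg = Xs[sl]
        S0 += wg.sum()
        S1 += wg @ Xg
        S2 += Xg.T @ (wg[:, None] * Xg)
        dmask = so.event[sl] > 0
        d = int(dmask.sum())
        if d == 0:
            continue
        Xd = Xg[dmask]
        wd = wg[dmask]
        D0 = wd.sum()
        D1 = wd @ Xd
        D2 = Xd.T @ (wd[:, None] * Xd)
        ll += float(eta[sl][dmask].sum())
        grad += Xd.sum(axis=0)
        for l in range(d):
            f = l / d
            phi = S0 - f * D0
            m1 = (S1 - f * D1) / phi
            ll -= np.log(phi)
            grad -= m1
            info += (S2 - f * D2) / phi - np.outer(m1, m1)
    return ll, grad, info


def cox_stats(beta, X, so: SurvOrder):
    """Partial-likelihood value, gradient and observed information at ``beta``.

    ``X`` is n x p in the *original* sample order.
    """
    Xs = np.ascontiguousarray(np.asarray(X, dtype=float)[so.order])
    beta = np.asarray(beta, dtype=float)
    if so.no_ties:
        return _stats_no_ties(beta, Xs, so)
    return _stats_efron(beta, Xs, so)


def cox_loglik(beta, X, time, event) -> float:
    """Efron partial log-likelihood at ``beta`` (no fitting)."""
    so = survorder(time, event)
    return cox_stats(beta, X, so)[0]


@dataclass
class NewtonResult:
    beta: np.ndarray
    loglik: float
    info: np.ndarray          # observed information (unpenalized) at solution
    converged: bool
    n_iter: int
    flag: str | None = None   # e.g. "monotone_likelihood"


def newton_cox(
    X,
    time,
    event,
    l2: float | np.ndarray = 0.0,
    beta0: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
    so: SurvOrder | None = None,
) -> NewtonResult:
    """Maximize the (optionally L2-penalized) Efron partial likelihood.

    ``l2`` may be a scalar or per-coefficient vector of ridge penalties; the
    penalized objective is ``pl(beta) - 0.5 * sum(l2 * beta**2)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if so is None:
        so = survorder(time, event)
    if so.n_events < 1:
        raise ValueError("at least one observed event is required")
    l2 = np.broadcast_to(np.asarray(l2, dtype=float), (p,)).copy()
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)

    def objective(b):
        ll, grad, info = cox_stats(b, X, so)
        pll = ll - 0.5 * float(l2 @ (b * b))
        pgrad = grad - l2 * b
        pinfo = info + np.diag(l2)
        return ll, pll, pgrad, pinfo, info

    ll, pll, pgrad, pinfo, info = objective(beta)
    converged = False
    flag = None
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(pinfo, pgrad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(pinfo + 1e-8 * np.eye(p), pgrad)
        # step halving to guarantee ascent
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_c, pll_c, pgrad_c, pinfo_c, info_c = objective(cand)
            if pll_c >= pll - 1e-12:
                break
            alpha *= 0.5
        delta = float(np.max(np.abs(cand - beta)))
        beta, ll, pll, pgrad, pinfo, info = cand, ll_c, pll_c, pgrad_c, pinfo_c, info_c
        if np.max(np.abs(beta)) > MONOTONE_BETA_BOUND:
            flag = "monotone_likelihood"
            break
        if delta < tol:
            converged = True
            break
    # a separable covariate can flatten the likelihood (gradient underflow)
    # before |beta| reaches the bound: a "converged" unpenalized solution
    # with a large coefficient and vanishing curvature is separation
    if converged and not np.any(l2):
        d = np.diag(info) if p > 1 else np.asarray(info).ravel()
        if bool(np.any((np.abs(beta) > 5.0) & (d < 1e-6))):
            converged = False
            flag = "monotone_likelihood"
    return NewtonResult(beta=beta, loglik=ll, info=info, converged=converged,
                        n_iter=it, flag=flag)


@dataclass
class UnivariateBatch:
    beta: np.ndarray
    se: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray     # bool per column
    flag: np.ndarray          # object array: None | "monotone_likelihood" | "no_variation"


def _batch_stats(betas, Xs, so: SurvOrder):
    """Per-column (loglik, gradient, information) for independent univariate
    models sharing one survival outcome; loops only over tie groups."""
    eta = np.clip(Xs * betas[None, :], -_ETA_CLIP, _ETA_CLIP)
    w = np.exp(eta)
    p = Xs.shape[1]
    ll = np.zeros(p)
    grad = np.zeros(p)
    info = np.zeros(p)
    S0 = np.zeros(p)
    S1 = np.zeros(p)
    S2 = np.zeros(p)
    wx = w * Xs
    wxx = wx * Xs
    for s, e in zip(so.group_starts, so.group_ends):
        sl = slice(s, e)
        S0 += w[sl].sum(axis=0)
        S1 += wx[sl].sum(axis=0)
        S2 += wxx[sl].sum(axis=0)
        dmask = so.event[sl] > 0
        d = int(dmask.sum())
        if d == 0:
            continue
        D0 = w[sl][dmask].sum(axis=0)
        D1 = wx[sl][dmask].sum(axis=0)
        D2 = wxx[sl][dmask].sum(axis=0)
        ll += eta[sl][dmask].sum(axis=0)
        grad += Xs[sl][dmask].sum(axis=0)
        for l in range(d):
            f = l / d
            phi = S0 - f * D0
            m1 = (S1 - f * D1) / phi
            ll -= np.log(phi)
            grad -= m1
            info += (S2 - f * D2) / phi - m1 * m1
    return ll, grad, info


def newton_cox_univariate_batch(
    X,
    time,
    event,
    max_iter: int = 40,
    tol: float = 1e-9,
    so: SurvOrder | None = None,
) -> UnivariateBatch:
    """Fit one univariate Cox model per column of ``X`` (n x p), vectorized.

    Constant columns are flagged ``no_variation`` and never iterated;
    separable columns are flagged ``monotone_likelihood``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if so is None:
        so = survorder(time, event)
    if so.n_events < 1:
        raise ValueError("at least one observed event is required")
    Xs = np.ascontiguousarray(X[so.order])

    beta = np.zeros(p)
    flag = np.full(p, None, dtype=object)
    converged = np.zeros(p, dtype=bool)
    variation = np.ptp(X, axis=0) > 0
    flag[~variation] = "no_variation"
    active = variation.copy()

    ll = np.zeros(p)
    info = np.full(p, np.nan)
    for _ in range(max_iter):
        if not active.any():
            break
        ll_a, grad_a, info_a = _batch_stats(beta, Xs, so)
        ll = ll_a
        info = info_a
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info_a > 1e-12, grad_a / np.maximum(info_a, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        step[~active] = 0.0
        beta = beta + step
        runaway = active & (np.abs(beta) > MONOTONE_BETA_BOUND)
        if runaway.any():
            flag[runaway] = "monotone_likelihood"
            active &= ~runaway
        done = active & (np.abs(step) < tol)
        converged |= done
        active &= ~done
    # final statistics at the solution
    ll, _, info = _batch_stats(beta, Xs, so)
    # flat-likelihood separation: large beta with vanishing curvature
    stuck = converged & (np.abs(beta) > 5.0) & (info < 1e-6)
    if stuck.any():
        flag[stuck] = "monotone_likelihood"
        converged &= ~stuck
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
    bad = flag != None  # noqa: E711  (object array comparison)
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    converged[bad] = False
    return UnivariateBatch(beta=beta, se=se, loglik=ll, converged=converged, flag=flag)
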