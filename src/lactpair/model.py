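"""Two-stage adaptive-LASSO Cox selection of gene-pair signatures.

Stage 1 fits a 10-fold cross-validated ridge Cox model over a descending
penalty grid and keeps the full coefficient vector at the deviance-minimal
penalty.  Stage 2 turns those ridge coefficients into per-feature penalty
weights w_j = 1/|beta_ridge_j| (capped) and fits a 10-fold cross-validated
weighted LASSO Cox path, selecting the penalty at the minimum mean
cross-validated partial-likelihood deviance and returning the nonzero
coefficients.  The weighting gives strong ridge effects a small L1 penalty,
which is what grants the adaptive LASSO its oracle selection behaviour.

The ridge stage uses the package's own penalized Newton solver; the
weighted L1 path is delegated to scikit-survival's Coxnet after the exact
reparameterization x_j -> x_j / w_j (a weighted L1 penalty on beta equals a
plain L1 penalty on the rescaled problem).  Binary pair features share the
{0,1} scale, so no standardization is applied anywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._cox import cox_loglik, newton_cox
from .pairs import GenePairSet, PairScoreMatrix, pair_from_label
from .survival import validate_clinical

logger = logging.getLogger(__name__)


@dataclass
class AdaptiveLassoConfig:
    n_folds: int = 10
    lambda_grid: np.ndarray | None = None       # data-driven when None
    n_lambda: int = 100
    lambda_min_ratio: float | str = "auto"      # glmnet rule: 1e-4 if n > p else 0.01
    weight_cap: float = 1e6
    ridge_lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(3, -2, 21)
    )
    fold_seed: int = 0
    selection_rule: str = "lambda_min"          # or "lambda_1se"

    def validate(self) -> "AdaptiveLassoConfig":
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        for grid in (self.lambda_grid, self.ridge_lambda_grid):
            if grid is not None:
                g = np.asarray(grid, dtype=float)
                if g.size < 2 or np.any(np.diff(g) >= 0) or np.any(g <= 0):
                    raise ValueError("penalty grids must be strictly descending and positive")
        if self.selection_rule not in ("lambda_min", "lambda_1se"):
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")
        if self.weight_cap <= 0:
            raise ValueError("weight_cap must be positive")
        return self


@dataclass
class PairSignature:
    """A trained gene-pair index: selected pairs, their coefficients, and
    enough provenance to reproduce the fit."""

    pairs: GenePairSet
    coefficients: np.ndarray
    lambda_selected: float
    ridge_lambda: float
    ridge_betas: pd.Series            # all screened pairs, labelled
    n_folds: int
    fold_seed: int
    weight_cap: float
    selection_rule: str
    stage_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.pairs) != len(self.coefficients):
            raise ValueError("pairs and coefficients must align")
        if np.any(np.asarray(self.coefficients) == 0):
            raise ValueError("signature coefficients must be nonzero")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.pairs.labels(),
                         name="coefficient")


def assign_folds(sample_ids, event, n_folds: int, seed: int) -> np.ndarray:
    """Event-stratified fold labels keyed to sorted sample ids, so the
    assignment is invariant to the order samples arrive in."""
    sample_ids = list(sample_ids)
    event = np.asarray(event)
    folds = np.empty(len(sample_ids), dtype=int)
    pos = {sid: i for i, sid in enumerate(sample_ids)}
    for stratum in (0, 1):
        ids = sorted(sid for sid, e in zip(sample_ids, event) if e == stratum)
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, stratum])
        perm = rng.permutation(len(ids))
        for slot, j in enumerate(perm):
            folds[pos[ids[j]]] = slot % n_folds
    return folds


def _matrix_and_outcome(pair_matrix: PairScoreMatrix, clinical: pd.DataFrame):
    clinical = validate_clinical(clinical).loc[pair_matrix.sample_ids]
    X = pair_matrix.scores.to_numpy(dtype=float).T  # samples x pairs
    time = clinical["time_months"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=float)
    return X, time, event


def _cv_deviance(beta: np.ndarray, X, time, event, train_mask) -> float:
    """Verweij & van Houwelingen cross-validated partial-likelihood
    deviance contribution of one fold: -2 [ pl_all(b) - pl_train(b) ]."""
    ll_all = cox_loglik(beta, X, time, event)
    ll_train = cox_loglik(beta, X[train_mask], time[train_mask], event[train_mask])
    return -2.0 * (ll_all - ll_train)


@dataclass
class RidgeCVResult:
    beta: np.ndarray
    lambda_selected: float
    cv_deviance: np.ndarray           # mean deviance per grid point


def cv_ridge_cox(
    pair_matrix: PairScoreMatrix,
    clinical: pd.DataFrame,
    config: AdaptiveLassoConfig,
) -> RidgeCVResult:
    """K-fold cross-validated L2-penalized Cox fit; returns the full
    coefficient vector at the deviance-minimal ridge penalty."""
    config.validate()
    X, time, event = _matrix_and_outcome(pair_matrix, clinical)
    n_events = int(event.sum())
    if n_events < config.n_folds:
        raise ValueError(
            f"{n_events} events < {config.n_folds} folds; reduce n_folds"
        )
    grid = np.asarray(config.ridge_lambda_grid, dtype=float)
    folds = assign_folds(pair_matrix.sample_ids, event, config.n_folds,
                         config.fold_seed)
    dev = np.zeros((config.n_folds, grid.size))
    for k in range(config.n_folds):
        train = folds != k
        beta_ws = np.zeros(X.shape[1])
        for j, lam in enumerate(grid):
            res = newton_cox(X[train], time[train], event[train], l2=lam,
                             beta0=beta_ws)
            beta_ws = res.beta
            dev[k, j] = _cv_deviance(res.beta, X, time, event, train)
    mean_dev = dev.mean(axis=0)
    j_min = int(np.argmin(mean_dev))
    if config.selection_rule == "lambda_1se":
        se = dev.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
        ok = np.flatnonzero(mean_dev <= mean_dev[j_min] + se[j_min])
        j_min = int(ok[0])  # grid is descending: first index = largest penalty
    lam = float(grid[j_min])
    beta_full = np.zeros(X.shape[1])
    for l in grid[: j_min + 1]:  # warm-start down the path
        beta_full = newton_cox(X, time, event, l2=l, beta0=beta_full).beta
    return RidgeCVResult(beta=beta_full, lambda_selected=lam, cv_deviance=mean_dev)


def adaptive_weights(beta_ridge: np.ndarray, cap: float = 1e6) -> np.ndarray:
    """Per-feature L1 penalty weights w_j = 1/|beta_ridge_j|, truncated at
    ``cap`` (ridge betas are never exactly zero in theory, but near-zero
    values would otherwise yield numerically infinite penalties)."""
    beta_ridge = np.asarray(beta_ridge, dtype=float)
    if np.any(~np.isfinite(beta_ridge)):
        raise ValueError("ridge coefficients must be finite")
    with np.errstate(divide="ignore"):
        w = 1.0 / np.abs(beta_ridge)
    return np.minimum(w, cap)


def _coxnet_path(Xs, time, event, alphas):
    """Coefficients (p x n_alphas) of an L1 Cox path at fixed alphas."""
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=np.asarray(alphas, dtype=float), normalize=False,
        fit_baseline_model=False, tol=1e-7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y)
    fitted = np.asarray(model.alphas_, dtype=float)
    coefs = np.zeros((Xs.shape[1], len(alphas)))
    # map the fitted path back onto the requested grid (coxnet may stop early)
    for j, a in enumerate(alphas):
        k = int(np.argmin(np.abs(fitted - a)))
        coefs[:, j] = model.coef_[:, k]
    return coefs


@dataclass
class LassoCVResult:
    lambda_selected: float
    coefficients: np.ndarray          # dense, zeros included
    cv_deviance: np.ndarray
    lambda_grid: np.ndarray


def cv_weighted_lasso_cox(
    pair_matrix: PairScoreMatrix,
    clinical: pd.DataFrame,
    weights: np.ndarray,
    config: AdaptiveLassoConfig,
) -> LassoCVResult:
    """K-fold cross-validated weighted-L1 Cox fit.

    The weighted penalty sum_j w_j |beta_j| is solved exactly as a plain
    LASSO on the rescaled design x_j / w_j, then mapped back.  The penalty
    at the minimum mean CV partial-likelihood deviance is selected.  An
    empty model at every penalty is a valid outcome (returned with a
    warning), e.g. under a pure-noise null.
    """
    config.validate()
    weights = np.asarray(weights, dtype=float)
    if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
        raise ValueError("penalty weights must be positive and finite")
    X, time, event = _matrix_and_outcome(pair_matrix, clinical)
    if int(event.sum()) < config.n_folds:
        raise ValueError("fewer events than folds; reduce n_folds")
    Xs = X / weights[None, :]
    if config.lambda_grid is not None:
        grid = np.asarray(config.lambda_grid, dtype=float)
    else:
        y = Surv.from_arrays(event=event.astype(bool), time=time)
        probe = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=config.n_lambda,
            alpha_min_ratio=config.lambda_min_ratio, normalize=False,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe.fit(Xs, y)
        grid = np.asarray(probe.alphas_, dtype=float)
    folds = assign_folds(pair_matrix.sample_ids, event, config.n_folds,
                         config.fold_seed)
    dev = np.zeros((config.n_folds, grid.size))
    for k in range(config.n_folds):
        train = folds != k
        coefs = _coxnet_path(Xs[train], time[train], event[train], grid)
        for j in range(grid.size):
            dev[k, j] = _cv_deviance(coefs[:, j], Xs, time, event, train)
    mean_dev = dev.mean(axis=0)
    j_min = int(np.argmin(mean_dev))
    if config.selection_rule == "lambda_1se":
        se = dev.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
        ok = np.flatnonzero(mean_dev <= mean_dev[j_min] + se[j_min])
        j_min = int(ok[0])
    coefs_full = _coxnet_path(Xs, time, event, grid)
    beta = coefs_full[:, j_min] / weights
    if not np.any(beta):
        logger.warning("weighted LASSO selected the empty model at every "
                       "compatible penalty (no prognostic pairs retained)")
    return LassoCVResult(
        lambda_selected=float(grid[j_min]),
        coefficients=beta,
        cv_deviance=mean_dev,
        lambda_grid=grid,
    )


def fit_signature(
    pair_matrix: PairScoreMatrix,
    clinical: pd.DataFrame,
    config: AdaptiveLassoConfig | None = None,
) -> PairSignature:
    """Ridge penalty weights -> weighted LASSO -> sparse pair signature.

    Deterministic given (data, config): folds are derived from sample ids
    under the fold seed, never from sample order.
    """
    config = (config or AdaptiveLassoConfig()).validate()
    ridge = cv_ridge_cox(pair_matrix, clinical, config)
    weights = adaptive_weights(ridge.beta, cap=config.weight_cap)
    lasso = cv_weighted_lasso_cox(pair_matrix, clinical, weights, config)
    nz = np.flatnonzero(lasso.coefficients)
    labels = [pair_matrix.scores.index[j] for j in nz]
    pairs = GenePairSet(tuple(pair_from_label(l) for l in labels),
                        provenance="adaptive-LASSO signature")
    return PairSignature(
        pairs=pairs,
        coefficients=lasso.coefficients[nz],
        lambda_selected=lasso.lambda_selected,
        ridge_lambda=ridge.lambda_selected,
        ridge_betas=pd.Series(ridge.beta, index=pair_matrix.scores.index,
                              name="ridge_beta"),
        n_folds=config.n_folds,
        fold_seed=config.fold_seed,
        weight_cap=config.weight_cap,
        selection_rule=config.selection_rule,
        stage_counts={"pairs_in": len(pair_matrix.pairs),
                      "pairs_selected": int(nz.size)},
    )
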