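"""Censored-survival statistics for screening and evaluation.

Cox partial-likelihood fits use the package's own Newton solver
(:mod:`lactpair._cox`, Efron ties); Kaplan-Meier, log-rank and concordance
are delegated to lifelines / scikit-survival, and the time-dependent AUC is
the IPCW cumulative/dynamic estimator of scikit-survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

from ._cox import (
    newton_cox,
    newton_cox_univariate_batch,
    survorder,
    cox_stats,
)

logger = logging.getLogger(__name__)

REQUIRED_CLINICAL_COLUMNS = ("time_months", "event")


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table: unique sample ids (index), nonnegative
    times, binary events. Returns the table unchanged."""
    for col in REQUIRED_CLINICAL_COLUMNS:
        if col not in clinical.columns:
            raise ValueError(f"clinical table is missing required column {col!r}")
    if clinical.index.has_duplicates:
        dup = clinical.index[clinical.index.duplicated()][0]
        raise ValueError(f"duplicate sample id in clinical table: {dup!r}")
    t = clinical["time_months"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("time_months must be finite and nonnegative")
    ev = clinical["event"].to_numpy()
    if not np.isin(ev, [0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return clinical


def _time_event(clinical: pd.DataFrame):
    validate_clinical(clinical)
    return (clinical["time_months"].to_numpy(dtype=float),
            clinical["event"].to_numpy(dtype=float))


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit (Efron ties, Wald tests)."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n_events: int
    loglik: float
    flag: str | None = None

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def wald_z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p_value(self) -> np.ndarray:
        return 2.0 * sps.norm.sf(np.abs(self.wald_z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hazard_ratio": self.hazard_ratio,
                "z": self.wald_z,
                "p": self.p_value,
            },
            index=self.names,
        )


def fit_cox(x, clinical: pd.DataFrame, names: list[str] | None = None) -> CoxFit:
    """Fit a Cox model of ``x`` (1-D vector or samples-by-covariates array)
    on the (time, event) outcome of ``clinical``.

    Raises on constant covariates, missing values or zero events.  A
    monotone-likelihood (perfect separation) fit is returned with
    ``converged=False`` and ``flag='monotone_likelihood'`` rather than a
    silently huge coefficient.
    """
    time, event = _time_event(clinical)
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != time.size:
        raise ValueError("covariate rows must match clinical samples")
    if np.any(~np.isfinite(X)):
        raise ValueError("covariates contain missing or non-finite values")
    if event.sum() < 1:
        raise ValueError("at least one observed event is required")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise ValueError(
            f"covariate {int(np.flatnonzero(const)[0])} has no variation"
        )
    res = newton_cox(X, time, event)
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(res.info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(X.shape[1], np.nan)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return CoxFit(
        names=list(names),
        beta=res.beta,
        se=se,
        converged=res.converged,
        n_events=int(event.sum()),
        loglik=res.loglik,
        flag=res.flag,
    )


def univariate_cox_table(features: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """One univariate Cox fit per *row* of ``features`` (features x samples).

    Returns a DataFrame indexed by feature with columns beta, se,
    hazard_ratio, z, p, converged, flag.  Constant and separable features
    get NaN statistics and a diagnostic flag instead of an exception, so the
    table can drive bulk screens.
    """
    clinical = clinical.loc[list(features.columns)]
    time, event = _time_event(clinical)
    X = features.to_numpy(dtype=float).T  # samples x features
    if np.any(~np.isfinite(X)):
        raise ValueError("features contain missing or non-finite values")
    batch = newton_cox_univariate_batch(X, time, event)
    with np.errstate(invalid="ignore"):
        z = batch.beta / batch.se
        p = 2.0 * sps.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "beta": batch.beta,
            "se": batch.se,
            "hazard_ratio": np.exp(batch.beta),
            "z": z,
            "p": p,
            "converged": batch.converged,
            "flag": batch.flag,
        },
        index=features.index,
    )


def cox_score_test(x, clinical: pd.DataFrame) -> tuple[float, float]:
    """Score (Rao) test of a single covariate at beta = 0.

    Without tied event times this equals the two-group log-rank statistic
    when ``x`` is a group indicator.
    """
    time, event = _time_event(clinical)
    X = np.asarray(x, dtype=float)[:, None]
    so = survorder(time, event)
    _, grad, info = cox_stats(np.zeros(1), X, so)
    chi2 = float(grad[0] ** 2 / info[0, 0])
    return chi2, float(sps.chi2.sf(chi2, df=1))


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate (right-continuous step function)."""

    times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def at(self, t: float) -> float:
        """S(t) by step-function lookup."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival_prob[idx]) if idx >= 0 else 1.0


def km_curve(clinical: pd.DataFrame, label: str = "") -> SurvivalCurve:
    """Kaplan-Meier curve; at tied times deaths precede censorings."""
    time, event = _time_event(clinical)
    if time.size == 0:
        raise ValueError("empty clinical table")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
    return SurvivalCurve(times=times, survival_prob=surv, at_risk=at_risk, label=label)


def logrank_test(groups, clinical: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    time, event = _time_event(clinical)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly two groups, got {len(labels)}")
    if event.sum() < 1:
        raise ValueError("at least one observed event is required")
    m = g == labels[0]
    res = _ll_logrank(time[m], time[~m], event_observed_A=event[m],
                      event_observed_B=event[~m])
    return float(res.test_statistic), float(res.p_value)


def _surv_array(clinical: pd.DataFrame):
    time, event = _time_event(clinical)
    return Surv.from_arrays(event=event.astype(bool), time=time)


def time_dependent_auc(scores, clinical: pd.DataFrame, horizons) -> pd.Series:
    """Cumulative-case / dynamic-control AUC at each horizon (months) with
    inverse-probability-of-censoring weights from the Kaplan-Meier estimate
    of the censoring distribution.

    Higher score must mean higher risk.  Horizons beyond the last observed
    follow-up time raise a ValueError.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = _time_event(clinical)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if np.any(horizons >= time.max()):
        raise ValueError("horizon beyond last observed follow-up time")
    for h in horizons:
        if event[time <= h].sum() < 1:
            raise ValueError(f"no events observed by horizon {h}")
        if (time > h).sum() < 1:
            raise ValueError(f"no controls still at risk at horizon {h}")
    y = _surv_array(clinical)
    auc, _ = cumulative_dynamic_auc(y, y, scores, horizons)
    return pd.Series(auc, index=horizons, name="auc")


def concordance_index(scores, clinical: pd.DataFrame) -> float:
    """Harrell's C over usable pairs; ties in score count 1/2."""
    scores = np.asarray(scores, dtype=float)
    time, event = _time_event(clinical)
    if event.sum() < 1:
        raise ValueError("no comparable pairs: no events observed")
    c, *_ = concordance_index_censored(event.astype(bool), time, scores)
    return float(c)


def calibration_at(
    t: float,
    predicted_survival,
    clinical: pd.DataFrame,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Bin samples by predicted survival at ``t`` into quantile bins and
    compare mean predicted survival with the Kaplan-Meier observed survival
    per bin.  Degenerate (empty) quantile bins are merged, with a log note.
    """
    pred = np.asarray(predicted_survival, dtype=float)
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    time, event = _time_event(clinical)
    if pred.size != time.size:
        raise ValueError("predictions must align with clinical samples")
    try:
        bins = pd.qcut(pred, q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(pred.size, dtype=int)
    # constant predictions make every quantile edge identical -> all-NaN bins
    bins = np.where(pd.isna(bins), 0, bins).astype(int)
    n_eff = int(pd.Series(bins).nunique())
    if n_eff < n_bins:
        logger.info("calibration: %d requested bins collapsed to %d", n_bins, n_eff)
    rows = []
    for b in sorted(pd.unique(bins)):
        m = bins == b
        kmf = KaplanMeierFitter().fit(time[m], event[m])
        rows.append(
            {
                "bin": int(b),
                "n": int(m.sum()),
                "mean_predicted": float(pred[m].mean()),
                "km_observed": float(kmf.predict(t)),
            }
        )
    return pd.DataFrame(rows)
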