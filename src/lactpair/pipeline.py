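"""End-to-end orchestration of the gene-pair prognostic index.

Training: short-followup exclusion -> univariate Cox gene screen -> pair
enumeration -> binary pair scoring -> consistency filter -> univariate Cox
pair screen -> adaptive-LASSO signature -> index scoring -> median
stratification -> survival evaluation.  A frozen signature can then score
any new cohort whose expression contains the signature genes, on any
within-sample-comparable scale.

Screens use raw p < alpha thresholds with no multiple-testing correction:
the screens are deliberately liberal pre-filters and the penalized fit is
the arbiter of the final model, so corrected screens would starve it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AdaptiveLassoConfig, PairSignature, fit_signature
from .pairs import (
    GenePairSet,
    PairScoreMatrix,
    build_pair_matrix,
    consistency_filter,
    drop_incomplete_genes,
    enumerate_candidate_pairs,
    validate_expression,
)
from .survival import (
    calibration_at,
    concordance_index,
    fit_cox,
    km_curve,
    logrank_test,
    time_dependent_auc,
    univariate_cox_table,
    validate_clinical,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    gene_screen_alpha: float = 0.05
    pair_screen_alpha: float = 0.05
    consistency_threshold: float = 0.70
    min_followup_months: float = 1.0
    evaluation_horizons: tuple[float, ...] = (12.0, 36.0, 60.0)
    adaptive: AdaptiveLassoConfig = field(default_factory=AdaptiveLassoConfig)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for a in (self.gene_screen_alpha, self.pair_screen_alpha):
            if not 0.0 < a < 1.0:
                raise ValueError("screen alphas must lie in (0, 1)")
        if not 0.5 <= self.consistency_threshold < 1.0:
            raise ValueError("consistency threshold must lie in [0.5, 1)")
        self.adaptive.validate()
        return self


@dataclass
class RiskProfile:
    """Per-sample index values with the dichotomizing cutoff."""

    sample_ids: list[str]
    lrgpi: np.ndarray
    cutoff: float
    group: np.ndarray     # "high" | "low"; high iff lrgpi > cutoff

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lrgpi": self.lrgpi, "group": self.group},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def exclude_short_followup(clinical: pd.DataFrame, min_months: float = 1.0) -> pd.DataFrame:
    """Drop samples observed for strictly less than ``min_months`` (very
    short follow-up mostly reflects perioperative events, not tumor
    biology, and destabilizes the index)."""
    validate_clinical(clinical)
    keep = clinical["time_months"].to_numpy(dtype=float) >= min_months
    removed = int((~keep).sum())
    if removed:
        logger.info("excluded %d sample(s) with follow-up < %g months",
                    removed, min_months)
    out = clinical.loc[keep]
    if out.empty:
        raise ValueError("all samples excluded by the follow-up filter")
    return out


def screen_prognostic_genes(
    expr: pd.DataFrame, clinical: pd.DataFrame, alpha: float = 0.05
) -> pd.Series:
    """Univariate Cox Wald screen of each gene's expression; returns the
    p-values of genes with p < alpha, sorted ascending.  Constant or
    separable genes are skipped with a warning."""
    validate_expression(expr)
    clinical = validate_clinical(clinical)
    expr = expr[clinical.index]
    table = univariate_cox_table(expr, clinical)
    skipped = table.index[table["flag"].notna()]
    if len(skipped):
        logger.warning("gene screen skipped %d gene(s): %s", len(skipped),
                       ", ".join(map(str, skipped[:5])))
    ok = table[table["flag"].isna()]
    hits = ok.loc[ok["p"] < alpha, "p"].sort_values(kind="stable")
    return hits


def screen_prognostic_pairs(
    pair_matrix: PairScoreMatrix, clinical: pd.DataFrame, alpha: float = 0.05
) -> PairScoreMatrix:
    """Retain pairs whose binary score is associated with outcome at
    p < alpha by univariate Cox (original pair order preserved)."""
    if len(pair_matrix.pairs) == 0:
        return pair_matrix
    clinical = validate_clinical(clinical).loc[pair_matrix.sample_ids]
    table = univariate_cox_table(pair_matrix.scores, clinical)
    keep = table["flag"].isna() & (table["p"] < alpha)
    labels = [l for l in pair_matrix.scores.index if keep[l]]
    return pair_matrix.subset(labels, provenance="Cox-screened")


def compute_lrgpi(pair_matrix: PairScoreMatrix, signature: PairSignature) -> pd.Series:
    """Index value per sample: sum of signature coefficients over the pairs
    scoring 1 in that sample."""
    labels = signature.pairs.labels()
    missing = [l for l in labels if l not in pair_matrix.scores.index]
    if missing:
        raise ValueError(f"signature pair(s) missing from score matrix: {missing}")
    if not labels:
        return pd.Series(0.0, index=pair_matrix.sample_ids, name="lrgpi")
    scores = pair_matrix.scores.loc[labels].to_numpy(dtype=float)
    vals = signature.coefficients @ scores
    return pd.Series(vals, index=pair_matrix.sample_ids, name="lrgpi")


def score_cohort(expr: pd.DataFrame, signature: PairSignature) -> pd.Series:
    """Score a cohort's expression with a frozen signature (builds only the
    signature's own pairs).  Fails listing any missing signature gene."""
    validate_expression(expr)
    missing = sorted(signature.pairs.genes() - set(expr.index))
    if missing:
        raise ValueError(f"signature gene(s) missing from cohort: {missing}")
    if len(signature.pairs) == 0:
        return pd.Series(0.0, index=expr.columns, name="lrgpi")
    m = build_pair_matrix(expr.loc[sorted(signature.pairs.genes())], signature.pairs)
    return compute_lrgpi(m, signature)


def stratify(scores, cutoff="median") -> tuple[np.ndarray, float]:
    """Dichotomize scores: ``high`` iff score > cutoff (ties go to
    ``low``).  ``cutoff='median'`` uses the scores' own median."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("stratification requires at least two samples")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate stratification: all scores identical")
    cut = float(np.median(scores)) if cutoff == "median" else float(cutoff)
    group = np.where(scores > cut, "high", "low")
    if len(np.unique(group)) < 2:
        raise ValueError("degenerate stratification: cutoff outside score range")
    return group, cut


def _serializable_curve(curve) -> dict:
    return {
        "label": curve.label,
        "times": [float(t) for t in curve.times],
        "survival": [float(s) for s in curve.survival_prob],
        "at_risk": [float(r) for r in curve.at_risk],
    }


def evaluate(
    profile: RiskProfile,
    clinical: pd.DataFrame,
    covariates: list[str] | None = None,
    horizons=(12.0, 36.0, 60.0),
) -> dict:
    """Survival evaluation of a risk profile.

    Produces Kaplan-Meier curves and the log-rank test for the high/low
    groups, IPCW time-dependent AUCs of the continuous index, Harrell's C,
    a univariate Cox fit of the index, and — when covariates are supplied —
    a multivariable Cox model of index plus covariates whose linear
    predictor plays the role of a nomogram score, with a calibration table
    at the first horizon.
    """
    clinical = validate_clinical(clinical).loc[profile.sample_ids]
    time = clinical["time_months"].to_numpy(dtype=float)
    report: dict = {"n_samples": len(profile.sample_ids)}

    chi2, p = logrank_test(profile.group, clinical)
    report["logrank"] = {"chi2": chi2, "p": p}
    report["km"] = {
        g: _serializable_curve(km_curve(clinical.loc[profile.group == g], label=g))
        for g in ("low", "high")
    }

    usable = [float(h) for h in horizons if h < time.max()]
    dropped = [float(h) for h in horizons if h >= time.max()]
    if dropped:
        logger.warning("horizons beyond follow-up dropped: %s", dropped)
    aucs = {}
    for h in usable:
        try:
            aucs[h] = float(time_dependent_auc(profile.lrgpi, clinical, [h]).iloc[0])
        except ValueError as err:
            logger.warning("AUC at %g months unavailable: %s", h, err)
            aucs[h] = float("nan")
    report["auc"] = aucs
    report["c_index"] = concordance_index(profile.lrgpi, clinical)

    uni = fit_cox(np.asarray(profile.lrgpi, dtype=float), clinical, names=["lrgpi"])
    report["cox_univariate"] = uni.summary().to_dict(orient="index")

    if covariates:
        have = [c for c in covariates if c in clinical.columns]
        missing = [c for c in covariates if c not in clinical.columns]
        if missing:
            logger.warning("covariate(s) missing, adjusted model reduced: %s", missing)
        if have:
            X = np.column_stack(
                [np.asarray(profile.lrgpi, dtype=float)]
                + [clinical[c].to_numpy(dtype=float) for c in have]
            )
            adj = fit_cox(X, clinical, names=["lrgpi"] + have)
            report["cox_adjusted"] = adj.summary().to_dict(orient="index")
            report["nomogram_linear_predictor"] = {
                sid: float(v)
                for sid, v in zip(profile.sample_ids, X @ adj.beta)
            }
            # calibration of the adjusted model at the first usable horizon
            if usable:
                t0 = usable[0]
                base = km_curve(clinical)
                lp = X @ adj.beta
                lp_c = lp - lp.mean()
                s0 = base.at(t0)
                pred = np.clip(s0 ** np.exp(lp_c), 0.0, 1.0)
                report["calibration"] = calibration_at(
                    t0, pred, clinical, n_bins=4
                ).to_dict(orient="records")
    return report


@dataclass
class TrainResult:
    signature: PairSignature
    profile: RiskProfile
    report: dict


def train_lrgpi(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
    covariates: list[str] | None = None,
) -> TrainResult:
    """Train the gene-pair index end to end on one cohort.

    The report carries per-stage feature counts (genes in, prognostic
    genes, pairs generated / after filter / after screen / in signature)
    so shrinking stage outputs can be audited.
    """
    config = (config or PipelineConfig()).validate()
    validate_expression(expr)
    clinical = validate_clinical(clinical)
    shared = [s for s in expr.columns if s in set(clinical.index)]
    if not shared:
        raise ValueError("expression and clinical tables share no sample ids")
    expr = drop_incomplete_genes(expr[shared])
    clinical = clinical.loc[shared]

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    clinical = stage("exclude_short_followup", exclude_short_followup,
                     clinical, config.min_followup_months)
    expr = expr[clinical.index]

    gene_p = stage("screen_prognostic_genes", screen_prognostic_genes,
                   expr, clinical, config.gene_screen_alpha)
    counts = {"genes_in": int(expr.shape[0]),
              "samples": int(expr.shape[1]),
              "prognostic_genes": int(len(gene_p))}

    def empty_result(reason: str) -> TrainResult:
        # a cohort with no screenable signal is a legitimate outcome, not a
        # crash: return an empty signature and a flagged report
        logger.warning("empty signature: %s", reason)
        counts.setdefault("pairs_generated", 0)
        counts.setdefault("pairs_after_filter", 0)
        counts.setdefault("pairs_after_screen", 0)
        counts["pairs_in_signature"] = 0
        signature = PairSignature(
            pairs=GenePairSet((), provenance="adaptive-LASSO signature"),
            coefficients=np.empty(0), lambda_selected=float("nan"),
            ridge_lambda=float("nan"),
            ridge_betas=pd.Series(dtype=float, name="ridge_beta"),
            n_folds=config.adaptive.n_folds,
            fold_seed=config.adaptive.fold_seed,
            weight_cap=config.adaptive.weight_cap,
            selection_rule=config.adaptive.selection_rule,
            stage_counts=counts,
        )
        profile = RiskProfile(sample_ids=list(clinical.index),
                              lrgpi=np.zeros(len(clinical)),
                              cutoff=float("nan"),
                              group=np.array(["low"] * len(clinical)))
        report = {"stage_counts": counts, "seed": config.seed,
                  "empty_signature": True, "empty_reason": reason}
        return TrainResult(signature=signature, profile=profile, report=report)

    if len(gene_p) == 0:
        return empty_result("no gene passed the univariate screen")

    pairs = stage("enumerate_candidate_pairs", enumerate_candidate_pairs,
                  list(gene_p.index), list(expr.index),
                  priority=gene_p.to_dict())
    counts["pairs_generated"] = len(pairs)
    matrix = stage("build_pair_matrix", build_pair_matrix, expr, pairs)
    matrix = stage("consistency_filter", consistency_filter, matrix,
                   config.consistency_threshold)
    counts["pairs_after_filter"] = len(matrix.pairs)
    matrix = stage("screen_prognostic_pairs", screen_prognostic_pairs,
                   matrix, clinical, config.pair_screen_alpha)
    counts["pairs_after_screen"] = len(matrix.pairs)
    if len(matrix.pairs) == 0:
        return empty_result("no pair passed the univariate screen")

    signature = stage("fit_signature", fit_signature, matrix, clinical,
                      config.adaptive)
    counts["pairs_in_signature"] = len(signature)
    signature.stage_counts = counts
    logger.info("stage counts: %s", counts)

    scores = compute_lrgpi(matrix, signature) if len(signature) else pd.Series(
        0.0, index=matrix.sample_ids, name="lrgpi")
    report: dict = {"stage_counts": counts, "seed": config.seed}
    if len(signature) == 0 or np.ptp(scores.to_numpy()) == 0:
        logger.warning("empty or constant signature; no stratification possible")
        report["empty_signature"] = True
        profile = RiskProfile(sample_ids=list(scores.index),
                              lrgpi=scores.to_numpy(dtype=float),
                              cutoff=float("nan"),
                              group=np.array(["low"] * len(scores)))
        return TrainResult(signature=signature, profile=profile, report=report)

    group, cut = stage("stratify", stratify, scores.to_numpy(dtype=float), "median")
    profile = RiskProfile(sample_ids=list(scores.index),
                          lrgpi=scores.to_numpy(dtype=float),
                          cutoff=cut, group=group)
    report.update(stage("evaluate", evaluate, profile, clinical,
                        covariates, config.evaluation_horizons))
    return TrainResult(signature=signature, profile=profile, report=report)
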