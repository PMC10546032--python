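"""Synthetic expression + survival cohorts with planted gene-pair effects.

The generator emulates the statistical structure the gene-pair index
assumes in real tumor cohorts: log-scale expression with per-gene location
and scale, a proportional-hazards outcome whose log-hazard is a weighted
sum of within-sample ordering indicators for a set of "planted" gene
pairs, independent right-censoring calibrated to a target rate, and an
optional per-sample strictly monotone platform distortion standing in for
cross-platform normalization differences.

Event times are exponential given the covariates, so proportional hazards
holds by construction and a Cox fit of the true pair indicator is a valid
parameter-recovery oracle.  Times are in months throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairs import validate_expression

PLATFORM_TRANSFORMS = ("identity", "affine", "monotone_nonlinear")


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic cohort.

    planted_pairs holds (gene_index_a, gene_index_b, beta) triples: each
    contributes ``beta`` to a sample's log hazard whenever gene a is more
    expressed than gene b in that sample.  ``baseline_hazard`` is in events
    per month; ``max_followup`` bounds the uniform censoring times.
    """

    n_genes: int
    n_samples: int
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    gene_means: np.ndarray | None = None
    gene_sds: np.ndarray | None = None
    baseline_hazard: float = 0.04
    censoring_rate_target: float = 0.30
    max_followup: float = 180.0
    platform_transform: str = "identity"
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be positive")
        for a, b, _beta in self.planted_pairs:
            if a == b:
                raise ValueError("planted pair indices must be distinct")
            if not (0 <= a < self.n_genes and 0 <= b < self.n_genes):
                raise ValueError("planted pair index out of range")
        if self.gene_means is not None and len(self.gene_means) != self.n_genes:
            raise ValueError("gene_means length must equal n_genes")
        if self.gene_sds is not None:
            if len(self.gene_sds) != self.n_genes:
                raise ValueError("gene_sds length must equal n_genes")
            if np.any(np.asarray(self.gene_sds, dtype=float) <= 0):
                raise ValueError("gene_sds must be positive")
        if not 0.0 <= self.censoring_rate_target <= 1.0:
            raise ValueError("censoring_rate_target must lie in [0, 1]")
        if self.baseline_hazard <= 0 or self.max_followup <= 0:
            raise ValueError("baseline_hazard and max_followup must be positive")
        if self.platform_transform not in PLATFORM_TRANSFORMS:
            raise ValueError(f"unknown platform transform {self.platform_transform!r}")
        return self


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame          # genes x samples
    clinical: pd.DataFrame            # indexed by sample id
    truth: list[tuple[tuple[str, str], float]]  # ((gene_a, gene_b), beta)
    config: SimulationConfig

    @property
    def truth_pairs(self) -> list[tuple[str, str]]:
        return [p for p, _ in self.truth]


def default_config(
    n_genes: int,
    n_samples: int,
    n_planted: int = 0,
    beta: float = 1.0,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Convenience recipe with realistic marginals.

    Gene locations are drawn N(8, 1.5) on the log2 scale with per-gene
    scales U(0.8, 1.2) (typical of log-transformed tumor microarray/RNA-seq
    profiles).  The two genes of each planted pair share a location so the
    planted ordering indicator is balanced (~50% prevalence) and survives
    the consistency filter; planted betas alternate in sign.
    """
    rng = np.random.default_rng([int(seed), 0xC0F])
    means = rng.normal(8.0, 1.5, size=n_genes)
    sds = rng.uniform(0.8, 1.2, size=n_genes)
    if 2 * n_planted > n_genes:
        raise ValueError("not enough genes for the requested planted pairs")
    idx = rng.permutation(n_genes)
    planted = []
    for k in range(n_planted):
        a, b = int(idx[2 * k]), int(idx[2 * k + 1])
        means[b] = means[a]
        sds[b] = sds[a]
        planted.append((a, b, float(beta) * (1 if k % 2 == 0 else -1)))
    cfg = SimulationConfig(
        n_genes=n_genes,
        n_samples=n_samples,
        planted_pairs=planted,
        gene_means=means,
        gene_sds=sds,
        seed=int(seed),
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg.validate()


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def _calibrate_censoring(u: np.ndarray, t_event: np.ndarray, target: float,
                         max_followup: float) -> np.ndarray:
    """Censoring times ``u * U`` with the upper bound ``U`` found by
    bisection so the realized censoring fraction approaches ``target``.

    The realized fraction is monotone nonincreasing in U, so bisection on
    (0, max_followup] converges; if even U = max_followup censors more than
    the target (long event times), the bound is left at max_followup.
    """
    if target <= 0.0:
        return np.full_like(t_event, np.inf)

    def frac(upper: float) -> float:
        return float(np.mean(u * upper < t_event))

    lo, hi = 1e-9, float(max_followup)
    if frac(hi) >= target:
        return u * hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return u * hi


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort: expression, censored survival outcome, and the
    planted truth.  Deterministic given ``config`` (including its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    g, n = config.n_genes, config.n_samples
    means = (np.asarray(config.gene_means, dtype=float)
             if config.gene_means is not None else np.full(g, 8.0))
    sds = (np.asarray(config.gene_sds, dtype=float)
           if config.gene_sds is not None else np.ones(g))
    values = means[:, None] + sds[:, None] * rng.standard_normal((g, n))
    genes = _gene_ids(g)
    samples = _sample_ids(n)
    expr = pd.DataFrame(values, index=genes, columns=samples)

    log_hr = np.zeros(n)
    truth = []
    for a, b, beta in config.planted_pairs:
        indicator = (values[a] > values[b]).astype(float)
        log_hr += beta * indicator
        truth.append(((genes[a], genes[b]), float(beta)))
    hazard = config.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)

    u = 1.0 - rng.random(n)  # uniform on (0, 1]
    t_cens = _calibrate_censoring(u, t_event, config.censoring_rate_target,
                                  config.max_followup)
    # events at the censoring boundary count as observed
    time = np.minimum(t_event, t_cens)
    time = np.minimum(time, config.max_followup)
    event = (t_event <= t_cens) & (t_event <= config.max_followup)

    clinical = pd.DataFrame(
        {
            "time_months": time,
            "event": event.astype(int),
            "age": np.round(rng.normal(60.0, 10.0, size=n), 1),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    if config.platform_transform != "identity":
        expr = apply_platform_transform(expr, config.platform_transform,
                                        seed=config.seed + 1)
    return SyntheticCohort(expression=expr, clinical=clinical, truth=truth,
                           config=config)


def apply_platform_transform(expr: pd.DataFrame, kind: str, seed: int) -> pd.DataFrame:
    """Apply a per-sample strictly increasing map to every column.

    ``affine``: x -> a_s * x + b_s with a_s > 0.  ``monotone_nonlinear``:
    x -> a_s * x**3 + b_s * x + c_s with a_s, b_s > 0 (strictly increasing
    on all of R).  Either preserves every within-sample gene ordering, so
    pair scores are unchanged — the property the index relies on.
    """
    if kind not in PLATFORM_TRANSFORMS:
        raise ValueError(
            f"unknown or non-monotone transform {kind!r}; "
            f"choose one of {PLATFORM_TRANSFORMS}"
        )
    validate_expression(expr)
    if kind == "identity":
        return expr.copy()
    rng = np.random.default_rng(seed)
    n = expr.shape[1]
    x = expr.to_numpy(dtype=float)
    if kind == "affine":
        a = rng.uniform(0.5, 2.0, size=n)
        b = rng.normal(0.0, 2.0, size=n)
        out = x * a[None, :] + b[None, :]
    else:  # monotone_nonlinear
        a = rng.uniform(0.05, 0.5, size=n)
        b = rng.uniform(0.5, 2.0, size=n)
        c = rng.normal(0.0, 2.0, size=n)
        out = a[None, :] * x**3 + b[None, :] * x + c[None, :]
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
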