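"""Rank-based gene-pair encoding.

The core transformation of the index: within each sample, a gene pair
(A, B) scores 1 when A's expression strictly exceeds B's and 0 otherwise.
Because only within-sample orderings enter, the encoding is invariant to
any strictly increasing per-sample transform of the expression values,
which is what makes the downstream index portable across platforms and
normalization schemes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAIR_SEP = "|"


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes-by-samples expression matrix (unique gene symbols,
    unique sample ids, all values finite)."""
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][0]
        raise ValueError(f"duplicate gene symbol in expression matrix: {dup!r}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id in expression matrix: {dup!r}")
    values = expr.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite expression value at gene {expr.index[r]!r}, "
            f"sample {expr.columns[c]!r}"
        )
    return expr


def drop_incomplete_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with any missing value (pair scores are undefined on
    missing data); logs how many were removed."""
    keep = expr.notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d gene(s) with missing expression values", n_drop)
    return expr.loc[keep]


@dataclass(frozen=True)
class GenePairSet:
    """Ordered gene pairs; first member is the prognostic anchor gene."""

    pairs: tuple[tuple[str, str], ...]
    provenance: str = ""

    def __post_init__(self):
        seen: set[frozenset] = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"both orientations of {{{a}, {b}}} present")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def labels(self) -> list[str]:
        return [f"{a}{PAIR_SEP}{b}" for a, b in self.pairs]

    def genes(self) -> set[str]:
        return {g for p in self.pairs for g in p}


def pair_from_label(label: str) -> tuple[str, str]:
    a, sep, b = label.partition(PAIR_SEP)
    if not sep or not a or not b:
        raise ValueError(f"malformed pair label {label!r}")
    return a, b


@dataclass
class PairScoreMatrix:
    """Binary pairs-by-samples score matrix.

    ``scores`` is indexed by pair labels "A|B" with sample-id columns and
    uint8 {0, 1} entries, aligned row-for-row with ``pairs``.
    """

    pairs: GenePairSet
    scores: pd.DataFrame

    def __post_init__(self):
        if list(self.scores.index) != self.pairs.labels():
            raise ValueError("score rows do not match pair list")
        vals = self.scores.to_numpy()
        if vals.size and not np.isin(vals, [0, 1]).all():
            raise ValueError("pair scores must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def subset(self, labels: list[str], provenance: str | None = None) -> "PairScoreMatrix":
        """Row subset preserving the original pair order for labels given in
        that order."""
        prov = self.pairs.provenance if provenance is None else provenance
        pairs = GenePairSet(tuple(pair_from_label(l) for l in labels), provenance=prov)
        return PairScoreMatrix(pairs=pairs, scores=self.scores.loc[labels])


def score_pair(x_first: float, x_second: float) -> int:
    """1 if the first value strictly exceeds the second, else 0 (ties -> 0)."""
    if not (math.isfinite(x_first) and math.isfinite(x_second)):
        raise ValueError("pair scores are undefined for non-finite values")
    return int(x_first > x_second)


def enumerate_candidate_pairs(
    prognostic_genes,
    all_genes,
    priority: dict[str, float] | None = None,
) -> GenePairSet:
    """All pairs anchored by a prognostic gene, one orientation per
    unordered gene set.

    Each prognostic gene Gi is paired with every other gene Gj in the
    candidate universe.  When both genes of an unordered set are prognostic
    the pair would arise in both orientations; the orientation whose first
    gene has the smaller ``priority`` value (e.g. its univariate Cox
    p-value) is kept, falling back to position in ``prognostic_genes`` and
    then lexicographic order.  Keeping a single orientation matters because
    complementary score rows are perfectly collinear.
    """
    prognostic = list(prognostic_genes)
    universe = list(all_genes)
    missing = [g for g in prognostic if g not in set(universe)]
    if missing:
        raise ValueError(f"prognostic gene(s) not in candidate universe: {missing}")
    if len(set(prognostic)) != len(prognostic):
        raise ValueError("duplicate prognostic genes")

    def rank(gene: str):
        if priority is not None and gene in priority:
            return (0, priority[gene], gene)
        if gene in prognostic:
            return (1, prognostic.index(gene), gene)
        return (2, 0, gene)

    prog_set = set(prognostic)
    pairs: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    for gi in prognostic:
        for gj in universe:
            if gj == gi:
                continue
            key = frozenset((gi, gj))
            if key in seen:
                continue
            seen.add(key)
            if gj in prog_set and rank(gj) < rank(gi):
                pairs.append((gj, gi))
            else:
                pairs.append((gi, gj))
    return GenePairSet(tuple(pairs), provenance="candidate enumeration")


def build_pair_matrix(expr: pd.DataFrame, pairs: GenePairSet) -> PairScoreMatrix:
    """Binary score matrix: entry (pair, sample) = 1 iff the pair's first
    gene is more expressed than its second in that sample."""
    validate_expression(expr)
    missing = sorted(pairs.genes() - set(expr.index))
    if missing:
        raise ValueError(f"gene(s) missing from expression matrix: {missing}")
    if len(pairs) == 0:
        scores = pd.DataFrame(
            np.empty((0, expr.shape[1]), dtype=np.uint8), index=[], columns=expr.columns
        )
        return PairScoreMatrix(pairs=pairs, scores=scores)
    first = [a for a, _ in pairs.pairs]
    second = [b for _, b in pairs.pairs]
    a = expr.loc[first].to_numpy(dtype=float)
    b = expr.loc[second].to_numpy(dtype=float)
    scores = pd.DataFrame(
        (a > b).astype(np.uint8), index=pairs.labels(), columns=expr.columns
    )
    return PairScoreMatrix(pairs=pairs, scores=scores)


def consistency_filter(m: PairScoreMatrix, threshold: float = 0.70) -> PairScoreMatrix:
    """Drop near-constant pairs: a pair whose majority score occurs in
    strictly more than ``threshold`` of samples is abolished (a pair at
    exactly the threshold is retained).  Near-constant pairs carry almost
    no ordering information and would only add noise to the penalized fit.
    """
    if not (0.5 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0.5, 1)")
    if len(m.pairs) == 0 or m.scores.shape[1] == 0:
        return m
    vals = m.scores.to_numpy(dtype=float)
    ones = vals.mean(axis=1)
    majority = np.maximum(ones, 1.0 - ones)
    keep = majority <= threshold + 1e-12
    labels = [l for l, k in zip(m.scores.index, keep) if k]
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("consistency filter abolished %d of %d pairs", n_drop, len(keep))
    return m.subset(labels, provenance="consistency-filtered")
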