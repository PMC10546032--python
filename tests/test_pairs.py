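"""Gene-pair encoding: scoring, enumeration, consistency filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lactpair as lp
from lactpair.pairs import GenePairSet, PairScoreMatrix, pair_from_label


def _expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestScorePair:
    @pytest.mark.parametrize("a,b,expected", [(5.2, 3.1, 1), (3.1, 5.2, 0), (2.0, 2.0, 0)])
    def test_definition_including_ties(self, a, b, expected):
        assert lp.score_pair(a, b) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            lp.score_pair(float("nan"), 1.0)


class TestEnumeration:
    def test_three_gene_example(self):
        ps = lp.enumerate_candidate_pairs(["A", "B"], ["A", "B", "C"])
        assert set(ps.pairs) == {("A", "B"), ("A", "C"), ("B", "C")}
        assert len(ps) == 3

    def test_empty_prognostic_set(self):
        assert len(lp.enumerate_candidate_pairs([], ["A", "B"])) == 0

    def test_count_matches_brute_force_on_64_genes(self):
        genes = [f"g{i:02d}" for i in range(64)]
        prog = genes[:5]
        ps = lp.enumerate_candidate_pairs(prog, genes)
        # brute force: all ordered anchored pairs, deduplicated as unordered sets
        brute = {frozenset((gi, gj)) for gi in prog for gj in genes if gi != gj}
        assert len(ps) == len(brute) == 5 * 64 - 5 - 10
        assert {frozenset(p) for p in ps.pairs} == brute

    def test_orientation_follows_priority(self):
        ps = lp.enumerate_candidate_pairs(
            ["A", "B"], ["A", "B"], priority={"A": 0.04, "B": 0.001}
        )
        assert ps.pairs == (("B", "A"),)

    def test_absent_prognostic_gene_rejected(self):
        with pytest.raises(ValueError, match="not in candidate"):
            lp.enumerate_candidate_pairs(["Z"], ["A", "B"])

    def test_both_orientations_rejected_by_type(self):
        with pytest.raises(ValueError, match="orientations"):
            GenePairSet((("A", "B"), ("B", "A")))


class TestBuildPairMatrix:
    def test_elementwise_definition(self):
        expr = _expr([[2, 1, 3], [1, 2, 3]], genes=["a", "b"])
        m = lp.build_pair_matrix(expr, GenePairSet((("a", "b"),)))
        assert m.scores.loc["a|b"].tolist() == [1, 0, 0]

    def test_empty_pair_set_degenerate_shape(self):
        expr = _expr([[1, 2], [3, 4]])
        m = lp.build_pair_matrix(expr, GenePairSet(()))
        assert m.scores.shape == (0, 2)

    def test_missing_gene_named_in_error(self):
        expr = _expr([[1, 2], [3, 4]], genes=["a", "b"])
        with pytest.raises(ValueError, match="zz"):
            lp.build_pair_matrix(expr, GenePairSet((("a", "zz"),)))

    def test_monotone_nonlinear_transform_invariance(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.normal(8, 2, size=(12, 30)))
        pairs = lp.enumerate_candidate_pairs(list(expr.index[:4]), list(expr.index))
        m0 = lp.build_pair_matrix(expr, pairs)
        for kind in ("affine", "monotone_nonlinear"):
            m1 = lp.build_pair_matrix(
                lp.apply_platform_transform(expr, kind, seed=123), pairs
            )
            pd.testing.assert_frame_equal(m0.scores, m1.scores)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_complement_property(self, seed):
        """For ties-free data the (B,A) row is 1 - the (A,B) row."""
        rng = np.random.default_rng(seed)
        expr = _expr(rng.normal(size=(2, 8)), genes=["A", "B"])
        ab = lp.build_pair_matrix(expr, GenePairSet((("A", "B"),))).scores.to_numpy()
        ba = lp.build_pair_matrix(expr, GenePairSet((("B", "A"),))).scores.to_numpy()
        assert np.array_equal(ab, 1 - ba)


def _matrix_from_rows(rows):
    rows = np.asarray(rows, dtype=np.uint8)
    pairs = GenePairSet(tuple((f"a{i}", f"b{i}") for i in range(rows.shape[0])))
    scores = pd.DataFrame(rows, index=pairs.labels(),
                          columns=[f"s{j}" for j in range(rows.shape[1])])
    return PairScoreMatrix(pairs=pairs, scores=scores)


class TestConsistencyFilter:
    def test_exactly_seventy_percent_retained(self):
        m = _matrix_from_rows([[1] * 7 + [0] * 3])
        assert len(lp.consistency_filter(m, 0.70).pairs) == 1

    def test_eighty_percent_abolished(self):
        m = _matrix_from_rows([[1] * 8 + [0] * 2])
        assert len(lp.consistency_filter(m, 0.70).pairs) == 0

    def test_constant_rows_removed_exactly(self):
        rng = np.random.default_rng(1)
        balanced = rng.integers(0, 2, size=(100, 40))
        # force balance within the retention band
        balanced[:, :20] = 1
        balanced[:, 20:] = 0
        constant = np.concatenate([np.ones((3, 40)), np.zeros((2, 40))]).astype(int)
        m = _matrix_from_rows(np.vstack([balanced, constant]))
        kept = lp.consistency_filter(m, 0.70)
        # brute-force oracle: count majority frequency per row
        expect = [
            i for i, row in enumerate(m.scores.to_numpy())
            if max(row.mean(), 1 - row.mean()) <= 0.70
        ]
        assert len(kept.pairs) == len(expect) == 100

    def test_order_preserved_among_survivors(self):
        m = _matrix_from_rows([[1, 0, 1, 0], [1, 1, 1, 1], [0, 1, 0, 1]])
        kept = lp.consistency_filter(m, 0.70)
        assert list(kept.scores.index) == ["a0|b0", "a2|b2"]

    def test_empty_matrix_passthrough(self):
        m = _matrix_from_rows(np.empty((0, 4)))
        assert len(lp.consistency_filter(m).pairs) == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        m = _matrix_from_rows(rng.integers(0, 2, size=(20, 15)))
        once = lp.consistency_filter(m, 0.7)
        twice = lp.consistency_filter(once, 0.7)
        pd.testing.assert_frame_equal(once.scores, twice.scores)

    def test_threshold_validation(self):
        m = _matrix_from_rows([[1, 0]])
        with pytest.raises(ValueError):
            lp.consistency_filter(m, 0.4)


class TestValidation:
    def test_duplicate_gene_rejected(self):
        expr = _expr([[1, 2], [3, 4]], genes=["a", "a"])
        with pytest.raises(ValueError, match="duplicate gene"):
            lp.build_pair_matrix(expr, GenePairSet(()))

    def test_pair_label_round_trip(self):
        assert pair_from_label("LDHA|LDHB") == ("LDHA", "LDHB")
        with pytest.raises(ValueError):
            pair_from_label("LDHA")
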