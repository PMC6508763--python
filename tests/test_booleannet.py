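import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from boolnet import (
    ExpressionMatrix,
    build_network,
    classify_pair,
    count_quadrants,
    discretize,
    evaluate_pair,
    quadrant_test,
)
from boolnet.booleannet import QUADRANTS, QuadrantCounts
from boolnet.stepminer import HIGH, INTERMEDIATE, LOW, MISSING


def classify_oracle(a00, a01, a10, a11, s_min=3.0, e_max=0.1):
    """Independent brute-force reimplementation of the sparse-quadrant
    classifier, written from the defining formulas."""
    total = a00 + a01 + a10 + a11
    obs = {"00": a00, "01": a01, "10": a10, "11": a11}
    sparse = set()
    for q, o in obs.items():
        row = (a00 + a01) if q[0] == "0" else (a10 + a11)
        col = (a00 + a10) if q[1] == "0" else (a01 + a11)
        if total == 0 or row == 0 or col == 0:
            continue
        expected = row * col / total
        statistic = (expected - o) / math.sqrt(expected)
        err = (o / row + o / col) / 2.0
        if statistic > s_min and err < e_max:
            sparse.add(q)
    mapping = {
        frozenset({"01"}): "lolo",
        frozenset({"00"}): "lohi",
        frozenset({"11"}): "hilo",
        frozenset({"10"}): "hihi",
        frozenset({"01", "10"}): "eqv",
        frozenset({"00", "11"}): "opo",
    }
    return mapping.get(frozenset(sparse), "none")


counts_tables = st.tuples(*[st.integers(0, 60)] * 4).map(lambda t: QuadrantCounts(*t))


class TestCountQuadrants:
    def test_one_sample_per_quadrant(self):
        c = count_quadrants([LOW, LOW, HIGH, HIGH], [LOW, HIGH, LOW, HIGH])
        assert (c.a00, c.a01, c.a10, c.a11) == (1, 1, 1, 1)

    def test_intermediate_samples_ignored(self):
        c = count_quadrants([LOW, INTERMEDIATE, HIGH], [HIGH, HIGH, HIGH])
        assert c.total == 2
        assert c.a01 == 1 and c.a11 == 1

    def test_missing_samples_ignored(self):
        c = count_quadrants([LOW, MISSING, HIGH], [HIGH, HIGH, LOW])
        assert c.total == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            count_quadrants([LOW, HIGH], [LOW])

    def test_total_conservation(self, rng):
        for _ in range(20):
            a = rng.choice([LOW, INTERMEDIATE, HIGH, MISSING], size=50)
            b = rng.choice([LOW, INTERMEDIATE, HIGH, MISSING], size=50)
            c = count_quadrants(a, b)
            assert c.total == c.a00 + c.a01 + c.a10 + c.a11


class TestQuadrantTest:
    def test_hand_computed_example(self):
        t = quadrant_test(QuadrantCounts(40, 0, 30, 30), "01")
        assert t.expected == pytest.approx(12.0)
        assert t.statistic == pytest.approx((12 - 0) / math.sqrt(12))
        assert t.error_rate == 0.0
        assert t.sparse

    def test_independence_gives_zero_statistic(self):
        t = quadrant_test(QuadrantCounts(25, 25, 25, 25), "01")
        assert t.statistic == pytest.approx(0.0)
        assert t.error_rate == pytest.approx(0.5)
        assert not t.sparse

    def test_observed_equals_expected_gives_zero(self, rng):
        for _ in range(20):
            c = QuadrantCounts(*[int(v) for v in rng.integers(1, 40, 4)])
            for q in QUADRANTS:
                t = quadrant_test(c, q)
                if t.testable and abs(t.observed - t.expected) < 1e-12:
                    assert t.statistic == pytest.approx(0.0)

    def test_zero_margin_untestable(self):
        t = quadrant_test(QuadrantCounts(0, 0, 10, 10), "00")
        assert not t.testable and not t.sparse

    def test_monotone_in_observed(self):
        # with margins held fixed, fewer observed points => larger statistic
        base = QuadrantCounts(40, 5, 30, 30)
        tests = []
        for o in range(5, 0, -1):
            # keep margins fixed by moving mass between 01 and its margins'
            # complement is impossible exactly; test the formula directly
            row, col, total = 45, 35, 105
            e = row * col / total
            tests.append((e - o) / math.sqrt(e))
        assert all(x < y for x, y in zip(tests, tests[1:]))


class TestClassifyPair:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (QuadrantCounts(40, 0, 30, 30), "lolo"),
            (QuadrantCounts(25, 25, 25, 25), "none"),
            (QuadrantCounts(50, 0, 0, 50), "eqv"),
            (QuadrantCounts(0, 50, 50, 0), "opo"),
            (QuadrantCounts(0, 40, 30, 30), "lohi"),
            (QuadrantCounts(30, 30, 40, 0), "hilo"),
            (QuadrantCounts(30, 30, 0, 40), "hihi"),
        ],
    )
    def test_archetype_tables(self, counts, expected):
        assert classify_pair(counts) == expected

    @given(counts_tables)
    @settings(deadline=None, max_examples=500, derandomize=True)
    def test_agrees_with_brute_force_oracle(self, counts):
        assert classify_pair(counts) == classify_oracle(
            counts.a00, counts.a01, counts.a10, counts.a11
        )

    @given(counts_tables)
    @settings(deadline=None, max_examples=500, derandomize=True)
    def test_order_reversal_mapping(self, counts):
        forward = classify_pair(counts)
        backward = classify_pair(counts.swapped())
        mapping = {
            "lolo": "hihi", "hihi": "lolo",
            "lohi": "lohi", "hilo": "hilo",
            "eqv": "eqv", "opo": "opo", "none": "none",
        }
        assert backward == mapping[forward]

    @given(counts_tables)
    @settings(deadline=None, max_examples=500, derandomize=True)
    def test_negation_of_b_maps_classes(self, counts):
        # flipping B's LOW/HIGH swaps the columns of the table
        negated = QuadrantCounts(counts.a01, counts.a00, counts.a11, counts.a10)
        mapping = {
            "eqv": "opo", "opo": "eqv",
            "lolo": "lohi", "lohi": "lolo",
            "hihi": "hilo", "hilo": "hihi",
            "none": "none",
        }
        assert classify_pair(negated) == mapping[classify_pair(counts)]

    @given(counts_tables)
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_symmetric_classes_have_both_diagonals_sparse(self, counts):
        res = evaluate_pair(counts)
        if res.relationship == "eqv":
            assert res.tests["01"].sparse and res.tests["10"].sparse
        if res.relationship == "opo":
            assert res.tests["00"].sparse and res.tests["11"].sparse


def _matrix_from_states(states_a, states_b, n_extra_low=0):
    """Two-gene expression matrix realizing given binary state vectors."""
    lo, hi = 4.0, 9.0
    va = np.where(states_a, hi, lo).astype(float)
    vb = np.where(states_b, hi, lo).astype(float)
    frame = pd.DataFrame(
        [va, vb], index=["A", "B"],
        columns=[f"s{i}" for i in range(len(va))],
    )
    return ExpressionMatrix(frame)


class TestBuildNetwork:
    def test_perfect_equivalents_stored_both_directions(self):
        states = np.array([0] * 20 + [1] * 20, dtype=bool)
        matrix = _matrix_from_states(states, states)
        net = build_network(discretize(matrix))
        assert net.n_edges == 2
        assert set(zip(net.edges["gene_a"], net.edges["gene_b"])) == {
            ("A", "B"), ("B", "A")
        }
        assert set(net.edges["relationship"]) == {"eqv"}

    def test_planted_lolo_reversed_is_hihi(self, rng):
        a = rng.random(200) < 0.5
        b = np.where(a, rng.random(200) < 0.5, False)
        net = build_network(discretize(_matrix_from_states(a, b)))
        rels = dict(zip(zip(net.edges["gene_a"], net.edges["gene_b"]),
                        net.edges["relationship"]))
        assert rels[("A", "B")] == "lolo"
        assert rels[("B", "A")] == "hihi"

    def test_fewer_than_two_dynamic_genes_warns_empty(self):
        frame = pd.DataFrame(
            [[5.0] * 10, [1, 1, 1, 1, 1, 9, 9, 9, 9, 9]],
            index=["flat", "dyn"], columns=[f"s{i}" for i in range(10)],
        )
        tern = discretize(ExpressionMatrix(frame))
        with pytest.warns(UserWarning, match="fewer than 2 dynamic genes"):
            net = build_network(tern)
        assert net.n_edges == 0

    def test_vectorized_scan_agrees_with_pairwise_classification(
        self, planted_dataset
    ):
        tern = discretize(planted_dataset.matrix)
        net = build_network(tern)
        genes = net.genes
        codes = tern.codes
        expected = {}
        for ga in genes:
            for gb in genes:
                if ga == gb:
                    continue
                rel = classify_pair(
                    count_quadrants(codes.loc[ga].to_numpy(), codes.loc[gb].to_numpy())
                )
                if rel != "none":
                    expected[(ga, gb)] = rel
        got = dict(zip(zip(net.edges["gene_a"], net.edges["gene_b"]),
                       net.edges["relationship"]))
        assert got == expected

    def test_deterministic(self, planted_dataset):
        tern = discretize(planted_dataset.matrix)
        n1 = build_network(tern)
        n2 = build_network(tern)
        pd.testing.assert_frame_equal(n1.edges, n2.edges)
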