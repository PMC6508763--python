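"""Sparse-quadrant implication testing and the six relationship classes.

For an ordered pair of discretized genes (A, B), samples where both calls
are extreme (LOW or HIGH) populate a 2x2 quadrant table; INTERMEDIATE and
MISSING calls are ignored.  A quadrant (A=i, B=j) with row margin R,
column margin C and total T has expected occupancy E = R*C/T under
independence; it is "sparse" when the statistic

    S = (E - O) / sqrt(E)

exceeds ``s_min`` (default 3) and the error rate

    e = (O/R + O/C) / 2

stays below ``e_max`` (default 0.1), O being the observed count.  The
sparse-quadrant pattern determines the relationship:

=================  =============================  =========
sparse quadrants   implication                    label
=================  =============================  =========
{01}               A low  => B low                lolo
{00}               A low  => B high               lohi
{11}               A high => B low                hilo
{10}               A high => B high               hihi
{01, 10}           A equivalent B                 eqv
{00, 11}           A opposite B                   opo
anything else      no relationship                none
=================  =============================  =========

Quadrant "ij" means A in state i and B in state j with 0 = low, 1 = high.
A quadrant whose row or column margin is zero is untestable and treated
as not sparse; combined with the dynamic-range gate this keeps vacuous
implications out of the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .stepminer import (
    HIGH,
    LOW,
    TernaryMatrix,
    default_dynamic_minimum,
)

__all__ = [
    "DEFAULT_STAT_MIN",
    "DEFAULT_ERR_MAX",
    "QUADRANTS",
    "RELATIONSHIPS",
    "QuadrantCounts",
    "QuadrantTest",
    "ImplicationResult",
    "BooleanNetwork",
    "count_quadrants",
    "quadrant_test",
    "evaluate_pair",
    "classify_pair",
    "build_network",
]

DEFAULT_STAT_MIN = 3.0
DEFAULT_ERR_MAX = 0.1

QUADRANTS = ("00", "01", "10", "11")

RELATIONSHIPS = ("lolo", "lohi", "hilo", "hihi", "eqv", "opo")

#: sparse-quadrant pattern -> relationship label
_PATTERN_TO_LABEL = {
    frozenset({"01"}): "lolo",
    frozenset({"00"}): "lohi",
    frozenset({"11"}): "hilo",
    frozenset({"10"}): "hihi",
    frozenset({"01", "10"}): "eqv",
    frozenset({"00", "11"}): "opo",
}

#: relationship label -> its sparse quadrants (the quadrants it forbids)
SPARSE_QUADRANTS = {label: tuple(sorted(q)) for q, label in _PATTERN_TO_LABEL.items()}


@dataclass(frozen=True)
class QuadrantCounts:
    """Occupancy of the four quadrants for one ordered gene pair.

    a_ij counts samples with gene A in state i and gene B in state j
    (0 = low, 1 = high), over samples where both genes have extreme calls.
    """

    a00: int
    a01: int
    a10: int
    a11: int

    @property
    def total(self) -> int:
        return self.a00 + self.a01 + self.a10 + self.a11

    def quadrant(self, q: str) -> int:
        return {"00": self.a00, "01": self.a01, "10": self.a10, "11": self.a11}[q]

    def swapped(self) -> "QuadrantCounts":
        """Counts for the reversed pair (B, A): transpose of the table."""
        return QuadrantCounts(self.a00, self.a10, self.a01, self.a11)


class QuadrantTest(NamedTuple):
    observed: float
    expected: float
    statistic: float
    error_rate: float
    testable: bool
    sparse: bool


@dataclass(frozen=True)
class ImplicationResult:
    """Full sparse-quadrant evaluation for one ordered pair."""

    counts: QuadrantCounts
    tests: dict[str, QuadrantTest]
    relationship: str
    pair: tuple[str, str] | None = None


def count_quadrants(ternary_a: Sequence[int], ternary_b: Sequence[int]) -> QuadrantCounts:
    """Count quadrant occupancy, ignoring INTERMEDIATE and MISSING calls.

    A sample contributes only when both genes' calls are LOW or HIGH.
    """
    a = np.asarray(ternary_a)
    b = np.asarray(ternary_b)
    if a.shape != b.shape:
        raise ValueError(f"code vectors differ in length: {a.shape} vs {b.shape}")
    al, ah = a == LOW, a == HIGH
    bl, bh = b == LOW, b == HIGH
    return QuadrantCounts(
        a00=int((al & bl).sum()),
        a01=int((al & bh).sum()),
        a10=int((ah & bl).sum()),
        a11=int((ah & bh).sum()),
    )


def _margins(counts: QuadrantCounts, quadrant: str) -> tuple[int, int]:
    i, j = quadrant
    row = counts.a00 + counts.a01 if i == "0" else counts.a10 + counts.a11
    col = counts.a00 + counts.a10 if j == "0" else counts.a01 + counts.a11
    return row, col


def quadrant_test(
    counts: QuadrantCounts,
    quadrant: str,
    s_min: float = DEFAULT_STAT_MIN,
    e_max: float = DEFAULT_ERR_MAX,
) -> QuadrantTest:
    """Sparseness test for one quadrant of a pair's count table.

    Returns observed O, expected E = R*C/total, statistic S = (E-O)/sqrt(E)
    and error rate e = (O/R + O/C)/2.  A quadrant with a zero row or column
    margin (one gene never reaches the required state among the jointly
    extreme samples) is untestable and reported not sparse.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    total = counts.total
    row, col = _margins(counts, quadrant)
    if total == 0 or row == 0 or col == 0:
        return QuadrantTest(
            observed=float(counts.quadrant(quadrant)),
            expected=float("nan"),
            statistic=float("nan"),
            error_rate=float("nan"),
            testable=False,
            sparse=False,
        )
    observed = float(counts.quadrant(quadrant))
    expected = row * col / total
    statistic = (expected - observed) / np.sqrt(expected)
    error_rate = (observed / row + observed / col) / 2.0
    return QuadrantTest(
        observed=observed,
        expected=float(expected),
        statistic=float(statistic),
        error_rate=float(error_rate),
        testable=True,
        sparse=bool(statistic > s_min and error_rate < e_max),
    )


def evaluate_pair(
    counts: QuadrantCounts,
    s_min: float = DEFAULT_STAT_MIN,
    e_max: float = DEFAULT_ERR_MAX,
    pair: tuple[str, str] | None = None,
) -> ImplicationResult:
    """Run all four quadrant tests and assign the relationship label.

    Patterns with no sparse quadrant, an adjacent (same-row / same-column)
    sparse pair, or three or more sparse quadrants map to "none".
    """
    tests = {q: quadrant_test(counts, q, s_min=s_min, e_max=e_max) for q in QUADRANTS}
    pattern = frozenset(q for q in QUADRANTS if tests[q].sparse)
    relationship = _PATTERN_TO_LABEL.get(pattern, "none")
    return ImplicationResult(counts=counts, tests=tests, relationship=relationship, pair=pair)


def classify_pair(
    counts: QuadrantCounts,
    s_min: float = DEFAULT_STAT_MIN,
    e_max: float = DEFAULT_ERR_MAX,
) -> str:
    """Relationship label for one ordered pair's quadrant counts."""
    return evaluate_pair(counts, s_min=s_min, e_max=e_max).relationship


@dataclass
class BooleanNetwork:
    """A classified implication network over the dynamic genes.

    ``edges`` holds one row per ordered pair with a non-"none" relationship
    (symmetric classes therefore appear in both orders), with the sparse
    quadrants' statistics and error rates semicolon-joined and the four
    quadrant counts.  ``params`` records the thresholds used.
    """

    genes: list[str]
    edges: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def relationship_multiset(self) -> list[tuple[str, str, str]]:
        return sorted(
            zip(self.edges["gene_a"], self.edges["gene_b"], self.edges["relationship"])
        )


_EDGE_COLUMNS = [
    "gene_a",
    "gene_b",
    "relationship",
    "statistic",
    "error_rate",
    "a00",
    "a01",
    "a10",
    "a11",
]


def _fmt(values) -> str:
    return ";".join(f"{v:.6g}" for v in values)


def build_network(
    ternary: TernaryMatrix,
    s_min: float = DEFAULT_STAT_MIN,
    e_max: float = DEFAULT_ERR_MAX,
    min_low: int | None = None,
    min_high: int | None = None,
) -> BooleanNetwork:
    """Classify all ordered pairs of dynamic genes into a network.

    All pairwise quadrant tables are assembled with boolean matrix products
    over the LOW/HIGH indicator matrices, so the full ordered-pair scan is
    a handful of dense matrix multiplications.  Deterministic given inputs.
    """
    n_samples = len(ternary.sample_ids)
    if min_low is None:
        min_low = default_dynamic_minimum(n_samples)
    if min_high is None:
        min_high = default_dynamic_minimum(n_samples)
    params = {
        "margin": ternary.margin,
        "s_min": s_min,
        "e_max": e_max,
        "min_low": min_low,
        "min_high": min_high,
    }
    genes = ternary.dynamic_genes(min_low=min_low, min_high=min_high)
    empty = pd.DataFrame(columns=_EDGE_COLUMNS)
    if len(genes) < 2:
        warnings.warn(
            f"fewer than 2 dynamic genes ({len(genes)}); network is empty",
            stacklevel=2,
        )
        return BooleanNetwork(genes=genes, edges=empty, params=params)

    codes = ternary.codes.loc[genes].to_numpy()
    lo = (codes == LOW).astype(np.float64)
    hi = (codes == HIGH).astype(np.float64)
    # Pairwise quadrant tables: A00[i, j] = #samples with gene i LOW & gene j LOW, etc.
    A00 = lo @ lo.T
    A01 = lo @ hi.T
    A10 = hi @ lo.T
    A11 = hi @ hi.T
    total = A00 + A01 + A10 + A11
    r_low = A00 + A01
    r_high = A10 + A11
    c_low = A00 + A10
    c_high = A01 + A11

    sparse = {}
    stats = {}
    errs = {}
    quadrant_data = {
        "00": (A00, r_low, c_low),
        "01": (A01, r_low, c_high),
        "10": (A10, r_high, c_low),
        "11": (A11, r_high, c_high),
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        for q, (obs, row, col) in quadrant_data.items():
            expected = row * col / total
            s = (expected - obs) / np.sqrt(expected)
            e = (obs / row + obs / col) / 2.0
            testable = (total > 0) & (row > 0) & (col > 0)
            sparse[q] = testable & (s > s_min) & (e < e_max)
            stats[q] = s
            errs[q] = e

    # Encode each pair's sparse pattern as a 4-bit integer and map to labels.
    pattern = (
        sparse["00"].astype(np.int8)
        + 2 * sparse["01"].astype(np.int8)
        + 4 * sparse["10"].astype(np.int8)
        + 8 * sparse["11"].astype(np.int8)
    )
    label_of = {1: "lohi", 2: "lolo", 4: "hihi", 8: "hilo", 6: "eqv", 9: "opo"}

    records = []
    n = len(genes)
    ii, jj = np.nonzero(np.isin(pattern, list(label_of)) & ~np.eye(n, dtype=bool))
    for i, j in zip(ii, jj):
        label = label_of[int(pattern[i, j])]
        qs = SPARSE_QUADRANTS[label]
        records.append(
            {
                "gene_a": genes[i],
                "gene_b": genes[j],
                "relationship": label,
                "statistic": _fmt(stats[q][i, j] for q in qs),
                "error_rate": _fmt(errs[q][i, j] for q in qs),
                "a00": int(A00[i, j]),
                "a01": int(A01[i, j]),
                "a10": int(A10[i, j]),
                "a11": int(A11[i, j]),
            }
        )
    edges = pd.DataFrame(records, columns=_EDGE_COLUMNS)
    if len(edges):
        edges = edges.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(
            drop=True
        )
    return BooleanNetwork(genes=genes, edges=edges, params=params)
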