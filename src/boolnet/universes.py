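"""Tissue universes and candidate logical invariants.

A universe is a coherent subset of samples — e.g. all root samples form
the root universe, and the union of every tissue forms the all-samples
universe.  A Boolean relationship that held for *every* possible sample of
a universe would be a logical invariant of that universe; finite data can
never establish that, so this module only flags *candidates*: pairs whose
relationship passes the sparse-quadrant thresholds within the universe.

By default the per-gene thresholds fitted on the full matrix are reused
inside every universe (quadrant membership of a sample then does not
depend on which universe it is viewed in); ``rediscretize=True`` refits
thresholds within each universe instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .booleannet import (
    DEFAULT_ERR_MAX,
    DEFAULT_STAT_MIN,
    SPARSE_QUADRANTS,
    count_quadrants,
    evaluate_pair,
)
from .matrix_io import ExpressionMatrix
from .stepminer import (
    DEFAULT_MARGIN,
    HIGH,
    INTERMEDIATE,
    LOW,
    MISSING,
    DegenerateInputError,
    fit_step,
)

__all__ = [
    "ALL_SAMPLES",
    "Universe",
    "InvariantReport",
    "make_universes",
    "evaluate_invariant",
]

ALL_SAMPLES = "all-samples"


@dataclass(frozen=True)
class Universe:
    """A named, non-empty subset of the annotated samples."""

    name: str
    sample_ids: tuple[str, ...]

    def __post_init__(self):
        if not self.sample_ids:
            raise ValueError(f"universe {self.name!r} has no samples")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class InvariantReport:
    """Evaluation of one gene pair inside one universe.

    ``violations`` counts the samples of the universe falling inside the
    sparse quadrant(s) of the *globally* assigned relationship; ``candidate``
    is True iff the pair's relationship within the universe is not "none".
    """

    pair: tuple[str, str]
    universe: str
    n_samples: int
    relationship: str
    statistics: tuple[float, ...]
    error_rates: tuple[float, ...]
    violations: int
    candidate: bool
    testable: bool = True


def _canon(label: str) -> str:
    return str(label).strip().casefold()


def make_universes(
    annotation: pd.DataFrame, tissue_labels: Sequence[str]
) -> list[Universe]:
    """One universe per requested tissue plus the all-samples universe.

    Membership is by exact tissue-label match after case-folding and
    whitespace trimming; a requested label matching no samples emits a
    warning and is omitted.  Unannotated tissue cells contribute only to
    the all-samples universe.  The result is order-independent in the
    annotation rows.
    """
    sample_ids = annotation["sample_id"].astype(str)
    tissues = annotation["tissue"].map(_canon)
    universes: list[Universe] = []
    for label in tissue_labels:
        want = _canon(label)
        members = tuple(sample_ids[tissues == want])
        if not members:
            warnings.warn(f"tissue label {label!r} matches no samples; universe omitted",
                          stacklevel=2)
            continue
        universes.append(Universe(name=f"{want}-universe", sample_ids=members))
    universes.append(Universe(name=ALL_SAMPLES, sample_ids=tuple(sample_ids)))
    return universes


def _codes_for(values: np.ndarray, threshold: float, margin: float) -> np.ndarray:
    codes = np.full(values.shape, INTERMEDIATE, dtype=np.int8)
    codes[values > threshold + margin] = HIGH
    codes[values < threshold - margin] = LOW
    codes[np.isnan(values)] = MISSING
    return codes


def evaluate_invariant(
    pair: tuple[str, str],
    matrix: ExpressionMatrix,
    universes: Sequence[Universe],
    rediscretize: bool = False,
    margin: float = DEFAULT_MARGIN,
    s_min: float = DEFAULT_STAT_MIN,
    e_max: float = DEFAULT_ERR_MAX,
) -> list[InvariantReport]:
    """Evaluate one gene pair's relationship in each universe.

    For each universe the samples are subset, the pair is re-counted and
    re-classified, and the violation count (occupancy of the sparse
    quadrant(s) of the relationship assigned on the full matrix) is
    reported.  A universe with fewer than 2 jointly usable values for
    either gene is reported untestable.
    """
    gene_a, gene_b = pair
    for g in (gene_a, gene_b):
        if g not in matrix.values.index:
            raise KeyError(f"gene {g!r} not in matrix")
    va = matrix.values.loc[gene_a].to_numpy(dtype=float)
    vb = matrix.values.loc[gene_b].to_numpy(dtype=float)
    fit_a = fit_step(va)
    fit_b = fit_step(vb)
    global_codes_a = _codes_for(va, fit_a.threshold, margin)
    global_codes_b = _codes_for(vb, fit_b.threshold, margin)
    global_result = evaluate_pair(
        count_quadrants(global_codes_a, global_codes_b), s_min=s_min, e_max=e_max
    )
    global_sparse = SPARSE_QUADRANTS.get(global_result.relationship, ())

    col_pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    reports: list[InvariantReport] = []
    for uni in universes:
        idx = np.array([col_pos[s] for s in uni.sample_ids if s in col_pos], dtype=int)
        ua, ub = va[idx], vb[idx]
        if rediscretize:
            try:
                ca = _codes_for(ua, fit_step(ua).threshold, margin)
                cb = _codes_for(ub, fit_step(ub).threshold, margin)
            except DegenerateInputError:
                reports.append(
                    InvariantReport(
                        pair=pair, universe=uni.name, n_samples=len(idx),
                        relationship="none", statistics=(), error_rates=(),
                        violations=0, candidate=False, testable=False,
                    )
                )
                continue
        else:
            ca = global_codes_a[idx]
            cb = global_codes_b[idx]
        if len(idx) < 2:
            reports.append(
                InvariantReport(
                    pair=pair, universe=uni.name, n_samples=len(idx),
                    relationship="none", statistics=(), error_rates=(),
                    violations=0, candidate=False, testable=False,
                )
            )
            continue
        counts = count_quadrants(ca, cb)
        result = evaluate_pair(counts, s_min=s_min, e_max=e_max)
        qs = SPARSE_QUADRANTS.get(result.relationship, ())
        reports.append(
            InvariantReport(
                pair=pair,
                universe=uni.name,
                n_samples=len(idx),
                relationship=result.relationship,
                statistics=tuple(result.tests[q].statistic for q in qs),
                error_rates=tuple(result.tests[q].error_rate for q in qs),
                violations=int(sum(counts.quadrant(q) for q in global_sparse)),
                candidate=result.relationship != "none",
            )
        )
    return reports
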