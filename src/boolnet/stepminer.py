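"""Step-function thresholding and ternary discretization of expression.

Each gene's expression values, sorted ascending, are fitted with a rising
one-step function: for every breakpoint k the first k values are modelled
by their mean m1 and the remainder by their mean m2, and the breakpoint
minimizing the residual sum of squares is kept.  The gene's threshold t is
the midpoint (m1 + m2) / 2 of the fitted segment means, which makes the
threshold shift-equivariant (adding a constant to a gene shifts t by that
constant).  Values above t + margin are called HIGH, below t - margin LOW,
and INTERMEDIATE inside the margin band; the margin defaults to 0.5 log2
units.

Genes without usable dynamic range (too few LOW or HIGH calls) produce
vacuous implications downstream and are gated out via :func:`is_dynamic`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix_io import ExpressionMatrix

__all__ = [
    "LOW",
    "INTERMEDIATE",
    "HIGH",
    "MISSING",
    "CODE_LABELS",
    "DEFAULT_MARGIN",
    "StepFit",
    "TernaryMatrix",
    "DegenerateInputError",
    "fit_step",
    "discretize",
    "is_dynamic",
    "default_dynamic_minimum",
]

# Ternary codes. MISSING is kept negative so {0,1,2} are the real calls.
LOW = 0
INTERMEDIATE = 1
HIGH = 2
MISSING = -1

CODE_LABELS = {LOW: "low", INTERMEDIATE: "intermediate", HIGH: "high", MISSING: "NA"}

DEFAULT_MARGIN = 0.5


class DegenerateInputError(ValueError):
    """Fewer than 2 non-missing values: no step can be fitted."""


@dataclass(frozen=True)
class StepFit:
    """A fitted rising one-step function for one gene.

    Attributes
    ----------
    threshold
        Midpoint of the two segment means, in log2 units.
    breakpoint
        Number of values in the low segment (1 <= breakpoint <= n-1).
    low_mean, high_mean
        Means of the low and high segments (low_mean <= high_mean).
    sse
        Residual sum of squares of the two-segment fit.
    n
        Number of non-missing values used.
    degenerate
        True when all values are identical (threshold is the common value).
    """

    threshold: float
    breakpoint: int
    low_mean: float
    high_mean: float
    sse: float
    n: int
    degenerate: bool = False


def fit_step(values: Sequence[float]) -> StepFit:
    """Fit a rising one-step function to a gene's expression values.

    Values are sorted ascending; for each breakpoint k in [1, n-1] the SSE
    of the two-segment mean model is computed and the minimizing k is
    returned, ties broken toward the smallest k.

    Raises
    ------
    DegenerateInputError
        With fewer than 2 non-missing values.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise DegenerateInputError(
            f"need at least 2 non-missing values to fit a step, got {n}"
        )
    x = np.sort(x)
    if x[0] == x[-1]:
        v = float(x[0])
        return StepFit(v, 1, v, v, 0.0, n, degenerate=True)
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    k = np.arange(1, n)
    left_sum = cs[k - 1]
    left_sse = css[k - 1] - left_sum**2 / k
    right_sum = cs[-1] - left_sum
    right_sse = (css[-1] - css[k - 1]) - right_sum**2 / (n - k)
    sse = np.maximum(left_sse, 0.0) + np.maximum(right_sse, 0.0)
    best = int(np.argmin(sse))  # argmin returns the first (smallest-k) minimum
    kopt = int(k[best])
    m1 = float(left_sum[best] / kopt)
    m2 = float(right_sum[best] / (n - kopt))
    return StepFit(
        threshold=(m1 + m2) / 2.0,
        breakpoint=kopt,
        low_mean=m1,
        high_mean=m2,
        sse=float(sse[best]),
        n=n,
    )


def default_dynamic_minimum(n: int) -> int:
    """Default per-extreme call minimum for the dynamic-range gate."""
    return max(3, math.ceil(0.025 * n))


def is_dynamic(
    ternary_row: Sequence[int], min_low: int, min_high: int
) -> bool:
    """True iff the gene has at least min_low LOW and min_high HIGH calls."""
    codes = np.asarray(ternary_row)
    return bool(
        (codes == LOW).sum() >= min_low and (codes == HIGH).sum() >= min_high
    )


@dataclass
class TernaryMatrix:
    """Discretized expression calls plus the per-probe step fits.

    ``codes`` has the same shape and id order as the source matrix, with
    int8 entries in {LOW, INTERMEDIATE, HIGH, MISSING}.
    """

    codes: pd.DataFrame
    fits: dict[str, StepFit]
    margin: float = DEFAULT_MARGIN

    @property
    def probe_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.codes.columns)

    def thresholds_frame(
        self, min_low: int | None = None, min_high: int | None = None
    ) -> pd.DataFrame:
        """Per-probe threshold table (probe, t, breakpoint, sse, dynamic)."""
        n = len(self.sample_ids)
        if min_low is None:
            min_low = default_dynamic_minimum(n)
        if min_high is None:
            min_high = default_dynamic_minimum(n)
        rows = []
        for probe in self.probe_ids:
            f = self.fits[probe]
            rows.append(
                {
                    "probe_id": probe,
                    "threshold": f.threshold,
                    "breakpoint": f.breakpoint,
                    "low_mean": f.low_mean,
                    "high_mean": f.high_mean,
                    "sse": f.sse,
                    "n": f.n,
                    "degenerate": f.degenerate,
                    "dynamic": is_dynamic(
                        self.codes.loc[probe].to_numpy(), min_low, min_high
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("probe_id")

    def dynamic_genes(
        self, min_low: int | None = None, min_high: int | None = None
    ) -> list[str]:
        """Probes passing the dynamic-range gate (computed from codes only)."""
        n = len(self.sample_ids)
        if min_low is None:
            min_low = default_dynamic_minimum(n)
        if min_high is None:
            min_high = default_dynamic_minimum(n)
        codes = self.codes.to_numpy()
        n_low = (codes == LOW).sum(axis=1)
        n_high = (codes == HIGH).sum(axis=1)
        keep = (n_low >= min_low) & (n_high >= min_high)
        return [p for p, ok in zip(self.probe_ids, keep) if ok]


def discretize(matrix: ExpressionMatrix, margin: float = DEFAULT_MARGIN) -> TernaryMatrix:
    """Discretize every gene of a matrix into LOW / INTERMEDIATE / HIGH.

    Each gene's threshold is fitted on its non-missing values; a cell maps
    to HIGH iff value > t + margin, LOW iff value < t - margin, and
    INTERMEDIATE otherwise.  Missing cells map to MISSING.  Genes with
    fewer than 2 non-missing values raise :class:`DegenerateInputError`.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    vals = matrix.values.to_numpy(dtype=float)
    codes = np.full(vals.shape, INTERMEDIATE, dtype=np.int8)
    fits: dict[str, StepFit] = {}
    for i, probe in enumerate(matrix.probe_ids):
        row = vals[i]
        fit = fit_step(row)
        fits[probe] = fit
        t = fit.threshold
        codes[i, row > t + margin] = HIGH
        codes[i, row < t - margin] = LOW
        codes[i, np.isnan(row)] = MISSING
    frame = pd.DataFrame(
        codes, index=matrix.probe_ids, columns=matrix.sample_ids, dtype=np.int8
    )
    return TernaryMatrix(codes=frame, fits=fits, margin=margin)
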