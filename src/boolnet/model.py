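"""Model/Results interface over the implication-network pipeline.

:class:`BooleanNetworkModel` wraps an expression matrix (and optional
sample annotation); ``fit()`` runs per-gene step-function thresholding,
ternary discretization, the dynamic-range gate and the all-pairs
sparse-quadrant scan, returning a :class:`BooleanNetworkResults` that
carries the per-gene threshold diagnostics, the classified network, and
the downstream analyses (per-probe relationship counts, universe
invariant evaluation, network comparison, scatter export/plotting).

    >>> model = BooleanNetworkModel.from_dataframe(frame, annotation=annot)
    >>> res = model.fit(margin=0.5, stat_min=3, err_max=0.1)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import booleannet, matrix_io, netcompare, stepminer, universes as universes_mod
from .booleannet import BooleanNetwork
from .matrix_io import ExpressionMatrix
from .stepminer import TernaryMatrix

__all__ = ["BooleanNetworkModel", "BooleanNetworkResults"]


class BooleanNetworkModel:
    """Boolean implication network model of a gene expression matrix.

    Parameters
    ----------
    matrix
        :class:`~boolnet.matrix_io.ExpressionMatrix` of normalized
        log2-scale values (probes x samples).
    annotation
        Optional sample annotation table (sample_id, tissue, accession)
        used for universe construction and scatter export.
    """

    def __init__(self, matrix: ExpressionMatrix, annotation: pd.DataFrame | None = None):
        self.matrix = matrix
        if annotation is not None:
            unknown = set(annotation["sample_id"]) - set(matrix.sample_ids)
            if unknown:
                raise ValueError(
                    f"annotation names samples absent from the matrix: "
                    f"{sorted(unknown)[:5]}"
                )
        self.annotation = annotation

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, annotation: pd.DataFrame | None = None
    ) -> "BooleanNetworkModel":
        """Build from a probes-x-samples DataFrame of log2 values."""
        return cls(ExpressionMatrix(frame), annotation=annotation)

    @classmethod
    def from_tsv(
        cls, path, dialect: str = "tsv", annotation_path=None
    ) -> "BooleanNetworkModel":
        matrix = matrix_io.read_expression_matrix(path, dialect=dialect)
        annotation = (
            matrix_io.read_annotation(annotation_path) if annotation_path else None
        )
        return cls(matrix, annotation=annotation)

    def fit(
        self,
        margin: float = stepminer.DEFAULT_MARGIN,
        stat_min: float = booleannet.DEFAULT_STAT_MIN,
        err_max: float = booleannet.DEFAULT_ERR_MAX,
        min_low: int | None = None,
        min_high: int | None = None,
    ) -> "BooleanNetworkResults":
        """Threshold, discretize, gate and classify all ordered gene pairs."""
        ternary = stepminer.discretize(self.matrix, margin=margin)
        network = booleannet.build_network(
            ternary, s_min=stat_min, e_max=err_max, min_low=min_low, min_high=min_high
        )
        return BooleanNetworkResults(model=self, ternary=ternary, network=network)


@dataclass
class BooleanNetworkResults:
    """Fitted thresholds plus the classified implication network."""

    model: BooleanNetworkModel
    ternary: TernaryMatrix
    network: BooleanNetwork

    @property
    def params(self) -> dict:
        return dict(self.network.params)

    @property
    def thresholds(self) -> pd.DataFrame:
        """Per-probe StepFit diagnostics and dynamic-range flags."""
        return self.ternary.thresholds_frame(
            min_low=self.network.params.get("min_low"),
            min_high=self.network.params.get("min_high"),
        )

    @property
    def edges(self) -> pd.DataFrame:
        return self.network.edges

    def relationship_counts(self) -> pd.DataFrame:
        """Per-probe counts of the six relationship classes."""
        return netcompare.count_relationships(self.network)

    def make_universes(self, tissue_labels: Sequence[str]) -> list:
        if self.model.annotation is None:
            raise ValueError("model was built without a sample annotation table")
        return universes_mod.make_universes(self.model.annotation, tissue_labels)

    def evaluate_invariant(
        self,
        pair: tuple[str, str],
        tissue_labels: Sequence[str],
        rediscretize: bool = False,
    ):
        """Candidate-invariant reports for one pair across tissue universes."""
        unis = self.make_universes(tissue_labels)
        p = self.network.params
        return universes_mod.evaluate_invariant(
            pair,
            self.model.matrix,
            unis,
            rediscretize=rediscretize,
            margin=p["margin"],
            s_min=p["s_min"],
            e_max=p["e_max"],
        )

    def compare(self, other: "BooleanNetworkResults | BooleanNetwork",
                alpha: float = netcompare.DEFAULT_ALPHA) -> netcompare.NetworkComparison:
        """Class-by-class paired comparison against another fitted network."""
        other_net = other.network if isinstance(other, BooleanNetworkResults) else other
        return netcompare.compare_networks(
            netcompare.count_relationships(self.network),
            netcompare.count_relationships(other_net),
            alpha=alpha,
        )

    def scatter_data(self, gene_a: str, gene_b: str) -> tuple[pd.DataFrame, dict]:
        """Per-sample scatter table for one pair plus both thresholds.

        Returns (frame, meta): one row per sample with ids, annotation,
        both expression values and both ternary codes; meta carries the two
        fitted thresholds and the margin — enough to redraw a quadrant
        scatterplot with sparse-quadrant highlighting.
        """
        values = self.model.matrix.values
        for g in (gene_a, gene_b):
            if g not in values.index:
                gl = str(g).lower()
                near = [
                    str(p) for p in values.index
                    if gl in str(p).lower() or str(p).lower() in gl
                ][:5]
                raise KeyError(f"unknown gene {g!r}; near matches: {near}")
        frame = pd.DataFrame(
            {
                "sample_id": self.model.matrix.sample_ids,
                "value_a": values.loc[gene_a].to_numpy(),
                "value_b": values.loc[gene_b].to_numpy(),
                "code_a": [
                    stepminer.CODE_LABELS[c] for c in self.ternary.codes.loc[gene_a]
                ],
                "code_b": [
                    stepminer.CODE_LABELS[c] for c in self.ternary.codes.loc[gene_b]
                ],
            }
        )
        if self.model.annotation is not None:
            ann = self.model.annotation.set_index("sample_id")
            frame["tissue"] = frame["sample_id"].map(ann["tissue"]).fillna("")
            frame["accession"] = frame["sample_id"].map(ann["accession"]).fillna("")
        else:
            frame["tissue"] = ""
            frame["accession"] = ""
        meta = {
            "gene_a": gene_a,
            "gene_b": gene_b,
            "threshold_a": self.ternary.fits[gene_a].threshold,
            "threshold_b": self.ternary.fits[gene_b].threshold,
            "margin": self.ternary.margin,
        }
        return frame, meta

    def plot_pair(self, gene_a: str, gene_b: str, ax=None):
        """Quadrant scatterplot of one pair with the fitted thresholds."""
        import matplotlib.pyplot as plt

        frame, meta = self.scatter_data(gene_a, gene_b)
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(frame["value_a"], frame["value_b"], s=10, alpha=0.6)
        ax.axvline(meta["threshold_a"], color="crimson", lw=1)
        ax.axhline(meta["threshold_b"], color="crimson", lw=1)
        ax.set_xlabel(f"{gene_a} (log2 expression)")
        ax.set_ylabel(f"{gene_b} (log2 expression)")
        row = self.edges[
            (self.edges["gene_a"] == gene_a) & (self.edges["gene_b"] == gene_b)
        ]
        rel = row["relationship"].iloc[0] if len(row) else "none"
        ax.set_title(f"{gene_a} vs {gene_b}: {rel}")
        return ax

    def summary(self) -> str:
        """Readable fit summary: parameters, gate, class breakdown."""
        p = self.network.params
        n_probes, n_samples = self.model.matrix.shape
        counts = self.edges["relationship"].value_counts() if len(self.edges) else {}
        lines = [
            "Boolean Implication Network Results",
            "=" * 43,
            f"Probes:                {n_probes}",
            f"Samples:               {n_samples}",
            f"Dynamic genes:         {len(self.network.genes)}",
            f"Margin (log2):         {p['margin']}",
            f"Statistic threshold:   > {p['s_min']}",
            f"Error-rate threshold:  < {p['e_max']}",
            f"Dynamic gate:          >= {p['min_low']} low and >= {p['min_high']} high calls",
            f"Classified edges:      {self.network.n_edges}",
            "-" * 43,
        ]
        for rel in booleannet.RELATIONSHIPS:
            n = int(counts.get(rel, 0)) if len(self.edges) else 0
            lines.append(f"  {rel:<6} {n:>8}")
        lines.append("=" * 43)
        return "\n".join(lines)
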