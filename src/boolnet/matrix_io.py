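"""I/O for expression matrices, sample annotations and network edge lists.

Expression matrices are rectangular probe x sample tables of normalized
log2-scale values (RMA output for microarrays, or transformed TPM for
RNA-seq, see :func:`transform_tpm`).  Two tab-delimited dialects are
supported:

``tsv``
    Row 1 is ``ProbeID<TAB>sample1<TAB>...``; each following row is a probe
    id and its values.
``pcl``
    The PCL flavour of the same layout: the header carries an extra weight
    column after the probe id, the second row is the per-sample weight
    (EWEIGHT) row and is skipped, and the weight column is dropped.

Cells equal to ``NA``, ``na`` or the empty string are read as missing and
written back out as ``NA``.  Lines starting with ``#`` are treated as
comments in every format this module reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MatrixFormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "transform_tpm",
    "write_edge_list",
    "read_edge_list",
]

_MISSING_TOKENS = {"NA", "na", ""}

ANNOTATION_COLUMNS = ("sample_id", "tissue", "accession")

EDGE_COLUMNS = (
    "gene_a",
    "gene_b",
    "relationship",
    "statistic",
    "error_rate",
    "a00",
    "a01",
    "a10",
    "a11",
)


class MatrixFormatError(ValueError):
    """Malformed matrix file (ragged row, bad header, ...)."""


@dataclass
class ExpressionMatrix:
    """A probe x sample table of log2-scale expression values.

    Parameters
    ----------
    values
        Float DataFrame indexed by probe id with sample ids as columns.
        ``NaN`` marks a missing measurement; all other entries must be
        finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("expression values must be finite or missing (NaN)")
        self.values = self.values.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy())


def _read_rows(path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def read_expression_matrix(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"tsv"`` (plain) or ``"pcl"`` (extra weight column, EWEIGHT row).

    Raises
    ------
    MatrixFormatError
        On a ragged row (message names the offending line number).
    ValueError
        On duplicate probe or sample ids.
    """
    if dialect not in ("tsv", "pcl"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'pcl'")
    rows = _read_rows(path)
    if not rows:
        raise MatrixFormatError(f"{path}: empty file")
    header_no, header = rows[0]
    data_start = 1
    value_col = 1
    if dialect == "pcl":
        value_col = 3  # ID, NAME, GWEIGHT, then samples
        # Second header row holds per-sample weights (EWEIGHT); skip it.
        if len(rows) > 1 and rows[1][1][0].upper() == "EWEIGHT":
            data_start = 2
    sample_ids = header[value_col:]
    width = len(header)
    probe_ids: list[str] = []
    data: list[list[float]] = []
    for lineno, fields in rows[data_start:]:
        if len(fields) != width:
            raise MatrixFormatError(
                f"{path}: line {lineno} has {len(fields)} columns, expected {width}"
            )
        probe_ids.append(fields[0])
        row_vals = []
        for tok in fields[value_col:]:
            if tok in _MISSING_TOKENS:
                row_vals.append(math.nan)
            else:
                try:
                    row_vals.append(float(tok))
                except ValueError as exc:
                    raise MatrixFormatError(
                        f"{path}: line {lineno}: non-numeric value {tok!r}"
                    ) from exc
        data.append(row_vals)
    frame = pd.DataFrame(data, index=probe_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(frame)


def write_expression_matrix(
    matrix: ExpressionMatrix, path, comments: Iterable[str] = ()
) -> None:
    """Write a matrix in the plain ``tsv`` dialect (missing cells as NA)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("ProbeID\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        vals = matrix.values.to_numpy(dtype=float)
        for probe, row in zip(matrix.probe_ids, vals):
            cells = ["NA" if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(probe) + "\t" + "\t".join(cells) + "\n")


def read_annotation(path) -> pd.DataFrame:
    """Read a sample annotation table (columns sample_id, tissue, accession)."""
    rows = _read_rows(path)
    if not rows:
        raise MatrixFormatError(f"{path}: empty annotation file")
    header = rows[0][1]
    frame = pd.DataFrame(
        [dict(zip(header, fields)) for _, fields in rows[1:]], columns=header
    )
    for col in ("sample_id", "tissue"):
        if col not in frame.columns:
            raise MatrixFormatError(f"{path}: annotation lacks column {col!r}")
    if "accession" not in frame.columns:
        frame["accession"] = ""
    if frame["sample_id"].duplicated().any():
        dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in annotation: {dups[:5]}")
    return frame.loc[:, list(ANNOTATION_COLUMNS)].fillna("")


def write_annotation(annotation: pd.DataFrame, path, comments: Iterable[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        annotation.loc[:, list(ANNOTATION_COLUMNS)].to_csv(fh, sep="\t", index=False)


def transform_tpm(tpm):
    """Piecewise log transform mapping TPM abundances to expression values.

    Returns ``log2(tpm)`` when ``tpm > 1`` and ``tpm - 1`` when ``tpm < 1``;
    both branches agree (are 0) at ``tpm = 1``, so the map is continuous and
    monotonically non-decreasing on [0, inf).  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any input is negative.
    """
    arr = np.asarray(tpm, dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM values must be non-negative")
    with np.errstate(divide="ignore"):
        out = np.where(arr > 1.0, np.log2(np.where(arr > 1.0, arr, 1.0)), arr - 1.0)
    if np.isscalar(tpm) or np.ndim(tpm) == 0:
        return float(out)
    return out


def write_edge_list(network, path, comments: Iterable[str] = ()) -> None:
    """Write a classified network as a deterministic tab-delimited edge list.

    One row per stored (non-"none") ordered pair, sorted lexicographically
    by gene_a then gene_b.  The statistic and error_rate columns carry the
    sparse-quadrant values, semicolon-joined for the symmetric classes.
    """
    edges = network.edges
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        if len(edges):
            ordered = edges.sort_values(["gene_a", "gene_b"], kind="mergesort")
            for row in ordered.itertuples(index=False):
                fh.write(
                    "\t".join(
                        [
                            str(row.gene_a),
                            str(row.gene_b),
                            row.relationship,
                            row.statistic,
                            row.error_rate,
                            str(int(row.a00)),
                            str(int(row.a01)),
                            str(int(row.a10)),
                            str(int(row.a11)),
                        ]
                    )
                    + "\n"
                )


def read_edge_list(path):
    """Read an edge list written by :func:`write_edge_list`.

    Returns a :class:`~boolnet.booleannet.BooleanNetwork` whose gene universe
    is the set of genes appearing in the edges.
    """
    from .booleannet import BooleanNetwork

    rows = _read_rows(path)
    if not rows:
        raise MatrixFormatError(f"{path}: empty edge list")
    header = rows[0][1]
    if tuple(header) != EDGE_COLUMNS:
        raise MatrixFormatError(f"{path}: unexpected edge-list header {header!r}")
    records = []
    for lineno, fields in rows[1:]:
        if len(fields) != len(EDGE_COLUMNS):
            raise MatrixFormatError(
                f"{path}: line {lineno} has {len(fields)} columns, "
                f"expected {len(EDGE_COLUMNS)}"
            )
        rec = dict(zip(EDGE_COLUMNS, fields))
        for c in ("a00", "a01", "a10", "a11"):
            rec[c] = int(rec[c])
        records.append(rec)
    edges = pd.DataFrame(records, columns=list(EDGE_COLUMNS))
    genes = sorted(set(edges["gene_a"]) | set(edges["gene_b"])) if len(edges) else []
    return BooleanNetwork(genes=genes, edges=edges, params={})
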