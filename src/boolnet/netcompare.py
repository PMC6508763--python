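"""Head-to-head comparison of two implication networks.

For every probe A of a network, the number of partners X per relationship
class of the ordered pair (A, X) is tabulated.  Two networks over a shared
id set are compared class by class with a two-sided Wilcoxon signed-rank
test on the paired per-probe counts (zero-difference pairs dropped), plus
log2(count + 1) scatter data for a log-log comparison plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .booleannet import RELATIONSHIPS, BooleanNetwork

__all__ = [
    "DEFAULT_ALPHA",
    "NetworkComparison",
    "count_relationships",
    "compare_networks",
]

DEFAULT_ALPHA = 0.001


def count_relationships(network: BooleanNetwork) -> pd.DataFrame:
    """Per-probe counts of each of the six relationship classes.

    Row index: every gene of the network's universe (plus any edge gene);
    columns: lolo, lohi, hilo, hihi, eqv, opo.  Symmetric edges are stored
    in both orders, so each contributes to both endpoints' eqv/opo counts.
    """
    genes = sorted(set(network.genes) | set(network.edges.get("gene_a", [])))
    table = pd.DataFrame(0, index=pd.Index(genes, name="probe_id"),
                         columns=list(RELATIONSHIPS), dtype=int)
    if len(network.edges):
        grouped = (
            network.edges.groupby(["gene_a", "relationship"]).size().unstack(fill_value=0)
        )
        for col in grouped.columns:
            table.loc[grouped.index, col] += grouped[col]
    return table


@dataclass
class NetworkComparison:
    """Per-class comparison report plus scatter data.

    ``per_type`` is indexed by relationship class with columns
    n_probes, n_nonzero_pairs, p_value, median_diff, median_diff_sign,
    total_x, total_y, significant.  ``scatter`` holds one row per
    (probe, class) with log2(count + 1) coordinates for each network.
    """

    per_type: pd.DataFrame
    scatter: pd.DataFrame
    alpha: float = DEFAULT_ALPHA

    def significant_types(self) -> list[str]:
        return list(self.per_type.index[self.per_type["significant"]])


def compare_networks(
    table_x: pd.DataFrame,
    table_y: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> NetworkComparison:
    """Compare two per-probe relationship count tables class by class.

    The probe universe is the union of the two tables' ids, probes absent
    from one table getting zero counts; an empty id intersection is a
    validation error (the networks share no probes to match).  The paired
    test is a two-sided Wilcoxon signed-rank with zero differences dropped;
    a class with no nonzero differences gets p_value = NaN and is never
    flagged significant.  Differences are oriented Y - X.
    """
    ids_x = set(table_x.index)
    ids_y = set(table_y.index)
    if not ids_x & ids_y:
        raise ValueError("the two networks share no probe ids")
    probes = sorted(ids_x | ids_y)
    x = table_x.reindex(index=probes, columns=list(RELATIONSHIPS), fill_value=0).fillna(0)
    y = table_y.reindex(index=probes, columns=list(RELATIONSHIPS), fill_value=0).fillna(0)

    rows = []
    scatter_parts = []
    for rel in RELATIONSHIPS:
        cx = x[rel].to_numpy(dtype=float)
        cy = y[rel].to_numpy(dtype=float)
        diff = cy - cx
        nonzero = int((diff != 0).sum())
        if nonzero:
            p_value = float(
                stats.wilcoxon(cy, cx, zero_method="wilcox", alternative="two-sided").pvalue
            )
        else:
            p_value = float("nan")
        median_diff = float(np.median(diff))
        rows.append(
            {
                "relationship": rel,
                "n_probes": len(probes),
                "n_nonzero_pairs": nonzero,
                "p_value": p_value,
                "median_diff": median_diff,
                "median_diff_sign": int(np.sign(median_diff)),
                "total_x": int(cx.sum()),
                "total_y": int(cy.sum()),
                "significant": bool(p_value < alpha) if nonzero else False,
            }
        )
        scatter_parts.append(
            pd.DataFrame(
                {
                    "probe_id": probes,
                    "relationship": rel,
                    "log2_count_x": np.log2(cx + 1.0),
                    "log2_count_y": np.log2(cy + 1.0),
                }
            )
        )
    per_type = pd.DataFrame(rows).set_index("relationship")
    scatter = pd.concat(scatter_parts, ignore_index=True)
    return NetworkComparison(per_type=per_type, scatter=scatter, alpha=alpha)
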