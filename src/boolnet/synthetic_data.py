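"""Synthetic expression data with known ground truth.

Emulates the statistical structure of a normalized (RMA-style, log2)
multi-tissue expression compendium:

* each *dynamic* gene is a two-component Gaussian mixture — per sample it
  is either in its low state (mean ``low_mean``) or high state
  (``high_mean``), plus measurement noise of sd ``noise_sd``;
* dynamic genes belong to co-activation blocks, each block being switched
  on in a random subset of tissues (this is what makes quadrants fill
  tissue-by-tissue, and what induces gene-gene correlation);
* *flat* genes are unimodal: a single Gaussian at a random baseline with
  technical spread ``flat_sd`` and no tissue signal;
* *planted pairs* are extra dynamic genes whose joint states obey a chosen
  implication class exactly, except that each sample independently falls
  into the forbidden (sparse) quadrant with probability ``leakage`` — the
  direct analogue of the classifier's error rate.

Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .booleannet import RELATIONSHIPS
from .matrix_io import ExpressionMatrix
from .stepminer import DEFAULT_MARGIN

__all__ = ["GeneratorSpec", "SyntheticDataset", "generate", "generate_duplicate_fixture"]

_DEF_TISSUES = {"root": 0.3, "shoot": 0.2, "leaf": 0.3, "flower": 0.2}


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic expression generator.

    ``planted_pairs`` entries are (gene_a, gene_b, relationship, leakage)
    tuples; the two genes are created by the pair itself and must not be
    reused by another pair.  ``high_mean - low_mean`` must exceed
    ``2 * margin + 4 * noise_sd`` so the two modes are separable by the
    default discretization margin of 0.5 log2 units.
    """

    n_samples: int = 300
    tissues: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_TISSUES))
    n_dynamic_genes: int = 20
    n_flat_genes: int = 5
    low_mean: float = 4.0
    high_mean: float = 9.0
    noise_sd: float = 0.5
    flat_sd: float = 0.2
    p_active: float = 0.9
    p_inactive: float = 0.1
    planted_pairs: Sequence[tuple[str, str, str, float]] = ()
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.tissues.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"tissue fractions must sum to 1, got {total}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        sep = self.high_mean - self.low_mean
        if sep <= 2 * DEFAULT_MARGIN + 4 * self.noise_sd:
            raise ValueError(
                "high_mean - low_mean must exceed 2*margin + 4*noise_sd "
                f"({sep} <= {2 * DEFAULT_MARGIN + 4 * self.noise_sd})"
            )
        seen: set[str] = set()
        for ga, gb, rel, eps in self.planted_pairs:
            if rel not in RELATIONSHIPS:
                raise ValueError(f"unknown planted relationship {rel!r}")
            if not (0 <= eps < 0.5):
                raise ValueError(f"leakage must be in [0, 0.5), got {eps}")
            if ga == gb or ga in seen or gb in seen:
                raise ValueError(
                    f"planted pair ({ga}, {gb}) reuses a gene already constrained "
                    "by another planted pair"
                )
            seen.update((ga, gb))


@dataclass
class SyntheticDataset:
    """Generated matrix + annotation + ground truth tables."""

    matrix: ExpressionMatrix
    annotation: pd.DataFrame
    gene_truth: pd.DataFrame  # gene, kind (dynamic/flat/planted), block
    pair_truth: pd.DataFrame  # gene_a, gene_b, relationship, leakage, n_violations


#: joint occupancy of the allowed quadrants for each planted relationship.
#: Quadrant "ij": gene A state i, gene B state j (0 = low, 1 = high).  The
#: two corner quadrants of the implication carry weight 0.4 and the free
#: quadrant 0.2, so both genes keep balanced low/high margins — a planted
#: implication should be detectable by design when the leakage is well
#: below the classifier's error-rate threshold.
_ALLOWED_QUADRANTS = {
    "eqv": {"00": 0.5, "11": 0.5},
    "opo": {"01": 0.5, "10": 0.5},
    "lolo": {"00": 0.4, "10": 0.2, "11": 0.4},  # forbids 01
    "lohi": {"01": 0.4, "10": 0.4, "11": 0.2},  # forbids 00
    "hihi": {"00": 0.4, "01": 0.2, "11": 0.4},  # forbids 10
    "hilo": {"00": 0.2, "01": 0.4, "10": 0.4},  # forbids 11
}

#: the sparse quadrant(s) each relationship forbids; leaked samples go here
_FORBIDDEN_QUADRANTS = {
    "eqv": ("01", "10"),
    "opo": ("00", "11"),
    "lolo": ("01",),
    "lohi": ("00",),
    "hihi": ("10",),
    "hilo": ("11",),
}


def _planted_states(
    rng: np.random.Generator, n: int, relationship: str, eps: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Joint binary states for a planted pair; each sample independently
    violates the implication with probability eps, violations landing in
    the forbidden (sparse) quadrant."""
    allowed = _ALLOWED_QUADRANTS[relationship]
    forbidden = _FORBIDDEN_QUADRANTS[relationship]
    allowed_q = list(allowed)
    allowed_p = np.array([allowed[q] for q in allowed_q])
    violate = rng.random(n) < eps
    quadrants = np.empty(n, dtype=object)
    idx_ok = ~violate
    quadrants[idx_ok] = rng.choice(allowed_q, size=int(idx_ok.sum()),
                                   p=allowed_p / allowed_p.sum())
    quadrants[violate] = rng.choice(forbidden, size=int(violate.sum()))
    a = np.array([q[0] == "1" for q in quadrants])
    b = np.array([q[1] == "1" for q in quadrants])
    return a, b, int(violate.sum())


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Draw one synthetic dataset from a generator specification."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    tissue_names = list(spec.tissues)
    probs = np.array([spec.tissues[t] for t in tissue_names], dtype=float)
    tissue_idx = rng.choice(len(tissue_names), size=n, p=probs / probs.sum())
    sample_ids = [f"S{i:04d}" for i in range(n)]
    annotation = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": [tissue_names[i] for i in tissue_idx],
            "accession": "SYN0001",
        }
    )

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth_rows: list[dict] = []
    amplitude = spec.high_mean - spec.low_mean

    # Dynamic genes: one co-activation block per tissue; each block is "on"
    # in a random non-empty subset of tissues.
    n_blocks = max(1, len(tissue_names))
    block_active = np.zeros((n_blocks, len(tissue_names)), dtype=bool)
    for b in range(n_blocks):
        size = int(rng.integers(1, len(tissue_names) + 1))
        on = rng.choice(len(tissue_names), size=size, replace=False)
        block_active[b, on] = True
    for g in range(spec.n_dynamic_genes):
        block = int(rng.integers(0, n_blocks))
        p_on = np.where(block_active[block, tissue_idx], spec.p_active, spec.p_inactive)
        state = rng.random(n) < p_on
        values = spec.low_mean + amplitude * state + rng.normal(0, spec.noise_sd, n)
        gid = f"G{g:04d}"
        gene_ids.append(gid)
        rows.append(values)
        truth_rows.append({"gene": gid, "kind": "dynamic", "block": block})

    for g in range(spec.n_flat_genes):
        baseline = rng.uniform(spec.low_mean, spec.high_mean)
        values = rng.normal(baseline, spec.flat_sd, n)
        gid = f"F{g:04d}"
        gene_ids.append(gid)
        rows.append(values)
        truth_rows.append({"gene": gid, "kind": "flat", "block": -1})

    pair_rows: list[dict] = []
    for ga, gb, rel, eps in spec.planted_pairs:
        sa, sb, n_viol = _planted_states(rng, n, rel, eps)
        for gid, state in ((ga, sa), (gb, sb)):
            values = spec.low_mean + amplitude * state + rng.normal(0, spec.noise_sd, n)
            gene_ids.append(gid)
            rows.append(values)
            truth_rows.append({"gene": gid, "kind": "planted", "block": -1})
        pair_rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "relationship": rel,
                "leakage": eps,
                "n_violations": n_viol,
            }
        )

    matrix = ExpressionMatrix(
        pd.DataFrame(np.array(rows) if rows else np.empty((0, n)),
                     index=gene_ids, columns=sample_ids, dtype=float)
    )
    gene_truth = pd.DataFrame(truth_rows, columns=["gene", "kind", "block"])
    pair_truth = pd.DataFrame(
        pair_rows, columns=["gene_a", "gene_b", "relationship", "leakage", "n_violations"]
    )
    return SyntheticDataset(
        matrix=matrix, annotation=annotation, gene_truth=gene_truth, pair_truth=pair_truth
    )


def generate_duplicate_fixture(
    n_files: int, dup_groups: Sequence[int], seed: int, out_dir
) -> dict:
    """Write n_files small binary files with planted byte-identical groups.

    Each entry of ``dup_groups`` is the size of one duplicate group; the
    remaining files get distinct random contents.  Returns (and writes as
    ``manifest.json``) a manifest mapping group index -> member file names.
    Regeneration with the same seed is byte-identical.
    """
    if sum(dup_groups) > n_files:
        raise ValueError("sum of duplicate group sizes exceeds n_files")
    if any(size < 2 for size in dup_groups):
        raise ValueError("duplicate groups must have at least 2 members")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    names = [f"sample_{i:03d}.cel" for i in range(n_files)]
    order = list(rng.permutation(n_files))
    groups: dict[str, list[str]] = {}
    cursor = 0
    for gi, size in enumerate(dup_groups):
        content = rng.bytes(128)
        members = sorted(names[order[cursor + k]] for k in range(size))
        for name in members:
            (out_dir / name).write_bytes(content)
        groups[str(gi)] = members
        cursor += size
    for k in range(cursor, n_files):
        (out_dir / names[order[k]]).write_bytes(rng.bytes(128))
    manifest = {"n_files": n_files, "seed": seed, "groups": groups}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
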