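import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from boolnet import ExpressionMatrix, discretize, fit_step, is_dynamic
from boolnet.stepminer import (
    HIGH,
    INTERMEDIATE,
    LOW,
    MISSING,
    DegenerateInputError,
    default_dynamic_minimum,
)
from boolnet.synthetic_data import GeneratorSpec, generate


def step_fit_oracle(values):
    """Exhaustive breakpoint scan: (k, sse) minimizing the two-segment SSE,
    ties broken toward the smallest k."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    best_k, best_sse = None, np.inf
    for k in range(1, n):
        m1 = x[:k].mean()
        m2 = x[k:].mean()
        sse = float(((x[:k] - m1) ** 2).sum() + ((x[k:] - m2) ** 2).sum())
        if sse < best_sse:
            best_k, best_sse = k, sse
    return best_k, best_sse


class TestFitStep:
    def test_clean_two_level_vector(self):
        fit = fit_step([1, 1, 1, 5, 5, 5])
        assert fit.breakpoint == 3
        assert fit.low_mean == pytest.approx(1.0)
        assert fit.high_mean == pytest.approx(5.0)
        assert fit.threshold == pytest.approx(3.0)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_is_degenerate(self):
        fit = fit_step([2, 2, 2, 2])
        assert fit.degenerate
        assert fit.threshold == pytest.approx(2.0)
        assert fit.sse == 0.0

    def test_too_few_values(self):
        with pytest.raises(DegenerateInputError):
            fit_step([3.0])
        with pytest.raises(DegenerateInputError):
            fit_step([np.nan, np.nan, 1.0])

    def test_missing_values_dropped(self):
        fit = fit_step([1, np.nan, 1, 5, np.nan, 5])
        assert fit.n == 4
        assert fit.breakpoint == 2

    def test_matches_exhaustive_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 200))
            x = rng.normal(5, 2, n)
            fit = fit_step(x)
            k, sse = step_fit_oracle(x)
            assert fit.breakpoint == k
            assert fit.sse == pytest.approx(sse, rel=1e-9, abs=1e-9)

    def test_sse_bounded_by_one_segment_model(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, int(rng.integers(2, 100)))
            total_ss = float(((x - x.mean()) ** 2).sum())
            assert fit_step(x).sse <= total_ss + 1e-9

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=60),
        st.floats(-100, 100),
    )
    @settings(deadline=None, max_examples=100)
    def test_shift_equivariance(self, values, c):
        x = np.asarray(values)
        if np.ptp(x) == 0:
            return
        f0 = fit_step(x)
        f1 = fit_step(x + c)
        assert f1.threshold == pytest.approx(f0.threshold + c, abs=1e-6)
        assert f1.breakpoint == f0.breakpoint

    def test_threshold_between_segment_means(self, rng):
        for _ in range(50):
            f = fit_step(rng.normal(0, 1, 40))
            assert f.low_mean <= f.threshold <= f.high_mean


class TestDiscretize:
    def test_margin_rule(self):
        # values splitting into modes at 1 and 5: t = 3.0
        frame = pd.DataFrame(
            [[1.0, 1.0, 3.6, 3.0, 5.0, 2.4]],
            index=["g"],
            columns=list("abcdef"),
        )
        tern = discretize(ExpressionMatrix(frame))
        t = tern.fits["g"].threshold
        assert t == pytest.approx(8.0 / 3.0, rel=1e-6)
        codes = tern.codes.loc["g"]
        assert codes["c"] == HIGH      # 3.6 > t + 0.5
        assert codes["d"] == INTERMEDIATE  # 3.0 inside the margin band
        assert codes["a"] == LOW
        assert codes["e"] == HIGH

    def test_value_exactly_at_threshold_is_intermediate(self):
        frame = pd.DataFrame([[1, 1, 1, 5, 5, 5, 3.0]], index=["g"],
                             columns=list("abcdefg"))
        tern = discretize(ExpressionMatrix(frame))
        # t close to 3: the 3.0 cell lies strictly inside (t-0.5, t+0.5)
        assert tern.codes.loc["g", "g"] == INTERMEDIATE

    def test_codes_partition_samples(self, planted_dataset):
        tern = discretize(planted_dataset.matrix)
        n = len(tern.sample_ids)
        counts = np.stack(
            [(tern.codes.to_numpy() == c).sum(axis=1) for c in (LOW, INTERMEDIATE, HIGH, MISSING)]
        )
        assert (counts.sum(axis=0) == n).all()

    def test_missing_cells_map_to_missing(self, small_matrix):
        tern = discretize(small_matrix)
        assert tern.codes.loc["gC", "s2"] == MISSING

    def test_sample_permutation_permutes_codes(self, rng, planted_dataset):
        matrix = planted_dataset.matrix
        perm = rng.permutation(len(matrix.sample_ids))
        shuffled = ExpressionMatrix(matrix.values.iloc[:, perm])
        t1 = discretize(matrix)
        t2 = discretize(shuffled)
        assert (t2.codes.to_numpy() == t1.codes.to_numpy()[:, perm]).all()

    def test_constant_shift_leaves_codes_unchanged(self, planted_dataset):
        matrix = planted_dataset.matrix
        shifted = ExpressionMatrix(matrix.values + 7.25)
        t1 = discretize(matrix)
        t2 = discretize(shifted)
        assert (t1.codes.to_numpy() == t2.codes.to_numpy()).all()
        for probe in matrix.probe_ids:
            assert t2.fits[probe].threshold == pytest.approx(
                t1.fits[probe].threshold + 7.25, abs=1e-9
            )


class TestDynamicGate:
    def test_all_intermediate_gene_is_not_dynamic(self):
        assert not is_dynamic([INTERMEDIATE] * 30, 1, 1)

    def test_direct_count_comparison(self):
        row = [LOW] * 10 + [HIGH] * 10 + [INTERMEDIATE] * 5
        assert is_dynamic(row, 5, 5)
        assert not is_dynamic(row, 11, 5)

    def test_default_minimum(self):
        assert default_dynamic_minimum(100) == 3
        assert default_dynamic_minimum(300) == 8
        assert default_dynamic_minimum(2) == 3

    def test_flat_genes_flagged_non_dynamic(self):
        """Unimodal genes have no low/high regimes: the gate should drop
        them in nearly every replicate at default generator settings."""
        hits = 0
        n_reps = 200
        for seed in range(n_reps):
            spec = GeneratorSpec(
                n_samples=300, n_dynamic_genes=0, n_flat_genes=1, seed=seed
            )
            data = generate(spec)
            tern = discretize(data.matrix)
            if not tern.dynamic_genes():
                hits += 1
        assert hits >= 0.95 * n_reps

    def test_bimodal_genes_flagged_dynamic(self):
        spec = GeneratorSpec(n_samples=300, n_dynamic_genes=10, n_flat_genes=0, seed=3)
        data = generate(spec)
        tern = discretize(data.matrix)
        assert len(tern.dynamic_genes()) == 10
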