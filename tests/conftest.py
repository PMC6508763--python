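import numpy as np
import pandas as pd
import pytest

from boolnet import ExpressionMatrix, GeneratorSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20190320)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, one missing cell."""
    frame = pd.DataFrame(
        [
            [2.0, 2.1, 8.0, 8.2],
            [7.5, 3.0, 3.1, 7.9],
            [5.0, np.nan, 5.2, 4.9],
        ],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(frame)


@pytest.fixture
def planted_dataset():
    """Synthetic dataset with one planted pair per relationship class."""
    spec = GeneratorSpec(
        n_samples=300,
        n_dynamic_genes=10,
        n_flat_genes=3,
        planted_pairs=[
            ("P_lolo_a", "P_lolo_b", "lolo", 0.02),
            ("P_lohi_a", "P_lohi_b", "lohi", 0.02),
            ("P_hilo_a", "P_hilo_b", "hilo", 0.02),
            ("P_hihi_a", "P_hihi_b", "hihi", 0.02),
            ("P_eqv_a", "P_eqv_b", "eqv", 0.02),
            ("P_opo_a", "P_opo_b", "opo", 0.02),
        ],
        seed=42,
    )
    return generate(spec)
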