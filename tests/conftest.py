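import numpy as np
import pandas as pd
import pytest

from monokaryo import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-chromosome, two-group cohort with planted DE genes."""
    spec = SyntheticSpec(
        n_chromosomes=4,
        genes_per_chromosome=200,
        n_samples_per_group=3,
        de_fraction=0.10,
        seed=101,
    )
    counts, annotation, truth = generate_dataset(spec)
    return spec, counts, annotation, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_log_expr(rng):
    """A dense random log-expression matrix, 60 genes x 6 samples."""
    return pd.DataFrame(
        rng.normal(6.0, 1.0, (60, 6)),
        index=[f"g{i:03d}" for i in range(60)],
        columns=[f"s{j}" for j in range(6)],
    )
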