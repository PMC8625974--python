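import numpy as np
import pandas as pd
import pytest

from cernakit.io_core import ExpressionMatrix, LocalizationTable, SampleDesign
from cernakit.synthetic import SimConfig, simulate_timecourse

SAMPLES = [f"{s}_{r}" for s in ("E8", "E13", "D1", "D10") for r in (1, 2, 3)]


@pytest.fixture(scope="session")
def small_dataset():
    """Default synthetic dataset, shared across read-only tests."""
    return simulate_timecourse(SimConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_dataset():
    return simulate_timecourse(SimConfig(seed=12, noise_sd=0.0, n_triplets=5))


@pytest.fixture
def design():
    return SampleDesign.from_sample_ids(SAMPLES)


def make_matrix(rows: dict[str, list[float]], gene_class: str = "mRNA",
                samples=None) -> ExpressionMatrix:
    samples = samples if samples is not None else SAMPLES
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)
    return ExpressionMatrix(df, gene_class)


@pytest.fixture
def localization_all_cyto(small_dataset):
    return LocalizationTable(
        {g: "Cytoplasm" for g in small_dataset.lnc_expr.gene_ids}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
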