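import numpy as np
import pandas as pd
import pytest

from ubigen.formats_io import ExpressionMatrix
from ubigen.scoring_core import ScoringConfig, compose_scores
from ubigen.synthetic_data import (
    SyntheticSpec,
    simulate_drug_stats,
    simulate_expression,
    simulate_paired_datasets,
)


def make_matrix(rows: dict[str, list[float]], samples: list[str] | None = None) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from a gene -> values mapping."""
    n = len(next(iter(rows.values())))
    samples = samples or [f"s{i + 1}" for i in range(n)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.index.name = "gene_id"
    return ExpressionMatrix(df.astype(float))


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec()


@pytest.fixture(scope="session")
def synth(default_spec):
    """Default synthetic matrix + truth labels (seed 1)."""
    return simulate_expression(default_spec)


@pytest.fixture(scope="session")
def synth_scores(synth):
    matrix, _ = synth
    return compose_scores(matrix, ScoringConfig())


@pytest.fixture(scope="session")
def paired(default_spec):
    return simulate_paired_datasets(default_spec, perturb_fraction=0.3)


@pytest.fixture(scope="session")
def drug_stats(synth):
    _, labels = synth
    return simulate_drug_stats(labels, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
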