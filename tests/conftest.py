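import numpy as np
import pandas as pd
import pytest

from lncmeta.normalize import StudyCounts


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_study(
    rng, study_id="s1", n_genes=50, n_case=5, n_control=5, lam=100.0, tissue="brain"
):
    """Small Poisson study with no planted effect."""
    n = n_case + n_control
    counts = pd.DataFrame(
        rng.poisson(lam, size=(n_genes, n)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"{study_id}_s{j}" for j in range(n)],
    )
    design = pd.DataFrame(
        {
            "group": ["case"] * n_case + ["control"] * n_control,
            "study_id": study_id,
            "tissue_class": tissue,
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return StudyCounts(study_id=study_id, counts=counts, design=design)


@pytest.fixture
def small_studies(rng):
    return [make_study(rng, f"s{i}", n_genes=40, n_case=6, n_control=6) for i in range(3)]
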