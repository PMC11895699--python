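import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from exonbalance import CountTable, ExonModel
from exonbalance import simulate as sim


@pytest.fixture
def small_counts() -> CountTable:
    df = pd.DataFrame(
        {"s1": [10, 20, 30], "s2": [5, 10, 15]},
        index=["f1", "f2", "f3"],
    )
    return CountTable(df)


@pytest.fixture
def exon_model() -> ExonModel:
    return ExonModel()


@pytest.fixture
def balanced_tpm(exon_model) -> pd.DataFrame:
    """Noiseless balanced profile: every exon at the same length-normalized rate."""
    from exonbalance import compute_exon_tpm

    lengths = np.asarray(exon_model.exon_lengths)
    counts = pd.DataFrame(
        {"s1": lengths * 10, "s2": lengths * 3}, index=exon_model.feature_ids
    )
    return compute_exon_tpm(CountTable(counts), exon_model)


@pytest.fixture
def deg_fixture():
    spec = sim.DegSimSpec(
        n_features=300, n_per_group=10, n_up=20, n_dn=20, dispersion=0.05, seed=5
    )
    return sim.simulate_deg_counts(spec)
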