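import numpy as np
import pandas as pd
import pytest

from cerna_triad import ExpressionMatrix, SimulationConfig


def make_matrix(values, classes, groups, lengths=None, feature_ids=None, sample_ids=None):
    """Build a small ExpressionMatrix from plain lists."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samp)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=sample_ids),
        feature_class=pd.Series(classes, index=feature_ids),
        groups=pd.Series(groups, index=sample_ids),
        feature_length=None if lengths is None else pd.Series(lengths, index=feature_ids, dtype=float),
    )


@pytest.fixture
def tiny_matrix():
    """3 features x 4 samples, two groups, with lengths."""
    return make_matrix(
        values=[[10, 12, 30, 28], [5, 6, 5, 6], [100, 90, 10, 12]],
        classes=["mRNA", "miRNA", "lncRNA"],
        groups=["control", "control", "treatment", "treatment"],
        lengths=[1000, 22, 2000],
    )


@pytest.fixture
def noiseless_config():
    """One planted triplet, one miRNA per triplet, no noise."""
    return SimulationConfig(
        n_samples_per_group=3, n_mirna=5, n_mrna=20, n_lncrna=10,
        n_planted_triplets=1, mirnas_per_triplet=1,
        noise_sd=0.0, repression_strength=1.0, extra_mre_rate=0.0, seed=7,
    )
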