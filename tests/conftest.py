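import numpy as np
import pytest

from rpslearner import ExpressionMatrix, LabelVector, SyntheticConfig, generate


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 genes, stage=counts."""
    return ExpressionMatrix(
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        sample_ids=["s1", "s2", "s3"],
        gene_ids=["g1", "g2"],
        stage="counts",
    )


@pytest.fixture
def small_dataset():
    """Separable two-class dataset small enough for fast pipeline fits."""
    cfg = SyntheticConfig(
        n_samples=80,
        n_genes=300,
        n_signal_genes=40,
        effect_size_delta=2.5,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture
def binary_labels():
    return LabelVector(
        labels=["a", "b", "a", "b", "a", "a"],
        label_set=["a", "b"],
        positive_class="b",
    )
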