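import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ncbind as nb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cefsqc():
    """The six-mer used as the worked example for all three encodings."""
    return nb.PeptideRecord(id="p1", sequence="CEFSQC")


@pytest.fixture
def toy_dataset():
    """Linearly separable 20-sample set: poly-A binders vs poly-V non-binders."""
    pos = [nb.PeptideRecord(id=f"p{i}", sequence="A" * 9) for i in range(10)]
    neg = [nb.PeptideRecord(id=f"n{i}", sequence="V" * 9) for i in range(10)]
    labels = np.concatenate([np.ones(10, dtype=int), np.zeros(10, dtype=int)])
    return nb.LabeledDataset(records=pos + neg, labels=labels, ratio=1)


@pytest.fixture
def tiny_config():
    """A deliberately small architecture for fast structural/training tests."""
    return nb.ModelConfig(
        embedding_dim=8, conv_filters=8, lstm_units=8, dense_units=8,
        epochs=5, batch_size=8, validation_fraction=0.0, dropout_rate=0.2,
        seed=0,
    )
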