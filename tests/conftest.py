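import numpy as np
import pytest

from m6age.data_io import RnaSample, SampleSet
from m6age.synthetic_data import SynthConfig, generate_dataset


def make_set(seqs, labels=None, prefix="s", relaxed=True):
    """SampleSet from raw sequences (labels default to all-1)."""
    labels = labels if labels is not None else [1] * len(seqs)
    return SampleSet([
        RnaSample(f"{prefix}{i}", s, int(l))
        for i, (s, l) in enumerate(zip(seqs, labels))
    ], relaxed=relaxed)


@pytest.fixture(scope="session")
def small_balanced():
    """200-sample balanced L=21 synthetic set with a clear motif."""
    return generate_dataset(SynthConfig(n_pos=100, n_neg=100, L=21,
                                        motif_strength=0.9, seed=11))


@pytest.fixture(scope="session")
def random_sequences():
    """500 random L=25 sequences with a center A (both classes)."""
    return generate_dataset(SynthConfig(n_pos=250, n_neg=250, L=25,
                                        motif_strength=0.0, seed=12))
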