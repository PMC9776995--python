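import numpy as np
import pytest

from rccc_pred.features import extract_features
from rccc_pred.io_formats import CLASS_ORDER, FeatureRow
from rccc_pred.synthetic import SyntheticSpec, gen_separable_dataset


def features_for(samples):
    """Extract labeled FeatureRows for a list of SequenceSamples."""
    return [
        FeatureRow(s.sample_id, extract_features(s.sequence).as_tuple(), s.class_label)
        for s in samples
    ]


@pytest.fixture(scope="session")
def separable_rows():
    """Strong-separation synthetic dataset (delta 0.9, 50/class), as features."""
    spec = SyntheticSpec(n_per_class=50, length_range=(200, 300), delta=0.9, seed=11)
    return features_for(gen_separable_dataset(spec))


@pytest.fixture(scope="session")
def separable_rows_strong():
    """Acceptance-regime dataset: delta 0.9, 50/class, fixed length 900."""
    spec = SyntheticSpec(n_per_class=50, length_range=(800, 1000), delta=0.9, seed=11)
    return features_for(gen_separable_dataset(spec))


@pytest.fixture(scope="session")
def small_random_rows():
    """20 random labeled feature rows (arbitrary features, balanced-ish labels)."""
    rng = np.random.default_rng(5)
    labels = [CLASS_ORDER[i % 3] for i in range(20)]
    return [
        FeatureRow(f"s{i:02d}", tuple(rng.normal(size=6)), labels[i]) for i in range(20)
    ]


@pytest.fixture()
def ref_fasta(tmp_path):
    path = tmp_path / "refs.fasta"
    path.write_text(">g1\nACGTACGT\n>g2\nTTTTCCCC\n")
    return path
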