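import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from regulonml.classify import ClassifierConfig
from regulonml.features import AssemblyConfig, assemble
from regulonml.motifs import build_pssm
from regulonml.sigma import default_sigma_pssms
from regulonml.synthetic import (
    SyntheticConfig,
    generate_pentamer_table,
    generate_regulon_dataset,
)


@pytest.fixture(scope="session")
def shape_table():
    return generate_pentamer_table(seed=0)


@pytest.fixture(scope="session")
def sigma_pssms():
    return default_sigma_pssms()


@pytest.fixture(scope="session")
def demo_dataset():
    """The reference study conditions: 500 promoters, 40 positives,
    one planted 10 bp / 12 bit motif, seed 7."""
    config = SyntheticConfig(seed=7)
    promoters, labels, truth = generate_regulon_dataset(config)
    return config, promoters, labels, truth


@pytest.fixture(scope="session")
def demo_matrix(demo_dataset, sigma_pssms, shape_table):
    """Engineered feature matrix assembled from the reference dataset."""
    _, promoters, labels, truth = demo_dataset
    pssm = build_pssm(probabilities=truth.planted_pwm, name="planted", source="ICA")
    label_df = labels.to_frame(name="planted").astype(int)
    return assemble(
        promoters, [pssm], sigma_pssms, shape_table, label_df,
        config=AssemblyConfig(),
    )


@pytest.fixture()
def classifier_config():
    return ClassifierConfig(seed=7)
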