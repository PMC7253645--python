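from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cardiochain.datamodel import (
    ChainConfig,
    PipelineConfig,
    SmoteConfig,
)
from cardiochain.synth import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    """Small deterministic config for unit-level model fits."""
    return replace(
        PipelineConfig(seed=7),
        chain=ChainConfig(stacking_inner_folds=2, downstream_signal="hard_label"),
        smote=SmoteConfig(enabled=False),
    ).validate()


@pytest.fixture(scope="session")
def small_bundle():
    """Shared 40-drug synthetic bundle for structural tests."""
    return generate_dataset(GeneratorConfig(n_drugs=40, n_genes=25, seed=11))


def write_tsv(path, frame: pd.DataFrame) -> str:
    frame.to_csv(path, sep="\t", index=False)
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
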