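import numpy as np
import pandas as pd
import pytest

from rbptraits.annotation import GeneModels
from rbptraits.simulate import (RbpSpec, SimConfig, default_panel,
                                generate_annotation, generate_cohort)


@pytest.fixture(scope="session")
def small_annotation() -> pd.DataFrame:
    return generate_annotation(30, seed=7)


@pytest.fixture(scope="session")
def small_models(small_annotation) -> GeneModels:
    return GeneModels.from_table(small_annotation)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial cohort: one RBP per class, 40 samples."""
    cfg = SimConfig(
        n_genes=300, n_samples=40,
        rbps=default_panel(n_per_class=1, n_targets=30),
        seed=11,
    )
    rna, ribo, truth = generate_cohort(cfg)
    return cfg, rna, ribo, truth
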