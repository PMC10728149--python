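import numpy as np
import pandas as pd
import pytest

from cardiolinc.io import ExpressionMatrix
from cardiolinc.synthdata import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the study's default conditions."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def null_dataset():
    """Generator with every planted effect switched off."""
    cfg = GeneratorConfig(seed=1, marker_log2_shift=0.0, subpop_log2fc=0.0,
                          module_latent_sd=1e-9, module_type_log2_shift=0.0)
    return generate_dataset(cfg)


@pytest.fixture
def tiny_matrix():
    values = np.array([[1.0, 2.0], [0.0, 3.0], [4.0, 0.0]])
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2"], unit="fpkm")


@pytest.fixture
def annotation():
    return pd.DataFrame(
        {"symbol": ["Pln", "Tpm1", "Lnc1", "Pc1"],
         "biotype": ["coding", "coding", "lncRNA", "pcRNA"],
         "length_bp": [1000, 2000, 1500, 800]},
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
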