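import numpy as np
import pandas as pd
import pytest

from growthlaws import synthetic


@pytest.fixture(scope="session")
def design():
    """Standard 8-condition x 3-replicate design, growth rates 0.05-0.28."""
    return synthetic.generate_design(seed=1)


@pytest.fixture(scope="session")
def truth(design):
    """Default ground-truth parameters for 400 genes."""
    return synthetic.generate_gene_parameters(400, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_matrix():
    """Tiny positive genes x samples frame."""
    r = np.random.default_rng(7)
    return pd.DataFrame(
        r.uniform(1, 10, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(4)],
    )
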