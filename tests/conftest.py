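import numpy as np
import pandas as pd
import pytest

from mirscreen import ScreenSimSpec, gen_screen


@pytest.fixture
def rng():
    return np.random.default_rng(20160907)


@pytest.fixture
def small_annotation():
    """Six proteins: 4 oncogenic, 2 tumor suppressor, covering all pathways."""
    return pd.DataFrame(
        {
            "cls": ["oncogenic", "oncogenic", "oncogenic", "oncogenic",
                    "tumor_suppressor", "tumor_suppressor"],
            "pathway": ["PI3K", "PI3K", "MAPK", "cell_cycle", "MAPK", "cell_cycle"],
        },
        index=pd.Index([f"P{i}" for i in range(1, 7)], name="protein_id"),
    )


@pytest.fixture
def noiseless_screen():
    """Tiny planted screen with no noise: structure must be recovered exactly."""
    spec = ScreenSimSpec(
        n_mirnas=30, n_proteins=8, n_onco_proteins=5,
        n_planted_ts=4, n_planted_onco=3, effect_size=1.0, noise_sd=0.0, seed=7,
    )
    return gen_screen(spec)
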