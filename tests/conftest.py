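import numpy as np
import pytest

import bonemet as bm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact planted cohort shared by depnet/pipeline tests."""
    cfg = bm.SynthConfig(
        n_genes=60,
        n_patients=400,
        n_planted_pairs=5,
        effect_size=0.5,
        seed=11,
    )
    scaffold = bm.synth.generate_scaffold(cfg)
    expr, clinical, truth = bm.synth.generate_cohort(cfg, scaffold)
    return cfg, scaffold, expr, clinical, truth
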