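import numpy as np
import pytest

import guidepost as gp
from guidepost.io import table_to_pairs


@pytest.fixture(scope="session")
def sim_world():
    """A moderate synthetic dataset shared across the suite.

    ~4k sites from 40 guides with planted mismatch/GC signal, the genome
    they live on, extracted features and the ground-truth sidecar.
    """
    spec = gp.SyntheticSpec(n_guides=40, sites_per_guide=100, seed=3)
    genome, table, sidecar = gp.simulate_sites(spec)
    featurizer = gp.Featurizer({"chrSim": genome})
    pairs = table_to_pairs(table)
    featurizer.fit_norm_stats(pairs[:500])
    xs, xp = featurizer.features(pairs)
    return {
        "spec": spec,
        "genome": genome,
        "table": table,
        "sidecar": sidecar,
        "featurizer": featurizer,
        "pairs": pairs,
        "xs": xs,
        "xp": xp,
        "y": table["read_count"].to_numpy(),
    }


@pytest.fixture(scope="session")
def trained_zinb(sim_world):
    """A compact ZINB model trained on the shared synthetic dataset."""
    cfg = gp.TrainConfig(learning_rate=1e-3, max_epochs=35,
                         early_stopping_patience=15, seed=11,
                         split_fractions=(0.8, 0.1, 0.1))
    return gp.train((sim_world["xs"], sim_world["xp"], sim_world["y"]),
                    cfg, head="zinb", net_config=gp.NetworkConfig.compact(),
                    count_scale=1.0)
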