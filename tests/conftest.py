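import numpy as np
import pandas as pd
import pytest

from cerna_seeker import diffexpr, targets
from cerna_seeker.simulate import SimulationConfig, simulate_counts


def small_config(**kw) -> SimulationConfig:
    """A reduced study: fewer features, same planted structure."""
    defaults = dict(
        n_pairs=20, n_mrna=80, n_mirna=40, n_lncrna=60,
        n_modules=2, module_size=15, n_triplets=5, mirnas_per_triplet=4,
        n_bg_lnc_targets=4, n_bg_mrna_targets=5, n_decoys=50, seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def nb_counts(rng, mean, dispersion):
    """Direct NB draws (variance = mu + d*mu^2), independent of the generator."""
    mean = np.asarray(mean, float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_counts(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def condition(default_dataset):
    st = default_dataset.sample_table
    return pd.Series(st["condition"].to_numpy(), index=st["sample_id"])


@pytest.fixture(scope="session")
def de_sets(default_dataset, condition):
    out = {}
    for cls in ("mrna", "mirna", "lncrna"):
        res = diffexpr.nb_wald_test(default_dataset.counts[cls], condition)
        s = diffexpr.filter_de(res)
        out[cls] = s["up"] | s["down"]
    return out


@pytest.fixture(scope="session")
def default_bipartite(default_dataset, de_sets):
    filtered = targets.filter_interactions(default_dataset.interactions)
    return targets.build_bipartite(filtered, de_sets["mirna"],
                                   de_sets["lncrna"], de_sets["mrna"])
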