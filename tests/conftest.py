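import numpy as np
import pandas as pd
import pytest

from phytotime import de as de_mod
from phytotime import prep
from phytotime.pseudotime import ConsensusPseudotime, normalize_for_pseudotime
from phytotime.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def noiseless_pop():
    """Noiseless population: every non-flat gene is exactly monotone in age."""
    cfg = SimulationConfig(noise_sd=0.0, dropout_prob=0.0, frac_flat=0.0,
                           n_genes=400, seed=11)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def default_pop():
    """One draw under the default (noisy) study-population configuration."""
    return simulate_population(SimulationConfig(seed=5))


def run_pseudotime(pop, n_groups=100, seed=0):
    """Shared helper: DE -> normalisation -> oriented consensus ordering."""
    cpm = prep.cpm_from_counts(pop.expression)
    de = de_mod.de_table(cpm, pop.traits["bolted"])
    norm, _ = normalize_for_pseudotime(pop.expression, de)
    cp = ConsensusPseudotime(n_groups=n_groups, random_state=seed).fit(norm.T)
    cp.orient(pop.traits["bolted"])
    return cp, de, norm


@pytest.fixture(scope="session")
def noiseless_pseudotime(noiseless_pop):
    return run_pseudotime(noiseless_pop)


@pytest.fixture()
def toy_expression():
    return pd.DataFrame(
        {"s1": [1.0, 5.0, 0.0], "s2": [2.0, 4.0, 0.1], "s3": [3.0, 3.0, 0.2]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
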