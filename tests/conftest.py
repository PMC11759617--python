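import numpy as np
import pandas as pd
import pytest

from pcmatch import simulate
from pcmatch.containers import GenotypeMatrix, default_variant_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """300 samples x 500 variants, two populations, moderate divergence."""
    panel = simulate.draw_ancestral_frequencies(500, 2, 0.1, seed=11)
    admix = simulate.draw_admixture(300, [1.0, 1.0], seed=12)
    G = simulate.simulate_genotypes(panel, admix, seed=13)
    return panel, admix, G


def toy_genotypes(dosages, samples=None, positions=None):
    d = np.asarray(dosages, dtype=np.int8)
    variants = default_variant_table(d.shape[1])
    if positions is not None:
        variants["pos"] = positions
    return GenotypeMatrix(d, samples or [], variants)
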