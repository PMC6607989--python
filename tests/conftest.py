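import numpy as np
import pytest

from rarevar.synthetic_data import PanelSpec, SimSpec


@pytest.fixture
def small_spec() -> SimSpec:
    """Reduced-scale study: 3 families, 40 patients, 8 sites, tiny universe."""
    return SimSpec(
        n_families=3,
        n_offspring=2,
        cohort_n=40,
        variant_freqs=(0.05, 0.1, 0.02, 0.2, 0.15, 0.08, 0.3, 0.12),
        panels=(PanelSpec("tuscany", 214), PanelSpec("dbsnp", 5000)),
        n_genes=30,
        candidate_set_size=5,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
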