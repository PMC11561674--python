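import numpy as np
import pytest

from rapagen import simdata


@pytest.fixture(scope="session")
def small_panel():
    """60 lines x ~300 markers with LD and some missing calls, polymorphic only."""
    from rapagen.quantgen import qc_markers

    G = simdata.simulate_genotypes(
        60, 300, maf_range=(0.1, 0.5), ld_decay=0.8, missing_rate=0.03, seed=42
    )
    return qc_markers(G, 0.01, 0.0)


@pytest.fixture(scope="session")
def panel_phenotype(small_panel):
    pheno, truth = simdata.simulate_phenotype(small_panel, h2=0.5, seed=7)
    return pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
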