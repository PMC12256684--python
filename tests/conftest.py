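import numpy as np
import pandas as pd
import pytest

import stemcss as scs


@pytest.fixture(scope="session")
def sc_sim():
    """One default single-cell simulation shared across test modules."""
    return scs.simulate_sc(scs.default_sc_config(seed=0))


@pytest.fixture(scope="session")
def lognorm(sc_sim):
    return sc_sim.counts.log_normalize()


@pytest.fixture(scope="session")
def de_tables(sc_sim, lognorm):
    """The four pipeline contrasts on the shared simulation."""
    cells = sc_sim.cells
    cl = cells["cluster"]
    tumor = cells["tissue"] == "tumor"
    lap = cells.index[cl == "stem_laptm4b"]
    lgr = cells.index[cl == "stem_lgr5"]
    return {
        "epi_vs_other": scs.diff_expr(lognorm, cells.index[tumor], cells.index[~tumor]),
        "lap_vs_rest": scs.diff_expr(lognorm, lap, cells.index[tumor & (cl != "stem_laptm4b")]),
        "lap_vs_sib": scs.diff_expr(lognorm, lap, lgr),
        "lgr_vs_rest": scs.diff_expr(lognorm, lgr, cells.index[tumor & (cl != "stem_lgr5")]),
    }


@pytest.fixture(scope="session")
def bulk_sim():
    return scs.simulate_bulk(scs.default_bulk_config(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
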