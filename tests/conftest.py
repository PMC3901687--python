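"""Shared fixtures: graphs, motifs, and (session-scoped) simulation panels."""

import numpy as np
import pytest

import sequon as sq
from sequon.simulate import simulate_panel
from sequon.synth import gen_site_span_panel, gen_study_panel


@pytest.fixture(scope="session")
def graph():
    return sq.MutationGraph()


@pytest.fixture(scope="session")
def nxst():
    return sq.MotifSpec.nxst()


@pytest.fixture(scope="session")
def study_panel():
    """30 secretory-like genes with A+T/G+C compositional spread."""
    return gen_study_panel(seed=101)


@pytest.fixture(scope="session")
def study_sim(study_panel):
    """Neutral mutagenesis of the study panel (branch length 0.2)."""
    params = sq.SimParams(branch_length=0.2, seed=102, replicates=150)
    return simulate_panel(study_panel, params)


@pytest.fixture(scope="session")
def span_panel():
    """Genes with exact planted site counts spanning 0..15."""
    return gen_site_span_panel(seed=103)


@pytest.fixture(scope="session")
def span_sim(span_panel):
    """Neutral mutagenesis of the site-span panel (branch length 0.5)."""
    params = sq.SimParams(branch_length=0.5, seed=104, replicates=220)
    return simulate_panel(span_panel, params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
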