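"""Shared fixtures: small deterministic model draws, trees and alignments."""

from __future__ import annotations

import numpy as np
import pytest

from codonmss.codon_model import (
    NucExchangeabilities,
    PositionalFrequencies,
    cf3x4_correct,
    make_spec,
)
from codonmss.genetic_code import UNIVERSAL_CODE, restricted_code
from codonmss.simulate import ParametricSimConfig, simulate_alignment
from codonmss.trees import PhyloTree


@pytest.fixture(scope="session")
def theta():
    return NucExchangeabilities(theta=(0.6, 1.0, 0.4, 0.5, 1.3, 0.8))


@pytest.fixture(scope="session")
def freqs():
    rng = np.random.default_rng(123)
    return cf3x4_correct(PositionalFrequencies(pi=rng.dirichlet(np.ones(4) * 8, size=3)))


@pytest.fixture(scope="session")
def uniform_freqs():
    return PositionalFrequencies.uniform()


@pytest.fixture(scope="session")
def tree4():
    return PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.1);")


@pytest.fixture(scope="session")
def tree6():
    return PhyloTree.from_newick(
        "((t0:0.12,t1:0.1):0.06,(t2:0.1,t3:0.13):0.05,(t4:0.15,t5:0.1):0.07);"
    )


@pytest.fixture(scope="session")
def small_code():
    """Restricted code whose pair universe has D = 4 (four 2-codon amino
    acids), small enough for exhaustive partition enumeration."""
    return restricted_code({"K", "N", "D", "E"}, name="KNDE")


@pytest.fixture(scope="session")
def mg94_gene(theta, freqs, tree6):
    """A 300-codon gene simulated under the baseline MG94 model."""
    spec = make_spec("standard").with_rates(beta=0.3, renormalize=False)
    cfg = ParametricSimConfig(
        spec=spec, theta=theta, freqs=freqs, tree=tree6, n_sites=300, seed=9
    )
    return simulate_alignment(cfg), tree6
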