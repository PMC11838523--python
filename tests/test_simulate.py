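"""Simulators: parametric sampling, selection schemes, Wright–Fisher."""

import numpy as np
import pytest
from scipy import stats

from codonmss.codon_model import make_spec, stationary_distribution
from codonmss.genetic_code import ALL_CODONS, UNIVERSAL_CODE
from codonmss.simulate import (
    ForwardSimConfig,
    ParametricSimConfig,
    Population,
    default_selection_scheme,
    generate_ancestral_sequence,
    make_site_fitness,
    run_forward_simulation,
    simulate_alignment,
    truth_contingency,
    wf_generation,
)
from codonmss.trees import PhyloTree


# --- parametric ----------------------------------------------------------


def test_zero_branches_give_identical_leaves(theta, freqs):
    tree = PhyloTree.from_newick("(A:0.0,B:0.0,C:0.0);")
    spec = make_spec("standard").with_rates(beta=0.3, renormalize=False)
    cfg = ParametricSimConfig(spec=spec, theta=theta, freqs=freqs, tree=tree, n_sites=50, seed=1)
    aln = simulate_alignment(cfg)
    assert np.all(aln.codons == aln.codons[0])


def test_long_branches_reach_stationarity(theta, freqs):
    """Leaf codon frequencies on a very long branch match the stationary
    distribution (chi-squared goodness of fit not rejected)."""
    tree = PhyloTree.from_newick("(A:50.0,B:50.0);")
    spec = make_spec("standard").with_rates(beta=0.3, renormalize=False)
    cfg = ParametricSimConfig(spec=spec, theta=theta, freqs=freqs, tree=tree, n_sites=10_000, seed=2)
    aln = simulate_alignment(cfg)
    pi = stationary_distribution(freqs)
    counts = np.bincount(aln.codons[0], minlength=61)
    _, p = stats.chisquare(counts, pi * aln.n_sites)
    assert p > 0.001


def test_same_seed_reproduces(theta, freqs, tree4):
    spec = make_spec("standard").with_rates(beta=0.3, renormalize=False)
    cfg = ParametricSimConfig(spec=spec, theta=theta, freqs=freqs, tree=tree4, n_sites=30, seed=7)
    a1 = simulate_alignment(cfg)
    a2 = simulate_alignment(cfg)
    assert np.array_equal(a1.codons, a2.codons)


def test_ancestral_sequence_generation():
    rng = np.random.default_rng(3)
    mass = np.zeros(61)
    mass[UNIVERSAL_CODE.sense_codons.index("AAA")] = 1.0
    seq = generate_ancestral_sequence(mass, 300, rng)
    assert len(seq) == 300 and np.all(seq == UNIVERSAL_CODE.sense_codons.index("AAA"))
    assert len(generate_ancestral_sequence(mass, 0, rng)) == 0
    uniform = np.full(61, 1 / 61)
    seq = generate_ancestral_sequence(uniform, 20_000, rng)
    counts = np.bincount(seq, minlength=61)
    _, p = stats.chisquare(counts)
    assert p > 0.001
    with pytest.raises(ValueError):
        generate_ancestral_sequence(np.full(61, 0.5), 10, rng)


# --- selection schemes ---------------------------------------------------


def test_default_scheme_shape():
    scheme = default_selection_scheme(-2.0, 50)
    labels = scheme.truth_labels()
    assert len(labels) == 67
    assert sum(1 for v in labels.values() if v == "SELECTED") == 25
    assert scheme.s == pytest.approx(2.0 / 100)
    assert scheme.nonsyn_s == pytest.approx(-0.1)
    # neutral run: realized labels all NEUTRAL, nominal labels keep the design
    neutral = default_selection_scheme(0.0, 50)
    assert set(neutral.truth_labels().values()) == {"NEUTRAL"}
    assert sum(
        1 for v in neutral.truth_labels(nominal=True).values() if v == "SELECTED"
    ) == 25


def _tiny_population(n_copies=20, L=5, scheme=None, codon="AAA"):
    scheme = scheme or default_selection_scheme(0.0, 10)
    anc = np.full(L, ALL_CODONS.index(codon), dtype=np.int16)
    fitness = make_site_fitness(anc, scheme)
    return Population(codons=np.tile(anc, (n_copies, 1)), site_fitness=fitness)


def test_site_fitness_rules():
    scheme = default_selection_scheme(-2.0, 50)
    anc = np.array([ALL_CODONS.index("GCT")])  # Ala, favored class is {GCC, GCT}
    table = make_site_fitness(anc, scheme)
    assert table[0, ALL_CODONS.index("GCT")] == 1.0
    assert table[0, ALL_CODONS.index("GCC")] == 1.0
    assert table[0, ALL_CODONS.index("GCA")] == pytest.approx(1.0 - scheme.s)
    assert table[0, ALL_CODONS.index("TAA")] == 0.0  # stop is lethal
    assert table[0, ALL_CODONS.index("AAA")] == pytest.approx(1.0 + scheme.nonsyn_s)


# --- Wright–Fisher -------------------------------------------------------


def test_population_size_conserved():
    rng = np.random.default_rng(5)
    pop = _tiny_population(n_copies=30)
    for _ in range(50):
        pop = wf_generation(pop, mu=1e-3, rng=rng)
        assert pop.n_copies == 30


def test_neutral_resampling_preserves_frequencies_on_average():
    """With s = 0 and mu = 0 a generation is a plain multinomial resample:
    the expected allele-frequency change is zero."""
    rng = np.random.default_rng(6)
    pop = _tiny_population(n_copies=40)
    # mark half the copies with a synonymous variant (AAA -> AAG, both class 0)
    pop.codons[:20, 0] = ALL_CODONS.index("AAG")
    pop.log_fitness = pop._full_log_fitness()
    assert np.allclose(pop.log_fitness, pop.log_fitness[0])  # truly neutral
    changes = []
    for _ in range(400):
        child = wf_generation(pop, mu=0.0, rng=rng)
        freq = np.mean(child.codons[:, 0] == ALL_CODONS.index("AAG"))
        changes.append(freq - 0.5)
    assert abs(np.mean(changes)) < 0.02


def test_forward_simulation_smoke():
    """Reduced-scale neutral run: 11 sampled populations, requested gene
    length, several distinct haplotypes, and a split-history tree."""
    cfg = ForwardSimConfig(
        N=50, n_codons=60, mu=2e-4, burn_in_multiplier=20, depth=1200, seed=8
    )
    scheme = default_selection_scheme(0.0, 50)
    res = run_forward_simulation(cfg, scheme)
    assert res.alignment.codons.shape == (11, 60)
    assert len(set(map(tuple, res.alignment.codons))) >= 4
    assert sorted(res.tree.leaf_names) == sorted(f"pop{i}" for i in range(11))
    assert set(res.truth_labels.values()) == {"NEUTRAL"}


def test_split_schedule_validation():
    with pytest.raises(ValueError):
        ForwardSimConfig(N=50, split_schedule=[(10, 0), (10, 0)])
    with pytest.raises(ValueError):
        ForwardSimConfig(N=1)


# --- classification scoring ---------------------------------------------


def test_truth_contingency_perfect_and_null():
    pairs = [f"p{i}" for i in range(67)]
    truth = {p: ("SELECTED" if i < 25 else "NEUTRAL") for i, p in enumerate(pairs)}
    res = truth_contingency(truth, truth)
    assert res["mcc"] == pytest.approx(1.0)
    all_selected = {p: "SELECTED" for p in pairs}
    res = truth_contingency(all_selected, truth)
    assert res["mcc"] == 0.0  # constant margin


def test_truth_contingency_published_strong_selection_table():
    """The printed strong-selection contingency table (24,1;0,42) gives
    MCC 0.97 and Fisher p about 2.6e-17."""
    pairs = [f"p{i}" for i in range(67)]
    truth = {p: ("SELECTED" if i < 25 else "NEUTRAL") for i, p in enumerate(pairs)}
    inferred = dict(truth)
    inferred["p24"] = "NEUTRAL"  # one selected pair missed
    res = truth_contingency(inferred, truth)
    assert res["table"].tolist() == [[24, 1], [0, 42]]
    assert res["mcc"] == pytest.approx(0.97, abs=0.005)
    assert res["fisher_p"] == pytest.approx(2.6e-17, rel=0.2)


def test_truth_contingency_universe_mismatch():
    with pytest.raises(ValueError):
        truth_contingency({"a": "NEUTRAL"}, {"b": "NEUTRAL"})
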