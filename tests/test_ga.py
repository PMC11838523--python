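"""CHC search machinery: canonicalization, fitness, weights, averaging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonmss.codon_model import (
    NucExchangeabilities,
    PositionalFrequencies,
    cf3x4_correct,
    make_spec,
)
from codonmss.codon_model import _implied_observed
from codonmss.fit import fit_gene
from codonmss.ga import (
    FitnessEvaluator,
    GAConfig,
    akaike_weights,
    canonicalize,
    categorize_model,
    chc_search,
    model_average_categorize,
)
from codonmss.genetic_code import enumerate_synonymous_pairs
from codonmss.simulate import ParametricSimConfig, simulate_alignment


# --- canonicalization ----------------------------------------------------


def test_canonicalize_worked_example():
    assert canonicalize((1, 0, 0, 1, 0)) == (0, 1, 1, 0, 1)


def test_canonicalize_idempotent_and_validated():
    v = (0, 1, 1, 0, 2)
    assert canonicalize(v) == v
    assert canonicalize(canonicalize((2, 1, 0, 2))) == canonicalize((2, 1, 0, 2))
    with pytest.raises(ValueError):
        canonicalize((0, 3), n_classes=3)


def test_canonicalize_permutation_oracle():
    """All class relabelings of a vector share one canonical form
    (exhaustive over permutations for D <= 6, M <= 3)."""
    for D, M in ((4, 2), (5, 3), (6, 3)):
        for v in itertools.product(range(M), repeat=D):
            canon = canonicalize(v)
            for perm in itertools.permutations(range(M)):
                relabeled = tuple(perm[x] for x in v)
                assert canonicalize(relabeled) == canon


# --- Akaike weights ------------------------------------------------------


def test_akaike_weights_examples():
    assert akaike_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])
    w = akaike_weights([0.0, 2.0])
    assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)))
    assert w[1] == pytest.approx(1 - 1 / (1 + np.exp(-1.0)))
    with pytest.raises(ValueError):
        akaike_weights([])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=1, max_size=40)
)
def test_akaike_weights_normalize(scores):
    w = akaike_weights(scores)
    assert abs(w.sum() - 1.0) < 1e-12
    # weights are positive up to floating-point underflow for huge BIC gaps
    assert np.all(w >= 0)
    assert w[np.argmin(np.asarray(scores))] > 0
    assert np.argmax(w) == np.argmin(np.asarray(scores))


# --- categorization ------------------------------------------------------


def test_categorize_worked_example():
    cats = categorize_model((0, 1, 1, 2, 0, 2), (1.0, 0.8, 1.4))
    assert cats == ["INT 1", "SELECTED", "SELECTED", "NEUTRAL", "INT 1", "NEUTRAL"]


def test_categorize_single_class():
    cats = categorize_model((0, 0, 0), (1.0,))
    assert len(set(cats)) == 1


def test_ambiguity_threshold(monkeypatch):
    from codonmss.ga import EvaluatedModel, GATrace

    # two 2-class models over 2 pairs with controlled BIC gap
    def trace_with_gap(gap):
        m1 = EvaluatedModel((0, 1), bic=0.0, logL=0.0, alpha=(1.0, 2.0))
        m2 = EvaluatedModel((0, 0), bic=gap, logL=0.0, alpha=(1.0,))
        return GATrace(
            models={m.encoding: m for m in (m1, m2)},
            best_per_generation=[(0, 0.0)],
            termination="converged",
            baseline_bic=gap,
            config=GAConfig(seed=0),
            n_chars=100,
            pair_names=["AAA:AAG", "AAC:AAT"],
        )

    # nearly all weight on one model: unambiguous
    res = model_average_categorize(trace_with_gap(50.0))
    assert res.labels[0] == "SELECTED" and not res.ambiguous[0]
    # a close race: ambiguous
    res = model_average_categorize(trace_with_gap(0.2))
    assert res.ambiguous[0]


# --- fitness over a tiny instance ----------------------------------------


@pytest.fixture(scope="module")
def tiny_instance(small_code, tree6):
    """Genes simulated on the D=4 restricted code under a 2-class truth."""
    rng = np.random.default_rng(41)
    p0 = rng.dirichlet(np.ones(4) * 6, size=3)
    target = _implied_observed(p0 / p0.sum(axis=1, keepdims=True), small_code)
    freqs = cf3x4_correct(PositionalFrequencies(pi=target), small_code)
    theta = NucExchangeabilities(theta=(0.7, 1.0, 0.5, 0.6, 1.2, 0.9))
    true_enc = (0, 0, 1, 1)  # K,N fast; D,E slow
    spec = make_spec(
        "ga", code=small_code, class_assignment=true_enc, alpha=[1.0, 0.25], beta=0.3
    )
    genes = []
    for g in range(4):
        cfg = ParametricSimConfig(
            spec=spec, theta=theta, freqs=freqs, tree=tree6,
            n_sites=500, seed=600 + g, code=small_code,
        )
        genes.append((simulate_alignment(cfg), tree6))
    return genes, true_enc


@pytest.fixture(scope="module")
def tiny_evaluator(tiny_instance):
    genes, _ = tiny_instance
    return FitnessEvaluator(genes, seed=3)


def test_null_model_fitness_is_baseline(tiny_evaluator):
    null = tiny_evaluator.evaluate((0, 0, 0, 0))
    assert null.bic == pytest.approx(tiny_evaluator.baseline_bic)
    assert null.alpha == (1.0,)


def test_fitness_cache_contract(tiny_evaluator):
    enc = (0, 1, 0, 1)
    first = tiny_evaluator.evaluate(enc)
    evals_before = tiny_evaluator.n_likelihood_evals
    second = tiny_evaluator.evaluate((1, 0, 1, 0))  # same partition, relabeled
    assert second is first
    assert tiny_evaluator.n_likelihood_evals == evals_before


def test_true_partition_beats_null(tiny_instance, tiny_evaluator):
    genes, true_enc = tiny_instance
    null = tiny_evaluator.evaluate((0, 0, 0, 0))
    truem = tiny_evaluator.evaluate(true_enc)
    assert truem.bic < null.bic
    assert truem.alpha[1] < 0.6  # the slow class rate is recovered as slow


def test_chc_matches_exhaustive_enumeration(tiny_instance, tiny_evaluator):
    """On D = 4 the partition space is enumerable: the GA's best model must
    be the global BIC optimum."""
    genes, _ = tiny_instance
    best_exhaustive = None
    for v in itertools.product(range(2), repeat=4):
        m = tiny_evaluator.evaluate(v)
        if best_exhaustive is None or m.bic < best_exhaustive.bic:
            best_exhaustive = m
    config = GAConfig(P=8, Gconv=2, fstagnant=3, seed=5, max_generations=30)
    trace = chc_search(genes, M=2, config=config, evaluator=tiny_evaluator)
    assert trace.best_model.bic == pytest.approx(best_exhaustive.bic)
    assert trace.best_model.encoding == best_exhaustive.encoding


def test_best_bic_monotone_and_unique_population(tiny_instance):
    genes, _ = tiny_instance
    config = GAConfig(P=6, Gconv=2, fstagnant=3, seed=11, max_generations=15)
    trace = chc_search(genes, M=2, config=config)
    best = [b for _, b in trace.best_per_generation]
    assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))


def test_chc_input_validation(tiny_instance):
    genes, _ = tiny_instance
    with pytest.raises(ValueError):
        chc_search(genes, M=1, config=GAConfig(seed=0))
    with pytest.raises(ValueError):
        chc_search([], M=2, config=GAConfig(seed=0))
    with pytest.raises(ValueError):
        chc_search(genes, M=40, config=GAConfig(seed=0))


def test_ga_config_defaults_match_published_values():
    cfg = GAConfig(seed=0)
    assert (cfg.P, cfg.frel, cfg.fstagnant, cfg.mu, cfg.deltaBIC, cfg.Gconv) == (
        32, 1e-6, 25, 0.20, 0.01, 100,
    )
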