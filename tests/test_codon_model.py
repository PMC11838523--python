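"""Rate-matrix construction: frequencies, CF3x4, MSS specs, generators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonmss.alignments import CodonAlignment
from codonmss.codon_model import (
    MSSSpec,
    NucExchangeabilities,
    PositionalFrequencies,
    build_rate_matrix,
    cf3x4_correct,
    empirical_position_frequencies,
    make_spec,
    stationary_distribution,
)
from codonmss.codon_model import _implied_observed
from codonmss.genetic_code import UNIVERSAL_CODE, GeneticCode
from codonmss.genetic_code import _UNIVERSAL_TABLE
from codonmss.likelihood import DecomposedQ


def _random_freqs(seed: int) -> PositionalFrequencies:
    rng = np.random.default_rng(seed)
    return PositionalFrequencies(pi=rng.dirichlet(np.ones(4) * 5, size=3))


# --- empirical frequencies ---------------------------------------------


def test_empirical_frequencies_counts():
    aln = CodonAlignment.from_sequences(["a", "b"], ["AAAAAA", "AAAAAA"])
    f = empirical_position_frequencies(aln)
    assert np.allclose(f.pi[:, 0], 1.0)

    aln = CodonAlignment.from_sequences(["a", "b"], ["AAA", "GGG"])
    f = empirical_position_frequencies(aln)
    assert np.allclose(f.pi[:, 0], 0.5) and np.allclose(f.pi[:, 2], 0.5)

    aln = CodonAlignment.from_sequences(["a", "b"], ["ATGAAA", "ATGAAA"])
    f = empirical_position_frequencies(aln)
    # hand count over codons ATG, AAA (x2 sequences)
    assert np.allclose(f.pi[0], [1.0, 0, 0, 0])
    assert np.allclose(f.pi[1], [0.5, 0, 0, 0.5])  # T and A at position 2
    assert np.allclose(f.pi[2], [0.5, 0, 0.5, 0])  # G and A at position 3


# --- CF3x4 --------------------------------------------------------------


def test_cf3x4_identity_without_stops():
    nostop = GeneticCode(
        {c: (a if a != "*" else "X") for c, a in _UNIVERSAL_TABLE.items()},
        name="nostop",
    )
    raw = _random_freqs(1)
    corrected = cf3x4_correct(raw, nostop)
    assert np.allclose(corrected.pi, raw.pi)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cf3x4_fixed_point_residual(seed):
    """The corrected frequencies reproduce the observed ones through the
    stop-codon-excluded codon distribution (the defining fixed point)."""
    raw = (
        PositionalFrequencies.uniform()
        if seed == 0
        else _random_freqs(seed)
    )
    corrected = cf3x4_correct(raw)
    implied = _implied_observed(corrected.pi, UNIVERSAL_CODE)
    assert np.max(np.abs(implied - raw.pi)) < 1e-8
    if seed == 0:
        # the correction must actually move uniform rows
        assert not np.allclose(corrected.pi, 0.25)


def test_cf3x4_preserves_zero_mass():
    pi = np.array([[0.5, 0.5, 0.0, 0.0], [0.25] * 4, [0.25] * 4])
    corrected = cf3x4_correct(PositionalFrequencies(pi=pi))
    assert corrected.pi[0, 2] == 0.0 and corrected.pi[0, 3] == 0.0


# --- stationary distribution -------------------------------------------


def test_stationary_uniform_and_degenerate():
    uniform = stationary_distribution(PositionalFrequencies.uniform())
    assert np.allclose(uniform, 1 / 61)
    mass_a = PositionalFrequencies(
        pi=np.array([[1.0, 0, 0, 0]] * 3)
    )
    pi = stationary_distribution(mass_a)
    aaa = UNIVERSAL_CODE.sense_codons.index("AAA")
    assert pi[aaa] == 1.0


def test_stationary_matches_direct_enumeration():
    freqs = _random_freqs(3)
    pi = stationary_distribution(freqs)
    expected = []
    from codonmss.genetic_code import NUC_INDEX

    for codon in UNIVERSAL_CODE.sense_codons:
        p = 1.0
        for pos, n in enumerate(codon):
            p *= freqs.pi[pos, NUC_INDEX[n]]
        expected.append(p)
    expected = np.array(expected)
    expected /= expected.sum()
    assert np.allclose(pi, expected)


# --- specs ---------------------------------------------------------------


def test_make_spec_families():
    src = make_spec("synrevcodon")
    assert src.n_classes == 67 and src.n_free_alpha == 66
    sr = make_spec("synrev")
    assert sr.n_classes == 18 and sr.n_free_alpha == 17
    std = make_spec("standard")
    assert std.n_free_alpha == 0 and std.pair_alphas().tolist() == [1.0] * 67


def test_mean_one_constraint_enforced():
    rng = np.random.default_rng(5)
    spec = make_spec("synrev").with_rates(alpha=rng.gamma(2, 0.7, 18))
    assert abs(spec.pair_alphas().mean() - 1.0) < 1e-12


def test_reference_constraint_and_class_range():
    enc = [0, 1] * 33 + [0]
    spec = make_spec("ga", class_assignment=enc, alpha=[1.0, 0.4])
    assert spec.alpha[0] == 1.0
    with pytest.raises(ValueError):
        make_spec("ga", class_assignment=enc, alpha=[0.9, 0.4])  # reference not 1
    with pytest.raises(ValueError):
        make_spec("ga", class_assignment=[19] * 67, alpha=[1.0] * 20)  # too many classes
    with pytest.raises(ValueError):
        make_spec("synrev", alpha=[-1.0] * 18)


def test_spec_json_roundtrip(tmp_path):
    rng = np.random.default_rng(6)
    spec = make_spec("synrevcodon").with_rates(alpha=rng.gamma(2, 0.5, 67), beta=0.2)
    path = tmp_path / "spec.json"
    spec.to_json(path)
    loaded = MSSSpec.from_json(path)
    assert loaded.family == spec.family
    assert np.allclose(loaded.alpha, spec.alpha)
    assert loaded.beta == spec.beta


# --- rate matrices -------------------------------------------------------


def test_table_rate_rules(theta, freqs):
    """Single-step entries factor as alpha/beta x theta x target-frequency;
    multi-nucleotide entries are zero."""
    rng = np.random.default_rng(8)
    spec = make_spec("synrevcodon").with_rates(alpha=rng.gamma(2, 0.5, 67), beta=0.37)
    Q = build_rate_matrix(spec, theta, freqs, normalize=False)
    codons = list(Q.codons)
    i, j = codons.index("AGC"), codons.index("AGT")
    pair_idx = [p.name for p in spec.pairs].index("AGC:AGT")
    alpha = spec.pair_alphas()[pair_idx]
    theta_ct = theta.as_dict()["CT"]
    pi_t3 = freqs.pi[2, 3]
    assert np.isclose(Q.q[i, j], alpha * theta_ct * pi_t3)
    # nonsynonymous single-step: AGC -> ACC exchanges G/C at position 2
    k = codons.index("ACC")
    assert np.isclose(Q.q[i, k], spec.beta * theta.as_dict()["CG"] * freqs.pi[1, 1])
    # two-nucleotide change is impossible
    assert Q.q[codons.index("TCC"), codons.index("AGC")] == 0.0


def test_uniform_parameters_give_equal_offdiagonals(uniform_freqs):
    spec = make_spec("standard")
    Q = build_rate_matrix(
        spec, NucExchangeabilities(), uniform_freqs, normalize=False
    )
    off = Q.q[Q.q > 0]
    assert np.allclose(off, off[0])


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_generator_invariants(seed):
    """Rows sum to zero and detailed balance holds for random MSS draws."""
    rng = np.random.default_rng(seed)
    freqs = cf3x4_correct(
        PositionalFrequencies(pi=rng.dirichlet(np.ones(4) * 4, size=3))
    )
    theta = NucExchangeabilities(theta=(rng.uniform(0.2, 2.0), 1.0, *rng.uniform(0.2, 2.0, 4)))
    family = ["standard", "synrev", "synrevcodon"][seed % 3]
    spec = make_spec(family)
    if family != "standard":
        spec = spec.with_rates(alpha=rng.gamma(2.0, 0.5, spec.n_classes), beta=rng.uniform(0.05, 1.0))
    Q = build_rate_matrix(spec, theta, freqs)
    assert np.max(np.abs(Q.q.sum(axis=1))) < 1e-10
    flux = Q.stationary[:, None] * Q.q
    assert np.max(np.abs(flux - flux.T)) < 1e-10
    assert np.all(Q.q - np.diag(np.diag(Q.q)) >= 0)


def test_nesting_is_bitwise(theta, freqs):
    """A SynREV spec re-expressed pair-by-pair as SynREVCodon builds the
    identical generator."""
    rng = np.random.default_rng(11)
    sr = make_spec("synrev").with_rates(alpha=rng.gamma(2, 0.5, 18), beta=0.3)
    src = make_spec("synrevcodon").with_rates(alpha=sr.pair_alphas(), beta=0.3)
    q1 = build_rate_matrix(sr, theta, freqs).q
    q2 = build_rate_matrix(src, theta, freqs).q
    assert np.array_equal(q1, q2)
    # and standard == all-ones synrevcodon
    std = make_spec("standard").with_rates(beta=0.3, renormalize=False)
    ones = make_spec("synrevcodon").with_rates(alpha=np.ones(67), beta=0.3)
    assert np.array_equal(
        build_rate_matrix(std, theta, freqs).q,
        build_rate_matrix(ones, theta, freqs).q,
    )


def test_alpha_zero_is_allowed(theta, freqs):
    alpha = np.ones(67)
    alpha[:5] = 0.0
    spec = make_spec("synrevcodon").with_rates(alpha=alpha)
    Q = build_rate_matrix(spec, theta, freqs)
    assert np.max(np.abs(Q.q.sum(axis=1))) < 1e-10


def test_transition_rows_and_long_time_limit(theta, freqs):
    spec = make_spec("standard").with_rates(beta=0.4, renormalize=False)
    Q = build_rate_matrix(spec, theta, freqs)
    dq = DecomposedQ.from_rate_matrix(Q)
    for t in (0.0, 0.01, 0.5, 5.0):
        P = dq.transition(t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
    P_long = dq.transition(50.0)
    assert np.max(np.abs(P_long - Q.stationary[None, :])) < 1e-6


def test_scaling_convention(theta, freqs):
    """Normalized generators have expected rate 3 substitutions per codon,
    i.e. branch lengths count substitutions per nucleotide site."""
    spec = make_spec("standard").with_rates(beta=0.2, renormalize=False)
    Q = build_rate_matrix(spec, theta, freqs)
    rate = -(Q.stationary * np.diag(Q.q)).sum()
    assert np.isclose(rate, 3.0)
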