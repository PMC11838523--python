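"""MG94xREV-based codon rate matrices with multiclass synonymous rates.

The instantaneous rate of substitution between sense codons x -> y that
differ at exactly one position, exchanging nucleotides n and m (target m) at
codon position p, is

    q(x, y) = alpha(x, y) * theta_nm * pi_pm    (synonymous)
    q(x, y) = beta        * theta_nm * pi_pm    (nonsynonymous)

and zero for multi-nucleotide changes.  ``theta`` is the symmetric GTR-style
nucleotide exchangeability (theta_AG = 1 for identifiability), ``pi_pm`` the
equilibrium frequency of the target nucleotide at position p (the corrected
F3x4, CF3x4, estimator), ``beta`` the shared nonsynonymous rate (dN/dS when
the synonymous rates average 1), and ``alpha(x, y)`` the relative synonymous
rate of the codon pair — the parameter the MSS family of models is about.

Model families (the ``alpha`` parameterization):

==============  ============================================  ==============
family          alpha(x, y)                                   free alphas
==============  ============================================  ==============
standard        1                                             0
a_priori / ga   alpha_i, class i assigned to each pair;       K - 1
                reference class fixed to 1
synrev          one rate per amino acid, mean over pairs = 1  17 (universal)
synrevcodon     one rate per pair, mean over pairs = 1        66 (universal)
==============  ============================================  ==============
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import optimize

from codonmss.genetic_code import (
    NUC_INDEX,
    NUCLEOTIDES,
    GeneticCode,
    SynonymousPair,
    UNIVERSAL_CODE,
    enumerate_synonymous_pairs,
    amino_acid_pair_groups,
)

NUC_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")
_NUC_PAIR_INDEX = {p: i for i, p in enumerate(NUC_PAIRS)}
FAMILIES = ("standard", "a_priori", "ga", "synrev", "synrevcodon")

# families whose alpha vector is constrained to average 1 over the pair set
MEAN_ONE_FAMILIES = ("synrev", "synrevcodon")
# families with a designated reference class whose rate is fixed at 1
REFERENCE_FAMILIES = ("a_priori", "ga")


def nuc_pair_index(n: str, m: str) -> int:
    """Index of the unordered nucleotide pair {n, m} in ``NUC_PAIRS``."""
    key = "".join(sorted(n + m))
    return _NUC_PAIR_INDEX[key]


@dataclass(frozen=True)
class NucExchangeabilities:
    """Symmetric nucleotide exchangeabilities; theta_AG == 1 by convention."""

    theta: tuple[float, ...] = (1.0,) * 6  # ordered as NUC_PAIRS

    def __post_init__(self) -> None:
        if len(self.theta) != 6:
            raise ValueError("need 6 exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if any(t < 0 for t in self.theta):
            raise ValueError("exchangeabilities must be nonnegative")

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "NucExchangeabilities":
        return cls(theta=tuple(float(d["".join(sorted(p))]) for p in NUC_PAIRS))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(NUC_PAIRS, self.theta))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.theta, dtype=float)


@dataclass(frozen=True)
class PositionalFrequencies:
    """Per-codon-position nucleotide frequencies (3 x 4, rows sum to 1)."""

    pi: np.ndarray
    source: str = "raw"  # "raw" (F3x4) or "cf3x4"

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (3, 4):
            raise ValueError("positional frequencies must be 3 x 4")
        if np.any(pi < -1e-12) or np.any(pi > 1 + 1e-12):
            raise ValueError("frequencies must lie in [0, 1]")
        if not np.allclose(pi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each position's frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "PositionalFrequencies":
        return cls(pi=np.full((3, 4), 0.25))


def empirical_position_frequencies(alignment) -> PositionalFrequencies:
    """Observed F3x4 frequencies: per-position nucleotide counts over all
    non-missing codons in a :class:`~codonmss.phylo.CodonAlignment`."""
    counts = np.zeros((3, 4))
    for codon in alignment.iter_codons():
        for p, n in enumerate(codon):
            counts[p, NUC_INDEX[n]] += 1
    if counts.sum() == 0:
        raise ValueError("alignment has no non-missing codons")
    return PositionalFrequencies(pi=counts / counts.sum(axis=1, keepdims=True), source="raw")


@lru_cache(maxsize=None)
def _codon_position_onehot(code: GeneticCode) -> np.ndarray:
    """(n_sense, 3, 4) indicator of each sense codon's nucleotide per position."""
    sense = code.sense_codons
    out = np.zeros((len(sense), 3, 4))
    for i, codon in enumerate(sense):
        for p, n in enumerate(codon):
            out[i, p, NUC_INDEX[n]] = 1.0
    return out


def _implied_observed(pi: np.ndarray, code: GeneticCode) -> np.ndarray:
    """Position-specific nucleotide frequencies implied by the product-of-
    positions codon distribution restricted to sense codons."""
    onehot = _codon_position_onehot(code)
    # probability of each sense codon before stop-exclusion renormalization
    probs = np.prod(np.einsum("cpn,pn->cp", onehot, pi), axis=1)
    total = probs.sum()
    if total <= 0:
        raise ValueError("degenerate frequencies: zero mass on sense codons")
    probs = probs / total
    return np.einsum("c,cpn->pn", probs, onehot)


def cf3x4_correct(
    raw: PositionalFrequencies,
    code: GeneticCode = UNIVERSAL_CODE,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> PositionalFrequencies:
    """Corrected F3x4 (CF3x4) position-specific nucleotide frequencies.

    Finds corrected frequencies ``p`` such that the codon distribution formed
    by their per-position product, renormalized after excluding stop codons,
    reproduces the observed frequencies ``raw``.  Solved by damped fixed-point
    iteration (multiplicative update), with a nonlinear least-squares fallback.

    For a code without stop codons the correction is the identity.
    """
    target = np.asarray(raw.pi, dtype=float)
    if not code.stop_codons:
        return PositionalFrequencies(pi=target.copy(), source="cf3x4")

    p = target.copy()
    for _ in range(max_iter):
        implied = _implied_observed(p, code)
        with np.errstate(divide="ignore", invalid="ignore"):
            update = np.where(implied > 0, target / implied, 1.0)
        # zero observed mass must stay zero; damp the multiplicative step
        p_new = p * np.where(target > 0, update**0.5, 0.0)
        p_new /= p_new.sum(axis=1, keepdims=True)
        if np.max(np.abs(_implied_observed(p_new, code) - target)) < tol:
            return PositionalFrequencies(pi=p_new, source="cf3x4")
        if np.max(np.abs(p_new - p)) < 1e-16:
            break
        p = p_new

    # fallback: least squares on the 9 free parameters
    free = target > 0

    def unpack(x: np.ndarray) -> np.ndarray:
        q = np.zeros_like(target)
        q[free] = np.abs(x)
        return q / q.sum(axis=1, keepdims=True)

    def resid(x: np.ndarray) -> np.ndarray:
        return (_implied_observed(unpack(x), code) - target).ravel()

    sol = optimize.least_squares(resid, p[free].ravel(), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    p_fit = unpack(sol.x)
    residual = np.max(np.abs(_implied_observed(p_fit, code) - target))
    if residual > 1e-8:
        raise RuntimeError(f"CF3x4 solver did not converge (residual {residual:.3g})")
    return PositionalFrequencies(pi=p_fit, source="cf3x4")


def stationary_distribution(
    freqs: PositionalFrequencies, code: GeneticCode = UNIVERSAL_CODE
) -> np.ndarray:
    """Muse–Gaut stationary codon frequencies: per-position product of
    nucleotide frequencies, renormalized over sense codons."""
    onehot = _codon_position_onehot(code)
    probs = np.prod(np.einsum("cpn,pn->cp", onehot, freqs.pi), axis=1)
    total = probs.sum()
    if total <= 0:
        raise ValueError("zero total mass on sense codons")
    return probs / total


@dataclass(frozen=True)
class MSSSpec:
    """A synonymous-rate parameterization of the codon model.

    ``class_of[i]`` gives the rate class of pair ``i`` in the canonical
    (lexicographic) pair ordering; ``alpha[k]`` is the rate of class ``k``;
    ``beta`` the shared nonsynonymous rate.
    """

    family: str
    pairs: tuple[SynonymousPair, ...]
    class_of: tuple[int, ...]
    alpha: tuple[float, ...]
    beta: float = 1.0
    constraint: str = "none"  # none | reference_class_fixed_to_1 | mean_over_pairs_equals_1
    reference_class: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.class_of) != len(self.pairs):
            raise ValueError("class_of must assign every pair")
        n_classes = len(self.alpha)
        if any(not 0 <= c < n_classes for c in self.class_of):
            raise ValueError("class index out of range")
        if any(a < 0 for a in self.alpha) or self.beta < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def n_classes(self) -> int:
        return len(self.alpha)

    @property
    def n_free_alpha(self) -> int:
        """Identifiable alpha parameters (one lost to the constraint)."""
        if self.family == "standard":
            return 0
        return len(self.alpha) - 1

    def pair_alphas(self) -> np.ndarray:
        """Per-pair alpha values in canonical pair order."""
        alpha = np.asarray(self.alpha, dtype=float)
        return alpha[np.asarray(self.class_of, dtype=int)]

    def with_rates(self, alpha=None, beta=None, renormalize: bool = True) -> "MSSSpec":
        """Copy with new class rates; re-applies the mean-1 constraint for
        synrev/synrevcodon unless ``renormalize`` is off."""
        new_alpha = tuple(float(a) for a in (alpha if alpha is not None else self.alpha))
        if renormalize and self.constraint == "mean_over_pairs_equals_1":
            per_pair = np.asarray(new_alpha)[np.asarray(self.class_of, dtype=int)]
            mean = per_pair.mean()
            if mean <= 0:
                raise ValueError("cannot normalize all-zero alpha vector")
            if abs(mean - 1.0) > 1e-13:  # idempotent within tolerance
                new_alpha = tuple(a / mean for a in new_alpha)
        return replace(self, alpha=new_alpha, beta=float(beta if beta is not None else self.beta))

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "pairs": [p.name for p in self.pairs],
            "class_of": list(self.class_of),
            "alpha": list(self.alpha),
            "beta": self.beta,
            "constraint": self.constraint,
            "reference_class": self.reference_class,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict, code: GeneticCode = UNIVERSAL_CODE) -> "MSSSpec":
        pairs = enumerate_synonymous_pairs(code)
        if [p.name for p in pairs] != d["pairs"]:
            raise ValueError("pair list does not match the genetic code's canonical ordering")
        return cls(
            family=d["family"],
            pairs=pairs,
            class_of=tuple(d["class_of"]),
            alpha=tuple(d["alpha"]),
            beta=d["beta"],
            constraint=d["constraint"],
            reference_class=d.get("reference_class", 0),
        )

    @classmethod
    def from_json(cls, path: str | Path, code: GeneticCode = UNIVERSAL_CODE) -> "MSSSpec":
        return cls.from_dict(json.loads(Path(path).read_text()), code)


def make_spec(
    family: str,
    code: GeneticCode = UNIVERSAL_CODE,
    class_assignment: list[int] | tuple[int, ...] | None = None,
    alpha: list[float] | tuple[float, ...] | None = None,
    beta: float = 1.0,
    reference_class: int = 0,
) -> MSSSpec:
    """Construct and validate an :class:`MSSSpec` for a model family.

    ``class_assignment`` (pair index -> class) is required for the
    ``a_priori`` and ``ga`` families and ignored otherwise; ``alpha`` gives
    initial class rates (defaults to all ones, then constrained).
    """
    pairs = enumerate_synonymous_pairs(code)
    D = len(pairs)
    if family == "standard":
        spec = MSSSpec(family, pairs, (0,) * D, (1.0,), beta, constraint="none")
        return spec
    if family == "synrev":
        groups = sorted(amino_acid_pair_groups(code))
        aa_class = {aa: k for k, aa in enumerate(groups)}
        class_of = tuple(aa_class[p.amino_acid] for p in pairs)
        n_classes = len(groups)
        constraint = "mean_over_pairs_equals_1"
    elif family == "synrevcodon":
        class_of = tuple(range(D))
        n_classes = D
        constraint = "mean_over_pairs_equals_1"
    elif family in ("a_priori", "ga"):
        if class_assignment is None:
            raise ValueError(f"{family} family requires a class assignment")
        class_of = tuple(int(c) for c in class_assignment)
        n_classes = max(class_of) + 1
        n_amino = len(amino_acid_pair_groups(code))
        if not 1 <= n_classes <= n_amino:
            raise ValueError(f"class count {n_classes} out of range (1..{n_amino})")
        constraint = "reference_class_fixed_to_1"
    else:
        raise ValueError(f"unknown family {family!r}")

    alpha_t = tuple(float(a) for a in (alpha if alpha is not None else (1.0,) * n_classes))
    if len(alpha_t) != n_classes:
        raise ValueError(f"expected {n_classes} class rates, got {len(alpha_t)}")
    spec = MSSSpec(family, pairs, class_of, alpha_t, beta, constraint, reference_class)
    if constraint == "mean_over_pairs_equals_1":
        spec = spec.with_rates(alpha=alpha_t)  # applies the normalization
    elif constraint == "reference_class_fixed_to_1":
        if abs(spec.alpha[reference_class] - 1.0) > 1e-12:
            raise ValueError("reference class rate must be fixed to 1")
    return spec


@dataclass(frozen=True)
class CodonRateMatrix:
    """A reversible generator over sense codons.

    ``q`` is scaled so that one unit of branch length corresponds to one
    expected substitution per *nucleotide* site at stationarity (i.e. the
    expected per-codon rate is 3).  ``scale`` records the pre-normalization
    expected substitutions per codon per unit time.
    """

    q: np.ndarray
    stationary: np.ndarray
    scale: float
    codons: tuple[str, ...]


@lru_cache(maxsize=None)
def _single_step_table(code: GeneticCode):
    """Structural arrays for all ordered single-nucleotide sense transitions.

    Returns (i, j, pos, target_nuc, theta_idx, synonymous, pair_idx) arrays;
    pair_idx indexes the canonical pair list (or -1 for nonsynonymous).
    """
    sense = code.sense_codons
    idx = {c: i for i, c in enumerate(sense)}
    pair_index = {
        frozenset((p.codon_a, p.codon_b)): k
        for k, p in enumerate(enumerate_synonymous_pairs(code))
    }
    rows = []
    for a in sense:
        for p in range(3):
            for m in NUCLEOTIDES:
                if m == a[p]:
                    continue
                b = a[:p] + m + a[p + 1:]
                if code.is_stop(b):
                    continue
                syn = code.table[a] == code.table[b]
                pk = pair_index[frozenset((a, b))] if syn else -1
                rows.append(
                    (idx[a], idx[b], p, NUC_INDEX[m], nuc_pair_index(a[p], m), syn, pk)
                )
    arr = np.array(rows, dtype=np.int64)
    return tuple(arr[:, k].copy() for k in range(7))


def build_rate_matrix(
    spec: MSSSpec,
    theta: NucExchangeabilities,
    freqs: PositionalFrequencies,
    code: GeneticCode = UNIVERSAL_CODE,
    normalize: bool = True,
) -> CodonRateMatrix:
    """Assemble the 61x61 (universal code) MSS generator.

    Off-diagonal entries follow the single-step rate rules; multi-nucleotide
    changes are 0; substitutions into stop codons are excluded from the state
    space; the diagonal makes rows sum to zero.  With ``normalize`` the matrix
    is rescaled so branch lengths measure expected substitutions per
    nucleotide site.
    """
    return assemble_rate_matrix(
        spec.pair_alphas(), spec.beta, theta.as_array(), freqs, code, normalize
    )


def assemble_rate_matrix(
    pair_alpha: np.ndarray,
    beta: float,
    theta_arr: np.ndarray,
    freqs: PositionalFrequencies,
    code: GeneticCode = UNIVERSAL_CODE,
    normalize: bool = True,
    stationary: np.ndarray | None = None,
) -> CodonRateMatrix:
    """Generator assembly from raw per-pair rates (the validated-spec path
    goes through :func:`build_rate_matrix`; hot loops may call this
    directly, optionally passing the precomputed stationary vector)."""
    i_idx, j_idx, pos, tnuc, th_idx, syn, pair_idx = _single_step_table(code)
    n = len(code.sense_codons)
    mult = np.where(syn == 1, pair_alpha[np.where(pair_idx >= 0, pair_idx, 0)], beta)
    rates = mult * theta_arr[th_idx] * freqs.pi[pos, tnuc]
    q = np.zeros((n, n))
    q[i_idx, j_idx] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    pi = stationary_distribution(freqs, code) if stationary is None else stationary
    rate_per_codon = float(-(pi * np.diag(q)).sum())
    if normalize:
        if rate_per_codon <= 0:
            raise ValueError("degenerate rate matrix: zero total rate")
        q = q * (3.0 / rate_per_codon)
    return CodonRateMatrix(q=q, stationary=pi, scale=rate_per_codon, codons=code.sense_codons)
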