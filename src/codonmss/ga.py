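"""CHC genetic-algorithm search over synonymous-rate partitions.

A candidate model is a partition of the D synonymous codon pairs (67 under
the universal code) into M rate classes, encoded as a D-vector of integers in
[0, M).  Vectors are kept in canonical class-sorted form — the first
occurrence of class 0 precedes the first occurrence of class 1, and so on —
so each partition has exactly one encoding.

Fitness is the BIC of the corresponding a-priori-style model fitted to all
training alignments with per-gene nuisance parameters (branch lengths,
exchangeabilities, frequencies, nonsynonymous rate) frozen at their baseline
MG94 estimates; the rate of class 0 is the reference, fixed to 1.  The search
is the elitist CHC scheme: free recombination, truncation selection over
parents plus offspring, and cataclysmic mutagenesis of everything but the
best individual when the population becomes too uniform or stagnant.

The final per-pair assignment is obtained by model averaging: every model
ever evaluated receives an Akaike weight from its BIC, its class rates are
ranked (smallest = SELECTED, largest = NEUTRAL, INT k in between), and each
pair accumulates weight per category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from codonmss.alignments import CodonAlignment
from codonmss.codon_model import (
    assemble_rate_matrix,
    build_rate_matrix,
    make_spec,
    stationary_distribution,
)
from codonmss.fit import GeneFit, fit_gene
from codonmss.genetic_code import GeneticCode, enumerate_synonymous_pairs
from codonmss.likelihood import (
    BatchedGeneLikelihood,
    DecomposedQ,
    GeneLikelihood,
    same_tree_structure,
)
from codonmss.trees import PhyloTree

RATE_BOUND = 100.0


def canonicalize(v: Sequence[int], n_classes: int | None = None) -> tuple[int, ...]:
    """Class-sorted canonical form: relabel classes by order of first
    occurrence.  Idempotent; any two encodings of the same partition map to
    the same output."""
    v = [int(x) for x in v]
    if n_classes is not None and any(not 0 <= x < n_classes for x in v):
        raise ValueError(f"entries must lie in [0, {n_classes})")
    relabel: dict[int, int] = {}
    out = []
    for x in v:
        if x < 0:
            raise ValueError("entries must be nonnegative")
        if x not in relabel:
            relabel[x] = len(relabel)
        out.append(relabel[x])
    return tuple(out)


@dataclass
class GAConfig:
    """CHC control parameters (population size, diversity/stagnation triggers,
    mutation rate, convergence window) and the run seed."""

    P: int = 32
    frel: float = 1e-6
    fstagnant: int = 25
    mu: float = 0.20
    deltaBIC: float = 0.01
    Gconv: int = 100
    seed: int = 0
    max_generations: int = 10_000
    refit_beta: bool = False  # refit the nonsynonymous rate per candidate

    def __post_init__(self) -> None:
        if self.P < 2:
            raise ValueError("population size must be at least 2")
        if not 0 <= self.mu <= 1:
            raise ValueError("mutation probability must lie in [0, 1]")


@dataclass
class EvaluatedModel:
    encoding: tuple[int, ...]
    bic: float
    logL: float
    alpha: tuple[float, ...]  # class rates, class 0 = reference = 1


@dataclass
class GATrace:
    """Everything the search touched: every evaluated model, the per-
    generation best, and why the run stopped."""

    models: dict[tuple[int, ...], EvaluatedModel]
    best_per_generation: list[tuple[int, float]]  # (generation, best BIC)
    termination: str
    baseline_bic: float
    config: GAConfig
    n_chars: int
    pair_names: list[str]

    @property
    def best_model(self) -> EvaluatedModel:
        return min(self.models.values(), key=lambda m: m.bic)

    def to_dict(self) -> dict:
        return {
            "pair_names": self.pair_names,
            "baseline_bic": self.baseline_bic,
            "termination": self.termination,
            "sample_size": self.n_chars,
            "best_per_generation": self.best_per_generation,
            "models": [
                {
                    "encoding": list(m.encoding),
                    "bic": m.bic,
                    "logL": m.logL,
                    "alpha": list(m.alpha),
                }
                for m in self.models.values()
            ],
        }


class FitnessEvaluator:
    """BIC fitness of rate partitions over a fixed gene collection.

    Baseline MG94 fits supply the frozen nuisance parameters; evaluations are
    cached by canonical encoding, so a model is never refitted.
    """

    def __init__(
        self,
        genes: Sequence[tuple[CodonAlignment, PhyloTree]],
        baseline_fits: Sequence[GeneFit] | None = None,
        refit_beta: bool = False,
        seed: int = 0,
        baseline_maxiter: int = 200,
    ):
        if not genes:
            raise ValueError("need at least one training alignment")
        self.code: GeneticCode = genes[0][0].code
        self.pairs = enumerate_synonymous_pairs(self.code)
        self.D = len(self.pairs)
        self.refit_beta = refit_beta
        if baseline_fits is None:
            baseline_fits = []
            for g, (aln, tree) in enumerate(genes):
                try:
                    baseline_fits.append(
                        fit_gene(aln, tree, "standard", seed=seed, maxiter=baseline_maxiter)
                    )
                except Exception as exc:
                    raise RuntimeError(f"baseline fit failed for gene {g}: {exc}") from exc
        self.baseline = list(baseline_fits)
        # single-precision pruning: the parabolic rate search and BIC ranking
        # only need ~1e-3 logL resolution, and float32 matmuls are ~2x faster
        self.engines = [
            GeneLikelihood(aln, tree, dtype=np.float32) for aln, tree in genes
        ]
        # gene collections sharing one tree structure (e.g. replicate
        # simulations) evaluate all genes in one batched pruning pass
        self._batched = None
        self._batched_lengths = None
        if len(self.engines) > 1 and same_tree_structure(self.engines):
            self._batched = BatchedGeneLikelihood(self.engines)
            self._batched_lengths = np.stack(
                [f.branch_lengths for f in self.baseline]
            )
        self.n_chars = sum(aln.n_taxa * aln.n_sites for aln, _ in genes)
        # frozen per-gene quantities reused by every candidate evaluation
        self._theta_arrs = [f.theta.as_array() for f in self.baseline]
        self._stationaries = [
            stationary_distribution(f.freqs, self.code) for f in self.baseline
        ]
        self.k_baseline = sum(f.k for f in self.baseline)
        self.baseline_logL = sum(f.logL for f in self.baseline)
        self.cache: dict[tuple[int, ...], EvaluatedModel] = {}
        self.n_likelihood_evals = 0

    @property
    def baseline_bic(self) -> float:
        return self.k_baseline * np.log(self.n_chars) - 2.0 * self.baseline_logL

    def _gene_Q(self, g: int, pair_alpha: np.ndarray, beta: float):
        base = self.baseline[g]
        return assemble_rate_matrix(
            pair_alpha, beta, self._theta_arrs[g], base.freqs, self.code,
            stationary=self._stationaries[g],
        )

    def _gene_logL(self, engine, g, class_of, alpha, beta) -> float:
        pair_alpha = np.asarray(alpha, float)[np.asarray(class_of, int)]
        # float64 decomposition is required: small transition probabilities
        # carry the signal when class rates approach 0, and a low-precision
        # eigenreconstruction perturbs them with absolute-scale error
        Q = self._gene_Q(g, pair_alpha, beta)
        return engine.log_likelihood(
            DecomposedQ.from_rate_matrix(Q), self.baseline[g].branch_lengths
        )

    def _sum_logL(self, class_of: tuple[int, ...], alpha: np.ndarray) -> float:
        pair_alpha = np.asarray(alpha, float)[np.asarray(class_of, int)]
        if self._batched is not None and not self.refit_beta:
            dqs = []
            for g, base in enumerate(self.baseline):
                dq = DecomposedQ.from_rate_matrix(
                    self._gene_Q(g, pair_alpha, base.spec.beta)
                )
                if dq.lam is None:
                    break  # degenerate stationary vector: use the slow path
                dqs.append(dq)
            else:
                lls = self._batched.log_likelihoods(dqs, self._batched_lengths)
                self.n_likelihood_evals += 1
                if not np.all(np.isfinite(lls)):
                    return -1e12
                return float(lls.sum())
        total = 0.0
        for g, (engine, base) in enumerate(zip(self.engines, self.baseline)):
            if self.refit_beta:
                res = optimize.minimize_scalar(
                    lambda b: -self._gene_logL(engine, g, class_of, alpha, b),
                    bounds=(0.0, RATE_BOUND),
                    method="bounded",
                    options={"xatol": 1e-3},
                )
                ll = -res.fun
            else:
                ll = self._gene_logL(engine, g, class_of, alpha, base.spec.beta)
            if not np.isfinite(ll):
                return -1e12
            total += ll
        self.n_likelihood_evals += 1
        return total

    def evaluate(
        self, encoding: Sequence[int], init_alpha: Sequence[float] | None = None
    ) -> EvaluatedModel:
        """Fitness of one partition; ``init_alpha`` warm-starts the class-rate
        optimization (e.g. from a parent model during recombination)."""
        enc = canonicalize(encoding)
        if len(enc) != self.D:
            raise ValueError(f"encoding must have length {self.D}")
        hit = self.cache.get(enc)
        if hit is not None:
            return hit
        m = max(enc) + 1
        if m == 1:
            model = EvaluatedModel(
                encoding=enc,
                bic=self.baseline_bic,
                logL=self.baseline_logL,
                alpha=(1.0,),
            )
        else:
            n_free = m - 1

            def neg(a_free: np.ndarray) -> float:
                alpha = np.concatenate([[1.0], np.abs(a_free)])
                return -self._sum_logL(enc, alpha)

            x0 = np.ones(n_free)
            if init_alpha is not None and len(init_alpha) >= m:
                x0 = np.clip(np.asarray(init_alpha[1:m], dtype=float), 1e-4, RATE_BOUND)
            if n_free == 1:
                alpha_free, best_neg = _optimize_1d(
                    lambda a: neg(np.array([a])), float(x0[0])
                )
                alpha_free = np.array([alpha_free])
            else:
                res = optimize.minimize(
                    neg,
                    x0,
                    method="L-BFGS-B",
                    bounds=[(0.0, RATE_BOUND)] * n_free,
                    options={"maxiter": 200, "ftol": 1e-8},
                )
                alpha_free = np.abs(res.x)
                best_neg = res.fun
            logL = -best_neg
            k = self.k_baseline + n_free
            bic = k * np.log(self.n_chars) - 2.0 * logL
            model = EvaluatedModel(
                encoding=enc,
                bic=float(bic),
                logL=float(logL),
                alpha=(1.0, *alpha_free),
            )
        self.cache[enc] = model
        return model


def _optimize_1d(f, x0: float, n_rounds: int = 3) -> tuple[float, float]:
    """Successive parabolic refinement of a 1-d rate in log space.

    Cheap replacement for a full bracketed line search: starts from ``x0``
    (a warm start such as a parent model's rate), expands if the minimum sits
    on the edge of the probe triple, and shrinks the probe width each round.
    Rates live in [0, RATE_BOUND].
    """
    eps = 1e-6
    u = np.log(max(x0, eps))
    u_hi = np.log(RATE_BOUND)
    u_lo = np.log(eps)
    evaluated: dict[float, float] = {}

    def g(ui: float) -> float:
        ui = min(max(ui, u_lo), u_hi)
        if ui not in evaluated:
            evaluated[ui] = f(float(np.exp(ui)))
        return evaluated[ui]

    h = 0.8
    for round_idx in range(n_rounds):
        expanded = False
        for _ in range(6):  # expand toward a bracket if needed
            fm, fl, fr = g(u), g(u - h), g(u + h)
            if fl < fm and u - h > u_lo:
                u -= h
                expanded = True
            elif fr < fm and u + h < u_hi:
                u += h
                expanded = True
            else:
                break
        fl, fm, fr = g(u - h), g(u), g(u + h)
        denom = fl - 2 * fm + fr
        step = 0.0
        if denom > 0:
            step = float(np.clip(0.5 * h * (fl - fr) / denom, -h, h))
            u = min(max(u + step, u_lo), u_hi)
        # a refined, non-expanding round with a tiny parabolic step is
        # converged; exiting mid-travel (expansion) is never allowed
        if round_idx >= 1 and not expanded and abs(step) < 0.1:
            break
        h *= 0.3
    u_best = min(evaluated, key=evaluated.get)
    return float(np.exp(u_best)), evaluated[u_best]


def _unique_random_vectors(
    rng: np.random.Generator, D: int, M: int, count: int,
    exclude: set[tuple[int, ...]] | None = None,
) -> list[tuple[int, ...]]:
    out: list[tuple[int, ...]] = []
    seen = set(exclude or set())
    attempts = 0
    while len(out) < count and attempts < 1000 * count:
        v = canonicalize(rng.integers(0, M, size=D))
        attempts += 1
        if v not in seen:
            seen.add(v)
            out.append(v)
    if len(out) < count:
        raise RuntimeError("could not generate enough unique model vectors")
    return out


def chc_search(
    genes: Sequence[tuple[CodonAlignment, PhyloTree]],
    M: int,
    config: GAConfig,
    baseline_fits: Sequence[GeneFit] | None = None,
    evaluator: FitnessEvaluator | None = None,
) -> GATrace:
    """CHC search for the best M-class partition of synonymous pairs.

    Returns the full trace (every model evaluated, with its BIC and class
    rates), from which the best model and the model-averaged categorical
    assignment are derived.
    """
    if M < 2:
        raise ValueError("need at least 2 rate classes to search over")
    if evaluator is None:
        evaluator = FitnessEvaluator(
            genes, baseline_fits=baseline_fits,
            refit_beta=config.refit_beta, seed=config.seed,
        )
    D = evaluator.D
    n_amino = len({p.amino_acid for p in evaluator.pairs})
    if M > n_amino:
        raise ValueError(f"M={M} exceeds the number of amino acids with pairs ({n_amino})")
    rng = np.random.default_rng(config.seed)

    population = _unique_random_vectors(rng, D, M, config.P)
    fitness = {v: evaluator.evaluate(v).bic for v in population}
    best_bic = min(fitness.values())
    best_per_generation = [(0, best_bic)]
    no_improvement = 0
    stagnant = 0
    termination = "max_generations"

    for gen in range(1, config.max_generations + 1):
        # --- recombination: P offspring by 50-50 free recombination ----
        offspring: list[tuple[int, ...]] = []
        hints: dict[tuple[int, ...], tuple[float, ...]] = {}
        pop_set = set(population)
        for _ in range(config.P):
            i, j = rng.choice(len(population), size=2, replace=False)
            mask = rng.random(D) < 0.5
            child = np.where(mask, population[i], population[j])
            child_c = canonicalize(child)
            if child_c not in pop_set and child_c not in offspring:
                offspring.append(child_c)
                better = min(population[i], population[j], key=lambda v: fitness[v])
                hints[child_c] = evaluator.cache[better].alpha

        new_entered = False
        for child in offspring:
            fitness[child] = evaluator.evaluate(child, init_alpha=hints.get(child)).bic

        # --- elitist truncation of parents + offspring ------------------
        combined = sorted(
            set(population) | set(offspring), key=lambda v: (fitness[v], v)
        )
        new_population = combined[: config.P]
        new_entered = any(v not in pop_set for v in new_population)
        population = new_population

        gen_best = fitness[population[0]]
        if best_bic - gen_best > config.deltaBIC:
            no_improvement = 0
        else:
            no_improvement += 1
        best_bic = min(best_bic, gen_best)
        best_per_generation.append((gen, best_bic))
        stagnant = 0 if new_entered else stagnant + 1

        # --- termination -------------------------------------------------
        if no_improvement >= config.Gconv:
            termination = "converged"
            break

        # --- cataclysmic mutagenesis ------------------------------------
        # triggered by population uniformity, by generations without any new
        # member, or periodically during a best-fitness plateau (with larger
        # populations new models keep trickling into the bottom ranks while
        # the top is frozen, so the plateau trigger is what actually fires)
        bics = [fitness[v] for v in population]
        rel_range = (max(bics) - min(bics)) / max(abs(min(bics)), 1e-12)
        plateau = no_improvement > 0 and no_improvement % config.fstagnant == 0
        if rel_range < config.frel or stagnant >= config.fstagnant or plateau:
            mutated = [population[0]]
            seen = {population[0]}
            for v in population[1:]:
                cand = v
                for _ in range(10):
                    arr = np.array(v)
                    mask = rng.random(D) < config.mu
                    arr[mask] = rng.integers(0, M, size=int(mask.sum()))
                    cand = canonicalize(arr)
                    if cand not in seen:
                        break
                seen.add(cand)
                mutated.append(cand)
            population = list(dict.fromkeys(mutated))
            for v in population:
                if v not in fitness:
                    fitness[v] = evaluator.evaluate(v).bic
            stagnant = 0

    return GATrace(
        models=dict(evaluator.cache),
        best_per_generation=best_per_generation,
        termination=termination,
        baseline_bic=evaluator.baseline_bic,
        config=config,
        n_chars=evaluator.n_chars,
        pair_names=[p.name for p in evaluator.pairs],
    )


def akaike_weights(bic_scores: Sequence[float]) -> np.ndarray:
    """w(m) = exp((min BIC - BIC(m)) / 2), normalized to sum to 1."""
    scores = np.asarray(bic_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores given")
    if not np.all(np.isfinite(scores)):
        raise ValueError("BIC scores must be finite")
    w = np.exp((scores.min() - scores) / 2.0)
    return w / w.sum()


CATEGORY_SELECTED = "SELECTED"
CATEGORY_NEUTRAL = "NEUTRAL"


def _rank_categories(n_classes: int) -> list[str]:
    """Category names for class-rate ranks: smallest -> SELECTED, largest ->
    NEUTRAL, INT k in between.  A single-class model is all NEUTRAL."""
    if n_classes == 1:
        return [CATEGORY_NEUTRAL]
    names = [CATEGORY_SELECTED]
    names += [f"INT {k}" for k in range(1, n_classes - 1)]
    names.append(CATEGORY_NEUTRAL)
    return names


def categorize_model(encoding: Sequence[int], alpha: Sequence[float]) -> list[str]:
    """Per-pair categorical labels for one model: rank its class rates and
    map each pair's class to SELECTED / INT k / NEUTRAL."""
    alpha = np.asarray(alpha, dtype=float)
    n_classes = len(alpha)
    order = np.argsort(alpha, kind="stable")
    rank_of_class = np.empty(n_classes, dtype=int)
    rank_of_class[order] = np.arange(n_classes)
    names = _rank_categories(n_classes)
    return [names[rank_of_class[c]] for c in encoding]


@dataclass
class ModelAverageResult:
    """Akaike-weighted categorical assignment per synonymous pair."""

    pair_names: list[str]
    category_weights: list[dict[str, float]]  # per pair
    labels: list[str]  # max-weight category per pair
    ambiguous: list[bool]  # True when max weight < threshold
    threshold: float = 0.90

    def binary_labels(self) -> dict[str, str]:
        """SELECTED/NEUTRAL per pair by which of the two received more
        model-averaged support."""
        out = {}
        for name, weights in zip(self.pair_names, self.category_weights):
            sel = weights.get(CATEGORY_SELECTED, 0.0)
            neu = weights.get(CATEGORY_NEUTRAL, 0.0)
            out[name] = CATEGORY_SELECTED if sel > neu else CATEGORY_NEUTRAL
        return out

    @property
    def n_ambiguous(self) -> int:
        return int(sum(self.ambiguous))

    def to_dict(self) -> dict:
        return {
            "pair_names": self.pair_names,
            "labels": self.labels,
            "ambiguous": self.ambiguous,
            "category_weights": self.category_weights,
            "threshold": self.threshold,
        }


def model_average_categorize(trace: GATrace, threshold: float = 0.90) -> ModelAverageResult:
    """Accumulate Akaike weight per category per pair over every model in the
    trace; a pair's assignment is unambiguous when its top category holds at
    least ``threshold`` of the weight."""
    models = list(trace.models.values())
    if not models:
        raise ValueError("empty trace")
    for m in models:
        if not m.alpha:
            raise ValueError(f"model {m.encoding} lacks rate estimates")
    weights = akaike_weights([m.bic for m in models])
    D = len(trace.pair_names)
    acc: list[dict[str, float]] = [{} for _ in range(D)]
    for w, m in zip(weights, models):
        cats = categorize_model(m.encoding, m.alpha)
        for i, cat in enumerate(cats):
            acc[i][cat] = acc[i].get(cat, 0.0) + float(w)
    labels = []
    ambiguous = []
    for d in acc:
        top_cat, top_w = max(d.items(), key=lambda kv: kv[1])
        labels.append(top_cat)
        ambiguous.append(top_w < threshold)
    return ModelAverageResult(
        pair_names=list(trace.pair_names),
        category_weights=acc,
        labels=labels,
        ambiguous=ambiguous,
        threshold=threshold,
    )
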