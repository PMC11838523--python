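"""Maximum-likelihood fitting of MSS codon models and nested-model comparison.

Single-gene fits proceed in stages, the way large phylogenetic packages
organize codon-model optimization: a baseline MG94xREV fit of branch lengths,
nucleotide exchangeabilities and the nonsynonymous rate; then, for MSS
families, the synonymous class rates (with the nonsynonymous rate) against
the frozen baseline; then an optional joint polish of all parameters.
Equilibrium frequencies are plug-in CF3x4 estimates throughout — they are not
optimized by likelihood, but they are counted toward the parameter total for
information criteria (9 per alignment).

Multi-gene ("fully shared") fits estimate one set of synonymous class rates
across genes while holding each gene's baseline MG94 nuisance parameters
(frequencies, exchangeabilities, nonsynonymous rate, relative branch lengths)
at their single-gene estimates; each gene keeps one free multiplicative
branch-length scaler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from codonmss.alignments import CodonAlignment
from codonmss.codon_model import (
    MSSSpec,
    NucExchangeabilities,
    PositionalFrequencies,
    build_rate_matrix,
    cf3x4_correct,
    empirical_position_frequencies,
    make_spec,
)
from codonmss.genetic_code import GeneticCode
from codonmss.likelihood import DecomposedQ, GeneLikelihood
from codonmss.trees import PhyloTree

BRANCH_BOUNDS = (0.0, 20.0)
THETA_BOUNDS = (1e-4, 100.0)
RATE_BOUNDS = (0.0, 100.0)  # alpha and beta
N_FREQ_PARAMS = 9  # 3 positions x (4 - 1) free nucleotide frequencies

# nesting relations used by the likelihood ratio test
_NESTED_IN = {
    "standard": {"a_priori", "ga", "synrev", "synrevcodon"},
    "synrev": {"synrevcodon"},
}


@dataclass
class GeneFit:
    """Result of a single-gene maximum-likelihood fit."""

    logL: float
    spec: MSSSpec
    theta: NucExchangeabilities
    freqs: PositionalFrequencies
    branch_lengths: np.ndarray  # indexed by TreeIndex node id
    k: int
    converged: bool
    n_taxa: int
    n_sites: int
    family: str

    @property
    def omega(self) -> float:
        """dN/dS relative to the family's synonymous-rate constraint."""
        return self.spec.beta

    def to_dict(self) -> dict:
        return {
            "logL": self.logL,
            "family": self.family,
            "omega": self.omega,
            "spec": self.spec.to_dict(),
            "theta": self.theta.as_dict(),
            "freqs": self.freqs.pi.tolist(),
            "k": self.k,
            "converged": self.converged,
            "n_taxa": self.n_taxa,
            "n_sites": self.n_sites,
        }


@dataclass
class JointFit:
    """Result of a shared-rates fit over several genes."""

    logL: float
    spec: MSSSpec
    scalers: np.ndarray
    gene_fits: list[GeneFit]
    k: int
    converged: bool


def _spec_for_family(
    family: str, code: GeneticCode, class_assignment=None
) -> MSSSpec:
    return make_spec(family, code=code, class_assignment=class_assignment)


def _mean_normalized(spec: MSSSpec, raw_alpha: np.ndarray) -> np.ndarray:
    """Normalize raw class rates so the per-pair mean is exactly 1."""
    per_pair = raw_alpha[np.asarray(spec.class_of, dtype=int)]
    mean = per_pair.mean()
    if mean <= 0:
        return np.full_like(raw_alpha, 1.0)
    return raw_alpha / mean


class _GeneObjective:
    """Shared machinery: map parameter vectors to -logL for one gene.

    Finite-difference optimization perturbs one coordinate at a time, so the
    generator (and its eigendecomposition) is cached on the rate parameters,
    and the per-branch transition matrices are updated incrementally when
    only branch lengths move.
    """

    def __init__(
        self,
        engine: GeneLikelihood,
        spec: MSSSpec,
        freqs: PositionalFrequencies,
        code: GeneticCode,
    ):
        self.engine = engine
        self.spec = spec
        self.freqs = freqs
        self.code = code
        self.n_branches = engine.idx.n_branches
        self.branch_nodes = engine.idx.branch_nodes
        self._q_key: bytes | None = None
        self._dq: DecomposedQ | None = None

    def lengths_from(self, branch_params: np.ndarray) -> np.ndarray:
        lengths = np.zeros(self.engine.idx.n_nodes)
        lengths[self.branch_nodes] = branch_params
        return lengths

    def _decomposed(self, theta_free, beta, alpha) -> DecomposedQ:
        key = np.concatenate([theta_free, [beta], alpha]).tobytes()
        if key != self._q_key:
            theta = NucExchangeabilities(
                theta=(theta_free[0], 1.0, *theta_free[1:])  # AG pinned to 1
            )
            spec = self.spec.with_rates(alpha=alpha, beta=beta, renormalize=False)
            Q = build_rate_matrix(spec, theta, self.freqs, self.code)
            self._dq = DecomposedQ.from_rate_matrix(Q)
            self._q_key = key
        return self._dq

    def neg_logL(
        self,
        branch_params: np.ndarray,
        theta_free: np.ndarray,
        beta: float,
        alpha: np.ndarray,
    ) -> float:
        if self.spec.constraint == "mean_over_pairs_equals_1":
            alpha = _mean_normalized(self.spec, alpha)
        dq = self._decomposed(np.asarray(theta_free, float), float(beta),
                              np.asarray(alpha, float))
        ll = self.engine.log_likelihood(dq, self.lengths_from(branch_params))
        return -ll if np.isfinite(ll) else 1e12


def _minimize(fun, x0, bounds, maxiter=500):
    res = optimize.minimize(
        fun,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-9, "maxfun": 10**6},
    )
    return res


def initial_branch_lengths(engine: GeneLikelihood, floor: float = 1e-3) -> np.ndarray:
    """Starting branch lengths: the tree's own lengths where present, else a
    small default."""
    given = engine.idx.edge_length[engine.idx.branch_nodes]
    out = np.where(given > 0, given, 0.05)
    return np.maximum(out, floor)


def fit_gene(
    aln: CodonAlignment,
    tree: PhyloTree,
    family: str = "standard",
    class_assignment: Sequence[int] | None = None,
    seed: int = 0,
    n_starts: int | None = None,
    polish: bool = True,
    maxiter: int = 500,
    count_frequency_params: bool = True,
) -> GeneFit:
    """Fit one model family to one gene by staged direct optimization.

    ``n_starts`` controls random multi-starts for the synonymous-rate stage
    (default 3 for the rate-rich synrev/synrevcodon families, 1 otherwise);
    all randomness derives from ``seed``.
    """
    code = aln.code
    engine = GeneLikelihood(aln, tree)
    freqs = cf3x4_correct(empirical_position_frequencies(aln), code)
    spec0 = _spec_for_family(family, code, class_assignment)
    obj = _GeneObjective(engine, spec0, freqs, code)
    rng = np.random.default_rng(seed)
    if n_starts is None:
        n_starts = 3 if family in ("synrev", "synrevcodon") else 1

    nb = obj.n_branches
    bl0 = initial_branch_lengths(engine)
    theta0 = np.ones(5)
    beta0 = 0.5
    ones_alpha = np.ones(spec0.n_classes)

    # --- stage A: baseline MG94 (alpha == 1) ---------------------------
    def neg_a(x):
        return obj.neg_logL(x[:nb], x[nb : nb + 5], x[nb + 5], ones_alpha)

    x0 = np.concatenate([bl0, theta0, [beta0]])
    bounds = [BRANCH_BOUNDS] * nb + [THETA_BOUNDS] * 5 + [RATE_BOUNDS]
    res_a = _minimize(neg_a, x0, bounds, maxiter=maxiter)
    bl = res_a.x[:nb]
    theta_free = res_a.x[nb : nb + 5]
    beta = res_a.x[nb + 5]
    logL = -res_a.fun
    converged = bool(res_a.success)
    alpha = ones_alpha.copy()

    if family != "standard":
        # --- stage B: class rates + beta against the frozen baseline ---
        free_alpha_idx = [
            k for k in range(spec0.n_classes)
            if not (spec0.constraint == "reference_class_fixed_to_1"
                    and k == spec0.reference_class)
        ]
        n_free = len(free_alpha_idx)

        def unpack_alpha(a_free: np.ndarray) -> np.ndarray:
            a = np.ones(spec0.n_classes)
            a[free_alpha_idx] = a_free
            return a

        def neg_b(x):
            return obj.neg_logL(bl, theta_free, x[-1], unpack_alpha(x[:-1]))

        starts = [np.concatenate([np.ones(n_free), [beta]])]
        for _ in range(n_starts - 1):
            starts.append(
                np.concatenate([rng.gamma(2.0, 0.5, n_free), [beta * rng.uniform(0.5, 2.0)]])
            )
        best = None
        for s0 in starts:
            res_b = _minimize(neg_b, s0, [RATE_BOUNDS] * (n_free + 1), maxiter=maxiter)
            if best is None or res_b.fun < best.fun:
                best = res_b
        alpha = unpack_alpha(best.x[:-1])
        beta = best.x[-1]
        logL = -best.fun
        converged = converged and bool(best.success)

        if polish and n_free > 20:
            # --- stage C (rate-rich): block-coordinate polish ----------
            # Baseline branch lengths were fitted under the wrong (single-
            # rate) model; re-fit nuisance given the rates, then the rates
            # given the nuisance, warm-started.  Two half-cycles capture
            # most of the correction at a fraction of the joint cost.
            for _ in range(2):
                a_cur = alpha.copy()

                def neg_n(x):
                    return obj.neg_logL(x[:nb], x[nb : nb + 5], x[nb + 5], a_cur)

                res_n = _minimize(
                    neg_n, np.concatenate([bl, theta_free, [beta]]), bounds,
                    maxiter=maxiter,
                )
                if -res_n.fun >= logL:
                    bl = res_n.x[:nb]
                    theta_free = res_n.x[nb : nb + 5]
                    beta = res_n.x[nb + 5]
                    logL = -res_n.fun

                res_r = _minimize(
                    neg_b, np.concatenate([alpha[free_alpha_idx], [beta]]),
                    [RATE_BOUNDS] * (n_free + 1), maxiter=maxiter,
                )
                if -res_r.fun >= logL:
                    alpha = unpack_alpha(res_r.x[:-1])
                    beta = res_r.x[-1]
                    logL = -res_r.fun
        elif polish:
            # --- stage C: everything together, warm-started -----------
            def neg_c(x):
                return obj.neg_logL(
                    x[:nb], x[nb : nb + 5], x[nb + 5], unpack_alpha(x[nb + 6 :])
                )

            xc0 = np.concatenate([bl, theta_free, [beta], alpha[free_alpha_idx]])
            bounds_c = bounds + [RATE_BOUNDS] * n_free
            res_c = _minimize(neg_c, xc0, bounds_c, maxiter=maxiter)
            if -res_c.fun >= logL:
                bl = res_c.x[:nb]
                theta_free = res_c.x[nb : nb + 5]
                beta = res_c.x[nb + 5]
                alpha = unpack_alpha(res_c.x[nb + 6 :])
                logL = -res_c.fun
                converged = converged and bool(res_c.success)

    if spec0.constraint == "mean_over_pairs_equals_1":
        alpha = _mean_normalized(spec0, alpha)
    theta = NucExchangeabilities(theta=(theta_free[0], 1.0, *theta_free[1:]))
    spec = spec0.with_rates(alpha=alpha, beta=beta, renormalize=False)
    k = (
        nb
        + 5
        + (N_FREQ_PARAMS if count_frequency_params else 0)
        + spec.n_free_alpha
        + 1
    )
    return GeneFit(
        logL=float(logL),
        spec=spec,
        theta=theta,
        freqs=freqs,
        branch_lengths=obj.lengths_from(bl),
        k=k,
        converged=converged,
        n_taxa=aln.n_taxa,
        n_sites=aln.n_sites,
        family=family,
    )


def fit_joint(
    genes: Sequence[tuple[CodonAlignment, PhyloTree]],
    family: str = "synrev",
    class_assignment: Sequence[int] | None = None,
    baseline_fits: Sequence[GeneFit] | None = None,
    seed: int = 0,
    maxiter: int = 500,
) -> JointFit:
    """Shared synonymous rates across G > 1 genes with frozen per-gene
    nuisance parameters and one branch-length scaler per gene."""
    if len(genes) < 2:
        raise ValueError("joint fitting requires G > 1 genes")
    code = genes[0][0].code
    if baseline_fits is None:
        baseline_fits = []
        for g, (aln, tree) in enumerate(genes):
            try:
                baseline_fits.append(fit_gene(aln, tree, "standard", seed=seed))
            except Exception as exc:
                raise RuntimeError(f"baseline MG94 fit failed for gene {g}: {exc}") from exc
    spec0 = _spec_for_family(family, code, class_assignment)
    engines = [GeneLikelihood(aln, tree) for aln, tree in genes]

    free_alpha_idx = [
        k for k in range(spec0.n_classes)
        if not (spec0.constraint == "reference_class_fixed_to_1"
                and k == spec0.reference_class)
    ]
    n_free = len(free_alpha_idx)
    G = len(genes)

    def unpack_alpha(a_free: np.ndarray) -> np.ndarray:
        a = np.ones(spec0.n_classes)
        a[free_alpha_idx] = a_free
        if spec0.constraint == "mean_over_pairs_equals_1":
            a = _mean_normalized(spec0, a)
        return a

    def neg(x):
        alpha = unpack_alpha(x[:n_free])
        scalers = x[n_free:]
        total = 0.0
        for g, (engine, base) in enumerate(zip(engines, baseline_fits)):
            spec = spec0.with_rates(alpha=alpha, beta=base.spec.beta, renormalize=False)
            Q = build_rate_matrix(spec, base.theta, base.freqs, code)
            ll = engine.log_likelihood(
                DecomposedQ.from_rate_matrix(Q), base.branch_lengths * scalers[g]
            )
            if not np.isfinite(ll):
                return 1e12
            total += ll
        return -total

    x0 = np.concatenate([np.ones(n_free), np.ones(G)])
    bounds = [RATE_BOUNDS] * n_free + [(1e-3, 100.0)] * G
    res = _minimize(neg, x0, bounds, maxiter=maxiter)
    alpha = unpack_alpha(res.x[:n_free])
    # shared beta is held per gene; the joint spec records the mean omega
    mean_beta = float(np.mean([b.spec.beta for b in baseline_fits]))
    spec = spec0.with_rates(alpha=alpha, beta=mean_beta, renormalize=False)
    k = sum(b.k for b in baseline_fits) + spec.n_free_alpha + G
    return JointFit(
        logL=float(-res.fun),
        spec=spec,
        scalers=res.x[n_free:].copy(),
        gene_fits=list(baseline_fits),
        k=k,
        converged=bool(res.success),
    )


@dataclass
class ComparisonResult:
    lrt: float
    df: int
    p_value: float
    aic_null: float
    aic_alt: float
    bic_null: float
    bic_alt: float
    sample_size: int


def information_criteria(
    fit: GeneFit | JointFit, sample_size_rule: str = "codon_sites"
) -> tuple[float, float]:
    """AIC and BIC; BIC sample size n = sum over alignments of
    sequences x sites ('codon_sites' counts codon columns as sites,
    'nucleotides' counts nucleotide characters)."""
    n = bic_sample_size(fit, sample_size_rule)
    aic = 2 * fit.k - 2 * fit.logL
    bic = fit.k * np.log(n) - 2 * fit.logL
    return float(aic), float(bic)


def bic_sample_size(fit: GeneFit | JointFit, rule: str = "codon_sites") -> int:
    if isinstance(fit, JointFit):
        n = sum(f.n_taxa * f.n_sites for f in fit.gene_fits)
    else:
        n = fit.n_taxa * fit.n_sites
    if rule == "nucleotides":
        n *= 3
    elif rule != "codon_sites":
        raise ValueError(f"unknown sample size rule {rule!r}")
    return n


def lrt(null: GeneFit, alt: GeneFit, sample_size_rule: str = "codon_sites") -> ComparisonResult:
    """Likelihood ratio test of nested model families, with AIC/BIC."""
    if alt.family not in _NESTED_IN.get(null.family, set()):
        raise ValueError(f"{null.family!r} is not nested in {alt.family!r}")
    statistic = 2.0 * (alt.logL - null.logL)
    df = alt.k - null.k
    if df <= 0:
        raise ValueError("alternative must have more free parameters than the null")
    p = float(stats.chi2.sf(max(statistic, 0.0), df))
    aic0, bic0 = information_criteria(null, sample_size_rule)
    aic1, bic1 = information_criteria(alt, sample_size_rule)
    return ComparisonResult(
        lrt=float(statistic),
        df=int(df),
        p_value=p,
        aic_null=aic0,
        aic_alt=aic1,
        bic_null=bic0,
        bic_alt=bic1,
        sample_size=bic_sample_size(null, sample_size_rule),
    )


def p_adjust(pvalues: Sequence[float], method: str = "holm_bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: Holm step-down or Benjamini–Hochberg
    step-up, with monotonicity enforced."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    key = {"holm_bonferroni": "holm", "benjamini_hochberg": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=key)[1]
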