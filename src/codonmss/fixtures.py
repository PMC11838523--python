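"""Deterministic synthetic fixtures: small gene collections for tests and
examples, generated entirely in memory from a seed (no downloads)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from codonmss.codon_model import (
    NucExchangeabilities,
    PositionalFrequencies,
    cf3x4_correct,
    make_spec,
)
from codonmss.gene_io import write_gene_file
from codonmss.genetic_code import GeneticCode, UNIVERSAL_CODE
from codonmss.simulate import ParametricSimConfig, simulate_alignment
from codonmss.trees import PhyloTree


def random_tree(
    n_taxa: int, rng: np.random.Generator, mean_branch: float = 0.08
) -> PhyloTree:
    """Random bifurcating topology by sequential attachment, with
    exponential branch lengths."""
    names = [f"t{i}" for i in range(n_taxa)]

    def bl() -> float:
        return float(max(rng.exponential(mean_branch), 1e-3))

    subtrees = [f"{n}:{bl():.5f}" for n in names]
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        merged = f"({subtrees[i]},{subtrees[j]}):{bl():.5f}"
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [merged]
    newick = "(" + ",".join(subtrees) + ");"
    return PhyloTree.from_newick(newick)


def fixture_model(rng: np.random.Generator, family: str = "standard", code: GeneticCode = UNIVERSAL_CODE):
    """A plausible parameter draw: GC-leaning frequencies, transition bias."""
    pi = rng.dirichlet(np.full(4, 10.0), size=3)
    freqs = cf3x4_correct(PositionalFrequencies(pi=pi), code)
    theta = NucExchangeabilities(
        theta=tuple(np.concatenate([[rng.uniform(0.3, 0.8)], [1.0],
                                    rng.uniform(0.3, 0.8, 2), [rng.uniform(0.8, 1.5)],
                                    [rng.uniform(0.3, 0.8)]]))
    )
    spec = make_spec(family, code=code)
    if family in ("synrev", "synrevcodon"):
        spec = spec.with_rates(alpha=rng.gamma(4.0, 0.25, spec.n_classes), beta=0.25)
    else:
        spec = spec.with_rates(beta=0.25, renormalize=False)
    return spec, theta, freqs


def make_gene_collection(
    n_genes: int = 4,
    n_taxa: int = 8,
    n_codons: int = 150,
    family: str = "standard",
    seed: int = 42,
    code: GeneticCode = UNIVERSAL_CODE,
    shared_tree: PhyloTree | None = None,
    mean_branch: float = 0.08,
):
    """Simulate a small collection of genes under one model (shared spec,
    theta, frequencies; one tree per gene unless ``shared_tree`` is given)."""
    rng = np.random.default_rng(seed)
    spec, theta, freqs = fixture_model(rng, family, code)
    genes = []
    for g in range(n_genes):
        tree = shared_tree if shared_tree is not None else random_tree(n_taxa, rng, mean_branch)
        cfg = ParametricSimConfig(
            spec=spec, theta=theta, freqs=freqs, tree=tree,
            n_sites=n_codons, seed=int(rng.integers(0, 2**31 - 1)), code=code,
        )
        genes.append((simulate_alignment(cfg), tree))
    return genes, (spec, theta, freqs)


def write_gene_collection(
    out_dir: str | Path,
    genes,
    list_name: str = "files.txt",
) -> Path:
    """Write gene files plus a file list; returns the list path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for g, (aln, tree) in enumerate(genes):
        p = out_dir / f"gene{g:03d}.fas"
        write_gene_file(p, aln, tree)
        paths.append(p.name)
    list_path = out_dir / list_name
    list_path.write_text("\n".join(paths) + "\n")
    return list_path
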