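"""Per-codon-pair covariates of selection on synonymous substitutions.

Two independent lines of evidence can corroborate (or contradict) inferred
synonymous substitution rates:

* polymorphism — per-pair synonymous SNP density in a population sample of
  haplotypes (pairs under purifying selection should segregate less), and
* translation — the ratio of cognate tRNA decoder-pool abundances for the
  two codons of a pair (pairs bridging very unequal tRNA pools should be
  selected against, hence evolve slowly).

The tRNA pooling implements wobble-modification rules: inosine-modified
anticodons additionally decode A- and C-ending synonymous codons, queuosine-
modified anticodons additionally decode the cognate U-ending codons, and six
residual codons without a measured decoder inherit the abundance of the
isoacceptor predicted to serve them by wobble pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from codonmss.alignments import MISSING, CodonAlignment
from codonmss.genetic_code import (
    GeneticCode,
    SynonymousPair,
    UNIVERSAL_CODE,
    enumerate_synonymous_pairs,
)

# Anticodons (RNA alphabet) whose wobble A is modified to inosine in
# eukaryotes; an inosine-carrying tRNA also decodes A- and C-ending codons.
INOSINE_ANTICODONS = ("AGC", "AGG", "ACG", "AGA", "AAG", "AAC", "AAT", "AGT")

# Amino acids whose wobble-G anticodons carry queuosine, expanding decoding
# to the U-ending codon of the pair.
QUEUOSINE_AMINO_ACIDS = ("H", "D", "N", "Y")

# Residual codons with no direct decoder measurement: each inherits the
# pooled abundance of the listed donor codon (wobble-rule prediction),
# written in DNA alphabet.
AMBIGUOUS_CODON_DONORS = {
    "TTT": "TTC",
    "AGT": "AGC",
    "TGT": "TGC",
    "CGG": "CGA",
    "GGG": "GGA",
    "GGT": "GGC",
}


def _rna_to_dna(s: str) -> str:
    return s.upper().replace("U", "T")


def anticodon_to_codon(anticodon: str) -> str:
    """The Watson–Crick cognate codon of an anticodon (both 5'->3')."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    ac = _rna_to_dna(anticodon)
    return "".join(comp[n] for n in reversed(ac))


def read_trna_table(path: str | Path) -> pd.DataFrame:
    """Tab-delimited (anticodon, amino_acid, count) raw transcript counts."""
    df = pd.read_csv(path, sep="\t")
    required = {"anticodon", "amino_acid", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"tRNA table must have columns {sorted(required)}")
    return df


def pool_trna_abundances(
    table: pd.DataFrame, code: GeneticCode = UNIVERSAL_CODE
) -> dict[str, float]:
    """Per-codon decoder-pool abundance from raw anticodon transcript counts.

    Counts are normalized to counts per million (CPM); each anticodon's CPM
    is credited to its cognate codon; inosine- and queuosine-eligible
    anticodons are additionally credited to the codons their modification
    lets them decode; finally the six residual codons inherit their donors'
    pools.  Returns a pool for each sense codon with a stated decoder.
    """
    counts = table["count"].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    cpm = counts / total * 1e6 if total > 0 else counts
    pools: dict[str, float] = {}
    inosine = {_rna_to_dna(a) for a in INOSINE_ANTICODONS}
    for (_, row), value in zip(table.iterrows(), cpm):
        anticodon = _rna_to_dna(str(row["anticodon"]))
        if len(anticodon) != 3 or any(n not in "ACGT" for n in anticodon):
            raise ValueError(f"unknown anticodon {row['anticodon']!r}")
        cognate = anticodon_to_codon(anticodon)
        if code.table.get(cognate, "*") == "*":
            raise ValueError(f"anticodon {row['anticodon']!r} decodes a stop codon")
        aa = code.table[cognate]
        targets = {cognate}
        if anticodon in inosine:
            # wobble A -> inosine: also decodes synonymous A- and C-ending codons
            for end in "AC":
                t = cognate[:2] + end
                if code.table.get(t) == aa:
                    targets.add(t)
        if anticodon[0] == "G" and aa in QUEUOSINE_AMINO_ACIDS:
            # wobble G -> queuosine: also decodes the synonymous T-ending codon
            t = cognate[:2] + "T"
            if code.table.get(t) == aa:
                targets.add(t)
        for t in targets:
            pools[t] = pools.get(t, 0.0) + float(value)
    for orphan, donor in AMBIGUOUS_CODON_DONORS.items():
        if donor in pools:
            pools[orphan] = pools[donor]
    return pools


def abundance_ratio(pair: SynonymousPair, pools: dict[str, float]) -> float | None:
    """Decoder-pool abundance ratio for a pair, more common / less common
    (always >= 1).  Returns None when either pool is absent or zero."""
    a = pools.get(pair.codon_a)
    b = pools.get(pair.codon_b)
    if a is None or b is None or min(a, b) <= 0:
        return None
    return max(a, b) / min(a, b)


def snp_density_per_pair(
    population_aln: CodonAlignment, code: GeneticCode = UNIVERSAL_CODE
) -> dict[str, float]:
    """Per-pair synonymous SNP density in one gene's haplotype sample.

    A codon column contributes one SNP count to pair (a, b) when exactly the
    codons a and b segregate there (a single-nucleotide synonymous
    difference); columns with more than two segregating codons or any
    nonsynonymous segregation contribute nothing.  The density divides the
    pair's count by the number of codons of the pair's amino acid in the
    sample's majority-consensus sequence.
    """
    pairs = enumerate_synonymous_pairs(code)
    pair_index = {frozenset((p.codon_a, p.codon_b)): p for p in pairs}
    sense = code.sense_codons
    counts = {p.name: 0 for p in pairs}
    aa_counts: dict[str, int] = {}
    for col in range(population_aln.n_sites):
        column = population_aln.codons[:, col]
        observed = set(int(v) for v in column if v != MISSING)
        if not observed:
            continue
        # consensus codon for the amino-acid denominator
        vals, freq = np.unique(column[column != MISSING], return_counts=True)
        consensus = sense[int(vals[np.argmax(freq)])]
        aa = code.table[consensus]
        aa_counts[aa] = aa_counts.get(aa, 0) + 1
        if len(observed) == 2:
            a, b = (sense[v] for v in sorted(observed))
            key = frozenset((a, b))
            if key in pair_index:
                counts[pair_index[key].name] += 1
    out: dict[str, float] = {}
    for p in pairs:
        denom = aa_counts.get(p.amino_acid, 0)
        out[p.name] = counts[p.name] / denom if denom else 0.0
    return out


def mean_snp_density(
    genes: list[CodonAlignment], code: GeneticCode = UNIVERSAL_CODE
) -> dict[str, float]:
    """Simple mean of per-gene SNP densities across genes."""
    if not genes:
        raise ValueError("no genes given")
    per_gene = [snp_density_per_pair(g, code) for g in genes]
    return {
        name: float(np.mean([d[name] for d in per_gene])) for name in per_gene[0]
    }


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class PairCovariateTable:
    """Tidy per-pair covariates: SNP density, tRNA abundance ratio, and an
    externally supplied substitution-rate estimate."""

    frame: pd.DataFrame

    @classmethod
    def assemble(
        cls,
        snp_density: dict[str, float] | None = None,
        pools: dict[str, float] | None = None,
        rates: dict[str, float] | None = None,
        code: GeneticCode = UNIVERSAL_CODE,
    ) -> "PairCovariateTable":
        pairs = enumerate_synonymous_pairs(code)
        rows = []
        for p in pairs:
            rows.append(
                {
                    "pair": p.name,
                    "amino_acid": p.amino_acid,
                    "snp_density": None if snp_density is None else snp_density.get(p.name),
                    "abundance_ratio": None if pools is None else abundance_ratio(p, pools),
                    "rate": None if rates is None else rates.get(p.name),
                }
            )
        return cls(frame=pd.DataFrame(rows))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)
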