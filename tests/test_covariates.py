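"""SNP densities, tRNA pooling and rank correlations."""

import numpy as np
import pandas as pd
import pytest

from codonmss.alignments import CodonAlignment
from codonmss.covariates import (
    PairCovariateTable,
    abundance_ratio,
    anticodon_to_codon,
    mean_snp_density,
    pool_trna_abundances,
    rank_correlation,
    snp_density_per_pair,
)
from codonmss.genetic_code import UNIVERSAL_CODE, enumerate_synonymous_pairs

PAIRS = {p.name: p for p in enumerate_synonymous_pairs(UNIVERSAL_CODE)}


# --- SNP density ---------------------------------------------------------


def _gene(rows: list[str]) -> CodonAlignment:
    return CodonAlignment.from_sequences([f"h{i}" for i in range(len(rows))], rows)


def test_snp_density_direct_division():
    """One AAA/AAG segregating column among ten lysine codons gives the
    AAA:AAG pair a density of 0.1."""
    base = "AAA" * 10
    variant = "AAG" + "AAA" * 9
    aln = _gene([base, variant, base, base])
    dens = snp_density_per_pair(aln)
    assert dens["AAA:AAG"] == pytest.approx(1 / 10)
    assert all(v == 0 for k, v in dens.items() if k != "AAA:AAG")


def test_monomorphic_gene_has_zero_densities():
    aln = _gene(["AAAGGGCAT" * 3] * 4)
    assert set(snp_density_per_pair(aln).values()) == {0.0}


def test_nonsynonymous_segregation_is_excluded():
    aln = _gene(["AAA", "GAA"])  # Lys/Glu: nonsynonymous
    dens = snp_density_per_pair(aln)
    assert set(dens.values()) == {0.0}


def test_multiallelic_column_is_excluded():
    aln = _gene(["GGA", "GGC", "GGG"])  # three glycine codons segregate
    dens = snp_density_per_pair(aln)
    assert set(dens.values()) == {0.0}


def test_mean_snp_density_averages_genes():
    g1 = _gene(["AAA" * 10, "AAG" + "AAA" * 9])
    g2 = _gene(["AAA" * 5, "AAA" * 5])
    mean = mean_snp_density([g1, g2])
    assert mean["AAA:AAG"] == pytest.approx((0.1 + 0.0) / 2)


# --- tRNA pooling --------------------------------------------------------


def test_anticodon_cognate():
    assert anticodon_to_codon("GAA") == "TTC"  # Phe
    assert anticodon_to_codon("AGC") == "GCT"  # Ala, inosine-eligible


def _table(rows):
    return pd.DataFrame(rows, columns=["anticodon", "amino_acid", "count"])


def test_cpm_normalization_and_inosine_expansion():
    table = _table([("AGC", "A", 75.0), ("GAA", "F", 25.0)])
    pools = pool_trna_abundances(table)
    # inosine-modified Ala anticodon serves GCT (cognate) plus GCA and GCC
    assert pools["GCT"] == pytest.approx(750_000.0)
    assert pools["GCA"] == pytest.approx(750_000.0)
    assert pools["GCC"] == pytest.approx(750_000.0)
    assert "GCG" not in pools
    assert pools["TTC"] == pytest.approx(250_000.0)


def test_queuosine_expansion():
    table = _table([("GTG", "H", 10.0)])  # His anticodon, wobble G
    pools = pool_trna_abundances(table)
    assert pools["CAC"] == pools["CAT"] == pytest.approx(1e6)


def test_wobble_donor_codons():
    table = _table(
        [("GAA", "F", 1.0), ("GCT", "S", 2.0), ("GCA", "C", 3.0),
         ("TCG", "R", 4.0), ("TCC", "G", 5.0), ("GCC", "G", 6.0)]
    )
    pools = pool_trna_abundances(table)
    assert pools["TTT"] == pools["TTC"]
    assert pools["AGT"] == pools["AGC"]
    assert pools["TGT"] == pools["TGC"]
    assert pools["CGG"] == pools["CGA"]
    assert pools["GGG"] == pools["GGA"]
    assert pools["GGT"] == pools["GGC"]


def test_zero_count_table_gives_zero_pools():
    table = _table([("GAA", "F", 0.0)])
    pools = pool_trna_abundances(table)
    assert pools["TTC"] == 0.0


def test_unknown_anticodon_rejected():
    with pytest.raises(ValueError):
        pool_trna_abundances(_table([("XXX", "?", 1.0)]))
    with pytest.raises(ValueError):
        pool_trna_abundances(_table([("TTA", "*", 1.0)]))  # decodes a stop


# --- abundance ratios ----------------------------------------------------


def test_abundance_ratio_rules():
    pair = PAIRS["TTC:TTT"]
    assert abundance_ratio(pair, {"TTC": 4.0, "TTT": 1.0}) == pytest.approx(4.0)
    assert abundance_ratio(pair, {"TTC": 1.0, "TTT": 4.0}) == pytest.approx(4.0)
    assert abundance_ratio(pair, {"TTC": 2.0, "TTT": 2.0}) == pytest.approx(1.0)
    assert abundance_ratio(pair, {"TTC": 2.0, "TTT": 0.0}) is None
    assert abundance_ratio(pair, {"TTC": 2.0}) is None


# --- rank correlation ----------------------------------------------------


def test_rank_correlation_limits_and_ties():
    x = np.arange(10.0)
    rho, _ = rank_correlation(x, x**3)
    assert rho == pytest.approx(1.0)
    rho, _ = rank_correlation(x, -x)
    assert rho == pytest.approx(-1.0)
    # hand-ranked n=5 with one tie: ranks x = (1,2,3,4,5), average ranks
    # y = (4,1,2.5,2.5,5); with ties rho is the Pearson correlation of ranks
    x5 = [1.0, 2.0, 3.0, 4.0, 5.0]
    y5 = [10.0, 1.0, 5.0, 5.0, 20.0]
    expected = np.corrcoef([1, 2, 3, 4, 5], [4.0, 1.0, 2.5, 2.5, 5.0])[0, 1]
    rho, _ = rank_correlation(x5, y5)
    assert rho == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        rank_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        rank_correlation([1.0], [2.0])


def test_snp_density_tracks_selection_in_forward_population():
    """In a Wright–Fisher population under synonymous selection, the mean
    SNP density of selected pairs is below that of neutral pairs."""
    from codonmss.genetic_code import ALL_CODONS
    from codonmss.simulate import (
        Population,
        default_selection_scheme,
        generate_ancestral_sequence,
        make_site_fitness,
        population_alignment,
        wf_generation,
    )

    rng = np.random.default_rng(19)
    scheme = default_selection_scheme(-5.0, 30)
    sense = UNIVERSAL_CODE.sense_codons
    anc_sense = generate_ancestral_sequence(np.full(61, 1 / 61), 80, rng)
    all_index = {c: i for i, c in enumerate(ALL_CODONS)}
    anc64 = np.array([all_index[sense[i]] for i in anc_sense], dtype=np.int16)
    pop = Population(
        codons=np.tile(anc64, (60, 1)),
        site_fitness=make_site_fitness(anc64, scheme),
    )
    for _ in range(3000):
        pop = wf_generation(pop, mu=3e-4, rng=rng)
    sample = population_alignment(pop, 24, rng)
    dens = snp_density_per_pair(sample)
    truth = scheme.truth_labels()
    neutral = [dens[k] for k, v in truth.items() if v == "NEUTRAL"]
    selected = [dens[k] for k, v in truth.items() if v == "SELECTED"]
    assert min(dens.values()) >= 0.0
    assert np.mean(neutral) > np.mean(selected)


def test_covariate_table_assembly(tmp_path):
    pools = {"TTC": 4.0, "TTT": 1.0}
    table = PairCovariateTable.assemble(
        snp_density={"TTC:TTT": 0.2}, pools=pools, rates={"TTC:TTT": 1.4}
    )
    row = table.frame.set_index("pair").loc["TTC:TTT"]
    assert row["abundance_ratio"] == pytest.approx(4.0)
    assert row["snp_density"] == pytest.approx(0.2)
    assert row["rate"] == pytest.approx(1.4)
    out = tmp_path / "cov.tsv"
    table.to_tsv(out)
    assert len(pd.read_csv(out, sep="\t")) == 67
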