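"""Genetic-code tables and enumeration of single-step synonymous codon pairs.

The combinatorial backbone of every multiclass synonymous substitution (MSS)
model is the set of unordered pairs of sense codons that (i) translate to the
same amino acid and (ii) differ at exactly one nucleotide position.  Under the
universal genetic code there are 67 such pairs, distributed over 18 amino
acids (methionine and tryptophan are excluded because each is encoded by a
single codon).  Every MSS parameterization assigns a relative synonymous rate
to each of these pairs, so a stable, deterministic ordering of the pairs is
established here (lexicographic by codon) and used everywhere else.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

NUCLEOTIDES = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
STOP = "*"

# 3-letter amino acid names for human-readable output.
AA_3LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
    STOP: "STOP",
}

# Universal (standard) genetic code, DNA alphabet, codon -> 1-letter symbol.
_UNIVERSAL_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP, "TAG": STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": STOP, "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

ALL_CODONS = tuple(sorted("".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)))


class CodonError(ValueError):
    """Raised for codons outside the ACGT alphabet or misuse of stop codons."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid translation table.

    Parameters
    ----------
    table
        Mapping of all 64 codons (DNA alphabet, upper case) to a one-letter
        amino-acid symbol or ``"*"`` for stop.
    name
        Identifier for the code.
    """

    table: dict[str, str] = field(hash=False)
    name: str = "universal"

    def __post_init__(self) -> None:
        if set(self.table) != set(ALL_CODONS):
            missing = set(ALL_CODONS) - set(self.table)
            extra = set(self.table) - set(ALL_CODONS)
            raise CodonError(
                f"genetic code must cover all 64 codons exactly "
                f"(missing={sorted(missing)[:3]}, extra={sorted(extra)[:3]})"
            )

    def __hash__(self) -> int:  # hashable so derived tables can be cached
        return hash((self.name, tuple(sorted(self.table.items()))))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticCode):
            return NotImplemented
        return self.table == other.table

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Sense codons in lexicographic order (61 for the universal code)."""
        return tuple(c for c in ALL_CODONS if self.table[c] != STOP)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.table[c] == STOP)

    def is_stop(self, codon: str) -> bool:
        return self.table[_check_codon(codon)] == STOP

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"name": self.name, "table": self.table}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneticCode":
        data = json.loads(Path(path).read_text())
        return cls(table=data["table"], name=data.get("name", "custom"))


UNIVERSAL_CODE = GeneticCode(table=dict(_UNIVERSAL_TABLE))


@dataclass(frozen=True, order=True)
class SynonymousPair:
    """An unordered pair of sense codons one nucleotide apart that translate
    to the same amino acid.

    ``codon_a < codon_b`` lexicographically, so each pair has a unique
    canonical representation.  ``position`` is the differing codon position
    (1-based) and ``nucleotides`` the unordered nucleotide pair exchanged.
    """

    codon_a: str
    codon_b: str
    amino_acid: str
    position: int
    nucleotides: tuple[str, str]

    @property
    def name(self) -> str:
        return f"{self.codon_a}:{self.codon_b}"


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or any(n not in NUC_INDEX for n in codon):
        raise CodonError(f"not a valid ACGT codon: {codon!r}")
    return codon


def translate(codon: str, code: GeneticCode = UNIVERSAL_CODE) -> str:
    """Translate a codon to its one-letter amino-acid symbol (``"*"`` = stop)."""
    return code.table[_check_codon(codon)]


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _make_pair(a: str, b: str, code: GeneticCode) -> SynonymousPair:
    a, b = min(a, b), max(a, b)
    (pos,) = [i for i in range(3) if a[i] != b[i]]
    return SynonymousPair(
        codon_a=a,
        codon_b=b,
        amino_acid=code.table[a],
        position=pos + 1,
        nucleotides=tuple(sorted((a[pos], b[pos]))),  # type: ignore[arg-type]
    )


@lru_cache(maxsize=None)
def enumerate_synonymous_pairs(code: GeneticCode = UNIVERSAL_CODE) -> tuple[SynonymousPair, ...]:
    """All single-step synonymous codon pairs, lexicographically ordered.

    For the universal code this returns the 67 pairs whose relative rates the
    codon-pair-level model (SynREVCodon) estimates.  The ordering fixes the
    meaning of index ``i`` in every model-vector encoding.
    """
    sense = code.sense_codons
    pairs = []
    for a, b in itertools.combinations(sense, 2):
        if code.table[a] == code.table[b] and hamming(a, b) == 1:
            pairs.append(_make_pair(a, b, code))
    return tuple(sorted(pairs, key=lambda p: (p.codon_a, p.codon_b)))


def amino_acid_pair_groups(code: GeneticCode = UNIVERSAL_CODE) -> dict[str, list[SynonymousPair]]:
    """Group single-step synonymous pairs by amino acid.

    Keys are exactly the amino acids with at least one exchangeable pair
    (18 for the universal code); the amino-acid-level model (SynREV) assigns
    one rate per key.
    """
    groups: dict[str, list[SynonymousPair]] = {}
    for pair in enumerate_synonymous_pairs(code):
        groups.setdefault(pair.amino_acid, []).append(pair)
    return groups


def one_step_neighbors(
    codon: str,
    code: GeneticCode = UNIVERSAL_CODE,
    include_stops: bool = False,
) -> list[tuple[str, bool]]:
    """The 9 single-nucleotide neighbors of a sense codon.

    Returns ``(neighbor, synonymous)`` tuples; neighbors that are stop codons
    are excluded unless ``include_stops`` is set (they are never synonymous).
    """
    codon = _check_codon(codon)
    if code.is_stop(codon):
        raise CodonError(f"{codon} is a stop codon under code {code.name!r}")
    aa = code.table[codon]
    out = []
    for pos in range(3):
        for n in NUCLEOTIDES:
            if n == codon[pos]:
                continue
            nb = codon[:pos] + n + codon[pos + 1:]
            if code.is_stop(nb):
                if include_stops:
                    out.append((nb, False))
                continue
            out.append((nb, code.table[nb] == aa))
    return out


def restricted_code(amino_acids: set[str] | frozenset[str], name: str | None = None) -> GeneticCode:
    """A code keeping only the given amino acids' codons as sense codons.

    All other codons are remapped to stop.  Useful for small, fully
    enumerable model-selection instances (e.g. a code whose pair universe has
    D <= 6 so exhaustive partition search is feasible).
    """
    table = {
        c: (aa if aa in amino_acids else STOP) for c, aa in _UNIVERSAL_TABLE.items()
    }
    if not any(v != STOP for v in table.values()):
        raise CodonError("restricted code has no sense codons")
    return GeneticCode(table=table, name=name or ("restricted:" + "".join(sorted(amino_acids))))
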