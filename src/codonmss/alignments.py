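"""Codon-aware alignments: validation, codon indexing, FASTA/NEXUS IO."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import AlignIO, SeqIO

from codonmss.genetic_code import GeneticCode, UNIVERSAL_CODE, NUC_INDEX

MISSING = -1


@dataclass
class CodonAlignment:
    """An in-frame alignment stored as sense-codon indices.

    ``codons`` is a (taxa x sites) integer matrix indexing into
    ``code.sense_codons``; cells containing gaps or ambiguous nucleotides are
    ``MISSING`` (-1) and are marginalized over in likelihood computations.
    Stop codons in non-missing cells are rejected.
    """

    names: list[str]
    codons: np.ndarray
    code: GeneticCode = UNIVERSAL_CODE

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if self.codons.ndim != 2:
            raise ValueError("codon matrix must be 2-D (taxa x sites)")
        if len(self.names) != self.codons.shape[0]:
            raise ValueError("one name per sequence required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        if len(self.names) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        n_sense = len(self.code.sense_codons)
        if self.codons.size and (self.codons.max() >= n_sense or self.codons.min() < MISSING):
            raise ValueError("codon index out of range")

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    @property
    def n_sites(self) -> int:
        """Number of codon columns."""
        return self.codons.shape[1]

    def iter_codons(self) -> Iterator[str]:
        """All non-missing codon strings, row by row."""
        sense = self.code.sense_codons
        for value in self.codons.ravel():
            if value != MISSING:
                yield sense[value]

    # --- construction ---------------------------------------------------
    @classmethod
    def from_sequences(
        cls, names: list[str], seqs: list[str], code: GeneticCode = UNIVERSAL_CODE
    ) -> "CodonAlignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"nucleotide length {length} is not a multiple of 3")
        sense_index = {c: i for i, c in enumerate(code.sense_codons)}
        mat = np.full((len(seqs), length // 3), MISSING, dtype=np.int16)
        for r, seq in enumerate(seqs):
            seq = seq.upper().replace("U", "T")
            for s in range(0, length, 3):
                codon = seq[s : s + 3]
                if codon in sense_index:
                    mat[r, s // 3] = sense_index[codon]
                elif all(n in NUC_INDEX for n in codon):
                    if code.table[codon] == "*":
                        raise ValueError(
                            f"stop codon {codon} at nucleotide {s} in sequence {names[r]!r}"
                        )
                # anything with gaps/ambiguity stays MISSING
        return cls(names=list(names), codons=mat, code=code)

    @classmethod
    def from_codon_indices(
        cls, names: list[str], codons: np.ndarray, code: GeneticCode = UNIVERSAL_CODE
    ) -> "CodonAlignment":
        return cls(names=list(names), codons=codons, code=code)

    @classmethod
    def read(cls, path: str | Path, code: GeneticCode = UNIVERSAL_CODE) -> "CodonAlignment":
        """Read FASTA or NEXUS (by extension, falling back to FASTA)."""
        path = Path(path)
        fmt = "nexus" if path.suffix.lower() in (".nex", ".nexus") else "fasta"
        if fmt == "nexus":
            aln = AlignIO.read(str(path), "nexus")
            records = list(aln)
        else:
            records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls.from_sequences(
            [r.id for r in records], [str(r.seq) for r in records], code=code
        )

    # --- output ---------------------------------------------------------
    def sequence_string(self, row: int) -> str:
        sense = self.code.sense_codons
        return "".join(
            sense[v] if v != MISSING else "---" for v in self.codons[row]
        )

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r, name in enumerate(self.names):
                fh.write(f">{name}\n{self.sequence_string(r)}\n")

    def pattern_compress(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns and their multiplicities (columns, weights)."""
        patterns, counts = np.unique(self.codons, axis=1, return_counts=True)
        return patterns, counts.astype(float)
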