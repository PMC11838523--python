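"""Gene-file IO: alignment+tree bundles and newline-separated file lists.

A "gene file" is a FASTA codon alignment followed by a Newick tree on its own
line (the format consumed by the published multi-gene fitters); multi-gene
inputs are newline-separated lists of such files.
"""

from __future__ import annotations

from pathlib import Path

from codonmss.alignments import CodonAlignment
from codonmss.genetic_code import GeneticCode, UNIVERSAL_CODE
from codonmss.trees import PhyloTree


def read_gene_file(
    path: str | Path, code: GeneticCode = UNIVERSAL_CODE
) -> tuple[CodonAlignment, PhyloTree]:
    """Read one FASTA-plus-Newick gene file."""
    path = Path(path)
    names: list[str] = []
    seqs: list[str] = []
    tree_text = None
    current: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if names:
                seqs.append("".join(current))
            names.append(line[1:].split()[0])
            current = []
        elif line.startswith("(") or line.endswith(";"):
            tree_text = line
        else:
            current.append(line)
    if names:
        seqs.append("".join(current))
    if not names:
        raise ValueError(f"no sequences found in {path}")
    if tree_text is None:
        raise ValueError(f"no Newick tree found in {path}")
    aln = CodonAlignment.from_sequences(names, seqs, code=code)
    tree = PhyloTree.from_newick(tree_text)
    return aln, tree


def write_gene_file(
    path: str | Path, aln: CodonAlignment, tree: PhyloTree
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for r, name in enumerate(aln.names):
            fh.write(f">{name}\n{aln.sequence_string(r)}\n")
        fh.write(tree.to_newick() + "\n")


def read_file_list(
    path: str | Path, code: GeneticCode = UNIVERSAL_CODE, deduplicate: bool = True
) -> list[tuple[CodonAlignment, PhyloTree]]:
    """Read every gene file named in a newline-separated list (paths are
    resolved relative to the list's directory); duplicates are dropped."""
    path = Path(path)
    base = path.parent
    entries = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if deduplicate:
        seen: set[str] = set()
        unique = []
        for e in entries:
            if e not in seen:
                seen.add(e)
                unique.append(e)
        entries = unique
    genes = []
    for entry in entries:
        p = Path(entry)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"gene file {p} (from list {path}) does not exist")
        genes.append(read_gene_file(p, code=code))
    return genes
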