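"""File formats: FASTA alignments, partition tables, group definitions,
presence matrices, and newick trees.

Partition files use the RAxML/IQ-TREE convention ``MODEL, name = start-end``
with 1-based inclusive coordinates; internal coordinates are 0-based
half-open.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import Alignment, GenePartitionSet, Supermatrix
from .trees import PhyloTree

__all__ = [
    "read_fasta", "write_fasta",
    "read_partitions", "write_partitions",
    "read_groups", "write_groups",
    "read_tree", "write_tree",
    "read_supermatrix", "write_supermatrix",
]


def read_fasta(path) -> Alignment:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return Alignment.from_strings(seqs)


def write_fasta(aln: Alignment, path) -> None:
    records = [SeqRecord(Seq(s), id=lab, description="")
               for lab, s in aln.to_strings().items()]
    SeqIO.write(records, str(path), "fasta")


_PART_RE = re.compile(r"^\s*(?P<model>[\w+.-]+)\s*,\s*(?P<name>\S+)\s*=\s*"
                      r"(?P<start>\d+)\s*-\s*(?P<end>\d+)\s*$")


def write_partitions(parts: GenePartitionSet, path, model: str = "POISSON") -> None:
    with open(path, "w") as fh:
        for p in parts:
            fh.write(f"{model}, {p.name} = {p.start + 1}-{p.end}\n")


def read_partitions(path) -> GenePartitionSet:
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        m = _PART_RE.match(line)
        if not m:
            raise ValueError(f"unparseable partition line: {line!r}")
        entries.append((m["name"], int(m["start"]) - 1, int(m["end"])))
    return GenePartitionSet(entries)


def read_groups(path) -> dict[str, list[str]]:
    """TSV with columns group, taxon (one membership per row)."""
    df = pd.read_csv(path, sep="\t")
    if not {"group", "taxon"} <= set(df.columns):
        raise ValueError("group file needs 'group' and 'taxon' columns")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["group"]), []).append(str(row["taxon"]))
    return out


def write_groups(groups: dict[str, list[str]], path) -> None:
    rows = [{"group": g, "taxon": t} for g, members in groups.items() for t in members]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tree(path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def write_tree(tree: PhyloTree, path, decimals: int | None = None) -> None:
    Path(path).write_text(tree.to_newick(decimals=decimals) + "\n")


def write_supermatrix(sm: Supermatrix, fasta_path, partition_path,
                      model: str = "POISSON") -> None:
    write_fasta(sm.alignment, fasta_path)
    write_partitions(sm.partitions, partition_path, model=model)


def read_supermatrix(fasta_path, partition_path) -> Supermatrix:
    return Supermatrix(read_fasta(fasta_path), read_partitions(partition_path))
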