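"""Amino-acid alignments, gene partitions, and supermatrices.

Residues are stored as small integer codes in PAML order
(``ARNDCQEGHILKMFPSTWYV``); code 20 is the single MISSING state, to which
gaps (``-``), ``?``, ``X`` and all non-canonical letters are mapped.  A
supermatrix is an alignment plus a set of contiguous, non-overlapping gene
partitions covering its full width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20
MISSING = 20

_CODE = np.full(128, MISSING, dtype=np.uint8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _CODE[ord(_aa)] = _i
    _CODE[ord(_aa.lower())] = _i

_CHAR = np.array(list(AMINO_ACIDS + "-"))


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string to integer codes (unknowns -> MISSING)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[np.minimum(raw, 127)]


def decode(codes: np.ndarray) -> str:
    return "".join(_CHAR[codes])


class Alignment:
    """Rectangular amino-acid alignment over 20 residues plus MISSING.

    Parameters
    ----------
    labels : sequence of str
        Unique taxon labels, one per row.
    data : ndarray of uint8, shape (n_taxa, n_sites)
        Residue codes; ``MISSING`` (20) marks gaps/ambiguity/absence.
    """

    def __init__(self, labels: Sequence[str], data: np.ndarray):
        labels = list(labels)
        data = np.asarray(data, dtype=np.uint8)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (taxa x sites)")
        if len(labels) != data.shape[0]:
            raise ValueError("label count does not match row count")
        if len(set(labels)) != len(labels):
            raise ValueError("taxon labels must be unique")
        if data.size and data.max() > MISSING:
            raise ValueError("residue codes must be in 0..20")
        self.labels = labels
        self.data = data
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- constructors -------------------------------------------------
    @classmethod
    def from_strings(cls, seqs: Mapping[str, str]) -> "Alignment":
        labels = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        n = lengths.pop() if lengths else 0
        data = np.empty((len(labels), n), dtype=np.uint8)
        for i, lab in enumerate(labels):
            data[i] = encode(seqs[lab])
        return cls(labels, data)

    # -- basic properties ---------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.data[self._index[label]]

    def has_taxon(self, label: str) -> bool:
        return label in self._index

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_taxa, n_sites) mask of MISSING cells."""
        return self.data == MISSING

    def to_strings(self) -> dict[str, str]:
        return {lab: decode(self.data[i]) for i, lab in enumerate(self.labels)}

    # -- manipulation --------------------------------------------------
    def subset_taxa(self, labels: Iterable[str]) -> "Alignment":
        labels = list(labels)
        idx = [self._index[lab] for lab in labels]
        return Alignment(labels, self.data[idx].copy())

    def drop_taxa(self, labels: Iterable[str]) -> "Alignment":
        drop = set(labels)
        unknown = drop - set(self.labels)
        if unknown:
            raise KeyError(f"unknown taxa: {sorted(unknown)}")
        keep = [lab for lab in self.labels if lab not in drop]
        return self.subset_taxa(keep)

    def select_columns(self, cols: np.ndarray) -> "Alignment":
        return Alignment(list(self.labels), self.data[:, cols].copy())

    def remove_gap_only_columns(self) -> "Alignment":
        keep = ~(self.data == MISSING).all(axis=0)
        return self.select_columns(np.flatnonzero(keep))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.labels == other.labels
            and self.data.shape == other.data.shape
            and bool((self.data == other.data).all())
        )

    def __repr__(self) -> str:
        return f"Alignment({self.n_taxa} taxa x {self.n_sites} sites)"


@dataclass(frozen=True)
class Partition:
    name: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


class GenePartitionSet:
    """Contiguous, non-overlapping gene partitions covering a supermatrix.

    Internal coordinates are 0-based half-open; partition files on disk use
    the field's 1-based inclusive convention.
    """

    def __init__(self, entries: Sequence[tuple[str, int, int]] | Sequence[Partition]):
        parts = [e if isinstance(e, Partition) else Partition(*e) for e in entries]
        names = [p.name for p in parts]
        if len(set(names)) != len(names):
            raise ValueError("duplicate partition names")
        pos = 0
        for p in parts:
            if p.start != pos:
                raise ValueError(
                    f"partition {p.name!r} starts at {p.start}, expected {pos} "
                    "(partitions must be contiguous)"
                )
            if p.end <= p.start:
                raise ValueError(f"partition {p.name!r} is empty or reversed")
            pos = p.end
        self.entries = parts

    @classmethod
    def from_lengths(cls, names_lengths: Sequence[tuple[str, int]]) -> "GenePartitionSet":
        entries, pos = [], 0
        for name, length in names_lengths:
            entries.append(Partition(name, pos, pos + length))
            pos += length
        return cls(entries)

    @property
    def total_sites(self) -> int:
        return self.entries[-1].end if self.entries else 0

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, key) -> Partition:
        if isinstance(key, str):
            for p in self.entries:
                if p.name == key:
                    return p
            raise KeyError(key)
        return self.entries[key]


@dataclass
class Supermatrix:
    """A concatenated alignment with its gene partition table."""

    alignment: Alignment
    partitions: GenePartitionSet

    def __post_init__(self):
        if self.partitions.total_sites != self.alignment.n_sites:
            raise ValueError("partitions do not cover the alignment width")

    @property
    def labels(self) -> list[str]:
        return self.alignment.labels

    def gene(self, name: str) -> Alignment:
        p = self.partitions[name]
        return self.alignment.select_columns(np.arange(p.start, p.end))

    def genes(self) -> list[tuple[str, Alignment]]:
        return [(p.name, self.gene(p.name)) for p in self.partitions]

    def gene_presence(self) -> np.ndarray:
        """Boolean (n_taxa, n_genes): taxon has >=1 non-MISSING cell in gene."""
        miss = self.alignment.missing_mask()
        out = np.empty((self.alignment.n_taxa, len(self.partitions)), dtype=bool)
        for j, p in enumerate(self.partitions):
            out[:, j] = ~miss[:, p.start:p.end].all(axis=1)
        return out
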