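"""Supermatrix curation: assembly ranking, coverage filters, outlier
removal, ambiguous-site masking, concatenation, dataset tiers, and
completeness diagnostics.

Coverage semantics follow the source protocol exactly: species are dropped
when *less than* 60% of the ortholog set was recovered (a species at
exactly the threshold is retained), genes are kept when *at least* 50% of
species have a hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .alignment import (AMINO_ACIDS, MISSING, Alignment, GenePartitionSet,
                        Supermatrix)

__all__ = [
    "AssemblyScore",
    "GroupDefinitions",
    "DatasetTier",
    "CoverageReport",
    "read_assembly_scores",
    "rank_assemblies",
    "filter_species_by_coverage",
    "filter_genes_by_coverage",
    "detect_outlier_sequences",
    "mask_ambiguous_sites",
    "drop_taxa",
    "concatenate",
    "compile_dataset",
    "completeness",
]

_BLOSUM = substitution_matrices.load("BLOSUM62")
_B62 = np.zeros((21, 21))
for _i, _a in enumerate(AMINO_ACIDS):
    for _j, _b in enumerate(AMINO_ACIDS):
        _B62[_i, _j] = _BLOSUM[_a, _b]


@dataclass(frozen=True)
class AssemblyScore:
    species: str
    assembly_id: str
    genes_assigned: int
    cumulative_length: int

    def __post_init__(self):
        if self.genes_assigned < 0 or self.cumulative_length < 0:
            raise ValueError("counts and lengths must be nonnegative")


class DatasetTier(str, Enum):
    UNREDUCED = "unreduced"
    INTERMEDIATE = "intermediate"
    STRICT = "strict"


class GroupDefinitions:
    """Named taxon sets used for the intermediate tier and FcLM groups."""

    def __init__(self, groups: Mapping[str, Sequence[str]]):
        self.groups = {name: list(taxa) for name, taxa in groups.items()}
        for name, taxa in self.groups.items():
            if not taxa:
                raise ValueError(f"group {name!r} is empty")

    def validate_against(self, taxa: Iterable[str]) -> None:
        known = set(taxa)
        for name, members in self.groups.items():
            unknown = set(members) - known
            if unknown:
                raise KeyError(f"group {name!r} has unknown taxa: {sorted(unknown)}")

    def items(self):
        return self.groups.items()

    def __len__(self):
        return len(self.groups)


def read_assembly_scores(path) -> list[AssemblyScore]:
    """TSV with columns species, assembly_id, genes_assigned, cumulative_length."""
    df = pd.read_csv(path, sep="\t")
    need = {"species", "assembly_id", "genes_assigned", "cumulative_length"}
    if not need <= set(df.columns):
        raise ValueError(f"assembly score table needs columns {sorted(need)}")
    return [AssemblyScore(str(r.species), str(r.assembly_id),
                          int(r.genes_assigned), int(r.cumulative_length))
            for r in df.itertuples()]


def rank_assemblies(scores: Sequence[AssemblyScore]) -> dict[str, str]:
    """Best assembly per species by cumulative assigned length.

    Ties broken by genes_assigned, then lexicographically smallest id.
    """
    if not scores:
        raise ValueError("no assembly scores given")
    best: dict[str, AssemblyScore] = {}
    for s in sorted(scores, key=lambda s: (s.species, -s.cumulative_length,
                                           -s.genes_assigned, s.assembly_id)):
        best.setdefault(s.species, s)
    return {sp: s.assembly_id for sp, s in best.items()}


def filter_species_by_coverage(
    table: pd.DataFrame, ortholog_set_size: int, threshold: float = 0.60
) -> tuple[list[str], dict[str, float]]:
    """Drop species recovering < threshold of the ortholog set.

    ``table`` is a boolean genes x species presence frame.  Returns
    (retained species, coverage of the excluded ones).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    coverage = table.sum(axis=0) / float(ortholog_set_size)
    excluded = {sp: float(c) for sp, c in coverage.items() if c < threshold}
    retained = [sp for sp in table.columns if sp not in excluded]
    return retained, excluded


def filter_genes_by_coverage(table: pd.DataFrame, threshold: float = 0.50) -> list[str]:
    """Keep genes with presence in >= threshold of the species (columns)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    frac = table.sum(axis=1) / table.shape[1]
    return [g for g, f in frac.items() if f >= threshold]


def _consensus(data: np.ndarray) -> np.ndarray:
    """Majority non-MISSING residue per column (ties -> lowest code)."""
    n_sites = data.shape[1]
    cons = np.zeros(n_sites, dtype=np.uint8)
    for j in range(n_sites):
        col = data[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            cons[j] = MISSING
        else:
            cons[j] = np.bincount(col, minlength=20).argmax()
    return cons


def detect_outlier_sequences(
    aln: Alignment, cutoff: float = 3.5, min_sequences: int = 4
) -> list[str]:
    """Flag sequences whose BLOSUM62 similarity to the column consensus is
    an extreme low outlier (robust z below -cutoff via median/MAD)."""
    if aln.n_taxa < min_sequences:
        warnings.warn("too few sequences for outlier detection; no flags")
        return []
    cons = _consensus(aln.data)
    scores = np.full(aln.n_taxa, np.nan)
    for i in range(aln.n_taxa):
        row = aln.data[i]
        ok = (row != MISSING) & (cons != MISSING)
        if ok.any():
            scores[i] = _B62[row[ok], cons[ok]].mean()
    med = np.nanmedian(scores)
    mad = np.nanmedian(np.abs(scores - med))
    if not np.isfinite(mad) or mad == 0:
        return []
    z = (scores - med) / (1.4826 * mad)
    return [aln.labels[i] for i in np.flatnonzero(z < -cutoff)]


def mask_ambiguous_sites(
    aln: Alignment,
    window: int = 6,
    reps: int = 100,
    seed=0,
    quantile: float = 1.0,
) -> np.ndarray:
    """Monte-Carlo sliding-window masking of randomly similar sites.

    For every sequence pair, BLOSUM62 window scores over shared (both
    non-MISSING) columns are compared against scores of ``reps`` residue
    shuffles of the same pair; a column survives if *some* window covering
    it, in *some* pair, exceeds the null quantile (default: the null
    maximum).  Columns never beating the null, and gap-only columns, are
    masked.  Returns the sorted masked column indices.
    """
    if window < 1 or reps < 1:
        raise ValueError("window and reps must be >= 1")
    rng = np.random.default_rng(seed)
    n, L = aln.n_taxa, aln.n_sites
    supported = np.zeros(L, dtype=bool)
    kernel = np.ones(window)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = aln.data[i], aln.data[j]
            shared = np.flatnonzero((x != MISSING) & (y != MISSING))
            if shared.size < window:
                continue
            xs, ys = x[shared], y[shared]
            obs = np.convolve(_B62[xs, ys], kernel, mode="valid")
            null_scores = np.empty((reps, obs.size))
            for r in range(reps):
                xp = rng.permutation(xs)
                yp = rng.permutation(ys)
                null_scores[r] = np.convolve(_B62[xp, yp], kernel, mode="valid")
            thresh = np.quantile(null_scores, quantile)
            good = obs > thresh
            # a shared column is supported if any covering window is good
            col_good = np.convolve(good.astype(float), kernel, mode="full")[:shared.size] > 0
            supported[shared[col_good]] = True
    gap_only = (aln.data == MISSING).all(axis=0)
    masked = (~supported) | gap_only
    return np.flatnonzero(masked)


def drop_taxa(
    genes: list[tuple[str, Alignment]], taxa: Iterable[str]
) -> list[tuple[str, Alignment]]:
    """Remove taxa from every gene; gap-only columns are removed too."""
    taxa = set(taxa)
    all_taxa = {lab for _, aln in genes for lab in aln.labels}
    unknown = taxa - all_taxa
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    out = []
    for g, aln in genes:
        reduced = aln.drop_taxa(taxa & set(aln.labels))
        out.append((g, reduced.remove_gap_only_columns()))
    return out


def concatenate(
    genes: list[tuple[str, Alignment]],
    all_taxa: Sequence[str] | None = None,
) -> Supermatrix:
    """Concatenate genes into a supermatrix; absent species become MISSING."""
    names = [g for g, _ in genes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene names")
    if all_taxa is None:
        all_taxa = sorted({lab for _, aln in genes for lab in aln.labels})
    else:
        all_taxa = list(all_taxa)
    width = sum(aln.n_sites for _, aln in genes)
    data = np.full((len(all_taxa), width), MISSING, dtype=np.uint8)
    index = {lab: i for i, lab in enumerate(all_taxa)}
    pos = 0
    for _, aln in genes:
        for lab in aln.labels:
            if lab in index:
                data[index[lab], pos:pos + aln.n_sites] = aln.row(lab)
        pos += aln.n_sites
    parts = GenePartitionSet.from_lengths([(g, aln.n_sites) for g, aln in genes])
    return Supermatrix(Alignment(all_taxa, data), parts)


def compile_dataset(
    sm: Supermatrix,
    tier: DatasetTier | str,
    groups: GroupDefinitions | None = None,
) -> Supermatrix:
    """Reduce a supermatrix to a coverage tier.

    unreduced: all genes; intermediate: genes with >= 1 present member of
    every defined group; strict: genes present in every species.
    """
    tier = DatasetTier(tier)
    presence = sm.gene_presence()
    labels = sm.labels
    if tier is DatasetTier.UNREDUCED:
        keep = list(sm.partitions.names)
    elif tier is DatasetTier.STRICT:
        keep = [p.name for j, p in enumerate(sm.partitions) if presence[:, j].all()]
    else:
        if groups is None:
            raise ValueError("intermediate tier requires group definitions")
        groups.validate_against(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        keep, first_fail = [], {}
        for j, p in enumerate(sm.partitions):
            ok = True
            for gname, members in groups.items():
                if not presence[[idx[m] for m in members], j].any():
                    ok = False
                    first_fail.setdefault(p.name, gname)
                    break
            if ok:
                keep.append(p.name)
        if not keep:
            detail = "; ".join(f"{g}: no member of {grp}" for g, grp in
                               list(first_fail.items())[:5])
            raise ValueError(f"intermediate tier empty ({detail})")
    if not keep:
        raise ValueError(f"{tier.value} tier is empty")
    return concatenate([(g, sm.gene(g)) for g in keep], all_taxa=labels)


@dataclass
class CoverageReport:
    overall_completeness: float                 # Ca: share of non-MISSING cells
    per_species: pd.Series                      # fraction of genes recovered
    per_gene: pd.Series                         # fraction of species present
    pairwise_shared: pd.DataFrame               # column overlap fractions

    def __post_init__(self):
        assert np.allclose(self.pairwise_shared, self.pairwise_shared.T)


def completeness(sm: Supermatrix) -> CoverageReport:
    present = ~sm.alignment.missing_mask()
    ca = float(present.mean())
    gp = sm.gene_presence()
    per_species = pd.Series(gp.mean(axis=1), index=sm.labels)
    per_gene = pd.Series(gp.mean(axis=0), index=sm.partitions.names)
    shared = (present.astype(float) @ present.T.astype(float)) / sm.alignment.n_sites
    pairwise = pd.DataFrame(shared, index=sm.labels, columns=sm.labels)
    return CoverageReport(ca, per_species, per_gene, pairwise)
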