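"""Four-cluster Likelihood Mapping (FcLM) with signal-destroying
permutations.

Quartets are drawn one taxon per group (group 4 = outgroup), each quartet's
three topology log-likelihoods are maximized, and the normalized likelihood
weights place the quartet in one of seven simplex regions (three corners =
resolved splits, three edges, one center).  Besides the 7-region counts the
summary reports the 3-region ("basin") percentages in which every informative
quartet is assigned to its maximum-weight corner.

Three permutation schemes destroy phylogenetic signal in controlled ways:

I   : per taxon row, per partition, permute the non-MISSING residues —
      missingness and per-taxon-per-gene composition are preserved exactly;
II  : per partition, shuffle all non-MISSING residues across all cells —
      missingness preserved, composition homogenized (no SRH violation
      possible);
III : scheme II plus re-assignment of which (taxon, gene) blocks are
      missing, preserving only the per-partition count of missing taxa.

Support that survives in the permuted data cannot be phylogenetic;
``net_support`` subtracts it corner by corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import MISSING, Alignment, Supermatrix
from .likelihood import optimize_quartet
from .models import SubstModel

__all__ = [
    "FourGroups",
    "QuartetEval",
    "FcLMSummary",
    "PermutationScheme",
    "REGIONS",
    "draw_quartets",
    "eval_quartet",
    "assign_region",
    "likelihood_weights",
    "permute",
    "summarize",
    "net_support",
    "run_fclm",
]

REGIONS = ("corner1", "corner2", "corner3", "edge12", "edge13", "edge23",
           "center", "uninformative")

# topology order: T1 = (g1,g2|g3,g4), T2 = (g1,g3|g2,g4), T3 = (g1,g4|g2,g3)
_SPLITS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


class PermutationScheme(str, Enum):
    I = "I"
    II = "II"
    III = "III"


@dataclass
class FourGroups:
    """Four disjoint, nonempty taxon groups; group 4 is the outgroup."""

    groups: tuple[list[str], list[str], list[str], list[str]]

    def __post_init__(self):
        if len(self.groups) != 4 or any(not g for g in self.groups):
            raise ValueError("need four nonempty groups")
        flat = [t for g in self.groups for t in g]
        if len(set(flat)) != len(flat):
            raise ValueError("groups must be disjoint")

    @classmethod
    def from_dict(cls, d) -> "FourGroups":
        keys = sorted(d)
        if len(keys) != 4:
            raise ValueError("need exactly four groups")
        return cls(tuple(list(d[k]) for k in keys))

    def validate_against(self, labels: Sequence[str]) -> None:
        known = set(labels)
        missing = [t for g in self.groups for t in g if t not in known]
        if missing:
            raise KeyError(f"group taxa absent from supermatrix: {missing}")

    @property
    def n_quartets(self) -> int:
        return int(np.prod([len(g) for g in self.groups]))


@dataclass
class QuartetEval:
    taxa: tuple[str, str, str, str]
    log_likelihoods: np.ndarray | None   # (3,) per topology, None if uninformative
    weights: np.ndarray | None
    region: str
    n_sites: int


@dataclass
class FcLMSummary:
    counts: dict[str, int]
    total: int

    @property
    def percentages(self) -> dict[str, float]:
        return {r: 100.0 * c / self.total for r, c in self.counts.items()}

    def corner_percentages(self, among: str = "basin") -> np.ndarray:
        """Three corner percentages.

        among='basin': every informative quartet assigned to its
        maximum-weight corner (percent of informative quartets);
        among='corners': 7-region corner counts renormalized among corners;
        among='total': 7-region corner counts as percent of all draws.
        """
        c = np.array([self.counts[f"corner{k}"] for k in (1, 2, 3)], dtype=float)
        if among == "total":
            return 100.0 * c / self.total
        if among == "corners":
            return 100.0 * c / c.sum() if c.sum() else np.full(3, np.nan)
        b = np.asarray(self.basin_counts, dtype=float)
        return 100.0 * b / b.sum() if b.sum() else np.full(3, np.nan)

    basin_counts: tuple[int, int, int] = (0, 0, 0)


def draw_quartets(groups: FourGroups, cap: int = 1000, seed=0) -> list[tuple[str, str, str, str]]:
    """One taxon per group: exhaustive if the product is <= cap, else a
    uniform subsample of distinct combinations (seeded)."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    sizes = [len(g) for g in groups.groups]
    total = int(np.prod(sizes))
    if total <= cap:
        idx = np.arange(total)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(total, size=cap, replace=False)
    out = []
    for k in idx:
        sel = []
        rem = int(k)
        for size in reversed(sizes):
            sel.append(rem % size)
            rem //= size
        sel.reverse()
        out.append(tuple(groups.groups[g][i] for g, i in enumerate(sel)))
    return out


def likelihood_weights(lnls: np.ndarray) -> np.ndarray:
    """Normalized exponentiated lnL differences (softmax)."""
    lnls = np.asarray(lnls, dtype=float)
    w = np.exp(lnls - lnls.max())
    return w / w.sum()


def assign_region(w: np.ndarray, corner_cut: float = 2.0 / 3.0,
                  edge_cut: float = 1.0 / 6.0) -> str:
    """Seven-region simplex partition: corner if a weight >= 2/3, else edge
    of the top two if the minimum weight < 1/6, else center."""
    w = np.asarray(w, dtype=float)
    k = int(w.argmax())
    if w[k] >= corner_cut:
        return f"corner{k + 1}"
    if w.min() < edge_cut:
        top = sorted(np.argsort(w)[-2:] + 1)
        return f"edge{top[0]}{top[1]}"
    return "center"


def eval_quartet(
    sm: Supermatrix | Alignment,
    draw: tuple[str, str, str, str],
    model: SubstModel,
    min_sites: int = 50,
    tol: float = 1e-4,
    max_sweeps: int = 30,
    xatol: float = 1e-3,
    dtype=np.float32,
) -> QuartetEval:
    """Optimize all three topologies for one quartet and map it.

    Single precision is the default here: per-quartet lnL differences are
    O(0.1) or larger where they matter, far above float32 rounding at this
    problem size."""
    aln = sm.alignment if isinstance(sm, Supermatrix) else sm
    sub = aln.subset_taxa(draw)
    n_usable = int((~(sub.data == MISSING).any(axis=0)).sum())
    if n_usable < min_sites:
        return QuartetEval(tuple(draw), None, None, "uninformative", n_usable)
    lnls = np.empty(3)
    for t, (p1, p2) in enumerate(_SPLITS):
        split = ((draw[p1[0]], draw[p1[1]]), (draw[p2[0]], draw[p2[1]]))
        _, lnls[t] = optimize_quartet(sub, split, model, tol=tol,
                                      max_sweeps=max_sweeps, xatol=xatol,
                                      min_sites=min_sites, dtype=dtype)
    w = likelihood_weights(lnls)
    return QuartetEval(tuple(draw), lnls, w, assign_region(w), n_usable)


def summarize(evals: Sequence[QuartetEval]) -> FcLMSummary:
    counts = {r: 0 for r in REGIONS}
    basin = [0, 0, 0]
    for e in evals:
        counts[e.region] += 1
        if e.weights is not None:
            basin[int(np.asarray(e.weights).argmax())] += 1
    return FcLMSummary(counts, len(evals), tuple(basin))


# -- permutation schemes ------------------------------------------------------

def permute(
    sm: Supermatrix,
    scheme: PermutationScheme | str,
    seed=0,
) -> Supermatrix:
    scheme = PermutationScheme(scheme)
    rng = np.random.default_rng(seed)
    data = sm.alignment.data.copy()
    if scheme is PermutationScheme.I:
        for p in sm.partitions:
            block = data[:, p.start:p.end]
            for row in block:
                ok = np.flatnonzero(row != MISSING)
                if ok.size > 1:
                    row[ok] = row[ok[rng.permutation(ok.size)]]
    else:
        for p in sm.partitions:
            block = data[:, p.start:p.end]
            mask = block != MISSING
            vals = block[mask]
            rng.shuffle(vals)
            block[mask] = vals
        if scheme is PermutationScheme.III:
            # rebuild the missing-block layout per partition, preserving the
            # number of absent taxa; residues are redistributed over the new
            # present cells
            n_taxa = data.shape[0]
            for p in sm.partitions:
                block = data[:, p.start:p.end]
                absent = np.flatnonzero((block == MISSING).all(axis=1))
                vals = block[block != MISSING]
                new_absent = rng.choice(n_taxa, size=absent.size, replace=False)
                block[:] = MISSING
                present = np.setdiff1d(np.arange(n_taxa), new_absent)
                cells = present.size * (p.end - p.start)
                if vals.size > cells:
                    vals = rng.choice(vals, size=cells, replace=False)
                elif vals.size < cells:
                    extra = rng.choice(vals, size=cells - vals.size, replace=True)
                    vals = np.concatenate([vals, extra])
                rng.shuffle(vals)
                block[present, :] = vals.reshape(present.size, -1)
    from .alignment import Alignment as _A, Supermatrix as _S
    return _S(_A(list(sm.labels), data), sm.partitions)


def net_support(original: FcLMSummary, permuted: FcLMSummary,
                among: str = "basin") -> np.ndarray:
    """Per-corner support not explainable by confounding signal:
    max(0, original% - permuted%)."""
    diff = original.corner_percentages(among) - permuted.corner_percentages(among)
    return np.maximum(diff, 0.0)


@dataclass
class FcLMResult:
    original: FcLMSummary
    permuted: dict[str, FcLMSummary] = field(default_factory=dict)
    evals: dict[str, list[QuartetEval]] = field(default_factory=dict)

    def net(self, scheme: str = "I", among: str = "basin") -> np.ndarray:
        return net_support(self.original, self.permuted[scheme], among)


def run_fclm(
    sm: Supermatrix,
    groups: FourGroups,
    model: SubstModel,
    cap: int = 1000,
    seed: int = 0,
    schemes: Sequence[str] = ("I",),
    n_permutation_replicates: int = 1,
    min_sites: int = 50,
) -> FcLMResult:
    """FcLM on the original matrix and on permuted baselines.

    Permuted baselines may pool several independent permutation replicates
    (fresh permutation + fresh quartet draw each) for a stabler estimate of
    the confounding-signal corner distribution.
    """
    groups.validate_against(sm.labels)
    ss = np.random.SeedSequence(seed)
    draw_seed, *rest = ss.spawn(1 + len(schemes))
    draws = draw_quartets(groups, cap, np.random.default_rng(draw_seed))
    evals = [eval_quartet(sm, d, model, min_sites=min_sites) for d in draws]
    result = FcLMResult(summarize(evals))
    result.evals["original"] = evals
    for scheme, scheme_seed in zip(schemes, rest):
        pooled: list[QuartetEval] = []
        for rep_seed in scheme_seed.spawn(n_permutation_replicates):
            r1, r2 = rep_seed.spawn(2)
            perm = permute(sm, scheme, np.random.default_rng(r1))
            rep_draws = draw_quartets(groups, cap, np.random.default_rng(r2))
            pooled.extend(eval_quartet(perm, d, model, min_sites=min_sites)
                          for d in rep_draws)
        result.permuted[scheme] = summarize(pooled)
        result.evals[scheme] = pooled
    return result


def summary_frame(result: FcLMResult) -> pd.DataFrame:
    """Long-format region percentages for the original and each scheme."""
    rows = []
    for name, summ in [("original", result.original)] + list(result.permuted.items()):
        row = {"dataset": name, "total": summ.total}
        row.update({r: summ.counts[r] for r in REGIONS})
        for k, v in zip((1, 2, 3), summ.corner_percentages("basin")):
            row[f"basin{k}_pct"] = v
        rows.append(row)
    return pd.DataFrame(rows)
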