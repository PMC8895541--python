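"""Quartet Sampling branch support.

For every internal branch the four surrounding subtree sets are sampled
(one taxon each, N times); each sampled quartet's three topologies are
optimized and the quartet is *resolved* when the best topology beats the
runner-up by at least delta log-likelihood units, otherwise *uncertain*.

Scores per branch:
  QC (concordance, [-1, 1]): 1 + sum_t p_t log3 p_t over the resolved
      topology frequencies, signed negative unless the concordant topology
      is the unique most frequent;
  QD (differential, [0, 1]): 1 - |d1 - d2| / (d1 + d2), the skew of the two
      discordant counts; defined as 1 when there is no discordance;
  QI (informativeness, [0, 1]): resolved / N.
Per taxon, QF (fidelity) is the fraction of its resolved quartets that were
concordant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import MISSING, Supermatrix
from .likelihood import optimize_quartet
from .models import SubstModel
from .trees import Node, PhyloTree

__all__ = [
    "QSConfig",
    "QSBranchScores",
    "BranchContext",
    "branch_contexts",
    "score_branch",
    "qd_score",
    "qc_score",
    "qf_scores",
    "annotate_tree",
    "run_qs",
]


@dataclass
class QSConfig:
    n_per_branch: int = 100
    delta: float = 2.0
    seed: int = 0
    min_sites: int = 50
    tol: float = 1e-4
    max_sweeps: int = 30
    xatol: float = 1e-3
    dtype: type = np.float32

    def __post_init__(self):
        if self.n_per_branch < 1:
            raise ValueError("need at least one quartet per branch")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")


@dataclass
class BranchContext:
    branch_id: str
    sets: tuple[list[str], list[str], list[str], list[str]]  # (L1, L2, R1, R2)
    node: Node | None = None

    def __post_init__(self):
        union = [t for s in self.sets for t in s]
        assert len(union) == len(set(union))


@dataclass
class QSBranchScores:
    branch_id: str
    n: int
    concordant: int
    discordant1: int
    discordant2: int
    uncertain: int
    qc: float | None
    qd: float | None
    qi: float

    def __post_init__(self):
        assert self.concordant + self.discordant1 + self.discordant2 + \
            self.uncertain == self.n


def _unrooted(tree: PhyloTree) -> PhyloTree:
    """Copy with a trifurcating root (binary roots suppressed)."""
    t = tree.copy()
    root = t.root
    if len(root.children) == 2:
        internal = next((c for c in root.children if not c.is_leaf), None)
        if internal is None:
            return t  # two-leaf tree; nothing to score anyway
        other = next(c for c in root.children if c is not internal)
        other.length = (other.length or 0.0) + (internal.length or 0.0)
        internal.children.append(other)
        other.parent = internal
        internal.parent = None
        internal.length = None
        t.root = internal
        t.rooted = False
    return t


def _split_sets(parts: list[frozenset[str]]) -> tuple[list[str], list[str]]:
    """Two taxon sets from >= 2 sibling components (extras merged)."""
    first = sorted(parts[0])
    rest = sorted(set().union(*parts[1:]))
    return first, rest


def branch_contexts(tree: PhyloTree) -> list[BranchContext]:
    """The four induced taxon sets around every internal branch.

    Branches adjacent to a leaf carry no QS score and are skipped.
    """
    if tree.n_leaves < 4:
        raise ValueError("QS needs at least four leaves")
    t = _unrooted(tree)
    all_leaves = frozenset(t.leaf_labels())
    below: dict[int, frozenset[str]] = {}
    for n in t.postorder():
        below[id(n)] = (frozenset([n.label]) if n.is_leaf
                        else frozenset().union(*(below[id(c)] for c in n.children)))
    contexts = []
    for v in t.postorder():
        if v is t.root or v.is_leaf:
            continue
        u = v.parent
        left_parts = [below[id(c)] for c in v.children]
        right_parts = [below[id(c)] for c in u.children if c is not v]
        if u.parent is not None:
            right_parts.append(all_leaves - below[id(u)])
        if len(right_parts) < 2:
            continue
        l1, l2 = _split_sets(left_parts)
        r1, r2 = _split_sets(right_parts)
        side = below[id(v)]
        bid = "|".join(min(sorted(side), sorted(all_leaves - side)))
        contexts.append(BranchContext(bid, (l1, l2, r1, r2), node=v))
    return contexts


def qd_score(d1: int, d2: int) -> float:
    """Quartet differential: skew of the two discordant counts."""
    if d1 < 0 or d2 < 0:
        raise ValueError("counts must be nonnegative")
    if d1 + d2 == 0:
        return 1.0
    return 1.0 - abs(d1 - d2) / (d1 + d2)


def qc_score(c: int, d1: int, d2: int) -> float | None:
    """Entropy-scaled quartet concordance over resolved quartets."""
    resolved = c + d1 + d2
    if resolved == 0:
        return None
    p = np.array([c, d1, d2], dtype=float) / resolved
    nz = p > 0
    ent = 1.0 + float((p[nz] * np.log(p[nz]) / np.log(3.0)).sum())
    concordant_top = c > d1 and c > d2
    return ent if concordant_top else -ent


@dataclass
class _DrawRecord:
    taxa: tuple[str, str, str, str]
    outcome: str  # 'c', 'd1', 'd2', 'u'


def score_branch(
    sm: Supermatrix,
    context: BranchContext,
    model: SubstModel,
    config: QSConfig,
    rng: np.random.Generator | None = None,
    records: list[_DrawRecord] | None = None,
) -> QSBranchScores:
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    aln = sm.alignment
    counts = {"c": 0, "d1": 0, "d2": 0, "u": 0}
    for _ in range(config.n_per_branch):
        draw = tuple(s[rng.integers(len(s))] for s in context.sets)
        outcome = "u"
        sub = aln.subset_taxa(draw)
        usable = int((~(sub.data == MISSING).any(axis=0)).sum())
        if usable >= config.min_sites:
            lnls = np.empty(3)
            splits = (((draw[0], draw[1]), (draw[2], draw[3])),   # concordant
                      ((draw[0], draw[2]), (draw[1], draw[3])),   # d1
                      ((draw[0], draw[3]), (draw[1], draw[2])))   # d2
            for t, split in enumerate(splits):
                _, lnls[t] = optimize_quartet(
                    sub, split, model, tol=config.tol,
                    max_sweeps=config.max_sweeps, xatol=config.xatol,
                    min_sites=config.min_sites, dtype=config.dtype)
            order = np.argsort(lnls)[::-1]
            if lnls[order[0]] - lnls[order[1]] >= config.delta:
                outcome = ("c", "d1", "d2")[order[0]]
        counts[outcome] += 1
        if records is not None:
            records.append(_DrawRecord(draw, outcome))
    c, d1, d2, u = counts["c"], counts["d1"], counts["d2"], counts["u"]
    resolved = c + d1 + d2
    return QSBranchScores(
        context.branch_id, config.n_per_branch, c, d1, d2, u,
        qc=qc_score(c, d1, d2),
        qd=qd_score(d1, d2) if resolved else None,
        qi=resolved / config.n_per_branch,
    )


def qf_scores(records: list[_DrawRecord]) -> pd.Series:
    """Per-taxon quartet fidelity over all resolved draws (NaN if none)."""
    seen: dict[str, list[int]] = {}
    for rec in records:
        if rec.outcome == "u":
            continue
        for t in rec.taxa:
            seen.setdefault(t, []).append(1 if rec.outcome == "c" else 0)
    return pd.Series({t: float(np.mean(v)) for t, v in sorted(seen.items())},
                     dtype=float)


def annotate_tree(tree: PhyloTree, scores: list[QSBranchScores]) -> PhyloTree:
    """Copy of the tree with internal branches labelled "QC/QD/QI"
    (2 decimals; NA where unscored)."""
    t = _unrooted(tree)
    by_id = {s.branch_id: s for s in scores}
    all_leaves = frozenset(t.leaf_labels())
    below: dict[int, frozenset[str]] = {}
    for n in t.postorder():
        below[id(n)] = (frozenset([n.label]) if n.is_leaf
                        else frozenset().union(*(below[id(c)] for c in n.children)))
    for n in t.postorder():
        if n.is_leaf or n is t.root:
            continue
        bid = "|".join(min(sorted(below[id(n)]), sorted(all_leaves - below[id(n)])))
        s = by_id.get(bid)
        if s is None:
            n.label = "NA"
        else:
            fmt = lambda x: "NA" if x is None else f"{x:.2f}"
            n.label = f"{fmt(s.qc)}/{fmt(s.qd)}/{fmt(s.qi)}"
    return t


def run_qs(
    sm: Supermatrix,
    tree: PhyloTree,
    model: SubstModel,
    config: QSConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, PhyloTree]:
    """Score every internal branch; returns (branch table, QF series,
    annotated tree)."""
    config = config or QSConfig()
    rng = np.random.default_rng(config.seed)
    records: list[_DrawRecord] = []
    scores = []
    for ctx in branch_contexts(tree):
        scores.append(score_branch(sm, ctx, model, config, rng=rng,
                                   records=records))
    table = pd.DataFrame([{
        "branch": s.branch_id, "N": s.n, "concordant": s.concordant,
        "discordant1": s.discordant1, "discordant2": s.discordant2,
        "uncertain": s.uncertain, "QC": s.qc, "QD": s.qd, "QI": s.qi,
    } for s in scores])
    return table, qf_scores(records), annotate_tree(tree, scores)
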