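"""Placement hypotheses and approximately-unbiased (AU) topology tests.

Candidate placements of a focal taxon are built by pruning it from a
backbone tree and regrafting at the midpoint of named edges.  Per-site
log-likelihoods on each fixed topology (branch lengths re-optimized by
default) feed a multiscale RELL bootstrap: for scale factors r the sites
are resampled to size ceil(r*n), the per-topology winning proportions
BP_k(r) are probit-transformed and fitted by weighted least squares to
z(r) = d*sqrt(r) + c/sqrt(r); the AU p-value is 1 - Phi(d - c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alignment import Supermatrix
from .likelihood import TreeLikelihood
from .models import SubstModel
from .trees import Node, PhyloTree

DEFAULT_SCALES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)

__all__ = [
    "PlacementHypothesis",
    "AUResult",
    "build_placements",
    "per_site_lnL",
    "site_lnl_table",
    "rell",
    "au_pvalue",
    "au_test",
    "DEFAULT_SCALES",
]


@dataclass
class PlacementHypothesis:
    label: str
    focal: str
    edge: str          # canonical id of the attachment edge on the pruned backbone
    tree: PhyloTree


def _edge_index(tree: PhyloTree) -> dict[str, Node]:
    """Canonical id -> child node for every edge (both side spellings)."""
    out: dict[str, Node] = {}
    for child, below, above in tree.edge_bipartitions():
        out["|".join(sorted(below))] = child
        out["|".join(sorted(above))] = child
        out["|".join(min(sorted(below), sorted(above)))] = child
    return out


def edge_ids(tree: PhyloTree) -> list[str]:
    """Canonical (smaller-side, sorted) ids of all edges."""
    return ["|".join(min(sorted(b), sorted(a)))
            for _, b, a in tree.edge_bipartitions()]


def build_placements(
    backbone: PhyloTree,
    focal: str,
    edges: list[str],
    labels: list[str] | None = None,
    stub_length: float = 0.1,
) -> list[PlacementHypothesis]:
    """Prune the focal leaf and regraft it at the midpoint of each edge.

    Edges are named by the sorted, '|'-joined taxa of either side of the
    bipartition on the *pruned* backbone.
    """
    if labels is None:
        labels = [f"H{i + 1}" for i in range(len(edges))]
    pruned = backbone.copy()
    pruned.prune_leaf(focal)
    out = []
    for label, edge in zip(labels, edges):
        key = "|".join(sorted(edge.split("|"))) if isinstance(edge, str) else edge
        tree = pruned.copy()
        index = _edge_index(tree)
        if key not in index:
            raise KeyError(f"unknown edge {edge!r} on the pruned backbone")
        child = index[key]
        parent = child.parent
        half = (child.length or 0.0) / 2.0
        mid = Node(None, half)
        parent.children[parent.children.index(child)] = mid
        mid.parent = parent
        mid.add(child)
        child.length = half
        mid.add(Node(focal, stub_length))
        out.append(PlacementHypothesis(label, focal, key,
                                       PhyloTree(tree.root, rooted=tree.rooted)))
    return out


def per_site_lnL(
    tree: PhyloTree,
    sm: Supermatrix,
    model: SubstModel,
    optimize_branches: bool = True,
    tol: float = 1e-4,
    max_sweeps: int = 20,
    xatol: float = 1e-3,
) -> np.ndarray:
    """Per-site log-likelihood row for one fixed topology."""
    aln = sm.alignment if isinstance(sm, Supermatrix) else sm
    if set(tree.leaf_labels()) != set(aln.labels):
        raise KeyError("tree leaves and alignment taxa must match")
    engine = TreeLikelihood(tree, aln, model)
    if optimize_branches:
        engine.optimize_branch_lengths(tol=tol, max_sweeps=max_sweeps, xatol=xatol)
    return engine.site_log_likelihoods()


def site_lnl_table(
    trees: list[PhyloTree],
    sm: Supermatrix,
    model: SubstModel,
    optimize_branches: bool = True,
) -> np.ndarray:
    """(topologies x sites) matrix of per-site log-likelihoods."""
    return np.stack([per_site_lnL(t, sm, model, optimize_branches) for t in trees])


def rell(
    table: np.ndarray,
    scales=DEFAULT_SCALES,
    n_boot: int = 10000,
    seed=0,
) -> dict[float, np.ndarray]:
    """Multiscale RELL bootstrap winning proportions.

    For each scale r, n_boot multinomial resamples of ceil(r*n) site indices
    are drawn; BP_k(r) is the fraction of resamples in which topology k has
    the highest resampled total (exact ties split uniformly at random via an
    infinitesimal jitter).
    """
    table = np.atleast_2d(np.asarray(table, dtype=float))
    n_topo, n_sites = table.shape
    rng = np.random.default_rng(seed)
    out: dict[float, np.ndarray] = {}
    for r in scales:
        m = int(np.ceil(r * n_sites))
        if n_topo == 1:
            out[float(r)] = np.ones(1)
            continue
        idx = rng.integers(0, n_sites, size=(n_boot, m))
        totals = table.T[idx].sum(axis=1)
        eps = (np.abs(totals).max() + 1.0) * 1e-12
        winners = (totals + rng.random(totals.shape) * eps).argmax(axis=1)
        out[float(r)] = np.bincount(winners, minlength=n_topo) / n_boot
    return out


@dataclass
class AUResult:
    p_values: pd.Series
    d: pd.Series
    c: pd.Series
    degenerate: pd.Series
    bp: pd.DataFrame  # scales x topologies


def au_pvalue(bp_curves: dict[float, np.ndarray], n_boot: int,
              labels: list[str] | None = None) -> AUResult:
    """AU p-values from multiscale bootstrap proportions.

    BPs are continuity-corrected by 1/(2B); topologies whose raw BP is 0 or
    1 at fewer than two scales strictly inside (0,1) get a clamped p-value
    and a degenerate flag.
    """
    scales = np.array(sorted(bp_curves))
    bp = np.stack([bp_curves[r] for r in scales])  # (nscale, ntopo)
    n_topo = bp.shape[1]
    if labels is None:
        labels = [f"T{k + 1}" for k in range(n_topo)]
    lo = 1.0 / (2.0 * n_boot)
    ps, ds, cs, flags = [], [], [], []
    sq = np.sqrt(scales)
    X = np.column_stack([sq, 1.0 / sq])
    for k in range(n_topo):
        raw = bp[:, k]
        usable = (raw > 0) & (raw < 1)
        if usable.sum() < 2:
            ps.append(0.0 if raw.mean() < 0.5 else 1.0)
            ds.append(np.nan)
            cs.append(np.nan)
            flags.append(True)
            continue
        p_corr = np.clip(raw, lo, 1.0 - lo)
        z = norm.isf(p_corr)          # Phi^-1(1 - BP)
        var = p_corr * (1 - p_corr) / (n_boot * norm.pdf(z) ** 2)
        w = 1.0 / var
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        d_k, c_k = beta
        ps.append(float(norm.sf(d_k - c_k)))
        ds.append(float(d_k))
        cs.append(float(c_k))
        flags.append(False)
    idx = pd.Index(labels, name="topology")
    return AUResult(
        pd.Series(ps, index=idx, name="p_au"),
        pd.Series(ds, index=idx, name="d"),
        pd.Series(cs, index=idx, name="c"),
        pd.Series(flags, index=idx, name="degenerate"),
        pd.DataFrame(bp, index=scales, columns=labels),
    )


def au_test(
    table: np.ndarray,
    scales=DEFAULT_SCALES,
    n_boot: int = 10000,
    seed=0,
    labels: list[str] | None = None,
) -> AUResult:
    """RELL + AU in one step on a (topologies x sites) lnL table."""
    return au_pvalue(rell(table, scales, n_boot, seed), n_boot, labels)
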