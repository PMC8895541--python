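"""Synthetic sequence evolution with the failure modes the pipeline is
built to detect: lineage-specific compositional shifts (SRH violations),
whole-gene missingness, misassigned (outlier) sequences, and gene-tree
conflict around a four-group split.

Randomness discipline: every public entry point takes a seed (or Generator);
multi-gene generators spawn one independent substream per gene via
``numpy.random.SeedSequence.spawn``, so per-gene output is invariant to how
many other genes are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import MISSING, N_STATES, Alignment
from .models import SubstModel
from .trees import Node, PhyloTree

__all__ = [
    "HeterogeneitySpec",
    "MissingnessSpec",
    "OutlierSpec",
    "FourGroupFixture",
    "simulate_gene",
    "simulate_nonstationary",
    "apply_missingness",
    "inject_outliers",
    "make_fourgroup_fixture",
    "fourgroup_tree",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class HeterogeneitySpec:
    """Compositional shift applied on part of the tree.

    Branches whose full descendant leaf set lies inside ``affected_taxa``
    (including terminal branches of those taxa) evolve under a model rebuilt
    with ``freqs_alt``; everything else uses the base model.  ``fraction``
    is the share of genes the shift applies to in multi-gene generators.
    """

    affected_taxa: frozenset[str] | set[str]
    freqs_alt: np.ndarray
    fraction: float = 1.0

    def __post_init__(self):
        f = np.asarray(self.freqs_alt, dtype=float)
        if f.shape != (N_STATES,) or np.any(f <= 0) or not np.isclose(f.sum(), 1.0, atol=1e-6):
            raise ValueError("freqs_alt must be 20 positive values summing to 1")
        self.affected_taxa = frozenset(self.affected_taxa)
        self.freqs_alt = f / f.sum()


@dataclass
class MissingnessSpec:
    """Whole-gene-per-species missingness.

    Either a scalar presence probability for every (species, gene) cell, a
    per-species probability mapping, or an explicit boolean presence matrix
    (species x genes).  ``group_presence`` optionally gives per-group
    probabilities producing group-correlated patterns.
    """

    presence_prob: float | dict[str, float] | None = 0.8
    presence_matrix: pd.DataFrame | None = None
    group_presence: dict[str, tuple[Sequence[str], float]] | None = None


@dataclass
class OutlierSpec:
    """Misassigned-sequence contamination.

    ``mode='offtree'`` replaces rows with sequences simulated on an
    unrelated random star tree (mimicking orthology misassignment);
    ``mode='shuffle'`` permutes the row's own residues.
    """

    n_genes: int = 0
    n_sequences_per_gene: int = 1
    mode: str = "offtree"

    def __post_init__(self):
        if self.mode not in ("offtree", "shuffle"):
            raise ValueError("mode must be 'offtree' or 'shuffle'")


def _sample_transitions(parent_states: np.ndarray, P: np.ndarray,
                        cats: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Child states given parent states, per-site categories, P (ncat,20,20)."""
    child = np.empty_like(parent_states)
    u = rng.random(parent_states.size)
    cum = np.cumsum(P, axis=2)
    for k in range(P.shape[0]):
        sel = cats == k
        if not sel.any():
            continue
        rows = cum[k, parent_states[sel]]
        child[sel] = (rows < u[sel, None]).sum(axis=1)
    return np.minimum(child, N_STATES - 1)


def _branch_models(tree: PhyloTree, model: SubstModel,
                   het: HeterogeneitySpec | None) -> dict[int, SubstModel]:
    """Per-node substitution model honouring a heterogeneity spec."""
    out: dict[int, SubstModel] = {}
    if het is None:
        return out
    affected = set(het.affected_taxa)
    unknown = affected - set(tree.leaf_labels())
    if unknown:
        raise KeyError(f"heterogeneity spec names unknown taxa: {sorted(unknown)}")
    shifted = model.with_frequencies(het.freqs_alt)
    leafsets: dict[int, set[str]] = {}
    for n in tree.postorder():
        if n.is_leaf:
            leafsets[id(n)] = {n.label}
        else:
            leafsets[id(n)] = set().union(*(leafsets[id(c)] for c in n.children))
        if n.parent is not None and leafsets[id(n)] <= affected:
            out[id(n)] = shifted
    return out


def simulate_gene(
    tree: PhyloTree,
    model: SubstModel,
    length: int,
    seed,
    het: HeterogeneitySpec | None = None,
) -> Alignment:
    """Simulate one gene alignment along a tree (root drawn from pi).

    With ``het``, branches inside the affected clade(s) evolve under the
    composition-shifted model, producing SRH violations downstream.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    overrides = _branch_models(tree, model, het)
    cats = rng.integers(0, len(model.category_rates), size=length)
    states = {id(tree.root): rng.choice(N_STATES, size=length, p=model.freqs)}
    for n in tree.preorder():
        if n is tree.root:
            continue
        m = overrides.get(id(n), model)
        P = m.transitions(n.length or 0.0)
        states[id(n)] = _sample_transitions(states[id(n.parent)], P, cats, rng)
    leaves = tree.leaves()
    data = np.stack([states[id(n)] for n in leaves]).astype(np.uint8)
    return Alignment([n.label for n in leaves], data)


def simulate_nonstationary(
    tree: PhyloTree,
    model: SubstModel,
    het: HeterogeneitySpec,
    length: int,
    seed,
) -> Alignment:
    """Alias of :func:`simulate_gene` with a mandatory heterogeneity spec."""
    return simulate_gene(tree, model, length, seed, het=het)


def apply_missingness(
    genes: list[tuple[str, Alignment]],
    spec: MissingnessSpec,
    seed,
) -> tuple[list[tuple[str, Alignment]], pd.DataFrame]:
    """Remove whole species from whole genes; returns the realized presence
    matrix (species x genes, True = present) as ground truth."""
    rng = _rng(seed)
    gene_names = [g for g, _ in genes]
    species = sorted({lab for _, aln in genes for lab in aln.labels})
    if spec.presence_matrix is not None:
        presence = spec.presence_matrix.astype(bool)
        presence = presence.reindex(index=species, columns=gene_names)
        if presence.isna().any().any():
            raise ValueError("explicit presence matrix does not cover all species/genes")
    else:
        prob = pd.DataFrame(1.0, index=species, columns=gene_names)
        if isinstance(spec.presence_prob, dict):
            for sp, p in spec.presence_prob.items():
                prob.loc[sp] = p
        elif spec.presence_prob is not None:
            prob.iloc[:, :] = float(spec.presence_prob)
        if spec.group_presence:
            for _, (members, p) in spec.group_presence.items():
                for sp in members:
                    prob.loc[sp] = p
        presence = pd.DataFrame(
            rng.random(prob.shape) < prob.to_numpy(), index=species, columns=gene_names
        )
    out: list[tuple[str, Alignment]] = []
    for g, aln in genes:
        absent = [lab for lab in aln.labels if not presence.at[lab, g]]
        keep = aln.drop_taxa(absent) if absent else aln
        # reflect species never present in this gene's source
        for lab in species:
            if lab not in aln.labels:
                presence.at[lab, g] = False
        out.append((g, keep))
    return out, presence


def inject_outliers(
    genes: list[tuple[str, Alignment]],
    spec: OutlierSpec,
    seed,
    model: SubstModel | None = None,
) -> tuple[list[tuple[str, Alignment]], list[tuple[str, str]]]:
    """Replace random rows in random genes; truth list is [(gene, taxon)]."""
    rng = _rng(seed)
    if spec.n_genes == 0:
        return [(g, aln) for g, aln in genes], []
    if spec.n_genes > len(genes):
        raise ValueError("more contaminated genes requested than genes available")
    target_idx = rng.choice(len(genes), size=spec.n_genes, replace=False)
    truth: list[tuple[str, str]] = []
    out = []
    for i, (g, aln) in enumerate(genes):
        if i not in target_idx:
            out.append((g, aln))
            continue
        if spec.n_sequences_per_gene > aln.n_taxa:
            raise ValueError(f"gene {g}: not enough sequences to contaminate")
        rows = rng.choice(aln.n_taxa, size=spec.n_sequences_per_gene, replace=False)
        data = aln.data.copy()
        for r in rows:
            present = data[r] != MISSING
            if spec.mode == "shuffle":
                vals = data[r, present]
                rng.shuffle(vals)
                data[r, present] = vals
            else:
                m = model
                if m is None:
                    raise ValueError("offtree outlier mode needs a model")
                # unrelated lineage: a long two-branch path from a pi-draw
                root = rng.choice(N_STATES, size=int(present.sum()), p=m.freqs)
                P = m.transitions(2.0)
                cats = rng.integers(0, len(m.category_rates), size=root.size)
                data[r, present] = _sample_transitions(root, P, cats, rng)
            truth.append((g, aln.labels[r]))
        out.append((g, Alignment(list(aln.labels), data)))
    return out, truth


# -- four-group fixtures ------------------------------------------------------

def fourgroup_tree(
    groups: dict[str, list[str]],
    internal_branch: float,
    topology: tuple[tuple[str, str], tuple[str, str]],
    terminal_range: tuple[float, float],
    rng: np.random.Generator,
    stem_length: float = 0.05,
) -> PhyloTree:
    """Tree ((Gi,Gj),(Gk,Gl)) with the central edge = internal_branch.

    Groups with several taxa hang off their stem as a rake of terminal
    branches drawn uniformly from ``terminal_range``.
    """
    (gi, gj), (gk, gl) = topology

    def group_node(name: str, length: float) -> Node:
        node = Node(None, length)
        members = groups[name]
        if len(members) == 1:
            return Node(members[0], length + float(rng.uniform(*terminal_range)))
        for lab in members:
            node.add(Node(lab, float(rng.uniform(*terminal_range))))
        return node

    root = Node()
    root.add(group_node(gi, stem_length))
    root.add(group_node(gj, stem_length))
    right = root.add(Node(None, internal_branch))
    right.add(group_node(gk, stem_length))
    right.add(group_node(gl, stem_length))
    return PhyloTree(root, rooted=False)


def star_tree(groups: dict[str, list[str]], terminal_range: tuple[float, float],
              rng: np.random.Generator) -> PhyloTree:
    root = Node()
    for members in groups.values():
        for lab in members:
            root.add(Node(lab, float(rng.uniform(*terminal_range))))
    return PhyloTree(root, rooted=False)


@dataclass
class FourGroupFixture:
    genes: list[tuple[str, Alignment]]
    groups: dict[str, list[str]]
    truth: pd.DataFrame                 # per gene: topology label, tree newick
    presence: pd.DataFrame | None
    outlier_truth: list[tuple[str, str]] = field(default_factory=list)
    internal_branch: float = 0.0


_TOPO_LABELS = {
    "T1": (("G1", "G2"), ("G3", "G4")),
    "T2": (("G1", "G3"), ("G2", "G4")),
    "T3": (("G1", "G4"), ("G2", "G3")),
}


def make_fourgroup_fixture(
    group_sizes: Sequence[int] = (2, 2, 2, 2),
    internal_branch: float = 0.2,
    conflict_rho: float = 0.0,
    n_genes: int = 50,
    gene_length: int = 500,
    model: SubstModel | None = None,
    het: HeterogeneitySpec | None = None,
    miss: MissingnessSpec | None = None,
    outliers: OutlierSpec | None = None,
    seed=0,
    terminal_range: tuple[float, float] = (0.05, 0.25),
    alternative_topologies: tuple[str, ...] = ("T2", "T3"),
    star: bool = False,
) -> FourGroupFixture:
    """Multi-gene fixture around a four-group split with known truth.

    A fraction ``conflict_rho`` of genes is simulated under the alternative
    quartet topologies (split equally among ``alternative_topologies``),
    modelling gene-tree discordance as a topology mixture.  Group 4 is the
    outgroup by convention.
    """
    if not 0 <= conflict_rho <= 1:
        raise ValueError("conflict_rho must be in [0, 1]")
    if len(group_sizes) != 4 or any(s < 1 for s in group_sizes):
        raise ValueError("need four groups with >= 1 taxon each")
    from .models import poisson_model
    model = model or poisson_model()
    groups = {
        f"G{g + 1}": [f"g{g + 1}_t{i + 1}" for i in range(size)]
        for g, size in enumerate(group_sizes)
    }
    ss = np.random.SeedSequence(seed)
    spawned = ss.spawn(n_genes + 3)
    gene_seeds, topo_seed, miss_seed, out_seed = (
        spawned[:n_genes], spawned[-3], spawned[-2], spawned[-1])
    top_rng = np.random.default_rng(topo_seed)

    labels = []
    for i in range(n_genes):
        if conflict_rho > 0 and top_rng.random() < conflict_rho:
            labels.append(alternative_topologies[i % len(alternative_topologies)])
        else:
            labels.append("T1")

    genes, rows = [], []
    for i in range(n_genes):
        g_rng = np.random.default_rng(gene_seeds[i])
        if star:
            tree = star_tree(groups, terminal_range, g_rng)
            label = "star"
        else:
            label = labels[i]
            tree = fourgroup_tree(groups, internal_branch, _TOPO_LABELS[label],
                                  terminal_range, g_rng)
        use_het = het if (het is not None and g_rng.random() < het.fraction) else None
        aln = simulate_gene(tree, model, gene_length, g_rng, het=use_het)
        name = f"gene{i + 1:04d}"
        genes.append((name, aln))
        rows.append({"gene": name, "topology": label,
                     "het": use_het is not None, "newick": tree.to_newick(decimals=5)})
    truth = pd.DataFrame(rows).set_index("gene")

    presence = None
    if miss is not None:
        genes, presence = apply_missingness(genes, miss, np.random.default_rng(miss_seed))
    outlier_truth: list[tuple[str, str]] = []
    if outliers is not None:
        genes, outlier_truth = inject_outliers(
            genes, outliers, np.random.default_rng(out_seed), model=model)
    return FourGroupFixture(genes, groups, truth, presence, outlier_truth, internal_branch)
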