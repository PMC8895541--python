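"""Felsenstein pruning likelihoods on fixed trees, branch-length
optimization, and a brute-force enumeration oracle.

The engine compresses site patterns, gathers tip conditionals directly from
transition-matrix columns, and rescales partials per node, so quartet
evaluation over large supermatrix slices stays cheap.  MISSING residues
contribute all-ones partials (total ambiguity), hence a fully-MISSING
column has likelihood 1.

Branch lengths are optimized by cyclic bounded scalar (Brent-type)
minimization on [1e-8, 10]; a sweep updates every edge once, and sweeps
stop when the total log-likelihood improves by less than ``tol``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import MISSING, N_STATES, Alignment
from .models import SubstModel
from .trees import Node, PhyloTree

BRANCH_MIN = 1e-8
BRANCH_MAX = 10.0

__all__ = [
    "TreeLikelihood",
    "site_log_likelihoods",
    "total_log_likelihood",
    "brute_force_lnL",
    "optimize_quartet",
    "UninformativeQuartetError",
]


class UninformativeQuartetError(ValueError):
    """Raised when a quartet has no columns usable for evaluation."""


def _compress_columns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique columns of a (taxa x sites) code matrix.

    Returns (patterns (taxa x npat), counts, inverse site->pattern map).
    """
    k, n = codes.shape
    if k <= 13:
        packed = np.zeros(n, dtype=np.int64)
        for row in codes:
            packed = packed * 21 + row
        uniq, inverse, counts = np.unique(packed, return_inverse=True, return_counts=True)
        patterns = np.empty((k, uniq.size), dtype=np.uint8)
        rem = uniq.copy()
        for i in range(k - 1, -1, -1):
            patterns[i] = rem % 21
            rem //= 21
        return patterns, counts, inverse
    uniq, inverse, counts = np.unique(codes, axis=1, return_inverse=True, return_counts=True)
    return uniq, counts, np.asarray(inverse).ravel()


class TreeLikelihood:
    """Pruning likelihood of an alignment on a fixed tree under one model."""

    def __init__(self, tree: PhyloTree, aln: Alignment, model: SubstModel):
        if aln.n_sites == 0:
            raise ValueError("empty alignment")
        labels = tree.leaf_labels()
        missing = [lab for lab in labels if not aln.has_taxon(lab)]
        if missing:
            raise KeyError(f"tree leaves absent from alignment: {missing}")
        self.tree = tree
        self.model = model
        self.n_sites = aln.n_sites

        self.nodes: list[Node] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.lengths = np.array(
            [n.length if (n is not tree.root and n.length is not None) else 0.0
             for n in self.nodes]
        )
        codes = np.stack([aln.row(lab) for lab in labels])
        self.patterns, self.counts, self.site_to_pattern = _compress_columns(codes)
        self.n_patterns = self.patterns.shape[1]
        leaf_iter = iter(range(len(labels)))
        self.tip_codes: dict[int, np.ndarray] = {}
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                self.tip_codes[i] = self.patterns[next(leaf_iter)]

    # -- conditional likelihood vectors --------------------------------
    @property
    def ncat(self) -> int:
        return len(self.model.category_rates)

    def _edge_P(self, i: int) -> np.ndarray:
        return self.model.transitions(self.lengths[i])

    def _child_contrib(self, i: int, P: np.ndarray, clv: np.ndarray | None) -> np.ndarray:
        """(ncat, 20, npat) contribution of child i seen from its parent."""
        if clv is None:  # tip
            codes = self.tip_codes[i]
            contrib = P[:, :, np.minimum(codes, N_STATES - 1)].copy()
            miss = codes == MISSING
            if miss.any():
                contrib[:, :, miss] = 1.0
            return contrib
        out = np.empty((self.ncat, N_STATES, self.n_patterns))
        for c in range(self.ncat):
            out[c] = P[c] @ clv[c]
        return out

    def _postorder_clvs(self):
        """clv and cumulative log-scaler per node (tips store None)."""
        clvs: list[np.ndarray | None] = [None] * len(self.nodes)
        scales = [np.zeros(self.n_patterns) for _ in self.nodes]
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                continue
            acc = np.ones((self.ncat, N_STATES, self.n_patterns))
            sc = np.zeros(self.n_patterns)
            for c in n.children:
                j = self.index[id(c)]
                acc *= self._child_contrib(j, self._edge_P(j), clvs[j])
                sc += scales[j]
            m = acc.max(axis=(0, 1))
            safe = np.where(m > 0, m, 1.0)
            acc /= safe
            with np.errstate(divide="ignore"):
                sc += np.log(np.where(m > 0, m, 0.0))
            clvs[i], scales[i] = acc, sc
        return clvs, scales

    # -- likelihoods -----------------------------------------------------
    def pattern_log_likelihoods(self) -> np.ndarray:
        clvs, scales = self._postorder_clvs()
        r = len(self.nodes) - 1  # root is last in postorder
        pi = self.model.freqs
        clv = clvs[r]
        if clv is None:  # degenerate single-leaf tree
            codes = self.tip_codes[r]
            lik = np.where(codes == MISSING, 1.0, pi[np.minimum(codes, N_STATES - 1)])
            return np.log(lik)
        lik = np.einsum("j,cjp->p", pi, clv) / self.ncat
        with np.errstate(divide="ignore"):
            return np.log(lik) + scales[r]

    def site_log_likelihoods(self) -> np.ndarray:
        return self.pattern_log_likelihoods()[self.site_to_pattern]

    def total_log_likelihood(self) -> float:
        return float(self.pattern_log_likelihoods() @ self.counts)

    # -- branch-length optimization ---------------------------------------
    def _outside(self, target: int, clvs, scales):
        """Outside partial A (incl. pi) at the parent end of target's edge.

        Returns (A (ncat,20,npat), log-scale vector constant in t_target).
        """
        path = []
        node = self.nodes[target]
        while node.parent is not None:
            path.append(node)
            node = node.parent
        path.reverse()  # root's child ... target
        pi = self.model.freqs
        A = np.broadcast_to(pi[None, :, None],
                            (self.ncat, N_STATES, self.n_patterns)).copy()
        sc = np.zeros(self.n_patterns)
        current = self.tree.root
        for step in path:
            for c in current.children:
                if c is step:
                    continue
                j = self.index[id(c)]
                A *= self._child_contrib(j, self._edge_P(j), clvs[j])
                sc += scales[j]
            if step is self.nodes[target]:
                break
            j = self.index[id(step)]
            P = self._edge_P(j)
            nxt = np.empty_like(A)
            for c in range(self.ncat):
                nxt[c] = P[c].T @ A[c]
            A = nxt
            m = A.max(axis=(0, 1))
            safe = np.where(m > 0, m, 1.0)
            A /= safe
            with np.errstate(divide="ignore"):
                sc += np.log(np.where(m > 0, m, 0.0))
            current = step
        return A, sc

    def _edge_lnL(self, target: int, t: float, A, const_scale, B) -> float:
        P = self.model.transitions(t)
        if B is None:
            codes = self.tip_codes[target]
            W = P[:, :, np.minimum(codes, N_STATES - 1)].copy()
            miss = codes == MISSING
            if miss.any():
                W[:, :, miss] = 1.0
        else:
            W = np.empty_like(A)
            for c in range(self.ncat):
                W[c] = P[c] @ B[c]
        lik = np.einsum("cjp,cjp->p", A, W) / self.ncat
        with np.errstate(divide="ignore"):
            return float((np.log(lik) + const_scale) @ self.counts)

    def optimize_branch_lengths(
        self,
        tol: float = 1e-6,
        max_sweeps: int = 50,
        bounds: tuple[float, float] = (BRANCH_MIN, BRANCH_MAX),
        xatol: float = 1e-6,
    ) -> float:
        """Cyclic per-edge Brent optimization; returns the final lnL.

        The total lnL is non-decreasing across updates: a proposed length is
        kept only if it does not lower the edge likelihood.
        """
        lo, hi = bounds
        self.lengths = np.clip(self.lengths, lo, hi)
        self.lengths[-1] = 0.0  # root carries no edge
        last = -np.inf
        clvs, scales = self._postorder_clvs()
        for _ in range(max_sweeps):
            for i, node in enumerate(self.nodes[:-1]):
                # clv[i] depends only on edges strictly below i; processing
                # edges in postorder keeps every cached clv current
                if not node.is_leaf:
                    acc = np.ones((self.ncat, N_STATES, self.n_patterns))
                    sc_i = np.zeros(self.n_patterns)
                    for ch in node.children:
                        j = self.index[id(ch)]
                        acc *= self._child_contrib(j, self._edge_P(j), clvs[j])
                        sc_i += scales[j]
                    m = acc.max(axis=(0, 1))
                    acc /= np.where(m > 0, m, 1.0)
                    with np.errstate(divide="ignore"):
                        sc_i += np.log(np.where(m > 0, m, 0.0))
                    clvs[i], scales[i] = acc, sc_i
                A, sc = self._outside(i, clvs, scales)
                B = clvs[i]
                sc_b = sc + scales[i]
                cur = self._edge_lnL(i, self.lengths[i], A, sc_b, B)
                res = minimize_scalar(
                    lambda t: -self._edge_lnL(i, t, A, sc_b, B),
                    bounds=(lo, hi), method="bounded",
                    options={"xatol": xatol},
                )
                if -res.fun >= cur:
                    self.lengths[i] = float(res.x)
            total = self.total_log_likelihood()
            if total - last < tol:
                last = max(total, last)
                break
            last = total
        self.apply_lengths()
        return last

    def apply_lengths(self) -> None:
        for i, n in enumerate(self.nodes):
            if n is not self.tree.root:
                n.length = float(self.lengths[i])


# -- module-level convenience ------------------------------------------------

def site_log_likelihoods(tree: PhyloTree, aln: Alignment, model: SubstModel) -> np.ndarray:
    return TreeLikelihood(tree, aln, model).site_log_likelihoods()


def total_log_likelihood(tree: PhyloTree, aln: Alignment, model: SubstModel) -> float:
    return TreeLikelihood(tree, aln, model).total_log_likelihood()


def brute_force_lnL(tree: PhyloTree, aln: Alignment, model: SubstModel) -> float:
    """Explicit enumeration over all internal-node (and MISSING-tip) states.

    Independent oracle for the pruning engine; refuses trees with more than
    six leaves.
    """
    if tree.n_leaves > 6:
        raise ValueError("brute force oracle limited to <= 6 leaves")
    if aln.n_sites == 0:
        raise ValueError("empty alignment")
    nodes = list(tree.postorder())
    lengths = {id(n): (n.length or 0.0) for n in nodes if n is not tree.root}
    rates = model.category_rates
    pi = model.freqs
    total = 0.0
    for s in range(aln.n_sites):
        free: list[Node] = []
        fixed: dict[int, int] = {}
        for n in nodes:
            if n.is_leaf:
                code = int(aln.row(n.label)[s])
                if code == MISSING:
                    free.append(n)
                else:
                    fixed[id(n)] = code
            else:
                free.append(n)
        k = len(free)
        grid = N_STATES ** k
        if grid > 600_000_000:
            raise ValueError("state space too large for enumeration")
        pos = {id(n): k - 1 - i for i, n in enumerate(free)}  # digit position

        site_lik = 0.0
        for r in rates:
            Ps = {id(n): model.transition(lengths[id(n)], r)
                  for n in nodes if n is not tree.root}
            for start in range(0, grid, 4_000_000):
                idx = np.arange(start, min(start + 4_000_000, grid))

                def states_of(n: Node) -> np.ndarray | int:
                    if id(n) in fixed:
                        return fixed[id(n)]
                    return (idx // (N_STATES ** pos[id(n)])) % N_STATES

                prod = pi[states_of(tree.root)] * np.ones(idx.size)
                for n in nodes:
                    if n is tree.root:
                        continue
                    prod = prod * Ps[id(n)][states_of(n.parent), states_of(n)]
                site_lik += prod.sum() / len(rates)
        total += float(np.log(site_lik))
    return total


class QuartetEngine:
    """Fast quartet likelihood on complete (no-MISSING) columns.

    For the split (a,b | c,d) rooted at the a/b junction the site
    likelihood is  sum_x pi_x PA[x,a] PB[x,b] (P5 @ (PC[:,c] * PD[:,d]))[x];
    optimizing one edge leaves everything else fixed, so a Brent step needs
    at most one 20x20 @ 20xnpat product.  Gamma categories are averaged
    with equal weights.
    """

    # edge order: 0=a, 1=b, 2=internal, 3=c, 4=d
    def __init__(self, codes: np.ndarray, counts: np.ndarray, model: SubstModel,
                 init_length: float = 0.1, dtype=np.float64):
        self.model = model
        self.t = np.full(5, float(init_length))
        self.dtype = np.dtype(dtype)
        self.pi = model.freqs.astype(self.dtype)
        # pair-compress: sites enter only through their (a,b) and (c,d)
        # residue pairs, of which there are at most 400 each
        ab, self.ab_idx = np.unique(
            codes[0].astype(np.int32) * 20 + codes[1], return_inverse=True)
        cd, self.cd_idx = np.unique(
            codes[2].astype(np.int32) * 20 + codes[3], return_inverse=True)
        self.a, self.b = ab // 20, ab % 20
        self.c, self.d = cd // 20, cd % 20
        self.flat = self.ab_idx * cd.size + self.cd_idx
        self.counts = counts.astype(float)

    @property
    def ncat(self) -> int:
        return len(self.model.category_rates)

    def _P(self, t: float) -> np.ndarray:
        return self.model.transitions(t).astype(self.dtype, copy=False)

    def _pair(self, t1: float, t2: float, s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
        """(ncat, 20, m) joint tip contribution for a cherry (two tips)."""
        return self._P(t1)[:, :, s1] * self._P(t2)[:, :, s2]

    def _cells_lnL(self, cells: np.ndarray) -> float:
        """Total lnL from the (m_ab x m_cd) per-category-summed cell table."""
        lik = cells.ravel()[self.flat].astype(np.float64) / self.ncat
        return float(np.log(lik) @ self.counts)

    def log_likelihood(self) -> float:
        G1 = self.pi[None, :, None] * self._pair(self.t[0], self.t[1], self.a, self.b)
        G2 = self._pair(self.t[3], self.t[4], self.c, self.d)
        P5 = self._P(self.t[2])
        cells = sum(G1[k].T @ (P5[k] @ G2[k]) for k in range(self.ncat))
        return self._cells_lnL(cells)

    def _pair_distance(self, s1: np.ndarray, s2: np.ndarray,
                       bounds: tuple[float, float], xatol: float) -> float:
        """1-D ML distance between two tips (eigen-reduced line search)."""
        lam, right, left = self.model.eigen
        rates = self.model.category_rates
        # lik_p(t) = pi[s1] * P(t)[s1, s2] = sum_e e^(lam_e t) T[e, p]
        T = (self.pi[s1][None, :] * right[s1].T) * left[:, s2]
        T = T.astype(self.dtype)
        rate_lam = np.outer(rates, lam)

        def f(t: float) -> float:
            E = np.exp(rate_lam * t).astype(self.dtype)
            lik = (E @ T).mean(axis=0) if E.shape[0] > 1 else E[0] @ T
            if np.any(lik <= 0):
                return np.inf
            return -float(np.log(lik.astype(np.float64)) @ self.counts)

        res = minimize_scalar(f, bounds=bounds, method="bounded",
                              options={"xatol": xatol})
        return float(res.x)

    def init_from_distances(self, bounds: tuple[float, float] = (BRANCH_MIN, BRANCH_MAX),
                            xatol: float = 1e-3) -> None:
        """Initialize the five lengths from pairwise ML distances via the
        four-point decomposition; a near-optimal start that avoids long
        coordinate-descent ridges."""
        pa, pb = self.a[self.ab_idx], self.b[self.ab_idx]
        pc, pd = self.c[self.cd_idx], self.d[self.cd_idx]
        d = {}
        for key, (s1, s2) in {"ab": (pa, pb), "cd": (pc, pd), "ac": (pa, pc),
                              "ad": (pa, pd), "bc": (pb, pc)}.items():
            d[key] = self._pair_distance(s1, s2, bounds, xatol)
        ta = (d["ab"] + d["ac"] - d["bc"]) / 2.0
        tb = d["ab"] - ta
        tc = (d["cd"] + d["ac"] - d["ad"]) / 2.0
        td = d["cd"] - tc
        t5 = d["ac"] - ta - tc
        lo, hi = bounds
        self.t = np.clip([ta, tb, t5, tc, td], lo, hi)

    def _brent(self, fun, cur_t: float, cur_val: float,
               bounds: tuple[float, float], xatol: float) -> tuple[float, float]:
        res = minimize_scalar(lambda t: -fun(t), bounds=bounds,
                              method="bounded", options={"xatol": xatol})
        if -res.fun > cur_val:
            return float(res.x), float(-res.fun)
        return cur_t, cur_val

    def optimize(
        self,
        tol: float = 1e-6,
        max_sweeps: int = 50,
        bounds: tuple[float, float] = (BRANCH_MIN, BRANCH_MAX),
        xatol: float = 1e-4,
    ) -> float:
        """Cyclic Brent over the five edges.

        Each edge's likelihood is first reduced through the model's
        eigendecomposition to lik_p(t) = sum_e T[e,p] exp(lam_e r_c t) with
        T fixed during that edge's line search, so a Brent evaluation is a
        single weighted exponential sum.
        """
        lam, right, left = self.model.eigen
        lam = lam.astype(self.dtype)
        right = right.astype(self.dtype)
        left = left.astype(self.dtype)
        rates = self.model.category_rates
        last = -np.inf
        val = -np.inf

        rate_lam = np.outer(rates, lam)

        def line_search(T: np.ndarray, edge: int) -> float:
            # T: (ncat, 20, npat); lik(t) = mean_c sum_e T[c,e,p] e^(lam_e r_c t)
            T0 = T[0]

            def f(t: float) -> float:
                E = np.exp(rate_lam * t).astype(self.dtype)
                if self.ncat == 1:
                    lik = E[0] @ T0
                else:
                    lik = np.einsum("ce,cep->p", E, T) / self.ncat
                if np.any(lik <= 0):
                    return -np.inf
                return float(np.log(lik.astype(np.float64)) @ self.counts)

            cur = f(self.t[edge])
            res = minimize_scalar(lambda t: -f(t), bounds=bounds,
                                  method="bounded", options={"xatol": xatol})
            if -res.fun > cur:
                self.t[edge] = float(res.x)
                return float(-res.fun)
            return cur

        # per-pattern residue codes of the four tips
        pa, pb = self.a[self.ab_idx], self.b[self.ab_idx]
        pc, pd = self.c[self.cd_idx], self.d[self.cd_idx]
        npat = self.ab_idx.size
        for _ in range(max_sweeps):
            # terminal edges; 3/4 use the tree rerooted at the c/d junction,
            # valid under reversibility
            for edge in (0, 1, 3, 4):
                if edge in (0, 1):
                    far = self._pair(self.t[3], self.t[4], self.c, self.d)
                    far_idx = self.cd_idx
                    sib_e, sib_s = (self.t[1], pb) if edge == 0 else (self.t[0], pa)
                    own_s = pa if edge == 0 else pb
                else:
                    far = self._pair(self.t[0], self.t[1], self.a, self.b)
                    far_idx = self.ab_idx
                    sib_e, sib_s = (self.t[4], pd) if edge == 3 else (self.t[3], pc)
                    own_s = pc if edge == 3 else pd
                P5 = self._P(self.t[2])
                Psib = self._P(sib_e)
                T = np.empty((self.ncat, right.shape[1], npat), dtype=self.dtype)
                for k in range(self.ncat):
                    K = (self.pi[:, None] * Psib[k][:, sib_s]
                         * (P5[k] @ far[k])[:, far_idx])
                    T[k] = (right.T @ K) * left[:, own_s]
                val = line_search(T, edge)
            # internal edge
            G1 = self.pi[None, :, None] * self._pair(self.t[0], self.t[1], self.a, self.b)
            G2 = self._pair(self.t[3], self.t[4], self.c, self.d)
            T = np.empty((self.ncat, right.shape[1], self.flat.size), dtype=self.dtype)
            for k in range(self.ncat):
                A = G1[k].T @ right            # (m_ab, 20)
                Bm = left @ G2[k]              # (20, m_cd)
                T[k] = A[self.ab_idx].T * Bm[:, self.cd_idx]
            val = line_search(T, 2)
            if val - last < tol:
                last = max(val, last)
                break
            last = val
        return last


def optimize_quartet(
    aln4: Alignment,
    split: tuple[tuple[str, str], tuple[str, str]],
    model: SubstModel,
    init_length: float = 0.1,
    tol: float = 1e-6,
    max_sweeps: int = 50,
    min_sites: int = 1,
    xatol: float = 1e-4,
    dtype=np.float64,
    init: str = "distance",
) -> tuple[np.ndarray, float]:
    """ML branch lengths and lnL of a 4-taxon alignment on one quartet split.

    Only columns where all four taxa are non-MISSING are used.  Returns
    (lengths, lnL) with lengths ordered (a, b, internal, c, d) for the
    split (a,b | c,d).
    """
    (a, b), (c, d) = split
    taxa = [a, b, c, d]
    if aln4.n_taxa != 4 or set(taxa) != set(aln4.labels):
        raise ValueError("split labels must match the 4 alignment taxa")
    sub = aln4.subset_taxa(taxa)
    complete = ~(sub.data == MISSING).any(axis=0)
    if complete.sum() < max(min_sites, 1):
        raise UninformativeQuartetError(
            f"only {int(complete.sum())} usable columns (< {max(min_sites, 1)})"
        )
    codes = sub.data[:, complete]
    patterns, counts, _ = _compress_columns(codes)
    engine = QuartetEngine(patterns, counts, model, init_length, dtype=dtype)
    if init == "distance":
        engine.init_from_distances(xatol=xatol)
    lnl = engine.optimize(tol=tol, max_sweeps=max_sweeps, xatol=xatol)
    return engine.t.copy(), lnl
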