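"""Bowker matched-pairs tests of symmetry for SRH-violation screening.

For two aligned sequences the 20x20 divergence table n_ij counts columns
with residue i in the first and j in the second sequence.  Under the
stationary, reversible, homogeneous (SRH) conditions the table is expected
symmetric; Bowker's statistic

    S = sum_{i<j} (n_ij - n_ji)^2 / (n_ij + n_ji)

is chi-squared with df = #{i<j : n_ij + n_ji > 0}.  Pairs with df = 0
(e.g. identical sequences) are untestable and excluded from violation
percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .alignment import MISSING, N_STATES, Supermatrix

__all__ = [
    "BowkerResult",
    "divergence_matrix",
    "bowker",
    "all_pairs",
    "percent_violating",
    "rank_offenders",
]


@dataclass(frozen=True)
class BowkerResult:
    statistic: float
    df: int
    p_value: float
    testable: bool

    def __post_init__(self):
        assert self.statistic >= 0 and self.df >= 0 and 0 <= self.p_value <= 1


class EmptyOverlapError(ValueError):
    """Two taxa share no non-MISSING columns."""


def divergence_matrix(sm_or_aln, taxon_a: str, taxon_b: str) -> np.ndarray:
    """20x20 residue-pair counts over columns where both taxa have data."""
    aln = sm_or_aln.alignment if isinstance(sm_or_aln, Supermatrix) else sm_or_aln
    x, y = aln.row(taxon_a), aln.row(taxon_b)
    ok = (x != MISSING) & (y != MISSING)
    if not ok.any():
        raise EmptyOverlapError(f"{taxon_a} and {taxon_b} share no columns")
    counts = np.bincount(
        x[ok].astype(np.int64) * N_STATES + y[ok], minlength=N_STATES * N_STATES
    )
    return counts.reshape(N_STATES, N_STATES)


def bowker(dm: np.ndarray) -> BowkerResult:
    dm = np.asarray(dm, dtype=float)
    if dm.sum() == 0:
        raise ValueError("empty divergence matrix")
    iu = np.triu_indices(N_STATES, k=1)
    nij, nji = dm[iu], dm.T[iu]
    tot = nij + nji
    nz = tot > 0
    df = int(nz.sum())
    if df == 0:
        return BowkerResult(0.0, 0, 1.0, testable=False)
    s = float(((nij[nz] - nji[nz]) ** 2 / tot[nz]).sum())
    return BowkerResult(s, df, float(chi2.sf(s, df)), testable=True)


def all_pairs(sm: Supermatrix | None = None, alignment=None) -> pd.DataFrame:
    """Symmetric matrix of Bowker p-values (NaN on diagonal and untestable
    pairs)."""
    aln = alignment if alignment is not None else sm.alignment
    if aln.n_taxa < 2:
        raise ValueError("need at least two taxa")
    labels = aln.labels
    p = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            try:
                res = bowker(divergence_matrix(aln, a, b))
            except EmptyOverlapError:
                continue
            if res.testable:
                p.loc[a, b] = p.loc[b, a] = res.p_value
    return p


def percent_violating(p_matrix: pd.DataFrame, alpha: float = 0.05) -> float:
    """Share (in %) of testable pairs with p < alpha."""
    iu = np.triu_indices(len(p_matrix), k=1)
    vals = p_matrix.to_numpy()[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return 100.0 * float((vals < alpha).mean())


def rank_offenders(p_matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Taxa ordered by their share of violating pairs (desc, label tiebreak).

    Columns: taxon, n_testable, n_violating, share.
    """
    if len(p_matrix) < 3:
        raise ValueError("offender ranking needs at least three taxa")
    rows = []
    for t in p_matrix.index:
        vals = p_matrix.loc[t].drop(t).to_numpy()
        vals = vals[~np.isnan(vals)]
        n_v = int((vals < alpha).sum())
        rows.append({"taxon": t, "n_testable": vals.size, "n_violating": n_v,
                     "share": n_v / vals.size if vals.size else np.nan})
    out = pd.DataFrame(rows).sort_values(
        ["share", "taxon"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out


def heatmap(p_matrix: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Write a p-value heat map with the percent-violating figure in the
    title (visual companion to the TSV output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(p_matrix.to_numpy(), vmin=0, vmax=1, cmap="RdYlGn")
    ax.set_xticks(range(len(p_matrix)), p_matrix.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(p_matrix)), p_matrix.index, fontsize=5)
    pv = percent_violating(p_matrix, alpha)
    ax.set_title(f"Bowker p-values (p<{alpha}: {pv:.2f}%)")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
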