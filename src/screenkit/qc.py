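"""Screen quality control and RNAi-profile classification of cell lines.

QC covers replicate agreement (Pearson/Spearman across replicate log2FC
profiles), the recurrently-depleted "common essential" gene set (depleted
with p < 0.05 in at least ``min_lines`` lines), and Fisher's exact overlap
of that set with reference essential-gene lists.

Cell lines are classified by unsupervised hierarchical clustering of their
dropout z-profiles: features are hairpins significantly depleted in at
least ``min_lines`` lines, restricted to the most variable fraction (IQR of
z across lines above the 70th-percentile cutoff, i.e. the top 30%);
line-line distance is 1 - Pearson correlation and merging is complete
linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "OverlapTest",
    "Dendrogram",
    "replicate_correlation",
    "common_essentials",
    "overlap_test",
    "cluster_lines",
]


@dataclass
class OverlapTest:
    """Fisher's exact test of the overlap between two gene sets."""

    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    odds_ratio: float
    p: float

    def table(self) -> np.ndarray:
        a = self.n_overlap
        b = self.n_set_a - a
        c = self.n_set_b - a
        d = self.n_universe - self.n_set_a - self.n_set_b + a
        return np.array([[a, b], [c, d]])


@dataclass
class Dendrogram:
    """Complete-linkage merge history over cell lines.

    ``linkage`` is a scipy linkage matrix over ``labels`` (lexicographically
    ordered); ``distance`` names the metric used.
    """

    linkage: np.ndarray
    labels: list[str]
    distance: str = "1 - Pearson"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> dict[str, int]:
        """Partition at k clusters: line -> cluster id."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        body = rec(tree, tree.dist)
        # strip the root's zero-length branch
        return body.rsplit(":", 1)[0] + ";"


def replicate_correlation(
    lfc: pd.DataFrame,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-line Pearson and Spearman correlation between replicate log2FCs.

    Input: the (line, replicate) MultiIndex log2FC table. Constant replicate
    vectors give missing (NaN) correlations off the diagonal.
    """
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for line in lfc.columns.get_level_values("line").unique():
        block = lfc[line]
        if block.shape[1] < 2:
            raise ValueError(f"line {line} has fewer than 2 replicates")
        pear = block.corr(method="pearson")
        spear = block.corr(method="spearman")
        for mat in (pear, spear):
            np.fill_diagonal(mat.values, 1.0)
        out[str(line)] = {"pearson": pear, "spearman": spear}
    return out


def common_essentials(
    stats_df: pd.DataFrame,
    library: pd.DataFrame,
    p_cut: float = 0.05,
    min_lines: int = 3,
) -> set[str]:
    """Genes significantly depleted (p < p_cut, negative log2FC) in >= min_lines lines.

    A gene counts as depleted in a line when *any* of its hairpins is.
    """
    gene_of = library.set_index("hairpin_id")["gene_id"]
    hits = stats_df[(stats_df["p"] < p_cut) & (stats_df["log2fc"] < 0)].copy()
    hits["gene_id"] = gene_of.reindex(hits["hairpin_id"]).to_numpy()
    n_lines = hits.groupby("gene_id")["line"].nunique()
    return set(n_lines.index[n_lines >= min_lines])


def overlap_test(
    set_a: set[str] | Sequence[str],
    set_b: set[str] | Sequence[str],
    universe: set[str] | Sequence[str],
    alternative: str = "two-sided",
) -> OverlapTest:
    """Fisher's exact test of the overlap of two sets in a universe.

    ``alternative`` is two-sided by default; 'greater' gives the one-sided
    over-representation tail. The odds ratio uses the Haldane 0.5 correction
    when any 2x2 cell is zero.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a_set, b_set = set(set_a), set(set_b)
    if not a_set <= uni or not b_set <= uni:
        raise ValueError("sets must be subsets of the universe")
    k = len(a_set & b_set)
    table = np.array(
        [
            [k, len(a_set) - k],
            [len(b_set) - k, len(uni) - len(a_set) - len(b_set) + k],
        ]
    )
    _, p = sps.fisher_exact(table, alternative=alternative)
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return OverlapTest(
        n_universe=len(uni),
        n_set_a=len(a_set),
        n_set_b=len(b_set),
        n_overlap=k,
        odds_ratio=float(odds),
        p=float(min(p, 1.0)),
    )


def select_cluster_features(
    stats_df: pd.DataFrame,
    p_cut: float = 0.05,
    min_lines: int = 4,
    iqr_quantile: float = 0.70,
) -> pd.DataFrame:
    """Hairpin x line z matrix restricted to recurrent, high-variance features.

    Hairpins depleted (p < p_cut, log2FC < 0) in >= min_lines lines are kept,
    then filtered to those whose IQR of z across lines is strictly above the
    ``iqr_quantile`` quantile (linear-interpolation convention), retaining
    the top (1 - iqr_quantile) fraction when IQRs are all distinct.
    """
    dep = (stats_df["p"] < p_cut) & (stats_df["log2fc"] < 0)
    n_dep = stats_df[dep].groupby("hairpin_id")["line"].nunique()
    keep = set(n_dep.index[n_dep >= min_lines])
    zmat = stats_df.pivot(index="hairpin_id", columns="line", values="z")
    zmat = zmat.loc[sorted(keep & set(zmat.index)), sorted(zmat.columns)]
    if len(zmat) == 0:
        return zmat
    iqr = zmat.quantile(0.75, axis=1) - zmat.quantile(0.25, axis=1)
    cut = float(np.quantile(iqr.to_numpy(), iqr_quantile))
    return zmat.loc[iqr > cut]


def cluster_lines(
    stats_df: pd.DataFrame,
    p_cut: float = 0.05,
    min_lines: int = 4,
    iqr_quantile: float = 0.70,
) -> Dendrogram:
    """Complete-linkage clustering of cell lines on dropout z-profiles.

    Distance between two lines is 1 - Pearson correlation of their z values
    over the selected features. Lines are ordered lexicographically before
    clustering so the result does not depend on input order.
    """
    feats = select_cluster_features(stats_df, p_cut, min_lines, iqr_quantile)
    if feats.shape[0] < 2:
        raise ValueError(
            f"only {feats.shape[0]} features survive the filters; cannot cluster"
        )
    if feats.shape[1] < 3:
        raise ValueError("need >= 3 lines to cluster")
    labels = sorted(feats.columns)
    corr = feats[labels].corr(method="pearson").to_numpy()
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return Dendrogram(linkage=link, labels=list(labels))
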