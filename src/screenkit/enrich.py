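"""Functional enrichment of candidate gene lists.

Two complementary views: one-sided Fisher over-representation of a
candidate list against each gene set (with Benjamini-Hochberg correction
across sets), and a ranked, weighted Kolmogorov-Smirnov enrichment test of
a set against a genome-wide statistic with a gene-label permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GseaResult", "fisher_enrichment", "gsea_test", "running_es"]


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    n_perm: int


def fisher_enrichment(
    candidates: Sequence[str],
    collection: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    ease: bool = False,
) -> pd.DataFrame:
    """One-sided over-representation Fisher test per gene set, BH-corrected.

    Candidate genes outside the universe are dropped with a warning; set
    members are restricted to the universe. ``ease=True`` subtracts one
    from the overlap (a conservative variant used by some annotation
    servers) before computing the hypergeometric tail.

    Returns rows (set_name, k, K, n, N, p, q) sorted by p.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    cand = [g for g in dict.fromkeys(candidates)]
    outside = [g for g in cand if g not in uni_set]
    if outside:
        logger.warning("dropping %d candidate genes outside the universe", len(outside))
        cand = [g for g in cand if g in uni_set]
    cand_set = set(cand)
    N, n = len(uni), len(cand)
    rows = []
    for name, members in collection.items():
        mem = set(members) & uni_set
        if not mem:
            continue
        K = len(mem)
        k = len(mem & cand_set)
        k_eff = max(k - 1, 0) if ease else k
        # P(X >= k_eff) for X ~ Hypergeom(N, K, n)
        p = float(sps.hypergeom.sf(k_eff - 1, N, K, n)) if k_eff > 0 else 1.0
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "set_name"]).reset_index(drop=True)
    return table


def running_es(
    stat: pd.Series, gene_set: set[str] | Sequence[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    Genes are ranked by statistic descending (ties broken by gene id
    ascending, a stable deterministic convention). Hits increment the
    running sum proportionally to |stat|^weight (normalized over hits);
    misses decrement uniformly. ES is the running-sum value of maximal
    magnitude. With weight 0 this is the classic K-S distance statistic.
    """
    s = stat.astype(float)
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    ranked = s.loc[order]
    in_set = ranked.index.isin(set(gene_set))
    n_hit = int(in_set.sum())
    n_miss = len(ranked) - n_hit
    if n_hit < 2:
        raise ValueError("gene set has fewer than 2 members in the ranking")
    if n_miss == 0:
        raise ValueError("gene set covers the whole universe")
    w = np.abs(ranked.to_numpy()) ** weight
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all-hit statistics zero: fall back to unweighted
        hit_w = in_set.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~in_set) / n_miss
    run = np.cumsum(steps)
    es = float(run[np.argmax(np.abs(run))])
    return es, run


def gsea_test(
    stat: pd.Series,
    gene_set: set[str] | Sequence[str],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    set_name: str = "set",
) -> GseaResult:
    """Ranked enrichment test of one gene set with a gene-label permutation null.

    The null re-draws random sets of the same size from the ranking; NES is
    ES divided by the mean |null ES| of the same sign, and p is the add-one
    corrected fraction of same-signed null scores at least as extreme.
    """
    members = set(gene_set) & set(stat.index)
    es, _ = running_es(stat, members, weight=weight)
    rng = np.random.default_rng(seed)
    genes = np.asarray(stat.index)
    k = len(members)
    null = np.empty(n_perm)
    for b in range(n_perm):
        draw = rng.choice(genes, size=k, replace=False)
        null[b], _ = running_es(stat, set(draw), weight=weight)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same) == 0:
        nes = float("nan")
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / float(np.abs(same).mean())
        p = (1 + int((np.abs(same) >= abs(es)).sum())) / (len(same) + 1)
    return GseaResult(set_name=set_name, es=es, nes=float(nes), p_perm=float(p), n_perm=n_perm)
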