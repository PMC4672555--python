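"""Group meta-analysis of per-line dropout z-scores and candidate selection.

Per-line hairpin z-scores are combined within a cell-line group with the
Stouffer statistic Z = sum(z_i)/sqrt(k), which is standard normal when its
inputs are. Two groups are contrasted with a difference-form Stouffer
comparative score z_comp = (Z_a - Z_b)/sqrt(2), preserving the N(0,1) null
so a two-tailed p < 0.05 corresponds to |z_comp| >= 1.96; negative z_comp
means depletion in group a relative to group b.

Candidate genes then pass three filters: a significant negative comparative
score; log2FC <= -1 (abundance at most halved) in every line of the target
group; and no significant strong depletion in any non-transformed line.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["stouffer_z", "ibc_comparative", "select_candidates"]

GROUP_IBC = "IBC"
GROUP_NONIBC = "nonIBC"
GROUP_NT = "nonTransformed"


def stouffer_z(z_values: Sequence[float]) -> float:
    """Stouffer integrated Z = sum(z_i) / sqrt(k)."""
    z = np.asarray(list(z_values), dtype=float)
    if z.size == 0:
        raise ValueError("stouffer_z needs at least one z value")
    if not np.isfinite(z).all():
        raise ValueError("stouffer_z requires finite z values")
    return float(z.sum() / np.sqrt(z.size))


def _pivot_z(stats_df: pd.DataFrame) -> pd.DataFrame:
    return stats_df.pivot(index="hairpin_id", columns="line", values="z")


def ibc_comparative(
    stats_df: pd.DataFrame,
    group_map: Mapping[str, str],
    group_a: str = GROUP_IBC,
    group_b: str = GROUP_NONIBC,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-hairpin comparative score between two cell-line groups.

    Returns a DataFrame indexed by hairpin with z_a (pooled Stouffer Z over
    group_a lines), z_b, z_comp = (z_a - z_b)/sqrt(2), the combined
    two-tailed normal p, and passes_cutoff (p < alpha AND z_comp < 0,
    the depletion direction).

    Hairpins missing a z in any required line are excluded (logged).
    """
    lines_a = sorted(ln for ln, g in group_map.items() if g == group_a)
    lines_b = sorted(ln for ln, g in group_map.items() if g == group_b)
    if not lines_a or not lines_b:
        raise ValueError(f"need >=1 line in each of {group_a!r} and {group_b!r}")
    zmat = _pivot_z(stats_df)
    missing_lines = set(lines_a + lines_b) - set(zmat.columns)
    if missing_lines:
        raise ValueError(f"stats table lacks lines {sorted(missing_lines)}")
    required = zmat[lines_a + lines_b]
    keep = required.notna().all(axis=1)
    if (~keep).any():
        logger.info(
            "excluding %d hairpins missing a z in a required line", int((~keep).sum())
        )
    z = required[keep]
    z_a = z[lines_a].sum(axis=1) / np.sqrt(len(lines_a))
    z_b = z[lines_b].sum(axis=1) / np.sqrt(len(lines_b))
    z_comp = (z_a - z_b) / np.sqrt(2.0)
    p_comb = 2.0 * sps.norm.sf(np.abs(z_comp))
    out = pd.DataFrame(
        {
            "z_a": z_a,
            "z_b": z_b,
            "z_comp": z_comp,
            "p_comb": p_comb,
            "passes_cutoff": (p_comb < alpha) & (z_comp < 0),
        }
    )
    out.index.name = "hairpin_id"
    return out


def select_candidates(
    comparative: pd.DataFrame,
    stats_df: pd.DataFrame,
    group_map: Mapping[str, str],
    library: pd.DataFrame,
    p_cut: float = 0.05,
    log2fc_cut: float = -1.0,
    min_hairpins: int = 1,
    target_group: str = GROUP_IBC,
    other_group: str = GROUP_NONIBC,
    exclude_group: str = GROUP_NT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three candidate filters; aggregate passing hairpins to genes.

    A hairpin passes when (1) its comparative p < p_cut with negative
    z_comp, (2) its log2FC <= log2fc_cut in *every* target-group line, and
    (3) it is not strongly depleted (p < p_cut and log2FC < log2fc_cut) in
    any line of ``exclude_group``. A gene qualifies when at least
    ``min_hairpins`` of its hairpins pass; genes are ranked by the most
    negative z_comp of their best hairpin.

    Returns ``(genes, passing_hairpins)``.
    """
    lines_t = sorted(ln for ln, g in group_map.items() if g == target_group)
    lines_o = sorted(ln for ln, g in group_map.items() if g == other_group)
    lines_x = sorted(ln for ln, g in group_map.items() if g == exclude_group)
    if not lines_x:
        logger.warning(
            "no %s lines supplied; exclusion clause skipped", exclude_group
        )

    lfc = stats_df.pivot(index="hairpin_id", columns="line", values="log2fc")
    pmat = stats_df.pivot(index="hairpin_id", columns="line", values="p")
    zmat = _pivot_z(stats_df)
    idx = comparative.index

    clause1 = (comparative["p_comb"] < p_cut) & (comparative["z_comp"] < 0)
    clause2 = (lfc.loc[idx, lines_t] <= log2fc_cut).all(axis=1)
    if lines_x:
        strong = (pmat.loc[idx, lines_x] < p_cut) & (lfc.loc[idx, lines_x] < log2fc_cut)
        clause3 = ~strong.any(axis=1)
    else:
        clause3 = pd.Series(True, index=idx)
    passing = comparative[clause1 & clause2 & clause3].copy()

    gene_of = library.set_index("hairpin_id")["gene_id"]
    passing["gene_id"] = gene_of.reindex(passing.index)
    rows = []
    for gene, sub in passing.groupby("gene_id"):
        if len(sub) < min_hairpins:
            continue
        best = sub["z_comp"].idxmin()
        row = {
            "gene_id": gene,
            "best_hairpin": best,
            "n_hairpins_passing": len(sub),
            "z_comp": float(sub.loc[best, "z_comp"]),
            "mean_log2fc_target": float(lfc.loc[best, lines_t].mean()),
            "mean_log2fc_other": float(lfc.loc[best, lines_o].mean()) if lines_o else np.nan,
        }
        for ln in lines_t + lines_o:
            row[f"z_{ln}"] = float(zmat.loc[best, ln])
        rows.append(row)
    genes = pd.DataFrame(rows)
    if len(genes):
        genes = genes.sort_values("z_comp").reset_index(drop=True)
    return genes, passing
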