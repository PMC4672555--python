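"""Per-cell-line dropout statistics for pooled shRNA screens.

Counts are normalized to within-sample proportions, converted to a log2
fold-change (T10 vs T0) per replicate, summarized per hairpin with an
empirical-Bayes moderated one-sample t-test that shrinks the replicate
variance toward a prior shared across all hairpins (stabilizing n = 3
designs), and z-scored against a Gaussian fitted to the line's log2FC
distribution so that evidence is comparable across cell lines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "VariancePrior",
    "normalize_log2fc",
    "zscore_fit",
    "moderated_t",
    "depletion_stats",
]


@dataclass
class VariancePrior:
    """Shared variance prior of the moderated t-test.

    ``d0`` prior degrees of freedom (``inf`` means full pooling to ``s0_sq``),
    ``s0_sq`` prior variance, ``d`` residual df per hairpin (n_replicates - 1).
    """

    d0: float
    s0_sq: float
    d: int

    def posterior_var(self, s_sq: np.ndarray) -> np.ndarray:
        if math.isinf(self.d0):
            return np.full_like(np.asarray(s_sq, dtype=float), self.s0_sq)
        return (self.d0 * self.s0_sq + self.d * s_sq) / (self.d0 + self.d)


def normalize_log2fc(cm, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-replicate log2 fold-change of T10 vs T0 normalized abundance.

    log2FC = log2((c10/N10 + q) / (c0/N0 + q)), with N the sample's total
    count and q = pseudocount / (mean sample depth) so the offset lives on
    the proportion scale. T0 replicate r is paired with T10 replicate r when
    both exist; unpaired T10 replicates are matched to the T0 mean proportion.

    Returns a DataFrame indexed by hairpin with MultiIndex columns
    (line, replicate).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    values = cm.values
    depths = values.sum(axis=0).astype(float)
    if (depths == 0).any():
        zero = list(depths.index[depths == 0])
        raise ValueError(f"zero column sum in samples {zero}")
    q = pseudocount / depths.mean()
    props = values / depths

    out = {}
    for line in cm.lines:
        t0 = cm.samples_for(line, "T0")
        t10 = cm.samples_for(line, "T10")
        rep_of = cm.sample_meta["replicate"]
        t0_by_rep = {int(rep_of[s]): s for s in t0}
        t0_mean = props[t0].mean(axis=1)
        for s10 in t10:
            rep = int(rep_of[s10])
            base = props[t0_by_rep[rep]] if rep in t0_by_rep else t0_mean
            out[(line, rep)] = np.log2((props[s10] + q) / (base + q))
    lfc = pd.DataFrame(out)
    lfc.columns = pd.MultiIndex.from_tuples(lfc.columns, names=["line", "replicate"])
    lfc.index.name = "hairpin_id"
    return lfc


def zscore_fit(log2fc_mean: pd.Series, robust: bool = True) -> pd.Series:
    """Gaussian z-scores of per-hairpin mean log2FC within one cell line.

    The Gaussian location/scale are fitted to the line's own log2FC
    distribution: robustly (median and 1.4826*MAD, default — dropout tails
    are heavy) or by moments.
    """
    x = log2fc_mean.astype(float)
    if len(x) < 2:
        raise ValueError("need at least 2 hairpins to fit a Gaussian")
    if robust:
        mu = float(x.median())
        sigma = 1.4826 * float((x - mu).abs().median())
    else:
        mu = float(x.mean())
        sigma = float(x.std(ddof=1))
    if sigma == 0 or not np.isfinite(sigma):
        raise ValueError("degenerate scale: log2FC distribution has zero spread")
    return (x - mu) / sigma


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def fit_variance_prior(s_sq: np.ndarray, d: int) -> VariancePrior:
    """Estimate (d0, s0^2) by matching moments of log s^2 to a scaled
    inverse-chi-square prior (via digamma/trigamma equations).

    Falls back to full pooling (d0 = inf) when the observed log-variance
    spread does not exceed the sampling spread.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() < 2:
        raise ValueError("all replicate variances are zero; cannot fit prior")
    z = np.log(s_sq[ok])
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        if not np.isfinite(d0):
            logger.warning("variance-prior d0 non-finite; pooling variances")
            d0 = math.inf
    else:
        d0 = math.inf
    if math.isinf(d0):
        s0 = math.exp(emean)
    else:
        s0 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return VariancePrior(d0=d0, s0_sq=s0, d=d)


def moderated_t(lfc_line: pd.DataFrame) -> tuple[pd.DataFrame, VariancePrior]:
    """Moderated one-sample t on replicate log2FCs of a single line.

    Input: hairpin x replicate log2FC. The hairpin variance is shrunk to
    s~^2 = (d0*s0^2 + d*s^2)/(d0 + d); t = mean / (s~/sqrt(n)); the p-value
    uses d0 + d degrees of freedom (standard normal when d0 = inf).
    """
    n = lfc_line.shape[1]
    if n < 2:
        raise ValueError("moderated t needs >= 2 replicates")
    mean = lfc_line.mean(axis=1)
    s_sq = lfc_line.var(axis=1, ddof=1)
    prior = fit_variance_prior(s_sq.to_numpy(), d=n - 1)
    post = prior.posterior_var(s_sq.to_numpy())
    t = mean.to_numpy() / np.sqrt(post / n)
    df_total = prior.d0 + prior.d
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {"log2fc": mean, "s_sq": s_sq, "s_tilde_sq": post, "t": t, "p": p},
        index=lfc_line.index,
    )
    return out, prior


def depletion_stats(
    cm, pseudocount: float = 0.5, robust_z: bool = True
) -> tuple[pd.DataFrame, dict[str, VariancePrior]]:
    """Full per-(hairpin, line) DepletionStat table.

    Returns a tidy DataFrame with columns hairpin_id, line, log2fc, t, p, z
    and the per-line variance priors.
    """
    lfc = normalize_log2fc(cm, pseudocount=pseudocount)
    frames = []
    priors: dict[str, VariancePrior] = {}
    for line in lfc.columns.get_level_values("line").unique():
        tab, prior = moderated_t(lfc[line])
        priors[line] = prior
        tab = tab[["log2fc", "t", "p"]].copy()
        tab["z"] = zscore_fit(tab["log2fc"], robust=robust_z)
        tab.insert(0, "line", line)
        frames.append(tab.reset_index())
    stats_df = pd.concat(frames, ignore_index=True)
    return stats_df, priors
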