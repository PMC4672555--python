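"""Synthetic inputs with planted ground truth for both analysis arcs.

The screen generator emulates a pooled shRNA dropout screen: a hairpin
library with a log-normal baseline representation is propagated over ten
population doublings, planted essential genes deplete multiplicatively
(abundance x 2**effect over the window), and sequencing counts are drawn
from a negative-binomial around expected proportion x depth.

The expression generator emulates a tumor compendium containing one hub
regulator whose latent *activity* differs between two sample groups while
its own mRNA does not: direct targets carry signed linear effects of the
latent activity, chain genes are downstream of targets only (so indirect
hub-chain correlations exist and should be pruned by the data-processing
inequality), and the remaining genes are noise.

All generators are pure functions of their config, including the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimScreenConfig",
    "SimExprConfig",
    "PlantedTruth",
    "default_line_groups",
    "gen_library",
    "gen_screen",
    "gen_fastq",
    "gen_expression",
    "gen_gene_sets",
    "library_representation",
]

GROUP_IBC = "IBC"
GROUP_NONIBC = "nonIBC"
GROUP_NT = "nonTransformed"
_VALID_GROUPS = {GROUP_IBC, GROUP_NONIBC, GROUP_NT}


def default_line_groups() -> dict[str, str]:
    """An 8-line desk-scale panel: 2 IBC, 4 non-IBC (two subtypes), 2 non-transformed."""
    return {
        "IBC1": GROUP_IBC,
        "IBC2": GROUP_IBC,
        "LUM1": GROUP_NONIBC,
        "LUM2": GROUP_NONIBC,
        "BAS1": GROUP_NONIBC,
        "BAS2": GROUP_NONIBC,
        "NT1": GROUP_NT,
        "NT2": GROUP_NT,
    }


def default_subtypes() -> dict[str, str]:
    return {"LUM1": "luminal", "LUM2": "luminal", "BAS1": "basal", "BAS2": "basal"}


@dataclass
class SimScreenConfig:
    """Design of a synthetic pooled dropout screen.

    Effects are log2 depletion over the full T0→T10 window (ten doublings);
    an effect of -2 means the hairpin's relative abundance drops fourfold.
    """

    n_genes: int = 2000
    hairpins_per_gene: int = 3
    line_groups: dict[str, str] = field(default_factory=default_line_groups)
    subtype_map: dict[str, str] = field(default_factory=default_subtypes)
    n_replicates: int = 3
    depth: float = 2e6
    baseline_loc: float = 0.0
    baseline_scale: float = 1.0
    nb_dispersion: float = 0.01
    effect_general: float = -2.0
    effect_subtype: float = -2.0
    effect_ibc: float = -2.0
    frac_general: float = 0.05
    frac_subtype: float = 0.05
    frac_ibc: float = 0.015
    guide_len: int = 22
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "hairpins_per_gene", "n_replicates", "guide_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        fr = self.frac_general + self.frac_subtype + self.frac_ibc
        if not (0 <= fr <= 1):
            raise ValueError("planted fractions must be in [0, 1] and sum to <= 1")
        if not self.line_groups:
            raise ValueError("line_groups must be non-empty")
        bad = set(self.line_groups.values()) - _VALID_GROUPS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def lines(self) -> list[str]:
        return sorted(self.line_groups)


@dataclass
class SimExprConfig:
    """Design of a synthetic expression compendium with a planted hub regulator.

    ``hub_activity_shift`` is the standardized mean difference of the latent
    activity between group A and group B; ``hub_mrna_shift`` is the same for
    the hub's own mRNA (default 0: activity differs, expression does not).
    ``target_effect_range`` gives the magnitude range of the signed linear
    coefficients linking latent activity to direct-target expression; signs
    are drawn at random per target.
    """

    n_genes: int = 500
    n_per_group: int = 40
    hub_id: str = "HUB"
    n_targets: int = 30
    target_effect_range: tuple[float, float] = (0.6, 1.4)
    chain_depth: int = 1
    chain_coef: float = 0.8
    hub_activity_shift: float = 1.5
    hub_mrna_shift: float = 0.0
    noise_sd: float = 1.0
    hub_obs_noise_sd: float = 0.3
    n_compendium_per_group: int = 150
    seed: int = 0
    group_labels: tuple[str, str] = ("A", "B")

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_targets < 0 or self.chain_depth < 0:
            raise ValueError("n_targets and chain_depth must be >= 0")
        n_structured = 1 + self.n_targets * (1 + self.chain_depth)
        if self.n_genes < n_structured:
            raise ValueError(
                f"n_genes={self.n_genes} too small for hub + targets + chain genes "
                f"({n_structured})"
            )
        lo, hi = self.target_effect_range
        if lo < 0 or hi < lo:
            raise ValueError("target_effect_range must be 0 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, used to score recovery.

    ``essential_map`` maps gene id -> set of cell lines where the gene is a
    planted essential. ``regulon_truth`` maps direct-target gene -> sign of
    its planted coefficient. ``group_activity`` maps sample -> latent hub
    activity value.
    """

    essential_map: dict[str, set[str]] = field(default_factory=dict)
    regulon_truth: dict[str, float] = field(default_factory=dict)
    group_activity: dict[str, float] = field(default_factory=dict)

    def essential_in(self, line: str) -> set[str]:
        return {g for g, lines in self.essential_map.items() if line in lines}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "essential_map": {g: sorted(v) for g, v in self.essential_map.items()},
            "regulon_truth": self.regulon_truth,
            "group_activity": self.group_activity,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            essential_map={g: set(v) for g, v in d["essential_map"].items()},
            regulon_truth=dict(d["regulon_truth"]),
            group_activity=dict(d["group_activity"]),
        )


def library_representation(n_cells: float, n_hairpins: int) -> float:
    """Cells per library hairpin — the fold representation of the pool.

    A pool of 70e6 cells over a 58,493-hairpin library gives ~1000x coverage,
    the scale needed so that stochastic loss of hairpins does not masquerade
    as depletion.
    """
    if n_hairpins <= 0:
        raise ValueError("n_hairpins must be > 0")
    return n_cells / n_hairpins


# ---------------------------------------------------------------------------
# library


def gen_library(cfg: SimScreenConfig, max_retries: int = 20) -> pd.DataFrame:
    """Generate a hairpin library table (hairpin_id, gene_id, guide_seq).

    Guides are uniform random sequences over {A,C,G,T} of fixed length;
    duplicates are redrawn up to ``max_retries`` rounds before failing.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes * cfg.hairpins_per_gene
    digits_g = len(str(cfg.n_genes))
    genes = [f"G{i + 1:0{digits_g}d}" for i in range(cfg.n_genes)]
    records = {
        "hairpin_id": [
            f"{g}_sh{j + 1}" for g in genes for j in range(cfg.hairpins_per_gene)
        ],
        "gene_id": np.repeat(genes, cfg.hairpins_per_gene),
    }
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    seqs = rng.integers(0, 4, size=(n, cfg.guide_len))
    guide = [bytes(alphabet[row]).decode() for row in seqs]
    for _ in range(max_retries):
        dup = pd.Index(guide).duplicated()
        if not dup.any():
            break
        redraw = rng.integers(0, 4, size=(int(dup.sum()), cfg.guide_len))
        for pos, row in zip(np.flatnonzero(dup), redraw):
            guide[pos] = bytes(alphabet[row]).decode()
    else:
        raise RuntimeError(
            f"could not draw {n} unique guide sequences of length {cfg.guide_len} "
            f"after {max_retries} retries"
        )
    records["guide_seq"] = guide
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# screen counts


def _planted_effects(cfg: SimScreenConfig, genes: Sequence[str], rng) -> tuple[np.ndarray, dict]:
    """Log2-effect matrix (gene x line) and the essential_map ground truth."""
    lines = cfg.lines
    n_gen = int(round(cfg.frac_general * len(genes)))
    n_sub = int(round(cfg.frac_subtype * len(genes)))
    n_ibc = int(round(cfg.frac_ibc * len(genes)))
    order = rng.permutation(len(genes))
    idx_gen = order[:n_gen]
    idx_sub = order[n_gen : n_gen + n_sub]
    idx_ibc = order[n_gen + n_sub : n_gen + n_sub + n_ibc]

    subtypes = sorted(set(cfg.subtype_map.values())) if cfg.subtype_map else []
    effect = np.zeros((len(genes), len(lines)))
    essential_map: dict[str, set[str]] = {}
    line_idx = {ln: j for j, ln in enumerate(lines)}

    for gi in idx_gen:
        effect[gi, :] = cfg.effect_general
        essential_map[genes[gi]] = set(lines)
    for k, gi in enumerate(idx_sub):
        if not subtypes:
            break
        st = subtypes[k % len(subtypes)]
        st_lines = [ln for ln, s in cfg.subtype_map.items() if s == st]
        for ln in st_lines:
            effect[gi, line_idx[ln]] = cfg.effect_subtype
        essential_map[genes[gi]] = set(st_lines)
    ibc_lines = [ln for ln in lines if cfg.line_groups[ln] == GROUP_IBC]
    for gi in idx_ibc:
        for ln in ibc_lines:
            effect[gi, line_idx[ln]] = cfg.effect_ibc
        essential_map[genes[gi]] = set(ibc_lines)
    return effect, essential_map


def _nb_sample(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion*mean^2); Poisson at dispersion 0."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_screen(
    cfg: SimScreenConfig, library: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate hairpin counts for every (line, timepoint, replicate).

    Returns ``(counts, sample_meta, truth)``: counts is hairpin x sample,
    sample_meta has one row per sample (line, group, timepoint, replicate).
    The expected T10 abundance of a hairpin is its T0 abundance times
    2**effect, renormalized so every sample sums to the sequencing depth.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes = list(dict.fromkeys(library["gene_id"]))
    gene_pos = {g: i for i, g in enumerate(genes)}
    hp_gene = library["gene_id"].map(gene_pos).to_numpy()

    effect, essential_map = _planted_effects(cfg, genes, rng)

    w = rng.lognormal(cfg.baseline_loc, cfg.baseline_scale, size=len(library))
    p0 = w / w.sum()

    cols, col_meta = [], []
    data = {}
    for line in cfg.lines:
        eff_hp = effect[hp_gene, cfg.lines.index(line)]
        p10 = p0 * np.exp2(eff_hp)
        p10 = p10 / p10.sum()
        for tp, props in (("T0", p0), ("T10", p10)):
            for rep in range(1, cfg.n_replicates + 1):
                sample = f"{line}_{tp}_r{rep}"
                data[sample] = _nb_sample(rng, props * cfg.depth, cfg.nb_dispersion)
                cols.append(sample)
                col_meta.append(
                    {
                        "sample": sample,
                        "line": line,
                        "group": cfg.line_groups[line],
                        "timepoint": tp,
                        "replicate": rep,
                    }
                )
    counts = pd.DataFrame(data, index=pd.Index(library["hairpin_id"], name="hairpin_id"))
    meta = pd.DataFrame(col_meta).set_index("sample")
    return counts, meta, PlantedTruth(essential_map=essential_map)


# ---------------------------------------------------------------------------
# FASTQ

DEFAULT_FLANK5 = "TAGTGAAGCCACAGATGTA"
DEFAULT_FLANK3 = "TGCCTACTGCCTCGGACTTCAAGGGGCTACTTTAGGAGCAATTATCTTGTTT"


def gen_fastq(
    counts: pd.DataFrame,
    library: pd.DataFrame,
    out_dir: str | Path,
    read_len: int = 50,
    flank5: str = DEFAULT_FLANK5,
    flank3: str = DEFAULT_FLANK3,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write one FASTQ per sample; each read embeds a guide between fixed flanks.

    Per-hairpin read counts equal the count matrix exactly before error
    injection; substitution errors are applied per base at ``error_rate``.
    Returns a mapping sample -> FASTQ path. Samples with zero total count get
    an empty file.
    """
    guide_len = len(library["guide_seq"].iloc[0])
    if read_len < guide_len:
        raise ValueError(f"read_len={read_len} shorter than guide length {guide_len}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    lib = library.set_index("hairpin_id")
    templates = {}
    for hp, row in lib.iterrows():
        t = flank5 + row["guide_seq"] + flank3
        if len(t) < read_len:
            t = t + "A" * (read_len - len(t))
        templates[hp] = t[:read_len]
    alphabet = np.array(list("ACGT"))
    qual = "I" * read_len
    paths: dict[str, Path] = {}
    for sample in counts.columns:
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as fh:
            col = counts[sample]
            i = 0
            for hp, n in col.items():
                for _ in range(int(n)):
                    seq = templates[hp]
                    if error_rate > 0:
                        hits = np.flatnonzero(rng.random(read_len) < error_rate)
                        if hits.size:
                            arr = np.array(list(seq))
                            # substitute with a different base
                            shift = rng.integers(1, 4, size=hits.size)
                            base_idx = np.searchsorted(alphabet, arr[hits])
                            arr[hits] = alphabet[(base_idx + shift) % 4]
                            seq = "".join(arr)
                    fh.write(f"@{sample}:{i} {hp}\n{seq}\n+\n{qual}\n")
                    i += 1
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# expression compendium


def gen_expression(
    cfg: SimExprConfig, draw_id: int = 0, n_per_group: int | None = None,
    activity_shift: float | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate a genes x samples expression matrix with a planted hub regulon.

    Latent activity a = group shift + e, e ~ N(0,1). The hub's mRNA tracks
    only the within-group fluctuation e (plus noise), so between-group
    activity differences leave hub expression untouched unless
    ``hub_mrna_shift`` is nonzero. Direct targets respond to the full
    activity a with signed coefficients; chain genes respond only to their
    parent in the previous layer.

    The planted *structure* (which genes are targets, their signed
    coefficients) depends only on ``cfg.seed``: two draws with different
    ``draw_id`` share the same regulon ground truth but have independent
    noise and samples, emulating an inference compendium and a separate
    scoring cohort from the same underlying biology. ``n_per_group`` and
    ``activity_shift`` override the config for such alternative draws.
    """
    cfg.validate()
    struct_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, draw_id]))
    la, lb = cfg.group_labels
    n = cfg.n_per_group if n_per_group is None else n_per_group
    shift = cfg.hub_activity_shift if activity_shift is None else activity_shift
    samples = [f"{la}_{i + 1:03d}" for i in range(n)] + [
        f"{lb}_{i + 1:03d}" for i in range(n)
    ]
    grp_ind = np.r_[np.ones(n), np.zeros(n)]

    e = rng.normal(size=2 * n)
    activity = shift * grp_ind + e

    rows: dict[str, np.ndarray] = {}
    # The hub transcript tracks the within-group activity fluctuation e with
    # low observation noise (regulator mRNA must be an informative readout for
    # transcript-based network inference), but carries none of the
    # between-group activity shift unless hub_mrna_shift says so.
    rows[cfg.hub_id] = (
        cfg.hub_mrna_shift * grp_ind + e + cfg.hub_obs_noise_sd * rng.normal(size=2 * n)
    )

    lo, hi = cfg.target_effect_range
    signs = struct_rng.choice([-1.0, 1.0], size=cfg.n_targets)
    betas = signs * struct_rng.uniform(lo, hi, size=cfg.n_targets)
    regulon_truth: dict[str, float] = {}
    digits = len(str(max(cfg.n_targets, 1)))
    target_ids = [f"T{i + 1:0{digits}d}" for i in range(cfg.n_targets)]
    for tid, beta in zip(target_ids, betas):
        rows[tid] = beta * activity + cfg.noise_sd * rng.normal(size=2 * n)
        regulon_truth[tid] = float(np.sign(beta)) if beta != 0 else 0.0

    parents = target_ids
    for depth in range(1, cfg.chain_depth + 1):
        layer = []
        for pid in parents:
            cid = f"C{depth}_{pid}"
            rows[cid] = cfg.chain_coef * rows[pid] + cfg.noise_sd * rng.normal(size=2 * n)
            layer.append(cid)
        parents = layer

    n_decoys = cfg.n_genes - len(rows)
    digits_d = len(str(max(n_decoys, 1)))
    for i in range(n_decoys):
        rows[f"N{i + 1:0{digits_d}d}"] = rng.normal(size=2 * n)

    expr = pd.DataFrame(rows, index=pd.Index(samples, name="sample")).T
    expr.index.name = "gene_id"
    truth = PlantedTruth(
        regulon_truth=regulon_truth,
        group_activity={s: float(a) for s, a in zip(samples, activity)},
    )
    return expr, truth


# ---------------------------------------------------------------------------
# gene sets


def gen_gene_sets(
    universe: Sequence[str],
    planted_set: set[str] | Sequence[str],
    n_decoys: int = 20,
    sizes: tuple[int, int] = (10, 50),
    seed: int = 0,
    planted_name: str = "planted",
) -> dict[str, list[str]]:
    """A GMT-style collection: the planted set plus uniform-random decoy sets."""
    planted = sorted(set(planted_set))
    uni = list(dict.fromkeys(universe))
    missing = set(planted) - set(uni)
    if missing:
        raise ValueError(f"planted genes outside universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    collection = {planted_name: planted}
    lo, hi = sizes
    for i in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(uni), size=size, replace=False)
        collection[f"decoy_{i + 1:03d}"] = sorted(uni[j] for j in members)
    return collection


def config_to_dict(cfg) -> dict:
    """Round-trippable plain-dict form of a config dataclass."""
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
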