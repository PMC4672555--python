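"""File formats of the screen arc and FASTQ → hairpin-count deconvolution.

The deconvolution rule: for each read, every library guide is scored at
every ungapped offset; the unique best-scoring guide with at most
``max_mismatch`` mismatches is the primary read and increments its hairpin's
count. Reads whose best score is shared by two or more distinct hairpins are
marked ambiguous and not utilized; reads with no qualifying guide are
unmapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "DeconvolutionReport",
    "read_library",
    "write_library",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "deconvolve_reads",
]

_LIB_COLUMNS = ["hairpin_id", "gene_id", "guide_seq"]
_GUIDE_ALPHABET = set("ACGT")
_META_COLUMNS = ["line", "group", "timepoint", "replicate"]


@dataclass
class CountMatrix:
    """Hairpin x sample integer counts plus per-sample metadata.

    ``values``: DataFrame indexed by hairpin_id, one column per sample.
    ``sample_meta``: DataFrame indexed by sample with columns line, group,
    timepoint (T0/T10) and replicate.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def validate(self, library: pd.DataFrame | None = None) -> "CountMatrix":
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        for col in _META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        bad_tp = set(self.sample_meta["timepoint"]) - {"T0", "T10"}
        if bad_tp:
            raise ValueError(f"timepoint must be T0/T10, got {sorted(bad_tp)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative counts")
        meta = self.sample_meta.loc[list(self.values.columns)]
        for line, sub in meta.groupby("line"):
            tps = set(sub["timepoint"])
            if tps != {"T0", "T10"}:
                raise ValueError(f"line {line} lacks both timepoints (has {sorted(tps)})")
        if library is not None:
            unknown = set(self.values.index) - set(library["hairpin_id"])
            if unknown:
                raise ValueError(
                    f"count rows not in library: {sorted(unknown)[:5]} ..."
                )
        return self

    def samples_for(self, line: str, timepoint: str) -> list[str]:
        m = self.sample_meta
        sel = m[(m["line"] == line) & (m["timepoint"] == timepoint)]
        return list(sel.sort_values("replicate").index)

    @property
    def lines(self) -> list[str]:
        return sorted(set(self.sample_meta.loc[self.values.columns, "line"]))

    def group_of(self, line: str) -> str:
        g = self.sample_meta.loc[self.sample_meta["line"] == line, "group"].unique()
        if len(g) != 1:
            raise ValueError(f"line {line} maps to multiple groups: {list(g)}")
        return str(g[0])

    def line_groups(self) -> dict[str, str]:
        return {ln: self.group_of(ln) for ln in self.lines}


@dataclass
class DeconvolutionReport:
    """Read-assignment bookkeeping for a deconvolution run."""

    n_reads: int = 0
    n_assigned: int = 0
    n_ambiguous: int = 0
    n_unmapped: int = 0
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def assigned_fraction(self) -> float:
        return self.n_assigned / self.n_reads if self.n_reads else float("nan")

    def check(self) -> None:
        if self.n_assigned + self.n_ambiguous + self.n_unmapped != self.n_reads:
            raise AssertionError("read categories do not sum to n_reads")

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_assigned": self.n_assigned,
            "n_ambiguous": self.n_ambiguous,
            "n_unmapped": self.n_unmapped,
            "assigned_fraction": self.assigned_fraction,
            "per_sample": self.per_sample,
        }


# ---------------------------------------------------------------------------
# library / counts TSV


def read_library(path: str | Path) -> pd.DataFrame:
    """Read and validate a library TSV (hairpin_id, gene_id, guide_seq)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _LIB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        lineno = i + 2  # 1-based, after header
        if row.isna().any():
            raise ValueError(f"{path}: malformed row at line {lineno}")
        bad = set(row["guide_seq"]) - _GUIDE_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: guide of hairpin {row['hairpin_id']} (line {lineno}) "
                f"contains invalid characters {sorted(bad)}"
            )
    dup = df["hairpin_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate hairpin ids: {sorted(df.loc[dup, 'hairpin_id'])[:5]}"
        )
    if len(df) == 0:
        logger.warning("%s: library file is empty (header only)", path)
    elif df["guide_seq"].str.len().nunique() > 1:
        raise ValueError(f"{path}: guide sequences have mixed lengths")
    return df.reset_index(drop=True)


def write_library(library: pd.DataFrame, path: str | Path) -> None:
    library[_LIB_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read counts TSV (index hairpin_id) + sample-metadata TSV into a CountMatrix.

    Integral float counts ("3.0") are accepted; fractional counts are an error.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    arr = values.to_numpy()
    if not np.allclose(arr, np.round(arr), atol=0, rtol=0):
        bad = values.columns[np.where(arr != np.round(arr))[1][0]]
        raise ValueError(f"{path}: non-integer counts (e.g. in sample {bad})")
    values = values.round().astype(np.int64)
    if (values.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    cm = CountMatrix(values=values, sample_meta=meta)
    cm.validate()
    return cm


def write_counts(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    cm.values.to_csv(path, sep="\t")
    cm.sample_meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
        name, _desc, *members = parts
        if name in sets:
            raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
        sets[name] = [m for m in members if m]
    return sets


def write_gmt(collection: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# deconvolution


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _best_assignment(
    read: str,
    guides: np.ndarray,
    guide_len: int,
    min_score: int,
) -> tuple[np.ndarray, int]:
    """Indices of guides achieving the best qualifying score, and that score."""
    r = _encode(read)
    n_off = len(r) - guide_len + 1
    if n_off <= 0:
        return np.empty(0, dtype=int), -1
    windows = np.lib.stride_tricks.sliding_window_view(r, guide_len)
    # guides: (G, L); windows: (n_off, L) → scores (G, n_off)
    scores = (guides[:, None, :] == windows[None, :, :]).sum(axis=2)
    best_per_guide = scores.max(axis=1)
    best = int(best_per_guide.max())
    if best < min_score:
        return np.empty(0, dtype=int), best
    return np.flatnonzero(best_per_guide == best), best


def deconvolve_reads(
    fastq_paths: Mapping[str, str | Path],
    library: pd.DataFrame,
    max_mismatch: int = 1,
    revcomp: bool = False,
) -> tuple[pd.DataFrame, DeconvolutionReport]:
    """Assign reads to hairpins; returns (counts hairpin x sample, report).

    Ties across distinct hairpins at the best score are ambiguous; the same
    guide matching at several offsets is a single assignment. By default only
    the given strand is searched; ``revcomp=True`` also searches the reverse
    complement of each read.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    guide_len = len(library["guide_seq"].iloc[0])
    guides = np.stack([_encode(g) for g in library["guide_seq"]])
    min_score = guide_len - max_mismatch
    hairpins = library["hairpin_id"].to_numpy()
    exact = {g: i for i, g in enumerate(library["guide_seq"])}

    comp = str.maketrans("ACGTN", "TGCAN")
    counts = pd.DataFrame(
        0,
        index=pd.Index(hairpins, name="hairpin_id"),
        columns=list(fastq_paths),
        dtype=np.int64,
    )
    report = DeconvolutionReport()
    for sample, path in fastq_paths.items():
        col = np.zeros(len(hairpins), dtype=np.int64)
        n_reads = n_assigned = n_ambig = n_unmapped = 0
        try:
            records = SeqIO.parse(str(path), "fastq")
            for rec in records:
                n_reads += 1
                read = str(rec.seq).upper()
                variants = [read]
                if revcomp:
                    variants.append(read.translate(comp)[::-1])
                # fast path: unique exact substring hit
                hit_idx: set[int] = set()
                exact_hit = False
                for var in variants:
                    for off in range(len(var) - guide_len + 1):
                        j = exact.get(var[off : off + guide_len])
                        if j is not None:
                            hit_idx.add(j)
                            exact_hit = True
                if exact_hit:
                    # an exact hit outranks any mismatched guide, so ties can
                    # only be other exact hits — skip the full scan
                    idx, best = np.array(sorted(hit_idx)), guide_len
                else:
                    idx_all, best = np.empty(0, dtype=int), -1
                    for var in variants:
                        ii, b = _best_assignment(var, guides, guide_len, min_score)
                        if b > best:
                            idx_all, best = ii, b
                        elif b == best and b >= min_score:
                            idx_all = np.union1d(idx_all, ii)
                    idx = idx_all
                if best < min_score or len(idx) == 0:
                    n_unmapped += 1
                elif len(idx) > 1:
                    n_ambig += 1
                else:
                    col[idx[0]] += 1
                    n_assigned += 1
        except ValueError as exc:
            raise ValueError(
                f"{path}: unreadable FASTQ record near read {n_reads + 1}: {exc}"
            ) from exc
        counts[sample] = col
        report.n_reads += n_reads
        report.n_assigned += n_assigned
        report.n_ambiguous += n_ambig
        report.n_unmapped += n_unmapped
        report.per_sample[sample] = {
            "n_reads": n_reads,
            "n_assigned": n_assigned,
            "n_ambiguous": n_ambig,
            "n_unmapped": n_unmapped,
        }
    report.check()
    return counts, report
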