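"""Per-base coverage and tiling-window normalization.

Coverage is the number of aligned reads overlapping a base.  Chromosomes
are tiled into non-overlapping windows of a fixed width (the last window
may be short); the window value is the *sum* of per-base depths inside
the window.  Two normalizations are provided:

``per_chromosome``
    window value divided by the total window coverage of that sample on
    that chromosome, so windows of one sample on one chromosome sum to 1
    — the form used for the genome-wide enrichment screen.

``genome_wide``
    window value divided by the sample's total coverage over *all*
    chromosomes (mitochondrial included) — the form used to express
    mitochondrial enrichment relative to the whole sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from netome.seqio import AlignedRead

__all__ = [
    "CoverageTrack",
    "WindowTable",
    "compute_coverage",
    "window_coverage",
    "normalize_per_chromosome",
    "normalize_genome_wide",
    "gene_sample_vs_mean",
    "write_window_table",
]

WINDOW_SIZES = (20, 100, 500, 5000)


@dataclass
class CoverageTrack:
    """Integer read-depth arrays for one sample, one per chromosome."""

    sample: str
    depths: dict[str, np.ndarray]
    n_reads: dict[str, int] = field(default_factory=dict)
    n_filtered: int = 0  # reads dropped by the MAPQ floor

    @property
    def chrom_totals(self) -> dict[str, int]:
        return {c: int(d.sum()) for c, d in self.depths.items()}

    @property
    def genome_total(self) -> int:
        return sum(self.chrom_totals.values())

    def mean_depth(self, chrom: str) -> float:
        d = self.depths[chrom]
        return float(d.mean()) if d.size else 0.0


def compute_coverage(
    alignments: Iterable[AlignedRead],
    chrom_lengths: dict[str, int],
    sample: str,
    min_mapq: int = 0,
) -> CoverageTrack:
    """Pile alignments into per-base depth via a difference array.

    ``depth[p]`` counts reads whose half-open interval contains ``p``.
    Reads below ``min_mapq`` are excluded and counted.  A read extending
    past its chromosome end is an error.
    """
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_lengths.items()}
    n_reads: dict[str, int] = {c: 0 for c in chrom_lengths}
    n_filtered = 0
    for a in alignments:
        if a.chrom not in diffs:
            raise ValueError(f"read {a.name} on unknown chromosome {a.chrom}")
        if a.end > chrom_lengths[a.chrom]:
            raise ValueError(
                f"read {a.name} extends past the end of {a.chrom} "
                f"({a.end} > {chrom_lengths[a.chrom]})"
            )
        if a.mapq < min_mapq:
            n_filtered += 1
            continue
        diffs[a.chrom][a.start] += 1
        diffs[a.chrom][a.end] -= 1
        n_reads[a.chrom] += 1
    depths = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return CoverageTrack(sample=sample, depths=depths, n_reads=n_reads,
                         n_filtered=n_filtered)


@dataclass
class WindowTable:
    """Window grid x samples with raw or normalized coverage values.

    ``data`` has columns ``chrom``, ``start``, ``end`` followed by one
    column per sample.  ``mode`` is one of ``raw``, ``per_chromosome``,
    ``genome_wide``.  Normalized tables keep the raw genome totals so the
    genome-wide fraction can be audited.
    """

    w: int
    mode: str
    data: pd.DataFrame
    samples: list[str]
    pseudocount: float = 0.0
    genome_totals: dict[str, float] = field(default_factory=dict)

    def values(self, sample: str) -> np.ndarray:
        return self.data[sample].to_numpy()


def _window_starts(length: int, w: int) -> np.ndarray:
    return np.arange(0, length, w, dtype=np.int64)


def window_coverage(
    tracks: Sequence[CoverageTrack] | CoverageTrack, w: int
) -> WindowTable:
    """Tile every chromosome into windows of width ``w`` and sum depths.

    Windows are ``[i*w, min((i+1)*w, L))``; a read spanning a boundary
    contributes each overlapped base to its own window.
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    if not tracks:
        raise ValueError("no coverage tracks given")
    chroms = list(tracks[0].depths)
    for t in tracks[1:]:
        if list(t.depths) != chroms or any(
            t.depths[c].size != tracks[0].depths[c].size for c in chroms
        ):
            raise ValueError("tracks disagree on chromosomes or lengths")

    frames = []
    for chrom in chroms:
        length = tracks[0].depths[chrom].size
        starts = _window_starts(length, w)
        ends = np.minimum(starts + w, length)
        cols = {"chrom": chrom, "start": starts, "end": ends}
        for t in tracks:
            cols[t.sample] = np.add.reduceat(t.depths[chrom], starts)
        frames.append(pd.DataFrame(cols))
    data = pd.concat(frames, ignore_index=True)
    samples = [t.sample for t in tracks]
    totals = {t.sample: float(t.genome_total) for t in tracks}
    return WindowTable(w=w, mode="raw", data=data, samples=samples,
                       genome_totals=totals)


def normalize_per_chromosome(wt: WindowTable, pseudocount: float = 0.0) -> WindowTable:
    """Divide each window by that sample's total on that chromosome.

    value <- (raw + pseudocount) / sum over the chromosome's windows of
    (raw + pseudocount).  Chromosomes with zero total and zero
    pseudocount yield NaN (absent; excluded downstream).
    """
    if wt.mode != "raw":
        raise ValueError("normalize_per_chromosome expects a raw table")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    data = wt.data.copy()
    for s in wt.samples:
        v = data[s].to_numpy(dtype=float) + pseudocount
        denom = pd.Series(v).groupby(data["chrom"], sort=False).transform("sum")
        denom = denom.to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            data[s] = np.where(denom > 0, v / denom, np.nan)
    return WindowTable(w=wt.w, mode="per_chromosome", data=data,
                       samples=list(wt.samples), pseudocount=pseudocount,
                       genome_totals=dict(wt.genome_totals))


def normalize_genome_wide(wt: WindowTable, pseudocount: float = 0.0) -> WindowTable:
    """Divide each window by the sample's total coverage over the genome."""
    if wt.mode != "raw":
        raise ValueError("normalize_genome_wide expects a raw table")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    data = wt.data.copy()
    for s in wt.samples:
        total = float(wt.data[s].sum())
        if total <= 0:
            raise ValueError(f"sample {s} has zero genome-wide coverage")
        data[s] = (data[s].to_numpy(dtype=float) + pseudocount) / total
    return WindowTable(w=wt.w, mode="genome_wide", data=data,
                       samples=list(wt.samples), pseudocount=pseudocount,
                       genome_totals=dict(wt.genome_totals))


def gene_sample_vs_mean(values: Sequence[float]) -> tuple[float, ...] | None:
    """Per-sample coverage of one gene divided by the three-sample mean.

    A visualization-only rescaling: each of exactly three per-sample
    values is divided by their average.  All-zero input returns ``None``
    (gene excluded from plots).
    """
    if len(values) != 3:
        raise ValueError("gene_sample_vs_mean expects exactly 3 samples")
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("coverage values must be >= 0")
    m = v.mean()
    if m == 0:
        return None
    return tuple(float(x) for x in v / m)


def write_window_table(path, wt: WindowTable) -> None:
    """Serialize a window table as long-format TSV (bedGraph-like)."""
    long = wt.data.melt(
        id_vars=["chrom", "start", "end"], value_vars=wt.samples,
        var_name="sample", value_name="value",
    )
    long["mode"] = wt.mode
    long["w"] = wt.w
    long.to_csv(path, sep="\t", index=False)
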