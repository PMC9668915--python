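"""Genome-wide enrichment/depletion screen over normalized windows.

For every window and every choice of focal sample among the three, the
focal sample's normalized value is compared with the other two under two
criteria: *simultaneous* (at least ``cutoff``-fold against each other
sample individually) and *vs_average* (at least ``cutoff``-fold against
the mean of the other two).  Depletion is the reciprocal condition.
Consecutive flagged windows with the same focal sample and direction are
merged into regions, which are then intersected with gene and exon
annotation and with external gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from netome.coverage import WindowTable, gene_sample_vs_mean
from netome.seqio import GeneInterval

__all__ = [
    "EnrichmentCall",
    "Region",
    "fold_change_screen",
    "merge_regions",
    "overlap_genes",
    "roi_profile",
    "expression_overlap",
    "default_ratio_pseudocount",
]


@dataclass(frozen=True)
class EnrichmentCall:
    """One window flagged enriched or depleted for one focal sample."""

    sample: str
    chrom: str
    start: int
    end: int
    direction: str  # "enriched" | "depleted"
    fold_vs_each: float  # min over others (enriched) / max (depleted)
    fold_vs_average: float
    criterion: str  # "simultaneous" | "vs_average" | "both"


@dataclass(frozen=True)
class Region:
    """A maximal run of consecutive same-direction windows for one sample."""

    sample: str
    direction: str
    chrom: str
    start: int
    end: int
    n_windows: int
    best_fold: float


def default_ratio_pseudocount(wt: WindowTable) -> float:
    """Half the smallest positive normalized value in the table."""
    vals = wt.data[wt.samples].to_numpy(dtype=float)
    pos = vals[np.isfinite(vals) & (vals > 0)]
    if pos.size == 0:
        return 1e-12
    return float(pos.min()) / 2.0


def fold_change_screen(
    wt: WindowTable,
    cutoff: float = 1.5,
    ratio_pseudocount: float | None = None,
    criterion: str = "either",
) -> list[EnrichmentCall]:
    """Flag windows where one sample stands >= ``cutoff``-fold apart.

    Runs on per-chromosome-normalized values for exactly three samples.
    ``criterion`` selects which of the two comparison rules must hold:
    ``simultaneous``, ``vs_average``, or ``either`` (their union; the
    rule actually satisfied is recorded on each call).  Windows with an
    absent value in any sample are skipped.
    """
    if wt.mode != "per_chromosome":
        raise ValueError("screen runs on per-chromosome normalized windows")
    if len(wt.samples) != 3:
        raise ValueError(f"screen requires exactly 3 samples, got {len(wt.samples)}")
    if cutoff <= 1:
        raise ValueError("cutoff must be > 1")
    if criterion not in {"simultaneous", "vs_average", "either"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    pc = (
        default_ratio_pseudocount(wt)
        if ratio_pseudocount is None
        else float(ratio_pseudocount)
    )
    if pc < 0:
        raise ValueError("ratio pseudocount must be >= 0")

    vals = {s: wt.data[s].to_numpy(dtype=float) for s in wt.samples}
    valid = np.all(np.isfinite(np.column_stack(list(vals.values()))), axis=1)
    chroms = wt.data["chrom"].to_numpy()
    starts = wt.data["start"].to_numpy()
    ends = wt.data["end"].to_numpy()

    calls: list[EnrichmentCall] = []
    for focal in wt.samples:
        others = [s for s in wt.samples if s != focal]
        f = vals[focal] + pc
        oa, ob = vals[others[0]] + pc, vals[others[1]] + pc
        r_a, r_b = f / oa, f / ob
        r_min = np.minimum(r_a, r_b)
        r_max = np.maximum(r_a, r_b)
        r_avg = f / ((vals[others[0]] + vals[others[1]]) / 2.0 + pc)

        enr_sim = r_min >= cutoff
        dep_sim = r_max <= 1.0 / cutoff
        enr_avg = r_avg >= cutoff
        dep_avg = r_avg <= 1.0 / cutoff
        if criterion == "simultaneous":
            enr, dep = enr_sim, dep_sim
        elif criterion == "vs_average":
            enr, dep = enr_avg, dep_avg
        else:
            enr, dep = enr_sim | enr_avg, dep_sim | dep_avg

        for direction, mask, sim_mask, avg_mask, fold_each in (
            ("enriched", enr, enr_sim, enr_avg, r_min),
            ("depleted", dep, dep_sim, dep_avg, r_max),
        ):
            for i in np.flatnonzero(mask & valid):
                sim, avg = bool(sim_mask[i]), bool(avg_mask[i])
                crit = "both" if sim and avg else ("simultaneous" if sim else "vs_average")
                calls.append(
                    EnrichmentCall(
                        sample=focal,
                        chrom=str(chroms[i]),
                        start=int(starts[i]),
                        end=int(ends[i]),
                        direction=direction,
                        fold_vs_each=float(fold_each[i]),
                        fold_vs_average=float(r_avg[i]),
                        criterion=crit,
                    )
                )
    calls.sort(key=lambda c: (c.chrom, c.start, c.sample, c.direction))
    return calls


def merge_regions(calls: Iterable[EnrichmentCall]) -> list[Region]:
    """Merge maximal runs of adjacent windows sharing focal sample and
    direction (gap 0: each window must start where the previous ended)."""
    by_key: dict[tuple[str, str, str], list[EnrichmentCall]] = {}
    for c in calls:
        by_key.setdefault((c.sample, c.direction, c.chrom), []).append(c)
    regions: list[Region] = []
    for (sample, direction, chrom), group in by_key.items():
        group.sort(key=lambda c: c.start)
        run: list[EnrichmentCall] = []
        for c in group:
            if run and c.start == run[-1].end:
                run.append(c)
            else:
                if run:
                    regions.append(_close_run(sample, direction, chrom, run))
                run = [c]
        if run:
            regions.append(_close_run(sample, direction, chrom, run))
    regions.sort(key=lambda r: (r.chrom, r.start, r.sample, r.direction))
    return regions


def _close_run(sample: str, direction: str, chrom: str,
               run: list[EnrichmentCall]) -> Region:
    folds = [c.fold_vs_each for c in run]
    best = max(folds) if direction == "enriched" else min(folds)
    return Region(
        sample=sample, direction=direction, chrom=chrom,
        start=run[0].start, end=run[-1].end,
        n_windows=len(run), best_fold=float(best),
    )


def _annotation_trees(
    annotation: Sequence[GeneInterval],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in annotation:
        trees.setdefault((g.chrom, g.kind), IntervalTree()).addi(g.start, g.end, g)
    return trees


def overlap_genes(
    regions: Sequence[Region],
    annotation: Sequence[GeneInterval],
) -> pd.DataFrame:
    """Intersect regions with gene and exon features (>= 1 nt overlap).

    Returns one row per (region, feature) pair with the overlap length;
    gene- and exon-level hits are distinguished by the ``kind`` column.
    Regions on chromosomes absent from the annotation are skipped and
    counted in ``df.attrs["skipped_chromosomes"]``.
    """
    trees = _annotation_trees(annotation)
    annotated_chroms = {c for c, _ in trees}
    rows = []
    skipped: dict[str, int] = {}
    for r in regions:
        if r.chrom not in annotated_chroms:
            skipped[r.chrom] = skipped.get(r.chrom, 0) + 1
            continue
        for kind in ("gene", "exon"):
            tree = trees.get((r.chrom, kind))
            if tree is None:
                continue
            for hit in sorted(tree.overlap(r.start, r.end)):
                g: GeneInterval = hit.data
                rows.append(
                    {
                        "sample": r.sample,
                        "direction": r.direction,
                        "chrom": r.chrom,
                        "region_start": r.start,
                        "region_end": r.end,
                        "best_fold": r.best_fold,
                        "gene_id": g.gene_id,
                        "symbol": g.symbol,
                        "kind": kind,
                        "overlap_nt": min(r.end, g.end) - max(r.start, g.start),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample", "direction", "chrom", "region_start", "region_end",
            "best_fold", "gene_id", "symbol", "kind", "overlap_nt",
        ],
    )
    df.attrs["skipped_chromosomes"] = skipped
    return df


def roi_profile(
    gene_symbols: Iterable[str],
    wt: WindowTable,
    annotation: Sequence[GeneInterval],
    focal: str,
) -> pd.DataFrame:
    """Per-gene per-sample summary of normalized window coverage.

    For each resolvable gene symbol, the mean and max normalized window
    value across windows overlapping the gene body is reported per
    sample, plus the focal sample's value divided by the three-sample
    mean (the visualization rescaling).  Unresolvable symbols are listed
    in ``df.attrs["unresolved"]``; an empty resolvable set is an error.
    """
    if wt.mode != "per_chromosome":
        raise ValueError("roi_profile expects per-chromosome normalized windows")
    if focal not in wt.samples:
        raise ValueError(f"focal sample {focal!r} not in window table")
    genes = {
        g.symbol.casefold(): g for g in annotation if g.kind == "gene"
    }
    wanted = [s.strip() for s in gene_symbols if s.strip()]
    resolved = [(s, genes[s.casefold()]) for s in wanted if s.casefold() in genes]
    unresolved = [s for s in wanted if s.casefold() not in genes]
    if not resolved:
        raise ValueError("none of the requested gene symbols resolve in the annotation")

    chroms = wt.data["chrom"].to_numpy()
    starts = wt.data["start"].to_numpy()
    ends = wt.data["end"].to_numpy()
    rows = []
    for symbol, g in resolved:
        mask = (chroms == g.chrom) & (starts < g.end) & (ends > g.start)
        row: dict[str, object] = {
            "symbol": symbol, "chrom": g.chrom, "start": g.start, "end": g.end,
        }
        means = []
        for s in wt.samples:
            v = wt.data.loc[mask, s].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            row[f"{s}_mean"] = float(v.mean()) if v.size else np.nan
            row[f"{s}_max"] = float(v.max()) if v.size else np.nan
            means.append(row[f"{s}_mean"])
        ratios = (
            gene_sample_vs_mean(means)
            if all(np.isfinite(m) for m in means)
            else None
        )
        fi = wt.samples.index(focal)
        if ratios is None:
            row["focal_vs_mean"] = np.nan
            row["focal_vs_others"] = np.nan
        else:
            row["focal_vs_mean"] = ratios[fi]
            others = [m for j, m in enumerate(means) if j != fi]
            om = float(np.mean(others))
            row["focal_vs_others"] = means[fi] / om if om > 0 else np.inf
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["unresolved"] = unresolved
    return df


def expression_overlap(
    hit_genes: Iterable[str],
    external_gene_list: Iterable[str],
) -> dict:
    """Set overlap between screen gene hits and an external expression list.

    Symbols are case-folded before comparison.  Returns the intersection
    and the two set differences with their counts.
    """
    hits = {g.strip().casefold() for g in hit_genes if g.strip()}
    external = {g.strip().casefold() for g in external_gene_list if g.strip()}
    if not external:
        raise ValueError("external gene list is empty")
    inter = sorted(hits & external)
    only_hits = sorted(hits - external)
    only_external = sorted(external - hits)
    return {
        "n_in_list": len(inter),
        "n_not_in_list": len(only_hits),
        "n_list_not_hit": len(only_external),
        "in_list": inter,
        "not_in_list": only_hits,
        "list_not_hit": only_external,
    }
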