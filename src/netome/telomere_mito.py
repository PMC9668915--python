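"""Telomeric repeat counting and mitochondrial enrichment.

Telomeric content is quantified by counting occurrences of the tandem
motif (default the 12-mer ``TTAGGGTTAGGG``) in read sequences, grouped
by the chromosome each read maps to, on both strands.  Mitochondrial
enrichment is the genome-wide-normalized coverage of MT windows: window
coverage on MT divided by the sample's total coverage over all
chromosomes.  Both feed a one-way ANOVA across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from netome.coverage import (
    CoverageTrack,
    normalize_genome_wide,
    window_coverage,
)
from netome.seqio import AlignedRead, revcomp
from netome.stats import TestResult, anova_oneway

__all__ = [
    "TELOMERE_MOTIF",
    "TelomereCountTable",
    "MitoEnrichment",
    "count_motif_in_sequence",
    "count_motif",
    "telomere_compare",
    "mito_enrichment",
]

TELOMERE_MOTIF = "TTAGGGTTAGGG"
_MT_NAMES = {"MT", "CHRM", "CHRMT", "M"}


def count_motif_in_sequence(seq: str, motif: str, mode: str = "non-overlapping") -> int:
    """Count motif occurrences in one sequence.

    Non-overlapping counting advances past each match; overlapping
    counting advances one base at a time.
    """
    if mode == "non-overlapping":
        return seq.count(motif)
    if mode == "overlapping":
        n = 0
        i = seq.find(motif)
        while i != -1:
            n += 1
            i = seq.find(motif, i + 1)
        return n
    raise ValueError(f"unknown counting mode {mode!r}")


@dataclass
class TelomereCountTable:
    """Motif occurrence counts per sample x chromosome.

    ``data`` columns: sample, chrom, reads, motif_count, per_million
    (motif_count / reads * 1e6; NaN where a chromosome received no
    reads).  Unmapped-read counts, when present in the input, are kept
    under the pseudo-chromosome ``*``.
    """

    motif: str
    mode: str
    both_strands: bool
    data: pd.DataFrame


def count_motif(
    alignments_by_sample: dict[str, Iterable[AlignedRead]],
    motif: str = TELOMERE_MOTIF,
    mode: str = "non-overlapping",
    both_strands: bool = True,
) -> TelomereCountTable:
    """Count a telomeric motif in read sequences, per sample and chromosome.

    Each read's occurrences are counted in its stored sequence and, when
    ``both_strands`` is set, in the reverse complement as well; totals
    accumulate on the chromosome the read maps to.
    """
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be non-empty uppercase ACGT, got {motif!r}")
    rc = revcomp(motif)
    rows = []
    for sample, alignments in alignments_by_sample.items():
        counts: dict[str, int] = {}
        reads: dict[str, int] = {}
        for a in alignments:
            chrom = a.chrom if a.chrom else "*"
            reads[chrom] = reads.get(chrom, 0) + 1
            if a.seq is None:
                continue
            seq = a.seq.upper()
            n = count_motif_in_sequence(seq, motif, mode)
            if both_strands:
                n += count_motif_in_sequence(seq, rc, mode)
            counts[chrom] = counts.get(chrom, 0) + n
        for chrom in sorted(reads):
            r = reads[chrom]
            c = counts.get(chrom, 0)
            rows.append(
                {
                    "sample": sample,
                    "chrom": chrom,
                    "reads": r,
                    "motif_count": c,
                    "per_million": c / r * 1e6 if r > 0 else np.nan,
                }
            )
    data = pd.DataFrame(
        rows, columns=["sample", "chrom", "reads", "motif_count", "per_million"]
    )
    return TelomereCountTable(motif=motif, mode=mode, both_strands=both_strands,
                              data=data)


def telomere_compare(
    table: TelomereCountTable,
    exclude_chroms: Sequence[str] | None = None,
) -> TestResult:
    """One-way ANOVA across samples on per-chromosome per-million counts.

    Per-chromosome per-million counts serve as replicates within each
    sample.  By default the mitochondrial chromosome (which carries no
    telomeric arrays) and unmapped reads are excluded; pass an explicit
    ``exclude_chroms`` (possibly empty) to override.
    """
    df = table.data
    if exclude_chroms is None:
        excl = {c for c in df["chrom"].unique() if c.upper() in _MT_NAMES} | {"*"}
    else:
        excl = set(exclude_chroms)
    df = df[~df["chrom"].isin(excl)].dropna(subset=["per_million"])
    groups = [g["per_million"].to_numpy() for _, g in df.groupby("sample", sort=True)]
    if len(groups) < 2:
        raise ValueError("telomere_compare needs at least 2 samples")
    if any(g.size < 2 for g in groups):
        raise ValueError("each sample needs >= 2 chromosomes with counts")
    return anova_oneway(*groups)


@dataclass
class MitoEnrichment:
    """Genome-wide-normalized MT window profile and per-sample summary."""

    w: int
    mt_name: str
    profile: pd.DataFrame  # chrom, start, end + one column per sample
    summary: dict[str, float]  # sample -> sum of normalized MT windows
    anova: TestResult


def mito_enrichment(
    tracks: Sequence[CoverageTrack],
    w: int = 500,
    mt_name: str = "MT",
) -> MitoEnrichment:
    """Mitochondrial enrichment by position and in summary.

    MT is tiled into ``w``-nt windows whose coverage is divided by each
    sample's total genome coverage (MT included in the denominator); the
    per-sample summary is the sum of those normalized windows, and an
    ANOVA across samples is run on the window values.
    """
    missing = [t.sample for t in tracks if mt_name not in t.depths]
    if missing:
        raise ValueError(
            f"chromosome {mt_name!r} missing from samples: {', '.join(missing)}"
        )
    raw = window_coverage(list(tracks), w)
    norm = normalize_genome_wide(raw)
    profile = norm.data[norm.data["chrom"] == mt_name].reset_index(drop=True)
    samples = [t.sample for t in tracks]
    summary = {s: float(profile[s].sum()) for s in samples}
    groups = [profile[s].to_numpy(dtype=float) for s in samples]
    anova = anova_oneway(*groups)
    return MitoEnrichment(w=w, mt_name=mt_name, profile=profile,
                          summary=summary, anova=anova)
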