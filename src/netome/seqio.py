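"""File formats and read trimming.

All coordinates inside the package are 0-based half-open; conversion to
and from the 1-based conventions of SAM and GFF3 happens here and only
here.  FASTA/FASTQ go through Biopython, SAM through pysam restricted to
a minimal dialect (single-``M`` CIGAR run), and a 6-column TSV dialect is
accepted as a plain-text alternative to SAM.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "GeneInterval",
    "AlignedRead",
    "TrimSummary",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_alignments",
    "write_alignments",
    "read_intervals",
    "write_intervals",
    "trim_read",
    "trim_fastq",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    name: str
    seq: str
    quals: tuple[int, ...]
    chrom: str | None = None
    start: int | None = None  # 0-based, when mapped

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.name}: {len(self.seq)} bases but "
                f"{len(self.quals)} quality values"
            )
        if self.start is not None and self.start < 0:
            raise ValueError(f"read {self.name}: negative mapped start")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneInterval:
    """A gene or exon feature, 0-based half-open."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "gene"  # "gene" | "exon"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedRead:
    """An aligned read: placement on the reference, 0-based half-open.

    ``seq`` is the read sequence as aligned to the forward strand (SAM
    convention); reads that originated from the reverse strand carry
    ``strand == "-"``.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    mapq: int = 60
    seq: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"{self.name}: invalid alignment [{self.start}, {self.end})"
            )
        if self.seq is not None and len(self.seq) != self.end - self.start:
            raise ValueError(f"{self.name}: SEQ length does not match interval")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file into an ordered ``{name: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, genome: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(
            name=rec.id,
            seq=str(rec.seq),
            quals=tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(path: str | os.PathLike, reads: Iterable[Read]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.name, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Alignments: minimal SAM dialect (single M run) or 6-column TSV

def write_alignments(
    path: str | os.PathLike,
    alignments: Iterable[AlignedRead],
    chrom_lengths: dict[str, int],
) -> None:
    """Write alignments as SAM (.sam) or 6-column TSV (anything else)."""
    path = str(path)
    if path.endswith(".sam"):
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_lengths.items()],
        }
        with pysam.AlignmentFile(path, "w", header=header) as sam:
            for a in alignments:
                seg = pysam.AlignedSegment(sam.header)
                seg.query_name = a.name
                seg.flag = 16 if a.strand == "-" else 0
                seg.reference_name = a.chrom
                seg.reference_start = a.start
                seg.mapping_quality = a.mapq
                seg.cigarstring = f"{a.end - a.start}M"
                if a.seq is not None:
                    seg.query_sequence = a.seq
                sam.write(seg)
    else:
        with open(path, "w") as fh:
            fh.write("read_id\tchrom\tstart0\tend0\tstrand\tmapq\n")
            for a in alignments:
                fh.write(
                    f"{a.name}\t{a.chrom}\t{a.start}\t{a.end}\t{a.strand}\t{a.mapq}\n"
                )


def read_alignments(
    path: str | os.PathLike,
    chrom_lengths: dict[str, int] | None = None,
) -> list[AlignedRead]:
    """Read SAM (.sam) or 6-column TSV alignments.

    When ``chrom_lengths`` is given, alignments on unknown chromosomes
    raise an error listing the offenders.
    """
    path = str(path)
    out: list[AlignedRead] = []
    if path.endswith(".sam"):
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for seg in sam:
                if seg.is_unmapped:
                    continue
                cig = seg.cigartuples
                if cig is not None and (len(cig) != 1 or cig[0][0] != 0):
                    raise ValueError(
                        f"{path}: read {seg.query_name} has CIGAR "
                        f"{seg.cigarstring}; only a single M run is supported"
                    )
                out.append(
                    AlignedRead(
                        name=seg.query_name,
                        chrom=seg.reference_name,
                        start=seg.reference_start,
                        end=seg.reference_end,
                        strand="-" if seg.is_reverse else "+",
                        mapq=seg.mapping_quality,
                        seq=seg.query_sequence,
                    )
                )
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "read_id":  # header
                    continue
                if len(fields) != 6:
                    raise ValueError(
                        f"{path}:{lineno}: expected 6 tab-separated fields, "
                        f"got {len(fields)}"
                    )
                try:
                    out.append(
                        AlignedRead(
                            name=fields[0],
                            chrom=fields[1],
                            start=int(fields[2]),
                            end=int(fields[3]),
                            strand=fields[4],
                            mapq=int(fields[5]),
                        )
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if chrom_lengths is not None:
        unknown = sorted({a.chrom for a in out} - set(chrom_lengths))
        if unknown:
            raise ValueError(
                f"{path}: alignments on chromosomes absent from the genome: "
                + ", ".join(unknown)
            )
    return out


# ---------------------------------------------------------------------------
# Gene / exon intervals: BED6 or GFF3

def read_intervals(path: str | os.PathLike) -> list[GeneInterval]:
    """Read gene/exon features from BED6 (0-based) or GFF3 (1-based).

    The dialect is chosen by extension: ``.gff``/``.gff3`` is GFF3,
    everything else is BED.  BED name fields of the form ``id|symbol``
    carry both identifiers; otherwise the name serves as both.
    """
    path = str(path)
    feats: list[GeneInterval] = []
    is_gff = path.endswith((".gff", ".gff3"))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if is_gff:
                    if len(fields) < 9:
                        raise ValueError("GFF3 line has fewer than 9 fields")
                    chrom, _, kind, start1, end1, _, strand, _, attrs = fields[:9]
                    if kind not in {"gene", "exon"}:
                        continue
                    attr = dict(
                        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                    )
                    gid = attr.get("ID") or attr.get("Parent") or f"feat{lineno}"
                    symbol = attr.get("Name", gid)
                    feats.append(
                        GeneInterval(
                            gene_id=gid,
                            symbol=symbol,
                            chrom=chrom,
                            start=int(start1) - 1,  # 1-based inclusive -> 0-based
                            end=int(end1),
                            strand=strand if strand in "+-" else ".",
                            kind=kind,
                        )
                    )
                else:
                    if len(fields) < 4:
                        raise ValueError("BED line has fewer than 4 fields")
                    chrom, start0, end0, name = fields[:4]
                    strand = fields[5] if len(fields) > 5 else "."
                    kind = fields[6] if len(fields) > 6 else "gene"
                    gid, _, symbol = name.partition("|")
                    feats.append(
                        GeneInterval(
                            gene_id=gid,
                            symbol=symbol or gid,
                            chrom=chrom,
                            start=int(start0),
                            end=int(end0),
                            strand=strand if strand in "+-" else ".",
                            kind=kind,
                        )
                    )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return feats


def write_intervals(path: str | os.PathLike, feats: Iterable[GeneInterval]) -> None:
    """Write features as BED6 + a 7th ``kind`` column."""
    with open(path, "w") as fh:
        for f in feats:
            name = f.gene_id if f.gene_id == f.symbol else f"{f.gene_id}|{f.symbol}"
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\t{f.kind}\n"
            )


# ---------------------------------------------------------------------------
# Read trimming

@dataclass
class TrimSummary:
    """Counts accumulated over a trimming pass."""

    kept: int = 0
    discarded_short: int = 0
    discarded_quality: int = 0
    bases_removed: int = 0


def trim_read(
    r: Read,
    trim3: int = 15,
    qmin: int = 25,
    min_len: int = 20,
    discard_whole_read: bool = False,
    summary: TrimSummary | None = None,
) -> Read | None:
    """Trim a read at its 3' end: a fixed cut, then quality trimming.

    First ``trim3`` bases are removed from the 3' end (primer removal),
    then further 3' bases are removed while the terminal base quality is
    below ``qmin``.  Reads shorter than ``min_len`` afterwards are
    discarded (``None``).  With ``discard_whole_read``, any base below
    ``qmin`` discards the read instead of being trimmed.
    """
    if trim3 < 0:
        raise ValueError("trim3 must be >= 0")
    if not 0 <= qmin <= 60:
        raise ValueError("qmin must be in [0, 60]")
    n = len(r)
    end = max(0, n - trim3)
    if discard_whole_read:
        if any(q < qmin for q in r.quals[:end]):
            if summary:
                summary.discarded_quality += 1
            return None
    else:
        while end > 0 and r.quals[end - 1] < qmin:
            end -= 1
    if end < min_len:
        if summary:
            summary.discarded_short += 1
        return None
    if summary:
        summary.kept += 1
        summary.bases_removed += n - end
    if end == n:
        return r
    return replace(r, seq=r.seq[:end], quals=r.quals[:end])


def trim_fastq(
    in_path: str | os.PathLike,
    out_path: str | os.PathLike,
    trim3: int = 15,
    qmin: int = 25,
    min_len: int = 20,
    discard_whole_read: bool = False,
) -> TrimSummary:
    """Trim every read of a FASTQ file; returns the kept/discarded summary."""
    summary = TrimSummary()

    def _gen() -> Iterator[Read]:
        for r in read_fastq(in_path):
            t = trim_read(r, trim3, qmin, min_len, discard_whole_read, summary)
            if t is not None:
                yield t

    write_fastq(out_path, _gen())
    return summary
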