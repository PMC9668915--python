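"""Synthetic inputs with a recorded truth set.

Everything the pipeline consumes can be generated here: a toy genome
whose autosomes carry perfect tandem telomeric arrays at both ends plus
a small circular mitochondrial chromosome, gene/exon annotation, three
samples of pre-aligned reads with planted copy-number signal
(enriched/depleted intervals, differential mitochondrial copy number,
differential telomeric read content), FASTQ with 3'-decaying qualities,
and a two-group LFQ protein table with planted differential proteins.
Reads are emitted pre-aligned — the true placement *is* the alignment —
so coverage oracles are exact.  Every generator is a pure function of
its spec and seed, and the planted truth is returned as a serializable
:class:`TruthRecord`.

Default study conditions: three equal 100 kb autosomes at depth 10,
read length 100; per sample one 25 kb x2.0 interval and one 50 kb x0.5
interval on that sample's own chromosome (so the per-chromosome read
total stays neutral in expectation); mitochondrial copy number 10x in
the trap-like sample; telomeric read rates 2,000/2,000/6,000 motif-
bearing reads per million.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from netome.seqio import (
    AlignedRead,
    GeneInterval,
    Read,
    revcomp,
    write_alignments,
    write_fasta,
    write_fastq,
    write_intervals,
)

__all__ = [
    "SyntheticGenomeSpec",
    "PlantedInterval",
    "PlantedSignal",
    "SyntheticLFQSpec",
    "TruthRecord",
    "make_genome",
    "simulate_alignments",
    "simulate_lfq",
    "default_planted_signal",
    "DEFAULT_SAMPLES",
]

TELOMERE_UNIT = "TTAGGG"
DEFAULT_SAMPLES = ("HL60", "dHL60", "ecTrap")


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


@dataclass
class SyntheticGenomeSpec:
    """Layout of the toy genome."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 100_000, "chr3": 100_000}
    )
    telomere_array_len: int = 600
    mt_name: str = "MT"
    mt_len: int = 2_000
    mt_circular: bool = True
    gc_fraction: float = 0.41
    seed: int = 0

    def validate(self) -> None:
        _require(bool(self.chrom_lengths), "chrom_lengths", "must be non-empty")
        for c, n in self.chrom_lengths.items():
            _require(n > 0, "chrom_lengths", f"length of {c} must be > 0")
            _require(
                n > 2 * self.telomere_array_len,
                "chrom_lengths",
                f"{c} must be longer than two telomeric arrays",
            )
        _require(self.telomere_array_len > 0, "telomere_array_len", "must be > 0")
        _require(
            self.telomere_array_len % len(TELOMERE_UNIT) == 0,
            "telomere_array_len",
            f"must be a multiple of {len(TELOMERE_UNIT)}",
        )
        _require(self.mt_len >= 500, "mt_len",
                 "must be >= 500 so at least one full 500-nt window exists")
        _require(0.0 < self.gc_fraction < 1.0, "gc_fraction", "must be in (0, 1)")

    @property
    def autosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def all_lengths(self) -> dict[str, int]:
        out = dict(self.chrom_lengths)
        out[self.mt_name] = self.mt_len
        return out


@dataclass(frozen=True)
class PlantedInterval:
    sample: str
    chrom: str
    start: int
    end: int
    multiplier: float

    @property
    def direction(self) -> str:
        if self.multiplier >= 1.5:
            return "enriched"
        if self.multiplier <= 1.0 / 1.5:
            return "depleted"
        return "neutral"


@dataclass
class PlantedSignal:
    """Ground-truth signal planted into the simulated samples."""

    intervals: list[PlantedInterval] = field(default_factory=list)
    mt_multiplier: dict[str, float] = field(default_factory=dict)
    telomere_rate: dict[str, float] = field(default_factory=dict)  # per million

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        by_sample: dict[str, list[PlantedInterval]] = {}
        for iv in self.intervals:
            _require(iv.multiplier > 0, "intervals", "multiplier must be > 0")
            _require(iv.chrom in chrom_lengths, "intervals",
                     f"unknown chromosome {iv.chrom}")
            _require(
                0 <= iv.start < iv.end <= chrom_lengths[iv.chrom],
                "intervals",
                f"interval [{iv.start}, {iv.end}) outside {iv.chrom}",
            )
            by_sample.setdefault(iv.sample, []).append(iv)
        for sample, ivs in by_sample.items():
            ivs = sorted(ivs, key=lambda i: (i.chrom, i.start))
            for a, b in zip(ivs, ivs[1:]):
                _require(
                    a.chrom != b.chrom or a.end <= b.start,
                    "intervals",
                    f"overlapping intervals for sample {sample}",
                )
        for s, m in self.mt_multiplier.items():
            _require(m > 0, "mt_multiplier", f"multiplier for {s} must be > 0")
        for s, r in self.telomere_rate.items():
            _require(r >= 0, "telomere_rate", f"rate for {s} must be >= 0")

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for s in (
            [iv.sample for iv in self.intervals]
            + list(self.mt_multiplier)
            + list(self.telomere_rate)
        ):
            if s not in seen:
                seen.append(s)
        return seen


def default_planted_signal(
    spec: SyntheticGenomeSpec,
    samples=DEFAULT_SAMPLES,
    w: int = 5000,
) -> PlantedSignal:
    """Study-condition signal: per sample, one x2.0 enriched interval of
    5 windows and one x0.5 depleted interval of 10 windows on that
    sample's own chromosome; 10x mitochondrial copy number and a 3x
    telomeric read rate in the trap-like (last) sample."""
    chroms = spec.autosomes
    intervals = []
    for i, sample in enumerate(samples):
        chrom = chroms[i % len(chroms)]
        length = spec.chrom_lengths[chrom]
        enr_start = 2 * w
        enr_end = enr_start + 5 * w
        dep_start = enr_end + 2 * w
        dep_end = dep_start + 10 * w
        if dep_end > length - spec.telomere_array_len:
            raise ValueError(
                f"chromosome {chrom} too short for the default planted layout"
            )
        intervals.append(PlantedInterval(sample, chrom, enr_start, enr_end, 2.0))
        intervals.append(PlantedInterval(sample, chrom, dep_start, dep_end, 0.5))
    trap = samples[-1]
    return PlantedSignal(
        intervals=intervals,
        mt_multiplier={s: (10.0 if s == trap else 1.0) for s in samples},
        telomere_rate={s: (6000.0 if s == trap else 2000.0) for s in samples},
    )


@dataclass
class SyntheticLFQSpec:
    """Layout of the synthetic two-group LFQ experiment."""

    n_proteins: int = 1000
    n_differential: int = 50
    effect_size: float = 4.0  # true linear group-mean ratio of planted proteins
    cv: float = 0.15  # multiplicative replicate coefficient of variation
    missing_rate: float = 0.2  # ceiling of the low-abundance missing probability
    log10_mean: float = 7.0
    log10_sd: float = 1.25  # spans > 5 orders of magnitude over ~1000 proteins
    missing_quantile: float = 0.2  # abundance quantile where missingness centres
    group_sizes: tuple[int, int] = (3, 3)
    group_names: tuple[str, str] = ("benzonase", "untreated")
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_proteins >= 1, "n_proteins", "must be >= 1")
        _require(0 <= self.n_differential <= self.n_proteins,
                 "n_differential", "must be in [0, n_proteins]")
        _require(self.effect_size > 0, "effect_size", "must be > 0")
        _require(self.cv > 0, "cv", "must be > 0")
        _require(0 <= self.missing_rate < 1, "missing_rate", "must be in [0, 1)")
        _require(all(g >= 2 for g in self.group_sizes),
                 "group_sizes", "each group needs >= 2 replicates")


@dataclass
class TruthRecord:
    """Machine-readable record of everything the generator planted."""

    planted: PlantedSignal | None = None
    differential_proteins: list[tuple[str, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted": None
            if self.planted is None
            else {
                "intervals": [asdict(iv) for iv in self.planted.intervals],
                "mt_multiplier": self.planted.mt_multiplier,
                "telomere_rate": self.planted.telomere_rate,
            },
            "differential_proteins": [list(t) for t in self.differential_proteins],
            "params": self.params,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        payload = json.loads(text)
        planted = None
        if payload.get("planted") is not None:
            p = payload["planted"]
            planted = PlantedSignal(
                intervals=[PlantedInterval(**iv) for iv in p["intervals"]],
                mt_multiplier=dict(p["mt_multiplier"]),
                telomere_rate=dict(p["telomere_rate"]),
            )
        return cls(
            planted=planted,
            differential_proteins=[tuple(t) for t in payload["differential_proteins"]],
            params=dict(payload["params"]),
        )


# ---------------------------------------------------------------------------
# Genome + annotation

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def make_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, str], list[GeneInterval]]:
    """Build the toy genome and its gene/exon annotation.

    Each autosome begins with ``telomere_array_len`` nt of tandem TTAGGG
    and ends with the same length of its reverse complement (the
    forward-strand sequence of a 3' telomere); this orientation choice
    is recorded in the truth record by :func:`simulate_alignments`.  At
    least 10 non-overlapping genes per autosome are placed between the
    arrays, each with 1-3 exons.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_unit = spec.telomere_array_len // len(TELOMERE_UNIT)
    head = TELOMERE_UNIT * n_unit
    tail = revcomp(TELOMERE_UNIT) * n_unit

    genome: dict[str, str] = {}
    genes: list[GeneInterval] = []
    for chrom, length in spec.chrom_lengths.items():
        core = _random_bases(rng, length - 2 * spec.telomere_array_len,
                             spec.gc_fraction)
        genome[chrom] = head + core + tail
        genes.extend(
            _place_genes(rng, chrom, length, spec.telomere_array_len)
        )
    genome[spec.mt_name] = _random_bases(rng, spec.mt_len, spec.gc_fraction)
    return genome, genes


def _place_genes(
    rng: np.random.Generator, chrom: str, length: int, telo: int, n_genes: int = 10
) -> list[GeneInterval]:
    lo, hi = telo, length - telo
    span = hi - lo
    slot = span // n_genes
    feats: list[GeneInterval] = []
    for i in range(n_genes):
        slot_lo = lo + i * slot
        gene_len = int(rng.integers(slot // 4, slot // 2))
        start = int(rng.integers(slot_lo, slot_lo + slot - gene_len))
        end = start + gene_len
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"{chrom}_g{i + 1}"
        symbol = f"GENE_{chrom.upper()}_{i + 1}"
        feats.append(GeneInterval(gid, symbol, chrom, start, end, strand, "gene"))
        n_exons = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(
            np.arange(start, end), size=2 * n_exons, replace=False))
        for k in range(n_exons):
            es, ee = int(bounds[2 * k]), int(bounds[2 * k + 1])
            if ee <= es:
                ee = es + 1
            feats.append(GeneInterval(f"{gid}.e{k + 1}", symbol, chrom,
                                      es, ee, strand, "exon"))
    return feats


# ---------------------------------------------------------------------------
# Read simulation

def _start_weights(
    spec: SyntheticGenomeSpec,
    planted: PlantedSignal,
    sample: str,
    chrom: str,
    read_len: int,
) -> np.ndarray:
    length = spec.all_lengths[chrom]
    n_starts = length - read_len + 1
    w = np.ones(n_starts)
    if chrom == spec.mt_name:
        w *= planted.mt_multiplier.get(sample, 1.0)
    for iv in planted.intervals:
        if iv.sample == sample and iv.chrom == chrom:
            w[iv.start : min(iv.end, n_starts)] *= iv.multiplier
    return w


def simulate_alignments(
    genome: dict[str, str],
    spec: SyntheticGenomeSpec,
    planted: PlantedSignal,
    mean_depth: float = 10.0,
    read_len: int = 100,
    seed: int = 0,
    q_decay_fraction: float = 0.2,
    samples=None,
) -> tuple[dict[str, list[AlignedRead]], dict[str, list[Read]], TruthRecord]:
    """Simulate pre-aligned reads for every sample with planted signal.

    Read starts are drawn with per-position sampling intensity 1.0,
    multiplied inside planted intervals by the interval's multiplier and
    on the mitochondrial chromosome by the sample's MT multiplier; the
    read count per chromosome is set so that background mean depth
    matches ``mean_depth``.  Extra telomeric reads are added at each
    sample's planted rate (motif-bearing reads per million), placed
    uniformly inside the telomeric arrays.  A ``q_decay_fraction`` of
    reads get 3' quality decay below Q25 (the rest are flat Q35).

    Returns per-sample alignments, per-sample FASTQ-ready reads and the
    truth record.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if read_len < 20:
        raise ValueError("read_len must be >= 20")
    spec.validate()
    planted.validate(spec.all_lengths)
    if samples is None:
        samples = planted.samples or list(DEFAULT_SAMPLES)
    rng = np.random.default_rng(seed)

    alignments: dict[str, list[AlignedRead]] = {}
    fastq: dict[str, list[Read]] = {}
    for sample in samples:
        alns: list[AlignedRead] = []
        serial = 0
        for chrom in spec.all_lengths:
            length = spec.all_lengths[chrom]
            if length < read_len:
                continue
            w = _start_weights(spec, planted, sample, chrom, read_len)
            total_w = float(w.sum())
            n_reads = int(round(mean_depth / read_len * total_w))
            if n_reads == 0:
                continue
            starts = rng.choice(w.size, size=n_reads, p=w / total_w)
            starts.sort()
            strands = rng.random(n_reads) < 0.5
            for s, minus in zip(starts, strands):
                serial += 1
                s = int(s)
                alns.append(
                    AlignedRead(
                        name=f"{sample}:{serial}",
                        chrom=chrom,
                        start=s,
                        end=s + read_len,
                        strand="-" if minus else "+",
                        mapq=60,
                        seq=genome[chrom][s : s + read_len],
                    )
                )
        # planted telomeric reads, uniform over the arrays of random autosomes
        rate = planted.telomere_rate.get(sample, 0.0)
        n_telo = int(round(rate * len(alns) / 1e6))
        telo = spec.telomere_array_len
        autosomes = spec.autosomes
        for _ in range(n_telo):
            serial += 1
            chrom = autosomes[int(rng.integers(len(autosomes)))]
            length = spec.chrom_lengths[chrom]
            if rng.random() < 0.5:
                s = int(rng.integers(0, max(1, telo - read_len + 1)))
            else:
                s = int(rng.integers(length - telo, length - read_len + 1))
            alns.append(
                AlignedRead(
                    name=f"{sample}:{serial}",
                    chrom=chrom,
                    start=s,
                    end=s + read_len,
                    strand="-" if rng.random() < 0.5 else "+",
                    mapq=60,
                    seq=genome[chrom][s : s + read_len],
                )
            )
        alignments[sample] = alns
        fastq[sample] = _to_fastq_reads(rng, alns, q_decay_fraction)

    truth = TruthRecord(
        planted=planted,
        params={
            "mean_depth": mean_depth,
            "read_len": read_len,
            "seed": seed,
            "q_decay_fraction": q_decay_fraction,
            "samples": list(samples),
            "genome": {
                "chrom_lengths": dict(spec.chrom_lengths),
                "telomere_array_len": spec.telomere_array_len,
                "telomere_3prime_orientation": "reverse-complement",
                "mt_name": spec.mt_name,
                "mt_len": spec.mt_len,
                "mt_circular": spec.mt_circular,
                "gc_fraction": spec.gc_fraction,
                "seed": spec.seed,
            },
        },
    )
    return alignments, fastq, truth


def _to_fastq_reads(
    rng: np.random.Generator, alns: list[AlignedRead], q_decay_fraction: float
) -> list[Read]:
    out: list[Read] = []
    for a in alns:
        n = a.end - a.start
        quals = np.full(n, 35, dtype=int)
        if rng.random() < q_decay_fraction:
            k = min(30, n)
            quals[n - k :] = np.linspace(35, 8, k).round().astype(int)
        seq = a.seq if a.strand == "+" else revcomp(a.seq)
        out.append(Read(name=a.name, seq=seq, quals=tuple(int(q) for q in quals),
                        chrom=a.chrom, start=a.start))
    return out


def write_simulation(
    outdir: str | os.PathLike,
    genome: dict[str, str],
    annotation: list[GeneInterval],
    alignments: dict[str, list[AlignedRead]],
    fastq: dict[str, list[Read]],
    truth: TruthRecord,
    spec: SyntheticGenomeSpec,
    fmt: str = "sam",
) -> dict[str, str]:
    """Write every simulated artifact to ``outdir``; returns the paths."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.bed"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(paths["genome"], genome)
    write_intervals(paths["annotation"], annotation)
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json() + "\n")
    ext = "sam" if fmt == "sam" else "tsv"
    for sample, alns in alignments.items():
        p = os.path.join(outdir, f"{sample}.{ext}")
        write_alignments(p, alns, spec.all_lengths)
        paths[f"alignments:{sample}"] = p
        q = os.path.join(outdir, f"{sample}.fastq")
        write_fastq(q, fastq[sample])
        paths[f"fastq:{sample}"] = q
    return paths


# ---------------------------------------------------------------------------
# LFQ simulation

def simulate_lfq(spec: SyntheticLFQSpec):
    """Simulate a two-group LFQ table with planted differential proteins.

    Baseline log10 intensities are normal (``log10_mean``,
    ``log10_sd``); exactly ``n_differential`` randomly chosen proteins
    get a true group-mean linear ratio equal to ``effect_size``, half up
    and half down.  Replicate noise is multiplicative log-normal with
    the stated CV.  A value goes missing only through the low-abundance
    mechanism: with probability ``missing_rate`` scaled by a logistic
    ramp centred on the ``missing_quantile`` abundance quantile, so
    high-abundance values are essentially never missing.

    Returns ``(LFQTable, TruthRecord)``.
    """
    from netome.proteomics import LFQTable  # deferred: avoid import cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    ids = [f"P{i + 1:05d}" for i in range(n)]
    base_log10 = rng.normal(spec.log10_mean, spec.log10_sd, size=n)

    diff_idx = rng.choice(n, size=spec.n_differential, replace=False)
    diff_idx.sort()
    direction = np.zeros(n)  # +1 up in group1, -1 up in group2
    for k, i in enumerate(diff_idx):
        direction[i] = 1.0 if k % 2 == 0 else -1.0

    shift = np.log10(spec.effect_size) * direction  # applied to group 1
    n1, n2 = spec.group_sizes
    sigma10 = np.sqrt(np.log(1.0 + spec.cv**2)) / np.log(10.0)
    log10_g1 = (base_log10 + shift)[:, None] + rng.normal(0, sigma10, size=(n, n1))
    log10_g2 = base_log10[:, None] + rng.normal(0, sigma10, size=(n, n2))
    log10_all = np.concatenate([log10_g1, log10_g2], axis=1)

    tau = float(np.quantile(base_log10, spec.missing_quantile))
    p_missing = spec.missing_rate / (1.0 + np.exp((log10_all - tau) / 0.3))
    missing = rng.random(log10_all.shape) < p_missing
    values = np.power(10.0, log10_all)
    values[missing] = np.nan

    g1, g2 = spec.group_names
    columns = [f"{g1}_rep{i + 1}" for i in range(n1)] + [
        f"{g2}_rep{i + 1}" for i in range(n2)
    ]
    design = {c: (g1 if i < n1 else g2) for i, c in enumerate(columns)}
    import pandas as pd

    table = LFQTable(
        data=pd.DataFrame(values, index=pd.Index(ids, name="protein"),
                          columns=columns),
        design=design,
    )
    truth = TruthRecord(
        differential_proteins=[
            (ids[i], "up" if direction[i] > 0 else "down") for i in diff_idx
        ],
        params={
            "n_proteins": n,
            "n_differential": spec.n_differential,
            "effect_size": spec.effect_size,
            "cv": spec.cv,
            "missing_rate": spec.missing_rate,
            "log10_mean": spec.log10_mean,
            "log10_sd": spec.log10_sd,
            "missing_quantile": spec.missing_quantile,
            "group_sizes": list(spec.group_sizes),
            "group_names": list(spec.group_names),
            "seed": spec.seed,
        },
    )
    return table, truth
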