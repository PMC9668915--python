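"""Scoring of pipeline output against the generator's planted truth.

Only meaningful for synthetic runs: the truth record says which windows
carry planted copy-number signal and which proteins are truly
differential, so the enrichment screen and the proteomics test can be
scored for sensitivity and false calls.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from netome.enrichment import EnrichmentCall
from netome.simulate import PlantedSignal

__all__ = ["expected_windows", "score_screen", "score_proteomics"]


def expected_windows(
    planted: PlantedSignal,
    w: int,
    chrom_lengths: dict[str, int],
) -> set[tuple[str, str, int, str]]:
    """(sample, chrom, window_start, direction) for every window fully
    inside a planted enriched/depleted interval."""
    out: set[tuple[str, str, int, str]] = set()
    for iv in planted.intervals:
        if iv.direction == "neutral":
            continue
        first = -(-iv.start // w)  # first window index fully inside
        start = first * w
        while start + w <= min(iv.end, chrom_lengths[iv.chrom]):
            out.add((iv.sample, iv.chrom, start, iv.direction))
            start += w
    return out


def score_screen(
    calls: Iterable[EnrichmentCall],
    planted: PlantedSignal,
    w: int,
    chrom_lengths: dict[str, int],
    samples: Sequence[str],
) -> dict:
    """Sensitivity on planted windows and false-call rate elsewhere.

    Sensitivity: fraction of (sample, window, direction) triples fully
    inside planted intervals that were called with that direction for
    that sample.  False-call rate: calls landing on windows that overlap
    *no* planted interval (any sample), divided by the number of such
    unplanted (window, focal-sample) pairs.
    """
    expected = expected_windows(planted, w, chrom_lengths)
    called = {(c.sample, c.chrom, c.start, c.direction) for c in calls}

    planted_spans: dict[str, list[tuple[int, int]]] = {}
    for iv in planted.intervals:
        planted_spans.setdefault(iv.chrom, []).append((iv.start, iv.end))

    def unplanted(chrom: str, start: int) -> bool:
        return not any(
            start < e and start + w > s for s, e in planted_spans.get(chrom, [])
        )

    n_unplanted_windows = 0
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, w):
            if unplanted(chrom, start):
                n_unplanted_windows += 1
    false_calls = sum(1 for (s, chrom, start, d) in called if unplanted(chrom, start))
    denom = n_unplanted_windows * len(samples)

    return {
        "n_planted_windows": len(expected),
        "n_recovered": len(expected & called),
        "sensitivity": (len(expected & called) / len(expected)) if expected else None,
        "n_false_calls": false_calls,
        "n_unplanted_window_sample_pairs": denom,
        "false_call_rate": false_calls / denom if denom else None,
    }


def score_proteomics(
    result: pd.DataFrame,
    differential_proteins: Sequence[tuple[str, str]],
) -> dict:
    """Sensitivity and realized false-discovery proportion of the
    differential test against the planted protein truth."""
    truth = {p for p, _ in differential_proteins}
    sig = set(result.index[result["significant"]].astype(str))
    n_true_hits = len(sig & truth)
    return {
        "n_planted": len(truth),
        "n_significant": len(sig),
        "n_true_hits": n_true_hits,
        "sensitivity": n_true_hits / len(truth) if truth else None,
        "false_discovery_proportion": (
            (len(sig) - n_true_hits) / len(sig) if sig else 0.0
        ),
    }
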