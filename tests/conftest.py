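"""Shared fixtures: one moderately sized synthetic run reused across
modules (session scope, fixed seed) plus small helpers."""

from __future__ import annotations

import numpy as np
import pytest

import netome


@pytest.fixture(scope="session")
def genome_spec():
    return netome.SyntheticGenomeSpec(seed=11)


@pytest.fixture(scope="session")
def demo_run(genome_spec):
    """Default study conditions: 3 x 100 kb autosomes + MT, depth 10,
    planted copy-number / MT / telomere signal, seed 11."""
    genome, annotation = netome.make_genome(genome_spec)
    planted = netome.default_planted_signal(genome_spec)
    alignments, fastq, truth = netome.simulate_alignments(
        genome, genome_spec, planted, mean_depth=10.0, read_len=100, seed=11
    )
    tracks = [
        netome.compute_coverage(alignments[s], genome_spec.all_lengths, s)
        for s in alignments
    ]
    return {
        "spec": genome_spec,
        "genome": genome,
        "annotation": annotation,
        "planted": planted,
        "alignments": alignments,
        "fastq": fastq,
        "truth": truth,
        "tracks": tracks,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_track(rng, sample="s", chroms=((("chrA", 100)), ("chrB", 57))):
    """Small random coverage track for oracle tests."""
    depths = {
        c: rng.integers(0, 8, size=n).astype(np.int64) for c, n in chroms
    }
    return netome.CoverageTrack(sample=sample, depths=depths)
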