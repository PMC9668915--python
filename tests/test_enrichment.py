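"""Fold-change screen, region merging and annotation overlap."""

import numpy as np
import pandas as pd
import pytest

import netome
from netome.coverage import WindowTable
from netome.enrichment import EnrichmentCall
from netome.seqio import GeneInterval


def make_table(values, w=10, chrom="c"):
    """Build a per-chromosome-normalized WindowTable from a dict
    sample -> list of normalized values (one chromosome)."""
    samples = list(values)
    n = len(values[samples[0]])
    data = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * w,
            "end": (np.arange(n) + 1) * w,
            **{s: values[s] for s in samples},
        }
    )
    return WindowTable(w=w, mode="per_chromosome", data=data, samples=samples)


class TestFoldChangeScreen:
    def test_identical_samples_no_calls(self):
        wt = make_table({s: [0.25, 0.25, 0.25, 0.25] for s in "abc"})
        assert netome.fold_change_screen(wt, ratio_pseudocount=0.0) == []

    def test_clear_enrichment_both_criteria(self):
        wt = make_table({"a": [0.3, 0.35], "b": [0.1, 0.45], "c": [0.1, 0.45]})
        calls = [
            c for c in netome.fold_change_screen(wt, ratio_pseudocount=0.0)
            if c.sample == "a" and c.start == 0
        ]
        (call,) = calls
        assert call.direction == "enriched"
        assert call.fold_vs_each == pytest.approx(3.0)
        assert call.fold_vs_average == pytest.approx(3.0)
        assert call.criterion == "both"

    def test_vs_average_only_recorded(self):
        # focal 0.30 vs 0.21 and 0.09: each-ratio 1.43 fails, avg-ratio 2.0
        wt = make_table(
            {"a": [0.30, 0.7], "b": [0.21, 0.79], "c": [0.09, 0.91]},
        )
        calls = netome.fold_change_screen(wt, ratio_pseudocount=0.0)
        first = [c for c in calls if c.sample == "a" and c.start == 0]
        (call,) = first
        assert call.criterion == "vs_average"
        crit_sim = netome.fold_change_screen(
            wt, ratio_pseudocount=0.0, criterion="simultaneous"
        )
        assert not [c for c in crit_sim if c.sample == "a" and c.start == 0]

    def test_depletion_is_reciprocal(self):
        wt = make_table({"a": [0.1, 0.9], "b": [0.3, 0.7], "c": [0.3, 0.7]})
        call = [
            c for c in netome.fold_change_screen(wt, ratio_pseudocount=0.0)
            if c.sample == "a" and c.start == 0
        ][0]
        assert call.direction == "depleted"
        assert call.fold_vs_each == pytest.approx(1 / 3)

    def test_cutoff_monotonicity(self, demo_run):
        wt = netome.normalize_per_chromosome(
            netome.window_coverage(demo_run["tracks"], 5000)
        )
        loose = netome.fold_change_screen(wt, cutoff=1.5, ratio_pseudocount=1e-9)
        strict = netome.fold_change_screen(wt, cutoff=2.0, ratio_pseudocount=1e-9)
        key = lambda c: (c.sample, c.chrom, c.start, c.direction)
        assert {key(c) for c in strict} <= {key(c) for c in loose}

    def test_label_symmetry_of_non_focal_samples(self, demo_run):
        tracks = demo_run["tracks"]
        wt1 = netome.normalize_per_chromosome(netome.window_coverage(tracks, 5000))
        swapped = [tracks[0], tracks[2], tracks[1]]
        wt2 = netome.normalize_per_chromosome(netome.window_coverage(swapped, 5000))
        focal = tracks[0].sample
        key = lambda c: (c.chrom, c.start, c.direction)
        calls1 = {key(c) for c in netome.fold_change_screen(wt1) if c.sample == focal}
        calls2 = {key(c) for c in netome.fold_change_screen(wt2) if c.sample == focal}
        assert calls1 == calls2

    def test_requires_three_samples(self):
        wt = make_table({"a": [0.5, 0.5], "b": [0.5, 0.5]})
        with pytest.raises(ValueError, match="3 samples"):
            netome.fold_change_screen(wt)


def _call(sample, chrom, start, end, direction="enriched", fold=2.0):
    return EnrichmentCall(sample, chrom, start, end, direction, fold, fold, "both")


class TestMergeRegions:
    def test_empty(self):
        assert netome.merge_regions([]) == []

    def test_two_adjacent_windows_merge(self):
        regions = netome.merge_regions(
            [_call("a", "c", 0, 10), _call("a", "c", 10, 20, fold=3.0)]
        )
        (r,) = regions
        assert (r.start, r.end, r.n_windows) == (0, 20, 2)
        assert r.best_fold == 3.0

    def test_run_length_encoding_oracle(self, rng):
        # alternating directions with random gaps equals brute-force RLE
        calls = []
        direction = []
        for i in range(40):
            if rng.random() < 0.6:
                d = "enriched" if rng.random() < 0.5 else "depleted"
                calls.append(_call("a", "c", i * 10, (i + 1) * 10, d))
                direction.append(d)
            else:
                direction.append(None)
        expected = 0
        prev = None
        for d in direction:
            if d is not None and d != prev:
                expected += 1
            prev = d
        assert len(netome.merge_regions(calls)) == expected

    def test_different_samples_never_merge(self):
        regions = netome.merge_regions(
            [_call("a", "c", 0, 10), _call("b", "c", 10, 20)]
        )
        assert len(regions) == 2


class TestOverlapGenes:
    ANN = [
        GeneInterval("g1", "ALPHA", "c", 100, 200, "+", "gene"),
        GeneInterval("g1.e1", "ALPHA", "c", 120, 150, "+", "exon"),
        GeneInterval("g2", "BETA", "c", 400, 500, "-", "gene"),
    ]

    def _regions(self, start, end):
        return [netome.Region("a", "enriched", "c", start, end, 1, 2.0)]

    def test_region_inside_gene(self):
        df = netome.overlap_genes(self._regions(110, 130), self.ANN)
        gene_rows = df[df["kind"] == "gene"]
        assert list(gene_rows["symbol"]) == ["ALPHA"]
        assert list(gene_rows["overlap_nt"]) == [20]

    def test_region_between_genes(self):
        assert netome.overlap_genes(self._regions(250, 350), self.ANN).empty

    def test_straddling_boundary_matches_base_count(self):
        df = netome.overlap_genes(self._regions(180, 260), self.ANN)
        # brute-force base membership: bases 180..199 fall in g1
        expected = sum(1 for p in range(180, 260) if 100 <= p < 200)
        assert df.loc[df["kind"] == "gene", "overlap_nt"].iloc[0] == expected

    def test_unannotated_chromosome_skipped(self):
        regions = [netome.Region("a", "enriched", "chrZ", 0, 10, 1, 2.0)]
        df = netome.overlap_genes(regions, self.ANN)
        assert df.empty
        assert df.attrs["skipped_chromosomes"] == {"chrZ": 1}


class TestRoiProfile:
    def test_equal_windows_give_fold_one(self):
        wt = make_table(
            {s: [0.25, 0.25, 0.25, 0.25] for s in ("a", "b", "f")}, w=10
        )
        ann = [GeneInterval("g1", "POI1", "c", 5, 25, "+", "gene")]
        df = netome.roi_profile(["POI1"], wt, ann, focal="f")
        assert df["focal_vs_mean"].iloc[0] == pytest.approx(1.0)

    def test_unresolved_symbols_listed_not_fatal(self):
        wt = make_table({s: [0.5, 0.5] for s in ("a", "b", "f")})
        ann = [GeneInterval("g1", "POI1", "c", 0, 15, "+", "gene")]
        df = netome.roi_profile(["POI1", "NOPE"], wt, ann, focal="f")
        assert df.attrs["unresolved"] == ["NOPE"]
        assert len(df) == 1

    def test_empty_resolvable_set_is_error(self):
        wt = make_table({s: [0.5, 0.5] for s in ("a", "b", "f")})
        with pytest.raises(ValueError, match="resolve"):
            netome.roi_profile(["NOPE"], wt, [], focal="f")

    def test_planted_interval_recovered_in_gene_fold(self, demo_run):
        # a synthetic locus inside the ecTrap x2 interval should show a
        # gene-level fold near 2 for the focal sample
        planted = demo_run["planted"]
        iv = next(
            i for i in planted.intervals
            if i.sample == "ecTrap" and i.direction == "enriched"
        )
        wt = netome.normalize_per_chromosome(
            netome.window_coverage(demo_run["tracks"], 20)
        )
        ann = [GeneInterval("poi", "POI_IN", iv.chrom, iv.start + 2000,
                            iv.start + 8000, "+", "gene")]
        df = netome.roi_profile(["POI_IN"], wt, ann, focal="ecTrap")
        # focal vs mean of the other two samples recovers the x2 plant
        assert 1.7 <= df["focal_vs_others"].iloc[0] <= 2.3
        # the all-three-mean rescaling gives 2/(4/3) = 1.5
        assert 1.35 <= df["focal_vs_mean"].iloc[0] <= 1.65


class TestExpressionOverlap:
    def test_identical_sets(self):
        genes = [f"G{i}" for i in range(10)]
        res = netome.expression_overlap(genes, genes)
        assert (res["n_in_list"], res["n_not_in_list"], res["n_list_not_hit"]) == (
            10, 0, 0,
        )

    def test_disjoint_sets(self):
        res = netome.expression_overlap(["A", "B"], ["C", "D", "E"])
        assert (res["n_in_list"], res["n_not_in_list"], res["n_list_not_hit"]) == (
            0, 2, 3,
        )

    def test_case_folding_and_random_oracle(self, rng):
        universe = [f"SYM{i}" for i in range(1000)]
        hits = list(rng.choice(universe, size=100, replace=False))
        ext = [s.lower() for s in rng.choice(universe, size=100, replace=False)]
        res = netome.expression_overlap(hits, ext)
        hs = {h.casefold() for h in hits}
        es = {e.casefold() for e in ext}
        assert res["n_in_list"] == len(hs & es)
        assert res["n_not_in_list"] == len(hs - es)
        assert res["n_list_not_hit"] == len(es - hs)

    def test_empty_external_rejected(self):
        with pytest.raises(ValueError):
            netome.expression_overlap(["A"], [])
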