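"""LFQ analyses: presence intersection, dynamic range, permutation-FDR
differential test and z-score clustering."""

import numpy as np
import pandas as pd
import pytest

import netome
from netome.proteomics import LFQTable


def make_table(values, n1=3, n2=3, g=("benzonase", "untreated")):
    """values: dict protein -> list of n1+n2 intensities (None = absent)."""
    cols = [f"{g[0]}_rep{i+1}" for i in range(n1)] + [
        f"{g[1]}_rep{i+1}" for i in range(n2)
    ]
    data = pd.DataFrame(
        {c: [np.nan if v[i] is None else float(v[i])
             for v in values.values()]
         for i, c in enumerate(cols)},
        index=pd.Index(list(values), name="protein"),
    )
    design = {c: (g[0] if i < n1 else g[1]) for i, c in enumerate(cols)}
    return LFQTable(data=data, design=design)


class TestLFQTable:
    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError, match="positive"):
            make_table({"p": [1, 2, 0, 4, 5, 6]})

    def test_rejects_single_replicate_group(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            make_table({"p": [1, 2, 3, 4]}, n1=1, n2=3)

    def test_tsv_round_trip(self, tmp_path):
        t = make_table({"p1": [1, 2, 3, 4, 5, 6], "p2": [7, None, 9, 1, 2, 3]})
        t.to_tsv(tmp_path / "lfq.tsv", tmp_path / "design.tsv")
        back = LFQTable.from_tsv(tmp_path / "lfq.tsv", tmp_path / "design.tsv")
        pd.testing.assert_frame_equal(t.data, back.data)
        assert back.design == t.design


class TestDetectCommon:
    def test_presence_rules(self):
        t = make_table({
            "all6": [1, 2, 3, 4, 5, 6],
            "g1only": [1, 2, 3, None, 5, 6],
            "partial": [1, None, 3, 4, 5, 6],
        })
        res = netome.detect_common(t)
        assert res["n_common"] == {"benzonase": 2, "untreated": 2}
        assert res["n_intersection"] == 1
        assert res["per_replicate"]["benzonase_rep2"] == 2

    def test_random_presence_matrix_oracle(self, rng):
        n = 200
        present = rng.random((n, 6)) < 0.7
        values = {
            f"p{i}": [10.0 if present[i, j] else None for j in range(6)]
            for i in range(n)
        }
        t = make_table(values)
        res = netome.detect_common(t)
        c1 = {f"p{i}" for i in range(n) if present[i, :3].all()}
        c2 = {f"p{i}" for i in range(n) if present[i, 3:].all()}
        assert set(res["common"]["benzonase"]) == c1
        assert res["n_intersection"] == len(c1 & c2)
        assert res["n_unique"]["untreated"] == len(c2 - c1)

    def test_column_order_invariance(self, rng):
        t = make_table({f"p{i}": list(rng.uniform(1, 10, 6)) for i in range(20)})
        shuffled_cols = list(t.data.columns)
        rng.shuffle(shuffled_cols)
        t2 = LFQTable(data=t.data[shuffled_cols], design=t.design)
        a, b = netome.detect_common(t), netome.detect_common(t2)
        assert a["n_common"] == b["n_common"]
        assert a["n_intersection"] == b["n_intersection"]


class TestDynamicRange:
    def test_single_protein(self):
        df = netome.dynamic_range(make_table({"p": [5, 5, 5, 1, 1, 1]}))
        assert df["rank"].tolist() == [1]
        assert df.attrs["span_orders"] == 0.0

    def test_span_in_orders_of_magnitude(self):
        values = {f"p{k}": [10 ** (2 + k)] * 6 for k in range(6)}
        df = netome.dynamic_range(make_table(values))
        assert df.attrs["span_orders"] == pytest.approx(5.0)

    def test_reference_in_top_k_oracle(self, rng):
        meds = rng.uniform(1e3, 1e9, size=300)
        values = {f"p{i}": [m, m, m, 1, 1, 1] for i, m in enumerate(meds)}
        ref = [f"p{i}" for i in rng.choice(300, size=30, replace=False)]
        df = netome.dynamic_range(make_table(values), reference_list=ref,
                                  top_k=100)
        order = np.argsort(-meds, kind="stable")
        top = {f"p{i}" for i in order[:100]}
        assert df.attrs["n_reference_in_top_k"] == len(top & set(ref))


class TestDifferentialTest:
    def test_equal_means_never_significant(self):
        t = make_table({
            f"p{i}": [100 + i, 101 + i, 102 + i] * 2 for i in range(30)
        })
        res = netome.differential_test(t)
        eq = res.loc["p0"]
        assert eq["signed_fc"] == pytest.approx(1.0)
        assert not res["significant"].any()

    def test_planted_four_fold_recovered(self):
        lfq, truth = netome.simulate_lfq(
            netome.SyntheticLFQSpec(seed=5, n_proteins=400, n_differential=20,
                                    missing_rate=0.0)
        )
        res = netome.differential_test(lfq, seed=5)
        planted = {p for p, _ in truth.differential_proteins}
        sig = set(res.index[res["significant"]])
        assert len(sig & planted) / len(planted) >= 0.9
        assert len(sig - planted) / max(1, len(sig)) <= 0.1

    def test_group_label_swap_preserves_q(self):
        lfq, _ = netome.simulate_lfq(
            netome.SyntheticLFQSpec(seed=8, n_proteins=100, n_differential=10)
        )
        res1 = netome.differential_test(lfq, seed=1)
        # present the untreated group first: statistics negate, q unchanged
        cols = lfq.columns_for("untreated") + lfq.columns_for("benzonase")
        lfq2 = LFQTable(data=lfq.data[cols], design=lfq.design)
        res2 = netome.differential_test(lfq2, seed=1)
        assert np.allclose(res1["q"], res2["q"])
        assert np.allclose(res1["t"], -res2["t"], equal_nan=True)

    def test_q_monotone_in_statistic(self):
        lfq, _ = netome.simulate_lfq(
            netome.SyntheticLFQSpec(seed=9, n_proteins=200, n_differential=10)
        )
        res = netome.differential_test(lfq, seed=9)
        s = res.reindex(res["t"].abs().sort_values(ascending=False).index)
        assert (np.diff(s["q"]) >= -1e-12).all()

    def test_min_valid_filter_and_errors(self):
        t = make_table({
            "ok": [1, 2, 3, 4, 5, 6],
            "sparse": [1, None, None, 4, 5, 6],
            "ok2": [2, 3, 4, 5, 6, 7],
        })
        res = netome.differential_test(t)
        assert "sparse" not in res.index
        with pytest.raises(ValueError, match="n_perm"):
            netome.differential_test(t, n_perm=5)

    def test_seeded_reproducibility(self):
        lfq, _ = netome.simulate_lfq(netome.SyntheticLFQSpec(seed=4))
        a = netome.differential_test(lfq, seed=7)
        b = netome.differential_test(lfq, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestZscoreCluster:
    def test_z_arithmetic_sample_sd(self):
        t = make_table({"p1": [2, 4, 8, 2, 4, 8], "p2": [3, 3, 4, 5, 6, 7]})
        res = netome.zscore_cluster(t)
        # log2 of (2,4,8,2,4,8) is (1,2,3,1,2,3); sample sd of (1,2,3,1,2,3)
        row = res["z"].loc["p1"].to_numpy()
        expect = (np.array([1, 2, 3, 1, 2, 3], dtype=float) - 2.0) / np.std(
            [1, 2, 3, 1, 2, 3], ddof=1
        )
        assert row == pytest.approx(expect)

    def test_identical_rows_merge_at_zero(self):
        t = make_table({
            "a": [2, 4, 8, 2, 4, 8],
            "b": [4, 8, 16, 4, 8, 16],  # same z-profile as a
            "c": [16, 8, 2, 4, 2, 1],
        })
        res = netome.zscore_cluster(t)
        assert res["linkage"][0, 2] == pytest.approx(0.0)

    def test_constant_rows_flagged_and_last(self):
        t = make_table({
            "flat": [5, 5, 5, 5, 5, 5],
            "a": [2, 4, 8, 2, 4, 8],
            "b": [16, 8, 2, 4, 2, 1],
        })
        res = netome.zscore_cluster(t)
        assert res["constant_rows"] == ["flat"]
        assert res["leaf_order"][-1] == "flat"

    def test_merge_heights_match_bruteforce_average_linkage(self, rng):
        values = {f"p{i}": list(rng.uniform(2, 100, 6)) for i in range(10)}
        t = make_table(values)
        res = netome.zscore_cluster(t)
        heights = sorted(res["linkage"][:, 2])
        assert heights == pytest.approx(
            sorted(_bruteforce_average_linkage(res["z"].to_numpy()))
        )

    def test_all_constant_rejected(self):
        t = make_table({"a": [1, 1, 1, 1, 1, 1], "b": [2, 2, 2, 2, 2, 2]})
        with pytest.raises(ValueError, match="constant"):
            netome.zscore_cluster(t)


def _bruteforce_average_linkage(z):
    """Independent O(n^3) agglomeration: average pairwise Euclidean
    distance between cluster members (UPGMA on raw distances)."""
    z = np.nan_to_num(z, nan=0.0)
    clusters = [[i] for i in range(len(z))]
    d = lambda a, b: float(np.linalg.norm(z[a] - z[b]))
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = float(np.mean(
                    [d(a, b) for a in clusters[i] for b in clusters[j]]
                ))
                if best is None or avg < best[0]:
                    best = (avg, i, j)
        avg, i, j = best
        heights.append(avg)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights
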