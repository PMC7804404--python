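"""Hi-C pipeline: counting, filtering, offsets, clustering."""
import numpy as np
import pandas as pd
import pytest

from chromdiff.genome import make_bins
from chromdiff.hic import (
    BackgroundEstimate,
    BinPairCounts,
    background_ligation_frequency,
    cluster_differential_interactions,
    count_bin_pairs,
    filter_bin_pairs,
    interaction_span_contrast,
    loess_offsets,
)
from chromdiff.stats import simes_p


def _reads(rows):
    return pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])


BINS = make_bins({"chr1": 500_000, "chr2": 300_000}, 25_000)


class TestCountBinPairs:
    def test_single_pair_off_diagonal(self):
        bp, inter = count_bin_pairs({"s": _reads([("chr1", 10, "chr1", 30_000)])}, BINS)
        assert bp.n_pairs == 1
        assert (bp.anchor1[0], bp.anchor2[0]) == (0, 1)
        assert bp.counts[0, 0] == 1

    def test_diagonal_pair(self):
        bp, _ = count_bin_pairs({"s": _reads([("chr1", 10, "chr1", 12_000)])}, BINS)
        assert (bp.anchor1[0], bp.anchor2[0]) == (0, 0)

    def test_matches_brute_force_accumulation(self, rng):
        rows = []
        for _ in range(10_000):
            c = rng.choice(["chr1", "chr2"])
            L = BINS.chrom_sizes[c]
            rows.append((c, int(rng.integers(0, L)), c, int(rng.integers(0, L))))
        bp, _ = count_bin_pairs({"s": _reads(rows)}, BINS)
        acc = {}
        for c, p1, _, p2 in rows:
            lo, _hi = BINS.index_range(c)
            b1, b2 = lo + p1 // 25_000, lo + p2 // 25_000
            key = (min(b1, b2), max(b1, b2))
            acc[key] = acc.get(key, 0) + 1
        fast = {
            (a1, a2): c
            for a1, a2, c in zip(bp.anchor1, bp.anchor2, bp.counts[:, 0])
        }
        assert fast == acc

    def test_conservation_of_read_pairs(self, rng):
        rows = []
        for _ in range(2_000):
            c1, c2 = rng.choice(["chr1", "chr2"], 2)
            rows.append(
                (c1, int(rng.integers(0, BINS.chrom_sizes[c1])),
                 c2, int(rng.integers(0, BINS.chrom_sizes[c2])))
            )
        bp, inter = count_bin_pairs({"s": _reads(rows)}, BINS)
        assert bp.counts.sum() + len(inter["s"]) == 2_000

    def test_position_outside_chromosome(self):
        with pytest.raises(ValueError, match="outside"):
            count_bin_pairs({"s": _reads([("chr1", 600_000, "chr1", 10)])}, BINS)


class TestBackground:
    def test_uniform_inter_matches_closed_form(self, rng):
        sizes = {"c1": 4_000_000, "c2": 4_000_000}
        n = 20_000
        reads = _reads(
            [
                ("c1", int(rng.integers(0, 4_000_000)), "c2", int(rng.integers(0, 4_000_000)))
                for _ in range(n)
            ]
        )
        bg = background_ligation_frequency({"s": reads}, sizes)
        # 2 x 2 two-Mb bins per chromosome -> 4 inter bin pairs
        expected = np.log2((n / 4 + 0.5) / n * 1e6)
        assert bg.log_cpm_2mb == pytest.approx(expected, abs=1e-9)

    def test_cpm_scale_invariant_to_depth(self, rng):
        sizes = {"c1": 4_000_000, "c2": 4_000_000}

        def sim(n):
            return _reads(
                [
                    ("c1", int(rng.integers(0, 4_000_000)), "c2", int(rng.integers(0, 4_000_000)))
                    for _ in range(n)
                ]
            )

        bg1 = background_ligation_frequency({"s": sim(5_000)}, sizes)
        bg2 = background_ligation_frequency({"s": sim(10_000)}, sizes)
        assert bg1.log_cpm_2mb == pytest.approx(bg2.log_cpm_2mb, abs=0.01)

    def test_single_chromosome_is_error(self):
        with pytest.raises(ValueError, match="background"):
            background_ligation_frequency(
                {"s": _reads([("c1", 0, "c1", 10)])}, {"c1": 1_000_000}
            )


def _bp_from_arrays(a1, a2, counts, bins=BINS, lib=None):
    counts = np.atleast_2d(np.asarray(counts))
    if counts.shape[0] != len(a1):
        counts = counts.T
    nsamp = counts.shape[1]
    return BinPairCounts(
        bins=bins,
        anchor1=np.asarray(a1),
        anchor2=np.asarray(a2),
        counts=counts,
        samples=[f"s{i}" for i in range(nsamp)],
        lib_sizes=np.full(nsamp, 1e6) if lib is None else np.asarray(lib, float),
    )


class TestFilter:
    def test_sixfold_boundary_is_strict(self):
        # choose a background so the sixfold threshold falls exactly at the
        # abundance of a count-7 pair (log2(7.5) CPM with a 1e6 library)
        log_cpm_2mb = np.log2(7.5) - np.log2(6) + 2 * np.log2(2_000_000 / 25_000)
        bg = BackgroundEstimate(log_cpm_2mb=log_cpm_2mb, bin_width=2_000_000, total_lib=1e6)
        bp = _bp_from_arrays([0, 0], [5, 8], [[7], [8]])
        out = filter_bin_pairs(bp, bg, min_bin_count=0)
        # exactly sixfold (count 7) is dropped by the strict "more than"
        assert out.n_pairs == 1
        assert out.anchor2[0] == 8

    def test_diagonal_always_dropped(self):
        bg = BackgroundEstimate(log_cpm_2mb=-30.0, bin_width=2_000_000, total_lib=1e6)
        bp = _bp_from_arrays([3, 3, 3], [3, 4, 5], [[100], [100], [100]])
        out = filter_bin_pairs(bp, bg, min_bin_count=0)
        assert list(out.anchor2) == [5]

    def test_matches_brute_force_predicates(self, rng):
        bg = BackgroundEstimate(log_cpm_2mb=-8.0, bin_width=2_000_000, total_lib=4e6)
        n = 400
        a1 = rng.integers(0, 15, n)
        a2 = a1 + rng.integers(0, 5, n)
        keyed = {}
        for i in range(n):
            keyed[(a1[i], a2[i])] = rng.integers(0, 30, 4)
        a1 = np.array([k[0] for k in keyed])
        a2 = np.array([k[1] for k in keyed])
        counts = np.array([v for v in keyed.values()])
        bp = _bp_from_arrays(a1, a2, counts, lib=np.full(4, 1e6))
        out = filter_bin_pairs(bp, bg, min_bin_count=5)
        # brute force
        marg = np.zeros(BINS.n_bins, dtype=int)
        for i in range(len(a1)):
            tot = counts[i].sum()
            marg[a1[i]] += tot
            if a2[i] != a1[i]:
                marg[a2[i]] += tot
        thr = bg.scaled_to(25_000) + np.log2(6)
        expected = set()
        for i in range(len(a1)):
            if marg[a1[i]] < 5 or marg[a2[i]] < 5:
                continue
            if a2[i] - a1[i] <= 1:
                continue
            abund = np.log2((counts[i].sum() + 0.5) / 4e6 * 1e6)
            if abund > thr:
                expected.add((a1[i], a2[i]))
        got = set(zip(out.anchor1, out.anchor2))
        assert got == expected

    def test_blacklist_drops_touching_pairs(self):
        bg = BackgroundEstimate(log_cpm_2mb=-30.0, bin_width=2_000_000, total_lib=1e6)
        bp = _bp_from_arrays([0, 4], [5, 9], [[50], [50]])
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [100_000], "end": [130_000]})
        out = filter_bin_pairs(bp, bg, blacklist=bl, min_bin_count=0)
        # blacklist covers bins 4 and 5 -> both pairs touch it
        assert out.n_pairs == 0


class TestLoessOffsets:
    def test_identical_samples_return_log_lib_size(self, rng):
        counts = rng.poisson(30, 300)
        bp = _bp_from_arrays(
            np.zeros(300, dtype=int) + np.arange(300) // 40,
            np.arange(300) % 40 + np.arange(300) // 40,
            np.column_stack([counts, counts]),
            bins=make_bins({"chr1": 10_000_000}, 25_000),
        )
        off = loess_offsets(bp, near_cutoff=100_000)
        np.testing.assert_allclose(off, np.log(1e6), atol=1e-8)

    def test_offsets_are_row_centred_on_mean_log_lib(self, rng):
        bins = make_bins({"chr1": 10_000_000}, 25_000)
        n = 400
        a1 = rng.integers(0, 200, n)
        a2 = a1 + rng.integers(2, 100, n)
        counts = rng.poisson(20, (n, 3)) + 1
        lib = np.array([8e5, 1e6, 1.2e6])
        bp = _bp_from_arrays(a1, a2, counts, bins=bins, lib=lib)
        off = loess_offsets(bp)
        np.testing.assert_allclose(
            off.mean(axis=1), np.mean(np.log(lib)), atol=1e-8
        )

    def test_planted_abundance_bias_is_removed(self, rng):
        bins = make_bins({"chr1": 20_000_000}, 25_000)
        n = 2000
        a1 = rng.integers(0, 400, n)
        a2 = a1 + rng.integers(6, 200, n)
        base = rng.lognormal(3.0, 1.0, n)
        c1 = rng.poisson(base)
        bias = np.where(base > np.median(base), 2.0, 1.0)
        c2 = rng.poisson(base * bias)
        bp = _bp_from_arrays(a1, a2, np.column_stack([c1, c2]), bins=bins)
        off = loess_offsets(bp, near_cutoff=100_000)
        # after applying offsets, M-vs-A trend should be flat: compare the
        # offset-corrected log ratio between high- and low-abundance halves
        lr = np.log2(c2 + 0.5) - np.log2(c1 + 0.5) - (off[:, 1] - off[:, 0]) / np.log(2)
        hi = base > np.median(base)
        assert abs(lr[hi].mean() - lr[~hi].mean()) < 0.12

    def test_single_sample_is_error(self):
        bp = _bp_from_arrays([0], [5], [[10]])
        with pytest.raises(ValueError):
            loess_offsets(bp)


def _di_frame(rows):
    df = pd.DataFrame(
        rows, columns=["chrom", "anchor1", "anchor2", "logFC", "p", "fdr"]
    )
    df["significant"] = df["fdr"] < 0.05
    df["span"] = (df["anchor2"] - df["anchor1"]) * 25_000.0
    df["direction"] = np.where(df["logFC"] > 0, "gained", "lost")
    return df


class TestClustering:
    def test_isolated_di_is_its_own_cluster(self):
        di = _di_frame([("chr1", 2, 10, 1.0, 0.001, 0.01)])
        cl = cluster_differential_interactions(di, BINS)
        assert len(cl) == 1
        assert cl["combined_p"].iloc[0] == pytest.approx(0.001)
        assert cl["n_members"].iloc[0] == 1

    def test_simes_combination_by_hand(self):
        di = _di_frame(
            [
                ("chr1", 2, 10, 1.0, 0.001, 0.01),
                ("chr1", 2, 11, 1.0, 0.004, 0.02),
            ]
        )
        cl = cluster_differential_interactions(di, BINS)
        assert len(cl) == 1
        assert cl["combined_p"].iloc[0] == pytest.approx(
            simes_p(np.array([0.001, 0.004]))
        ) == pytest.approx(0.002)

    def test_long_chain_is_split_into_bounded_boxes(self):
        bins = make_bins({"chr1": 10_000_000}, 25_000)
        # chain spanning 60 bins = 1.5 Mb = 3 x max size (500 kb = 20 bins)
        rows = [("chr1", 100 + k, 160 + k, 1.0, 0.001, 0.01) for k in range(60)]
        cl = cluster_differential_interactions(_di_frame(rows), bins, max_size=500_000)
        assert len(cl) >= 3
        for _, row in cl.iterrows():
            assert row["end1"] - row["start1"] <= 500_000
            assert row["end2"] - row["start2"] <= 500_000
        members = np.concatenate([row["members"] for _, row in cl.iterrows()])
        assert sorted(members) == list(range(60))

    def test_no_significant_pairs_gives_empty_table(self):
        di = _di_frame([("chr1", 2, 10, 1.0, 0.5, 0.9)])
        cl = cluster_differential_interactions(di, BINS)
        assert len(cl) == 0


class TestSpanContrast:
    def test_identical_distributions_give_small_t(self, rng):
        spans = rng.uniform(1e5, 1e6, 400)
        rows = []
        for i, s in enumerate(spans):
            rows.append(("chr1", 0, int(s / 25_000), 1.0 if i % 2 else -1.0, 0.001, 0.01))
        out = interaction_span_contrast(_di_frame(rows))
        assert abs(out["t"]) < 2.5

    def test_spans_equal_anchor_midpoint_distance_brute_force(self, rng):
        from chromdiff.hic import BinPairCounts

        bins = make_bins({"chr1": 10_000_000}, 25_000)
        a1 = rng.integers(0, 200, 100)
        a2 = a1 + rng.integers(0, 100, 100)
        bp = _bp_from_arrays(a1, a2, np.ones((100, 1), dtype=int), bins=bins)
        for k in range(100):
            mid1 = a1[k] * 25_000 + 12_500
            mid2 = a2[k] * 25_000 + 12_500
            assert bp.gap[k] == pytest.approx(abs(mid2 - mid1))

    def test_one_sided_directions_flagged(self):
        out = interaction_span_contrast(
            _di_frame([("chr1", 0, 10, 1.0, 0.001, 0.01)])
        )
        assert out.get("undefined", False)
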