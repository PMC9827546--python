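"""Peak/gene integration: overlap semantics, distances, metagene geometry."""

import numpy as np
import pandas as pd
import pytest

from mitoburst.config import AnalysisConfig
from mitoburst.io import PeakSet
from mitoburst.proximity import (binding_level_distribution, classify_bookmarked,
                                 distance_stratified_fisher, gene_bookmark_status,
                                 genes_bound_fraction, metagene_profile,
                                 nearest_peak_distance, site_count_distribution)


def peakset(rows, condition="interphase"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "height"])
    df["peak_id"] = [f"{condition[:2]}_{i}" for i in range(len(df))]
    return PeakSet(df=df[["chrom", "start", "end", "peak_id", "height"]], condition=condition)


def tss_table(positions, chrom="chr1", strand="+"):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(positions))],
                         "chrom": chrom, "pos": positions, "strand": strand})


class TestBookmarking:
    def test_single_bp_overlap_is_book(self):
        inter = peakset([("chr1", 100, 200, 1.0)])
        mito = peakset([("chr1", 199, 300, 1.0)], "mitotic")
        labels = classify_bookmarked(inter, mito)
        assert labels["label"].tolist() == ["Book"]
        # adjacency (no shared base) is not an overlap
        mito2 = peakset([("chr1", 200, 300, 1.0)], "mitotic")
        assert classify_bookmarked(inter, mito2)["label"].tolist() == ["Lost"]

    def test_empty_mitotic_set_gives_all_lost(self):
        inter = peakset([("chr1", 0, 10, 1.0), ("chr1", 50, 60, 1.0)])
        mito = peakset([], "mitotic")
        assert classify_bookmarked(inter, mito)["label"].tolist() == ["Lost", "Lost"]

    def test_identical_sets_give_all_book(self):
        rows = [("chr1", 0, 10, 1.0), ("chr2", 50, 60, 2.0)]
        labels = classify_bookmarked(peakset(rows), peakset(rows, "mitotic"))
        assert (labels["label"] == "Book").all()

    def test_chromosome_mismatch_is_an_error(self):
        inter = peakset([("chr1", 0, 10, 1.0)])
        mito = peakset([("chrM", 0, 5, 1.0)], "mitotic")
        with pytest.raises(ValueError, match="chrM"):
            classify_bookmarked(inter, mito)

    def test_book_plus_lost_partitions_interphase(self, small_sim):
        labels = classify_bookmarked(small_sim.peaks_interphase, small_sim.peaks_mitotic)
        assert len(labels) == len(small_sim.peaks_interphase)
        assert set(labels["label"]) <= {"Book", "Lost"}


class TestBoundFraction:
    def groups(self, n, cls="t40"):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)], "class": cls})

    def test_peak_inside_window_edge_counts(self, cfg):
        # 25-kb window: [TSS-12500, TSS+12500); peak at TSS+12300..12400 overlaps
        tss = tss_table([100_000])
        bound = genes_bound_fraction(self.groups(1),
                                     peakset([("chr1", 112_300, 112_400, 1.0)]).df,
                                     tss, cfg)
        assert bound.iloc[0]["pct_bound"] == 100.0

    def test_peak_beyond_window_does_not_count(self, cfg):
        tss = tss_table([100_000])
        bound = genes_bound_fraction(self.groups(1),
                                     peakset([("chr1", 112_600, 112_700, 1.0)]).df,
                                     tss, cfg)
        assert bound.iloc[0]["pct_bound"] == 0.0

    def test_no_peaks_gives_zero_percent_everywhere(self, cfg):
        groups = pd.concat([self.groups(3, "t40"), self.groups(2, "late")])
        groups["gene_id"] = [f"g{i}" for i in range(5)]
        bound = genes_bound_fraction(groups, peakset([]).df, tss_table(range(0, 50_000, 10_000)), cfg)
        assert (bound["pct_bound"] == 0.0).all()

    def test_monotone_in_window_size(self):
        rng = np.random.default_rng(8)
        tss = tss_table(rng.integers(0, 1_000_000, 50))
        peaks = peakset([("chr1", int(s), int(s) + 200, 1.0)
                         for s in rng.integers(0, 1_000_000, 30)]).df
        groups = self.groups(50)
        prev = -1.0
        for w in (2_000, 10_000, 50_000, 200_000):
            cfg = AnalysisConfig(tss_window_bp=w)
            pct = genes_bound_fraction(groups, peaks, tss, cfg).iloc[0]["pct_bound"]
            assert pct >= prev
            prev = pct

    def test_gene_level_book_lost_dichotomy(self, cfg):
        inter = peakset([("chr1", 99_000, 99_500, 1.0), ("chr1", 200_000, 200_500, 1.0)])
        mito = peakset([("chr1", 99_100, 99_200, 1.0)], "mitotic")
        labels = classify_bookmarked(inter, mito)
        status = gene_bookmark_status(inter, labels, tss_table([100_000, 201_000, 500_000]), cfg)
        assert status["status"].tolist() == ["bookmarked", "lost", "unbound"]


class TestNearestDistance:
    @staticmethod
    def brute_force(tss, peaks):
        out = []
        for _, t in tss.iterrows():
            best = np.inf
            for _, p in peaks.iterrows():
                if p["chrom"] != t["chrom"]:
                    continue
                best = min(best, max(p["start"] - t["pos"], t["pos"] - p["end"] + 1, 0))
            out.append(best)
        return np.array(out)

    def test_inside_peak_is_zero(self):
        d = nearest_peak_distance(tss_table([150]), peakset([("chr1", 100, 200, 1.0)]).df)
        assert d[0] == 0.0

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            n_t, n_p = int(rng.integers(1, 200)), int(rng.integers(0, 200))
            tss = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n_t)],
                                "chrom": rng.choice(["c1", "c2"], n_t),
                                "pos": rng.integers(0, 100_000, n_t),
                                "strand": "+"})
            starts = rng.integers(0, 100_000, n_p)
            peaks = pd.DataFrame({"chrom": rng.choice(["c1", "c2"], n_p),
                                  "start": starts,
                                  "end": starts + rng.integers(1, 5_000, n_p),
                                  "height": 1.0})
            fast = nearest_peak_distance(tss, peaks)
            assert np.array_equal(fast, self.brute_force(tss, peaks))


class TestDistributions:
    def test_no_peaks_puts_all_mass_at_zero(self, cfg):
        groups = pd.DataFrame({"gene_id": ["g0", "g1"], "class": "t40"})
        dist = site_count_distribution(groups, peakset([]).df, tss_table([100, 200]), cfg)
        assert dist.iloc[0]["count"] == 0 and dist.iloc[0]["scaled"] == 1.0

    def test_uniform_two_peaks_per_gene_is_a_point_mass(self, cfg):
        tss = tss_table([100_000, 300_000])
        rows = [("chr1", p - 100, p + 100, 1.0) for p in (99_000, 101_000, 299_000, 301_000)]
        groups = pd.DataFrame({"gene_id": ["g0", "g1"], "class": "t40"})
        dist = site_count_distribution(groups, peakset(rows).df, tss, cfg)
        assert dist["count"].tolist() == [2] and dist["proportion"].tolist() == [1.0]

    def test_binding_levels_empty_and_degenerate(self, cfg):
        groups = pd.DataFrame({"gene_id": ["g0"], "class": "t40"})
        empty = binding_level_distribution(groups, {"interphase": peakset([])},
                                           tss_table([100_000]), cfg)
        assert empty.empty
        same = binding_level_distribution(
            groups, {"interphase": peakset([("chr1", 99_000, 99_100, 7.0),
                                            ("chr1", 101_000, 101_100, 7.0)])},
            tss_table([100_000]), cfg)
        assert (same["height"] == 7.0).all() and len(same) == 2

    def test_planted_book_heights_recovered(self, small_sim, cfg):
        # planted Book peaks are drawn at twice the background height scale
        labels = classify_bookmarked(small_sim.peaks_interphase, small_sim.peaks_mitotic)
        merged = small_sim.peaks_interphase.df.merge(labels, on="peak_id")
        med_book = merged.loc[merged.label == "Book", "height"].median()
        med_lost = merged.loc[merged.label == "Lost", "height"].median()
        assert med_book > med_lost


class TestDistanceFisher:
    def test_all_inclusive_stratum_is_never_significant(self):
        cfg = AnalysisConfig(distance_grid_kb=(1, 10, 10_000))
        rng = np.random.default_rng(2)
        tss = tss_table(rng.integers(0, 900_000, 40))
        groups = pd.DataFrame({"gene_id": tss["gene_id"],
                               "class": ["grp"] * 20 + ["rest"] * 20})
        inter = peakset([("chr1", int(s), int(s) + 300, 1.0)
                         for s in rng.integers(0, 900_000, 25)])
        labels = classify_bookmarked(inter, peakset([], "mitotic"))
        track = distance_stratified_fisher(groups, inter, labels, tss, cfg)
        last = track[track["distance_kb"] == 10_000]
        lost_last = last[last["label"] == "Lost"]
        assert (lost_last["p"] == 1.0).all()
        # within-counts monotone in distance
        for (_, _), sub in track.groupby(["class", "label"]):
            assert sub.sort_values("distance_kb")["universe_within"].is_monotonic_increasing


class TestMetagene:
    def cov(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def test_rpm_arithmetic_on_uniform_coverage(self):
        cfg = AnalysisConfig(metagene_span_bp=1_000, metagene_bin_bp=100)
        cov = self.cov([("chr1", 0, 20_000, 0.1)])  # 0.1 per base -> 10 per 100-bp bin
        prof = metagene_profile(cov, tss_table([10_000]), library_size=2e6, cfg=cfg,
                                chrom_sizes={"chr1": 20_000})
        assert np.allclose(prof["rpm"], 10 / 2e6 * 1e6)  # = 5

    def test_symmetric_coverage_gives_symmetric_profile(self):
        cfg = AnalysisConfig(metagene_span_bp=2_000, metagene_bin_bp=100)
        cov = self.cov([("chr1", 9_000, 11_000, 2.0), ("chr1", 9_900, 10_100, 3.0)])
        prof = metagene_profile(cov, tss_table([10_000]), 1e6, cfg,
                                chrom_sizes={"chr1": 20_000})
        assert np.allclose(prof["rpm"].to_numpy(), prof["rpm"].to_numpy()[::-1])

    def test_minus_strand_downstream_peak_appears_right_of_center(self):
        cfg = AnalysisConfig(metagene_span_bp=4_000, metagene_bin_bp=100)
        # peak 1 kb downstream of a minus-strand TSS = 1 kb to its left genomically
        cov = self.cov([("chr1", 8_900, 9_100, 5.0)])
        prof = metagene_profile(cov, tss_table([10_000], strand="-"), 1e6, cfg,
                                chrom_sizes={"chr1": 20_000})
        peak_offset = prof.loc[prof["rpm"].idxmax(), "offset_bp"]
        assert peak_offset > 0
        # same geometry on the plus strand, mirrored coverage
        cov2 = self.cov([("chr1", 10_900, 11_100, 5.0)])
        prof2 = metagene_profile(cov2, tss_table([10_000], strand="+"), 1e6, cfg,
                                 chrom_sizes={"chr1": 20_000})
        assert prof2.loc[prof2["rpm"].idxmax(), "offset_bp"] == peak_offset

    def test_out_of_bounds_windows_dropped(self, caplog):
        import logging
        caplog.set_level(logging.INFO, logger="mitoburst")
        cfg = AnalysisConfig(metagene_span_bp=4_000, metagene_bin_bp=100)
        prof = metagene_profile(self.cov([("chr1", 0, 3_000, 1.0)]),
                                tss_table([500, 10_000]), 1e6, cfg,
                                chrom_sizes={"chr1": 20_000})
        assert any("dropped" in r.message for r in caplog.records)

    def test_nonpositive_library_size_rejected(self, cfg):
        with pytest.raises(ValueError):
            metagene_profile(self.cov([]), tss_table([100]), 0.0, cfg)
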