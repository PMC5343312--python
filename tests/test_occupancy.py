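"""Peak-to-gene assignment, co-occupancy ledger, TER, profiles, segments."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from isgscape import occupancy as occ


def peaks_df(rows, tf=None):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if tf is not None:
        df["tf"] = tf
    return df


def genes_df(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "tss", "strand", "class_label", "known_isg",
                 "is_pseudogene"],
    )


GENES = genes_df(
    [
        ("G1", "c1", 10_000, "+", "es-indISG", True, False),
        ("G2", "c1", 50_000, "-", "resISG", True, False),
        ("PG1", "c1", 30_000, "+", "other", False, True),
    ]
)


class TestAssignPeaks:
    def test_peak_on_tss_is_proximal_distance_zero(self):
        out = occ.assign_peaks(peaks_df([("c1", 9_750, 10_250)]), GENES)
        assert out.iloc[0]["distance"] == 0
        assert out.iloc[0]["proximal"] and out.iloc[0]["gene_id"] == "G1"

    @pytest.mark.parametrize("offset,proximal", [(5_000, True), (5_001, False)])
    def test_five_kb_boundary_inclusive(self, offset, proximal):
        center = 10_000 + offset
        out = occ.assign_peaks(peaks_df([("c1", center - 100, center + 100)]), GENES)
        assert bool(out.iloc[0]["proximal"]) is proximal

    def test_distance_tie_breaks_to_smaller_gene_id(self):
        genes = genes_df(
            [
                ("B", "c1", 1_000, "+", "other", False, False),
                ("A", "c1", 3_000, "+", "other", False, False),
            ]
        )
        out = occ.assign_peaks(peaks_df([("c1", 1_900, 2_100)]), genes)
        assert out.iloc[0]["gene_id"] == "A"

    def test_pseudogenes_excluded_by_default_included_by_flag(self):
        peak = peaks_df([("c1", 29_900, 30_100)])  # centered on the pseudogene
        default = occ.assign_peaks(peak, GENES)
        assert default.iloc[0]["gene_id"] == "G1"
        with_pg = occ.assign_peaks(peak, GENES, include_pseudogenes=True)
        assert with_pg.iloc[0]["gene_id"] == "PG1"

    def test_chrom_without_genes_flagged_unassigned(self):
        out = occ.assign_peaks(peaks_df([("cX", 0, 100)]), GENES)
        assert not out.iloc[0]["assigned"]
        assert np.isinf(out.iloc[0]["distance"])


class TestBuildLedger:
    def test_single_peak_singleton_region(self):
        ledger = occ.build_ledger(peaks_df([("c1", 0, 400)]), peaks_df([]))
        assert len(ledger) == 1
        assert ledger.iloc[0]["label"] == "isolated-STAT1"

    def test_overlapping_stat1_irf1_form_dual_region(self):
        ledger = occ.build_ledger(
            peaks_df([("c1", 100, 600)]), peaks_df([("c1", 550, 900)])
        )
        assert len(ledger) == 1
        row = ledger.iloc[0]
        assert (row["start"], row["end"], row["label"]) == (100, 900, "dual")

    def test_gap_beyond_link_distance_stays_isolated(self):
        ledger = occ.build_ledger(
            peaks_df([("c1", 0, 400)]), peaks_df([("c1", 1_500, 1_900)])
        )
        assert list(ledger["label"]) == ["isolated-STAT1", "isolated-IRF1"]

    def test_gap_at_exactly_link_distance_links(self):
        ledger = occ.build_ledger(
            peaks_df([("c1", 0, 400)]), peaks_df([("c1", 900, 1_200)])
        )
        assert list(ledger["label"]) == ["dual"]

    def test_strict_overlap_mode(self):
        ledger = occ.build_ledger(
            peaks_df([("c1", 0, 400)]), peaks_df([("c1", 500, 900)]), link_bp=0
        )
        assert len(ledger) == 2

    def test_partition_every_peak_in_exactly_one_region(self):
        rng = np.random.default_rng(4)
        s = peaks_df([("c1", int(x), int(x) + 300) for x in np.sort(rng.integers(0, 200_000, 25)) * 3])
        r = peaks_df([("c1", int(x), int(x) + 300) for x in np.sort(rng.integers(0, 200_000, 50)) * 3])
        ledger = occ.build_ledger(s, r)
        assert ledger["n_stat1"].sum() == len(s)
        assert ledger["n_irf1"].sum() == len(r)
        # regions are disjoint and separated by more than the link distance
        for chrom, grp in ledger.groupby("chrom"):
            gaps = grp["start"].to_numpy()[1:] - grp["end"].to_numpy()[:-1]
            assert (gaps > occ.DUAL_LINK_BP).all()
        counts = ledger["label"].value_counts()
        assert counts.sum() == len(ledger)


class TestSummarize:
    def test_empty_ledger_all_zero(self):
        summary = occ.summarize_cooccupancy(occ.build_ledger(peaks_df([]), peaks_df([])))
        assert summary["n_regions"] == 0
        assert all(v == 0 for v in summary["rounded"].values())

    def test_printed_ledger_shares(self):
        # 36 isolated STAT1 / 140 isolated IRF1 / 54 dual = 16% / 61% / 23%
        ledger = pd.DataFrame(
            {
                "chrom": "c1",
                "start": np.arange(230) * 10_000,
                "end": np.arange(230) * 10_000 + 500,
                "n_stat1": [1] * 36 + [0] * 140 + [1] * 52 + [2] * 2,
                "n_irf1": [0] * 36 + [1] * 140 + [1] * 52 + [2] * 2,
            }
        )
        ledger["label"] = np.where(
            (ledger.n_stat1 > 0) & (ledger.n_irf1 > 0),
            "dual",
            np.where(ledger.n_stat1 > 0, "isolated-STAT1", "isolated-IRF1"),
        )
        summary = occ.summarize_cooccupancy(ledger)
        assert summary["n_regions"] == 230
        assert summary["n_stat1_peaks"] == 92
        assert summary["n_irf1_peaks"] == 196
        assert summary["rounded"]["pct_isolated_stat1"] == 16
        assert summary["rounded"]["pct_isolated_irf1"] == 61
        assert summary["rounded"]["pct_dual"] == 23
        assert summary["rounded"]["pct_dual_of_stat1_peaks"] == 59
        assert summary["rounded"]["pct_dual_of_irf1_peaks"] == 28


class TestRandomSites:
    SEGMENTS = {"c1": 1_000_000, "c2": 500_000}

    def peaks(self):
        rng = np.random.default_rng(5)
        rows = [("c1", int(x), int(x) + 400) for x in rng.integers(0, 999_000, 30)]
        rows += [("c2", int(x), int(x) + 700) for x in rng.integers(0, 499_000, 10)]
        return peaks_df(rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    def test_length_multiset_matched(self):
        peaks = self.peaks()
        sites = occ.sample_random_sites(peaks, self.SEGMENTS, len(peaks), seed=0)
        assert sorted(sites["end"] - sites["start"]) == sorted(peaks["end"] - peaks["start"])

    def test_no_overlap_with_real_peaks(self):
        peaks = self.peaks()
        sites = occ.sample_random_sites(peaks, self.SEGMENTS, 200, seed=1)
        for chrom, grp in sites.groupby("chrom"):
            real = peaks[peaks["chrom"] == chrom]
            for s, e in zip(grp["start"], grp["end"]):
                assert not ((real["start"] < e) & (s < real["end"])).any()

    def test_deterministic_under_seed(self):
        peaks = self.peaks()
        a = occ.sample_random_sites(peaks, self.SEGMENTS, 50, seed=7)
        b = occ.sample_random_sites(peaks, self.SEGMENTS, 50, seed=7)
        assert a.equals(b)

    def test_per_segment_proportions_converge(self):
        peaks = self.peaks()  # 30 c1 : 10 c2
        sites = occ.sample_random_sites(peaks, self.SEGMENTS, 10_000, seed=2)
        observed = sites["chrom"].value_counts()
        stat = chisquare([observed["c1"], observed["c2"]], [7_500, 2_500])
        assert stat.pvalue > 0.01

    def test_saturated_segment_errors(self):
        peaks = peaks_df([("tiny", 0, 900)])
        with pytest.raises(RuntimeError, match="tiny"):
            occ.sample_random_sites(peaks, {"tiny": 1_000}, 5, seed=0)


def assigned_frame(rows):
    return pd.DataFrame(
        rows, columns=["tf", "gene_class", "proximal", "assigned"]
    ).assign(chrom="c1")


class TestTer:
    def test_identical_distributions_give_ter_one(self):
        rows = [("STAT1", "es-indISG", True, True)] * 6 + [
            ("STAT1", "other", False, True)
        ] * 2
        ter = occ.compute_ter(assigned_frame(rows), assigned_frame(rows))
        support = ter[ter["random_pct"] > 0]
        assert np.allclose(support["ter"], 1.0)

    def test_concentrated_observed_vs_uniform_random(self):
        # all TF sites at class X proximal; random uniform over 4 classes
        obs = assigned_frame([("STAT1", "X", True, True)] * 8)
        rand = assigned_frame(
            [(None, c, True, True) for c in ("X", "Y", "Z", "W") for _ in range(2)]
        )
        ter = occ.compute_ter(obs, rand)
        cell = ter[
            (ter["tf"] == "STAT1") & (ter["gene_class"] == "X") & (ter["location"] == "proximal")
        ].iloc[0]
        assert cell["ter"] == pytest.approx(4.0)
        assert cell["above_threshold"]

    def test_threshold_flag_only_above_two(self):
        obs = assigned_frame(
            [("STAT1", "X", True, True)] * 2 + [("STAT1", "Y", True, True)] * 2
        )
        rand = assigned_frame(
            [(None, "X", True, True)] * 1 + [(None, "Y", True, True)] * 3
        )
        ter = occ.compute_ter(obs, rand)
        x = ter[(ter["tf"] == "STAT1") & (ter["gene_class"] == "X") & (ter["location"] == "proximal")]
        y = ter[(ter["tf"] == "STAT1") & (ter["gene_class"] == "Y") & (ter["location"] == "proximal")]
        assert not x.iloc[0]["above_threshold"]  # ter = 2.0 exactly, not > 2
        assert not y.iloc[0]["above_threshold"]

    def test_zero_random_support_flagged_infinite(self):
        obs = assigned_frame([("STAT1", "X", True, True)])
        rand = assigned_frame([(None, "Y", True, True)])
        ter = occ.compute_ter(obs, rand)
        cell = ter[(ter["gene_class"] == "X") & (ter["location"] == "proximal") & (ter["tf"] == "STAT1")]
        assert np.isinf(cell.iloc[0]["ter"])


class TestBindingProfile:
    SEGMENTS = {"c1": 1_000_000}

    def one_gene(self, tss=500_000, strand="+"):
        return pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["c1"], "tss": [tss], "strand": [strand]}
        )

    def test_peak_at_tss_window_zero(self):
        prof = occ.binding_profile(
            peaks_df([("c1", 500_150, 500_350)]), self.one_gene(), self.SEGMENTS
        )
        assert len(prof) == 401
        assert prof.loc[prof["window"] == 0, "mean_freq"].iloc[0] == 1.0
        assert prof.loc[prof["window"] != 0, "mean_freq"].sum() == 0

    def test_strand_orientation_flips_offset(self):
        peaks = peaks_df([("c1", 509_900, 510_100)])  # +10 kb of the TSS
        plus = occ.binding_profile(peaks, self.one_gene(strand="+"), self.SEGMENTS)
        minus = occ.binding_profile(peaks, self.one_gene(strand="-"), self.SEGMENTS)
        assert plus.loc[plus["window"] == 10, "mean_freq"].iloc[0] == 1.0
        assert minus.loc[minus["window"] == -10, "mean_freq"].iloc[0] == 1.0

    def test_windows_beyond_segment_are_missing_not_zero(self):
        gene = self.one_gene(tss=50_000)  # 50 kb from the segment start
        prof = occ.binding_profile(peaks_df([]), gene, self.SEGMENTS)
        beyond = prof[prof["window"] < -49]
        assert (beyond["n_genes"] == 0).all()
        assert beyond["mean_freq"].isna().all()
        inside = prof[prof["window"] > -49]
        assert (inside["n_genes"] == 1).all()

    def test_mean_over_genes_ignores_missing(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "chrom": ["c1", "c1"],
                "tss": [500_000, 700_000],
                "strand": ["+", "+"],
            }
        )
        prof = occ.binding_profile(
            peaks_df([("c1", 500_100, 500_300)]), genes, self.SEGMENTS
        )
        row = prof[prof["window"] == 0].iloc[0]
        assert row["mean_freq"] == 0.5 and row["n_genes"] == 2

    def test_profile_conservation(self):
        rng = np.random.default_rng(6)
        peaks = peaks_df(
            [("c1", int(x), int(x) + 200) for x in np.sort(rng.integers(0, 990_000, 40))]
        )
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(5)],
                "chrom": "c1",
                "tss": rng.integers(250_000, 750_000, 5),
                "strand": "+",
            }
        )
        prof = occ.binding_profile(peaks, genes, self.SEGMENTS)
        total = np.nansum(prof["mean_freq"] * prof["n_genes"])
        centers = (peaks["start"] + peaks["end"]).to_numpy() / 2
        incidences = sum(
            int(((centers >= tss - 200_500) & (centers < tss + 200_500)).sum())
            for tss in genes["tss"]
        )
        assert total == pytest.approx(incidences, abs=1e-9)


class TestSegmentStats:
    def test_mhc_like_ratio_and_proximal_fractions(self):
        # 56 IRF1 vs 16 STAT1 -> 3.5:1; 26 gene-proximal + 17 pseudogene-
        # proximal of 56 IRF1 -> 77% proximal once pseudogenes count
        genes = [("G%02d" % i, "mhc", 100_000 + 60_000 * i, "+", "other", False, False)
                 for i in range(26)]
        genes += [("PG%02d" % i, "mhc", 3_000_000 + 60_000 * i, "+", "other", False, True)
                  for i in range(17)]
        genes = genes_df(genes)
        rows = []
        for i in range(26):  # IRF1 proximal to real genes
            rows.append(("mhc", 100_000 + 60_000 * i - 100, 100_000 + 60_000 * i + 100))
        for i in range(17):  # IRF1 proximal only to pseudogenes
            rows.append(("mhc", 3_000_000 + 60_000 * i - 100, 3_000_000 + 60_000 * i + 100))
        for i in range(13):  # remote IRF1
            rows.append(("mhc", 4_500_000 + 30_000 * i, 4_500_000 + 30_000 * i + 200))
        irf1 = peaks_df(rows, tf="IRF1")
        stat1 = peaks_df(
            [("mhc", 2_000_000 + 30_000 * i, 2_000_000 + 30_000 * i + 200) for i in range(16)],
            tf="STAT1",
        )
        peaks = pd.concat([stat1, irf1], ignore_index=True)
        stats = occ.segment_stats(peaks, genes, {"mhc": 5_000_000})
        row = stats[stats["segment"] == "mhc"].iloc[0]
        assert row["irf1_stat1_ratio"] == pytest.approx(3.5)
        irf1_only = occ.assign_peaks(irf1, genes, include_pseudogenes=True)
        assert round(100.0 * irf1_only["proximal"].mean()) == 77

    def test_es_density_and_isg_fraction(self):
        genes = genes_df(
            [("G%03d" % i, "s", 1_000 + 40 * i, "+",
              "es-indISG" if i < 31 else "other", i < 95, False)
             for i in range(375)]
        )
        stats = occ.segment_stats(
            peaks_df([], tf=None).assign(tf=[]), genes, {"s": 16_000_000}
        )
        row = stats[stats["segment"] == "s"].iloc[0]
        assert round(row["es_indisg_per_mb"], 1) == 1.9
        assert round(row["pct_known_isg"]) == 25

    def test_empty_segment_zeroes_and_undefined_ratio(self):
        stats = occ.segment_stats(
            peaks_df([], tf=None).assign(tf=[]),
            genes_df([("G1", "s", 100, "+", "other", False, False)]),
            {"s": 1_000_000, "empty": 1_000_000},
        )
        row = stats[stats["segment"] == "empty"].iloc[0]
        assert row["n_stat1"] == 0 and row["n_irf1"] == 0
        assert np.isnan(row["irf1_stat1_ratio"])


class TestBasalFractions:
    def test_study_fractions(self):
        peaks = pd.DataFrame(
            {
                "tf": ["STAT1"] * 94 + ["IRF1"] * 224,
                "condition": ["basal"] * 2 + ["induced"] * 92
                + ["basal"] * 28 + ["induced"] * 196,
            }
        )
        frac = occ.basal_induced_fractions(peaks)
        assert round(frac["STAT1"], 1) == 2.2
        assert round(frac["IRF1"], 1) == 14.3
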