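import io

import numpy as np
import pandas as pd
import pytest

from nascentlnc.genomic_io import GenomicInterval, units_to_bed
from nascentlnc.quantification import count_region
from nascentlnc.synthetic_data import (
    SimulationConfig,
    SimulationError,
    generate_annotation,
    simulate_chip_tracks,
    simulate_counts,
    simulate_gro_coverage,
)


def small_config(**kw):
    defaults = dict(seed=0, n_coding=10, n_p_lnc=10, n_erna=15, n_superenhancer_clusters=1)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_de=1.5)

    def test_negative_dispersion(self):
        with pytest.raises(ValueError):
            SimulationConfig(dispersion=-0.1)

    def test_retention_out_of_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(stability={"coding": 1.0, "p_lnc": 0.6, "eRNA": 1.3})

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"seed": 1, "bogus": 2})

    def test_cluster_members_exceed_erna(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_erna=5, n_superenhancer_clusters=2, se_cluster_members=4)


class TestGenerateAnnotation:
    def test_class_counts_by_construction(self):
        cfg = small_config(n_coding=12, n_p_lnc=7, n_erna=9, n_superenhancer_clusters=2,
                           se_cluster_members=3)
        _, truth = generate_annotation(cfg)
        counts = truth.transcripts["class"].value_counts().to_dict()
        assert counts == {"coding": 12, "p_lnc": 7, "eRNA": 9}

    def test_no_coding_only_lncrnas(self):
        cfg = small_config(n_coding=0, coregulated_frac=0.0)
        units, truth = generate_annotation(cfg)
        assert set(truth.transcripts["class"]) == {"p_lnc", "eRNA"}
        assert all(u.unit_class != "coding" for u in units)

    def test_same_seed_byte_identical_bed(self, tmp_path):
        cfg = small_config(seed=123)
        for i in (1, 2):
            units, _ = generate_annotation(cfg)
            units_to_bed(units, tmp_path / f"a{i}.bed")
        assert (tmp_path / "a1.bed").read_bytes() == (tmp_path / "a2.bed").read_bytes()

    def test_min_spacing_respected(self):
        _, truth = generate_annotation(small_config())
        t = truth.transcripts.sort_values(["chrom", "start"])
        for chrom, grp in t.groupby("chrom"):
            gaps = grp["start"].values[1:] - grp["end"].values[:-1]
            assert (gaps >= 1_500).all()  # cluster members
            # non-cluster neighbours must satisfy the 5 kb contract
            non_cluster = grp[grp["cluster_id"] == ""]
            gaps2 = non_cluster["start"].values[1:] - non_cluster["end"].values[:-1]
            assert (gaps2 >= 5_000).all()

    def test_cluster_members_within_stitch_distance(self):
        cfg = small_config(n_erna=20, n_superenhancer_clusters=2, se_cluster_members=4)
        _, truth = generate_annotation(cfg)
        for cid, crow in truth.clusters.iterrows():
            members = truth.transcripts.loc[crow["members"].split(",")]
            members = members.sort_values("start")
            gaps = members["start"].values[1:] - members["end"].values[:-1]
            assert (gaps <= 12_500).all()
            assert len(members) >= 3

    def test_lncrna_lengths_above_200(self):
        _, truth = generate_annotation(small_config())
        lnc = truth.transcripts[truth.transcripts["class"] != "coding"]
        assert ((lnc["end"] - lnc["start"]) > 200).all()

    def test_coregulated_lnc_within_100kb_and_shares_de(self):
        cfg = small_config(coregulated_frac=1.0, frac_de=0.5)
        _, truth = generate_annotation(cfg)
        t = truth.transcripts
        coreg = t[t["coregulated_with"] != ""]
        assert len(coreg) > 0
        for _, row in coreg.iterrows():
            gene = t.loc[row["coregulated_with"]]
            assert row["chrom"] == gene["chrom"]
            dist = max(gene["start"] - row["end"], row["start"] - gene["end"], 0)
            assert dist <= 100_000
            assert row["is_de"] == gene["is_de"]
            assert row["log2fc"] == gene["log2fc"]

    def test_infeasible_packing_raises(self):
        cfg = small_config(genome={"chr1": 100_000}, n_coding=50, n_p_lnc=0, n_erna=15)
        with pytest.raises(SimulationError):
            generate_annotation(cfg)

    def test_log2fc_zero_iff_not_de(self):
        _, truth = generate_annotation(small_config(frac_de=0.5))
        t = truth.transcripts
        assert ((t["log2fc"] == 0) == ~t["is_de"]).all()


class TestSimulateChipTracks:
    def test_noiseless_ratio_is_exact(self):
        cfg = small_config(chip_noise_cv=0.0, n_superenhancer_clusters=0, n_erna=5)
        _, truth = generate_annotation(cfg)
        tracks = simulate_chip_tracks(truth, cfg)
        for tid, rec in truth.transcripts.iterrows():
            win = GenomicInterval(rec["chrom"], max(0, rec["tss"] - 1000), rec["tss"] + 1000)
            me3 = tracks.me3.mean(win)
            me1 = tracks.me1.mean(win)
            ratio = me3 / me1
            want = (
                cfg.me_high_amp / cfg.me_low_amp
                if rec["class"] in ("coding", "p_lnc")
                else cfg.me_low_amp / cfg.me_high_amp
            )
            assert ratio == pytest.approx(want, rel=1e-6)

    def test_se_members_top_k27ac_in_active_condition(self):
        cfg = small_config(n_erna=20, n_superenhancer_clusters=1, se_cluster_members=4)
        _, truth = generate_annotation(cfg)
        tracks = simulate_chip_tracks(truth, cfg)
        crow = truth.clusters.iloc[0]
        track = tracks.k27ac_b if crow["active_in"] in ("B", "both") else tracks.k27ac_a
        member_ids = set(crow["members"].split(","))
        signals = {}
        for tid, rec in truth.transcripts.iterrows():
            if rec["class"] != "eRNA":
                continue
            win = GenomicInterval(rec["chrom"], max(0, rec["tss"] - 1500), rec["tss"] + 1500)
            signals[tid] = track.sum(win)
        top4 = sorted(signals, key=signals.get, reverse=True)[:4]
        assert set(top4) == member_ids

    def test_mean_bump_height_within_clt_bound(self):
        cfg = small_config(n_coding=0, n_p_lnc=100, n_erna=15, coregulated_frac=0.0,
                           genome={"chr1": 2_000_000, "chr2": 2_000_000})
        _, truth = generate_annotation(cfg)
        tracks = simulate_chip_tracks(truth, cfg)
        heights = []
        for tid, rec in truth.transcripts.iterrows():
            if rec["class"] != "p_lnc":
                continue
            win = GenomicInterval(rec["chrom"], rec["tss"] - 20, rec["tss"] + 20)
            heights.append(tracks.me3.mean(win))
        heights = np.array(heights)
        # peak height of the rasterized bump is ~ amp; noise CV 0.2, n=100
        expected = cfg.me_high_amp
        se = expected * cfg.chip_noise_cv / np.sqrt(len(heights))
        assert abs(heights.mean() - expected) <= 3.5 * se + 0.05 * expected

    def test_determinism(self):
        cfg = small_config(seed=7)
        _, truth = generate_annotation(cfg)
        t1 = simulate_chip_tracks(truth, cfg)
        t2 = simulate_chip_tracks(truth, cfg)
        assert t1.me3.total() == t2.me3.total()
        assert t1.k27ac_a.total() == t2.k27ac_a.total()


class TestSimulateCounts:
    def test_poisson_at_zero_dispersion(self):
        cfg = SimulationConfig(
            seed=3, n_coding=0, n_p_lnc=1500, n_erna=15, n_superenhancer_clusters=1,
            p_lnc_length=(500, 1500),
            genome={"chr1": 20_000_000, "chr2": 20_000_000},
            dispersion=0.0, frac_de=0.0, mean_sdlog=0.0, mean_expression=100.0,
            library_size_sigma=0.0, coregulated_frac=0.0,
        )
        _, truth = generate_annotation(cfg)
        gro, _ = simulate_counts(truth, cfg)
        # all rows share one mean: pool >10,000 null draws across samples
        vals = gro.counts.values.astype(float).ravel()
        ratio = vals.var() / vals.mean()
        assert 0.95 <= ratio <= 1.05

    def test_zero_retention_gives_all_zero_rnaseq(self):
        cfg = small_config(stability={"coding": 1.0, "p_lnc": 0.6, "eRNA": 0.0})
        _, truth = generate_annotation(cfg)
        _, rna = simulate_counts(truth, cfg)
        erna_ids = truth.transcripts.index[truth.transcripts["class"] == "eRNA"]
        assert (rna.counts.loc[erna_ids].values == 0).all()

    def test_null_config_truth_all_zero_lfc(self):
        cfg = small_config(frac_de=0.0)
        _, truth = generate_annotation(cfg)
        assert (truth.transcripts["log2fc"] == 0).all()
        assert (~truth.transcripts["is_de"]).all()

    def test_determinism(self):
        cfg = small_config(seed=9)
        _, truth = generate_annotation(cfg)
        gro1, rna1 = simulate_counts(truth, cfg)
        gro2, rna2 = simulate_counts(truth, cfg)
        pd.testing.assert_frame_equal(gro1.counts, gro2.counts)
        pd.testing.assert_frame_equal(rna1.counts, rna2.counts)

    @pytest.mark.parametrize(
        "phi,min_frac",
        [
            # at phi=0.1 the dispersion term alone caps P(|err| <= 0.5) near
            # 0.87 for n=4/4 regardless of mu, so 0.82 is the honest bound
            (0.1, 0.82),
            (0.05, 0.90),
        ],
    )
    def test_planted_lfc_recoverable(self, phi, min_frac):
        cfg = SimulationConfig(
            seed=11, n_coding=0, n_p_lnc=300, n_erna=15, n_superenhancer_clusters=1,
            genome={"chr1": 6_000_000, "chr2": 6_000_000},
            frac_de=0.3, lfc_magnitude=2.0, mean_expression=200.0, mean_sdlog=0.0,
            dispersion=phi, coregulated_frac=0.0, p_lnc_up_bias=0.5,
        )
        _, truth = generate_annotation(cfg)
        gro, _ = simulate_counts(truth, cfg)
        t = truth.transcripts
        de_rows = t.index[t["is_de"] & (t["class"] == "p_lnc")]
        a_cols = [s for s, c in gro.condition.items() if c == "A"]
        b_cols = [s for s, c in gro.condition.items() if c == "B"]
        est = np.log2((gro.counts.loc[de_rows, b_cols].mean(axis=1) + 0.5)
                      / (gro.counts.loc[de_rows, a_cols].mean(axis=1) + 0.5))
        err = np.abs(est - t.loc[de_rows, "log2fc"])
        assert (err <= 0.5).mean() >= min_frac


class TestSimulateGroCoverage:
    def test_noiseless_counts_round_trip(self):
        cfg = small_config(seed=4)
        _, truth = generate_annotation(cfg)
        gro, _ = simulate_counts(truth, cfg)
        coverage = simulate_gro_coverage(truth, gro, cfg)
        s = gro.sample_ids[0]
        for tid, rec in truth.transcripts.head(10).iterrows():
            interval = GenomicInterval(rec["chrom"], int(rec["start"]), int(rec["end"]), rec["strand"])
            got = count_region(coverage[s], interval, stranded=True)
            assert got == int(gro.counts.loc[tid, s])

    def test_signal_is_strand_specific(self):
        cfg = small_config(seed=4)
        _, truth = generate_annotation(cfg)
        gro, _ = simulate_counts(truth, cfg)
        coverage = simulate_gro_coverage(truth, gro, cfg)
        s = gro.sample_ids[0]
        plus_ids = truth.transcripts.index[truth.transcripts["strand"] == "+"]
        expected_plus = int(gro.counts.loc[plus_ids, s].sum())
        assert int(round(coverage[s].plus.total())) == expected_plus

    def test_background_adds_signal_everywhere(self):
        cfg = small_config(seed=4, gro_background=0.01, gro_noise=False)
        _, truth = generate_annotation(cfg)
        gro, _ = simulate_counts(truth, cfg)
        coverage = simulate_gro_coverage(truth, gro, cfg)
        s = gro.sample_ids[0]
        # an empty corner of the genome still has background signal
        total = coverage[s].plus.total()
        assert total > 0.009 * sum(cfg.genome.values())
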