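import numpy as np
import pandas as pd
import pytest

from repairscape import (
    BinnedSignal,
    GeneModel,
    GenomicInterval,
    ReadAlignment,
    classify_peaks,
    cluster_samples,
    compare_strands,
    count_in_bins,
    gene_metaprofile,
    genome_bins,
    normalize_chain,
    orient_plus_reversed,
    peak_profile,
    rpkm_from_counts,
    rpm_from_counts,
    select_genes,
    simulate_signal_tracks,
    stratify,
    tertile_boxstats,
    tpm_from_counts,
)


def _read(start, length=24, strand="+", chrom="I"):
    return ReadAlignment(GenomicInterval(chrom, start, start + length, strand))


def brute_force_counts(reads, regions, strand_mode, frac=0.5):
    """Independent O(n*m) oracle for the overlap-fraction counting rule."""
    counts = np.zeros(len(regions))
    for j, reg in enumerate(regions):
        for r in reads:
            if r.chrom != reg.chrom:
                continue
            ov = min(r.end, reg.end) - max(r.start, reg.start)
            if ov <= 0:
                continue
            if ov + 1e-9 < frac * r.read_length:
                continue
            if strand_mode == "same" and r.strand != reg.strand:
                continue
            if strand_mode == "opposite" and (
                r.strand == reg.strand or r.strand not in "+-"
            ):
                continue
            counts[j] += 1
    return counts


class TestGenomeBins:
    def test_exact_tiling(self):
        assert len(genome_bins({"I": 10_000}, 2000)) == 5

    def test_terminal_partial_bin(self):
        bins = genome_bins({"I": 10_500}, 2000)
        assert len(bins) == 6 and bins[-1].width == 500

    def test_total_count_is_sum_of_ceils(self):
        sizes = {"I": 10_500, "II": 4_000, "III": 1}
        bins = genome_bins(sizes, 2000)
        assert len(bins) == sum(-(-s // 2000) for s in sizes.values())


class TestCountInBins:
    def test_exact_half_overlap_counted(self):
        regions = [GenomicInterval("I", 100, 200, ".")]
        # 24-nt read with exactly 12 nt inside
        read = _read(88, 24)
        assert count_in_bins([read], regions)[0] == 1

    def test_just_under_half_not_counted(self):
        regions = [GenomicInterval("I", 100, 200, ".")]
        read = _read(87, 24)  # 11 of 24 nt inside
        assert count_in_bins([read], regions)[0] == 0

    def test_ts_convention(self):
        gene = GenomicInterval("I", 0, 1000, "+")
        plus_read = _read(100, strand="+")
        minus_read = _read(100, strand="-")
        # TS of a + gene is carried by - reads (opposite mode)
        assert count_in_bins([plus_read], [gene], strand_mode="opposite")[0] == 0
        assert count_in_bins([minus_read], [gene], strand_mode="opposite")[0] == 1
        assert count_in_bins([plus_read], [gene], strand_mode="same")[0] == 1

    def test_unstranded_region_with_strand_mode_raises(self):
        with pytest.raises(ValueError):
            count_in_bins([_read(0)], [GenomicInterval("I", 0, 10, ".")], "same")

    @pytest.mark.parametrize("strand_mode", ["any", "same", "opposite"])
    def test_matches_brute_force(self, rng, strand_mode):
        regions = [
            GenomicInterval("I", s, s + 50, "+" if k else "-")
            for k, s in enumerate(range(0, 5000, 50))
        ]
        reads = [
            _read(
                int(rng.integers(0, 5000)),
                length=int(rng.integers(10, 40)),
                strand="+" if rng.random() < 0.5 else "-",
            )
            for _ in range(1000)
        ]
        got = count_in_bins(reads, regions, strand_mode=strand_mode)
        want = brute_force_counts(reads, regions, strand_mode)
        assert np.array_equal(got, want)

    def test_strand_swap_symmetry(self, rng):
        """Flipping all read strands swaps TS and NTS counts exactly."""
        regions = [GenomicInterval("I", s, s + 100, "+") for s in range(0, 2000, 100)]
        reads = [
            _read(int(rng.integers(0, 2000)), strand="+" if rng.random() < 0.5 else "-")
            for _ in range(300)
        ]
        flipped = [
            ReadAlignment(
                GenomicInterval(r.chrom, r.start, r.end, "-" if r.strand == "+" else "+"),
            )
            for r in reads
        ]
        ts = count_in_bins(reads, regions, "opposite")
        nts = count_in_bins(reads, regions, "same")
        assert np.array_equal(count_in_bins(flipped, regions, "same"), ts)
        assert np.array_equal(count_in_bins(flipped, regions, "opposite"), nts)

    def test_rpm_normalization(self):
        regions = [GenomicInterval("I", 0, 100, ".")]
        reads = [_read(10), _read(600)]
        rpm = count_in_bins(reads, regions, normalize="RPM")
        assert rpm[0] == pytest.approx(1 * 1e6 / 2)


class TestClusterSamples:
    def test_duplicated_sample_distance_zero(self, rng):
        x = rng.random(50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.random(50)})
        res = cluster_samples(df)
        assert res.distance.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_rescaling_invariance(self, rng):
        x, y = rng.random(60), rng.random(60)
        d1 = cluster_samples(pd.DataFrame({"a": x, "b": y})).distance
        d2 = cluster_samples(pd.DataFrame({"a": np.exp(3 * x), "b": y})).distance
        assert d1.loc["a", "b"] == pytest.approx(d2.loc["a", "b"])

    def test_constant_sample_raises_with_name(self, rng):
        df = pd.DataFrame({"ok": rng.random(10), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(df)

    def test_two_class_recovery(self):
        profiles = np.vstack([np.linspace(0, 1, 100), np.linspace(1, 0, 100)])
        sep = 1.0
        hits = 0
        for s in range(20):
            df, labels = simulate_signal_tracks(
                100, 10, profiles, noise_sd=0.2 * sep, seed=s
            )
            cut = cluster_samples(df).cut(2)
            same = all(
                (cut[i] == cut[j]) == (labels[i] == labels[j])
                for i in range(10)
                for j in range(i + 1, 10)
            )
            hits += same
        assert hits == 20


class TestSelectGenes:
    def test_brute_force_on_toy_annotation(self):
        genes = [
            GeneModel(GenomicInterval("I", 0, 3000, "+"), "a"),
            GeneModel(GenomicInterval("I", 3400, 6500, "+"), "b"),
            GeneModel(GenomicInterval("I", 6600, 9000, "-"), "c"),
        ]

        def brute(gl, min_len=2000, min_gap=500):
            kept = []
            for g in gl:
                if g.length <= min_len:
                    continue
                dists = []
                for h in gl:
                    if h is g:
                        continue
                    dists.append(max(h.start - g.end, g.start - h.end))
                if not dists or min(dists) >= min_gap:
                    kept.append(g)
            return kept

        assert select_genes(genes) == brute(genes)

    def test_random_annotations_match_brute_force(self, rng):
        def brute(gl, min_len=2000, min_gap=500):
            kept = []
            for g in gl:
                if g.length <= min_len:
                    continue
                dists = [
                    max(h.start - g.end, g.start - h.end)
                    for h in gl
                    if h is not g and h.chrom == g.chrom
                ]
                if not dists or min(dists) >= min_gap:
                    kept.append(g)
            return kept

        for trial in range(10):
            genes = []
            for i in range(30):
                s = int(rng.integers(0, 80_000))
                L = int(rng.integers(500, 5000))
                genes.append(
                    GeneModel(
                        GenomicInterval(
                            rng.choice(["I", "II"]), s, s + L,
                            "+" if rng.random() < 0.5 else "-",
                        ),
                        f"g{trial}_{i}",
                    )
                )
            assert select_genes(genes) == brute(genes)

    def test_length_boundary_strict(self):
        g1999 = [GeneModel(GenomicInterval("I", 0, 1999, "+"), "x")]
        g2000 = [GeneModel(GenomicInterval("I", 0, 2000, "+"), "x")]
        g2001 = [GeneModel(GenomicInterval("I", 0, 2001, "+"), "x")]
        assert select_genes(g1999) == []
        assert select_genes(g2000) == []      # strictly greater than 2 kb
        assert len(select_genes(g2001)) == 1


class TestStratify:
    def test_equal_groups(self):
        sg = stratify([f"i{k}" for k in range(8)], np.arange(8), 4)
        assert [len(sg.members(i)) for i in range(4)] == [2, 2, 2, 2]
        assert list(sg.members(0)) == ["i0", "i1"]

    def test_trim_top_fraction(self):
        sg = stratify(
            [f"i{k:04d}" for k in range(1000)], np.arange(1000.0), 4,
            trim_top_fraction=0.005,
        )
        assert len(sg.item_ids) == 995
        assert sg.dropped_top == 5

    def test_exclude_zero(self):
        sg = stratify(list("abcdef"), [0, 1, 2, 0, 3, 4], 2, exclude_zero=True)
        assert sg.dropped_zero == 2
        assert len(sg.item_ids) == 4

    def test_all_tied_keys_follow_id_order(self):
        ids = ["d", "b", "a", "c"]
        sg = stratify(ids, [5.0] * 4, 2)
        assert list(sg.members(0)) == ["a", "b"]
        assert list(sg.members(1)) == ["c", "d"]

    def test_fewer_items_than_groups_raises(self):
        with pytest.raises(ValueError):
            stratify(["a"], [1.0], 2)


class TestGeneMetaprofile:
    def test_plus_gene_first_bin(self):
        genes = [GeneModel(GenomicInterval("I", 1000, 4000, "+"), "g")]
        reads = [ReadAlignment(GenomicInterval("I", 2, 10, "-"))]
        mp = gene_metaprofile(reads, genes, {"I": 10_000}, strand_mode="opposite")
        v = mp.per_gene.to_numpy()[0]
        assert v[0] == 1 and v[1:].sum() == 0

    def test_minus_gene_mirror(self):
        genes = [GeneModel(GenomicInterval("I", 1000, 4000, "-"), "g")]
        # window is [3500, 5000); transcription-order bin 0 is [4985, 5000)
        reads = [ReadAlignment(GenomicInterval("I", 4990, 4998, "+"))]
        mp = gene_metaprofile(reads, genes, {"I": 10_000}, strand_mode="opposite")
        v = mp.per_gene.to_numpy()[0]
        assert v[0] == 1 and v[1:].sum() == 0

    def test_off_chromosome_gene_skipped(self):
        genes = [
            GeneModel(GenomicInterval("I", 100, 2500, "+"), "edge"),
            GeneModel(GenomicInterval("I", 3000, 6000, "+"), "ok"),
        ]
        mp = gene_metaprofile([], genes, {"I": 10_000})
        assert mp.skipped == 1 and list(mp.per_gene.index) == ["ok"]


class TestCompareStrands:
    def test_fraction_arithmetic(self):
        res = compare_strands(
            pd.Series({"g": 3.0}), pd.Series({"g": 1.0})
        )
        assert res["mean_ts_fraction"].iloc[0] == pytest.approx(0.75)

    def test_identical_strands_give_p_one(self):
        ts = pd.Series(np.arange(1.0, 21.0), index=[f"g{i}" for i in range(20)])
        res = compare_strands(ts, ts.copy())
        assert res["wilcoxon_p"].iloc[0] == 1.0

    def test_zero_total_genes_excluded_and_counted(self):
        ts = pd.Series({"a": 0.0, "b": 2.0})
        nts = pd.Series({"a": 0.0, "b": 1.0})
        res = compare_strands(ts, nts)
        assert res["n_excluded_zero_total"].iloc[0] == 1
        assert res["n_informative"].iloc[0] == 1

    def test_bh_across_groups(self):
        rng = np.random.default_rng(0)
        idx = [f"g{i}" for i in range(60)]
        ts = pd.Series(rng.random(60) + 1.0, index=idx)
        nts = pd.Series(rng.random(60), index=idx)
        groups = {"q0": idx[:30], "q1": idx[30:]}
        res = compare_strands(ts, nts, groups)
        assert res["q_bh"].notna().all()
        assert (res["q_bh"] >= res["wilcoxon_p"] - 1e-12).all()


class TestPeakProfile:
    def test_center_bin_arithmetic(self):
        anchors = [GenomicInterval("I", 5000, 5001, ".")]
        reads = [ReadAlignment(GenomicInterval("I", 4996, 5004, "+"))]
        pp = peak_profile(reads, anchors, {"I": 10_000}, flank=1000, n_bins=201)
        assert pp.rel_starts[100] == -5  # bin 101 (1-based) spans [-5, +5)
        assert pp.plus.to_numpy()[0, 100] == 1

    def test_orientation_reverses_plus_only(self):
        anchors = [GenomicInterval("I", 5000, 5001, ".")]
        reads = [
            ReadAlignment(GenomicInterval("I", 4100, 4124, "+")),
            ReadAlignment(GenomicInterval("I", 4100, 4124, "-")),
        ]
        pp = peak_profile(reads, anchors, {"I": 10_000}, flank=1000, n_bins=201)
        ppo = orient_plus_reversed(pp)
        assert np.array_equal(
            ppo.plus.to_numpy()[0], pp.plus.to_numpy()[0][::-1]
        )
        assert np.array_equal(ppo.minus.to_numpy(), pp.minus.to_numpy())

    def test_orientation_involution(self, rng):
        anchors = [GenomicInterval("I", 5000, 5001, ".")]
        reads = [
            ReadAlignment(
                GenomicInterval("I", int(s), int(s) + 24,
                                "+" if rng.random() < 0.5 else "-")
            )
            for s in rng.integers(4000, 6000, 200)
        ]
        pp = peak_profile(reads, anchors, {"I": 10_000}, flank=1000, n_bins=201)
        back = orient_plus_reversed(orient_plus_reversed(pp))
        assert np.array_equal(back.plus.to_numpy(), pp.plus.to_numpy())
        assert back.oriented == pp.oriented

    def test_dyad_geometry(self):
        anchors = [GenomicInterval("I", 5000, 5001, ".")]
        pp = peak_profile([], anchors, {"I": 10_000}, flank=80, n_bins=81)
        assert pp.bin_size == 2
        assert pp.rel_starts[40] == -1  # center bin spans [-1, +1)

    def test_even_bins_warn(self):
        anchors = [GenomicInterval("I", 5000, 5001, ".")]
        with pytest.warns(UserWarning):
            peak_profile([], anchors, {"I": 10_000}, flank=1000, n_bins=126)

    def test_scale_region_mode(self):
        anchors = [GenomicInterval("I", 4000, 6000, ".")]
        reads = [ReadAlignment(GenomicInterval("I", 3500, 3524, "+"))]
        pp = peak_profile(
            reads, anchors, {"I": 10_000}, flank=500, n_bins=40,
            mode="scale_region",
        )
        # window [3500, 6500), 40 bins of 75 bp; read occupies the 1st bin
        assert pp.plus.to_numpy()[0, 0] == 1
        assert pp.plus.to_numpy()[0, 1:].sum() == 0


class TestNormalizeChain:
    @staticmethod
    def _sig(values):
        return BinnedSignal(np.asarray(values, dtype=float), 10.0)

    def test_all_ones_gives_zero(self):
        one = self._sig(np.ones(30))
        out, masked = normalize_chain(one, one, one, one, mode="damage_full")
        assert np.allclose(out.values, 0.0)
        assert masked == 0

    def test_library_scale_invariance_via_rpm(self):
        counts = np.arange(1.0, 31.0)
        a = rpm_from_counts(counts, 1_000)
        b = rpm_from_counts(counts * 10, 10_000)
        assert np.array_equal(a, b)

    def test_planted_enrichment_recovered(self):
        x = np.ones(100)
        x[50:61] = 2.0
        out, _ = normalize_chain(
            self._sig(x), sim_profile=self._sig(np.ones(100)), mode="xr_sim"
        )
        # 11-bin smoothing keeps the center of an 11-bin run at full height
        assert out.values[55] == pytest.approx(1.0)
        assert np.allclose(out.values[:40], 0.0)

    def test_nonpositive_denominator_masked_and_counted(self):
        x = self._sig(np.ones(20))
        sim = np.ones(20)
        sim[5] = 0.0
        out, masked = normalize_chain(
            x, sim_profile=self._sig(sim), mode="xr_sim", smooth_window=1
        )
        assert masked == 1 and np.isnan(out.values[5])

    def test_all_zero_denominator_raises(self):
        x = self._sig(np.ones(10))
        with pytest.raises(ValueError):
            normalize_chain(
                x, sim_profile=self._sig(np.zeros(10)), mode="xr_sim"
            )

    def test_damage_normalized_xr_mode(self):
        x = self._sig(np.full(30, 4.0))
        sim = self._sig(np.full(30, 2.0))
        dmg = self._sig(np.full(30, 2.0))
        out, _ = normalize_chain(
            x, sim_profile=sim, damage_profile=dmg, mode="xr_sim_damage",
            smooth_window=1,
        )
        assert np.allclose(out.values, 0.0)  # log2((4/2)/2) = 0


class TestClassifyPeaks:
    def test_upstream_extension_boundaries(self):
        genes = [GeneModel(GenomicInterval("I", 1000, 3000, "+"), "g")]
        near = [GenomicInterval("I", 850, 900, ".")]   # 150 bp upstream of TSS
        far = [GenomicInterval("I", 700, 799, ".")]    # 201 bp upstream
        assert classify_peaks(near, genes) == ["genic"]
        assert classify_peaks(far, genes) == ["intergenic"]

    def test_minus_strand_extension(self):
        genes = [GeneModel(GenomicInterval("I", 1000, 3000, "-"), "g")]
        peak = [GenomicInterval("I", 3100, 3150, ".")]  # upstream of - TSS
        assert classify_peaks(peak, genes) == ["genic"]

    def test_brute_force_labels(self, rng):
        genes = [
            GeneModel(
                GenomicInterval("I", int(s), int(s) + 2000,
                                "+" if rng.random() < 0.5 else "-"),
                f"g{i}",
            )
            for i, s in enumerate(rng.integers(0, 40_000, 3))
        ]
        peaks = [
            GenomicInterval("I", int(s), int(s) + 200, ".")
            for s in rng.integers(0, 45_000, 10)
        ]
        labels = classify_peaks(peaks, genes)
        for p, lab in zip(peaks, labels):
            hit = False
            for g in genes:
                s = g.start - 200 if g.strand == "+" else g.start
                e = g.end if g.strand == "+" else g.end + 200
                if p.start < e and s < p.end:
                    hit = True
            assert lab == ("genic" if hit else "intergenic")


class TestTertileBoxstats:
    @staticmethod
    def _frame(rng, shift_high=0.0, n=60):
        rows = []
        for g, delta in (("low", 0.0), ("med", 0.0), ("high", shift_high)):
            for t in ("t0", "t1"):
                vals = rng.normal(delta, 1.0, n)
                for i, v in enumerate(vals):
                    rows.append(
                        {"bin_id": f"{g}_{i}", "tertile": g, "timepoint": t,
                         "value": v}
                    )
        return pd.DataFrame(rows)

    def test_whisker_percentile_rule(self):
        df = pd.DataFrame(
            {"bin_id": [f"b{i}" for i in range(8)], "tertile": ["low"] * 8,
             "timepoint": ["t0"] * 8, "value": np.arange(1.0, 9.0)}
        )
        box, _ = tertile_boxstats(df, "t0")
        assert box["whisker_lo"].iloc[0] == pytest.approx(1.875)
        assert box["whisker_hi"].iloc[0] == pytest.approx(7.125)

    def test_null_mostly_nonsignificant(self, rng):
        df = self._frame(rng)
        _, tests = tertile_boxstats(df, "t0")
        assert (tests["q_bh"] >= 0.05).mean() >= 0.8

    def test_shifted_tertile_detected(self, rng):
        df = self._frame(rng, shift_high=10.0, n=200)
        _, tests = tertile_boxstats(df, "t0")
        between = tests[
            (tests["kind"] == "between_tertiles")
            & ((tests["tertile"] == "high") | (tests["other"] == "high"))
        ]
        assert (between["q_bh"] < 0.05).all()


class TestExpressionUnits:
    def test_single_gene_tpm(self):
        assert tpm_from_counts([7], [1234])[0] == pytest.approx(1e6)

    def test_two_gene_example(self):
        tpm = tpm_from_counts([10, 10], [1000, 2000])
        assert tpm[0] == pytest.approx(666666.6667, rel=1e-6)
        assert tpm[1] == pytest.approx(333333.3333, rel=1e-6)

    def test_tpm_sums_to_million(self, rng):
        tpm = tpm_from_counts(rng.integers(0, 500, 50), rng.integers(200, 9000, 50))
        assert tpm.sum() == pytest.approx(1e6, rel=1e-6)

    def test_rpkm_formula(self):
        # (reads / length_kb) / (library / 1e6)
        assert rpkm_from_counts([10], [2000], 1_000_000)[0] == pytest.approx(5.0)

    def test_all_zero_counts_warn(self):
        with pytest.warns(UserWarning):
            tpm = tpm_from_counts([0, 0], [100, 100])
        assert np.array_equal(tpm, [0.0, 0.0])
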