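"""Enrichment tracks, centromere calls, cluster filter, metaprofiles, phasing."""

import numpy as np
import pytest
from scipy import stats

from pancent import (
    MonomerRecord,
    RepeatClusterSummary,
    bin_coverage,
    call_centromere,
    classify_clusters,
    depth_array,
    enrichment_level,
    log2_ratio,
    metaprofile,
    phase_profile,
    quantile_groups,
)


def _track(chip, inp, bin_size=100):
    return log2_ratio(np.asarray(chip, float), np.asarray(inp, float), bin_size)


class TestBinCoverage:
    def test_uniform_depth(self):
        assert np.allclose(bin_coverage(np.full(1000, 10.0), 100), 10.0)

    def test_single_read_partial_occupancy(self):
        depth = depth_array([(0, 100)], 1000)
        assert bin_coverage(depth, 1000)[0] == pytest.approx(0.1)

    def test_terminal_partial_bin_uses_true_width(self):
        depth = np.ones(250)
        bins = bin_coverage(depth, 100)
        assert len(bins) == 3 and np.allclose(bins, 1.0)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(0)
        intervals = sorted(
            (int(s), int(s + rng.integers(20, 200)))
            for s in rng.integers(0, 9800, size=50)
        )
        got = bin_coverage(intervals, 1000, chrom_length=10_000)
        base = np.zeros(10_000)
        for s, e in intervals:
            for p in range(s, min(e, 10_000)):
                base[p] += 1
        oracle = [base[i : i + 1000].mean() for i in range(0, 10_000, 1000)]
        assert np.allclose(got, oracle)

    def test_unsorted_intervals_rejected(self):
        with pytest.raises(ValueError):
            bin_coverage([(100, 200), (0, 50)], 100, chrom_length=1000)


class TestLog2Ratio:
    def test_equal_tracks_are_zero(self):
        tr = _track(np.full(50, 7.0), np.full(50, 7.0))
        assert np.allclose(tr.log2_ratio, 0.0)

    def test_eightfold_approaches_three(self):
        # one 8x-enriched bin in 1000: normalized chip there ~ 8 /
        # (1 + 7/1000); with the pseudocount sent to zero the ratio is
        # log2 8, and at the default pseudocount it matches the closed form
        chip = np.full(1000, 100.0)
        chip[0] = 800.0
        inp = np.full(1000, 100.0)
        tr0 = log2_ratio(chip, inp, 100, pseudocount=1e-9)
        expected_fold = 8.0 / (1 + 7 / 1000)
        assert tr0.log2_ratio[0] == pytest.approx(np.log2(expected_fold), abs=1e-6)
        assert tr0.log2_ratio[0] == pytest.approx(3.0, abs=0.02)
        tr = log2_ratio(chip, inp, 100)  # default pseudocount 0.5
        assert tr.log2_ratio[0] == pytest.approx(
            np.log2((expected_fold + 0.5) / 1.5), abs=1e-6
        )

    def test_library_scaling_invariance(self):
        rng = np.random.default_rng(1)
        chip = rng.random(40) * 10
        inp = rng.random(40) * 10
        a = _track(chip, inp).log2_ratio
        b = _track(chip * 2, inp * 2).log2_ratio
        assert np.allclose(a, b)

    def test_zero_input_bins_stay_finite(self):
        tr = _track([0, 5, 10], [0, 0, 10])
        assert np.all(np.isfinite(tr.log2_ratio))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _track(np.ones(10), np.ones(11))


class TestCallCentromere:
    def test_flat_track_yields_no_call(self):
        tr = _track(np.full(100, 5.0), np.full(100, 5.0))
        assert call_centromere(tr, threshold_log2=1.0) is None

    def test_larger_summed_block_wins(self):
        chip = np.full(100, 1.0)
        chip[10:14] = 40.0  # small block
        chip[60:80] = 40.0  # large block
        tr = _track(chip, np.full(100, 1.0), bin_size=10)
        call = call_centromere(tr, threshold_log2=1.0, merge_gap=10)
        assert (call.start, call.end) == (600, 800)

    @pytest.mark.parametrize("fold", [4.0, 8.0, 16.0])
    def test_planted_interval_recovered_within_one_bin(self, fold):
        from pancent.synthgen import SimConfig, simulate_centromere, simulate_reads

        cfg = SimConfig(seed=13, n_copies=320, sub_rate=0.01, indel_rate=0.0,
                        flank_length=200_000)
        cfg.chip_spec.fold = fold
        cfg.chip_spec.coverage = 8
        cfg.chip_spec.phase_kappa = 0.0
        chrom, truth = simulate_centromere(cfg)
        chip, inp = simulate_reads(chrom, truth, cfg)
        bs = 5000
        tr = log2_ratio(
            bin_coverage(depth_array(chip.fragments, len(chrom)), bs),
            bin_coverage(depth_array(inp.fragments, len(chrom)), bs),
            bs,
        )
        call = call_centromere(tr, threshold_log2=1.0, merge_gap=50_000)
        assert abs(call.start - truth.centromere[0]) <= bs
        assert abs(call.end - truth.centromere[1]) <= bs


class TestEnrichmentLevel:
    def test_uniform_coverage_is_exactly_one(self):
        from pancent.cenprofile import CentromereCall, EnrichmentTrack

        tr = EnrichmentTrack("c", 100, np.full(100, 3.0), np.full(100, 3.0),
                             np.zeros(100))
        call = CentromereCall("c", 2000, 4000, 0.0)
        assert enrichment_level(call, tr) == 1.0

    def test_mixture_arithmetic(self):
        # 8-fold over 1 % of the genome: level = 8 / (0.99 + 0.08) ~ 7.48
        chip = np.full(1000, 1.0)
        chip[:10] = 8.0
        from pancent.cenprofile import CentromereCall, EnrichmentTrack

        tr = EnrichmentTrack("c", 100, chip, np.full(1000, 1.0), np.zeros(1000))
        call = CentromereCall("c", 0, 1000, 0.0)
        assert enrichment_level(call, tr) == pytest.approx(8 / 1.07, rel=1e-6)

    def test_invariant_to_depth_scaling(self):
        from pancent.cenprofile import CentromereCall, EnrichmentTrack

        rng = np.random.default_rng(2)
        chip = rng.random(200) + 0.5
        tr1 = EnrichmentTrack("c", 100, chip, chip, np.zeros(200))
        tr2 = EnrichmentTrack("c", 100, chip * 7, chip * 7, np.zeros(200))
        call = CentromereCall("c", 3000, 8000, 0.0)
        assert enrichment_level(call, tr1) == pytest.approx(enrichment_level(call, tr2))


class TestClassifyClusters:
    @pytest.mark.parametrize(
        "ratio,fraction,expected",
        [
            (2.7, 0.006, True),
            (2.5, 0.05, False),
            (2.6, 0.01, False),  # strict inequality on the ratio
            (3.0, 0.005, False),  # strict inequality on the fraction
        ],
    )
    def test_threshold_rule(self, ratio, fraction, expected):
        c = RepeatClusterSummary("c1", 0, 0, fraction, ratio=ratio)
        assert classify_clusters([c])[0].is_centromeric is expected

    def test_exhaustive_grid_matches_two_predicate_oracle(self):
        ratios = np.linspace(0, 6, 41)
        fractions = np.linspace(0, 0.02, 41)
        clusters = [
            RepeatClusterSummary(f"{i}_{j}", 0, 0, float(f), ratio=float(r))
            for i, r in enumerate(ratios)
            for j, f in enumerate(fractions)
        ]
        out = classify_clusters(clusters)
        for c in out:
            assert c.is_centromeric == (c.ratio > 2.6 and c.genome_fraction > 0.005)

    def test_ratio_computed_from_normalized_counts(self):
        # equal totals, cluster with 3x chip reads -> ratio 3
        cs = [
            RepeatClusterSummary("a", 300, 100, 0.01),
            RepeatClusterSummary("b", 700, 900, 0.5),
        ]
        out = classify_clusters(cs)
        assert out[0].ratio == pytest.approx(3.0)
        assert out[0].is_centromeric


class TestQuantileGroups:
    def test_decreasing_split_of_one_to_ten(self):
        labels = quantile_groups(np.arange(1, 11), 5)
        values_by_group = {
            g: sorted(v for v, lab in zip(range(1, 11), labels) if lab == g)
            for g in range(5)
        }
        assert values_by_group == {0: [9, 10], 1: [7, 8], 2: [5, 6], 3: [3, 4], 4: [1, 2]}

    def test_ties_fill_in_input_order(self):
        labels = quantile_groups(np.ones(6), 3)
        assert list(labels) == [0, 0, 1, 1, 2, 2]

    def test_group_sizes_differ_by_at_most_one(self):
        labels = quantile_groups(np.random.default_rng(3).random(23), 5)
        sizes = np.bincount(labels)
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_groups([1.0, 2.0], 3)


class TestMetaprofile:
    def _flat_track(self, value, nbins=100, bin_size=10):
        from pancent.cenprofile import EnrichmentTrack

        arr = np.full(nbins, float(value))
        return EnrichmentTrack("c", bin_size, arr, arr, arr.copy())

    def test_flat_track_gives_constant_profile(self):
        tr = self._flat_track(1.5)
        mp = metaprofile(tr, [(200, 400), (500, 700)], flank=50, body_bins=10)
        assert np.allclose(mp.profile, 1.5)

    def test_step_track_high_in_body_only(self):
        from pancent.cenprofile import EnrichmentTrack

        sig = np.zeros(100)
        sig[30:50] = 2.0  # covers 300..500
        tr = EnrichmentTrack("c", 10, sig, sig, sig)
        mp = metaprofile(tr, [(300, 500)], flank=100, body_bins=10)
        body = mp.profile[mp.flank_bins : mp.flank_bins + 10]
        flank = np.concatenate(
            [mp.profile[: mp.flank_bins], mp.profile[mp.flank_bins + 10 :]]
        )
        assert np.allclose(body, 2.0)
        assert np.allclose(flank, 0.0)

    def test_matches_bruteforce_feature_average(self):
        from pancent.cenprofile import EnrichmentTrack

        rng = np.random.default_rng(4)
        sig = rng.random(1000)
        tr = EnrichmentTrack("c", 10, sig, sig, sig)
        feats = [(1000, 2000), (3000, 4500), (5000, 5600)]
        body_bins, flank = 5, 100
        mp = metaprofile(tr, feats, flank=flank, body_bins=body_bins)
        per_base = np.repeat(sig, 10)
        rows = []
        for s, e in feats:
            edges = np.linspace(s, e, body_bins + 1)
            body = [
                per_base[int(np.floor(edges[j])) : int(np.ceil(edges[j + 1]))].mean()
                for j in range(body_bins)
            ]
            up = [per_base[s - flank + j * 10 : s - flank + (j + 1) * 10].mean()
                  for j in range(10)]
            down = [per_base[e + j * 10 : e + (j + 1) * 10].mean() for j in range(10)]
            rows.append(up + body + down)
        assert np.allclose(mp.profile, np.mean(rows, axis=0))

    def test_minus_strand_features_flipped(self):
        from pancent.cenprofile import EnrichmentTrack

        sig = np.arange(100, dtype=float)
        tr = EnrichmentTrack("c", 10, sig, sig, sig)
        plus = metaprofile(tr, [(300, 500, "+")], flank=0, body_bins=10)
        minus = metaprofile(tr, [(300, 500, "-")], flank=0, body_bins=10)
        assert np.allclose(minus.profile, plus.profile[::-1])

    def test_no_features_rejected(self):
        with pytest.raises(ValueError):
            metaprofile(self._flat_track(1.0), [], flank=10, body_bins=5)


def _monomers(n=50, length=156, start0=1000):
    return [
        MonomerRecord("c", start0 + i * length, start0 + (i + 1) * length, "+",
                      "A" * length, "sat", 1.0, "arr")
        for i in range(n)
    ]


class TestPhaseProfile:
    def test_planted_offset_recovered(self):
        from pancent.synthgen import SimConfig, simulate_centromere, simulate_reads

        cfg = SimConfig(seed=14, n_copies=300, sub_rate=0.01, indel_rate=0.0,
                        flank_length=5000)
        cfg.chip_spec.coverage = 25
        chrom, truth = simulate_centromere(cfg)
        chip, _ = simulate_reads(chrom, truth, cfg)
        mons = [
            MonomerRecord("c", s, e, st, chrom[s:e], "sat", 1.0, "arr")
            for (s, e), st in zip(truth.monomer_intervals, truth.monomer_strands)
        ]
        mids = [(s + e) // 2 for s, e in chip.fragments]
        density, peak = phase_profile(mids, mons)
        assert abs(peak - truth.phase_offset) <= 5

    def test_uniform_fragments_are_flat(self):
        rng = np.random.default_rng(5)
        mons = _monomers(64)
        lo, hi = mons[0].start, mons[-1].end
        mids = rng.integers(lo, hi, size=10_000)
        density, peak = phase_profile(mids, mons)
        counts = density * 10_000
        chi2, p = stats.chisquare(counts)
        assert p > 0.01

    def test_strand_reversal_keeps_peak(self):
        rng = np.random.default_rng(6)
        mons = _monomers(40)
        # place fragments at offset 30 within each monomer
        mids = [m.start + 30 for m in mons for _ in range(20)]
        _, peak_fwd = phase_profile(mids, mons, smooth=1)
        flipped = [
            MonomerRecord(m.chrom, m.start, m.end, "-", m.sequence, "sat", 1.0, "arr")
            for m in mons
        ]
        mids_rev = [m.start + (156 - 1 - 30) for m in flipped for _ in range(20)]
        _, peak_rev = phase_profile(mids_rev, flipped, smooth=1)
        assert peak_fwd == peak_rev == 30

    def test_no_hits_rejected(self):
        with pytest.raises(ValueError):
            phase_profile([10], _monomers(3, start0=5000))
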