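import numpy as np
import pytest

from g4kit.intervals import FragmentSet, GenomicInterval
from g4kit.metrics import (
    call_enriched_bins,
    coverage_track,
    fingerprint,
    frip,
    profile_matrix,
    telomeric_fraction,
)
from g4kit.tracks import BinnedTrack


def frags(spans, chrom="chr1"):
    return FragmentSet([GenomicInterval(chrom, s, e) for s, e in spans])


class TestCoverage:
    def test_rpgc_factor_one_when_fragments_tile_genome(self):
        fs = frags([(i * 50, i * 50 + 50) for i in range(20)])
        track = coverage_track(fs, {"chr1": 1000}, 5, "RPGC", 1000)
        assert np.allclose(track.concatenated(), 1.0)

    def test_rpgc_factor_two_at_half_depth(self):
        fs = frags([(i * 100, i * 100 + 50) for i in range(10)])
        track = coverage_track(fs, {"chr1": 1000}, 5, "RPGC", 1000)
        # covered bins get raw depth 1 scaled by factor 2
        assert track.data["chr1"][0] == pytest.approx(2.0)
        assert track.genome_mean() == pytest.approx(1.0)

    def test_raw_track_single_fragment(self):
        track = coverage_track(frags([(0, 10)]), {"chr1": 20}, 5)
        assert list(track.data["chr1"]) == [1.0, 1.0, 0.0, 0.0]

    def test_rpgc_requires_fragments_and_genome_size(self):
        with pytest.raises(ValueError):
            coverage_track(frags([]), {"chr1": 100}, 5, "RPGC", 100)
        with pytest.raises(ValueError):
            coverage_track(frags([(0, 10)]), {"chr1": 100}, 5, "RPGC")

    def test_rpgc_mean_one_within_bin_padding(self, rng):
        starts = rng.integers(0, 950, size=400)
        fs = frags([(int(s), int(s) + 37) for s in starts])
        track = coverage_track(fs, {"chr1": 987}, 5, "RPGC", 987)
        assert track.genome_mean() == pytest.approx(1.0, rel=1 / 5)


class TestFrip:
    def test_fraction_counted_per_fragment(self):
        fs = frags([(i * 100, i * 100 + 10) for i in range(10)])
        peaks = [GenomicInterval("chr1", 0, 305)]  # covers fragments 0-3
        assert frip(fs, peaks) == pytest.approx(0.4)

    def test_genome_wide_peaks(self):
        fs = frags([(0, 10), (50, 60)])
        assert frip(fs, [GenomicInterval("chr1", 0, 1000)]) == 1.0

    def test_no_peaks(self):
        assert frip(frags([(0, 10)]), []) == 0.0

    def test_empty_fragments_rejected(self):
        with pytest.raises(ValueError):
            frip(frags([]), [GenomicInterval("chr1", 0, 10)])

    def test_invariant_under_peak_merging(self, rng):
        fs = frags([(int(s), int(s) + 20) for s in rng.integers(0, 900, 200)])
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 900, 30)
        ]
        from g4kit.intervals import merge_intervals

        assert frip(fs, peaks) == frip(fs, merge_intervals(peaks))


class TestFingerprint:
    def test_uniform_counts_track_diagonal(self):
        fs = frags([(i * 100 + 10, i * 100 + 20) for i in range(10)])
        curve = fingerprint(fs, {"chr1": 1000}, 100)
        assert np.allclose(curve.ys, curve.xs)

    def test_single_hot_bin(self):
        fs = frags([(5, 15)] * 50)
        curve = fingerprint(fs, {"chr1": 1000}, 100)
        assert curve.ys[-1] == 1.0
        assert np.allclose(curve.ys[:-1], 0.0)

    def test_matches_sort_cumsum_oracle(self, rng):
        fs = frags([(int(s), int(s) + 30) for s in rng.integers(0, 960, 500)])
        curve = fingerprint(fs, {"chr1": 1000}, 50)
        mids = np.array([(f.start + f.end) // 2 for f in fs])
        counts = np.bincount(mids // 50, minlength=20)
        expected = np.cumsum(np.sort(counts)) / counts.sum()
        assert np.allclose(curve.ys[1:], expected)

    def test_invariant_to_chromosome_order(self, rng):
        spans = [(int(s), int(s) + 30) for s in rng.integers(0, 460, 100)]
        a = FragmentSet(
            [GenomicInterval("chr1", s, e) for s, e in spans[:50]]
            + [GenomicInterval("chr2", s, e) for s, e in spans[50:]]
        )
        b = FragmentSet(list(reversed(a.fragments)))
        ca = fingerprint(a, {"chr1": 500, "chr2": 500}, 50)
        cb = fingerprint(b, {"chr2": 500, "chr1": 500}, 50)
        assert np.allclose(ca.ys, cb.ys)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            fingerprint(frags([(0, 10)], chrom="chrX"), {"chr1": 100}, 10)


class TestTelomere:
    def test_tandem_repeat_counted(self):
        assert telomeric_fraction(["TTAGGG" * 5]) == 1.0

    def test_reverse_complement_counted(self):
        assert telomeric_fraction(["CCCTAA" * 5]) == 1.0

    def test_random_read_not_counted(self):
        assert telomeric_fraction(["ACGTACGTACGTACGTAC"]) == 0.0

    def test_orientation_invariance(self, rng):
        from g4kit.scan import reverse_complement

        reads = ["TTAGGG" * 4 + "ACGT", "ACGT" * 10, "CCCTAA" * 4]
        flipped = [reverse_complement(r) for r in reads]
        assert telomeric_fraction(reads) == telomeric_fraction(flipped)

    def test_min_tandem_threshold(self):
        read = "TTAGGG" * 2 + "ACGTACGT"
        assert telomeric_fraction([read], min_tandem=3) == 0.0
        assert telomeric_fraction([read], min_tandem=2) == 1.0

    def test_empty_reads_rejected(self):
        with pytest.raises(ValueError):
            telomeric_fraction([])


class TestProfileMatrix:
    def _track(self, values, bin_size=10, size=100):
        track = BinnedTrack(bin_size, {"chr1": size})
        track.data["chr1"][:] = values
        return track

    def test_constant_track(self):
        track = self._track([3.0] * 10)
        windows = [GenomicInterval("chr1", 20, 60)]
        mat = profile_matrix(track, windows, 4)
        assert np.allclose(mat, 3.0)

    def test_minus_strand_reversed(self):
        track = self._track(np.arange(10.0))
        plus = profile_matrix(
            track, [GenomicInterval("chr1", 20, 60, "+")], 4
        )
        minus = profile_matrix(
            track, [GenomicInterval("chr1", 20, 60, "-")], 4
        )
        assert np.allclose(minus[0], plus[0][::-1])

    def test_off_chromosome_is_nan_padded(self):
        track = self._track([1.0] * 10)
        mat = profile_matrix(track, [GenomicInterval("chr1", 80, 120)], 4)
        assert np.allclose(mat[0][:2], 1.0)
        assert np.isnan(mat[0][2:]).all()

    def test_window_width_must_match(self):
        track = self._track([1.0] * 10)
        windows = [GenomicInterval("chr1", 0, 40), GenomicInterval("chr1", 0, 20)]
        with pytest.raises(ValueError):
            profile_matrix(track, windows, 4)


class TestToyCaller:
    def _track(self, values, bin_size=10):
        track = BinnedTrack(bin_size, {"chr1": len(values) * bin_size})
        track.data["chr1"][:] = values
        return track

    def test_flat_track_yields_nothing(self):
        assert call_enriched_bins(self._track([1.0] * 50)) == []

    def test_single_spike_called_exactly(self):
        values = [1.0] * 196 + [10.0] * 4
        values = values[:100] + [10.0] * 4 + values[100:196]
        track = self._track(np.array(values))
        (peak,) = call_enriched_bins(track, z_threshold=3.0, min_run=2)
        assert (peak.start, peak.end) == (1000, 1040)
        assert peak.signal_value > 5  # fold over genome mean
        assert peak.score > 0

    def test_two_separated_spikes(self):
        values = np.ones(200)
        values[50:54] = 20.0
        values[150:154] = 20.0
        peaks = call_enriched_bins(self._track(values), min_run=2, merge_gap=1)
        assert len(peaks) == 2

    def test_nearby_spikes_merge_across_gap(self):
        values = np.ones(200)
        values[50:53] = 20.0
        values[54:57] = 20.0  # 1-bin gap
        (peak,) = call_enriched_bins(self._track(values), min_run=2, merge_gap=1)
        assert (peak.start, peak.end) == (500, 570)
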