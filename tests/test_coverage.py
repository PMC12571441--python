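import math

import numpy as np
import pytest

from ecidentity import (
    CoverageTrack,
    GenomicInterval,
    PeakCallParams,
    SimulationConfig,
    build_coverage,
    call_peaks,
    extend_reads,
    normalize_depth,
    poisson_upper_tail,
    subtract_control,
)
from ecidentity.coverage import log10_poisson_upper_tail, significance_threshold


def poisson_tail_series(k: int, lam: float) -> float:
    """Independent oracle: forward series summation of P(X >= k)."""
    if k == 0:
        return 1.0
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_term)
    total, j = 0.0, k
    while True:
        total += term
        j += 1
        term *= lam / j
        if term < 1e-18 * max(total, 1e-300):
            break
    return total


class TestReadExtension:
    def test_plus_strand_anchors_five_prime(self):
        (r,) = extend_reads(
            [GenomicInterval("chr1", 1000, 1036, "+")], 200
        ).itertuples(index=False)
        assert (r.start, r.end) == (1000, 1200)

    def test_minus_strand_extends_leftward(self):
        (r,) = extend_reads(
            [GenomicInterval("chr1", 1000, 1036, "-")], 200
        ).itertuples(index=False)
        assert (r.start, r.end) == (836, 1036)

    def test_zero_extension_is_identity(self):
        reads = [GenomicInterval("chr1", 5, 41, "+")]
        out = extend_reads(reads, 0)
        assert out.iloc[0]["start"] == 5 and out.iloc[0]["end"] == 41

    def test_missing_strand_errors(self):
        with pytest.raises(ValueError, match="strand"):
            extend_reads([GenomicInterval("chr1", 0, 36)], 200)

    def test_clipping_to_chromosome(self):
        out = extend_reads(
            [GenomicInterval("chr1", 50, 86, "-"),
             GenomicInterval("chr1", 900, 936, "+")],
            200, {"chr1": 1000},
        )
        assert out.iloc[0]["start"] == 0
        assert out.iloc[1]["end"] == 1000


class TestBuildCoverage:
    def test_exact_tiling(self):
        track = build_coverage(
            [GenomicInterval("chr1", 0, 200)], {"chr1": 500}, bin_size=10
        )
        arr = track.values["chr1"]
        assert arr[:20].tolist() == [1.0] * 20
        assert arr[20] == 0.0
        assert track.total_mass == 1.0

    def test_partial_overlap_counts(self):
        track = build_coverage(
            [GenomicInterval("chr1", 5, 15)], {"chr1": 100}, bin_size=10
        )
        assert track.values["chr1"][:3].tolist() == [1.0, 1.0, 0.0]

    def test_empty_is_all_zero(self):
        track = build_coverage([], {"chr1": 100}, bin_size=10)
        assert track.values["chr1"].sum() == 0.0

    def test_unknown_chromosome_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            build_coverage([GenomicInterval("chrX", 0, 10)], {"chr1": 100}, 10)


class TestNormalizeSubtract:
    def make_track(self, values, mass=None):
        arr = np.asarray(values, dtype=float)
        return CoverageTrack(10, {"chr1": len(arr) * 10}, {"chr1": arr},
                             total_mass=float(mass if mass is not None else arr.sum()))

    def test_normalize_scales_bins(self):
        track = self.make_track([1, 2, 3], mass=5e6)
        out = normalize_depth(track, 25e6)
        assert out.values["chr1"].tolist() == [5.0, 10.0, 15.0]
        assert out.total_mass == 25e6

    def test_normalize_identity_at_target(self):
        track = self.make_track([1, 2], mass=25e6)
        out = normalize_depth(track, 25e6)
        assert out.values["chr1"].tolist() == [1.0, 2.0]

    def test_zero_mass_errors(self):
        with pytest.raises(ValueError):
            normalize_depth(self.make_track([0, 0], mass=0), 25e6)

    def test_subtraction_clips_at_zero(self):
        t = self.make_track([10, 3, 5])
        c = self.make_track([4, 7, 0])
        out = subtract_control(t, c)
        assert out.values["chr1"].tolist() == [6.0, 0.0, 5.0]

    def test_grid_mismatch_errors(self):
        t = self.make_track([1, 2])
        c = CoverageTrack(5, {"chr1": 10}, {"chr1": np.array([1.0, 1.0])}, 2.0)
        with pytest.raises(ValueError):
            subtract_control(t, c)


class TestPoissonTail:
    def test_k_zero_is_one(self):
        assert poisson_upper_tail(0, 3.7) == 1.0

    def test_k5_lam1_matches_series(self):
        expected = 1 - sum(math.exp(-1) / math.factorial(j) for j in range(5))
        assert poisson_upper_tail(5, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_matches_series_oracle_on_grid(self):
        for lam in (0.1, 1.0, 5.0, 20.0, 50.0):
            for k in range(0, 301, 7):
                p = poisson_upper_tail(k, lam)
                oracle = poisson_tail_series(k, lam)
                if oracle >= 1e-300:  # documented stability range
                    assert abs(p - oracle) <= 1e-12 * oracle, (k, lam)

    def test_monotone_in_k_and_lam(self):
        ks = np.arange(0, 120)
        for lam in (0.5, 2.0, 10.0):
            p = poisson_upper_tail(ks, lam)
            assert np.all(np.diff(p) <= 0)
        for k in (3, 17, 60):
            ps = [poisson_upper_tail(k, lam) for lam in np.linspace(0.1, 40, 50)]
            assert np.all(np.diff(ps) >= 0)

    def test_stable_in_deep_tail(self):
        p = poisson_upper_tail(300, 2.0)
        assert 0 < p < 1e-300 or p == pytest.approx(
            poisson_tail_series(300, 2.0), rel=1e-10
        )

    def test_log10_tail_finite_past_underflow(self):
        lg = log10_poisson_upper_tail(700, 40.0)
        assert math.isfinite(lg) and lg < -300

    def test_invalid_lambda_errors(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(3, 0.0)


class TestCallPeaks:
    def flat_track(self, value, n_bins=1000):
        arr = np.full(n_bins, float(value))
        return CoverageTrack(10, {"chr1": n_bins * 10}, {"chr1": arr}, arr.sum())

    def test_flat_background_yields_no_peaks(self):
        peaks = call_peaks(self.flat_track(5), PeakCallParams())
        assert peaks == []

    def test_single_block_yields_single_peak(self):
        arr = np.zeros(1000)
        arr[:] = 2.0
        arr[400:430] = 80.0
        track = CoverageTrack(10, {"chr1": 10_000}, {"chr1": arr}, arr.sum())
        (peak,) = call_peaks(track, PeakCallParams())
        assert (peak.interval.start, peak.interval.end) == (4000, 4300)
        assert peak.summit == 4005  # leftmost maximal bin center

    def test_all_zero_track_errors(self):
        with pytest.raises(ValueError):
            call_peaks(self.flat_track(0), PeakCallParams())

    def test_matches_bin_by_bin_oracle_on_synthetic_track(self):
        rng = np.random.default_rng(42)
        lam = 2.0
        arr = rng.poisson(lam, size=100_000).astype(float)
        arr[50_000:50_300] = rng.poisson(400.0, size=300)
        track = CoverageTrack(10, {"chr1": 1_000_000}, {"chr1": arr}, arr.sum())
        params = PeakCallParams()
        peaks = call_peaks(track, params)
        # oracle: per-bin significance scan with the same global lambda
        glam = arr.mean()
        sig = np.array(
            [poisson_upper_tail(int(round(v)), glam) < params.p_cutoff for v in arr]
        )
        # reconstruct runs from the oracle mask
        idx = np.flatnonzero(sig)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        expected = [(int(r[0]) * 10, (int(r[-1]) + 1) * 10) for r in runs if r.size]
        assert [(p.interval.start, p.interval.end) for p in peaks] == expected
        # the planted region is recovered within 2 bins
        spans = [p for p in peaks if p.interval.end > 500_000 > p.interval.start
                 or abs(p.interval.start - 500_000) <= 20]
        assert spans
        big = max(spans, key=lambda p: p.interval.length)
        assert abs(big.interval.start - 500_000) <= 20
        assert abs(big.interval.end - 503_000) <= 20

    def test_invariant_to_chromosome_relabeling_and_fragment_order(self):
        rng = np.random.default_rng(0)
        frags = [
            GenomicInterval("chrA", int(s), int(s) + 200)
            for s in rng.integers(0, 9_800, size=300)
        ] + [GenomicInterval("chrA", 5_000 + 7 * i, 5_200 + 7 * i) for i in range(150)]
        params = PeakCallParams()

        def run(fr, chrom):
            renamed = [GenomicInterval(chrom, f.start, f.end) for f in fr]
            track = build_coverage(renamed, {chrom: 10_000}, 10)
            return [
                (p.interval.start, p.interval.end, p.score)
                for p in call_peaks(track, params)
            ]

        base = run(frags, "chrA")
        assert run(frags[::-1], "chrA") == base
        assert run(frags, "chrZ") == base

    def test_merge_gap_bridges_small_holes(self):
        arr = np.full(200, 1.0)
        arr[50:60] = 100.0
        arr[61:70] = 100.0
        track = CoverageTrack(10, {"chr1": 2000}, {"chr1": arr}, arr.sum())
        no_gap = call_peaks(track, PeakCallParams(merge_gap=0))
        bridged = call_peaks(track, PeakCallParams(merge_gap=1))
        assert len(no_gap) == 2
        assert len(bridged) == 1
        assert (bridged[0].interval.start, bridged[0].interval.end) == (500, 700)

    def test_background_only_simulations_rarely_false_positive(self):
        params = PeakCallParams()
        clean = 0
        for seed, lam in zip(range(10), np.linspace(1, 10, 10)):
            rng = np.random.default_rng(seed)
            arr = rng.poisson(lam, size=100_000).astype(float)
            track = CoverageTrack(10, {"chr1": 1_000_000}, {"chr1": arr}, arr.sum())
            clean += len(call_peaks(track, params)) == 0
        assert clean >= 9

    def test_significance_threshold_is_boundary(self):
        for lam in (1.0, 4.3, 40.0):
            k = significance_threshold(lam, 1e-30)
            assert poisson_upper_tail(k, lam) < 1e-30
            assert poisson_upper_tail(k - 1, lam) >= 1e-30
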