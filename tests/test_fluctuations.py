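import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speedpeaks import (
    CycleSet,
    PipelineConfig,
    SimConfig,
    UndefinedRError,
    analyze_recording,
    build_histogram,
    build_matrix,
    compute_R,
    compute_sipis,
    detect_speaks,
    fit_exponential,
    make_kernel,
    speed_profile,
    synth_recording,
)
from speedpeaks.fluctuations import (
    SPeakTrain,
    local_maxima,
    peaks_in_windows,
    residual_counts,
)
from speedpeaks.preprocess import SpeedSeries


def brute_force_r(intervals, bin_width=2, cutoff=10):
    """Independent direct evaluation of the R statistic.

    Bins intervals by explicit looping, fits log-counts by the closed-form
    two-parameter least-squares solution, and sums the residual terms
    directly. Shares no code with the pipeline path.
    """
    intervals = [float(v) for v in intervals]
    if not intervals:
        raise ValueError("empty")
    n_bins = max(math.ceil(v / bin_width) for v in intervals)
    counts = [0] * n_bins
    for v in intervals:
        counts[math.ceil(v / bin_width) - 1] += 1
    values = [bin_width * (i + 1) for i in range(n_bins)]
    fit_pts = [
        (v, math.log(c)) for v, c in zip(values, counts) if v <= cutoff and c > 0
    ]
    if len(fit_pts) >= 2:
        xs = [p[0] for p in fit_pts]
        ys = [p[1] for p in fit_pts]
        mx = sum(xs) / len(xs)
        my = sum(ys) / len(ys)
        sxx = sum((x - mx) ** 2 for x in xs)
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        slope = sxy / sxx
        icept = my - slope * mx
        amp, rate = math.exp(icept), -slope
    else:
        amp, rate = 0.0, 0.0
    num = 0.0
    den = 0.0
    for v, c in zip(values, counts):
        den += c * v
        if v > cutoff:
            fitted = amp * math.exp(-rate * v)
            num += max(0.0, c - fitted) * v * v
    return num / den


def pipeline_r(intervals, cfg=None):
    cfg = cfg or PipelineConfig()
    return compute_R(fit_exponential(build_histogram(np.asarray(intervals), cfg), cfg))


def make_speed(values):
    v = np.asarray(values, dtype=float)
    return SpeedSeries(
        speed=v,
        velocity=np.column_stack([v, np.zeros_like(v), np.zeros_like(v)]),
        sample_rate=240.0,
    )


class TestLocalMaxima:
    def test_single_bump(self):
        x = np.array([0, 1, 3, 2, 0], dtype=float)
        np.testing.assert_array_equal(local_maxima(x), [2])

    def test_plateau_counts_once_at_first_frame(self):
        x = np.array([0, 1, 2, 2, 1, 0], dtype=float)
        np.testing.assert_array_equal(local_maxima(x), [2])

    def test_plateau_brute_force_two_sample(self):
        # every placement of a 2-sample plateau in a 6-sample series
        for lead in range(1, 4):
            x = np.zeros(6)
            x[lead] = x[lead + 1] = 1.0
            got = local_maxima(x)
            np.testing.assert_array_equal(got, [lead])

    def test_endpoints_excluded(self):
        x = np.array([3.0, 1.0, 2.0, 1.0, 5.0])
        np.testing.assert_array_equal(local_maxima(x), [2])

    def test_monotone_no_peaks(self):
        assert local_maxima(np.arange(10.0)).size == 0

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31), n=st.integers(3, 60))
    def test_matches_naive_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, n).astype(float)  # ties likely
        got = set(local_maxima(x).tolist())
        # naive: i is a peak iff the nearest differing neighbors on both
        # sides are lower and i is the first frame of its plateau
        expected = set()
        for i in range(1, n - 1):
            if x[i - 1] >= x[i]:
                continue
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                expected.add(i)
        assert got == expected


class TestDetectSpeaks:
    def test_noiseless_stroke_single_peak(self, cfg, noiseless_rec5, kernel25):
        rec, truth = noiseless_rec5
        speed = speed_profile(rec, kernel25)
        train = peaks_in_windows(speed.speed, truth.stroke_windows)
        for p in train.peaks_by_cycle:
            assert p.size == 1

    def test_rest_peaks_excluded(self):
        # peaks at frames 5 (inside) and 15 (outside the single cycle)
        v = np.zeros(30)
        v[5] = 1.0
        v[15] = 1.0
        speed = make_speed(v)
        cs = CycleSet(cycles=((2, 6, 9),))
        train = detect_speaks(speed, cs)
        np.testing.assert_array_equal(train.peaks_by_cycle[0], [5])

    def test_peak_outside_bounds_raises(self):
        with pytest.raises(Exception):
            SPeakTrain(peaks_by_cycle=(np.array([50]),), bounds=((0, 10),))


class TestComputeSipis:
    def test_hand_example(self):
        train = SPeakTrain(
            peaks_by_cycle=(np.array([10, 14, 30]),), bounds=((0, 40),)
        )
        np.testing.assert_array_equal(sorted(compute_sipis(train)), [4, 16])

    def test_single_peak_cycles_empty(self):
        train = SPeakTrain(
            peaks_by_cycle=(np.array([3]), np.array([], dtype=int)),
            bounds=((0, 10), (20, 30)),
        )
        assert compute_sipis(train).size == 0

    def test_no_cross_cycle_intervals(self):
        a = SPeakTrain(peaks_by_cycle=(np.array([1, 5]),), bounds=((0, 10),))
        b = SPeakTrain(peaks_by_cycle=(np.array([21, 29]),), bounds=((20, 30),))
        both = SPeakTrain(
            peaks_by_cycle=(np.array([1, 5]), np.array([21, 29])),
            bounds=((0, 10), (20, 30)),
        )
        union = sorted(compute_sipis(a).tolist() + compute_sipis(b).tolist())
        assert sorted(compute_sipis(both).tolist()) == union


class TestBuildHistogram:
    def test_binning_oracle(self, cfg):
        hist = build_histogram(np.array([1, 2, 3]), cfg)
        np.testing.assert_array_equal(hist.counts, [2, 1])
        np.testing.assert_array_equal(hist.bin_values, [2.0, 4.0])

    def test_empty(self, cfg):
        hist = build_histogram(np.array([]), cfg)
        assert hist.counts.size == 0
        assert hist.n_intervals == 0

    @settings(max_examples=50, deadline=None)
    @given(
        intervals=st.lists(st.integers(1, 60), min_size=1, max_size=200),
    )
    def test_count_conservation_and_trim(self, intervals):
        cfg = PipelineConfig()
        hist = build_histogram(np.array(intervals), cfg)
        assert hist.counts.sum() == len(intervals)
        assert hist.counts[-1] > 0  # trailing empties trimmed
        # each interval lands in the bin whose half-open range holds it
        for v in intervals:
            idx = math.ceil(v / cfg.ipi_bin_width) - 1
            lo = cfg.ipi_bin_width * idx
            hi = cfg.ipi_bin_width * (idx + 1)
            assert lo < v <= hi


class TestFitExponential:
    def test_exact_recovery(self, cfg):
        a_true, lam_true = 120.0, 0.35
        values = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        counts = a_true * np.exp(-lam_true * values)
        hist = build_histogram(
            np.repeat(values, 1), cfg
        )  # structure only; replace counts
        hist = hist.__class__(
            bin_width=2,
            bin_values=values,
            counts=counts,
            fit_cutoff=10,
        )
        out = fit_exponential(hist, cfg)
        assert out.amplitude == pytest.approx(a_true, rel=1e-9)
        assert out.rate == pytest.approx(lam_true, rel=1e-9)

    def test_degenerate_all_above_cutoff(self, cfg):
        hist = build_histogram(np.array([20, 24, 30]), cfg)
        out = fit_exponential(hist, cfg)
        assert out.amplitude == 0.0
        assert out.rate == 0.0
        # all mass becomes residual
        assert residual_counts(out).sum() == 3

    def test_poisson_rate_recovery(self, cfg):
        rng = np.random.default_rng(42)
        rho = 0.25
        intervals = rng.exponential(1.0 / rho, size=5000)
        intervals = intervals[intervals > 0]
        hist = fit_exponential(build_histogram(intervals, cfg), cfg)
        assert hist.rate_stderr is not None
        assert abs(hist.rate - rho) < 3 * hist.rate_stderr


class TestComputeR:
    def test_hand_case_all_twenty(self, cfg):
        r = pipeline_r([20] * 10)
        assert r == pytest.approx(20.0)
        assert r == pytest.approx(brute_force_r([20] * 10))

    @pytest.mark.parametrize("t", [14, 20, 30, 100])
    def test_two_small_vs_one_double(self, t):
        assert pipeline_r([t, t]) == pytest.approx(t)
        assert pipeline_r([2 * t]) == pytest.approx(2 * t)

    def test_perfect_exponential_r_zero(self, cfg):
        # counts equal to the fit on every bin -> residuals vanish
        values = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0])
        counts = 50.0 * np.exp(-0.4 * values)
        from speedpeaks.fluctuations import IPIHistogramFit

        hist = IPIHistogramFit(
            bin_width=2, bin_values=values, counts=counts, fit_cutoff=10
        )
        out = fit_exponential(hist, cfg)
        assert compute_R(out) == pytest.approx(0.0, abs=1e-9)

    def test_empty_undefined(self, cfg):
        hist = fit_exponential(build_histogram(np.array([]), cfg), cfg)
        with pytest.raises(UndefinedRError):
            compute_R(hist)

    @settings(max_examples=100, deadline=None)
    @given(
        intervals=st.lists(st.integers(1, 80), min_size=1, max_size=300),
    )
    def test_matches_brute_force(self, intervals):
        assert pipeline_r(intervals) == pytest.approx(
            brute_force_r(intervals), rel=1e-12
        )

    @settings(max_examples=40, deadline=None)
    @given(
        intervals=st.lists(
            st.integers(6, 60).map(lambda v: 2 * v), min_size=1, max_size=100
        )
    )
    def test_doubling_even_intervals_doubles_r(self, intervals):
        # all intervals above the cutoff: degenerate fit, pure weighting
        r1 = pipeline_r(intervals)
        r2 = pipeline_r([2 * v for v in intervals])
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_invariant_under_cycle_reordering(self, cfg):
        rng = np.random.default_rng(5)
        cycles = [np.sort(rng.choice(np.arange(200), size=8, replace=False)) for _ in range(6)]
        bounds = tuple((0, 199) for _ in cycles)

        def r_of(order):
            train = SPeakTrain(
                peaks_by_cycle=tuple(cycles[i] for i in order),
                bounds=bounds,
            )
            return pipeline_r(compute_sipis(train))

        base = r_of(range(6))
        assert r_of([5, 3, 0, 1, 4, 2]) == pytest.approx(base, rel=1e-12)


class TestBuildMatrix:
    def make_train(self):
        return SPeakTrain(
            peaks_by_cycle=(np.array([400]),),
            bounds=((0, 800),),
            touches=(400,),
        )

    def test_single_peak_at_touch(self, cfg):
        m = build_matrix(self.make_train(), "touch", cfg)
        assert m.matrix.shape == (1, 800)
        assert m.touch_column == 400
        assert m.matrix[0, 400] == 1
        assert m.matrix.sum() == 1

    def test_column_counts_match_per_frame_histogram(self, cfg):
        rng = np.random.default_rng(2)
        peaks, bounds, touches = [], [], []
        for i in range(5):
            t = 500 + 1000 * i
            p = np.sort(rng.choice(np.arange(t - 300, t + 300), 10, replace=False))
            peaks.append(p)
            bounds.append((t - 400, t + 399))
            touches.append(t)
        train = SPeakTrain(
            peaks_by_cycle=tuple(peaks), bounds=tuple(bounds), touches=tuple(touches)
        )
        m = build_matrix(train, "touch", cfg)
        # brute-force per-column histogram
        expected = np.zeros(800, dtype=int)
        for p, t in zip(peaks, touches):
            for v in p:
                expected[v - t + 400] += 1
        np.testing.assert_array_equal(m.column_counts, expected)

    def test_mean_length_alignment(self, cfg):
        train = SPeakTrain(
            peaks_by_cycle=(np.array([10, 50]), np.array([210])),
            bounds=((0, 99), (200, 319)),
        )
        m = build_matrix(train, "mean-length", cfg)
        assert m.matrix.shape == (2, 110)  # mean of 100 and 120
        assert m.matrix[0, 10] == 1 and m.matrix[0, 50] == 1
        assert m.matrix[1, 10] == 1

    def test_binary_entries(self, cfg):
        rec, truth = synth_recording(SimConfig(n_cycles=3, snr_db=5, seed=9))
        report = analyze_recording(rec)
        assert set(np.unique(report.matrix.matrix)) <= {0, 1}


class TestAnalyzeRecording:
    def test_deterministic(self):
        rec, _ = synth_recording(SimConfig(n_cycles=5, seed=4), position_noise_sd=2e-4)
        r1 = analyze_recording(rec).r_value
        r2 = analyze_recording(rec).r_value
        assert r1 == r2

    def test_noiseless_closed_form(self, cfg):
        # one peak per stroke; the two peaks of each cycle sit T2+rest+T1
        # frames apart, so every s-IPI equals stroke_T + rest exactly
        sim = SimConfig(n_cycles=10)
        rec, truth = synth_recording(sim)
        report = analyze_recording(rec)
        intervals = compute_sipis(report.train)
        expected_spacing = sim.stroke_T + sim.rest  # 260
        assert set(np.unique(intervals)) == {expected_spacing}
        assert report.r_value == pytest.approx(
            brute_force_r(intervals.tolist())
        )
        assert report.r_value == pytest.approx(expected_spacing)

    def test_too_few_touches_error(self, make_uniform_recording):
        from speedpeaks import PipelineError

        rec = make_uniform_recording(n=1000, vx=0.1)
        with pytest.raises(PipelineError):
            analyze_recording(rec)

    def test_duplication_invariance(self):
        # same generative session duplicated (2x cycles): R moves by less
        # than 3x the across-seed spread of the single session
        from speedpeaks.simulator import _session_r

        cfg = PipelineConfig()
        rs = [
            _session_r(SimConfig(n_cycles=100, snr_db=10, seed=s), cfg)
            for s in range(8)
        ]
        r_double = _session_r(SimConfig(n_cycles=200, snr_db=10, seed=100), cfg)
        assert abs(r_double - np.mean(rs)) < 3 * np.std(rs) + 1e-12
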