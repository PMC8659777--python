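"""Extrema detection, fake-step rejection, motionless filter, pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magstep import (
    DetectorConfig,
    Extremum,
    GaitSimConfig,
    SampleSeries,
    Segment,
    SensorSpec,
    calibrate_motionless_threshold,
    detect_extrema,
    motionless_filter,
    run_pipeline,
    simulate_trace,
    threshold_filter,
)
from magstep.detection import normalize_alternating


# --- independent oracles ---------------------------------------------------

def brute_force_extrema(x):
    """Compare every interior point to both neighbours (no vectorisation)."""
    out = []
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            out.append((i, x[i], "peak"))
        elif x[i] < x[i - 1] and x[i] < x[i + 1]:
            out.append((i, x[i], "valley"))
    return out


def oracle_threshold_filter(extrema, threshold):
    """Independent formulation of the complementary-extremum skip rule.

    From the last accepted extremum at position i, the complementary
    candidates sit at i+1, i+3, i+5, … (alternating input); the first one
    whose amplitude gap reaches the threshold is accepted.
    """
    if not extrema:
        return []
    accepted = [extrema[0]]
    i = 0
    while True:
        j = i + 1
        while j < len(extrema) and abs(
            extrema[j].value - extrema[i].value
        ) < threshold:
            j += 2
        if j >= len(extrema):
            break
        accepted.append(extrema[j])
        i = j
    return accepted


def random_alternating(rng, n):
    start = rng.integers(0, 2)
    kinds = ["peak", "valley"]
    return [
        Extremum(index=i * 5, value=float(rng.normal(0, 1)),
                 kind=kinds[(start + i) % 2])
        for i in range(n)
    ]


# --- extrema detection -----------------------------------------------------

class TestDetectExtrema:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 3, 1], [(1, 3.0, "peak")]),
            ([3, 1, 3], [(1, 1.0, "valley")]),
            ([1, 2, 3], []),
            ([1, 2], []),
            ([], []),
            # plateau flanked by lower values: one peak at the run's start
            ([1, 2, 2, 2, 1], [(1, 2.0, "peak")]),
            # monotone shoulder plateau is not an extremum
            ([0, 1, 1, 2], []),
            ([3, 2, 2, 3], [(1, 2.0, "valley")]),
        ],
    )
    def test_small_cases(self, values, expected):
        got = [(e.index, e.value, e.kind) for e in detect_extrema(values)]
        assert got == expected

    def test_matches_brute_force_on_noisy_sinusoids(self, rng):
        for _ in range(50):
            t = np.arange(100) / 40.0
            x = np.sin(2 * np.pi * rng.uniform(0.5, 3) * t) + rng.normal(
                0, 0.3, 100
            )
            got = [(e.index, e.value, e.kind) for e in detect_extrema(x)]
            assert got == brute_force_extrema(x)

    def test_output_alternates(self, rng):
        x = rng.normal(0, 1, 500)
        kinds = [e.kind for e in detect_extrema(x)]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


# --- threshold comparator --------------------------------------------------

def _ext(seq):
    return [
        Extremum(index=i * 10, value=v, kind=k)
        for i, (k, v) in enumerate(seq)
    ]


class TestThresholdFilter:
    def test_small_gaps_collapse_to_first_extremum(self):
        ext = _ext([("peak", 10.0), ("valley", 9.8), ("peak", 10.1)])
        got = threshold_filter(ext, 0.5)
        assert [(e.kind, e.value) for e in got] == [("peak", 10.0)]

    def test_large_gaps_all_accepted(self):
        ext = _ext([("peak", 10.0), ("valley", 8.0), ("peak", 10.0)])
        assert threshold_filter(ext, 0.5) == ext

    def test_zero_threshold_is_identity(self, rng):
        ext = random_alternating(rng, 30)
        assert threshold_filter(ext, 0.0) == ext

    def test_empty_input(self):
        assert threshold_filter([], 0.5) == []

    def test_matches_independent_skip_rule_oracle(self, rng):
        for _ in range(300):
            ext = random_alternating(rng, int(rng.integers(0, 25)))
            thr = float(rng.uniform(0, 2))
            assert threshold_filter(ext, thr) == oracle_threshold_filter(ext, thr)

    def test_skip_rule_is_not_globally_monotone_in_threshold(self):
        """The skip rule is path-dependent: rejecting a candidate also
        skips a same-kind extremum, so a higher threshold can reroute the
        scan onto a path that accepts MORE extrema.  Frozen minimal
        counterexample: values (P4, V2, P3, V0, P3)."""
        ext = _ext(
            [("peak", 4.0), ("valley", 2.0), ("peak", 3.0),
             ("valley", 0.0), ("peak", 3.0)]
        )
        assert len(threshold_filter(ext, 1.5)) == 2  # P4, V2
        assert len(threshold_filter(ext, 2.5)) == 3  # P4, V0, P3

    def test_threshold_monotone_end_to_end_on_gait_traces(self):
        """On actual walking traces the accepted step count is a
        non-increasing function of the fake-step threshold."""
        series, _ = simulate_trace(GaitSimConfig(walk_speed_kmh=5.0, seed=3))
        counts = [
            run_pipeline(
                series,
                config=DetectorConfig(fake_step_threshold_uT=float(t)),
            ).step_count
            for t in np.linspace(0.05, 3.0, 15)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_non_alternating_input_normalized(self):
        ext = [
            Extremum(0, 10.0, "peak"),
            Extremum(5, 11.0, "peak"),  # same-kind run: keep the higher
            Extremum(9, 8.0, "valley"),
        ]
        got = threshold_filter(ext, 0.5)
        assert [(e.kind, e.value) for e in got] == [
            ("peak", 11.0),
            ("valley", 8.0),
        ]

    def test_normalize_keeps_more_extreme_representative(self):
        ext = [
            Extremum(0, 1.0, "valley"),
            Extremum(3, 0.5, "valley"),
            Extremum(6, 2.0, "peak"),
        ]
        got = normalize_alternating(ext)
        assert [(e.kind, e.value) for e in got] == [
            ("valley", 0.5),
            ("peak", 2.0),
        ]


# --- motionless detector ---------------------------------------------------

class TestMotionlessFilter:
    def test_standing_noise_yields_no_steps(self):
        cfg = GaitSimConfig(segments=(Segment("standing", 30.0),), seed=11)
        series, _ = simulate_trace(cfg)
        # feed the raw noise directly; deviations are far below threshold
        ext = detect_extrema(series.values)
        dcfg = DetectorConfig()
        survivors, labels = motionless_filter(series, ext, dcfg)
        assert survivors == []
        assert not labels.any()

    def test_walking_blocks_all_labelled_moving(self):
        cfg = GaitSimConfig(walk_speed_kmh=5.0, seed=12)
        series, _ = simulate_trace(cfg)
        ext = detect_extrema(series.values)
        survivors, labels = motionless_filter(series, ext, DetectorConfig())
        assert labels.all()
        assert survivors == ext

    def test_empty_extrema_list_passes_through(self):
        series = SampleSeries(values=np.zeros(100), sampling_hz=40.0)
        survivors, _ = motionless_filter(series, [], DetectorConfig())
        assert survivors == []


class TestCalibration:
    def test_constant_traces_give_zero(self):
        traces = [np.full(100, 5.0), np.full(50, -2.0)]
        assert calibrate_motionless_threshold(traces) == 0.0

    def test_gaussian_noise_matches_closed_form_mad(self, rng):
        # E|X - mean| = sigma * sqrt(2/pi) ~ 0.199 at sigma = 0.25
        traces = [rng.normal(0, 0.25, 20000) for _ in range(5)]
        got = calibrate_motionless_threshold(traces, safety_factor=1.0)
        assert got == pytest.approx(0.25 * np.sqrt(2 / np.pi), rel=0.03)

    def test_averaging_over_traces(self):
        d = 0.5
        t1 = np.tile([-d, d], 100)   # MAD d
        t2 = np.tile([-3 * d, 3 * d], 100)  # MAD 3d
        got = calibrate_motionless_threshold([t1, t2], safety_factor=1.0)
        assert got == pytest.approx(2 * d)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibrate_motionless_threshold([])


# --- full pipeline ---------------------------------------------------------

class TestRunPipeline:
    def test_noiseless_walk_recovers_exact_count(self, noiseless_walk_config):
        series, truth = simulate_trace(noiseless_walk_config)
        report = run_pipeline(series)
        assert report.step_count == truth.step_count

    def test_standing_only_counts_zero_steps(self):
        cfg = GaitSimConfig(segments=(Segment("standing", 30.0),), seed=4)
        series, _ = simulate_trace(cfg)
        assert run_pipeline(series).step_count == 0

    def test_mixed_walk_stand_walk(self):
        cfg = GaitSimConfig(
            walk_speed_kmh=5.0,
            segments=(
                Segment("walking", 30.0),
                Segment("standing", 20.0),
                Segment("walking", 30.0),
            ),
            seed=6,
        )
        series, truth = simulate_trace(cfg)
        report = run_pipeline(series)
        assert abs(report.step_count - truth.step_count) <= 2
        assert not all(report.block_motion_labels)

    def test_subthreshold_disturbances_do_not_change_count(self):
        from magstep import Disturbance

        base = GaitSimConfig(walk_speed_kmh=5.0, seed=8)
        rippled = GaitSimConfig(
            walk_speed_kmh=5.0,
            seed=8,
            disturbances=tuple(
                Disturbance(time_s=t, amplitude_uT=0.3, width_s=0.4)
                for t in (10.0, 25.0, 40.0, 55.0)
            ),
        )
        s0, _ = simulate_trace(base)
        s1, _ = simulate_trace(rippled)
        assert run_pipeline(s0).step_count == run_pipeline(s1).step_count

    def test_short_trace_warns_and_reports_zero(self):
        series = SampleSeries(values=np.zeros(50), sampling_hz=40.0)
        with pytest.warns(UserWarning, match="shorter than one block"):
            report = run_pipeline(series)
        assert report.step_count == 0
        assert report.warnings

    def test_report_counts_are_consistent(self):
        series, _ = simulate_trace(GaitSimConfig(walk_speed_kmh=4.0, seed=9))
        r = run_pipeline(series)
        assert r.step_count == (
            r.raw_extrema_count
            - r.rejected_by_threshold
            - r.rejected_by_motionless
        )

    def test_lsb_input_accepted(self):
        series, truth = simulate_trace(GaitSimConfig(walk_speed_kmh=5.0, seed=10))
        counts = series.to_lsb(0.1)
        report = run_pipeline(counts)
        assert abs(report.step_count - truth.step_count) <= 2

    def test_step_times_are_delay_corrected_and_in_range(
        self, noiseless_walk_config
    ):
        series, truth = simulate_trace(noiseless_walk_config)
        report = run_pipeline(series)
        times = report.step_times
        assert np.all(times >= 0)
        assert np.all(times <= series.duration_s)
        # detected times line up with the true extremum times
        assert np.max(np.abs(times - truth.step_times)) < 0.1

    def test_deterministic_for_fixed_input(self):
        series, _ = simulate_trace(GaitSimConfig(seed=13))
        assert run_pipeline(series).to_dict() == run_pipeline(series).to_dict()

    def test_block_size_below_filter_order_rejected(self):
        series, _ = simulate_trace(GaitSimConfig(seed=14))
        with pytest.raises(ValueError, match="block_size"):
            run_pipeline(series, config=DetectorConfig(block_size=40))
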