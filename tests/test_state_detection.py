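"""Trace idealization: transition detection, dwell extraction, stability."""

import numpy as np
import pytest

from kinlock.state_detection import (
    DwellRecord,
    DwellSet,
    TransitionList,
    chunk_stability,
    detect_transitions,
    extract_dwells,
)
from kinlock.synthetic_data import (
    ExtensionTrace,
    ProbeGeometry,
    build_two_state_scheme,
    gillespie_path,
    render_trace,
)

FRAME = 1.0 / 1300.0


def make_trace(extensions, rate=1300.0):
    extensions = np.asarray(extensions, dtype=float)
    return ExtensionTrace(times=np.arange(len(extensions)) / rate,
                          extensions=extensions, sampling_rate=rate)


class TestDetectTransitions:
    def test_flat_noisy_trace_has_no_transitions(self):
        rng = np.random.default_rng(0)
        trace = make_trace(rng.normal(0.0, 1.0, 20_000))
        assert len(detect_transitions(trace)) == 0

    def test_single_clean_step_detected_at_step_frame(self):
        x = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        t = detect_transitions(make_trace(x))
        assert len(t) == 1
        time, direction = t[0]
        assert direction == "open"
        assert time == pytest.approx(50 * FRAME)

    def test_noise_free_paths_recovered_exactly_above_two_frames(self):
        """On clean traces every dwell of >= 2 frames maps to one transition
        pair at the right frames."""
        x = np.concatenate([np.zeros(20), np.full(2, 10.0), np.zeros(7),
                            np.full(30, 10.0), np.zeros(20)])
        t = detect_transitions(make_trace(x))
        assert [d for _, d in t] == ["open", "close", "open", "close"]
        frames = np.round(t.times / FRAME).astype(int)
        assert list(frames) == [20, 22, 29, 59]

    def test_threshold_monotonicity(self, two_state_sim):
        """Raising the threshold never produces more detections."""
        _, _, trace, _ = two_state_sim
        counts = [len(detect_transitions(trace, threshold_nm=thr))
                  for thr in (5.0, 6.5, 8.0, 9.5, 11.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_directions_always_alternate(self, two_state_sim):
        _, _, trace, _ = two_state_sim
        dirs = detect_transitions(trace).directions
        assert all(x != y for x, y in zip(dirs, dirs[1:]))

    def test_detection_quality_on_noisy_simulation(self, two_state_sim):
        """At the probe conditions (10 ms dwells, 1.5 nm noise, 1300 Hz):
        >= 95% of true dwells longer than 5 frames are recovered with the
        right phase, and the mean open dwell is within 10% of 1/k_f."""
        _, _, trace, truth = two_state_sim
        states, starts, durs = truth
        trans = detect_transitions(trace)
        dwells = extract_dwells(trans, total_time=trace.duration)
        det_state = np.array([r.state for r in dwells.records])
        det_start = np.array([r.start for r in dwells.records])
        det_dur = np.array([r.duration for r in dwells.records])
        mids = starts + durs / 2
        idx = np.searchsorted(det_start, mids) - 1
        idx = np.clip(idx, 0, len(det_start) - 1)
        covered = (det_state[idx] == states) & (mids < det_start[idx] + det_dur[idx])
        long_true = durs > 5 * FRAME
        assert covered[long_true].mean() >= 0.95
        # the recovered mean open dwell carries only the sub-frame merging
        # inflation: within 10% of the ground-truth sample mean (= 1/k_f up
        # to simulation noise)
        mean_open = dwells.durations("open").mean()
        truth_open = durs[states == "open"].mean()
        assert truth_open == pytest.approx(0.01, rel=0.05)
        assert mean_open / truth_open - 1 < 0.10

    def test_empty_trace_raises(self):
        empty = ExtensionTrace(times=np.empty(0), extensions=np.empty(0), sampling_rate=1300.0)
        with pytest.raises(ValueError):
            detect_transitions(empty)

    def test_parameter_validation(self, two_state_sim):
        _, _, trace, _ = two_state_sim
        with pytest.raises(ValueError):
            detect_transitions(trace, threshold_nm=0.0)
        with pytest.raises(ValueError):
            detect_transitions(trace, tolerance_nm=9.0)  # above threshold
        with pytest.raises(ValueError):
            detect_transitions(trace, smooth_window=0)


class TestExtractDwells:
    def test_simple_pair_yields_one_open_dwell(self):
        t = TransitionList(np.array([1.0, 1.25]), np.array(["open", "close"], dtype=object))
        ds = extract_dwells(t, total_time=2.0)
        assert len(ds) == 1
        assert ds.records[0].state == "open"
        assert ds.records[0].duration == pytest.approx(0.25)

    def test_censored_tails_kept_on_request(self):
        t = TransitionList(np.array([1.0, 1.25]), np.array(["open", "close"], dtype=object))
        ds = extract_dwells(t, total_time=2.0, drop_censored=False)
        assert [r.state for r in ds.records] == ["closed", "open", "closed"]
        assert [r.censored for r in ds.records] == [True, False, True]
        assert sum(r.duration for r in ds.records) == pytest.approx(2.0)

    def test_empty_transitions_give_empty_set(self):
        ds = extract_dwells(TransitionList(np.empty(0), np.empty(0, dtype=object)), 5.0)
        assert len(ds) == 0

    def test_non_alternating_input_rejected(self):
        t = TransitionList(np.array([1.0, 2.0]), np.array(["open", "open"], dtype=object))
        with pytest.raises(ValueError, match="alternate"):
            extract_dwells(t, total_time=3.0)

    def test_consecutive_dwells_alternate_state(self):
        with pytest.raises(ValueError, match="alternate"):
            DwellSet(records=[DwellRecord("open", 0.0, 1.0), DwellRecord("open", 1.0, 1.0)],
                     total_time=2.0)


@pytest.fixture(scope="module")
def long_dwells():
    scheme = build_two_state_scheme(100.0, 100.0)
    path = gillespie_path(scheme, 800.0, seed=11)
    trace = render_trace(path, ProbeGeometry(), seed=12, scheme=scheme)
    trans = detect_transitions(trace)
    return extract_dwells(trans, total_time=800.0)


class TestChunkStability:

    def test_stationary_chunks_agree(self, long_dwells):
        table = chunk_stability(long_dwells, chunk_s=100.0, seed=0)
        assert len(table) == 8
        for tag in ("open", "closed"):
            means = table[f"mean_{tag}_s"]
            assert means.max() - means.min() < 1e-3  # 1 ms band
            assert (table[f"boot_sd_{tag}_s"] > 0).all()

    def test_single_chunk_equals_global_mean(self, long_dwells):
        table = chunk_stability(long_dwells, chunk_s=400.0, seed=0)
        pooled_open = long_dwells.durations("open")
        pooled_starts = long_dwells.starts("open")
        first = pooled_open[pooled_starts < 400.0]
        assert table["mean_open_s"].iloc[0] == pytest.approx(first.mean())

    def test_drift_produces_trending_chunk_means(self):
        """Two concatenated regimes (k_f doubled) show up as a monotone
        shift of per-chunk mean open dwells."""
        g = ProbeGeometry()
        p1 = gillespie_path(build_two_state_scheme(100.0, 100.0), 200.0, seed=21)
        p2 = gillespie_path(build_two_state_scheme(200.0, 100.0), 200.0, seed=22)
        t1 = render_trace(p1, g, seed=23, scheme=build_two_state_scheme(100.0, 100.0))
        t2 = render_trace(p2, g, seed=24, scheme=build_two_state_scheme(200.0, 100.0))
        joined = ExtensionTrace(
            times=np.arange(len(t1) + len(t2)) / g.sampling_rate,
            extensions=np.concatenate([t1.extensions, t2.extensions]),
            sampling_rate=g.sampling_rate,
        )
        dwells = extract_dwells(detect_transitions(joined), total_time=400.0)
        table = chunk_stability(dwells, chunk_s=100.0, seed=0)
        means = table["mean_open_s"].to_numpy()
        assert means[0] > means[-1]
        assert means[:2].mean() / means[-2:].mean() == pytest.approx(2.0, rel=0.15)

    def test_sparse_chunk_flagged(self):
        records, t = [], 0.0
        state = "open"
        while t < 250.0:
            records.append(DwellRecord(state, t, 1.0))
            state = "closed" if state == "open" else "open"
            t += 1.0
        ds = DwellSet(records=records, total_time=250.0)
        table = chunk_stability(ds, chunk_s=100.0, min_events=150, seed=0)
        assert table["flagged"].any()

    def test_too_short_record_rejected(self, long_dwells):
        with pytest.raises(ValueError):
            chunk_stability(long_dwells, chunk_s=500.0)
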