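"""Body-angle computation and movement-event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvamotor.kinematics import (
    AngleTrace,
    MovementEvent,
    PointTrack,
    assign_direction,
    classify_peak,
    compute_body_angle,
    detect_events,
    summarize,
)

from conftest import track_from_points


def brute_force_events(trace, rest_band=5.0, min_duration=3):
    """Independent frame-by-frame scan enumerating maximal excursions.

    Walks the trace one frame at a time collecting maximal runs outside
    the rest band, cuts each run wherever the signed angle changes
    side, then classifies by peak.  No vectorization shared with the
    implementation.
    """
    theta, signed, fps = trace.theta, trace.signed_theta, trace.frame_rate
    n = len(theta)
    events = []
    i = 0
    while i < n:
        if theta[i] <= 180.0 + rest_band:
            i += 1
            continue
        j = i
        while j < n and theta[j] > 180.0 + rest_band:
            j += 1
        # cut [i, j) at direction changes
        pieces = []
        a = i
        for k in range(i + 1, j):
            side_prev = 1 if signed[k - 1] >= 0 else -1
            side_k = 1 if signed[k] >= 0 else -1
            if side_k != side_prev:
                pieces.append((a, k))
                a = k
        pieces.append((a, j))
        for (a, b) in pieces:
            if b - a < min_duration:
                continue
            peak = max(theta[a:b])
            peak_at = a + int(np.argmax(theta[a:b]))
            events.append(
                MovementEvent(
                    onset=a / fps,
                    offset=b / fps,
                    peak_angle=float(peak),
                    direction="left" if signed[peak_at] >= 0 else "right",
                    event_class=classify_peak(float(peak)),
                    truncated=(j == n and b == j),
                    split=len(pieces) > 1,
                )
            )
        i = j
    return events


def half_sine_trace(peaks_dirs_durs, fps=300.0, gap_s=0.1, jitter=0.0, seed=0):
    """Signed-angle trace made of back-to-back half-sine excursions."""
    rng = np.random.default_rng(seed)
    total = gap_s + sum(d + gap_s for _, _, d in peaks_dirs_durs)
    n = int(round(total * fps)) + 1
    signed = rng.normal(0.0, jitter, n)
    t = np.arange(n) / fps
    start = gap_s
    for peak, direction, dur in peaks_dirs_durs:
        sel = (t >= start) & (t < start + dur)
        signed[sel] = direction * (peak - 180.0) * np.sin(
            np.pi * (t[sel] - start) / dur
        )
        start += dur + gap_s
    theta = 180.0 + np.abs(signed)
    return AngleTrace(frame_rate=fps, theta=theta, signed_theta=signed)


class TestBodyAngle:
    @pytest.mark.parametrize(
        "T, expected",
        [
            ((0.0, -1.0), 180.0),  # straight larva: resting angle
            ((1.0, 0.0), 270.0),  # tail perpendicular to trunk axis
            ((0.5, -0.8660254), 210.0),  # 150 deg between the two segments
        ],
    )
    def test_worked_configurations(self, T, expected):
        track = track_from_points([[0, 1, 0, 0, *T]] * 2)
        trace = compute_body_angle(track)
        assert trace.theta == pytest.approx([expected] * 2, abs=1e-6)

    def test_signed_theta_magnitude_and_direction(self):
        # tail to the right of the trunk axis => negative (right)
        track = track_from_points([[0, 1, 0, 0, 1, 0], [0, 1, 0, 0, -1, 0]])
        trace = compute_body_angle(track)
        assert trace.signed_theta[0] == pytest.approx(-90.0)
        assert trace.signed_theta[1] == pytest.approx(90.0)
        assert np.allclose(np.abs(trace.signed_theta), trace.theta - 180.0)

    def test_degenerate_frame_names_index(self):
        track = track_from_points([[0, 1, 0, 0, 0, -1], [0, 1, 0, 0, 0, 0]])
        with pytest.raises(ValueError, match="frame 1"):
            compute_body_angle(track)

    @given(
        st.lists(
            st.tuples(
                *[st.floats(-10, 10, allow_nan=False) for _ in range(6)]
            ).filter(
                lambda r: (r[0] - r[2]) ** 2 + (r[1] - r[3]) ** 2 > 1e-4
                and (r[4] - r[2]) ** 2 + (r[5] - r[3]) ** 2 > 1e-4
            ),
            min_size=2,
            max_size=20,
        )
    )
    @settings(derandomize=True, max_examples=100)
    def test_theta_range_invariant(self, rows):
        trace = compute_body_angle(track_from_points(rows))
        assert np.all(trace.theta >= 180.0 - 1e-9)
        assert np.all(trace.theta <= 360.0 + 1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.uniform(-5, 5, (8, 6))
        rows[:, 4:] += 0.5  # keep T off M
        rows[:, :2] -= 0.5  # keep H off M
        base = compute_body_angle(track_from_points(rows))
        angle = rng.uniform(0, 2 * np.pi)
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        shift = rng.uniform(-3, 3, 2)
        moved = np.empty_like(rows)
        for j in range(3):
            moved[:, 2 * j : 2 * j + 2] = rows[:, 2 * j : 2 * j + 2] @ R.T + shift
        rotated = compute_body_angle(track_from_points(moved))
        assert np.allclose(rotated.theta, base.theta, atol=1e-9)

    def test_mirror_flips_direction_only(self):
        trace = half_sine_trace([(250, 1, 0.06), (230, -1, 0.08)], jitter=0.5)
        # rebuild the two tracks from the signed angle
        def to_track(signed):
            psi = np.radians(signed)
            coords = np.column_stack(
                [
                    np.zeros_like(psi),
                    np.ones_like(psi),
                    np.zeros_like(psi),
                    np.zeros_like(psi),
                    -np.sin(psi),
                    -np.cos(psi),
                ]
            )
            return PointTrack(trace.frame_rate, coords)

        track = to_track(trace.signed_theta)
        mirrored_coords = np.array(track.coords)
        mirrored_coords[:, 0] *= -1  # reflect all x coordinates
        mirrored_coords[:, 2] *= -1
        mirrored_coords[:, 4] *= -1
        mirrored = PointTrack(trace.frame_rate, mirrored_coords)
        ev = detect_events(compute_body_angle(track))
        ev_m = detect_events(compute_body_angle(mirrored))
        assert len(ev) == len(ev_m)
        for a, b in zip(ev, ev_m):
            assert a.direction != b.direction
            assert a.event_class == b.event_class
            assert a.onset == b.onset and a.offset == b.offset
            assert a.peak_angle == pytest.approx(b.peak_angle, abs=1e-9)


class TestDetectEvents:
    def test_constant_rest_trace_yields_no_events(self):
        trace = AngleTrace(300.0, np.full(600, 180.0), np.zeros(600))
        assert detect_events(trace) == []

    def test_single_lam_duration_and_class(self):
        trace = half_sine_trace([(250, 1, 0.06)])
        events = detect_events(trace)
        assert len(events) == 1
        e = events[0]
        assert e.event_class == "lam"
        assert e.direction == "left"
        # rest-to-rest duration within two frame periods of the scheduled 60 ms
        assert e.duration == pytest.approx(0.06, abs=2 / 300.0 + 0.06 * 0.05)

    def test_wag_is_not_a_lam(self):
        trace = half_sine_trace([(190, -1, 0.05)])
        events = detect_events(trace)
        assert [e.event_class for e in events] == ["wag"]

    @pytest.mark.parametrize(
        "peak, expected", [(199.99, "wag"), (200.0, "wag"), (200.01, "lam"),
                           (269.99, "lam"), (270.0, "extreme"), (275.0, "extreme")]
    )
    def test_class_boundaries(self, peak, expected):
        assert classify_peak(peak) == expected

    def test_min_duration_discards_short_blips(self):
        theta = np.full(100, 180.0)
        theta[50:52] = 250.0  # two frames only
        signed = theta - 180.0
        assert detect_events(AngleTrace(300.0, theta, signed), min_duration=3) == []

    def test_truncated_final_event_flagged(self):
        theta = np.full(100, 180.0)
        theta[90:] = 250.0  # excursion runs into the end of the trace
        signed = theta - 180.0
        events = detect_events(AngleTrace(300.0, theta, signed))
        assert len(events) == 1 and events[0].truncated
        summary = summarize(events, window=1.0)
        assert summary.lam_count == 1
        assert summary.lam_durations.size == 0  # excluded from durations

    def test_direction_reversal_splits_and_flags(self):
        # excursion goes left then right without touching the rest band
        theta = np.full(60, 180.0)
        signed = np.zeros(60)
        signed[20:30] = 40.0
        signed[30:40] = -40.0
        theta = 180.0 + np.abs(signed)
        events = detect_events(AngleTrace(300.0, theta, signed))
        assert len(events) == 2
        assert [e.direction for e in events] == ["left", "right"]
        assert all(e.split for e in events)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 1000))
        signed = rng.normal(0, 2, n)
        # sprinkle excursions of varying width and side
        for _ in range(int(rng.integers(1, 8))):
            a = int(rng.integers(0, n - 10))
            w = int(rng.integers(2, 10))
            signed[a : a + w] = rng.choice([-1, 1]) * rng.uniform(6, 120)
        theta = 180.0 + np.abs(signed)
        trace = AngleTrace(300.0, theta, signed)
        got = detect_events(trace)
        expected = brute_force_events(trace)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g.onset == e.onset and g.offset == e.offset
            assert g.event_class == e.event_class
            assert g.direction == e.direction
            assert g.truncated == e.truncated

    def test_requires_signed_theta(self):
        with pytest.raises(ValueError, match="signed_theta"):
            detect_events(AngleTrace(300.0, np.full(10, 180.0)))


class TestAssignDirection:
    def test_constant_direction_within_excursion(self):
        trace = half_sine_trace([(250, 1, 0.06)], jitter=0.3, seed=5)
        track_signed = trace.signed_theta
        psi = np.radians(track_signed)
        coords = np.column_stack(
            [np.zeros_like(psi), np.ones_like(psi), np.zeros_like(psi),
             np.zeros_like(psi), -np.sin(psi), -np.cos(psi)]
        )
        track = PointTrack(trace.frame_rate, coords)
        refined = assign_direction(track, compute_body_angle(track))
        outside = refined.theta > 185.0
        signs = np.sign(refined.signed_theta[outside])
        assert np.all(signs == signs[0])


class TestSummarize:
    def test_counts_and_durations(self):
        fps = 300.0
        events = [
            MovementEvent(0.1, 0.157, 250.0, "left", "lam"),
            MovementEvent(0.5, 0.557, 240.0, "right", "lam"),
            MovementEvent(1.0, 1.057, 255.0, "left", "lam"),
            MovementEvent(2.0, 2.04, 190.0, "left", "wag"),
            MovementEvent(3.0, 3.08, 280.0, "right", "extreme"),
        ]
        s = summarize(events, window=20.0)
        assert s.lam_count == 3
        assert s.wag_count == 1
        assert s.extreme_count == 1  # extreme never counted as LAM
        assert s.lam_duration_mean == pytest.approx(0.057)
        assert s.lam_duration_sem == pytest.approx(0.0)

    def test_window_is_half_open(self):
        events = [
            MovementEvent(0.0, 0.05, 250.0, "left", "lam"),
            MovementEvent(20.0, 20.05, 250.0, "left", "lam"),
        ]
        assert summarize(events, window=20.0).lam_count == 1

    def test_empty_input_is_not_an_error(self):
        s = summarize([], window=20.0)
        assert s.lam_count == 0
        assert s.lam_durations.size == 0
        assert np.isnan(s.lam_duration_mean)

    def test_ecdf_right_continuous_and_normalized(self):
        events = [
            MovementEvent(t, t + d, 250.0, "left", "lam")
            for t, d in [(0.0, 0.04), (1.0, 0.05), (2.0, 0.06)]
        ]
        s = summarize(events)
        d = np.sort(s.lam_durations)
        assert s.ecdf(d[-1]) == pytest.approx(1.0)  # F(max) = 1
        assert s.ecdf(d[1]) == pytest.approx(2 / 3)  # right-continuous step
        assert s.ecdf(0.5 * (d[0] + d[1])) == pytest.approx(1 / 3)
        assert s.ecdf(0.0) == 0.0
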