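"""Body-angle kinematics for head-embedded larval zebrafish.

A head-embedded larva is filmed at high speed (typically 300 fps for
20 s) and three points are tracked in every frame: head ``H`` (between
the eyes), mid-trunk ``M`` (at the swim bladder) and tail ``T`` (a
little above the tip).  The body angle is the angle subtended at M by
lines M->H and M->T, mapped so that a straight larva reads 180 deg:

    theta(deg) = 360 - (180/pi) * arccos( (H-M).(T-M) / (|H-M| |T-M|) )

Because the arccos lies in [0, 180] deg, theta is confined to
[180, 360] deg; the left/right direction of a bend is recovered
separately from the sign of the planar cross product (H-M) x (T-M)
(positive = left, the convention used when plotting left-directed
movements above the resting line).

Tail movements are excursions of theta out of a rest band around
180 deg.  An event runs from the frame theta leaves the band until the
frame it first re-enters while bending to a single side.  Events are
classified by peak angle:

* ``wag``     — peak <= 200 deg: low-amplitude tail beat, occurs in clusters;
* ``lam``     — 200 < peak < 270 deg: large-angle movement, the
  startle/escape-scale movement whose rate and duration separate
  control from Mn-treated larvae;
* ``extreme`` — peak >= 270 deg: reported separately, never counted as a LAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PointTrack",
    "AngleTrace",
    "MovementEvent",
    "KinematicsSummary",
    "compute_body_angle",
    "assign_direction",
    "detect_events",
    "summarize",
    "WAG_LAM_BOUNDARY_DEG",
    "LAM_EXTREME_BOUNDARY_DEG",
    "REST_ANGLE_DEG",
]

REST_ANGLE_DEG = 180.0
WAG_LAM_BOUNDARY_DEG = 200.0
LAM_EXTREME_BOUNDARY_DEG = 270.0

#: column order of PointTrack.coords
TRACK_COLUMNS = ("Hx", "Hy", "Mx", "My", "Tx", "Ty")


@dataclass(frozen=True)
class PointTrack:
    """Per-frame planar coordinates of the three tracked body points.

    Parameters
    ----------
    frame_rate : float
        Acquisition rate in frames per second (> 0).
    coords : ndarray, shape (n_frames, 6)
        Columns ``Hx, Hy, Mx, My, Tx, Ty`` in arbitrary spatial units.
    """

    frame_rate: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if coords.ndim != 2 or coords.shape[1] != 6:
            raise ValueError(f"coords must have shape (n_frames, 6), got {coords.shape}")
        if coords.shape[0] < 2:
            raise ValueError("a point track needs at least 2 frames")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class AngleTrace:
    """Per-frame body angle, optionally with a signed (left/right) version.

    ``theta`` lies in [180, 360] degrees.  ``signed_theta`` is
    ``+(theta - 180)`` for left-directed bends and ``-(theta - 180)``
    for right-directed bends, so ``abs(signed_theta) == theta - 180``.
    """

    frame_rate: float
    theta: np.ndarray
    signed_theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if theta.ndim != 1:
            raise ValueError("theta must be one-dimensional")
        if self.signed_theta is not None:
            signed = np.asarray(self.signed_theta, dtype=float)
            object.__setattr__(self, "signed_theta", signed)
            if signed.shape != theta.shape:
                raise ValueError("signed_theta must match theta in length")

    @property
    def n_frames(self) -> int:
        return self.theta.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame k occurs at k / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class MovementEvent:
    """One detected tail movement.

    ``onset`` is the time of the first frame outside the rest band,
    ``offset`` the time of the first frame back inside it (rest-to-rest
    duration rule).  ``truncated`` marks an excursion still in progress
    at the end of the trace; such events are excluded from duration
    statistics.  ``split`` marks events produced by cutting a
    direction-reversing excursion at a signed-angle zero crossing.
    """

    onset: float
    offset: float
    peak_angle: float
    direction: str  # "left" | "right"
    event_class: str  # "wag" | "lam" | "extreme"
    truncated: bool = False
    split: bool = False

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("event onset must precede offset")
        if self.direction not in ("left", "right"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.event_class not in ("wag", "lam", "extreme"):
            raise ValueError(f"invalid event class {self.event_class!r}")

    @property
    def duration(self) -> float:
        """Rest-to-rest duration in seconds."""
        return self.offset - self.onset


@dataclass(frozen=True)
class KinematicsSummary:
    """Event-rate and duration summary over an observation window."""

    window: float
    lam_count: int
    wag_count: int
    extreme_count: int
    lam_durations: np.ndarray  # seconds, truncated events excluded
    wag_durations: np.ndarray
    lam_duration_mean: float
    lam_duration_sem: float
    wag_duration_mean: float
    wag_duration_sem: float
    ecdf: Callable[[np.ndarray | float], np.ndarray | float] = field(repr=False)


def classify_peak(peak_angle: float) -> str:
    """Class of an event from its peak body angle.

    Strict inequalities follow the LAM definition (>200 and <270 deg);
    a peak of exactly 200 deg is a wag and exactly 270 deg is extreme.
    """
    if peak_angle <= WAG_LAM_BOUNDARY_DEG:
        return "wag"
    if peak_angle < LAM_EXTREME_BOUNDARY_DEG:
        return "lam"
    return "extreme"


def compute_body_angle(track: PointTrack) -> AngleTrace:
    """Compute the body angle trace from tracked H, M, T points.

    Applies, per frame,

        theta = 360 - (180/pi) * arccos( (H-M).(T-M) / (|H-M| |T-M|) )

    with the arccos argument clamped to [-1, 1] to absorb floating-point
    overshoot on collinear configurations.  The signed version carries
    the bend direction from the sign of the planar cross product
    (H-M) x (T-M): positive (left) when the tail tip lies to the
    larva's left of the trunk axis.

    Raises
    ------
    ValueError
        If any frame has H == M or T == M (angle undefined); the error
        names the first offending frame index.
    """
    c = track.coords
    hx, hy = c[:, 0] - c[:, 2], c[:, 1] - c[:, 3]
    tx, ty = c[:, 4] - c[:, 2], c[:, 5] - c[:, 3]
    nh = np.hypot(hx, hy)
    nt = np.hypot(tx, ty)
    bad = (nh == 0) | (nt == 0)
    if np.any(bad):
        frame = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"degenerate frame {frame}: H or T coincides with M, angle undefined"
        )
    cos_arg = np.clip((hx * tx + hy * ty) / (nh * nt), -1.0, 1.0)
    theta = 360.0 - np.degrees(np.arccos(cos_arg))
    cross = hx * ty - hy * tx
    sign = np.where(cross > 0, 1.0, np.where(cross < 0, -1.0, 0.0))
    signed = sign * (theta - REST_ANGLE_DEG)
    return AngleTrace(frame_rate=track.frame_rate, theta=theta, signed_theta=signed)


def assign_direction(
    track: PointTrack, trace: AngleTrace, rest_band: float = 5.0
) -> AngleTrace:
    """Return ``trace`` with direction made constant within each excursion.

    The per-frame cross-product sign can waver for near-collinear
    frames; here every contiguous run of frames outside the rest band
    is assigned the direction observed at its peak angle, and frames
    inside the band keep a direction of none (sign 0, so signed_theta
    reflects only the jitter magnitude with its raw sign).
    """
    base = trace if trace.signed_theta is not None else compute_body_angle(track)
    theta = base.theta
    signed = np.array(base.signed_theta, dtype=float, copy=True)
    outside = theta > REST_ANGLE_DEG + rest_band
    for start, stop in _runs(outside):
        seg = slice(start, stop)
        peak = start + int(np.argmax(theta[seg]))
        s = np.sign(signed[peak]) or 1.0
        signed[seg] = s * (theta[seg] - REST_ANGLE_DEG)
    return replace(base, signed_theta=signed)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs in a boolean mask."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_events(
    trace: AngleTrace,
    rest_band: float = 5.0,
    min_duration: int = 3,
) -> list[MovementEvent]:
    """Detect wag / LAM / extreme events in a body-angle trace.

    An event spans from the first frame with theta above
    ``180 + rest_band`` degrees to the first frame back inside the band,
    bending to a single side throughout.  Excursions that reverse
    direction without returning to rest are split at signed-angle zero
    crossings and the pieces flagged ``split``.  Events shorter than
    ``min_duration`` frames are discarded.  If the trace ends mid-
    excursion the final event is flagged ``truncated`` (its offset is
    the end of the trace) and is later excluded from duration
    statistics.

    Parameters
    ----------
    trace : AngleTrace
        Must carry ``signed_theta`` (from :func:`compute_body_angle`).
    rest_band : float
        Half-width of the rest band about 180 deg, in degrees.  The
        exit and re-entry thresholds are identical.
    min_duration : int
        Minimum event length in frames.
    """
    if trace.signed_theta is None:
        raise ValueError("trace must carry signed_theta; use compute_body_angle")
    theta = trace.theta
    if theta.size == 0:
        return []
    signed = trace.signed_theta
    fps = trace.frame_rate
    n = theta.shape[0]
    outside = theta > REST_ANGLE_DEG + rest_band

    events: list[MovementEvent] = []
    for start, stop in _runs(outside):
        run_truncated = stop == n  # never re-entered the rest band
        # split the run where the bend direction reverses
        seg_sign = np.where(signed[start:stop] >= 0, 1, -1)
        breaks = np.flatnonzero(np.diff(seg_sign) != 0) + 1 + start
        bounds = [start, *breaks.tolist(), stop]
        was_split = len(bounds) > 2
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < min_duration:
                continue
            seg = slice(a, b)
            peak = float(np.max(theta[seg]))
            peak_idx = a + int(np.argmax(theta[seg]))
            direction = "left" if signed[peak_idx] >= 0 else "right"
            truncated = run_truncated and b == stop
            events.append(
                MovementEvent(
                    onset=a / fps,
                    offset=b / fps,
                    peak_angle=peak,
                    direction=direction,
                    event_class=classify_peak(peak),
                    truncated=truncated,
                    split=was_split,
                )
            )
    return events


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(x))
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return mean, sem


def _make_ecdf(values: np.ndarray):
    """Right-continuous ECDF F(x) = mean(values <= x)."""
    sorted_vals = np.sort(values)

    def ecdf(x):
        if sorted_vals.size == 0:
            return np.full_like(np.asarray(x, dtype=float), np.nan)
        out = np.searchsorted(sorted_vals, np.asarray(x, dtype=float), side="right")
        out = out / sorted_vals.size
        return float(out) if np.isscalar(x) else out

    return ecdf


def summarize(
    events: Sequence[MovementEvent], window: float = 20.0
) -> KinematicsSummary:
    """Summarize detected events over a half-open window [0, window) s.

    Counts events by class (events whose onset falls in the window),
    collects rest-to-rest durations of non-truncated events, and builds
    the right-continuous ECDF of LAM durations used to compare duration
    distributions across treatment groups.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    in_win = [e for e in events if 0.0 <= e.onset < window]
    if any(in_win[i].onset > in_win[i + 1].onset for i in range(len(in_win) - 1)):
        raise ValueError("events must be time-ordered")
    lams = [e for e in in_win if e.event_class == "lam"]
    wags = [e for e in in_win if e.event_class == "wag"]
    extremes = [e for e in in_win if e.event_class == "extreme"]
    lam_dur = np.array([e.duration for e in lams if not e.truncated])
    wag_dur = np.array([e.duration for e in wags if not e.truncated])
    lam_mean, lam_sem = _mean_sem(lam_dur)
    wag_mean, wag_sem = _mean_sem(wag_dur)
    return KinematicsSummary(
        window=window,
        lam_count=len(lams),
        wag_count=len(wags),
        extreme_count=len(extremes),
        lam_durations=lam_dur,
        wag_durations=wag_dur,
        lam_duration_mean=lam_mean,
        lam_duration_sem=lam_sem,
        wag_duration_mean=wag_mean,
        wag_duration_sem=wag_sem,
        ecdf=_make_ecdf(lam_dur),
    )
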