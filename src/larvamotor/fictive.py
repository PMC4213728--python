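"""Fictive swim motor pattern analysis.

Multiunit motor-neuron activity recorded extracellularly from a
paralyzed larva arrives as rapid spikes separated by quiescent periods.
Spike times are sorted into a two-level hierarchy purely from
inter-spike intervals (ISIs):

* consecutive spikes with ISI < 10 ms belong to the same **burst**
  (one burst corresponds to one unilateral tail bend);
* bursts separated by ISIs of 10–100 ms belong to the same **episode**
  (one episode corresponds to one swim bout);
* an ISI > 100 ms starts a new episode.

Boundary ISIs are resolved as: same burst iff ISI < 10 ms, same episode
iff ISI <= 100 ms (both thresholds configurable).  From the
segmentation four motor-pattern metrics are derived: spikes per burst,
burst duration (first to last spike of the burst), burst period
(difference between successive burst start times, computed only within
an episode) and bursts per episode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "VoltageTrace",
    "SpikeSegmentation",
    "BurstMetrics",
    "detect_spikes",
    "segment",
    "metrics",
    "INTRA_BURST_ISI_MAX_MS",
    "EPISODE_ISI_MAX_MS",
]

INTRA_BURST_ISI_MAX_MS = 10.0
EPISODE_ISI_MAX_MS = 100.0


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled extracellular voltage recording (mV)."""

    sample_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class SpikeSegmentation:
    """Spike times organized into bursts nested within episodes.

    ``bursts`` holds half-open spike-index ranges ``[first, last)``;
    ``episodes`` holds half-open burst-index ranges.  Every spike
    belongs to exactly one burst and every burst to exactly one
    episode.
    """

    spike_times: np.ndarray  # seconds, strictly increasing
    bursts: tuple[tuple[int, int], ...]
    episodes: tuple[tuple[int, int], ...]
    intra_burst_isi_max: float = INTRA_BURST_ISI_MAX_MS  # ms
    episode_isi_max: float = EPISODE_ISI_MAX_MS  # ms

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("spike_times must be strictly increasing")
        n_spikes = times.size
        covered = 0
        for a, b in self.bursts:
            if not (0 <= a < b <= n_spikes) or a != covered:
                raise ValueError("bursts must tile spike indices contiguously")
            covered = b
        if covered != n_spikes:
            raise ValueError("bursts must cover every spike")
        covered = 0
        for a, b in self.episodes:
            if not (0 <= a < b <= len(self.bursts)) or a != covered:
                raise ValueError("episodes must tile burst indices contiguously")
            covered = b
        if covered != len(self.bursts):
            raise ValueError("episodes must cover every burst")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    def burst_spike_times(self, burst: int) -> np.ndarray:
        a, b = self.bursts[burst]
        return self.spike_times[a:b]


@dataclass(frozen=True)
class BurstMetrics:
    """The four motor-pattern metrics plus per-recording mean and s.e.m.

    ``burst_periods`` is empty when no episode contains two bursts (the
    period is undefined, not zero, for a lone burst).
    """

    spikes_per_burst: np.ndarray
    burst_durations: np.ndarray  # seconds
    burst_periods: np.ndarray  # seconds, within-episode only
    bursts_per_episode: np.ndarray

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean and s.e.m. of each metric; NaN when undefined."""
        out = {}
        for name in (
            "spikes_per_burst",
            "burst_durations",
            "burst_periods",
            "bursts_per_episode",
        ):
            x = getattr(self, name)
            if x.size == 0:
                out[name] = (float("nan"), float("nan"))
            else:
                sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
                out[name] = (float(np.mean(x)), sem)
        return out


def detect_spikes(
    trace: VoltageTrace,
    threshold: float | None = None,
    refractory: float = 1.0,
) -> np.ndarray:
    """Detect spike times as rising-edge threshold crossings.

    One spike is reported per rising edge (sample crossing from below
    to at-or-above threshold), with successive spikes separated by at
    least ``refractory`` milliseconds.  When ``threshold`` is None an
    automatic threshold is derived from a robust noise estimate:

        threshold = median + 5 * MAD / 0.6745

    where MAD is the median absolute deviation of the trace (MAD/0.6745
    estimates the noise standard deviation for Gaussian noise).

    Returns spike times in seconds.

    Raises
    ------
    ValueError
        With an all-constant trace under the automatic threshold there
        is no spike activity detectable.
    """
    x = trace.samples
    if threshold is None:
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        if mad == 0.0 and np.ptp(x) == 0.0:
            raise ValueError("no spike activity detectable: trace is constant")
        threshold = med + 5.0 * mad / 0.6745
    above = x >= threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        rising = np.concatenate(([0], rising))
    if rising.size == 0:
        return np.empty(0)
    refractory_s = refractory / 1000.0
    times = rising / trace.sample_rate
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.asarray(kept)


def segment(
    spike_times: Sequence[float] | np.ndarray,
    intra_burst_isi_max: float = INTRA_BURST_ISI_MAX_MS,
    episode_isi_max: float = EPISODE_ISI_MAX_MS,
) -> SpikeSegmentation:
    """Sort spike times (seconds) into bursts nested within episodes.

    Single left-to-right pass over the ISIs (milliseconds):
    ISI < ``intra_burst_isi_max`` continues the current burst;
    ``intra_burst_isi_max`` <= ISI <= ``episode_isi_max`` starts a new
    burst within the same episode; ISI > ``episode_isi_max`` starts a
    new burst in a new episode.  A lone spike is a burst of one with
    duration zero.

    Raises
    ------
    ValueError
        If spike times are not strictly increasing, or the thresholds
        are not ordered 0 < intra < episode.
    """
    if not 0 < intra_burst_isi_max < episode_isi_max:
        raise ValueError("need 0 < intra_burst_isi_max < episode_isi_max")
    times = np.asarray(spike_times, dtype=float)
    if times.ndim != 1:
        raise ValueError("spike_times must be one-dimensional")
    if times.size == 0:
        return SpikeSegmentation(
            times, (), (), intra_burst_isi_max, episode_isi_max
        )
    if np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise ValueError(f"spike_times not strictly increasing at index {bad}")

    isi_ms = np.diff(times) * 1000.0
    bursts: list[tuple[int, int]] = []
    episodes: list[tuple[int, int]] = []
    burst_start = 0
    episode_start_burst = 0
    for i, isi in enumerate(isi_ms):
        if isi < intra_burst_isi_max:
            continue
        bursts.append((burst_start, i + 1))
        burst_start = i + 1
        if isi > episode_isi_max:
            episodes.append((episode_start_burst, len(bursts)))
            episode_start_burst = len(bursts)
    bursts.append((burst_start, times.size))
    episodes.append((episode_start_burst, len(bursts)))
    return SpikeSegmentation(
        times, tuple(bursts), tuple(episodes), intra_burst_isi_max, episode_isi_max
    )


def metrics(seg: SpikeSegmentation) -> BurstMetrics:
    """Compute the four motor-pattern metrics from a segmentation.

    Burst duration is last minus first spike time of the burst (zero
    for a single-spike burst, which still counts toward spikes-per-
    burst statistics).  Burst period is the difference between
    successive burst start times and is computed only between bursts of
    the same episode; computing it across the >100 ms episode gaps
    would conflate quiescence with swim cycle period.
    """
    times = seg.spike_times
    spb = np.array([b - a for a, b in seg.bursts], dtype=float)
    durations = np.array([times[b - 1] - times[a] for a, b in seg.bursts])
    starts = np.array([times[a] for a, _ in seg.bursts])
    periods: list[float] = []
    for ea, eb in seg.episodes:
        periods.extend(np.diff(starts[ea:eb]).tolist())
    bpe = np.array([eb - ea for ea, eb in seg.episodes], dtype=float)
    return BurstMetrics(
        spikes_per_burst=spb,
        burst_durations=durations,
        burst_periods=np.asarray(periods),
        bursts_per_episode=bpe,
    )
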