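"""Synthetic data with the structure of Mn-exposure phenotyping studies.

Generates the four kinds of input the analysis modules consume, with no
external data required:

* 20-s, 300-fps three-point tail tracks of a head-embedded larva,
  resting near 180 deg with clustered low-amplitude wags and sparse
  large-angle movements (LAMs) whose rate, duration and laterality
  depend on the phenotype preset (control / Mn-treated / recovered);
* 2-min extracellular voltage traces with episodic, rhythmically
  bursting motor-neuron spikes obeying the 10 / 100 ms ISI bands;
* endpoint dose-survival tables drawn from a log-logistic
  dose-response (binomial counts per dose);
* per-batch binomial phenotype-score tables (sideways floating, curved
  spine, spontaneous and on-tap circling).

Every generator also returns its ground truth (event list, spike
segmentation, underlying dose-response) so that the detection and
estimation modules can be tested closed-loop.  Given identical
parameters and seed the outputs are bit-for-bit reproducible.

Movement events are scheduled as half-sine angle excursions, which
pass smoothly through the rest band so the rest-to-rest duration rule
is well-posed; event counts are Poisson with uniform placement and
internal rescheduling of overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .fictive import SpikeSegmentation, VoltageTrace
from .group_stats import ContingencyTable, DoseSurvival
from .kinematics import MovementEvent, PointTrack, classify_peak

__all__ = [
    "TrajectoryParams",
    "SpikeTrainParams",
    "SurvivalParams",
    "BehaviorCountParams",
    "SimulatedTrajectory",
    "SimulatedSpikeTrain",
    "simulate_trajectory",
    "simulate_spike_train",
    "simulate_survival",
    "expected_survival",
    "simulate_behavior_counts",
    "trajectory_preset",
    "spike_train_preset",
    "behavior_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("control", "mn", "recovered")

_PLACEMENT_ATTEMPTS = 2000


# ---------------------------------------------------------------------------
# parameter sets


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of one simulated tail-kinematics recording.

    Defaults are the control phenotype: 13.2 LAMs of 57 ms mean
    duration in a 20-s window with alternating laterality, plus
    clustered wags of ~40 ms.  Peak-angle ranges must respect the event
    classes: wags in (180, 200) deg, LAMs in (200, 270) deg.
    """

    frame_rate: float = 300.0  # frames / s
    duration: float = 20.0  # s
    rest_angle: float = 180.0  # deg
    rest_jitter_sd: float = 0.8  # deg
    wag_cluster_rate: float = 0.6  # clusters / s
    wags_per_cluster: float = 4.0  # mean of 1 + Poisson(mean - 1)
    wag_peak_range: tuple[float, float] = (187.0, 196.0)  # deg
    wag_duration_mean: float = 39.8  # ms
    wag_duration_sd: float = 4.0  # ms
    lam_rate: float = 13.2  # events per recording window
    lam_duration_mean: float = 57.0  # ms
    lam_duration_sd: float = 15.0  # ms
    lam_peak_range: tuple[float, float] = (210.0, 260.0)  # deg
    laterality_mode: str = "alternating"  # alternating | unilateral | mixed
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.frame_rate > 0 and self.duration > 0):
            raise ValueError("frame_rate and duration must be > 0")
        if self.rest_angle != 180.0:
            raise ValueError("rest angle is 180 deg by definition of the body angle")
        wl, wh = self.wag_peak_range
        if not (180.0 < wl < wh < 200.0):
            raise ValueError("wag_peak_range must lie strictly inside (180, 200) deg")
        ll, lh = self.lam_peak_range
        if not (200.0 < ll < lh < 270.0):
            raise ValueError("lam_peak_range must lie strictly inside (200, 270) deg")
        if min(self.wag_duration_mean, self.lam_duration_mean) <= 0:
            raise ValueError("event durations must be > 0")
        if self.rest_jitter_sd < 0 or min(self.wag_duration_sd, self.lam_duration_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.laterality_mode not in ("alternating", "unilateral", "mixed"):
            raise ValueError(f"unknown laterality_mode {self.laterality_mode!r}")
        if self.lam_rate < 0 or self.wag_cluster_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.wags_per_cluster < 1:
            raise ValueError("wags_per_cluster must be >= 1")


@dataclass(frozen=True)
class SpikeTrainParams:
    """Parameters of one simulated 2-min fictive motor-pattern recording.

    The rhythm defaults (burst period ~35 ms, 4 spikes per ~10 ms
    burst, ~5 episodes per minute) describe a control-like swim motor
    pattern; all are overridable.  The generated structure respects the
    ISI bands of the segmentation rules: intra-burst ISIs < 10 ms,
    inter-burst gaps within an episode in (10, 100) ms, inter-episode
    gaps > 100 ms.
    """

    recording_duration: float = 120.0  # s
    episode_rate: float = 5.0  # episodes / min
    bursts_per_episode: float = 4.0  # mean of 1 + Poisson(mean - 1)
    burst_period_mean: float = 35.0  # ms
    burst_period_sd: float = 3.0  # ms
    burst_duration_mean: float = 10.0  # ms
    burst_duration_sd: float = 1.5  # ms
    spikes_per_burst: float = 4.0  # mean of 1 + Poisson(mean - 1)
    spike_amplitude: float = 1.0  # mV
    noise_sd: float = 0.05  # mV
    sample_rate: float = 10_000.0  # Hz
    fixed_counts: bool = False  # use rounded means instead of Poisson counts
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.recording_duration > 0 and self.sample_rate > 0):
            raise ValueError("recording_duration and sample_rate must be > 0")
        if self.episode_rate < 0:
            raise ValueError("episode_rate must be >= 0")
        if self.burst_duration_mean >= self.burst_period_mean:
            raise ValueError("burst_duration_mean must be < burst_period_mean")
        gap = self.burst_period_mean - self.burst_duration_mean
        if not 10.0 < gap < 100.0:
            raise ValueError(
                "mean inter-burst gap (period - duration) must lie in (10, 100) ms"
            )
        if self.spikes_per_burst < 1 or self.bursts_per_episode < 1:
            raise ValueError("count means must be >= 1")
        if self.spikes_per_burst > 1:
            isi = self.burst_duration_mean / (self.spikes_per_burst - 1)
            if isi >= 10.0:
                raise ValueError("mean intra-burst ISI must be < 10 ms")
        if self.noise_sd < 0 or self.spike_amplitude <= 0:
            raise ValueError("invalid amplitude / noise parameters")


@dataclass(frozen=True)
class SurvivalParams:
    """Log-logistic dose-survival with LC50 = 2 mM by default.

    The default dose ladder spans the 0.2-10 mM range of an
    Mn-exposure standardization series, with 20 larvae per dose.
    """

    lc50: float = 2.0  # mM
    hill_slope: float = 2.0
    doses: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0, 4.0, 10.0)  # mM
    n_per_dose: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lc50 <= 0 or self.hill_slope <= 0:
            raise ValueError("lc50 and hill_slope must be > 0")
        if len(self.doses) < 2 or any(d < 0 for d in self.doses):
            raise ValueError("need >= 2 non-negative doses")
        if self.n_per_dose <= 0:
            raise ValueError("n_per_dose must be > 0")


#: phenotype labels scored in behavior observations
PHENOTYPES = (
    "sideways_floating",
    "curved_spine",
    "circling_spontaneous",
    "circling_on_tap",
)

_DEFAULT_PHENOTYPE_P: dict[str, dict[str, float]] = {
    "control": {
        "sideways_floating": 0.0,
        "curved_spine": 0.0,
        "circling_spontaneous": 0.0,
        "circling_on_tap": 0.0,
    },
    "mn": {
        "sideways_floating": 0.98,
        "curved_spine": 0.65,
        "circling_spontaneous": 0.90,
        "circling_on_tap": 0.90,
    },
    "recovered": {
        "sideways_floating": 0.12,
        "curved_spine": 0.27,
        "circling_spontaneous": 0.02,
        "circling_on_tap": 0.50,
    },
}


@dataclass(frozen=True)
class BehaviorCountParams:
    """Per-batch binomial phenotype scoring (three batches of 20 larvae).

    Default probabilities follow the reported proportions where printed
    (sideways floating 98% Mn vs 12% recovered vs 0% control; curved
    spine 65% vs 27% vs 0%); circling probabilities are anchored to the
    qualitative pattern that spontaneous circling recovers completely
    and on-tap circling only partially.
    """

    conditions: tuple[str, ...] = PRESET_NAMES
    batches: int = 3
    larvae_per_batch: int = 20
    phenotype_probabilities: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(p) for c, p in _DEFAULT_PHENOTYPE_P.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batches <= 0 or self.larvae_per_batch <= 0:
            raise ValueError("batches and larvae_per_batch must be > 0")
        for cond in self.conditions:
            if cond not in self.phenotype_probabilities:
                raise ValueError(f"no phenotype probabilities for condition {cond!r}")
            for pheno, p in self.phenotype_probabilities[cond].items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability out of [0, 1] for {cond}/{pheno}")


# ---------------------------------------------------------------------------
# phenotype presets


def trajectory_preset(name: str, seed: int = 0) -> TrajectoryParams:
    """Tail-kinematics parameters for a named phenotype.

    control: 13.2 LAMs / 20 s of 57 ms, alternating laterality.
    mn: 2 LAMs / 20 s of 163.4 ms, unilateral, sparser wag clusters.
    recovered: 15.3 LAMs / 20 s of 54.7 ms, alternating.
    """
    base = TrajectoryParams(seed=seed)
    if name == "control":
        return base
    if name == "mn":
        return replace(
            base,
            lam_rate=2.0,
            lam_duration_mean=163.4,
            lam_duration_sd=40.0,
            laterality_mode="unilateral",
            wag_duration_mean=36.9,
            wag_cluster_rate=0.3,
        )
    if name == "recovered":
        return replace(
            base,
            lam_rate=15.3,
            lam_duration_mean=54.7,
            lam_duration_sd=14.0,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def spike_train_preset(name: str, seed: int = 0) -> SpikeTrainParams:
    """Fictive motor-pattern parameters for a named phenotype.

    Control-like rhythm by default; the Mn-like preset has more spikes
    per longer burst and a shorter cycle period, and the recovered-like
    preset restores the control period while bursts stay long — the
    orderings observed across treatment groups.
    """
    base = SpikeTrainParams(seed=seed)
    if name == "control":
        return base
    if name == "mn":
        return replace(
            base,
            spikes_per_burst=8.0,
            burst_duration_mean=19.0,
            burst_duration_sd=2.5,
            burst_period_mean=32.0,
            burst_period_sd=2.5,
        )
    if name == "recovered":
        return replace(
            base,
            spikes_per_burst=7.0,
            burst_duration_mean=17.0,
            burst_duration_sd=2.5,
            burst_period_mean=35.0,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def behavior_preset(seed: int = 0) -> BehaviorCountParams:
    return BehaviorCountParams(seed=seed)


# ---------------------------------------------------------------------------
# trajectory generator


@dataclass(frozen=True)
class SimulatedTrajectory:
    """A simulated point track plus its generating ground truth."""

    track: PointTrack
    events: tuple[MovementEvent, ...]  # scheduled ground truth, time-ordered
    signed_theta: np.ndarray  # ground-truth signed angle trace, degrees
    params: TrajectoryParams

    @property
    def theta(self) -> np.ndarray:
        return 180.0 + np.abs(self.signed_theta)


def _place_blocks(
    rng: np.random.Generator,
    block_durations: list[float],
    window: float,
    margin: float,
) -> list[float]:
    """Uniformly place non-overlapping blocks, rescheduling collisions.

    Returns start times in input order.  Raises if the window cannot
    fit the requested blocks after repeated rescheduling.
    """
    if sum(block_durations) + margin * len(block_durations) > window:
        raise ValueError("window cannot fit requested event count")
    placed: list[tuple[float, float]] = []
    starts = []
    for dur in block_durations:
        ok = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            s = rng.uniform(0.0, window - dur)
            if all(s + dur + margin <= a or b + margin <= s for a, b in placed):
                placed.append((s, s + dur))
                starts.append(s)
                ok = True
                break
        if not ok:
            raise ValueError("window cannot fit requested event count")
    return starts


def _directions(rng: np.random.Generator, n: int, mode: str) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if mode == "unilateral":
        return np.full(n, rng.choice([-1.0, 1.0]))
    if mode == "mixed":
        return rng.choice([-1.0, 1.0], size=n)
    first = rng.choice([-1.0, 1.0])
    return first * (-1.0) ** np.arange(n)


def simulate_trajectory(params: TrajectoryParams) -> SimulatedTrajectory:
    """Simulate a three-point tail track with known movement events.

    The signed body angle is built from rest jitter plus half-sine
    excursions for every scheduled wag and LAM; the head H = (0, 1) and
    mid-trunk M = (0, 0) stay fixed (the head is embedded) and the tail
    point is reconstructed at unit distance from M at the generated
    angle — the angle equation normalizes, so the distance is
    immaterial.  LAM counts are Poisson with the requested rate per
    window; wags arrive in Poisson-count clusters.  Returns the track
    together with the scheduled ground-truth event list and angle
    trace.
    """
    rng = np.random.default_rng(params.seed)
    fps = params.frame_rate
    n_frames = int(round(params.duration * fps))
    min_dur_s = 5.0 / fps  # keep every scheduled event at least 5 frames

    # --- draw LAMs ------------------------------------------------------
    n_lam = int(rng.poisson(params.lam_rate))
    lam_durs = np.maximum(
        rng.normal(params.lam_duration_mean, params.lam_duration_sd, n_lam) / 1000.0,
        min_dur_s,
    )
    lam_peaks = rng.uniform(*params.lam_peak_range, n_lam)

    # --- draw wag clusters ---------------------------------------------
    n_clusters = int(rng.poisson(params.wag_cluster_rate * params.duration))
    wag_gap = 0.010  # s between wags of a cluster
    clusters: list[list[tuple[float, float]]] = []  # (duration_s, peak)
    for _ in range(n_clusters):
        k = 1 + int(rng.poisson(params.wags_per_cluster - 1.0))
        durs = np.maximum(
            rng.normal(params.wag_duration_mean, params.wag_duration_sd, k) / 1000.0,
            min_dur_s,
        )
        peaks = rng.uniform(*params.wag_peak_range, k)
        clusters.append(list(zip(durs.tolist(), peaks.tolist())))

    # --- place LAMs and clusters without overlap -----------------------
    block_durs = [float(d) for d in lam_durs] + [
        sum(d for d, _ in cl) + wag_gap * (len(cl) - 1) for cl in clusters
    ]
    margin = 0.020  # s of rest guaranteed between events
    starts = _place_blocks(rng, block_durs, params.duration, margin)
    lam_starts = starts[:n_lam]
    cluster_starts = starts[n_lam:]

    lam_dirs = _directions(rng, n_lam, params.laterality_mode)
    # re-apply laterality in temporal order so "alternating" alternates in time
    order = np.argsort(lam_starts) if n_lam else np.empty(0, dtype=int)
    events: list[MovementEvent] = []
    for rank, idx in enumerate(order):
        d = lam_dirs[rank]
        events.append(
            MovementEvent(
                onset=float(lam_starts[idx]),
                offset=float(lam_starts[idx] + lam_durs[idx]),
                peak_angle=float(lam_peaks[idx]),
                direction="left" if d > 0 else "right",
                event_class=classify_peak(float(lam_peaks[idx])),
            )
        )
    for s, cl in zip(cluster_starts, clusters):
        t = s
        d = rng.choice([-1.0, 1.0])
        for dur, peak in cl:
            events.append(
                MovementEvent(
                    onset=float(t),
                    offset=float(t + dur),
                    peak_angle=float(peak),
                    direction="left" if d > 0 else "right",
                    event_class=classify_peak(peak),
                )
            )
            t += dur + wag_gap
            d = -d
    events.sort(key=lambda e: e.onset)

    # --- synthesize the signed angle trace ------------------------------
    signed = rng.normal(0.0, params.rest_jitter_sd, n_frames)
    times = np.arange(n_frames) / fps
    for e in events:
        sel = (times >= e.onset) & (times < e.offset)
        phase = (times[sel] - e.onset) / e.duration
        amp = e.peak_angle - 180.0
        sgn = 1.0 if e.direction == "left" else -1.0
        signed[sel] = sgn * amp * np.sin(np.pi * phase)

    # --- reconstruct the three tracked points ---------------------------
    psi = np.radians(signed)
    coords = np.empty((n_frames, 6))
    coords[:, 0] = 0.0  # Hx
    coords[:, 1] = 1.0  # Hy
    coords[:, 2] = 0.0  # Mx
    coords[:, 3] = 0.0  # My
    coords[:, 4] = -np.sin(psi)  # Tx (left bend => tail to the larva's left)
    coords[:, 5] = -np.cos(psi)  # Ty
    track = PointTrack(frame_rate=fps, coords=coords)
    return SimulatedTrajectory(track, tuple(events), signed, params)


# ---------------------------------------------------------------------------
# spike-train generator


@dataclass(frozen=True)
class SimulatedSpikeTrain:
    """Voltage trace, spike times and ground-truth segmentation."""

    trace: VoltageTrace
    spike_times: np.ndarray  # s
    truth: SpikeSegmentation
    params: SpikeTrainParams


def _count(rng: np.random.Generator, mean: float, fixed: bool) -> int:
    if fixed:
        return max(1, int(round(mean)))
    return 1 + int(rng.poisson(mean - 1.0))


def simulate_spike_train(params: SpikeTrainParams) -> SimulatedSpikeTrain:
    """Simulate an episodic bursting spike train and its voltage trace.

    Episodes are placed uniformly with inter-episode gaps well above
    100 ms; bursts within an episode follow the cycle-period law with
    inter-burst gaps clipped into (10, 100) ms; spikes within a burst
    are evenly spaced across the burst duration, keeping intra-burst
    ISIs below 10 ms.  The voltage trace is Gaussian baseline noise
    plus a stereotyped exponential-decay waveform (1 ms) at each spike
    time.  The returned ground-truth segmentation is built from the
    schedule itself.
    """
    rng = np.random.default_rng(params.seed)
    n_ep_mean = params.episode_rate * params.recording_duration / 60.0
    if params.fixed_counts:
        n_ep = int(round(n_ep_mean))
    else:
        n_ep = int(rng.poisson(n_ep_mean))

    episodes_spikes: list[list[np.ndarray]] = []  # per episode, per burst
    episode_spans: list[float] = []
    for _ in range(n_ep):
        nb = _count(rng, params.bursts_per_episode, params.fixed_counts)
        bursts: list[np.ndarray] = []
        t = 0.0
        prev_dur = 0.0
        for b in range(nb):
            k = _count(rng, params.spikes_per_burst, params.fixed_counts)
            if k == 1:
                dur = 0.0
            else:
                dur = rng.normal(params.burst_duration_mean, params.burst_duration_sd)
                dur = float(np.clip(dur, 1.0, (k - 1) * 9.5)) / 1000.0
            if b > 0:
                period = rng.normal(params.burst_period_mean, params.burst_period_sd)
                gap = float(np.clip(period / 1000.0 - prev_dur, 0.0105, 0.0990))
                t += prev_dur + gap
            bursts.append(t + np.linspace(0.0, dur, k))
            prev_dur = dur
        episodes_spikes.append(bursts)
        episode_spans.append(t + prev_dur)

    ep_starts = _place_blocks(
        rng, episode_spans, params.recording_duration, margin=0.150
    )
    order = np.argsort(ep_starts)

    spike_times: list[float] = []
    bursts_idx: list[tuple[int, int]] = []
    episodes_idx: list[tuple[int, int]] = []
    for ep in order:
        ep_burst_start = len(bursts_idx)
        for burst in episodes_spikes[ep]:
            a = len(spike_times)
            spike_times.extend((ep_starts[ep] + burst).tolist())
            bursts_idx.append((a, len(spike_times)))
        episodes_idx.append((ep_burst_start, len(bursts_idx)))

    times = np.asarray(spike_times)
    truth = SpikeSegmentation(times, tuple(bursts_idx), tuple(episodes_idx))

    # --- voltage synthesis ---------------------------------------------
    sr = params.sample_rate
    n_samples = int(round(params.recording_duration * sr))
    samples = rng.normal(0.0, params.noise_sd, n_samples)
    wf_len = max(2, int(round(0.001 * sr)))  # 1 ms stereotyped waveform
    waveform = params.spike_amplitude * np.exp(
        -np.arange(wf_len) / (0.2e-3 * sr)
    )
    for t in times:
        i = int(round(t * sr))
        j = min(i + wf_len, n_samples)
        if i < n_samples:
            samples[i:j] += waveform[: j - i]
    trace = VoltageTrace(sample_rate=sr, samples=samples)
    return SimulatedSpikeTrain(trace, times, truth, params)


# ---------------------------------------------------------------------------
# survival and behavior-count generators


def _logistic_survival(dose: np.ndarray, lc50: float, hill: float) -> np.ndarray:
    """p(d) = 1 / (1 + (d / LC50)^h); p(0) = 1, p(LC50) = 1/2."""
    p = np.ones_like(dose, dtype=float)
    pos = dose > 0
    p[pos] = 1.0 / (1.0 + (dose[pos] / lc50) ** hill)
    return p


def expected_survival(params: SurvivalParams) -> DoseSurvival:
    """Noise-free dose-survival table (the n -> infinity limit)."""
    dose = np.asarray(params.doses, dtype=float)
    return DoseSurvival(dose, _logistic_survival(dose, params.lc50, params.hill_slope))


def simulate_survival(params: SurvivalParams) -> DoseSurvival:
    """Draw binomial per-dose surviving counts from the dose-response.

    Raises
    ------
    ValueError
        If no dose pair brackets 50% survival in expectation (the LC50
        would be unidentifiable from the design).
    """
    dose = np.asarray(params.doses, dtype=float)
    p = _logistic_survival(dose, params.lc50, params.hill_slope)
    if not (p.max() >= 0.5 >= p.min()):
        raise ValueError("no dose pair brackets 50% survival in expectation")
    rng = np.random.default_rng(params.seed)
    surviving = rng.binomial(params.n_per_dose, p)
    n = np.full(dose.size, params.n_per_dose)
    return DoseSurvival(dose, surviving / params.n_per_dose, n)


def simulate_behavior_counts(
    params: BehaviorCountParams,
) -> dict[str, ContingencyTable]:
    """Draw per-batch binomial phenotype counts for every condition.

    Returns one batch-resolved :class:`ContingencyTable` per phenotype
    (rows = conditions, columns = batches).
    """
    rng = np.random.default_rng(params.seed)
    phenotypes = list(params.phenotype_probabilities[params.conditions[0]].keys())
    out: dict[str, ContingencyTable] = {}
    totals = np.full((len(params.conditions), params.batches), params.larvae_per_batch)
    for pheno in phenotypes:
        affected = np.empty((len(params.conditions), params.batches), dtype=int)
        for i, cond in enumerate(params.conditions):
            p = params.phenotype_probabilities[cond][pheno]
            affected[i] = rng.binomial(params.larvae_per_batch, p, params.batches)
        out[pheno] = ContingencyTable(params.conditions, affected, totals)
    return out
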