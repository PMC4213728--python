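"""Readers and writers for the plain-text formats used by the pipeline.

All inputs and outputs are human-auditable comma-separated tables or
key-value text: point tracks (``frame,Hx,Hy,Mx,My,Tx,Ty``), spike times
(one time in seconds per line), voltage traces (``time,voltage``),
dose-survival and phenotype-count tables, event tables and structured
reports.  Malformed rows are reported with their line number.  Numeric
formatting is fixed (angles to 0.01 deg, times to 0.01 ms, p-values to
three significant figures) so that identical results produce identical
bytes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fictive import BurstMetrics, VoltageTrace
from .group_stats import ContingencyTable, DoseSurvival
from .kinematics import KinematicsSummary, MovementEvent, PointTrack

__all__ = [
    "read_track",
    "write_track",
    "read_spike_times",
    "write_spike_times",
    "read_trace",
    "write_trace",
    "read_survival",
    "write_survival",
    "read_counts",
    "write_counts",
    "write_events",
    "read_events",
    "write_key_value",
    "read_key_value",
    "format_p",
    "kinematics_report",
    "metrics_report",
]

TRACK_HEADER = ["frame", "Hx", "Hy", "Mx", "My", "Tx", "Ty"]


def format_p(p: float) -> str:
    """p-values at three significant figures."""
    if np.isnan(p):
        return "NA"
    return f"{p:.3g}"


def _read_csv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=list(columns))
    df = pd.read_csv(path)
    if list(df.columns) != list(columns):
        raise ValueError(
            f"{path}: expected header {','.join(columns)}, got {','.join(df.columns)}"
        )
    return df


def _require_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = converted
    return df


# ---------------------------------------------------------------------------
# point tracks


def write_track(path: str | Path, track: PointTrack) -> None:
    df = pd.DataFrame(track.coords, columns=TRACK_HEADER[1:])
    df.insert(0, "frame", np.arange(track.n_frames))
    df.to_csv(path, index=False, float_format="%.9g")


def read_track(path: str | Path, frame_rate: float) -> PointTrack | None:
    """Read a three-point track table; returns None for an empty file."""
    df = _read_csv(path, TRACK_HEADER)
    if df.empty:
        return None
    df = _require_numeric(df, path)
    frames = df["frame"].to_numpy()
    if np.any(np.diff(frames) <= 0):
        line = int(np.flatnonzero(np.diff(frames) <= 0)[0]) + 3
        raise ValueError(f"{path}: frame numbers not increasing at line {line}")
    return PointTrack(frame_rate=frame_rate, coords=df[TRACK_HEADER[1:]].to_numpy())


# ---------------------------------------------------------------------------
# spike times and voltage traces


def write_spike_times(path: str | Path, times: Iterable[float]) -> None:
    with open(path, "w") as fh:
        for t in times:
            fh.write(f"{t:.9g}\n")


def read_spike_times(path: str | Path) -> np.ndarray:
    times = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s:
                continue
            try:
                t = float(s)
            except ValueError:
                raise ValueError(f"{path}: non-numeric spike time at line {lineno}")
            if times and t <= times[-1]:
                raise ValueError(
                    f"{path}: spike times not strictly increasing at line {lineno}"
                )
            times.append(t)
    return np.asarray(times)


def write_trace(path: str | Path, trace: VoltageTrace) -> None:
    df = pd.DataFrame({"time": trace.times, "voltage": trace.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def read_trace(path: str | Path) -> VoltageTrace | None:
    """Read a time,voltage table; the time grid must be uniform."""
    df = _read_csv(path, ["time", "voltage"])
    if df.empty:
        return None
    df = _require_numeric(df, path)
    t = df["time"].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.flatnonzero(dt <= 0)[0]) + 3
        raise ValueError(f"{path}: time not increasing at line {line}")
    if t.size > 1 and not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: time grid is not uniform")
    rate = 1.0 / dt[0] if t.size > 1 else 1.0
    return VoltageTrace(sample_rate=rate, samples=df["voltage"].to_numpy())


# ---------------------------------------------------------------------------
# survival and behavior-count tables


def write_survival(path: str | Path, data: DoseSurvival) -> None:
    df = pd.DataFrame(
        {"dose_mM": data.dose, "surviving_fraction": data.surviving_fraction}
    )
    if data.n_total is not None:
        df["n_total"] = data.n_total
    df.to_csv(path, index=False, float_format="%.6g")


def read_survival(path: str | Path) -> DoseSurvival:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:2] != ["dose_mM", "surviving_fraction"]:
        raise ValueError(
            f"{path}: expected columns dose_mM,surviving_fraction[,n_total], got {cols}"
        )
    df = _require_numeric(df, path)
    n = df["n_total"].to_numpy().astype(int) if "n_total" in cols else None
    return DoseSurvival(
        df["dose_mM"].to_numpy(), df["surviving_fraction"].to_numpy(), n
    )


COUNTS_HEADER = ["phenotype", "condition", "batch", "affected", "total"]


def write_counts(path: str | Path, tables: Mapping[str, ContingencyTable]) -> None:
    rows = []
    for pheno in tables:
        t = tables[pheno]
        affected = t.affected if t.has_batches else t.affected[:, None]
        totals = t.totals if t.has_batches else t.totals[:, None]
        for i, cond in enumerate(t.conditions):
            for b in range(affected.shape[1]):
                rows.append((pheno, cond, b, int(affected[i, b]), int(totals[i, b])))
    pd.DataFrame(rows, columns=COUNTS_HEADER).to_csv(path, index=False)


def read_counts(path: str | Path) -> dict[str, ContingencyTable]:
    df = _read_csv(path, COUNTS_HEADER)
    out: dict[str, ContingencyTable] = {}
    for pheno, sub in df.groupby("phenotype", sort=False):
        pivot_a = sub.pivot(index="condition", columns="batch", values="affected")
        pivot_n = sub.pivot(index="condition", columns="batch", values="total")
        conds = tuple(pd.unique(sub["condition"]))
        out[str(pheno)] = ContingencyTable(
            conds,
            pivot_a.loc[list(conds)].to_numpy(),
            pivot_n.loc[list(conds)].to_numpy(),
        )
    return out


# ---------------------------------------------------------------------------
# event tables and reports

EVENTS_HEADER = [
    "onset_s",
    "offset_s",
    "duration_ms",
    "peak_deg",
    "direction",
    "class",
    "truncated",
]


def write_events(path: str | Path, events: Sequence[MovementEvent]) -> None:
    rows = [
        (
            f"{e.onset:.6f}",
            f"{e.offset:.6f}",
            f"{e.duration * 1000:.2f}",
            f"{e.peak_angle:.2f}",
            e.direction,
            e.event_class,
            int(e.truncated),
        )
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENTS_HEADER).to_csv(path, index=False)


def read_events(path: str | Path) -> list[MovementEvent]:
    df = _read_csv(path, EVENTS_HEADER)
    return [
        MovementEvent(
            onset=float(row["onset_s"]),
            offset=float(row["offset_s"]),
            peak_angle=float(row["peak_deg"]),
            direction=str(row["direction"]),
            event_class=str(row["class"]),
            truncated=bool(int(row["truncated"])),
        )
        for _, row in df.iterrows()
    ]


def write_key_value(path: str | Path, data: Mapping[str, object]) -> None:
    """Structured key-value sidecar: one ``key: value`` per line."""
    with open(path, "w") as fh:
        for key, value in data.items():
            fh.write(f"{key}: {value}\n")


def read_key_value(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.rstrip("\n")
            if not s.strip():
                continue
            if ":" not in s:
                raise ValueError(f"{path}: malformed key-value line {lineno}")
            key, value = s.split(":", 1)
            out[key.strip()] = value.strip()
    return out


def _fmt_ms(x: float) -> str:
    return "NA" if np.isnan(x) else f"{x * 1000:.2f}"


def kinematics_report(summary: KinematicsSummary) -> dict[str, object]:
    return {
        "window_s": f"{summary.window:.2f}",
        "lam_count": summary.lam_count,
        "wag_count": summary.wag_count,
        "extreme_count": summary.extreme_count,
        "lam_duration_mean_ms": _fmt_ms(summary.lam_duration_mean),
        "lam_duration_sem_ms": _fmt_ms(summary.lam_duration_sem),
        "wag_duration_mean_ms": _fmt_ms(summary.wag_duration_mean),
        "wag_duration_sem_ms": _fmt_ms(summary.wag_duration_sem),
    }


def metrics_report(m: BurstMetrics) -> dict[str, object]:
    out: dict[str, object] = {
        "n_bursts": int(m.spikes_per_burst.size),
        "n_episodes": int(m.bursts_per_episode.size),
    }
    for name, (mean, sem) in m.summary().items():
        scale = 1000.0 if name in ("burst_durations", "burst_periods") else 1.0
        unit = "_ms" if scale == 1000.0 else ""
        out[f"{name}{unit}_mean"] = "NA" if np.isnan(mean) else f"{mean * scale:.2f}"
        out[f"{name}{unit}_sem"] = "NA" if np.isnan(sem) else f"{sem * scale:.2f}"
    return out
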