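"""CSV readers/writers binding the pipeline stages together.

All artifacts are plain CSV with a single header row; timestamps are
ISO-8601 UTC with millisecond precision. Raw accelerometer files carry one
session each (timestamp, accel_x, accel_y, accel_z in g); the activity log,
VO2 trace table, MET labels, feature table and experiment outputs are
single files per stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Cohort, RecordingSession, SessionVo2, Vo2Trace

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"

RAW_COLUMNS = ("timestamp", "accel_x", "accel_y", "accel_z")


def _session_filename(session: RecordingSession) -> str:
    return f"raw_{session.participant_id}_{session.activity_name}_{session.placement}.csv"


def write_session_csv(session: RecordingSession, path: Path) -> None:
    times = session.start_time + pd.to_timedelta(
        np.arange(session.n_samples) / session.sample_rate, unit="s"
    )
    df = pd.DataFrame(
        {
            "timestamp": times.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3],
            "accel_x": session.samples[:, 0],
            "accel_y": session.samples[:, 1],
            "accel_z": session.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_session_csv(
    path: Path,
    participant_id: str,
    activity_name: str,
    placement: str,
    *,
    column_map: dict[str, str] | None = None,
    skiprows: int = 0,
    sample_rate: float | None = None,
) -> RecordingSession:
    """Read one raw accelerometer CSV into a session.

    ``column_map`` remaps source column names onto the canonical
    (timestamp, accel_x, accel_y, accel_z) dialect, and ``skiprows``
    skips device-export header lines, so ActiGraph-style raw exports can be
    consumed with a config-only change. When ``sample_rate`` is omitted it
    is inferred from the median timestamp spacing.
    """
    df = pd.read_csv(path, skiprows=skiprows)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing raw columns {missing}")
    times = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    if sample_rate is None:
        dt = np.median(np.diff(times.astype("int64"))) / 1e9
        sample_rate = 1.0 / dt
    samples = df[["accel_x", "accel_y", "accel_z"]].to_numpy(dtype=float)
    start = times.iloc[0]
    stop = start + pd.to_timedelta(len(df) / sample_rate, unit="s")
    return RecordingSession(
        participant_id=participant_id,
        activity_name=activity_name,
        placement=placement,
        sample_rate=float(sample_rate),
        samples=samples,
        start_time=start,
        stop_time=stop,
    )


def write_activity_log(log: pd.DataFrame, path: Path) -> None:
    out = log.copy()
    for col in ("start", "stop"):
        out[col] = pd.to_datetime(out[col], utc=True).dt.strftime(
            "%Y-%m-%dT%H:%M:%S.%f"
        ).str[:-3]
    out.to_csv(path, index=False)


def read_activity_log(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("start", "stop"):
        df[col] = pd.to_datetime(df[col], utc=True, format="ISO8601")
    return df


def write_vo2_csv(traces: list[SessionVo2], path: Path) -> None:
    frames = []
    for sv in traces:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": sv.participant_id,
                    "activity": sv.activity_name,
                    "t_seconds": sv.trace.breath_times,
                    "vo2_ml_min_kg": sv.trace.vo2_values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_vo2_csv(path: Path) -> list[SessionVo2]:
    df = pd.read_csv(path)
    out = []
    for (pid, activity), grp in df.groupby(["participant_id", "activity"], sort=False):
        out.append(
            SessionVo2(
                participant_id=str(pid),
                activity_name=str(activity),
                trace=Vo2Trace(
                    breath_times=grp["t_seconds"].to_numpy(),
                    vo2_values=grp["vo2_ml_min_kg"].to_numpy(),
                ),
                true_met=float("nan"),
            )
        )
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(cohort: Cohort, out_dir: Path) -> dict:
    """Write a cohort to disk (raw CSVs, activity log, VO2 CSV) plus a
    manifest recording the seed and per-file checksums."""
    out_dir = Path(out_dir)
    raw_dir = out_dir / "raw"
    raw_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for session in cohort.sessions:
        path = raw_dir / _session_filename(session)
        write_session_csv(session, path)
        files.append(path)
    log_path = out_dir / "activity_log.csv"
    write_activity_log(cohort.activity_log, log_path)
    files.append(log_path)
    vo2_path = out_dir / "vo2.csv"
    write_vo2_csv(cohort.vo2, vo2_path)
    files.append(vo2_path)

    manifest = {
        "seed": cohort.seed,
        "n_participants": len(cohort.participants),
        "n_activities": len(cohort.roster),
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_raw_sessions(
    out_dir: Path, activity_log: pd.DataFrame, placements, **read_kwargs
) -> list[RecordingSession]:
    """Load every raw session named by the activity log that exists on disk."""
    raw_dir = Path(out_dir) / "raw"
    sessions = []
    for rec in activity_log.itertuples(index=False):
        for placement in placements:
            path = raw_dir / f"raw_{rec.participant_id}_{rec.activity}_{placement}.csv"
            if path.exists():
                sessions.append(
                    read_session_csv(
                        path, str(rec.participant_id), str(rec.activity), placement,
                        **read_kwargs,
                    )
                )
    return sessions
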