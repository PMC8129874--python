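"""Windowed time- and frequency-domain features from triaxial signals.

Raw recordings are segmented into contiguous, non-overlapping 16-second
windows; 15 summary features are computed per window from the vector
magnitude (VM) and the raw axes:

time domain (12): mean VM, SD of VM, mean and SD of the angle between a
reference axis and VM, lag-1 autocovariance of VM, skewness, excess
kurtosis, histogram entropy (bits), coefficient of variation (percent),
and the three pairwise axis correlations;

frequency domain (3): fraction of spectral moduli in the 0.6–2.5 Hz band,
dominant frequency, and fraction of moduli at the dominant frequency. The
DC term is excluded (the VM is mean-removed before the transform), moduli —
not squared moduli — are summed, and dominant-frequency ties break toward
the lowest frequency.

Degenerate windows are handled explicitly rather than producing NaN:
a constant VM yields zero SD/entropy/CV and flagged zero frequency
features; a zero-variance axis yields correlation 0 with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .placements import PLACEMENTS
from .synth import Cohort, RecordingSession

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 16.0
BAND_LOW_HZ = 0.6
BAND_HIGH_HZ = 2.5
ENTROPY_BINS = 20

#: Fixed feature order (12 time + 3 frequency = 15).
FEATURE_NAMES: tuple[str, ...] = (
    "mean_vm",
    "sd_vm",
    "mean_angle",
    "sd_angle",
    "autocov_vm",
    "skew_vm",
    "kurt_vm",
    "entropy_vm",
    "cv_vm",
    "corr_xy",
    "corr_yz",
    "corr_xz",
    "power_frac_band",
    "dom_freq",
    "frac_at_dom",
)

TIME_FEATURE_NAMES = FEATURE_NAMES[:12]
FREQ_FEATURE_NAMES = FEATURE_NAMES[12:]


@dataclass
class TriaxialWindow:
    """One fixed-duration window of a recording session."""

    samples: np.ndarray  # (n, 3) in g
    sample_rate: float
    window_start: pd.Timestamp
    participant_id: str
    activity_name: str
    placement: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")


def segment_windows(
    session: RecordingSession, window_s: float = DEFAULT_WINDOW_S
) -> list[TriaxialWindow]:
    """Split a session into contiguous non-overlapping windows.

    Windows start at the session start; a trailing partial window is
    discarded. A session shorter than one window yields an empty list.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    n_per = int(round(window_s * session.sample_rate))
    n_win = session.n_samples // n_per
    if n_win == 0:
        logger.info(
            "session %s/%s/%s shorter than one window; no windows emitted",
            session.participant_id,
            session.activity_name,
            session.placement,
        )
        return []
    out = []
    for i in range(n_win):
        out.append(
            TriaxialWindow(
                samples=session.samples[i * n_per : (i + 1) * n_per],
                sample_rate=session.sample_rate,
                window_start=session.start_time + pd.to_timedelta(i * window_s, unit="s"),
                participant_id=session.participant_id,
                activity_name=session.activity_name,
                placement=session.placement,
            )
        )
    return out


def vector_magnitude(window: TriaxialWindow | np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes."""
    samples = window.samples if isinstance(window, TriaxialWindow) else np.asarray(window)
    return np.sqrt(np.sum(samples * samples, axis=1))


def _histogram_entropy_bits(values: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    """Shannon entropy (bits) of an equal-width histogram over the value range.

    A constant sequence has zero range, a single occupied bin, and entropy 0
    (0·log 0 ≡ 0 throughout).
    """
    if np.ptp(values) == 0:
        return 0.0
    counts, _ = np.histogram(values, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _pearson_or_zero(a: np.ndarray, b: np.ndarray, label: str) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn(f"zero-variance axis in {label}; correlation reported as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def time_features(
    window: TriaxialWindow,
    *,
    angle_axis: int = 0,
    autocov_lag: int = 1,
    entropy_bins: int = ENTROPY_BINS,
) -> dict[str, float]:
    """Compute the 12 time-domain features for one window.

    ``angle_axis`` selects which raw axis the per-sample angle is taken
    against (default x); ``autocov_lag=0`` degrades the autocovariance to
    the plain variance.
    """
    x, y, z = window.samples.T
    vm = vector_magnitude(window)
    n = vm.size
    if n < 4:
        raise ValueError("need at least 4 samples for higher moments")

    mean_vm = float(vm.mean())
    sd_vm = float(vm.std(ddof=1))

    axis_vals = window.samples[:, angle_axis]
    ok = vm > 0
    if not np.any(ok):
        warnings.warn("all-zero VM: angle features undefined, reported as NaN")
        mean_angle = sd_angle = float("nan")
    else:
        if not np.all(ok):
            logger.warning(
                "%d samples with zero VM skipped for angle features", int((~ok).sum())
            )
        angles = np.arccos(np.clip(axis_vals[ok] / vm[ok], -1.0, 1.0))
        mean_angle = float(angles.mean())
        sd_angle = float(angles.std(ddof=1)) if angles.size > 1 else 0.0

    centered = vm - mean_vm
    lag = autocov_lag
    if lag == 0:
        autocov = float(np.sum(centered * centered) / (n - 1))
    else:
        autocov = float(np.sum(centered[:-lag] * centered[lag:]) / (n - 1 - lag))

    if sd_vm == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(vm, bias=True))
        kurt = float(stats.kurtosis(vm, bias=True))  # excess: normal -> 0

    entropy = _histogram_entropy_bits(vm, bins=entropy_bins)

    if mean_vm > 0:
        cv = 100.0 * sd_vm / mean_vm
    else:
        warnings.warn("non-positive mean VM: CV undefined, reported as NaN")
        cv = float("nan")

    return {
        "mean_vm": mean_vm,
        "sd_vm": sd_vm,
        "mean_angle": mean_angle,
        "sd_angle": sd_angle,
        "autocov_vm": autocov,
        "skew_vm": skew,
        "kurt_vm": kurt,
        "entropy_vm": entropy,
        "cv_vm": cv,
        "corr_xy": _pearson_or_zero(x, y, "corr_xy"),
        "corr_yz": _pearson_or_zero(y, z, "corr_yz"),
        "corr_xz": _pearson_or_zero(x, z, "corr_xz"),
    }


def frequency_features(
    window: TriaxialWindow,
    *,
    band: tuple[float, float] = (BAND_LOW_HZ, BAND_HIGH_HZ),
) -> dict[str, float]:
    """Compute the 3 spectral features from the mean-removed VM.

    Moduli are taken over the positive frequencies f_k = k·rate/n,
    k = 1..⌊n/2⌋. A constant VM (all-zero after mean removal) is flagged
    degenerate: band fraction 0, dominant fraction 0, dominant frequency 0.
    """
    vm = vector_magnitude(window)
    n = vm.size
    if n < 16:
        raise ValueError("need at least 16 samples for spectral features")
    centered = vm - vm.mean()

    spectrum = np.fft.rfft(centered)
    moduli = np.abs(spectrum[1 : n // 2 + 1])
    freqs = np.arange(1, n // 2 + 1) * window.sample_rate / n

    total = moduli.sum()
    if total == 0:
        logger.warning("constant VM window: spectral features degenerate")
        return {"power_frac_band": 0.0, "dom_freq": 0.0, "frac_at_dom": 0.0}

    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi)
    # ties break to the lowest frequency; a 1e-9 relative tolerance makes
    # equal-amplitude tones tie deterministically despite FFT rounding
    peak = moduli.max()
    k_dom = int(np.argmax(moduli >= peak * (1 - 1e-9)))
    return {
        "power_frac_band": float(moduli[in_band].sum() / total),
        "dom_freq": float(freqs[k_dom]),
        "frac_at_dom": float(moduli[k_dom] / total),
    }


def featurize_window(window: TriaxialWindow, **kwargs) -> dict[str, float]:
    """All 15 features for one window, in :data:`FEATURE_NAMES` order."""
    feats = time_features(window, **{k: v for k, v in kwargs.items() if k != "band"})
    feats.update(frequency_features(window, **({"band": kwargs["band"]} if "band" in kwargs else {})))
    return {name: feats[name] for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

LABEL_COLUMNS = (
    "participant_id",
    "activity",
    "window_index",
    "is_sedentary",
    "is_locomotion",
    "is_lifestyle",
    "met",
)


def feature_columns(placements=PLACEMENTS) -> list[str]:
    """Placement-namespaced feature column names in the fixed order."""
    return [f"{p}_{f}" for p in placements for f in FEATURE_NAMES]


def extract_feature_table(
    sessions: list[RecordingSession],
    activity_log: pd.DataFrame,
    window_s: float = DEFAULT_WINDOW_S,
    *,
    met_labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the modeling table: one row per (participant, activity, window).

    Feature columns are namespaced by placement (``hip_mean_vm``, ...) in the
    fixed placement order. Label columns carry the activity name, the three
    category flags and — when ``met_labels`` (participant_id, activity,
    met_value) is given — the session-level MET. Windows that do not lie
    entirely inside the logged [start, stop) interval are dropped and
    counted; placements missing for a session leave that placement's columns
    NaN.
    """
    if activity_log.empty:
        return pd.DataFrame(columns=list(LABEL_COLUMNS) + feature_columns())

    by_key: dict[tuple[str, str], dict[str, RecordingSession]] = {}
    for s in sessions:
        by_key.setdefault((s.participant_id, s.activity_name), {})[s.placement] = s

    met_map: dict[tuple[str, str], float] = {}
    if met_labels is not None:
        for rec in met_labels.itertuples(index=False):
            met_map[(rec.participant_id, rec.activity)] = float(rec.met_value)

    placements_present = [
        p for p in PLACEMENTS if any(p in d for d in by_key.values())
    ]
    n_dropped = 0
    rows = []
    for log in activity_log.itertuples(index=False):
        key = (log.participant_id, log.activity)
        placed = by_key.get(key, {})
        if not placed:
            continue
        per_placement: dict[str, dict[int, dict[str, float]]] = {}
        indices: set[int] = set()
        for placement, session in placed.items():
            feats_by_idx = {}
            for i, win in enumerate(segment_windows(session, window_s)):
                win_end = win.window_start + pd.to_timedelta(window_s, unit="s")
                if win.window_start < log.start or win_end > log.stop:
                    n_dropped += 1
                    continue
                feats_by_idx[i] = featurize_window(win)
            per_placement[placement] = feats_by_idx
            indices.update(feats_by_idx)
        for i in sorted(indices):
            row: dict[str, object] = {
                "participant_id": log.participant_id,
                "activity": log.activity,
                "window_index": i,
                "is_sedentary": log.category == "sedentary",
                "is_locomotion": log.category == "locomotion",
                "is_lifestyle": log.category == "lifestyle",
                "met": met_map.get(key, np.nan),
            }
            for p in placements_present:
                feats = per_placement.get(p, {}).get(i)
                if feats is None:
                    if p in placed or p in per_placement:
                        logger.warning(
                            "placement %s missing window %d for %s/%s",
                            p, i, log.participant_id, log.activity,
                        )
                    for f in FEATURE_NAMES:
                        row[f"{p}_{f}"] = np.nan
                else:
                    for f in FEATURE_NAMES:
                        row[f"{p}_{f}"] = feats[f]
            rows.append(row)
    if n_dropped:
        logger.info("%d windows dropped for crossing log boundaries", n_dropped)

    columns = list(LABEL_COLUMNS) + feature_columns(placements_present)
    return pd.DataFrame(rows, columns=columns)


def cohort_feature_table(
    cohort: Cohort,
    window_s: float = DEFAULT_WINDOW_S,
    *,
    met_labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: feature table straight from a simulated cohort."""
    return extract_feature_table(
        cohort.sessions, cohort.activity_log, window_s, met_labels=met_labels
    )
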