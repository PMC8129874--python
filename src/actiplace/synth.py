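"""Seeded synthetic cohorts: multi-placement accelerometer signals and VO2 traces.

The simulator produces the statistical structure the downstream analysis
assumes without any real recordings:

* five wear sites with placement-dependent signal character — strong
  0.6–2.5 Hz periodicity at the ankle/hip/thigh during locomotion, high
  wrist variability during lifestyle tasks, near-static gravity-dominated
  signals during sedentary tasks;
* activity rosters with three mutually exclusive categories (sedentary,
  locomotion, lifestyle) and activity-specific metabolic cost;
* breath-by-breath VO2 traces with an exponential onset that plateaus at
  the session's metabolic level roughly two minutes after activity start;
* per-participant random effects (signal amplitude, metabolic offset).

All randomness flows from a single cohort seed through per-session derived
seeds (a stable hash of participant × activity × placement), so identical
(config, seed) pairs regenerate byte-identical cohorts and any single
session can be regenerated in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .placements import PLACEMENTS, validate_placement

DEFAULT_SAMPLE_RATE = 100.0
DEFAULT_DURATION_RANGE = (360.0, 480.0)
REST_VO2 = 3.5  # mL·min⁻¹·kg⁻¹ per MET by convention

_CATEGORIES = ("sedentary", "locomotion", "lifestyle")

#: Approximate device orientation per wear site (unit gravity direction in
#: device coordinates). Values are design choices, varied across sites so the
#: orientation-sensitive features differ by placement.
_GRAVITY_AXES: dict[str, tuple[float, float, float]] = {
    "ankle": (0.10, 0.10, 0.99),
    "upper_arm": (0.90, 0.30, 0.31),
    "hip": (0.97, 0.05, 0.24),
    "thigh": (0.20, 0.95, 0.24),
    "wrist": (0.55, 0.55, 0.63),
}


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class SignalTemplate:
    """Generative description of one placement's signal for one activity.

    The simulated signal is ``gravity_axis`` plus a sum of sinusoids (each
    with its own axis-mixing vector), white Gaussian noise, and a slow
    random-walk drift.
    """

    gravity_axis: np.ndarray
    periodic_components: tuple[tuple[float, float, np.ndarray], ...] = ()
    noise_sd: float = 0.0
    drift_sd: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "gravity_axis", _unit(self.gravity_axis))
        comps = []
        for freq, amp, mix in self.periodic_components:
            if freq <= 0:
                raise ValueError(f"periodic frequency must be > 0, got {freq}")
            if amp < 0:
                raise ValueError(f"periodic amplitude must be >= 0, got {amp}")
            comps.append((float(freq), float(amp), _unit(mix)))
        object.__setattr__(self, "periodic_components", tuple(comps))
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise_sd and drift_sd must be >= 0")


@dataclass(frozen=True)
class ActivitySpec:
    """One scripted activity: category flags, metabolic cost, signal templates."""

    name: str
    is_sedentary: bool
    is_locomotion: bool
    is_lifestyle: bool
    duration_range: tuple[float, float] = DEFAULT_DURATION_RANGE
    true_met_mean: float = 1.0
    true_met_sd_between_participants: float = 0.2
    templates: dict[str, SignalTemplate] = field(default_factory=dict)

    def __post_init__(self):
        flags = (self.is_sedentary, self.is_locomotion, self.is_lifestyle)
        if sum(flags) != 1:
            raise ValueError(
                f"activity {self.name!r}: exactly one category flag must be set"
            )
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid duration_range {self.duration_range}")
        if self.true_met_mean < 0.9:
            raise ValueError("true_met_mean must be >= 0.9")

    @property
    def category(self) -> str:
        if self.is_sedentary:
            return "sedentary"
        if self.is_locomotion:
            return "locomotion"
        return "lifestyle"


@dataclass(frozen=True)
class ParticipantSpec:
    participant_id: str
    amplitude_factor: float = 1.0
    met_offset: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.amplitude_factor <= 0:
            raise ValueError("amplitude_factor must be > 0")


@dataclass
class RecordingSession:
    """One participant × activity × placement triaxial recording."""

    participant_id: str
    activity_name: str
    placement: str
    sample_rate: float
    samples: np.ndarray  # (n, 3) in g
    start_time: pd.Timestamp
    stop_time: pd.Timestamp

    @property
    def duration_s(self) -> float:
        return (self.stop_time - self.start_time).total_seconds()

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class Vo2Trace:
    """Breath-by-breath VO2 (mL·min⁻¹·kg⁻¹) at irregular breath times (s)."""

    breath_times: np.ndarray
    vo2_values: np.ndarray

    def __post_init__(self):
        self.breath_times = np.asarray(self.breath_times, dtype=float)
        self.vo2_values = np.asarray(self.vo2_values, dtype=float)
        if self.breath_times.shape != self.vo2_values.shape:
            raise ValueError("breath_times and vo2_values must align")
        if np.any(np.diff(self.breath_times) <= 0):
            raise ValueError("breath_times must be strictly increasing")
        if np.any(self.vo2_values <= 0):
            raise ValueError("vo2_values must be positive")


@dataclass
class SessionVo2:
    """A VO2 trace tied to its session plus the simulation's ground truth MET."""

    participant_id: str
    activity_name: str
    trace: Vo2Trace
    true_met: float


@dataclass
class Cohort:
    participants: list[ParticipantSpec]
    roster: list[ActivitySpec]
    sessions: list[RecordingSession]
    vo2: list[SessionVo2]
    activity_log: pd.DataFrame
    seed: int


# ---------------------------------------------------------------------------
# roster construction
# ---------------------------------------------------------------------------


def _locomotion_templates(rng: np.random.Generator) -> dict[str, SignalTemplate]:
    # Gait-like: a strong in-band (0.6–2.5 Hz) component at ankle/hip/thigh,
    # a weaker one carried to arm/wrist.
    step = rng.uniform(0.9, 2.2)
    amp = {"ankle": 0.75, "hip": 0.35, "thigh": 0.55, "upper_arm": 0.22, "wrist": 0.18}
    out = {}
    for p in PLACEMENTS:
        comps = [(step, amp[p] * rng.uniform(0.8, 1.2), rng.normal(size=3))]
        if 2 * step <= 5.0:  # harmonic, may fall outside the band
            comps.append((2 * step, 0.25 * amp[p], rng.normal(size=3)))
        out[p] = SignalTemplate(
            gravity_axis=_GRAVITY_AXES[p],
            periodic_components=tuple(comps),
            noise_sd=0.05,
            drift_sd=0.01,
        )
    return out


def _sedentary_templates(rng: np.random.Generator) -> dict[str, SignalTemplate]:
    # Near-static: gravity plus a faint sub-band respiratory wobble.
    breath = rng.uniform(0.2, 0.35)
    return {
        p: SignalTemplate(
            gravity_axis=_GRAVITY_AXES[p],
            periodic_components=((breath, 0.01, rng.normal(size=3)),),
            noise_sd=0.012,
            drift_sd=0.004,
        )
        for p in PLACEMENTS
    }


def _lifestyle_templates(rng: np.random.Generator) -> dict[str, SignalTemplate]:
    # Irregular household-task movement: broadband wrist activity, moderate
    # sub-band periodicity elsewhere.
    base = rng.uniform(0.3, 0.55)
    out = {}
    for p in PLACEMENTS:
        if p == "wrist":
            comps = (
                (base, 0.22 * rng.uniform(0.7, 1.3), rng.normal(size=3)),
                (base * 1.8, 0.10, rng.normal(size=3)),
            )
            noise = 0.22
        else:
            comps = ((base, 0.10 * rng.uniform(0.6, 1.4), rng.normal(size=3)),)
            noise = 0.07
        out[p] = SignalTemplate(
            gravity_axis=_GRAVITY_AXES[p],
            periodic_components=comps,
            noise_sd=noise,
            drift_sd=0.01,
        )
    return out


def build_default_roster(
    n_activities: int,
    n_sedentary: int,
    *,
    n_locomotion: int = 6,
    duration_range: tuple[float, float] = DEFAULT_DURATION_RANGE,
    met_sd_between: float = 0.2,
    seed: int = 0,
) -> list[ActivitySpec]:
    """Build a parameterized roster of activity specs.

    ``n_sedentary`` activities are sedentary (MET mean < 1.6),
    ``n_locomotion`` are locomotion (MET mean ≥ 2.5), the remainder are
    lifestyle. Per-activity metabolic costs and signal-template parameters
    are drawn deterministically from ``seed``.
    """
    if not 0 < n_sedentary < n_activities:
        raise ValueError(
            f"need 0 < n_sedentary < n_activities, got {n_sedentary}/{n_activities}"
        )
    n_locomotion = min(n_locomotion, n_activities - n_sedentary)
    n_lifestyle = n_activities - n_sedentary - n_locomotion

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA0C7)))
    roster: list[ActivitySpec] = []
    counts = {"sedentary": n_sedentary, "locomotion": n_locomotion, "lifestyle": n_lifestyle}
    for category in _CATEGORIES:
        for i in range(counts[category]):
            if category == "sedentary":
                met = rng.uniform(1.0, 1.5)
                templates = _sedentary_templates(rng)
            elif category == "locomotion":
                met = rng.uniform(2.5, 5.0)
                templates = _locomotion_templates(rng)
            else:
                met = rng.uniform(1.8, 4.8)
                templates = _lifestyle_templates(rng)
            roster.append(
                ActivitySpec(
                    name=f"{category}_{i + 1:02d}",
                    is_sedentary=category == "sedentary",
                    is_locomotion=category == "locomotion",
                    is_lifestyle=category == "lifestyle",
                    duration_range=duration_range,
                    true_met_mean=float(met),
                    true_met_sd_between_participants=met_sd_between,
                    templates=templates,
                )
            )
    return roster


# ---------------------------------------------------------------------------
# per-session simulation
# ---------------------------------------------------------------------------


def _derived_seed(seed: int, *parts: str) -> np.random.SeedSequence:
    """Stable per-session seed: cohort seed + CRC32 of the identity key."""
    key = "|".join(parts)
    return np.random.SeedSequence((int(seed), zlib.crc32(key.encode())))


def simulate_session(
    participant: ParticipantSpec,
    activity: ActivitySpec,
    placement: str,
    duration: float,
    seed,
    *,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    start_time: pd.Timestamp | None = None,
) -> RecordingSession:
    """Simulate one triaxial recording for a participant × activity × placement.

    Samples are ``gravity_axis + amplitude_factor × (periodic components +
    Gaussian noise + random-walk drift)``; deterministic given ``seed``.
    """
    validate_placement(placement)
    lo, hi = activity.duration_range
    if not lo <= duration <= hi:
        raise ValueError(
            f"duration {duration} outside activity range [{lo}, {hi}]"
        )
    if placement not in activity.templates:
        raise ValueError(f"activity {activity.name!r} has no template for {placement!r}")
    template = activity.templates[placement]

    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    dynamic = np.zeros((n, 3))
    for freq, amp, mix in template.periodic_components:
        phase = rng.uniform(0, 2 * np.pi)
        dynamic += amp * np.sin(2 * np.pi * freq * t + phase)[:, None] * mix
    if template.noise_sd > 0:
        dynamic += rng.normal(0.0, template.noise_sd, size=(n, 3))
    if template.drift_sd > 0:
        steps = rng.normal(0.0, template.drift_sd / np.sqrt(n), size=(n, 3))
        dynamic += np.cumsum(steps, axis=0)

    samples = template.gravity_axis + participant.amplitude_factor * dynamic

    if start_time is None:
        start_time = pd.Timestamp("2024-01-01T08:00:00Z")
    stop_time = start_time + pd.to_timedelta(duration, unit="s")
    return RecordingSession(
        participant_id=participant.participant_id,
        activity_name=activity.name,
        placement=placement,
        sample_rate=sample_rate,
        samples=samples,
        start_time=start_time,
        stop_time=stop_time,
    )


def session_true_met(
    participant: ParticipantSpec, activity: ActivitySpec, seed
) -> float:
    """Ground-truth MET for one session: activity mean + between-participant
    deviation + participant offset, floored at 0.9."""
    rng = np.random.default_rng(seed)
    dev = rng.normal(0.0, activity.true_met_sd_between_participants)
    return float(max(0.9, activity.true_met_mean + participant.met_offset + dev))


def simulate_vo2_trace(
    participant: ParticipantSpec,
    activity: ActivitySpec,
    duration: float,
    seed,
    *,
    onset_tau_s: float = 40.0,
    mean_breath_interval_s: float = 3.0,
    noise_sd: float = 0.5,
    session_met: float | None = None,
) -> Vo2Trace:
    """Simulate a breath-by-breath VO2 trace for one session.

    VO2 rises from rest (3.5 mL·min⁻¹·kg⁻¹) with an exponential onset of
    time constant ``onset_tau_s`` to a plateau at 3.5 × session MET, plus
    breath-level Gaussian noise. Breath intervals are irregular
    (shifted-exponential, mean ``mean_breath_interval_s``).

    Raises ValueError when ``duration`` < 180 s: too short for a
    steady-state plateau to be reachable.
    """
    if duration < 180:
        raise ValueError(f"duration {duration} s < 180 s: no steady state reachable")
    rng = np.random.default_rng(seed)
    if session_met is None:
        session_met = session_true_met(participant, activity, rng.integers(2**31))

    min_gap = min(0.5, mean_breath_interval_s / 2)
    intervals = []
    total = 0.0
    while total < duration:
        gap = min_gap + rng.exponential(mean_breath_interval_s - min_gap)
        intervals.append(gap)
        total += gap
    times = np.cumsum(intervals)
    times = times[times <= duration]

    plateau = REST_VO2 * session_met
    vo2 = REST_VO2 + (plateau - REST_VO2) * (1.0 - np.exp(-times / onset_tau_s))
    if noise_sd > 0:
        vo2 = vo2 + rng.normal(0.0, noise_sd, size=times.shape)
    vo2 = np.maximum(vo2, 0.1)
    return Vo2Trace(breath_times=times, vo2_values=vo2)


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------


def make_participants(n: int, seed: int) -> list[ParticipantSpec]:
    """Draw ``n`` participants with lognormal amplitude factors and Gaussian
    metabolic offsets."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x9A87)))
    out = []
    for i in range(n):
        out.append(
            ParticipantSpec(
                participant_id=f"P{i + 1:03d}",
                amplitude_factor=float(np.exp(rng.normal(0.0, 0.15))),
                met_offset=float(rng.normal(0.0, 0.15)),
                rng_seed=int(rng.integers(2**31)),
            )
        )
    return out


def simulate_cohort(
    n_participants: int,
    roster: list[ActivitySpec],
    seed: int,
    *,
    placements: tuple[str, ...] = PLACEMENTS,
    drop_probability: float = 0.0,
    vo2_noise_sd: float = 0.5,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    rest_gap_s: float = 300.0,
) -> Cohort:
    """Simulate a full cohort: sessions for every placement, VO2 traces and
    an activity log.

    Each participant performs every roster activity unless it is dropped at
    random with ``drop_probability`` (emulating incomplete protocols). At
    least 6 participants are required so outer CV folds are non-empty.
    """
    if n_participants < 6:
        raise ValueError("need at least 6 participants for non-empty outer folds")
    for p in placements:
        validate_placement(p)

    participants = make_participants(n_participants, seed)
    sessions: list[RecordingSession] = []
    vo2: list[SessionVo2] = []
    log_rows = []

    base_time = pd.Timestamp("2024-01-01T08:00:00Z")
    for participant in participants:
        clock = base_time
        for activity in roster:
            sess_seq = _derived_seed(seed, participant.participant_id, activity.name)
            sess_rng = np.random.default_rng(sess_seq)
            if drop_probability > 0 and sess_rng.uniform() < drop_probability:
                continue
            lo, hi = activity.duration_range
            duration = float(np.round(sess_rng.uniform(lo, hi)))
            true_met = session_true_met(
                participant, activity, sess_rng.integers(2**31)
            )
            for placement in placements:
                sessions.append(
                    simulate_session(
                        participant,
                        activity,
                        placement,
                        duration,
                        _derived_seed(
                            seed, participant.participant_id, activity.name, placement
                        ),
                        sample_rate=sample_rate,
                        start_time=clock,
                    )
                )
            vo2.append(
                SessionVo2(
                    participant_id=participant.participant_id,
                    activity_name=activity.name,
                    trace=simulate_vo2_trace(
                        participant,
                        activity,
                        duration,
                        _derived_seed(
                            seed, participant.participant_id, activity.name, "vo2"
                        ),
                        noise_sd=vo2_noise_sd,
                        session_met=true_met,
                    ),
                    true_met=true_met,
                )
            )
            log_rows.append(
                {
                    "participant_id": participant.participant_id,
                    "activity": activity.name,
                    "category": activity.category,
                    "start": clock,
                    "stop": clock + pd.to_timedelta(duration, unit="s"),
                }
            )
            clock = clock + pd.to_timedelta(duration + rest_gap_s, unit="s")

    activity_log = pd.DataFrame(
        log_rows, columns=["participant_id", "activity", "category", "start", "stop"]
    )
    return Cohort(
        participants=participants,
        roster=list(roster),
        sessions=sessions,
        vo2=vo2,
        activity_log=activity_log,
        seed=seed,
    )
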