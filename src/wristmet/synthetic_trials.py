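"""Synthetic activity-trial studies for exercising the full MET pipeline.

A study emulates a sequential activity protocol in which each participant
performs seven everyday activities in fixed order, from sedentary to
vigorous: sitting, standing still, slow walking, quick walking, ascending
and descending stairs, jogging, and run/rope skipping.  Children skip
jogging.  Each trial lasts 14–16 minutes; the first three minutes (metabolic
warm-up) and the last minute are excluded from analysis.

Per activity and group the generator is calibrated to published
indirect-calorimetry MET distributions (mean ± SD); a participant draws one
steady-state MET per trial from that distribution, ramps linearly from rest
toward it over the warm-up, and then fluctuates around it with small
minute-to-minute noise.  The accelerometer stream for every minute is a
cadence-frequency sinusoid whose amplitude grows with the MET above rest,
plus Gaussian jitter, so the extracted ``pa_avg`` is monotone in expectation
in the true MET — the generative link a wrist-worn device relies on.

All randomness flows from one master seed through per-participant
substreams, so a study is bit-identical given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Literal, Sequence

import numpy as np
from scipy.stats import truncnorm

from .io import MinuteRecord
from .signal_features import (
    SAMPLE_HZ,
    SAMPLES_PER_MINUTE,
    MinuteWindow,
    extract_minute_features,
)

Group = Literal["adult", "child"]
GROUPS: tuple[Group, ...] = ("adult", "child")

WARMUP_MINUTES = 3
TRAILING_EXCLUDED_MINUTES = 1
TRIAL_DURATION_CHOICES = (14, 15, 16)

#: default cohort sizes (24 adults, 18 children)
DEFAULT_N = {"adult": 24, "child": 18}


class ProtocolError(ValueError):
    """A request violates the activity protocol (unknown activity, short trial...)."""


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics of one participant; BMI is derived, never stored."""

    id: str
    group: str
    gender: str
    age: float
    height_cm: float
    weight_kg: float

    @property
    def bmi(self) -> float:
        """weight (kg) divided by height squared (m²)."""
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def gender_code(self) -> int:
        return 1 if self.gender == "male" else 0


@dataclass(frozen=True)
class MetDistribution:
    mean: float
    sd: float


@dataclass(frozen=True)
class ActivitySpec:
    """One protocol activity: nominal intensity, per-group MET calibration,
    and the cadence driving the accelerometer synthesizer."""

    name: str
    nominal_intensity: str  # SED | LPA | MPA | VPA
    mets: dict[str, MetDistribution | None]
    cadence: float  # steps/min

    def met_distribution(self, group: str) -> MetDistribution:
        dist = self.mets.get(group)
        if dist is None:
            raise ProtocolError(
                f"activity {self.name!r} is not part of the {group} protocol"
            )
        if dist.mean <= 0 or dist.sd < 0:
            raise ProtocolError(f"invalid MET calibration for {self.name!r}")
        return dist


def _spec(name, intensity, adult, child, cadence):
    return ActivitySpec(
        name=name,
        nominal_intensity=intensity,
        mets={
            "adult": MetDistribution(*adult) if adult else None,
            "child": MetDistribution(*child) if child else None,
        },
        cadence=cadence,
    )


#: The seven-activity protocol with per-group measured-MET calibration
#: (mean, SD).  Cadences are nominal steps/min for the synthesizer.
DEFAULT_PROTOCOL: tuple[ActivitySpec, ...] = (
    _spec("sitting", "SED", (1.01, 0.13), (1.04, 0.19), 0.0),
    _spec("standing_still", "SED", (1.11, 0.19), (1.19, 0.42), 0.0),
    _spec("slow_walking", "LPA", (2.23, 0.62), (2.52, 0.80), 70.0),
    _spec("quick_walking", "MPA", (3.66, 1.14), (3.56, 1.32), 110.0),
    _spec("stairs", "MPA", (5.30, 1.89), (6.01, 2.18), 95.0),
    _spec("jogging", "VPA", (6.41, 2.38), None, 150.0),
    _spec("run_rope_skipping", "VPA", (9.40, 3.74), (6.68, 2.58), 160.0),
)


@dataclass(frozen=True)
class Demographics:
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    height_mean: float
    height_sd: float
    weight_mean: float
    weight_sd: float


#: cohort demographics: mean ± SD, with hard age eligibility ranges
GROUP_DEMOGRAPHICS: dict[str, Demographics] = {
    "adult": Demographics(24.9, 2.6, (21.0, 34.0), 169.2, 7.2, 61.7, 8.7),
    "child": Demographics(12.3, 1.0, (9.0, 13.0), 160.5, 10.3, 52.6, 12.5),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunables of the study generator.

    minute_noise_factor
        SD of the within-trial minute-to-minute MET noise as a fraction of
        the activity's published SD (most of the published SD is attributed
        to between-participant steady states).
    jitter_sd
        Gaussian accelerometer noise per sample, signal units.
    amplitude_per_met
        Dominant-axis sinusoid amplitude per MET above rest.
    default_sway_hz
        Oscillation frequency used when an activity has zero cadence
        (postural sway for sitting/standing).
    p_not_worn / p_unstable
        Per-minute Bernoulli rates of the watch not being worn and of the
        energy expenditure being flagged unstable.
    met_floor
        Physiological floor for any simulated MET.
    """

    minute_noise_factor: float = 0.1
    jitter_sd: float = 0.02
    amplitude_per_met: float = 0.1
    default_sway_hz: float = 0.25
    p_not_worn: float = 0.02
    p_unstable: float = 0.03
    met_floor: float = 0.5
    train_fraction: float = 0.7
    protocol: tuple[ActivitySpec, ...] = DEFAULT_PROTOCOL

    def activity(self, name: str) -> ActivitySpec:
        for spec in self.protocol:
            if spec.name == name:
                return spec
        raise ProtocolError(f"unknown activity {name!r}")


@dataclass(frozen=True)
class TrialMinute:
    """One analyzed minute: criterion MET, raw window, watch record, QC flags."""

    participant_id: str
    activity: str
    minute_index: int  # 1-based within the trial
    true_met: float
    window: MinuteWindow | None
    record: MinuteRecord | None
    stable: bool
    worn: bool


@dataclass
class StudyDataset:
    """A complete synthetic study: cohort, every generated trial minute, and
    the participant-level train/test assignment."""

    group: str
    participants: list[ParticipantProfile]
    minutes: list[TrialMinute]
    split: dict[str, str]  # participant_id -> "train" | "test"
    seed: int | None = None

    def __post_init__(self) -> None:
        pids = {p.id for p in self.participants}
        if set(self.split) != pids:
            raise ValueError("split must assign every participant exactly once")
        orphans = {m.participant_id for m in self.minutes} - pids
        if orphans:
            raise ValueError(f"trial minutes reference unknown participants {orphans}")

    def participant(self, pid: str) -> ParticipantProfile:
        for p in self.participants:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def valid_minutes(self) -> list[TrialMinute]:
        """Analysis set: warm-up/last-minute trimmed, invalid minutes excluded."""
        out: list[TrialMinute] = []
        for (pid, activity), trial in _group_trials(self.minutes):
            out.extend(exclude_invalid(trim_trial(trial)))
        return out

    def _subset(self, which: str) -> list[TrialMinute]:
        return [m for m in self.valid_minutes() if self.split[m.participant_id] == which]

    def train_minutes(self) -> list[TrialMinute]:
        return self._subset("train")

    def test_minutes(self) -> list[TrialMinute]:
        return self._subset("test")

    def split_participants_of(self, which: str) -> list[ParticipantProfile]:
        return [p for p in self.participants if self.split[p.id] == which]


def _group_trials(minutes: Sequence[TrialMinute]):
    keys: list[tuple[str, str]] = []
    trials: dict[tuple[str, str], list[TrialMinute]] = {}
    for m in minutes:
        key = (m.participant_id, m.activity)
        if key not in trials:
            trials[key] = []
            keys.append(key)
        trials[key].append(m)
    for key in keys:
        yield key, trials[key]


def _truncnorm_rvs(rng, mean, sd, lower=-np.inf, upper=np.inf, size=None):
    if sd == 0:
        return np.full(size, mean) if size is not None else float(mean)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_participants(
    n: int, group: str, seed: int | np.random.SeedSequence = 0
) -> list[ParticipantProfile]:
    """Draw a cohort from the group's demographic distributions.

    Heights/weights are truncated normals (±4 SD) around the cohort mean ± SD;
    age respects the eligibility range.  Gender alternates for an exactly
    balanced cohort.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("need at least one participant")
    if group not in GROUP_DEMOGRAPHICS:
        raise ValueError(f"unknown group {group!r}")
    demo = GROUP_DEMOGRAPHICS[group]
    rng = np.random.default_rng(seed)
    ages = _truncnorm_rvs(rng, demo.age_mean, demo.age_sd, *demo.age_range, size=n)
    heights = _truncnorm_rvs(
        rng,
        demo.height_mean,
        demo.height_sd,
        demo.height_mean - 4 * demo.height_sd,
        demo.height_mean + 4 * demo.height_sd,
        size=n,
    )
    weights = _truncnorm_rvs(
        rng,
        demo.weight_mean,
        demo.weight_sd,
        demo.weight_mean - 4 * demo.weight_sd,
        demo.weight_mean + 4 * demo.weight_sd,
        size=n,
    )
    return [
        ParticipantProfile(
            id=f"{group}{i + 1:03d}",
            group=group,
            gender="male" if i % 2 == 0 else "female",
            age=float(round(ages[i], 1)),
            height_cm=float(round(heights[i], 1)),
            weight_kg=float(round(weights[i], 1)),
        )
        for i in range(n)
    ]


def simulate_true_mets(
    participant: ParticipantProfile,
    activity: ActivitySpec,
    duration: int,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    config: GeneratorConfig | None = None,
) -> np.ndarray:
    """Per-minute criterion MET series for one trial.

    The participant's steady state is one draw from the activity's
    Normal(mean, SD) truncated below at the physiological floor; minutes 1–3
    ramp linearly from 1.0 (rest) toward it, later minutes add
    Normal(0, minute_noise_factor·SD) noise around it.
    """
    cfg = config or GeneratorConfig()
    if duration not in TRIAL_DURATION_CHOICES:
        raise ProtocolError(f"trial duration must be one of {TRIAL_DURATION_CHOICES}")
    dist = activity.met_distribution(participant.group)
    rng = np.random.default_rng(seed)
    steady = float(_truncnorm_rvs(rng, dist.mean, dist.sd, lower=cfg.met_floor))
    mets = np.empty(duration)
    for k in range(1, WARMUP_MINUTES + 1):
        mets[k - 1] = 1.0 + (steady - 1.0) * k / (WARMUP_MINUTES + 1)
    noise = rng.normal(0.0, cfg.minute_noise_factor * dist.sd, duration - WARMUP_MINUTES)
    mets[WARMUP_MINUTES:] = steady + noise
    return np.maximum(mets, cfg.met_floor)


def synthesize_accel_stream(
    true_met: float,
    cadence: float,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    config: GeneratorConfig | None = None,
    minute_start: datetime | None = None,
) -> MinuteWindow:
    """One minute of raw 2 Hz triaxial samples consistent with a MET level.

    The dominant axis carries a sinusoid at the cadence-derived frequency
    (capped below Nyquist) with amplitude ``amplitude_per_met·(MET − 1)``,
    clamped at zero; the other two axes carry the same oscillation at half
    amplitude with independent phases.  Gaussian jitter is added throughout,
    so a resting minute still shows a small jitter-driven ``pa_avg``.
    """
    cfg = config or GeneratorConfig()
    if true_met < cfg.met_floor:
        raise ValueError(f"true_met must be >= {cfg.met_floor}")
    rng = np.random.default_rng(seed)
    freq = cadence / 60.0 if cadence > 0 else cfg.default_sway_hz
    freq = min(freq, 0.95 * SAMPLE_HZ / 2.0)  # keep below Nyquist
    amplitude = max(cfg.amplitude_per_met * (true_met - 1.0), 0.0)
    t = np.arange(SAMPLES_PER_MINUTE) / SAMPLE_HZ
    phases = rng.uniform(0.0, 2.0 * math.pi, size=3)
    jitter = rng.normal(0.0, cfg.jitter_sd, size=(3, SAMPLES_PER_MINUTE))
    x = amplitude * np.sin(2 * math.pi * freq * t + phases[0]) + jitter[0]
    y = 0.5 * amplitude * np.sin(2 * math.pi * freq * t + phases[1]) + jitter[1]
    z = 0.5 * amplitude * np.sin(2 * math.pi * freq * t + phases[2]) + jitter[2]
    return MinuteWindow(t=t, x=x, y=y, z=z, minute_start=minute_start)


def trim_trial(minutes: Sequence[TrialMinute]) -> list[TrialMinute]:
    """Drop the three warm-up minutes and the final minute of one trial."""
    if len(minutes) < WARMUP_MINUTES + TRAILING_EXCLUDED_MINUTES + 1:
        raise ProtocolError(
            f"trial must span at least "
            f"{WARMUP_MINUTES + TRAILING_EXCLUDED_MINUTES + 1} minutes"
        )
    last = max(m.minute_index for m in minutes)
    return [m for m in minutes if WARMUP_MINUTES < m.minute_index < last]


def exclude_invalid(minutes: Sequence[TrialMinute]) -> list[TrialMinute]:
    """Keep only minutes that were worn, metabolically stable, and recorded."""
    return [
        m
        for m in minutes
        if m.worn
        and m.stable
        and m.record is not None
        and np.isfinite([m.record.pa_avg, m.record.pa_var, m.record.steps]).all()
    ]


def split_participants(
    participants: Sequence[ParticipantProfile],
    train_fraction: float = 0.7,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> dict[str, str]:
    """Participant-level random train/test split (train size rounds half up)."""
    if len(participants) < 2:
        raise ValueError("need at least two participants to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = [p.id for p in participants]
    order = rng.permutation(len(ids))
    n_train = int(math.floor(len(ids) * train_fraction + 0.5))
    train = {ids[i] for i in order[:n_train]}
    return {pid: ("train" if pid in train else "test") for pid in ids}


def _draw_light_fields(rng) -> dict[str, float]:
    lux = rng.uniform(50.0, 500.0, size=3)
    uv = rng.uniform(0.0, 2.0, size=3)
    return {
        "lux1": round(float(lux[0]), 1),
        "lux2": round(float(lux[1]), 1),
        "lux3": round(float(lux[2]), 1),
        "uv1": round(float(uv[0]), 2),
        "uv2": round(float(uv[1]), 2),
        "uv3": round(float(uv[2]), 2),
    }


def generate_study(
    group: str,
    n: int | None = None,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> StudyDataset:
    """Simulate a complete study for one group.

    Every participant performs the group's full protocol in order; each trial
    draws its duration uniformly from 14–16 minutes.  Per-minute watch
    records are produced by running the real feature extractor on the
    synthesized raw stream, so the generated data exercise the same code path
    as field data.
    """
    cfg = config or GeneratorConfig()
    n = DEFAULT_N[group] if n is None else n
    root = np.random.SeedSequence(seed)
    demo_ss, split_ss, trials_ss = root.spawn(3)
    participants = simulate_participants(n, group, seed=demo_ss)
    split = split_participants(participants, cfg.train_fraction, seed=split_ss)

    protocol = [
        a for a in cfg.protocol if a.mets.get(group) is not None
    ]
    minutes: list[TrialMinute] = []
    per_participant = trials_ss.spawn(n)
    for p, pss in zip(participants, per_participant):
        rng = np.random.default_rng(pss)
        clock = datetime(2024, 1, 1, 8, 0)
        for activity in protocol:
            duration = int(rng.choice(TRIAL_DURATION_CHOICES))
            mets = simulate_true_mets(p, activity, duration, seed=rng, config=cfg)
            for idx in range(1, duration + 1):
                window = synthesize_accel_stream(
                    float(mets[idx - 1]),
                    activity.cadence,
                    seed=rng,
                    config=cfg,
                    minute_start=clock,
                )
                worn = bool(rng.random() >= cfg.p_not_worn)
                stable = bool(rng.random() >= cfg.p_unstable)
                record = None
                if worn:
                    feats = extract_minute_features(window)
                    record = MinuteRecord(
                        participant_id=p.id,
                        timestamp=clock,
                        pa_avg=feats.pa_avg,
                        pa_var=feats.pa_var,
                        steps=feats.steps,
                        wear_status="worn",
                        **_draw_light_fields(rng),
                    )
                minutes.append(
                    TrialMinute(
                        participant_id=p.id,
                        activity=activity.name,
                        minute_index=idx,
                        true_met=float(mets[idx - 1]),
                        window=window,
                        record=record,
                        stable=stable,
                        worn=worn,
                    )
                )
                clock += timedelta(minutes=1)
            clock += timedelta(minutes=5)  # inter-trial rest, not recorded
    return StudyDataset(
        group=group, participants=participants, minutes=minutes, split=split, seed=seed
    )
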