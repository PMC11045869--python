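"""Shared fixtures: a small simulated study, a trained model, and a
noiseless linearly-realizable study construction used for exact-recovery
tests."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import settings

from wristmet.io import MinuteRecord
from wristmet.met_model import train
from wristmet.synthetic_trials import (
    ParticipantProfile,
    TrialMinute,
    generate_study,
    split_participants,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def adult_study():
    return generate_study("adult", n=8, seed=7)


@pytest.fixture(scope="session")
def trained_adult(adult_study):
    model = train(adult_study.train_minutes(), adult_study.participants, seed=7)
    return model


def make_linear_study(
    n_participants: int = 8,
    minutes_per_class: int = 12,
    seed: int = 0,
    intercept: float = 0.8,
    slope: float = 2.0,
):
    """A study in which the true MET is an exact linear function of
    log(1 + pa_avg) and the three intensity classes are separated with a
    margin in that feature, so both model stages are exactly realizable.

    Returns (train_minutes, test_minutes, participants, (intercept, slope)).
    """
    rng = np.random.default_rng(seed)
    participants = [
        ParticipantProfile(
            id=f"p{i:02d}",
            group="adult",
            gender="male" if i % 2 == 0 else "female",
            age=25.0 + i,
            height_cm=165.0 + i,
            weight_kg=60.0 + 0.5 * i,
        )
        for i in range(n_participants)
    ]
    # log1p(pa_avg) bands per class, mapping through met = a + b*log1p(pa_avg)
    # into SED (<=1.49), LPA (1.50-2.99), MVPA (>=3.00) with safety margins
    bands = {"SED": (0.03, 0.30), "LPA": (0.42, 1.05), "MVPA": (1.22, 2.90)}
    minutes = []
    for p in participants:
        clock = datetime(2024, 1, 1, 9, 0)
        for cls, (lo, hi) in bands.items():
            for j in range(minutes_per_class):
                log_pa = rng.uniform(lo, hi)
                pa_avg = float(np.expm1(log_pa))
                met = intercept + slope * log_pa
                rec = MinuteRecord(
                    participant_id=p.id,
                    timestamp=clock,
                    pa_avg=pa_avg,
                    pa_var=0.5 * pa_avg,
                    steps=int(round(30 * pa_avg)),
                    lux1=100.0,
                    lux2=100.0,
                    lux3=100.0,
                    uv1=0.5,
                    uv2=0.5,
                    uv3=0.5,
                    wear_status="worn",
                )
                minutes.append(
                    TrialMinute(
                        participant_id=p.id,
                        activity=cls.lower(),
                        minute_index=j + 4,
                        true_met=met,
                        window=None,
                        record=rec,
                        stable=True,
                        worn=True,
                    )
                )
                clock += timedelta(minutes=1)
    split = split_participants(participants, 0.7, seed=seed + 1)
    train_minutes = [m for m in minutes if split[m.participant_id] == "train"]
    test_minutes = [m for m in minutes if split[m.participant_id] == "test"]
    return train_minutes, test_minutes, participants, (intercept, slope)
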