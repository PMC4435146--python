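"""Laboratory activity protocols and ACSM metabolic arithmetic.

The calibration study uses a standardized protocol — lying, sitting,
standing, then treadmill walking, treadmill running, ergometer cycling and
stair walking at three intensities each — to relate accelerometer counts
per minute (CPM) to energy expenditure measured by indirect calorimetry.
Intensity targets were chosen with the ACSM metabolic equations so that all
participants reach a metabolic steady state at the top intensity of each
activity type.

This module encodes the protocol (bout order, durations, sex-specific
targets, measurement windows) and the ACSM oxygen-uptake arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import yaml

__all__ = [
    "Activity",
    "STATIONARY_ACTIVITIES",
    "DYNAMIC_ACTIVITIES",
    "FEMALE",
    "MALE",
    "Bout",
    "Participant",
    "acsm_running_vo2",
    "acsm_cycling_vo2",
    "met_from_vo2",
    "build_standardized_protocol",
    "protocol_to_yaml",
    "protocol_from_yaml",
]


class Activity(str, Enum):
    """The seven protocol activity types plus the classifier's 'move' bin."""

    LYING = "lying"
    SITTING = "sitting"
    STANDING = "standing"
    WALKING = "walking"
    RUNNING = "running"
    CYCLING = "cycling"
    STAIRS = "stairs"
    MOVE = "move"


STATIONARY_ACTIVITIES = (Activity.LYING, Activity.SITTING, Activity.STANDING)
DYNAMIC_ACTIVITIES = (
    Activity.WALKING,
    Activity.RUNNING,
    Activity.CYCLING,
    Activity.STAIRS,
)

#: Sex coding used throughout, matching the cycling regression covariate.
FEMALE = 1
MALE = 2

#: Vertical rise of one stair step used in the protocol (m).
STAIR_STEP_HEIGHT_M = 0.173

#: Treadmill inclination for all walking and running bouts (fraction).
TREADMILL_GRADE = 0.01

#: Stairs measurement-window lengths (s) per cadence (steps/min), chosen so
#: an equal number of ascending and descending steps falls in the window.
STAIRS_WINDOW_S = {50: 115, 70: 110, 90: 128}

#: Default measurement window for non-stairs bouts: the last 2 minutes.
DEFAULT_WINDOW_S = 120


@dataclass(frozen=True)
class Participant:
    """One study participant. ``sex`` uses 1 = female, 2 = male."""

    id: str
    sex: int
    body_mass_kg: float
    height_cm: float = 170.0
    age_years: float = 28.0

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be {FEMALE} (female) or {MALE} (male)")
        if self.body_mass_kg <= 0:
            raise ValueError("body_mass_kg must be positive")


@dataclass(frozen=True)
class Bout:
    """One timed activity bout within a protocol.

    ``target`` carries the prescribed intensity in ``target_unit``
    (km/h for treadmill, rpm for the ergometer, steps/min for stairs);
    stationary bouts have intensity_index 0 and no target.
    ``window_before_end_s`` gives the measurement window as the
    (start, end) offsets in seconds counted back from the bout end, e.g.
    (120, 0) means "the last two minutes".
    """

    activity: Activity
    intensity_index: int
    duration_s: int
    target: float | None = None
    target_unit: str | None = None
    window_before_end_s: tuple[int, int] = (DEFAULT_WINDOW_S, 0)
    #: extra prescription details (cycling resistance, treadmill grade ...)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        w0, w1 = self.window_before_end_s
        if not (0 <= w1 < w0 <= self.duration_s):
            raise ValueError("measurement window must lie within the bout")
        if self.activity in STATIONARY_ACTIVITIES and self.intensity_index != 0:
            raise ValueError("stationary bouts have intensity_index 0")
        if self.activity in DYNAMIC_ACTIVITIES and self.intensity_index not in (1, 2, 3):
            raise ValueError("dynamic bouts have intensity_index in {1,2,3}")

    def window_abs(self, bout_start_s: float) -> tuple[float, float]:
        """Measurement window as absolute (start, end) given the bout start."""
        w0, w1 = self.window_before_end_s
        end = bout_start_s + self.duration_s
        return (end - w0, end - w1)


# ---------------------------------------------------------------------------
# ACSM metabolic equations
# ---------------------------------------------------------------------------

def acsm_running_vo2(speed_m_per_min: float, grade: float = 0.0) -> float:
    """ACSM running oxygen uptake (mL O2/kg/min).

    VO2 = 0.2·speed + 0.9·speed·grade + 3.5, with speed in m/min and grade
    as a fraction (1% = 0.01). The resting component of 3.5 mL/kg/min is
    included, so speed 0 returns 3.5.
    """
    if speed_m_per_min < 0:
        raise ValueError("speed must be non-negative")
    if not 0 <= grade < 1:
        raise ValueError("grade must be a fraction in [0, 1)")
    return 0.2 * speed_m_per_min + 0.9 * speed_m_per_min * grade + 3.5


def acsm_cycling_vo2(
    resistance_kp_per_kg: float, rpm: float, meters_per_rev: float = 6.0
) -> float:
    """ACSM leg-cycling oxygen uptake (mL O2/kg/min).

    With brake resistance expressed per kg of body mass (kp/kg), body mass
    cancels out of the work-rate term:

        VO2 = 1.8 · (resistance·rpm·meters_per_rev) + 3.5 + 3.5

    The two 3.5 terms are rest and unloaded cycling. The 6 m of flywheel
    travel per pedal revolution is the Monark ergometer convention.
    """
    if resistance_kp_per_kg < 0 or rpm < 0 or meters_per_rev < 0:
        raise ValueError("arguments must be non-negative")
    return 1.8 * resistance_kp_per_kg * rpm * meters_per_rev + 7.0


def met_from_vo2(vo2_ml_kg_min: float) -> float:
    """Convert oxygen uptake to MET at the conventional 3.5 mL/kg/min per MET."""
    if vo2_ml_kg_min < 0:
        raise ValueError("VO2 must be non-negative")
    return vo2_ml_kg_min / 3.5


# ---------------------------------------------------------------------------
# Protocol construction
# ---------------------------------------------------------------------------

WALKING_SPEEDS_KMH = (4.0, 5.0, 6.0)
RUNNING_SPEEDS_KMH = {FEMALE: (7.0, 8.0, 9.0), MALE: (7.0, 8.5, 10.0)}
CYCLING_RPM = (70, 85, 100)
CYCLING_RESISTANCE_KP_PER_KG = {FEMALE: 0.016, MALE: 0.02}
STAIRS_STEPS_PER_MIN = (50, 70, 90)

LYING_DURATION_S = 720
BOUT_DURATION_S = 300


def build_standardized_protocol(participant: Participant) -> list[Bout]:
    """The 15-bout standardized calibration protocol, in performance order.

    Lying (12 min), sitting, standing, then walking, running, cycling and
    stairs at three intensities each (5 min per bout). Running speeds and
    cycling resistance are sex-specific; the measurement window is the last
    2 min of each bout except stairs, which use cadence-specific windows to
    balance ascending and descending steps.
    """
    bouts: list[Bout] = [
        Bout(Activity.LYING, 0, LYING_DURATION_S),
        Bout(Activity.SITTING, 0, BOUT_DURATION_S),
        Bout(Activity.STANDING, 0, BOUT_DURATION_S),
    ]
    for i, speed in enumerate(WALKING_SPEEDS_KMH, start=1):
        bouts.append(
            Bout(
                Activity.WALKING,
                i,
                BOUT_DURATION_S,
                target=speed,
                target_unit="km/h",
                extras={"grade": TREADMILL_GRADE,
                        "vo2_target": acsm_running_vo2(speed * 1000 / 60)},
            )
        )
    for i, speed in enumerate(RUNNING_SPEEDS_KMH[participant.sex], start=1):
        bouts.append(
            Bout(
                Activity.RUNNING,
                i,
                BOUT_DURATION_S,
                target=speed,
                target_unit="km/h",
                extras={"grade": TREADMILL_GRADE,
                        "vo2_target": acsm_running_vo2(speed * 1000 / 60)},
            )
        )
    resistance = CYCLING_RESISTANCE_KP_PER_KG[participant.sex]
    for i, rpm in enumerate(CYCLING_RPM, start=1):
        bouts.append(
            Bout(
                Activity.CYCLING,
                i,
                BOUT_DURATION_S,
                target=float(rpm),
                target_unit="rpm",
                extras={
                    "resistance_kp": resistance * participant.body_mass_kg,
                    "vo2_target": acsm_cycling_vo2(resistance, rpm),
                },
            )
        )
    for i, spm in enumerate(STAIRS_STEPS_PER_MIN, start=1):
        bouts.append(
            Bout(
                Activity.STAIRS,
                i,
                BOUT_DURATION_S,
                target=float(spm),
                target_unit="steps/min",
                window_before_end_s=(STAIRS_WINDOW_S[spm], 0),
                extras={"step_height_m": STAIR_STEP_HEIGHT_M},
            )
        )
    return bouts


# ---------------------------------------------------------------------------
# Serialization (shared by the simulator and the CLI)
# ---------------------------------------------------------------------------

def protocol_to_yaml(bouts: Sequence[Bout]) -> str:
    """Serialize a bout list to YAML."""
    payload = [
        {
            "activity": b.activity.value,
            "intensity_index": b.intensity_index,
            "duration_s": b.duration_s,
            "target": b.target,
            "target_unit": b.target_unit,
            "window_before_end_s": list(b.window_before_end_s),
            "extras": b.extras,
        }
        for b in bouts
    ]
    return yaml.safe_dump(payload, sort_keys=False)


def protocol_from_yaml(text: str) -> list[Bout]:
    """Inverse of :func:`protocol_to_yaml`."""
    payload = yaml.safe_load(text)
    return [
        Bout(
            activity=Activity(d["activity"]),
            intensity_index=int(d["intensity_index"]),
            duration_s=int(d["duration_s"]),
            target=d.get("target"),
            target_unit=d.get("target_unit"),
            window_before_end_s=tuple(d["window_before_end_s"]),
            extras=d.get("extras") or {},
        )
        for d in payload
    ]
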