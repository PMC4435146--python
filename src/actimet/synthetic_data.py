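"""Synthetic dual-site accelerometry, heart rate and reference EE.

No public recordings exist for this kind of dual-site (thigh + hip)
calibration protocol, so this module generates them with the statistical
structure the downstream method assumes:

* raw acceleration per site = posture gravity vector + an activity-specific
  sinusoid (frequency set by the prescribed speed/cadence, amplitude rising
  with intensity) + white Gaussian noise. Postures separate by inclination,
  movement by signal SD — exactly the features the classifier uses. Stair
  walking additionally carries a slow (0.25 Hz) forward/backward pitch wave
  emulating alternating ascent/descent.
* reference energy expenditure is generated per bout from a ground-truth
  linear CPM→MET map (defaults: the published thigh-site regression bank)
  evaluated at the bout's *realized* CPM as computed by this package's own
  counts pipeline, plus optional Gaussian residual. Calibrating on a
  noiseless cohort therefore recovers the generating lines exactly.
* heart rate is an affine function of MET, HR = 60 + 22·(MET−1) + N(0,3),
  clipped to [40, 200] bpm — needed only for the sleeping-heart-rate rule
  and the external-estimate ingestion path.

Bout transitions get a 3–8 s linear cross-fade of posture vectors; those
seconds are marked 'transition' in the ground-truth labels and excluded
from classifier accuracy scoring.

Thigh-site sinusoid amplitudes (g) were anchored so that the realized CPM
of this counts pipeline at each prescribed intensity lands where the
published thigh regressions map the corresponding group-mean METs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import REGRESSION_BANK, STATIONARY_MET_MEANS, ActivityRegression
from .protocol import (
    Activity,
    Bout,
    Participant,
    FEMALE,
    MALE,
    STATIONARY_ACTIVITIES,
    DYNAMIC_ACTIVITIES,
    RUNNING_SPEEDS_KMH,
    WALKING_SPEEDS_KMH,
    CYCLING_RPM,
    CYCLING_RESISTANCE_KP_PER_KG,
    STAIRS_STEPS_PER_MIN,
)
from .signal_features import (
    AccelRecording,
    bout_average_cpm,
    calibration_cpm_window,
    compute_counts,
)

__all__ = [
    "SignalModel",
    "GroundTruthEEModel",
    "SimulatedRecording",
    "generate_participant_recording",
    "generate_semi_standardized_schedule",
    "default_cohort",
    "simulate_cohort",
    "cohort_bout_table",
]


# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------

#: Static gravity reading (unit g) per (activity, site); x points down the
#: body segment, z anterior. Upright segment → (1,0,0); horizontal → (0,0,1).
POSTURES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("lying", "thigh"): (0.0, 0.0, 1.0),
    ("lying", "hip"): (0.0, 0.0, 1.0),
    ("sitting", "thigh"): (0.0, 0.0, 1.0),
    ("sitting", "hip"): (1.0, 0.0, 0.0),
    ("standing", "thigh"): (1.0, 0.0, 0.0),
    ("standing", "hip"): (1.0, 0.0, 0.0),
    ("walking", "thigh"): (1.0, 0.0, 0.0),
    ("walking", "hip"): (1.0, 0.0, 0.0),
    ("running", "thigh"): (1.0, 0.0, 0.0),
    ("running", "hip"): (1.0, 0.0, 0.0),
    ("stairs", "thigh"): (1.0, 0.0, 0.0),
    ("stairs", "hip"): (1.0, 0.0, 0.0),
    # mid-stroke pedalling posture: thigh ~50 deg off vertical, trunk upright
    ("cycling", "thigh"): (0.6428, 0.0, 0.766),
    ("cycling", "hip"): (1.0, 0.0, 0.0),
}

#: Thigh sinusoid amplitude (g) per (activity, intensity_index). Anchored to
#: the published thigh regressions at the study's group-mean METs (see
#: module docstring); values are model defaults, not measured quantities.
THIGH_AMPLITUDE_G: dict[tuple[str, int], float] = {
    ("walking", 1): 0.213,
    ("walking", 2): 0.338,
    ("walking", 3): 0.587,
    ("running", 1): 0.937,
    ("running", 2): 1.735,
    ("running", 3): 2.928,
    ("cycling", 1): 0.436,
    ("cycling", 2): 0.596,
    ("cycling", 3): 0.859,
    ("stairs", 1): 0.13,
    ("stairs", 2): 0.276,
    ("stairs", 3): 0.509,
}

#: Fraction of the sinusoid amplitude placed on the anterior (z) axis.
Z_FRACTION = {"walking": 0.15, "running": 0.15, "cycling": 0.6, "stairs": 0.3}


def gait_frequency_hz(activity: str, target: float | None) -> float:
    """Fundamental signal frequency from the prescribed intensity target:
    0.3 Hz per km/h on the treadmill, cadence/60 for cycling and stairs."""
    if target is None:
        return 0.0
    if activity in ("walking", "running"):
        return 0.3 * target
    return target / 60.0  # rpm or steps/min


@dataclass
class SignalModel:
    """Parametric raw-signal generator settings."""

    fs: float = 30.0
    noise_sd_g: float = 0.03
    hip_amplitude_fraction: float = 0.6
    cycling_hip_amplitude_g: float = 0.05
    #: slow forward/backward pitch wave during stair walking
    stairs_pitch_amp_deg: float = 22.0
    stairs_pitch_hz: float = 0.25
    #: between-subject multiplicative spread of movement amplitude
    subject_amplitude_sd: float = 0.06
    transition_s: tuple[int, int] = (3, 8)
    postures: dict = field(default_factory=lambda: dict(POSTURES))
    amplitudes: dict = field(default_factory=lambda: dict(THIGH_AMPLITUDE_G))

    @classmethod
    def noiseless(cls) -> "SignalModel":
        """Deterministic signals: no sensor noise, no between-subject
        amplitude spread, fixed-length (5 s) transitions."""
        return cls(noise_sd_g=0.0, subject_amplitude_sd=0.0, transition_s=(5, 5))


@dataclass
class GroundTruthEEModel:
    """Ground-truth linear CPM→MET maps used to generate reference EE.

    ``site`` names the site whose realized CPM drives EE. ``residual_sd``
    maps activity → bout-level Gaussian residual SD (MET); the default uses
    each published regression's SEE. Stationary postures get per-subject
    fixed METs drawn around the published group means.
    """

    site: str = "thigh"
    regressions: dict[Activity, ActivityRegression] = field(
        default_factory=lambda: dict(REGRESSION_BANK["thigh"])
    )
    residual_sd: dict[str, float] = field(default_factory=dict)
    stationary_means: dict[Activity, float] = field(
        default_factory=lambda: dict(STATIONARY_MET_MEANS)
    )
    stationary_sds: dict[Activity, float] = field(
        default_factory=lambda: {
            Activity.LYING: 0.20,
            Activity.SITTING: 0.10,
            Activity.STANDING: 0.11,
        }
    )

    def __post_init__(self) -> None:
        if not self.residual_sd:
            self.residual_sd = {
                a.value: self.regressions[a].see for a in DYNAMIC_ACTIVITIES
            }
        for a in DYNAMIC_ACTIVITIES:
            if self.regressions[a].slope < 0:
                raise ValueError("ground-truth slopes must be non-negative")
        if any(v < 0 for v in self.residual_sd.values()):
            raise ValueError("residual SD must be non-negative")

    @classmethod
    def noiseless(cls) -> "GroundTruthEEModel":
        m = cls()
        m.residual_sd = {a.value: 0.0 for a in DYNAMIC_ACTIVITIES}
        m.stationary_sds = {a: 0.0 for a in STATIONARY_ACTIVITIES}
        return m


# ---------------------------------------------------------------------------
# Recording generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRecording:
    """Everything one simulated session produces, on a shared clock."""

    participant: Participant
    bouts: list[Bout]
    bout_starts_s: list[float]
    thigh: AccelRecording
    hip: AccelRecording
    hr: pd.DataFrame        # time_s, bpm (1 Hz)
    ee: pd.DataFrame        # time_s, met (1 Hz reference EE)
    truth_labels: pd.DataFrame  # second, label ('transition' during fades)
    bout_frame: pd.DataFrame    # per-bout realized CPM + reference MET


def _bout_site_signal(
    bout: Bout,
    site: str,
    n: int,
    fs: float,
    model: SignalModel,
    amp_factor: float,
) -> np.ndarray:
    """Noise-free signal for one bout at one site (n samples)."""
    act = bout.activity.value
    posture = np.asarray(model.postures[(act, site)], dtype=float)
    t = np.arange(n) / fs
    sig = np.tile(posture, (n, 1))

    if bout.activity == Activity.STAIRS:
        # slow pitch wave: rotate the posture vector in the x–z plane
        pitch = np.radians(model.stairs_pitch_amp_deg) * np.sin(
            2 * np.pi * model.stairs_pitch_hz * t
        )
        sig[:, 0] = np.cos(pitch) * posture[0] - np.sin(pitch) * posture[2]
        sig[:, 2] = np.sin(pitch) * posture[0] + np.cos(pitch) * posture[2]

    if bout.activity in DYNAMIC_ACTIVITIES:
        if bout.activity == Activity.CYCLING and site == "hip":
            amp = model.cycling_hip_amplitude_g
        else:
            amp = model.amplitudes[(act, bout.intensity_index)] * amp_factor
            if site == "hip":
                amp *= model.hip_amplitude_fraction
        f = gait_frequency_hz(act, bout.target)
        zf = Z_FRACTION[act]
        wave = np.sin(2 * np.pi * f * t)
        sig[:, 0] += amp * np.sqrt(1 - zf**2) * wave
        sig[:, 2] += amp * zf * wave
    return sig


def _generation_cpm_window(
    bout: Bout, start_s: float, fade_s: int
) -> tuple[float, float]:
    """Window whose mean CPM drives the bout's ground-truth EE.

    Standardized-length bouts use the calibration conventions (stairs: the
    cadence-specific window; others: bout minus first/last 30 s); short
    self-paced bouts use everything after the transition fade.
    """
    if bout.duration_s >= 90:
        return calibration_cpm_window(bout, start_s)
    return (start_s + fade_s, start_s + bout.duration_s)


def generate_participant_recording(
    participant: Participant,
    protocol: list[Bout],
    signal_model: SignalModel | None = None,
    ee_model: GroundTruthEEModel | None = None,
    seed: int = 0,
) -> SimulatedRecording:
    """Simulate one session: dual-site acceleration, HR, reference EE.

    Deterministic for a fixed (participant, protocol, models, seed).
    """
    if not protocol:
        raise ValueError("empty protocol")
    sm = signal_model or SignalModel()
    em = ee_model or GroundTruthEEModel()
    rng = np.random.default_rng(seed)

    amp_factor = float(
        np.clip(1.0 + sm.subject_amplitude_sd * rng.standard_normal(), 0.7, 1.3)
    )
    fixed_mets = {
        a: max(0.5, em.stationary_means[a] + em.stationary_sds[a] * rng.standard_normal())
        for a in STATIONARY_ACTIVITIES
    }

    fs = sm.fs
    starts: list[float] = []
    fades: list[int] = []
    t_cursor = 0.0
    chunks = {"thigh": [], "hip": []}
    for i, bout in enumerate(protocol):
        starts.append(t_cursor)
        fade = 0 if i == 0 else int(rng.integers(sm.transition_s[0],
                                                 sm.transition_s[1] + 1))
        fades.append(fade)
        n = int(round(bout.duration_s * fs))
        for site in ("thigh", "hip"):
            sig = _bout_site_signal(bout, site, n, fs, sm, amp_factor)
            if fade > 0:
                prev = protocol[i - 1]
                prev_post = np.asarray(
                    sm.postures[(prev.activity.value, site)], dtype=float
                )
                nf = int(round(fade * fs))
                w = np.linspace(0.0, 1.0, nf, endpoint=False)[:, None]
                sig[:nf] = (1 - w) * prev_post + w * sig[:nf]
            chunks[site].append(sig)
        t_cursor += bout.duration_s

    total_n = sum(len(c) for c in chunks["thigh"])
    time = np.arange(total_n) / fs
    recs = {}
    for site in ("thigh", "hip"):
        sig = np.concatenate(chunks[site], axis=0)
        if sm.noise_sd_g > 0:
            sig = sig + rng.normal(0.0, sm.noise_sd_g, size=sig.shape)
        recs[site] = AccelRecording(
            site=site,
            fs=fs,
            data=pd.DataFrame(
                {"time_s": time, "x_g": sig[:, 0], "y_g": sig[:, 1],
                 "z_g": sig[:, 2]}
            ),
        )

    # realized CPM per bout on both sites, via the package's own pipeline
    epochs = {s: compute_counts(recs[s]) for s in ("thigh", "hip")}
    rows = []
    total_s = int(round(t_cursor))
    ee_sec = np.empty(total_s)
    truth = np.empty(total_s, dtype=object)
    for bout, start, fade in zip(protocol, starts, fades):
        win = _generation_cpm_window(bout, start, fade)
        cpm = {s: bout_average_cpm(epochs[s], window=win) for s in ("thigh", "hip")}
        if bout.activity in STATIONARY_ACTIVITIES:
            met = fixed_mets[bout.activity]
        else:
            reg = em.regressions[bout.activity]
            met = float(reg.predict(cpm[em.site], sex=participant.sex))
            sd = em.residual_sd[bout.activity.value]
            if sd > 0:
                met += float(rng.normal(0.0, sd))
            met = max(met, 0.1)
        a, b = int(round(start)), int(round(start + bout.duration_s))
        ee_sec[a:b] = met
        truth[a:b] = bout.activity.value
        truth[a : a + fade] = "transition"
        rows.append(
            {
                "subject": participant.id,
                "sex": participant.sex,
                "activity": bout.activity.value,
                "intensity_index": bout.intensity_index,
                "bout_start_s": start,
                "duration_s": bout.duration_s,
                "cpm_thigh": cpm["thigh"],
                "cpm_hip": cpm["hip"],
                "met": met,
            }
        )

    sec = np.arange(total_s, dtype=float)
    hr = 60.0 + 22.0 * (ee_sec - 1.0) + rng.normal(0.0, 3.0, size=total_s)
    hr = np.clip(hr, 40.0, 200.0)
    return SimulatedRecording(
        participant=participant,
        bouts=list(protocol),
        bout_starts_s=starts,
        thigh=recs["thigh"],
        hip=recs["hip"],
        hr=pd.DataFrame({"time_s": sec, "bpm": hr}),
        ee=pd.DataFrame({"time_s": sec, "met": ee_sec}),
        truth_labels=pd.DataFrame({"second": sec, "label": truth}),
        bout_frame=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Semi-standardized schedule
# ---------------------------------------------------------------------------

def _random_durations(rng, n_bouts: int, total_s: int, min_bout_s: int) -> np.ndarray:
    slack = total_s - n_bouts * min_bout_s
    weights = rng.dirichlet(np.ones(n_bouts))
    extra = np.floor(weights * slack).astype(int)
    extra[0] += slack - extra.sum()
    return min_bout_s + extra


def _shuffle_no_adjacent(rng, items: list) -> list:
    for _ in range(100):
        order = list(rng.permutation(len(items)))
        acts = [items[i][0] for i in order]
        if all(acts[j] != acts[j + 1] for j in range(len(acts) - 1)):
            return [items[i] for i in order]
    return [items[i] for i in order]  # give up; adjacency is cosmetic


def generate_semi_standardized_schedule(
    seed: int,
    sex: int = FEMALE,
    body_mass_kg: float = 68.2,
    stationary_s: int = 600,
    physical_s: int = 1200,
    min_bout_s: int = 30,
) -> list[Bout]:
    """A self-paced 30-min schedule: 10 min of lying/sitting/standing, then
    20 min of walking/running/cycling/stairs, every activity appearing at
    least twice, every bout at least 30 s, order and durations randomized.
    Intensity targets are drawn from the standardized prescription levels.
    """
    rng = np.random.default_rng(seed)
    schedule: list[Bout] = []

    for acts, total in (
        (STATIONARY_ACTIVITIES, stationary_s),
        (DYNAMIC_ACTIVITIES, physical_s),
    ):
        reps = [(a, r) for a in acts for r in range(2)]
        extra_n = int(rng.integers(0, len(acts)))
        reps += [(rng.choice([a.value for a in acts]), None) for _ in range(extra_n)]
        reps = [(a if isinstance(a, Activity) else Activity(a), r) for a, r in reps]
        durations = _random_durations(rng, len(reps), total, min_bout_s)
        items = list(zip([a for a, _ in reps], durations.tolist()))
        items = _shuffle_no_adjacent(rng, items)
        for act, dur in items:
            if act in STATIONARY_ACTIVITIES:
                schedule.append(
                    Bout(act, 0, int(dur), window_before_end_s=(int(dur), 0))
                )
                continue
            level = int(rng.integers(1, 4))
            if act == Activity.WALKING:
                target, unit = WALKING_SPEEDS_KMH[level - 1], "km/h"
            elif act == Activity.RUNNING:
                target, unit = RUNNING_SPEEDS_KMH[sex][level - 1], "km/h"
            elif act == Activity.CYCLING:
                target, unit = float(CYCLING_RPM[level - 1]), "rpm"
            else:
                target, unit = float(STAIRS_STEPS_PER_MIN[level - 1]), "steps/min"
            extras = {}
            if act == Activity.CYCLING:
                extras["resistance_kp"] = (
                    CYCLING_RESISTANCE_KP_PER_KG[sex] * body_mass_kg
                )
            schedule.append(
                Bout(act, level, int(dur), target=target, target_unit=unit,
                     window_before_end_s=(int(dur), 0), extras=extras)
            )
    return schedule


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def default_cohort(
    n_female: int = 8, n_male: int = 6, seed: int = 0
) -> list[Participant]:
    """A cohort mirroring the study sample: 8 women (~63.3 ± 7.6 kg) and
    6 men (~73.8 ± 5.5 kg), 20–40 years."""
    rng = np.random.default_rng(seed)
    people = []
    for i in range(n_female):
        people.append(
            Participant(
                id=f"F{i+1:02d}", sex=FEMALE,
                body_mass_kg=float(np.clip(rng.normal(63.3, 7.6), 45, 90)),
                height_cm=float(rng.normal(165.5, 6.9)),
                age_years=float(np.clip(rng.normal(27.9, 4.6), 20, 40)),
            )
        )
    for i in range(n_male):
        people.append(
            Participant(
                id=f"M{i+1:02d}", sex=MALE,
                body_mass_kg=float(np.clip(rng.normal(73.8, 5.5), 55, 100)),
                height_cm=float(rng.normal(180.0, 3.6)),
                age_years=float(np.clip(rng.normal(27.6, 1.1), 20, 40)),
            )
        )
    return people


def simulate_cohort(
    participants: list[Participant],
    protocol_builder,
    signal_model: SignalModel | None = None,
    ee_model: GroundTruthEEModel | None = None,
    seed: int = 0,
) -> list[SimulatedRecording]:
    """Simulate every participant; ``protocol_builder(participant, subject_seed)``
    returns that subject's bout list. Per-subject seeds derive from ``seed``."""
    sims = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(participants)) % (2**31)
    for p, s in zip(participants, child_seeds):
        bouts = protocol_builder(p, int(s))
        sims.append(
            generate_participant_recording(p, bouts, signal_model, ee_model, int(s))
        )
    return sims


def cohort_bout_table(sims: list[SimulatedRecording], site: str) -> pd.DataFrame:
    """Stack per-bout rows across subjects into the calibration input table
    (columns subject, sex, activity, intensity_index, cpm, met)."""
    frames = []
    for sim in sims:
        f = sim.bout_frame.copy()
        f["cpm"] = f[f"cpm_{site}"]
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
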