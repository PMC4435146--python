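"""Activity-specific CPM→MET calibration, leave-one-subject-out.

The method's core: for each activity type performed in the standardized
protocol, ordinary least squares relates the trimmed-bout mean counts per
minute (CPM) to the energy expenditure (MET) measured by indirect
calorimetry. Cycling carries a sex covariate (1 = female, 2 = male) because
women and men pedalled against different resistances. Lying, sitting and
standing get fixed MET values instead of regressions. Calibration is
leave-one-subject-out (LOSO): the model applied to subject i is fit on all
other subjects, so no subject's estimate ever touches their own calibration
points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .protocol import Activity, STATIONARY_ACTIVITIES, DYNAMIC_ACTIVITIES

__all__ = [
    "ActivityRegression",
    "CalibrationModel",
    "REGRESSION_BANK",
    "fit_activity_regression",
    "loso_calibrate",
    "stationary_fixed_values",
    "standardized_bout_table",
    "sleeping_hr",
    "met_from_kcal",
]


@dataclass(frozen=True)
class ActivityRegression:
    """One CPM→MET line: MET = slope·CPM + sex_coefficient·sex + intercept."""

    activity: str
    slope: float
    intercept: float
    sex_coefficient: float = 0.0
    r2: float = float("nan")
    see: float = float("nan")
    n_points: int = 0

    def predict(self, cpm, sex: int | None = None):
        """Evaluate the line; ``sex`` is required when the sex term is used."""
        extra = 0.0
        if self.sex_coefficient != 0.0:
            if sex is None:
                raise ValueError(f"{self.activity} regression needs a sex value")
            extra = self.sex_coefficient * sex
        return self.slope * np.asarray(cpm, dtype=float) + extra + self.intercept


#: Published reference regressions (hip- and thigh-site banks) used as the
#: synthetic generator's ground truth defaults and in recovery tests.
#: Cycling uses the sex covariate (1 = female, 2 = male).
REGRESSION_BANK: dict[str, dict[Activity, ActivityRegression]] = {
    "hip": {
        Activity.WALKING: ActivityRegression("walking", 0.004, 2.003, 0.0, 0.64, 0.48),
        Activity.RUNNING: ActivityRegression("running", 0.002, 4.914, 0.0, 0.32, 0.92),
        Activity.CYCLING: ActivityRegression("cycling", 0.003, 5.293, 0.670, 0.26, 0.91),
        Activity.STAIRS: ActivityRegression("stairs", 0.003, 3.669, 0.0, 0.41, 0.61),
    },
    "thigh": {
        Activity.WALKING: ActivityRegression("walking", 0.003, 1.282, 0.0, 0.53, 0.53),
        Activity.RUNNING: ActivityRegression("running", 0.003, 2.889, 0.0, 0.61, 0.69),
        Activity.CYCLING: ActivityRegression("cycling", 0.003, -1.132, 1.094, 0.63, 0.64),
        Activity.STAIRS: ActivityRegression("stairs", 0.002, 3.187, 0.0, 0.09, 0.76),
    },
}

#: Group-mean resting METs for the three postures (cohort means measured by
#: indirect calorimetry); the synthetic generator draws around these.
STATIONARY_MET_MEANS = {
    Activity.LYING: 1.27,
    Activity.SITTING: 1.16,
    Activity.STANDING: 1.30,
}


@dataclass
class CalibrationModel:
    """Per-subject calibration bundle, tagged with the held-out subject."""

    held_out_subject_id: str
    site: str
    fixed_mets: dict[str, float]
    regressions: dict[str, ActivityRegression] = field(default_factory=dict)

    def __post_init__(self) -> None:
        needed = {a.value for a in DYNAMIC_ACTIVITIES}
        if set(self.regressions) != needed:
            raise ValueError(f"regressions must cover exactly {sorted(needed)}")
        if any(v <= 0 for v in self.fixed_mets.values()):
            raise ValueError("fixed METs must be positive")

    def to_json(self) -> str:
        payload = {
            "held_out_subject_id": self.held_out_subject_id,
            "site": self.site,
            "fixed_mets": self.fixed_mets,
            "regressions": {k: asdict(v) for k, v in self.regressions.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        regs = {k: ActivityRegression(**v) for k, v in d["regressions"].items()}
        return cls(d["held_out_subject_id"], d["site"], d["fixed_mets"], regs)


# ---------------------------------------------------------------------------
# Regression fitting
# ---------------------------------------------------------------------------

def fit_activity_regression(
    points: pd.DataFrame, activity: str, with_sex_term: bool = False
) -> ActivityRegression:
    """OLS fit of MET on CPM (and optionally sex) for one activity.

    ``points`` needs columns cpm, met and (when with_sex_term) sex. R² is
    the Pearson coefficient of determination of the fit; SEE is the residual
    standard deviation with denominator n − p (p = number of fitted
    parameters including the intercept).
    """
    n = len(points)
    p = 3 if with_sex_term else 2
    if n < p:
        raise ValueError(f"need at least {p} points, got {n}")
    cpm = points["cpm"].to_numpy(dtype=float)
    met = points["met"].to_numpy(dtype=float)
    if np.ptp(cpm) == 0:
        raise ValueError("degenerate design: all CPM values equal")
    cols = [cpm]
    if with_sex_term:
        sex = points["sex"].to_numpy(dtype=float)
        if np.ptp(sex) == 0:
            # single-sex data: the covariate is collinear with the intercept
            with_sex_term = False
            p = 2
        else:
            cols.append(sex)
    X = np.column_stack(cols + [np.ones(n)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design matrix")
    beta, *_ = np.linalg.lstsq(X, met, rcond=None)
    fitted = X @ beta
    resid = met - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((met - met.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    see = float(np.sqrt(ss_res / (n - p))) if n > p else 0.0
    return ActivityRegression(
        activity=activity,
        slope=float(beta[0]),
        sex_coefficient=float(beta[1]) if with_sex_term else 0.0,
        intercept=float(beta[-1]),
        r2=r2,
        see=see,
        n_points=n,
    )


def stationary_fixed_values(
    stationary: pd.DataFrame, subject_id: str, mode: str = "own_subject"
) -> dict[str, float]:
    """Fixed METs for lying/sitting/standing for one subject.

    ``stationary`` has one row per subject × posture with columns subject,
    activity, met. own_subject returns the subject's own measured values;
    loso_group_mean returns the mean over the other subjects.
    """
    if mode not in ("own_subject", "loso_group_mean"):
        raise ValueError(f"unknown mode: {mode}")
    out: dict[str, float] = {}
    for act in STATIONARY_ACTIVITIES:
        rows = stationary[stationary["activity"] == act.value]
        if mode == "own_subject":
            rows = rows[rows["subject"] == subject_id]
        else:
            rows = rows[rows["subject"] != subject_id]
        if rows.empty:
            raise ValueError(f"no {act.value} reference MET for mode {mode}")
        out[act.value] = float(rows["met"].mean())
    return out


def loso_calibrate(
    bout_table: pd.DataFrame,
    site: str,
    stationary_mode: str = "own_subject",
    cycling_sex_term: bool = True,
) -> dict[str, CalibrationModel]:
    """Leave-one-subject-out calibration over a standardized-protocol cohort.

    ``bout_table`` has one row per subject × bout: columns subject, sex,
    activity, cpm (trimmed-bout mean CPM; NaN allowed for stationary rows),
    met (reference MET from indirect calorimetry). Returns one
    :class:`CalibrationModel` per subject, each fit with that subject's rows
    excluded. With ``cycling_sex_term`` (default) cycling is one regression
    with the sex covariate; without it, cycling is fit separately per sex
    and each subject's model carries the line for their own sex.
    """
    subjects = list(pd.unique(bout_table["subject"]))
    if len(subjects) < 2:
        raise ValueError("LOSO calibration needs at least 2 subjects")
    stationary = bout_table[
        bout_table["activity"].isin([a.value for a in STATIONARY_ACTIVITIES])
    ]
    models: dict[str, CalibrationModel] = {}
    for sid in subjects:
        train = bout_table[bout_table["subject"] != sid]
        regs: dict[str, ActivityRegression] = {}
        for act in DYNAMIC_ACTIVITIES:
            pts = train[train["activity"] == act.value]
            if act == Activity.CYCLING and not cycling_sex_term:
                own_sex = bout_table.loc[bout_table["subject"] == sid, "sex"].iloc[0]
                pts = pts[pts["sex"] == own_sex]
                regs[act.value] = fit_activity_regression(pts, act.value, False)
            else:
                with_sex = cycling_sex_term and act == Activity.CYCLING
                regs[act.value] = fit_activity_regression(pts, act.value, with_sex)
        fixed = stationary_fixed_values(stationary, sid, stationary_mode)
        models[sid] = CalibrationModel(str(sid), site, fixed, regs)
    return models


def standardized_bout_table(
    epoch_table: pd.DataFrame,
    bouts,
    bout_starts_s,
    ee_1hz: pd.DataFrame,
    subject: str,
    sex: int,
) -> pd.DataFrame:
    """Build one subject's calibration points from pipeline outputs.

    For every bout of the standardized protocol, pairs the mean CPM over the
    calibration window (stairs: the cadence-specific window; others: bout
    minus first/last 30 s) with the reference MET averaged over the bout's
    EE measurement window (the last 2 min, or the stairs windows).
    """
    from .signal_features import bout_average_cpm, calibration_cpm_window

    t = ee_1hz["time_s"].to_numpy(dtype=float)
    met = ee_1hz["met"].to_numpy(dtype=float)
    rows = []
    for bout, start in zip(bouts, bout_starts_s):
        cpm = bout_average_cpm(
            epoch_table, window=calibration_cpm_window(bout, start)
        )
        w0, w1 = bout.window_abs(start)
        sel = (t >= w0 - 1e-9) & (t < w1 - 1e-9)
        if not sel.any():
            raise ValueError("EE measurement window contains no samples")
        rows.append(
            {
                "subject": subject,
                "sex": sex,
                "activity": bout.activity.value,
                "intensity_index": bout.intensity_index,
                "cpm": cpm,
                "met": float(met[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Utilities shared with the heart-rate and calorimetry branches
# ---------------------------------------------------------------------------

def sleeping_hr(lying_hr_1hz: np.ndarray | pd.Series, epoch_s: int = 60) -> float:
    """Predicted sleeping heart rate (bpm) from lying rest.

    The lowest mean over non-overlapping ``epoch_s`` epochs of the lying
    heart-rate series, reduced by 8% (resting → stage-4-sleep drop,
    e.g. 64 → 58.9 ≈ 59 bpm)."""
    hr = np.asarray(lying_hr_1hz, dtype=float)
    n_epochs = len(hr) // epoch_s
    if n_epochs == 0:
        raise ValueError(f"need at least one full {epoch_s}-s epoch")
    means = hr[: n_epochs * epoch_s].reshape(n_epochs, epoch_s).mean(axis=1)
    return float(means.min() * 0.92)


def met_from_kcal(
    kcal_per_h: float, body_mass_kg: float, device_mass_kg: float = 1.6
) -> float:
    """MET as kcal per hour per kg of (participant + worn-device) mass.

    The 1.6 kg default is the mass of the portable calorimeter carried
    during the protocols."""
    if body_mass_kg <= 0 or device_mass_kg < 0:
        raise ValueError("masses must be positive")
    if kcal_per_h < 0:
        raise ValueError("kcal_per_h must be non-negative")
    return kcal_per_h / (body_mass_kg + device_mass_kg)
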