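"""Per-epoch and per-period energy-expenditure estimators.

Three routes into a common :class:`EEEstimate` container:

* :func:`estimate_acti4` — the activity-type-aware method: each 10-s epoch
  gets its dominant activity label; stationary epochs receive the subject's
  fixed METs, dynamic epochs the activity-specific CPM→MET regression (with
  the sex covariate for cycling), and 'move' epochs fall back to the walking
  regression.
* :func:`estimate_activpal` — the fixed-MET + cadence method used by a
  thigh-worn posture monitor: lying/sitting 1.0 MET, standing 1.4 MET,
  stepping MET = 0.0186·(steps/min) + 1.4.
* :func:`ingest_external_estimates` — wraps per-epoch MET produced by any
  external algorithm (e.g. proprietary heart-rate branched models) so it can
  enter the agreement statistics unchanged.

Period summaries are time-weighted MET means over the stationary (first
10 min), physical (last 20 min) and total (30 min) windows; with uniform
epochs this equals summing kcal per epoch and converting back to MET.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .protocol import Activity, Participant, STATIONARY_ACTIVITIES

__all__ = [
    "EEEstimate",
    "estimate_acti4",
    "estimate_activpal",
    "activpal_collapse_labels",
    "ingest_external_estimates",
    "summarize_periods",
    "DEFAULT_PERIODS",
]

#: Semi-standardized protocol periods (s): stationary then physical.
DEFAULT_PERIODS = {"stationary": (0.0, 600.0), "physical": (600.0, 1800.0)}

ACTIVPAL_FIXED_METS = {"lying": 1.0, "sitting": 1.0, "standing": 1.4}
ACTIVPAL_STEP_SLOPE = 0.0186
ACTIVPAL_STEP_INTERCEPT = 1.4


@dataclass
class EEEstimate:
    """Per-epoch MET series for one method plus period summaries."""

    method: str
    epochs: pd.DataFrame  # columns: epoch_start_s, met
    summaries: dict[str, float] = field(default_factory=dict)

    def to_csv(self) -> str:
        buf = StringIO()
        buf.write(f"# method={self.method}\n")
        self.epochs.to_csv(buf, index=False, float_format="%.6f")
        for k, v in self.summaries.items():
            buf.write(f"# summary {k}={v:.6f}\n")
        return buf.getvalue()


def _epoch_length(epoch_start_s: np.ndarray) -> float:
    if len(epoch_start_s) > 1:
        return float(epoch_start_s[1] - epoch_start_s[0])
    return 10.0


def summarize_periods(
    epochs: pd.DataFrame, periods: dict[str, tuple[float, float]] | None = None
) -> dict[str, float]:
    """Time-weighted mean MET per period plus a duration-weighted total.

    Epochs fully inside [start, end) of each period contribute. 'total'
    combines the periods weighted by their durations.
    """
    periods = periods or DEFAULT_PERIODS
    starts = epochs["epoch_start_s"].to_numpy(dtype=float)
    met = epochs["met"].to_numpy(dtype=float)
    dt = _epoch_length(starts)
    out: dict[str, float] = {}
    total_num = 0.0
    total_dur = 0.0
    for name, (a, b) in periods.items():
        if a < starts.min() - 1e-9 or b > starts.max() + dt + 1e-9:
            raise ValueError(f"period {name} ({a}, {b}) outside the epoch series")
        inside = (starts >= a - 1e-9) & (starts + dt <= b + 1e-9)
        if not inside.any():
            raise ValueError(f"period {name} contains no full epoch")
        out[name] = float(met[inside].mean())
        dur = b - a
        total_num += out[name] * dur
        total_dur += dur
    out["total"] = total_num / total_dur
    return out


def estimate_acti4(
    epoch_table: pd.DataFrame,
    model: CalibrationModel,
    participant: Participant,
    periods: dict[str, tuple[float, float]] | None = None,
) -> EEEstimate:
    """Activity-type-aware EE estimate on a labelled epoch table.

    ``epoch_table`` needs columns epoch_start_s, cpm and label (the dominant
    activity per epoch). Stationary labels use the model's fixed METs;
    walking/running/cycling/stairs use the activity's regression, 'move'
    uses the walking regression of the same model.
    """
    labels = epoch_table["label"].to_numpy()
    cpm = epoch_table["cpm"].to_numpy(dtype=float)
    met = np.empty(len(labels))
    for i, (lab, c) in enumerate(zip(labels, cpm)):
        if lab in model.fixed_mets:
            met[i] = model.fixed_mets[lab]
            continue
        if lab == Activity.MOVE.value:
            lab = Activity.WALKING.value
        reg = model.regressions.get(lab)
        if reg is None:
            raise ValueError(f"no regression or fixed MET for label {lab!r}")
        met[i] = reg.predict(c, sex=participant.sex)
    epochs = pd.DataFrame(
        {"epoch_start_s": epoch_table["epoch_start_s"].to_numpy(dtype=float),
         "met": met}
    )
    name = f"AG{model.site}+Acti4"
    return EEEstimate(name, epochs, summarize_periods(epochs, periods))


def activpal_collapse_labels(labels: np.ndarray) -> np.ndarray:
    """Collapse the eight-label vocabulary to the posture monitor's four:
    lying/sitting/standing kept, every dynamic label becomes 'stepping'."""
    keep = {a.value for a in STATIONARY_ACTIVITIES}
    return np.asarray([lab if lab in keep else "stepping" for lab in labels],
                      dtype=object)


def estimate_activpal(
    epoch_table: pd.DataFrame,
    periods: dict[str, tuple[float, float]] | None = None,
) -> EEEstimate:
    """Posture-monitor style estimate: fixed METs for lying/sitting/standing,
    cadence regression for stepping epochs.

    ``epoch_table`` needs epoch_start_s, label (lying/sitting/standing/
    stepping) and cadence_spm for stepping epochs.
    """
    labels = epoch_table["label"].to_numpy()
    met = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab in ACTIVPAL_FIXED_METS:
            met[i] = ACTIVPAL_FIXED_METS[lab]
        elif lab == "stepping":
            cad = float(epoch_table["cadence_spm"].iloc[i])
            met[i] = ACTIVPAL_STEP_SLOPE * cad + ACTIVPAL_STEP_INTERCEPT
        else:
            raise ValueError(f"unknown posture-monitor label {lab!r}")
    epochs = pd.DataFrame(
        {"epoch_start_s": epoch_table["epoch_start_s"].to_numpy(dtype=float),
         "met": met}
    )
    return EEEstimate("ActivPAL", epochs, summarize_periods(epochs, periods))


def ingest_external_estimates(
    source: str | Path | pd.DataFrame,
    method: str,
    expected_grid: np.ndarray | None = None,
    periods: dict[str, tuple[float, float]] | None = None,
) -> EEEstimate:
    """Wrap externally computed per-epoch MET values.

    ``source`` is a CSV path/text (columns epoch_start_s, met) or a frame.
    Values pass through unchanged; if ``expected_grid`` is given the epoch
    grid must match it exactly.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError("external estimate file is empty")
    missing = {"epoch_start_s", "met"} - set(df.columns)
    if missing:
        raise ValueError(f"external estimates missing columns: {sorted(missing)}")
    if expected_grid is not None:
        grid = df["epoch_start_s"].to_numpy(dtype=float)
        if len(grid) != len(expected_grid) or not np.allclose(grid, expected_grid):
            raise ValueError("epoch grid mismatch in external estimates")
    epochs = df[["epoch_start_s", "met"]].astype(float)
    return EEEstimate(method, epochs, summarize_periods(epochs, periods))
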