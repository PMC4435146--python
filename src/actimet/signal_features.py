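"""Raw acceleration → epoch counts, CPM, cadence and classifier features.

Counts here are an open re-implementation of the band-pass / rectify /
deadband / quantize / integrate chain used by research-grade actigraphy
software: each axis is band-pass filtered (0.29–1.63 Hz Butterworth,
order 2), rectified, values below a deadband are zeroed, the remainder is
quantized in 0.01 g steps capped at 255 (8-bit style), and the quantized
signal is integrated over each epoch (sum divided by the sample rate).
The absolute scale therefore differs from proprietary ActiGraph counts;
this is harmless because every regression in this package is fit and
applied on the same counts pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .protocol import Bout

__all__ = [
    "AccelRecording",
    "CountsConfig",
    "compute_counts",
    "step_cadence",
    "bout_average_cpm",
    "trimmed_bout_window",
    "calibration_cpm_window",
    "inclination_features",
    "second_features",
]

#: Band-pass corner frequencies (Hz) of the counts filter.
COUNTS_BAND_HZ = (0.29, 1.63)
#: Rectified values below this are zeroed (g).
COUNTS_DEADBAND_G = 0.02
#: Quantization step (g); quantized values are capped at 255 steps.
COUNTS_LSB_G = 0.01
COUNTS_MAX_LEVEL = 255

DEFAULT_EPOCH_S = 10


@dataclass
class AccelRecording:
    """Tri-axial acceleration from one body site.

    ``data`` has columns time_s, x_g, y_g, z_g on a uniform grid; the x axis
    points down the body segment (thigh or hip mount), so an upright segment
    reads +1 g on x at rest. Units are g throughout.
    """

    site: str
    fs: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time_s", "x_g", "y_g", "z_g"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"recording missing columns: {sorted(missing)}")

    @property
    def duration_s(self) -> float:
        return len(self.data) / self.fs

    def xyz(self) -> np.ndarray:
        return self.data[["x_g", "y_g", "z_g"]].to_numpy(dtype=float)


def _check_uniform(recording: AccelRecording) -> None:
    t = recording.data["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("recording too short")
    dt = np.diff(t)
    if not np.allclose(dt, 1.0 / recording.fs, rtol=0, atol=1e-6):
        raise ValueError("non-uniform timestamps")


def _bandpass(
    x: np.ndarray, fs: float, band_hz: tuple[float, float] = COUNTS_BAND_HZ
) -> np.ndarray:
    """Counts band-pass; DC steady-state initial conditions so a pure
    constant offset produces exactly zero output (no start-up transient)."""
    b, a = sps.butter(2, band_hz, btype="bandpass", fs=fs)
    zi = sps.lfilter_zi(b, a)
    y, _ = sps.lfilter(b, a, x, zi=zi * x[0])
    return y


def _quantize(
    y: np.ndarray,
    deadband_g: float = COUNTS_DEADBAND_G,
    lsb_g: float = COUNTS_LSB_G,
) -> np.ndarray:
    r = np.abs(y)
    q = np.floor(r / lsb_g)
    q[r < deadband_g] = 0.0
    return np.minimum(q, COUNTS_MAX_LEVEL)


@dataclass(frozen=True)
class CountsConfig:
    epoch_length_s: int = DEFAULT_EPOCH_S
    axis_mode: str = "vector_magnitude"  # or "single_axis" (x only)


def compute_counts(
    recording: AccelRecording,
    epoch_length_s: int = DEFAULT_EPOCH_S,
    axis_mode: str = "vector_magnitude",
    band_hz: tuple[float, float] = COUNTS_BAND_HZ,
    deadband_g: float = COUNTS_DEADBAND_G,
    lsb_g: float = COUNTS_LSB_G,
) -> pd.DataFrame:
    """Per-epoch activity counts and CPM.

    Returns a frame with one row per complete epoch (a tail shorter than one
    epoch is dropped): epoch_start_s, counts_x/y/z, counts (per axis_mode)
    and cpm = counts · 60/epoch_length_s. The epoch grid is anchored at the
    recording start, intervals half-open [start, start+len).
    """
    if axis_mode not in ("vector_magnitude", "single_axis"):
        raise ValueError(f"unknown axis_mode: {axis_mode}")
    _check_uniform(recording)
    fs = recording.fs
    spe = int(round(epoch_length_s * fs))  # samples per epoch
    xyz = recording.xyz()
    n_epochs = len(xyz) // spe
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    xyz = xyz[: n_epochs * spe]

    per_axis = []
    for j in range(3):
        q = _quantize(_bandpass(xyz[:, j], fs, band_hz), deadband_g, lsb_g)
        # integrate: sum of quantized levels over the epoch, per second
        sums = q.reshape(n_epochs, spe).sum(axis=1) / fs
        per_axis.append(np.floor(sums))
    cx, cy, cz = per_axis
    if axis_mode == "vector_magnitude":
        counts = np.sqrt(cx**2 + cy**2 + cz**2)
    else:
        counts = cx
    t0 = recording.data["time_s"].iloc[0]
    out = pd.DataFrame(
        {
            "epoch_start_s": t0 + np.arange(n_epochs) * float(epoch_length_s),
            "counts_x": cx,
            "counts_y": cy,
            "counts_z": cz,
            "counts": counts,
            "cpm": counts * (60.0 / epoch_length_s),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Step cadence
# ---------------------------------------------------------------------------

#: Minimum band-passed peak height that counts as a step (g).
STEP_PEAK_HEIGHT_G = 0.1
#: Maximum step rate resolved by the peak picker (Hz).
STEP_MAX_RATE_HZ = 3.75


def step_cadence(
    recording: AccelRecording, epoch_length_s: int = DEFAULT_EPOCH_S
) -> pd.DataFrame:
    """Per-epoch step cadence (steps/min) from peaks of the band-passed
    longitudinal (x) axis. Sub-threshold signals yield cadence 0."""
    _check_uniform(recording)
    fs = recording.fs
    spe = int(round(epoch_length_s * fs))
    x = recording.xyz()[:, 0]
    n_epochs = len(x) // spe
    y = _bandpass(x[: n_epochs * spe], fs)
    peaks, _ = sps.find_peaks(
        y, height=STEP_PEAK_HEIGHT_G, distance=max(1, int(fs / STEP_MAX_RATE_HZ))
    )
    per_epoch = np.bincount(peaks // spe, minlength=n_epochs)
    t0 = recording.data["time_s"].iloc[0]
    return pd.DataFrame(
        {
            "epoch_start_s": t0 + np.arange(n_epochs) * float(epoch_length_s),
            "cadence_spm": per_epoch * (60.0 / epoch_length_s),
        }
    )


# ---------------------------------------------------------------------------
# Bout-window CPM
# ---------------------------------------------------------------------------

def bout_average_cpm(
    epoch_table: pd.DataFrame,
    bout: Bout | None = None,
    *,
    window: tuple[float, float] | None = None,
    bout_start_s: float | None = None,
) -> float:
    """Mean CPM over a bout's measurement window.

    The window may be given directly as absolute (start, end) seconds, or
    derived from a :class:`~actimet.protocol.Bout` plus its absolute start
    time. Only epochs lying fully inside the window are averaged; for a
    standard 5-min bout with the last-2-min window and 10-s epochs that is
    exactly 12 epochs, and for the trimmed-bout convention (first and last
    30 s removed) exactly 24.
    """
    if window is None:
        if bout is None or bout_start_s is None:
            raise ValueError("provide either window or (bout, bout_start_s)")
        window = bout.window_abs(bout_start_s)
    w0, w1 = window
    starts = epoch_table["epoch_start_s"].to_numpy(dtype=float)
    if len(starts) > 1:
        epoch_len = starts[1] - starts[0]
    else:
        epoch_len = float(DEFAULT_EPOCH_S)
    inside = (starts >= w0 - 1e-9) & (starts + epoch_len <= w1 + 1e-9)
    if not inside.any():
        raise ValueError(f"no full epoch inside window ({w0}, {w1})")
    return float(epoch_table.loc[inside, "cpm"].mean())


def trimmed_bout_window(bout_start_s: float, duration_s: float, trim_s: float = 30.0
                        ) -> tuple[float, float]:
    """The calibration convention: bout minus its first and last 30 s."""
    return (bout_start_s + trim_s, bout_start_s + duration_s - trim_s)


def calibration_cpm_window(bout: Bout, bout_start_s: float) -> tuple[float, float]:
    """CPM-averaging window used when building calibration points: stair
    bouts use their cadence-specific ascent/descent-balanced window, all
    other bouts drop the first and last 30 s."""
    from .protocol import Activity  # local to keep the module header light

    if (
        bout.activity == Activity.STAIRS
        and bout.window_before_end_s[0] < bout.duration_s
    ):
        return bout.window_abs(bout_start_s)
    return trimmed_bout_window(bout_start_s, bout.duration_s)


# ---------------------------------------------------------------------------
# Classifier features
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    # centered moving average with edge padding
    pad = n // 2
    xp = np.pad(x, (pad, n - 1 - pad), mode="edge")
    c = np.cumsum(np.insert(xp, 0, 0.0))
    return (c[n:] - c[:-n]) / n


def inclination_features(
    recording: AccelRecording, window_s: float = 2.0
) -> pd.DataFrame:
    """Low-pass posture angles sampled on the recording grid.

    inclination_deg is the angle between the low-pass-filtered acceleration
    vector and the segment's longitudinal (x) axis: ~0° for an upright
    segment, ~90° for a horizontal one. fb_angle_deg is the forward/backward
    pitch, atan2(z, x), of the same low-passed vector.
    """
    _check_uniform(recording)
    n = max(2, int(round(window_s * recording.fs)))
    xyz = recording.xyz()
    lp = np.column_stack([_moving_average(xyz[:, j], n) for j in range(3)])
    norm = np.linalg.norm(lp, axis=1)
    norm[norm == 0] = 1.0
    inclination = np.degrees(np.arccos(np.clip(lp[:, 0] / norm, -1.0, 1.0)))
    fb = np.degrees(np.arctan2(lp[:, 2], lp[:, 0]))
    return pd.DataFrame(
        {
            "time_s": recording.data["time_s"].to_numpy(),
            "inclination_deg": inclination,
            "fb_angle_deg": fb,
        }
    )


#: Window over which the forward/backward angle excursion is measured (s).
FB_INTERVAL_WINDOW_S = 5


def second_features(recording: AccelRecording) -> pd.DataFrame:
    """Per-second classifier features for one site.

    Columns: second, sd_g (total acceleration SD within the second, summed
    over axes), inclination_deg (from the 2-s low-passed vector at the
    second's midpoint) and fb_interval_deg (max−min of the low-passed
    forward/backward angle over a centered 5-s window).
    """
    _check_uniform(recording)
    fs = recording.fs
    spp = int(round(fs))  # samples per second
    xyz = recording.xyz()
    n_sec = len(xyz) // spp
    xyz = xyz[: n_sec * spp]

    blocks = xyz.reshape(n_sec, spp, 3)
    sd = np.sqrt(blocks.var(axis=1).sum(axis=1))

    angles = inclination_features(recording, window_s=2.0)
    incl = angles["inclination_deg"].to_numpy()[: n_sec * spp].reshape(n_sec, spp)
    incl_s = incl[:, spp // 2]
    fb = angles["fb_angle_deg"].to_numpy()[: n_sec * spp].reshape(n_sec, spp)
    fb_min = fb.min(axis=1)
    fb_max = fb.max(axis=1)

    half = FB_INTERVAL_WINDOW_S // 2
    fb_interval = np.empty(n_sec)
    for i in range(n_sec):
        lo = max(0, i - half)
        hi = min(n_sec, i + half + 1)
        fb_interval[i] = fb_max[lo:hi].max() - fb_min[lo:hi].min()

    t0 = recording.data["time_s"].iloc[0]
    return pd.DataFrame(
        {
            "second": t0 + np.arange(n_sec, dtype=float),
            "sd_g": sd,
            "inclination_deg": incl_s,
            "fb_interval_deg": fb_interval,
        }
    )
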