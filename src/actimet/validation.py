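"""Agreement statistics between estimated and reference energy expenditure.

The suite a method-comparison study reports: mean difference and its SD,
the mean square error combining both,

    MSE = ((N−1)/N)·s² + z̄²

(N subjects, s the sample SD of the between-method differences, z̄ their
mean), percent bias, Pearson's coefficient of determination, the intraclass
correlation ICC(2,1) (two-way random effects, absolute agreement, single
measures), a paired t test, and Bland–Altman limits of agreement
(mean difference ± 1.96 SD) with a bias-trend line of difference on
reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlandAltman",
    "AgreementReport",
    "mse",
    "percent_bias",
    "bland_altman",
    "bland_altman_plot",
    "icc",
    "paired_t",
    "pearson_r2",
    "agreement_report",
]


def _paired(measured, estimated) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(measured, dtype=float)
    y = np.asarray(estimated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("measured and estimated must be paired 1-d vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 paired observations")
    return x, y


def mse(differences) -> float:
    """Mean square error of between-method differences:
    ((N−1)/N)·s² + z̄² — algebraically the mean of the squared differences."""
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need at least 2 differences")
    n = len(d)
    s = d.std(ddof=1)
    zbar = d.mean()
    return float((n - 1) / n * s**2 + zbar**2)


def percent_bias(mean_measured: float, mean_estimated: float) -> float:
    """Group-level bias of the estimate relative to the reference, in percent
    (positive = overestimation). Full precision; round only for display."""
    if mean_measured <= 0:
        raise ValueError("mean_measured must be positive")
    return 100.0 * (mean_estimated - mean_measured) / mean_measured


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    trend_slope: float
    trend_intercept: float
    trend_r2: float


def bland_altman(measured, estimated) -> BlandAltman:
    """Bland–Altman block: differences (estimated − measured) against the
    reference, limits of agreement at mean ± 1.96 SD, plus the OLS trend of
    the difference on the reference (proportional-bias check)."""
    x, y = _paired(measured, estimated)
    d = y - x
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    X = np.column_stack([x, np.ones(len(x))])
    beta, *_ = np.linalg.lstsq(X, d, rcond=None)
    fitted = X @ beta
    ss_res = float(((d - fitted) ** 2).sum())
    ss_tot = float(((d - d.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return BlandAltman(
        mean_diff=md,
        sd_diff=sd,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        trend_slope=float(beta[0]),
        trend_intercept=float(beta[1]),
        trend_r2=r2,
    )


def bland_altman_plot(measured, estimated, path, title: str = "") -> None:
    """Write a Bland–Altman figure: reference on x, difference on y, solid
    mean-difference line, dashed ±1.96 SD limits, dotted trend line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _paired(measured, estimated)
    ba = bland_altman(measured, estimated)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y - x, s=18, color="k")
    ax.axhline(ba.mean_diff, color="tab:blue")
    ax.axhline(ba.loa_low, color="tab:blue", linestyle="--")
    ax.axhline(ba.loa_high, color="tab:blue", linestyle="--")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, ba.trend_slope * xs + ba.trend_intercept, "k:",
            label=f"trend R²={ba.trend_r2:.2f}")
    ax.set_xlabel("reference MET")
    ax.set_ylabel("estimated − reference (MET)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def icc(measured, estimated, form: str = "icc2_1") -> float:
    """Intraclass correlation between the two raters (methods).

    Default ICC(2,1): two-way random effects, absolute agreement, single
    measures, from the mean-squares decomposition of the n×2 table.
    ``form`` may also be 'icc3_1' (two-way mixed, consistency).
    """
    x, y = _paired(measured, estimated)
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse_ = ss_err / ((n - 1) * (k - 1))
    if form == "icc2_1":
        denom = msr + (k - 1) * mse_ + (k / n) * (msc - mse_)
        if denom == 0:
            raise ValueError("ICC undefined: no variance in either direction")
        return float((msr - mse_) / denom)
    if form == "icc3_1":
        denom = msr + (k - 1) * mse_
        if denom == 0:
            raise ValueError("ICC undefined: no variance in either direction")
        return float((msr - mse_) / denom)
    raise ValueError(f"unknown ICC form: {form}")


def paired_t(measured, estimated) -> tuple[float, float]:
    """Two-sided paired t test on (estimated − measured); returns (t, p)."""
    x, y = _paired(measured, estimated)
    if np.ptp(y - x) == 0:
        raise ValueError("zero variance of differences: t undefined")
    res = stats.ttest_rel(y, x)
    return float(res.statistic), float(res.pvalue)


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation (coefficient of determination)."""
    x, y = _paired(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r = stats.pearsonr(x, y).statistic
    return float(r**2)


@dataclass(frozen=True)
class AgreementReport:
    """Full method-vs-reference agreement block for one period."""

    method: str
    period: str
    n: int
    mean_measured: float
    mean_estimated: float
    mean_diff: float
    sd_diff: float
    mse: float
    percent_bias: float
    r2: float
    icc: float
    t: float
    p: float
    bland_altman: BlandAltman

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    def to_row(self) -> dict:
        d = asdict(self)
        ba = d.pop("bland_altman")
        d.update({f"ba_{k}": v for k, v in ba.items()})
        return d


def agreement_report(measured, estimated, method: str, period: str) -> AgreementReport:
    """Compute every agreement statistic for one method/period pair."""
    x, y = _paired(measured, estimated)
    d = y - x
    ba = bland_altman(x, y)
    try:
        t, p = paired_t(x, y)
    except ValueError:
        t, p = float("nan"), float("nan")
    try:
        r2 = pearson_r2(x, y)
    except ValueError:
        r2 = float("nan")
    try:
        icc_val = icc(x, y)
    except ValueError:
        icc_val = float("nan")
    return AgreementReport(
        method=method,
        period=period,
        n=len(x),
        mean_measured=float(x.mean()),
        mean_estimated=float(y.mean()),
        mean_diff=float(d.mean()),
        sd_diff=float(d.std(ddof=1)),
        mse=mse(d),
        percent_bias=percent_bias(float(x.mean()), float(y.mean())),
        r2=r2,
        icc=icc_val,
        t=t,
        p=p,
        bland_altman=ba,
    )
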