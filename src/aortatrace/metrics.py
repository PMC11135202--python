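"""Agreement statistics and profile summaries.

Automated and clinical diameters at the standard measurement sites are two
raters of the same subjects, so agreement is quantified with the
single-measure two-way random-effects intraclass correlation for absolute
agreement, ICC(2,1):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with MSR/MSC/MSE the subject, rater, and residual mean squares of the
two-way ANOVA, n subjects and k = 2 raters. Confidence bounds follow the
F-based formulas of McGraw & Wong; the p-value is the F test of MSR/MSE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

STANDARD_SITES = ("SOV", "STJ", "AA", "BCA", "T1", "T2", "IR", "DA", "D")


class DegenerateInputError(ValueError):
    """Too few pairs, or zero variance everywhere — ICC is undefined."""


@dataclass
class PairedMeasures:
    """Automated vs reference diameters (mm) at one anatomic site."""

    site_label: str
    auto_mm: Sequence[float]
    ref_mm: Sequence[float]

    def __post_init__(self):
        a = np.asarray(self.auto_mm, dtype=float)
        r = np.asarray(self.ref_mm, dtype=float)
        if a.shape != r.shape or a.ndim != 1:
            raise ValueError("auto and reference series must be equal-length 1D")
        keep = np.isfinite(a) & np.isfinite(r)  # pairwise deletion of missing
        self.auto_mm = a[keep]
        self.ref_mm = r[keep]
        if len(self.auto_mm) < 2:
            raise DegenerateInputError(
                f"{self.site_label}: need >= 2 complete pairs"
            )
        if (self.auto_mm <= 0).any() or (self.ref_mm <= 0).any():
            raise ValueError("diameters must be positive")

    @property
    def n(self) -> int:
        return len(self.auto_mm)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def icc_two_way_single(pairs: PairedMeasures, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    y = np.column_stack([pairs.auto_mm, pairs.ref_mm])  # n subjects x k raters
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((y - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise DegenerateInputError(
            f"{pairs.site_label}: zero variance, ICC undefined"
        )
    icc = (msr - mse) / denom

    # F test of the no-subject-effect null
    if mse == 0:
        p = 0.0
    else:
        p = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))

    # McGraw & Wong F-based interval for ICC(A,1)
    if mse == 0 and msc == msr:  # perfect agreement, interval collapses
        lo = hi = icc
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            lo = hi = 1.0
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1)
                + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (
                n * (msr - f_lo * mse)
                / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            hi = (
                n * (f_hi * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f_hi * msr)
            )
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return ICCResult(icc=float(icc), ci_low=lo, ci_high=hi, p_value=p, n=n)


def agreement_table(all_sites: Iterable[PairedMeasures]) -> pd.DataFrame:
    """Per-site agreement table (site, ICC, 95% CI, p, N, reason)."""
    sites = list(all_sites)
    if not sites:
        raise ValueError("no sites supplied")
    rows = []
    for pm in sites:
        try:
            res = icc_two_way_single(pm)
            rows.append(
                dict(site=pm.site_label, icc=res.icc, ci_low=res.ci_low,
                     ci_high=res.ci_high, p_value=res.p_value, n=res.n,
                     reason="")
            )
        except (DegenerateInputError, ValueError) as exc:
            rows.append(
                dict(site=pm.site_label, icc=np.nan, ci_low=np.nan,
                     ci_high=np.nan, p_value=np.nan, n=getattr(pm, "n", 0),
                     reason=str(exc))
            )
    return pd.DataFrame(rows)


def forest_plot(table: pd.DataFrame, out_path: str) -> None:
    """Point-and-whisker ICC plot, one row per site."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ok = table.dropna(subset=["icc"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.5 * max(len(ok), 2) + 1.5))
    ypos = np.arange(len(ok))[::-1]
    ax.errorbar(
        ok["icc"], ypos,
        xerr=[ok["icc"] - ok["ci_low"], ok["ci_high"] - ok["icc"]],
        fmt="o", color="k", capsize=3,
    )
    ax.set_yticks(ypos, ok["site"])
    ax.axvline(1.0, color="0.7", lw=0.8)
    ax.set_xlabel("ICC(2,1) with 95% CI")
    ax.set_xlim(min(0.0, float(ok["ci_low"].min()) - 0.05), 1.05)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


# ---- profile summaries ---------------------------------------------------


def spike_filter(trace, window: int = 15, threshold: float = 0.5) -> np.ndarray:
    """Flag steps whose max diameter exceeds a rolling median by >50%.

    Spikes arise where the measurement plane slips into head and neck
    vessels; flagged steps stay in the profile (they orient the reader) but
    are excluded from the automated peak. Traces shorter than the window
    are returned unflagged.
    """
    d = np.asarray(trace.max_diameters if hasattr(trace, "max_diameters") else trace,
                   dtype=float)
    if len(d) < window:
        return np.zeros(len(d), dtype=bool)
    med = (
        pd.Series(d).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    return d > (1.0 + threshold) * med


def peak_diameter(trace) -> tuple[float, float]:
    """Location (arc length, mm) and value (mm) of the largest non-spike
    diameter; ties resolve to the first occurrence."""
    d = np.asarray(trace.max_diameters, dtype=float)
    if len(d) == 0:
        raise ValueError("empty trace")
    flags = spike_filter(trace)
    if flags.all():
        raise ValueError("every step is spike-flagged; no peak")
    d = d.copy()
    d[flags] = -np.inf
    k = int(np.argmax(d))
    return float(trace.arc_lengths[k]), float(d[k])
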