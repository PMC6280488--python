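"""Measurement-quality diagnostics and goodness-of-fit plot data.

Blood-loss measurements in delivery-room conditions show two
characteristic artefacts: digit preference (heaping on multiples of 10,
50 and 100 mL/g) and a limit of detection near 50 mL below which the
recorded values behave like uniform noise. These diagnostics quantify
both and prepare the probability-plot / quantile-quantile / CDF-overlay
data used to judge the lognormal fit. Plot DATA are computed here;
rendering is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .distributions import cdf, quantile, sf
from .estimation import _logit_interval, _sf_gradient
from .fitting import BloodLossSample, FitResult

MULTIPLES = (10, 50, 100)
# relative frequency of multiples of 10/50/100 under plain integer-mL
# recording with no heaping
EXPECTED_FREQ = {10: 0.10, 50: 0.02, 100: 0.01}


@dataclass(frozen=True)
class DigitPreferenceReport:
    n: int
    expected_freq: dict[int, float]
    observed_freq: dict[int, float]
    ratio: dict[int, float]


@dataclass(frozen=True)
class LODReport:
    candidate_lod: float
    n_below: int
    uniformity_stat: float
    p_value: float
    flag: bool  # True = uniformity not rejected, LOD plausible
    skipped: bool = False
    note: str = ""


@dataclass(frozen=True)
class PlotData:
    kind: Literal["probability", "qq", "cdf_overlay"]
    x: np.ndarray
    y: np.ndarray
    reference: Optional[np.ndarray] = None
    band_lower: Optional[np.ndarray] = None
    band_upper: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)


def digit_preference(sample: BloodLossSample) -> DigitPreferenceReport:
    """Observed vs expected frequency of multiples of 10, 50 and 100.

    Non-integer recordings count as non-multiples. Under unheaped
    integer recording the expected column is exactly (0.10, 0.02, 0.01).
    """
    v = sample.volumes
    n = sample.n
    if n == 0:
        raise ValueError("empty sample")
    rounded = np.round(v)
    is_int = np.isclose(v, rounded, atol=1e-9)
    observed = {}
    for k in MULTIPLES:
        observed[k] = float(np.mean(is_int & (np.mod(rounded, k) == 0)))
    ratio = {k: observed[k] / EXPECTED_FREQ[k] for k in MULTIPLES}
    return DigitPreferenceReport(
        n=n, expected_freq=dict(EXPECTED_FREQ), observed_freq=observed, ratio=ratio
    )


def lod_assess(
    sample: BloodLossSample,
    candidates: Sequence[float] = (50.0, 100.0),
    min_below: int = 10,
    alpha: float = 0.05,
) -> list[LODReport]:
    """Kolmogorov-Smirnov uniformity check of sub-threshold values.

    For each candidate limit of detection L, the values recorded below L
    are tested against Uniform(0, L). flag=True (uniformity not
    rejected at ``alpha``) marks L as a plausible LOD. Candidates with
    fewer than ``min_below`` observations below them are skipped.
    """
    reports = []
    for L in candidates:
        below = sample.volumes[sample.volumes < L]
        if below.size < min_below:
            reports.append(
                LODReport(
                    candidate_lod=L, n_below=int(below.size),
                    uniformity_stat=np.nan, p_value=np.nan, flag=False,
                    skipped=True,
                    note=f"only {below.size} observations below {L}; need {min_below}",
                )
            )
            continue
        res = stats.kstest(below, stats.uniform(loc=0, scale=L).cdf)
        reports.append(
            LODReport(
                candidate_lod=L,
                n_below=int(below.size),
                uniformity_stat=float(res.statistic),
                p_value=float(res.pvalue),
                flag=bool(res.pvalue > alpha),
            )
        )
    return reports


def _check_fit(fit: FitResult) -> None:
    if not fit.converged:
        raise ValueError("plot data require a converged fit")


def probability_plot_data(sample: BloodLossSample, fit: FitResult) -> PlotData:
    """Probability-plot points with a pointwise ~95% order-statistic band.

    x: ordered volumes; y: standard-normal scores of the Hazen plotting
    positions (i - 0.5)/n. Under the fitted model the points should
    follow the line z = (log(x - t) - m)/s; the band maps the 2.5%/97.5%
    beta order-statistic quantiles through the fitted quantile function,
    giving bounds on the data axis at each position.
    """
    _check_fit(fit)
    v = np.sort(sample.volumes)
    n = v.size
    i = np.arange(1, n + 1)
    pp = (i - 0.5) / n
    y = stats.norm.ppf(pp)
    # order statistic i of n has cdf-value distributed Beta(i, n - i + 1)
    lo_p = stats.beta.ppf(0.025, i, n - i + 1)
    hi_p = stats.beta.ppf(0.975, i, n - i + 1)
    band_lower = quantile(np.clip(lo_p, 1e-12, 1 - 1e-12), fit.params)
    band_upper = quantile(np.clip(hi_p, 1e-12, 1 - 1e-12), fit.params)
    reference = quantile(pp, fit.params)  # model volume at each position
    return PlotData(
        kind="probability", x=v, y=y, reference=reference,
        band_lower=band_lower, band_upper=band_upper,
    )


def qq_data(sample: BloodLossSample, fit: FitResult) -> PlotData:
    """Fitted-model quantiles vs empirical order statistics (y = x line)."""
    _check_fit(fit)
    v = np.sort(sample.volumes)
    n = v.size
    pp = (np.arange(1, n + 1) - 0.5) / n
    x = quantile(pp, fit.params)
    return PlotData(kind="qq", x=x, y=v, reference=x.copy())


def cdf_overlay_data(
    sample: BloodLossSample, fit: FitResult, grid: Sequence[float]
) -> PlotData:
    """Empirical and fitted CDFs on a grid with 95% bands for both.

    The fitted-CDF band is the delta-method interval (logit scale,
    full parameter covariance); the empirical band is the pointwise
    logit-Wald binomial interval, matching the tail-estimation
    conventions.
    """
    _check_fit(fit)
    grid = np.asarray(grid, dtype=float)
    v = sample.volumes
    n = sample.n
    emp = np.array([np.mean(v <= g) for g in grid])
    fitted = np.atleast_1d(cdf(grid, fit.params))

    fit_lo = np.empty_like(fitted)
    fit_hi = np.empty_like(fitted)
    cov = fit.cov[: fit.k, : fit.k]
    cov_ok = np.all(np.isfinite(cov))
    for j, g in enumerate(grid):
        F = fitted[j]
        if not cov_ok or g <= fit.params.t or F in (0.0, 1.0):
            fit_lo[j] = fit_hi[j] = F
            continue
        grad = _sf_gradient(g, fit.params, fit.k)  # d sf = -d cdf, same variance
        var = float(grad @ cov @ grad)
        lo, hi = _logit_interval(F, np.sqrt(max(var, 0.0)))
        fit_lo[j], fit_hi[j] = lo, hi

    emp_lo = np.empty_like(emp)
    emp_hi = np.empty_like(emp)
    for j, F in enumerate(emp):
        if F in (0.0, 1.0):
            emp_lo[j] = emp_hi[j] = F
        else:
            se = np.sqrt(F * (1 - F) / n)
            emp_lo[j], emp_hi[j] = _logit_interval(F, se)

    return PlotData(
        kind="cdf_overlay", x=grid, y=emp, reference=fitted,
        band_lower=fit_lo, band_upper=fit_hi,
        extra={"empirical_lower": emp_lo, "empirical_upper": emp_hi},
    )


def plotdata_to_rows(pd_: PlotData) -> list[dict]:
    """Flatten PlotData to one dict per point for CSV serialisation."""
    rows = []
    for j in range(len(pd_.x)):
        row = {"kind": pd_.kind, "x": float(pd_.x[j]), "y": float(pd_.y[j])}
        if pd_.reference is not None:
            row["reference"] = float(np.atleast_1d(pd_.reference)[j])
        if pd_.band_lower is not None:
            row["band_lower"] = float(pd_.band_lower[j])
            row["band_upper"] = float(pd_.band_upper[j])
        for key, arr in pd_.extra.items():
            row[key] = float(arr[j])
        rows.append(row)
    return rows
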