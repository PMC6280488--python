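"""Tail-probability estimation: lognormal vs binomial approaches.

The clinical endpoints are postpartum haemorrhage (PPH, blood loss of
500 mL or more) and severe PPH (1000 mL or more). Two estimators of
P(V > cutoff) are provided:

* lognormal — the survival function of a fitted (threshold) lognormal
  evaluated at the cutoff; being a smooth function of maximum-likelihood
  estimates, it is itself an MLE and its CI comes from the delta method;
* binomial — the raw sample proportion above the cutoff with a
  maximum-likelihood (Wald) interval.

Both intervals are built on the logit scale by default and
back-transformed, which keeps them inside (0, 1) for the small
proportions involved. For the binomial count the event is ">= cutoff":
with continuous models ties carry no probability, but heaped real data
put genuine mass exactly at 500 and 1000, and the clinical definition
is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .distributions import LognormalParams, sf
from .fitting import BloodLossSample, FitResult

_Z975 = stats.norm.ppf(0.975)


@dataclass
class TailEstimate:
    cutoff: float
    approach: Literal["lognormal", "binomial"]
    p: float
    ci95: tuple[float, float]
    n: int
    arm_label: str = ""
    flagged: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.p <= hi <= 1.0):
            raise ValueError(
                f"inconsistent tail estimate: lower {lo}, p {self.p}, upper {hi}"
            )

    @property
    def width(self) -> float:
        return self.ci95[1] - self.ci95[0]


def _logit_interval(p: float, se_p: float) -> tuple[float, float]:
    """Wald interval for p transported to the logit scale and back."""
    if p <= 0.0 or p >= 1.0 or se_p == 0.0:
        return (p, p)
    se_logit = se_p / (p * (1 - p))
    eta = np.log(p / (1 - p))
    lo = 1 / (1 + np.exp(-(eta - _Z975 * se_logit)))
    hi = 1 / (1 + np.exp(-(eta + _Z975 * se_logit)))
    return float(lo), float(hi)


def _sf_gradient(cutoff: float, params: LognormalParams, k: int) -> np.ndarray:
    """Gradient of P(V > cutoff) w.r.t. (m, s[, t])."""
    shifted = cutoff - params.t
    z = (np.log(shifted) - params.m) / params.s
    phi = stats.norm.pdf(z)
    g = [phi / params.s, phi * z / params.s]
    if k == 3:
        g.append(phi / (params.s * shifted))
    return np.array(g)


def tail_lognormal(fit: FitResult, cutoff: float) -> TailEstimate:
    """P(V > cutoff) from a fitted lognormal, delta-method 95% CI.

    The gradient of the survival function with respect to all free
    parameters (including the threshold, whose uncertainty can be
    substantial) is propagated through the fit's covariance; the
    interval is built on the logit scale.
    """
    if not fit.converged:
        raise ValueError("tail estimation requires a converged fit")
    p = float(sf(cutoff, fit.params))
    if cutoff <= fit.params.t:
        return TailEstimate(
            cutoff=cutoff, approach="lognormal", p=1.0, ci95=(1.0, 1.0),
            n=fit.n, flagged=True, message="cutoff at or below threshold",
        )
    g = _sf_gradient(cutoff, fit.params, fit.k)
    cov = fit.cov[: fit.k, : fit.k]
    if np.any(~np.isfinite(cov)):
        var = np.nan
    else:
        var = float(g @ cov @ g)
    if not np.isfinite(var) or var < 0:
        ci = (p, p)
        flagged, msg = True, "parameter covariance unavailable; CI degenerate"
    else:
        ci = _logit_interval(p, np.sqrt(var))
        flagged, msg = False, ""
    label = fit.sample.arm_label if fit.sample is not None else ""
    return TailEstimate(
        cutoff=cutoff, approach="lognormal", p=p, ci95=ci, n=fit.n,
        arm_label=label, flagged=flagged, message=msg,
    )


def tail_binomial(
    sample: BloodLossSample,
    cutoff: float,
    interval: Literal["logit", "wald"] = "logit",
) -> TailEstimate:
    """Sample proportion with blood loss >= cutoff, ML (Wald) 95% CI."""
    v = sample.volumes
    n = sample.n
    x = int(np.sum(v >= cutoff))
    p = x / n
    if x == 0 or x == n:
        return TailEstimate(
            cutoff=cutoff, approach="binomial", p=p, ci95=(p, p), n=n,
            arm_label=sample.arm_label, flagged=True,
            message="boundary proportion; Wald interval degenerate",
        )
    se_p = np.sqrt(p * (1 - p) / n)
    if interval == "logit":
        ci = _logit_interval(p, se_p)
    else:
        ci = (max(0.0, p - _Z975 * se_p), min(1.0, p + _Z975 * se_p))
    return TailEstimate(
        cutoff=cutoff, approach="binomial", p=p, ci95=ci, n=n,
        arm_label=sample.arm_label,
    )


def width_ratio(lognormal_est: TailEstimate, binomial_est: TailEstimate) -> float:
    """Lognormal CI width as a percentage of the binomial CI width."""
    if lognormal_est.cutoff != binomial_est.cutoff:
        raise ValueError("estimates use different cutoffs")
    if binomial_est.width == 0.0:
        raise ValueError("binomial interval has zero width")
    return 100.0 * lognormal_est.width / binomial_est.width


def median_ratio(fit1: FitResult, fit2: FitResult) -> tuple[float, tuple[float, float]]:
    """Ratio of medians exp(m1 - m2) with a normal-theory 95% CI.

    On the log scale the difference of locations is the log median
    ratio; SEs combine in quadrature.
    """
    for f in (fit1, fit2):
        if not f.converged:
            raise ValueError("median comparison requires converged fits")
    d = fit1.params.m - fit2.params.m
    se = np.sqrt(fit1.se["m"] ** 2 + fit2.se["m"] ** 2)
    ratio = float(np.exp(d))
    ci = (float(np.exp(d - _Z975 * se)), float(np.exp(d + _Z975 * se)))
    return ratio, ci


def tail_table(
    samples: list[BloodLossSample],
    fits: list[FitResult],
    cutoffs: tuple[float, ...] = (500.0, 1000.0),
) -> list[dict]:
    """Per-arm, per-cutoff table of both approaches with width ratios."""
    rows = []
    for sample, fit in zip(samples, fits):
        for cutoff in cutoffs:
            b = tail_binomial(sample, cutoff)
            l = tail_lognormal(fit, cutoff)
            ratio = np.nan if b.width == 0 else 100.0 * l.width / b.width
            for est in (b, l):
                rows.append(
                    {
                        "arm": sample.arm_label,
                        "cutoff": cutoff,
                        "approach": est.approach,
                        "proportion": est.p,
                        "ci95_lower": est.ci95[0],
                        "ci95_upper": est.ci95[1],
                        "width": est.width,
                        "width_ratio_pct": ratio if est.approach == "lognormal" else np.nan,
                    }
                )
    return rows
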