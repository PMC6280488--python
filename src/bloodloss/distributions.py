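"""Two- and three-parameter (threshold) lognormal distribution functions.

The blood-loss volume V is modelled as ``t + exp(N(m, s^2))``: ``m`` and
``s`` are the mean and standard deviation of ``log(V - t)`` (natural
logarithms throughout), and ``t`` shifts the support to ``(t, infinity)``.
Setting ``t = 0`` recovers the plain two-parameter lognormal. ``exp(m)``
is the median of ``V - t``.

Every function is vectorised over the volume/probability argument and is
defined to be 0 (pdf, cdf) on ``v <= t`` rather than raising, so mixed
data can be evaluated in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class LognormalParams:
    """Parameter triple (m, s, t) of a threshold lognormal law.

    m : location, mean of log(V - t) (log-mL)
    s : scale, standard deviation of log(V - t); strictly positive
    t : threshold shift in mL (0 for the two-parameter case)
    """

    m: float
    s: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.m):
            raise ValueError(f"location m must be finite, got {self.m}")
        if not (np.isfinite(self.s) and self.s > 0):
            raise ValueError(f"scale s must be finite and > 0, got {self.s}")
        if not np.isfinite(self.t):
            raise ValueError(f"threshold t must be finite, got {self.t}")

    @property
    def median(self) -> float:
        """Median of V: t + exp(m)."""
        return self.t + float(np.exp(self.m))


def _z(v: np.ndarray, params: LognormalParams) -> np.ndarray:
    """Standardised log-excess (log(v-t) - m)/s; +inf where v <= t."""
    shifted = np.asarray(v, dtype=float) - params.t
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(np.where(shifted > 0, shifted, np.nan)) - params.m) / params.s
    return z


def pdf(v, params: LognormalParams):
    """Density of the threshold lognormal at volume ``v`` (1/mL).

    Returns 0 for ``v <= t`` (support boundary), the shifted lognormal
    density elsewhere.
    """
    v = np.asarray(v, dtype=float)
    shifted = v - params.t
    out = np.zeros_like(v)
    ok = shifted > 0
    if np.any(ok):
        out[ok] = stats.lognorm.pdf(shifted[ok], s=params.s, scale=np.exp(params.m))
    return out if out.ndim else float(out)


def cdf(v, params: LognormalParams):
    """P(V <= v) = Phi((log(v - t) - m)/s) for v > t, else 0."""
    v = np.asarray(v, dtype=float)
    z = _z(v, params)
    out = np.where(np.isnan(z), 0.0, stats.norm.cdf(np.nan_to_num(z)))
    return out if out.ndim else float(out)


def sf(v, params: LognormalParams):
    """P(V > v), computed through the normal survival function.

    Going via ``norm.sf`` rather than ``1 - cdf`` preserves relative
    precision deep in the right tail, where the clinically relevant
    severe-haemorrhage probabilities (~0.015-0.04) live.
    """
    v = np.asarray(v, dtype=float)
    z = _z(v, params)
    out = np.where(np.isnan(z), 1.0, stats.norm.sf(np.nan_to_num(z)))
    return out if out.ndim else float(out)


def quantile(p, params: LognormalParams):
    """Inverse cdf: t + exp(m + s * Phi^{-1}(p)) for p in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    out = params.t + np.exp(params.m + params.s * stats.norm.ppf(p))
    return out if out.ndim else float(out)


def normal_quantile(p):
    """Standard-normal quantile Phi^{-1}(p), p in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    out = stats.norm.ppf(p)
    return out if out.ndim else float(out)


def logpdf(v, params: LognormalParams):
    """Log-density; -inf on v <= t. Used by the likelihood machinery."""
    v = np.asarray(v, dtype=float)
    shifted = v - params.t
    out = np.full_like(v, -np.inf)
    ok = shifted > 0
    if np.any(ok):
        out[ok] = stats.lognorm.logpdf(shifted[ok], s=params.s, scale=np.exp(params.m))
    return out if out.ndim else float(out)
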