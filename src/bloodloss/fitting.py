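"""Maximum-likelihood and quantile-matching fits of the (threshold) lognormal.

The three-parameter fit uses a profile likelihood over the threshold t:
for each fixed t the location/scale MLEs of ``log(v - t)`` are available
in closed form, reducing the search to one dimension. The profile
likelihood of a threshold model is unbounded as t approaches the sample
minimum, so the fit reports the interior local maximum, constraining
t <= min(v) - eps, and falls back to the two-parameter fit when the
profile has no interior optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .distributions import LognormalParams, logpdf, quantile

Model = Literal["lognormal2p", "lognormal3p"]

_Z975 = stats.norm.ppf(0.975)


@dataclass
class BloodLossSample:
    """Per-arm blood-loss measurements.

    Volumes are in mL or grams (1 g of blood is treated as 1 mL
    equivalent; the unit is carried through, never converted).
    """

    arm_label: str
    volumes: np.ndarray
    unit: str = "mL"

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 1 or self.volumes.size < 1:
            raise ValueError("volumes must be a nonempty 1-d sequence")
        if self.unit not in ("mL", "g"):
            raise ValueError(f"unit must be 'mL' or 'g', got {self.unit!r}")
        bad = np.flatnonzero(~(np.isfinite(self.volumes) & (self.volumes > 0)))
        if bad.size:
            raise ValueError(
                f"volumes must be positive and finite; offending index {bad[0]} "
                f"(value {self.volumes[bad[0]]!r})"
            )

    @property
    def n(self) -> int:
        return int(self.volumes.size)


@dataclass
class FitResult:
    """Parameter estimates with uncertainty and fit-quality statistics.

    ``cov`` is the estimated parameter covariance in the order (m, s)
    for the 2p model and (m, s, t) for the 3p model; it feeds the
    delta-method tail intervals. ``suffstats`` holds the sufficient
    statistics (mean, variance) of log(v - t_hat).
    """

    params: LognormalParams
    model: Model
    n: int
    loglik: float
    aic: float
    bic: float
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    cov: np.ndarray
    suffstats: tuple[float, float]
    converged: bool = True
    degenerate: bool = False
    message: str = ""
    sample: Optional[BloodLossSample] = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return 2 if self.model == "lognormal2p" else 3

    def display_table(self) -> list[dict]:
        """Rounded per-parameter block (estimate, SE, 95% CI)."""
        rows = []
        names = ["location", "scale", "t"][: self.k]
        vals = [self.params.m, self.params.s, self.params.t]
        keys = ["m", "s", "t"]
        for name, key, val in zip(names, keys, vals):
            lo, hi = self.ci95.get(key, (np.nan, np.nan))
            rows.append(
                {
                    "parameter": name,
                    "estimate": round(val, 2),
                    "se": round(self.se.get(key, np.nan), 3),
                    "ci95_lower": round(lo, 3),
                    "ci95_upper": round(hi, 3),
                }
            )
        return rows


def _information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    return 2 * k - 2 * loglik, k * np.log(n) - 2 * loglik


def _loglik(v: np.ndarray, params: LognormalParams) -> float:
    return float(np.sum(logpdf(v, params)))


def fit_mle_2p(sample: BloodLossSample) -> FitResult:
    """Closed-form lognormal MLE: moments of log(v).

    The log-volume mean and (biased, MLE) variance are jointly
    sufficient; SEs come from the observed information,
    se(m) = s/sqrt(n), se(s) = s/sqrt(2n).
    """
    v = sample.volumes
    n = sample.n
    logv = np.log(v)
    mhat = float(logv.mean())
    s2hat = float(logv.var())
    shat = float(np.sqrt(s2hat))
    if np.ptp(v) == 0.0 or shat == 0.0:
        # all observations identical: scale MLE degenerate at 0
        params = LognormalParams(mhat, np.finfo(float).tiny, 0.0)
        return FitResult(
            params=params,
            model="lognormal2p",
            n=n,
            loglik=np.inf,
            aic=-np.inf,
            bic=-np.inf,
            se={"m": 0.0, "s": 0.0},
            ci95={"m": (mhat, mhat), "s": (0.0, 0.0)},
            cov=np.zeros((2, 2)),
            suffstats=(mhat, 0.0),
            converged=True,
            degenerate=True,
            message="all volumes identical; scale estimate degenerate at 0",
            sample=sample,
        )
    params = LognormalParams(mhat, shat, 0.0)
    ll = _loglik(v, params)
    aic, bic = _information_criteria(ll, 2, n)
    se_m = shat / np.sqrt(n)
    se_s = shat / np.sqrt(2 * n)
    ci = {
        "m": (mhat - _Z975 * se_m, mhat + _Z975 * se_m),
        "s": (shat - _Z975 * se_s, shat + _Z975 * se_s),
    }
    cov = np.diag([se_m**2, se_s**2])
    return FitResult(
        params=params,
        model="lognormal2p",
        n=n,
        loglik=ll,
        aic=aic,
        bic=bic,
        se={"m": se_m, "s": se_s},
        ci95=ci,
        cov=cov,
        suffstats=(mhat, s2hat),
        sample=sample,
    )


def _profile_loglik(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Log-likelihood maximised over (m, s) at fixed threshold(s) t.

    For fixed t the model is a plain lognormal on v - t, so the inner
    maximisation is the closed form of :func:`fit_mle_2p`.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    n = v.size
    w = np.log(v[None, :] - t[:, None])
    s2 = w.var(axis=1)
    out = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0) - w.sum(axis=1)
    return out


def _hessian(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_mle_3p(
    sample: BloodLossSample,
    n_grid: int = 160,
    compute_se: bool = True,
) -> FitResult:
    """Three-parameter lognormal MLE via profile likelihood over t.

    The profile is evaluated on a grid of threshold gaps
    ``g = min(v) - t`` log-spaced between eps and min(v) + 10*median(v)
    (thresholds may be positive, as long as they stay below every
    observation), then the best interior grid point is refined with a
    bounded scalar search. A profile that is monotone toward either
    boundary triggers a fall-back to the two-parameter fit (t = 0) with
    ``converged`` kept True but a warning message recorded.

    ``compute_se=False`` skips the numerical observed-information step
    (used inside bootstrap loops where only the point estimate matters).
    """
    v = sample.volumes
    n = sample.n
    if n < 10:
        raise ValueError(
            f"three-parameter fit needs n >= 10 (threshold not identifiable), got n={n}"
        )
    vmin = float(v.min())
    med = float(np.median(v))
    if np.ptp(v) == 0.0:
        res = fit_mle_2p(sample)
        res.message = "all volumes identical; 3p fit degenerate, returned 2p form"
        return res

    eps = max(1e-6 * abs(vmin), 1e-9)
    g_min = eps
    g_max = vmin + 10.0 * med  # t floor at -10 * median(v)
    g_grid = np.geomspace(g_min, g_max, n_grid)
    t_grid = vmin - g_grid
    ll_grid = _profile_loglik(t_grid, v)

    i_best = int(np.argmax(ll_grid))
    fallback = i_best == 0 or i_best == n_grid - 1
    if not fallback:
        # refine in log-gap space between the neighbours of the best point
        lo, hi = np.log(g_grid[i_best - 1]), np.log(g_grid[i_best + 1])
        opt = optimize.minimize_scalar(
            lambda lg: -_profile_loglik(vmin - np.exp(lg), v)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        that = vmin - float(np.exp(opt.x))
        w = np.log(v - that)
        mhat, s2hat = float(w.mean()), float(w.var())
        shat = float(np.sqrt(s2hat))
        params = LognormalParams(mhat, shat, that)
        ll = _loglik(v, params)
    if fallback:
        base = fit_mle_2p(sample)
        base.model = "lognormal3p"
        base.aic, base.bic = _information_criteria(base.loglik, 3, n)
        base.se["t"] = np.nan
        base.ci95["t"] = (np.nan, np.nan)
        cov3 = np.zeros((3, 3))
        cov3[:2, :2] = base.cov
        base.cov = cov3
        base.message = (
            "profile likelihood monotone toward the boundary; "
            "threshold not identifiable, fell back to t = 0"
        )
        warnings.warn(base.message, RuntimeWarning, stacklevel=2)
        return base

    se: dict[str, float] = {"m": np.nan, "s": np.nan, "t": np.nan}
    ci: dict[str, tuple[float, float]] = {k: (np.nan, np.nan) for k in se}
    cov = np.full((3, 3), np.nan)
    converged = bool(opt.success)
    msg = "" if converged else f"profile refinement did not converge: {opt.message}"
    if compute_se:
        def negll(x):
            m, s, t = x
            if s <= 0 or t >= vmin:
                return np.inf
            return -_loglik(v, LognormalParams(m, s, t))

        # the (m, t) direction is soft for threshold models: too-small
        # difference steps drown the smallest eigenvalue in cancellation
        # noise, so escalate the step until the information is PD
        x_opt = np.array([mhat, shat, that])
        for rel_step in (1e-5, 1e-4, 1e-3):
            H = _hessian(lambda x: -negll(x), x_opt, rel_step=rel_step)
            info = -H  # observed information
            try:
                eigs = np.linalg.eigvalsh(info)
                if eigs.min() <= 0:
                    msg = "observed information not positive definite; SEs unavailable"
                    continue
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                msg = "observed information singular; SEs unavailable"
                continue
            for key, est, sd in zip(
                ("m", "s", "t"), (mhat, shat, that), np.sqrt(np.diag(cov))
            ):
                se[key] = float(sd)
                ci[key] = (est - _Z975 * sd, est + _Z975 * sd)
            msg = ""
            break
        else:
            cov = np.full((3, 3), np.nan)

    aic, bic = _information_criteria(ll, 3, n)
    return FitResult(
        params=params,
        model="lognormal3p",
        n=n,
        loglik=ll,
        aic=aic,
        bic=bic,
        se=se,
        ci95=ci,
        cov=cov,
        suffstats=(mhat, s2hat),
        converged=converged,
        message=msg,
        sample=sample,
    )


@dataclass(frozen=True)
class QuantileSpec:
    """Reported (probability, volume) pairs for quantile matching."""

    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pairs = tuple((float(p), float(q)) for p, q in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        ps = np.array([p for p, _ in pairs])
        qs = np.array([q for _, q in pairs])
        if len(pairs) < 2:
            raise ValueError("need at least 2 (probability, volume) pairs")
        if np.any((ps <= 0) | (ps >= 1)) or np.any(np.diff(ps) <= 0):
            raise ValueError("probabilities must be strictly increasing in (0, 1)")
        if np.any(np.diff(qs) <= 0):
            raise ValueError("volumes must be strictly increasing")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for p, _ in self.pairs])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([q for _, q in self.pairs])


def fit_from_quantiles(spec: QuantileSpec, model: Model = "lognormal2p") -> FitResult:
    """Least-squares quantile matching within the lognormal family.

    Finds the distribution whose quantiles are closest (sum of squared
    differences) to the supplied pairs — the standard way to recover a
    distribution from published percentiles. With as many pairs as free
    parameters the fit interpolates exactly. No likelihood is available,
    so SEs, loglik, AIC and BIC are reported as NaN.
    """
    k = 2 if model == "lognormal2p" else 3
    ps, qs = spec.probabilities, spec.volumes
    if len(spec.pairs) < k:
        raise ValueError(f"{model} needs >= {k} pairs, got {len(spec.pairs)}")
    z = stats.norm.ppf(ps)

    # 2p start: regress log(q) on z -> intercept m, slope s
    slope, intercept = np.polyfit(z, np.log(qs), 1)
    m0, s0 = float(intercept), max(float(slope), 1e-6)

    if k == 2:
        sol = optimize.least_squares(
            lambda x: np.exp(x[0] + x[1] * z) - qs,
            np.array([m0, s0]),
            bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
        )
        m, s, t = float(sol.x[0]), float(sol.x[1]), 0.0
    else:
        t_hi = float(qs.min()) - 1e-9 * max(abs(qs.min()), 1.0)
        x0 = np.array([m0, s0, min(0.0, t_hi - 1.0)])

        def resid3(x):
            return x[2] + np.exp(x[0] + x[1] * z) - qs

        sol = optimize.least_squares(
            resid3,
            x0,
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, t_hi]),
        )
        m, s, t = float(sol.x[0]), float(sol.x[1]), float(sol.x[2])

    params = LognormalParams(m, s, t)
    names = ("m", "s") if k == 2 else ("m", "s", "t")
    return FitResult(
        params=params,
        model=model,
        n=len(spec.pairs),
        loglik=np.nan,
        aic=np.nan,
        bic=np.nan,
        se={nm: np.nan for nm in names},
        ci95={nm: (np.nan, np.nan) for nm in names},
        cov=np.full((k, k), np.nan),
        suffstats=(np.nan, np.nan),
        converged=bool(sol.success),
        message="quantile-matching fit: no likelihood-based uncertainty",
    )


def compare_fits(results: Sequence[FitResult]) -> list[dict]:
    """Rank fits of the same sample by AIC (BIC tiebreak), with deltas."""
    results = list(results)
    if not results:
        raise ValueError("no fits to compare")
    ns = {r.n for r in results}
    if len(ns) > 1:
        raise ValueError(f"fits come from different samples (n values {sorted(ns)})")
    ranked = sorted(results, key=lambda r: (r.aic, r.bic))
    best_aic, best_bic = ranked[0].aic, ranked[0].bic
    return [
        {
            "model": r.model,
            "aic": r.aic,
            "bic": r.bic,
            "delta_aic": r.aic - best_aic,
            "delta_bic": r.bic - best_bic,
            "loglik": r.loglik,
            "result": r,
        }
        for r in ranked
    ]
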