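"""Descriptive statistics and goodness-of-fit diagnostics (compute side).

``describe`` reports the standard univariate summary of a failure-time
sample: mean, quartiles (linear interpolation of order statistics),
sample variance (n-1 denominator), range, moment skewness m3/m2^(3/2),
and RAW kurtosis m4/m2^2 (normal = 3, not excess), with central moments
taken with 1/n weights.

``ecdf``, ``kaplan_meier`` and ``qq_points`` provide the numbers behind
the usual fitted-model graphics: the empirical CDF, the product-limit
survival estimate (via lifelines), and model-vs-empirical quantile pairs
at plotting positions (i - 0.5)/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .estimation import FitResult, _as_values

__all__ = ["DescriptiveStats", "describe", "ecdf", "kaplan_meier", "qq_points"]


@dataclass(frozen=True)
class DescriptiveStats:
    mean: float
    q1: float
    median: float
    q3: float
    variance: float
    minimum: float
    maximum: float
    range: float
    skewness: float
    kurtosis: float
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def describe(sample) -> DescriptiveStats:
    """Summary statistics of a positive sample (n >= 2 for the variance)."""
    v = _as_values(sample)
    if v.size < 2:
        raise ValueError("need n >= 2 for the sample variance")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    m2 = np.mean((v - v.mean()) ** 2)
    if m2 == 0.0:
        skew = kurt = float("nan")  # flagged undefined for a constant sample
    else:
        skew = float(sps.skew(v))                     # m3 / m2^(3/2)
        kurt = float(sps.kurtosis(v, fisher=False))   # raw m4 / m2^2
    return DescriptiveStats(
        mean=float(v.mean()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        variance=float(v.var(ddof=1)),
        minimum=float(v.min()),
        maximum=float(v.max()),
        range=float(v.max() - v.min()),
        skewness=skew,
        kurtosis=kurt,
        n=int(v.size),
    )


def ecdf(sample) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: value i/n at the i-th order statistic."""
    v = np.sort(_as_values(sample))
    n = v.size
    return v, np.arange(1, n + 1) / n


def kaplan_meier(sample, censored=None) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit survival estimate at the event times.

    ``censored`` flags right-censored observations (True = censored).
    With no censoring, KM survival equals 1 - ECDF at every event time.
    Returns (times, survival) at the distinct observed times.
    """
    v = _as_values(sample)
    if censored is None:
        censored = np.zeros(v.size, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    if censored.shape != v.shape:
        raise ValueError("censor flags must match the sample length")
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(v, event_observed=~censored)
    sf = km.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0  # drop the t=0 anchor row
    return times[keep], surv[keep]


def qq_points(sample, fitted: FitResult) -> np.ndarray:
    """Model-vs-empirical quantile pairs at plotting positions (i-0.5)/n.

    Column 0 holds the fitted model's quantiles, column 1 the order
    statistics; points near the identity line indicate good fit.
    """
    if not fitted.converged:
        raise ValueError("QQ points require a converged fit")
    from .distributions import FAMILIES, NBPVFParams, nbpvf_quantile, rival_cdf, RivalParams
    from scipy.optimize import brentq

    v = np.sort(_as_values(sample))
    n = v.size
    p = (np.arange(1, n + 1) - 0.5) / n
    if fitted.family == "nbpvf":
        theo = np.asarray(nbpvf_quantile(p, NBPVFParams(*fitted.params)))
    elif fitted.family == "vf_weibull":
        theo = np.asarray(
            nbpvf_quantile(p, NBPVFParams(fitted.params[0], fitted.params[1], 1.0))
        )
    else:
        rp = RivalParams(fitted.family, *fitted.params)

        def one(pi):
            f = lambda w: rival_cdf(w, rp) - pi
            lo, hi = 1e-12, 1.0
            while f(hi) < 0:
                hi *= 2.0
                if hi > 1e12:
                    raise RuntimeError("quantile bracket expansion failed")
            return brentq(f, lo, hi, xtol=1e-12, rtol=1e-10)

        theo = np.array([one(pi) for pi in p])
    return np.column_stack([theo, v])
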