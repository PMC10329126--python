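"""Information-criterion model comparison.

Four penalized -2*log-likelihood criteria, smaller is better:

    AIC  = 2k - 2*l          CAIC = 2nk/(n - k - 1) - 2*l
    BIC  = k*ln(n) - 2*l     HQIC = 2k*ln(ln(n)) - 2*l

with k the number of fitted parameters, n the sample size, and l the
maximized log-likelihood.  ``compare`` fits each requested family on a
sample and returns the rows ranked ascending by AIC (BIC tiebreak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitResult, fit_mle

__all__ = ["ICRow", "information_criteria", "compare", "comparison_table"]


@dataclass(frozen=True)
class ICRow:
    family: str
    k: int
    n: int
    loglik: float
    aic: float
    caic: float
    bic: float
    hqic: float
    params: tuple = ()
    converged: bool = True


def information_criteria(loglik: float, k: int, n: int, family: str = "",
                         params=(), converged: bool = True) -> ICRow:
    """Compute AIC, CAIC, BIC, HQIC from a maximized log-likelihood.

    The degenerate k = 0 "null model" is allowed (all penalties vanish);
    otherwise n > k + 1 is required for the CAIC denominator.
    """
    if not np.isfinite(loglik):
        raise ValueError("loglik must be finite")
    if k < 0 or n < 1:
        raise ValueError("k >= 0 and n >= 1 required")
    if k > 0 and n <= k + 1:
        raise ValueError("CAIC undefined: need n > k + 1")
    m2l = -2.0 * loglik
    aic = 2.0 * k + m2l
    caic = (2.0 * n * k / (n - k - 1.0) if k > 0 else 0.0) + m2l
    bic = k * np.log(n) + m2l
    hqic = 2.0 * k * np.log(np.log(n)) + m2l
    return ICRow(family=family, k=k, n=n, loglik=float(loglik), aic=float(aic),
                 caic=float(caic), bic=float(bic), hqic=float(hqic),
                 params=tuple(params), converged=converged)


def _row_from_fit(fit: FitResult) -> ICRow:
    return information_criteria(fit.loglik, fit.k, fit.n, family=fit.family,
                                params=tuple(fit.params), converged=fit.converged)


def compare(sample, families) -> list[ICRow]:
    """Fit every family and rank by AIC (ascending), BIC breaking ties.

    A family whose fit raises is flagged (converged=False, infinite
    criteria) and placed last; the other rows are unaffected.
    """
    rows = []
    for fam in families:
        try:
            rows.append(_row_from_fit(fit_mle(sample, family=fam)))
        except Exception:
            inf = float("inf")
            rows.append(ICRow(family=fam, k=0, n=0, loglik=-inf, aic=inf,
                              caic=inf, bic=inf, hqic=inf, converged=False))
    rows.sort(key=lambda r: (not r.converged, r.aic, r.bic))
    return rows


def comparison_table(rows) -> pd.DataFrame:
    """Ranked comparison as a DataFrame with columns Model, AIC, CAIC, BIC, HQIC."""
    return pd.DataFrame(
        [
            {"Model": r.family, "AIC": r.aic, "CAIC": r.caic,
             "BIC": r.bic, "HQIC": r.hqic}
            for r in rows
        ]
    )
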