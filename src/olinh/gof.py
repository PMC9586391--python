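"""Goodness-of-fit statistics and information-criterion model comparison.

All three EDF statistics are computed from the probability integral
transforms u_(i) = F(x_(i)) of the sorted sample:

    KS  = max_i max(i/n - u_(i), u_(i) - (i-1)/n)
    CvM = 1/(12n) + sum_i (u_(i) - (2i-1)/(2n))^2
    AD  = -n - (1/n) sum_i (2i-1) [ln u_(i) + ln(1 - u_(n+1-i))]

with the KS p-value from the asymptotic Kolmogorov law.  Information
criteria follow the standard definitions; CAIC here is the small-sample
corrected AIC, AIC + 2k(k+1)/(n-k-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .distribution import ObservationSet
from .mle import InhMLE, MleFit

__all__ = ["GofReport", "gof_report", "fit_inh", "compare_models",
           "comparison_markdown"]

_PIT_EPS = 1e-10


@dataclass(frozen=True)
class GofReport:
    ks_stat: float
    ks_pvalue: float
    cvm_stat: float
    ad_stat: float
    aic: float
    caic: float
    bic: float
    hqic: float
    n: int
    k: int
    loglik: float

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


def gof_report(data, cdf, k: int, loglik: float) -> GofReport:
    """EDF statistics and information criteria for a fitted CDF.

    `cdf` is a callable x -> F(x); `k` the number of fitted parameters and
    `loglik` the maximised log-likelihood.
    """
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    if not (k >= 1 and n > k + 1):
        raise ValueError("need k >= 1 fitted parameters and n > k + 1")
    u = np.asarray([float(cdf(xi)) for xi in x])
    u = np.clip(u, _PIT_EPS, 1.0 - _PIT_EPS)
    i = np.arange(1, n + 1)

    ks = float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))
    ksp = float(special.kolmogorov(np.sqrt(n) * ks))
    cvm = float(1.0 / (12.0 * n) + np.sum((u - (2 * i - 1) / (2.0 * n)) ** 2))
    ad = float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))

    aic = 2.0 * k - 2.0 * loglik
    caic = aic + 2.0 * k * (k + 1) / (n - k - 1)
    bic = k * np.log(n) - 2.0 * loglik
    hqic = 2.0 * k * np.log(np.log(n)) - 2.0 * loglik
    return GofReport(ks_stat=ks, ks_pvalue=ksp, cvm_stat=cvm, ad_stat=ad,
                     aic=aic, caic=caic, bic=bic, hqic=hqic,
                     n=n, k=k, loglik=loglik)


def fit_inh(data, ci_level: float = 0.95) -> MleFit:
    """MLE of the two-parameter INH baseline (comparator model)."""
    return InhMLE(data).fit(ci_level=ci_level)


def compare_models(data, fits) -> list[tuple[str, GofReport]]:
    """Rank fitted models by AIC (ascending), ties by BIC then name.

    `fits` is an iterable of (name, cdf, k, loglik) tuples.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to compare")
    reports = [(name, gof_report(data, cdf, k, ll)) for name, cdf, k, ll in fits]
    reports.sort(key=lambda item: (item[1].aic, item[1].bic, item[0]))
    return reports


def comparison_markdown(ranked) -> str:
    """Markdown table of a `compare_models` result."""
    header = ("| model | CvM | AD | KS | KS p | AIC | CAIC | BIC | HQIC |\n"
              "|---|---|---|---|---|---|---|---|---|")
    rows = [
        f"| {name} | {r.cvm_stat:.4f} | {r.ad_stat:.4f} | {r.ks_stat:.4f} "
        f"| {r.ks_pvalue:.4f} | {r.aic:.4f} | {r.caic:.4f} | {r.bic:.4f} "
        f"| {r.hqic:.4f} |"
        for name, r in ranked
    ]
    return "\n".join([header, *rows])
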