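"""Odd Lomax inverted Nadarajah-Haghighi (OLINH) distribution.

The inverted Nadarajah-Haghighi (INH) law is the distribution of 1/Y when Y
is Nadarajah-Haghighi; its CDF on x > 0 is

    G(x; delta, theta) = exp(1 - (1 + delta/x)**theta).

The odd Lomax-G (OL-G) transform maps a baseline CDF G to

    F(x) = 1 - beta**alpha * (beta + G/(1-G))**(-alpha),

adding two shape parameters alpha, beta > 0.  OLINH is OL-G applied to the
INH baseline, a four-parameter family (alpha, beta, delta, theta) with a
power-law right tail of index alpha (so the r-th moment exists iff r < alpha)
and decreasing or upside-down-bathtub hazard shapes.

All evaluators here work on the log scale where cancellation threatens:
writing s = 1 - (1 + delta/x)**theta (so the baseline CDF is e**s, s <= 0),
log(1 - e**s) is computed via expm1 and the survival function directly from
the OL-G form, never as 1 - CDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "InhParams",
    "OlinhParams",
    "ObservationSet",
    "inh_cdf",
    "inh_pdf",
    "inh_logpdf",
    "olg_cdf",
    "olinh_cdf",
    "olinh_sf",
    "olinh_logsf",
    "olinh_pdf",
    "olinh_logpdf",
    "olinh_hazard",
    "olinh_orf",
    "olinh_quantile",
    "olinh_rvs",
]


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be a finite positive real, got {value!r}")
    return value


@dataclass(frozen=True)
class InhParams:
    """Baseline INH parameter vector (delta, theta), both > 0."""

    delta: float
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", _require_positive("delta", self.delta))
        object.__setattr__(self, "theta", _require_positive("theta", self.theta))


@dataclass(frozen=True)
class OlinhParams:
    """Full OLINH parameter vector (alpha, beta, delta, theta), all > 0.

    alpha, beta are the odd Lomax shape parameters; (delta, theta) is the
    INH baseline.  alpha is also the right tail index.
    """

    alpha: float
    beta: float
    delta: float
    theta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "delta", "theta"):
            object.__setattr__(self, name, _require_positive(name, getattr(self, name)))

    @property
    def baseline(self) -> InhParams:
        return InhParams(self.delta, self.theta)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.delta, self.theta])

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "OlinhParams":
        a, b, d, t = np.asarray(list(arr), dtype=float)
        return cls(a, b, d, t)


class ObservationSet:
    """An ordered sample of strictly positive reals.

    Rejects NaN, zero and negative entries at construction so downstream
    likelihood code never has to re-validate.
    """

    def __init__(self, values: Iterable[float]):
        arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                         dtype=float).ravel()
        if arr.size < 1:
            raise ValueError("sample must contain at least one observation")
        bad = ~np.isfinite(arr) | (arr <= 0.0)
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"observation {idx} is {arr[idx]!r}; all values must be finite and > 0"
            )
        self.values = arr
        self.values.setflags(write=False)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.values)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __repr__(self) -> str:
        return f"ObservationSet(n={self.n}, min={self.values.min():g}, max={self.values.max():g})"


def _check_x(x, allow_zero: bool = False):
    x = np.asarray(x, dtype=float)
    if allow_zero:
        if np.any(x < 0.0) or np.any(np.isnan(x)):
            raise ValueError("x must be >= 0")
    else:
        if np.any(x <= 0.0) or np.any(np.isnan(x)) or np.any(np.isinf(x)):
            raise ValueError("x must be a finite positive real")
    return x


# ---------------------------------------------------------------------------
# INH baseline
# ---------------------------------------------------------------------------

def _inh_s(x, p: InhParams):
    """s = 1 - (1 + delta/x)**theta  (log of the baseline CDF)."""
    with np.errstate(divide="ignore", over="ignore"):
        t = np.exp(p.theta * np.log1p(p.delta / x))
    return 1.0 - t


def inh_cdf(x, p: InhParams):
    """Baseline CDF G(x) = exp(1 - (1 + delta/x)**theta); limits used at 0, inf."""
    x = _check_x(x, allow_zero=True)
    with np.errstate(divide="ignore"):
        out = np.where(np.isinf(x), 1.0, np.exp(_inh_s(np.where(x > 0, x, 1.0), p)))
    out = np.where(x == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def inh_logpdf(x, p: InhParams):
    x = _check_x(x)
    lw = np.log1p(p.delta / x)
    out = (np.log(p.delta * p.theta) - 2.0 * np.log(x) + (p.theta - 1.0) * lw
           + 1.0 - np.exp(p.theta * lw))
    return out if out.ndim else float(out)


def inh_pdf(x, p: InhParams):
    """Baseline density (delta*theta/x^2)(1+delta/x)^(theta-1) exp(1-(1+delta/x)^theta)."""
    out = np.exp(inh_logpdf(x, p))
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# OL-G transform
# ---------------------------------------------------------------------------

def olg_cdf(g, alpha: float, beta: float):
    """Odd Lomax transform of a baseline CDF value g in [0, 1].

    Returns 1 - beta**alpha * (beta + g/(1-g))**(-alpha); g = 1 is treated as
    the limit 1.
    """
    alpha = _require_positive("alpha", alpha)
    beta = _require_positive("beta", beta)
    g = np.asarray(g, dtype=float)
    if np.any(g < 0.0) or np.any(g > 1.0) or np.any(np.isnan(g)):
        raise ValueError("g must lie in [0, 1]")
    gg = np.where(g < 1.0, g, 0.5)
    # -expm1(log g) = 1 - g, but g is given directly here
    odds = gg / (1.0 - gg)
    out = -np.expm1(-alpha * np.log1p(odds / beta))
    out = np.where(g == 1.0, 1.0, out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# OLINH distribution functions
# ---------------------------------------------------------------------------

def _log_odds(x, w: OlinhParams):
    """log[G/(1-G)] for the INH baseline at x, stable in both tails."""
    s = _inh_s(x, w.baseline)
    # log(1 - e^s): for s << 0 this is ~ -e^s; expm1 handles both regimes
    with np.errstate(divide="ignore"):
        log1mG = np.log(-np.expm1(s))
    return s - log1mG, s, log1mG


def olinh_logsf(x, w: OlinhParams):
    """Log survival function, computed from the OL-G form (no cancellation)."""
    x = _check_x(x, allow_zero=True)
    xs = np.where(x > 0, x, 1.0)
    lr, _, _ = _log_odds(np.where(np.isinf(xs), 1.0, xs), w)
    # log sf = -alpha * log(1 + odds/beta)
    out = -w.alpha * np.logaddexp(0.0, lr - np.log(w.beta))
    out = np.where(x == 0.0, 0.0, out)
    out = np.where(np.isinf(x), -np.inf, out)
    return out if out.ndim else float(out)


def olinh_sf(x, w: OlinhParams):
    out = np.exp(olinh_logsf(x, w))
    return out if np.ndim(out) else float(out)


def olinh_cdf(x, w: OlinhParams):
    """OLINH CDF, the OL-G transform of the INH baseline CDF."""
    out = -np.expm1(olinh_logsf(x, w))
    return out if np.ndim(out) else float(out)


def olinh_logpdf(x, w: OlinhParams):
    """Stable log-density; finite wherever the density is positive."""
    x = _check_x(x)
    lr, s, log1mG = _log_odds(x, w)
    lw = np.log1p(w.delta / x)
    out = (np.log(w.alpha * w.theta * w.delta) + w.alpha * np.log(w.beta)
           - 2.0 * np.log(x) + (w.theta - 1.0) * lw + s - 2.0 * log1mG
           - (w.alpha + 1.0) * np.logaddexp(np.log(w.beta), lr))
    return out if out.ndim else float(out)


def olinh_pdf(x, w: OlinhParams):
    out = np.exp(olinh_logpdf(x, w))
    return out if np.ndim(out) else float(out)


def olinh_hazard(x, w: OlinhParams):
    """Hazard rate f/(1-F); decreasing or upside-down bathtub shaped."""
    out = np.exp(olinh_logpdf(x, w) - olinh_logsf(x, w))
    return out if np.ndim(out) else float(out)


def olinh_orf(x, w: OlinhParams):
    """Odds ratio of failure F/(1-F) = beta^-alpha (beta + G/(1-G))^alpha - 1."""
    x = _check_x(x)
    lr, _, _ = _log_odds(x, w)
    out = np.expm1(w.alpha * np.logaddexp(0.0, lr - np.log(w.beta)))
    return out if np.ndim(out) else float(out)


def olinh_quantile(q, w: OlinhParams):
    """Quantile function, the analytic inverse of the CDF.

    With c = (1-q)^(-1/alpha) - 1 and u = beta*c, the baseline CDF at the
    quantile is G_q = u/(1+u) and

        Q(q) = delta / ((1 - log G_q)**(1/theta) - 1).

    Evaluated via log1p/expm1 so that both tails (q -> 0, q -> 1) stay
    accurate.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0.0) or np.any(q >= 1.0) or np.any(np.isnan(q)):
        raise ValueError("q must lie strictly inside (0, 1)")
    # c = expm1(-log(1-q)/alpha), exact for q near 0 and near 1
    c = np.expm1(-np.log1p(-q) / w.alpha)
    u = w.beta * c
    # log G_q = -log(1 + 1/u)
    log_gq = -np.log1p(1.0 / u)
    # (1 - log G_q)^(1/theta) - 1
    denom = np.expm1(np.log1p(-log_gq) / w.theta)
    out = w.delta / denom
    return out if out.ndim else float(out)


def olinh_rvs(n: int, w: OlinhParams, seed) -> ObservationSet:
    """Draw n i.i.d. variates by inverse-transform sampling.

    `seed` may be an int or a numpy Generator; an int gives reproducible
    output.
    """
    if int(n) < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=int(n))
    # keep u away from the exact endpoints the quantile rejects
    eps = np.finfo(float).tiny
    u = np.clip(u, eps, 1.0 - 1e-16)
    return ObservationSet(olinh_quantile(u, w))
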