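"""Maximum-likelihood estimation for the OLINH and INH distributions.

Follows the statsmodels model/results convention: ``OlinhMLE(data).fit()``
returns an ``OlinhMLEResults`` carrying estimates, observed-information
standard errors and Wald intervals.

The four-parameter likelihood has a closed-form profile for the tail index
alpha,

    alpha_hat(beta, delta, theta) = n / sum_i log(B_i / beta),
    B_i = beta + G_i/(1 - G_i),  G_i = exp(1 - (1 + delta/x_i)**theta),

so the numerical search runs over (beta, delta, theta) only, on the log
scale, from several deterministic starting points (the delta-theta direction
is ridge-like on real data, so single-start fits are unreliable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .distribution import InhParams, ObservationSet, OlinhParams, inh_logpdf

__all__ = ["MleFit", "OlinhMLE", "InhMLE", "log_likelihood", "score",
           "profile_alpha", "fit_mle"]


# ---------------------------------------------------------------------------
# likelihood pieces (vectorised over the sample)
# ---------------------------------------------------------------------------

def _pieces(x: np.ndarray, w: OlinhParams):
    """Per-observation quantities shared by loglik and score.

    Returns dict with lw=log(1+delta/x), T=(1+delta/x)^theta, s=1-T,
    log1mG=log(1-e^s), lr=log odds, logD=log(beta+G/(1-G)).
    """
    lw = np.log1p(w.delta / x)
    with np.errstate(over="ignore"):
        T = np.exp(w.theta * lw)
    s = 1.0 - T
    with np.errstate(divide="ignore"):
        log1mG = np.log(-np.expm1(s))
    lr = s - log1mG
    logD = np.logaddexp(np.log(w.beta), lr)
    return {"lw": lw, "T": T, "s": s, "log1mG": log1mG, "lr": lr, "logD": logD}


def log_likelihood(data: ObservationSet, w: OlinhParams) -> float:
    """OLINH log-likelihood, the sum of the stable log-density over the sample."""
    x = np.asarray(data)
    n = x.size
    p = _pieces(x, w)
    return float(
        n * (np.log(w.alpha * w.theta * w.delta) + w.alpha * np.log(w.beta))
        - 2.0 * np.log(x).sum()
        + (w.theta - 1.0) * p["lw"].sum()
        + p["s"].sum()
        - 2.0 * p["log1mG"].sum()
        - (w.alpha + 1.0) * p["logD"].sum()
    )


def score(data: ObservationSet, w: OlinhParams) -> np.ndarray:
    """Analytic gradient of the log-likelihood in (alpha, beta, delta, theta)."""
    x = np.asarray(data)
    n = x.size
    p = _pieces(x, w)
    lw, T, s, log1mG, lr, logD = (p[k] for k in ("lw", "T", "s", "log1mG", "lr", "logD"))
    G = np.exp(s)
    one_mG = -np.expm1(s)
    D = np.exp(logD)
    # helper ratios: G/(1-G) and G/((1-G)^2 D)
    g_over = np.exp(lr)
    g_sq_D = np.exp(s - 2.0 * log1mG - logD)
    A = np.exp((w.theta - 1.0) * lw) / x          # (1+d/x)^(theta-1) / x
    L = T * lw                                     # (1+d/x)^theta log(1+d/x)

    d_alpha = n / w.alpha + n * np.log(w.beta) - logD.sum()
    d_beta = n * w.alpha / w.beta - (w.alpha + 1.0) * np.sum(1.0 / D)
    d_delta = (n / w.delta
               + (w.theta - 1.0) * np.sum(1.0 / (x + w.delta))
               - w.theta * A.sum()
               - 2.0 * w.theta * np.sum(A * g_over)
               + (w.alpha + 1.0) * w.theta * np.sum(A * g_sq_D))
    d_theta = (n / w.theta
               + lw.sum()
               - L.sum()
               - 2.0 * np.sum(L * g_over)
               + (w.alpha + 1.0) * np.sum(L * g_sq_D))
    return np.array([d_alpha, d_beta, d_delta, d_theta])


def profile_alpha(data: ObservationSet, beta: float, delta: float, theta: float) -> float:
    """Closed-form maximiser of the likelihood in alpha at fixed (beta, delta, theta)."""
    x = np.asarray(data)
    p = _pieces(x, OlinhParams(1.0, beta, delta, theta))
    # sum log(B_i/beta) = sum log1p(odds_i/beta) > 0 always
    denom = np.logaddexp(0.0, p["lr"] - np.log(beta)).sum()
    with np.errstate(divide="ignore"):
        return float(x.size / denom)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class MleFit:
    """Point estimates, observed-information SEs and Wald intervals."""

    estimates: object                 # OlinhParams or InhParams
    std_errors: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    ci_level: float
    ci_bounds: np.ndarray             # (k, 2), lower floored at 0
    param_names: Sequence[str]
    nobs: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        return np.array([getattr(self.estimates, n) for n in self.param_names])

    @property
    def bse(self) -> np.ndarray:
        return self.std_errors

    @property
    def llf(self) -> float:
        return self.loglik

    @property
    def k(self) -> int:
        return len(self.param_names)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * np.log(self.nobs) - 2.0 * self.loglik

    def conf_int(self) -> np.ndarray:
        return self.ci_bounds

    def summary(self) -> str:
        lines = [
            f"{type(self.estimates).__name__} maximum-likelihood fit  "
            f"(n={self.nobs}, loglik={self.loglik:.4f}, "
            f"converged={self.converged})",
            f"{'param':>8} {'estimate':>12} {'std err':>10} "
            f"{f'[{self.ci_level:.0%} Wald CI]':>24}",
        ]
        for i, name in enumerate(self.param_names):
            lo, hi = self.ci_bounds[i]
            lines.append(
                f"{name:>8} {self.params[i]:>12.4f} {self.std_errors[i]:>10.4f} "
                f"  [{lo:>9.4f}, {hi:>9.4f}]"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimates": dict(zip(self.param_names, self.params.tolist())),
            "std_errors": dict(zip(self.param_names, self.std_errors.tolist())),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "ci_level": self.ci_level,
            "ci_bounds": {n: list(map(float, b))
                          for n, b in zip(self.param_names, self.ci_bounds)},
            "n": self.nobs,
        }


def _central_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-parameter relative steps."""
    k = x0.size
    h = rel_step * np.maximum(np.abs(x0), 1e-8)
    H = np.empty((k, k))
    f0 = f(x0)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (f(x0 + ei) - 2.0 * f0 + f(x0 - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej)
                - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _wald_machinery(neg_loglik, est: np.ndarray, ci_level: float, info=None):
    """Covariance from the observed information, SEs and zero-floored CIs."""
    flagged = False
    H = _central_hessian(neg_loglik, est) if info is None else info
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0) or not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        flagged = True
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    ci = np.column_stack([np.maximum(est - z * se, 0.0), est + z * se])
    return cov, se, ci, flagged


# ---------------------------------------------------------------------------
# INH baseline fit
# ---------------------------------------------------------------------------

def _inh_quantile(q: float, delta: float, theta: float) -> float:
    return delta / (np.expm1(np.log1p(-np.log(q)) / theta))


def _inh_start(x: np.ndarray) -> tuple[float, float]:
    """Quantile-matched (delta, theta) start: match the sample quartiles."""
    q1, q3 = np.quantile(x, [0.25, 0.75])
    target = q3 / q1

    def ratio(log_theta):
        th = np.exp(log_theta)
        return (_inh_quantile(0.75, 1.0, th) / _inh_quantile(0.25, 1.0, th)) - target

    try:
        lo, hi = -6.0, 6.0
        if ratio(lo) * ratio(hi) < 0:
            lt = optimize.brentq(ratio, lo, hi, xtol=1e-10)
            theta = float(np.exp(lt))
        else:
            theta = 1.0
    except ValueError:
        theta = 1.0
    med = np.quantile(x, 0.5)
    delta = float(med * np.expm1(np.log1p(np.log(2.0)) / theta))
    return max(delta, 1e-6), theta


class InhMLE:
    """Two-parameter inverted Nadarajah-Haghighi model fitted by MLE."""

    param_names = ("delta", "theta")

    def __init__(self, data):
        self.data = data if isinstance(data, ObservationSet) else ObservationSet(data)

    def loglike(self, params) -> float:
        if isinstance(params, InhParams):
            p = params
        else:
            p = InhParams(*np.asarray(params, dtype=float))
        return float(inh_logpdf(np.asarray(self.data), p).sum())

    def fit(self, ci_level: float = 0.95) -> MleFit:
        x = np.asarray(self.data)
        if x.size < 3:
            raise ValueError("INH fit needs at least 3 observations")

        def nll_log(eta):
            return -self.loglike(np.exp(eta))

        d0, t0 = _inh_start(x)
        starts = [np.log([d0, t0]), np.log([d0 * 4, t0 / 2]), np.log([1.0, 1.0])]
        best = None
        for s0 in starts:
            r = optimize.minimize(nll_log, s0, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-10,
                                           "maxiter": 4000})
            if best is None or r.fun < best.fun:
                best = r
        est = np.exp(best.x)
        ll = -best.fun

        def nll_nat(p):
            return -self.loglike(np.abs(p))

        cov, se, ci, flagged = _wald_machinery(nll_nat, est, ci_level)
        return MleFit(
            estimates=InhParams(*est), std_errors=se, covariance=cov,
            loglik=ll, converged=bool(best.success), ci_level=ci_level,
            ci_bounds=ci, param_names=self.param_names, nobs=x.size,
            diagnostics={"hessian_pinv": flagged},
        )


# ---------------------------------------------------------------------------
# OLINH fit
# ---------------------------------------------------------------------------

class OlinhMLE:
    """Four-parameter OLINH model fitted by profile maximum likelihood."""

    param_names = ("alpha", "beta", "delta", "theta")

    def __init__(self, data):
        self.data = data if isinstance(data, ObservationSet) else ObservationSet(data)

    # -- likelihood surface ------------------------------------------------
    def loglike(self, params) -> float:
        w = params if isinstance(params, OlinhParams) else OlinhParams.from_array(params)
        return log_likelihood(self.data, w)

    def score(self, params) -> np.ndarray:
        w = params if isinstance(params, OlinhParams) else OlinhParams.from_array(params)
        return score(self.data, w)

    def profile_alpha(self, beta: float, delta: float, theta: float) -> float:
        return profile_alpha(self.data, beta, delta, theta)

    def _profile_obj(self, eta: np.ndarray):
        """Negative profiled loglik and its gradient in (log b, log d, log t)."""
        b, d, t = np.exp(eta)
        try:
            a = self.profile_alpha(b, d, t)
            w = OlinhParams(a, b, d, t)
            ll = log_likelihood(self.data, w)
            if not np.isfinite(ll):
                raise FloatingPointError
            # envelope theorem: d(profile)/d(eta) = (dl/d(param)) * param
            g = score(self.data, w)[1:] * np.array([b, d, t])
        except (FloatingPointError, OverflowError, ValueError, ZeroDivisionError):
            return 1e12, np.zeros(3)
        return -ll, -g

    def _starts(self) -> list[np.ndarray]:
        """Eight deterministic starts in (log beta, log delta, log theta).

        Built from the quantile-matched INH fit (delta0, theta0), crossed
        with small/large beta and two ridge directions in (delta, theta);
        alpha is profiled out so it needs no start.
        """
        x = np.asarray(self.data)
        d0, t0 = _inh_start(x)
        starts = []
        for d_scale, t_scale in ((1.0, 1.0), (8.0, 0.5), (64.0, 0.25), (0.25, 2.0)):
            for b0 in (0.5, 2.0):
                starts.append(np.log([b0, d0 * d_scale, t0 * t_scale]))
        return starts

    def observed_information(self, params, rel_step: float = 1e-5) -> np.ndarray:
        """Observed information: minus the (symmetrised) Jacobian of the
        analytic score, by central differences with per-parameter relative
        steps."""
        est = np.asarray(params, dtype=float) if not isinstance(params, OlinhParams) \
            else params.as_array()
        k = est.size
        J = np.empty((k, k))
        h = rel_step * np.abs(est)
        for j in range(k):
            p1 = est.copy(); p1[j] += h[j]
            p2 = est.copy(); p2[j] -= h[j]
            J[:, j] = (self.score(p1) - self.score(p2)) / (2.0 * h[j])
        return -(J + J.T) / 2.0

    def fit(self, ci_level: float = 0.95, starts=None, gtol: float = 1e-10,
            polish: bool = True) -> MleFit:
        x = np.asarray(self.data)
        if x.size < 5:
            raise ValueError("OLINH fit needs at least 5 observations (4 parameters)")
        start_list = [np.asarray(s, dtype=float) for s in starts] if starts is not None \
            else self._starts()

        best = None
        for s0 in start_list:
            r = optimize.minimize(self._profile_obj, s0, jac=True, method="L-BFGS-B",
                                  options={"maxiter": 500, "gtol": gtol, "ftol": 1e-13})
            if polish:
                # Nelder-Mead from the L-BFGS endpoint (ridge safety)
                r2 = optimize.minimize(lambda e: self._profile_obj(e)[0], r.x,
                                       method="Nelder-Mead",
                                       options={"xatol": 1e-9, "fatol": 1e-11,
                                                "maxiter": 2000})
                r = r2 if r2.fun < r.fun else r
            cand = r
            if best is None or cand.fun < best.fun - 1e-12 or (
                abs(cand.fun - best.fun) <= 1e-12
                and np.linalg.norm(cand.x) < np.linalg.norm(best.x)
            ):
                best = cand
        b, d, t = np.exp(best.x)
        a = self.profile_alpha(b, d, t)
        est = np.array([a, b, d, t])
        ll = self.loglike(est)

        cov, se, ci, flagged = _wald_machinery(
            None, est, ci_level, info=self.observed_information(est))
        converged = bool(np.isfinite(ll)) and best.fun < 1e11
        return MleFit(
            estimates=OlinhParams(*est), std_errors=se, covariance=cov,
            loglik=ll, converged=converged, ci_level=ci_level, ci_bounds=ci,
            param_names=self.param_names, nobs=x.size,
            diagnostics={"hessian_pinv": flagged,
                         "n_starts": len(start_list),
                         "max_score": float(np.max(np.abs(self.score(est))))},
        )


def fit_mle(data, ci_level: float = 0.95, **options) -> MleFit:
    """Convenience wrapper: fit the OLINH distribution by maximum likelihood."""
    return OlinhMLE(data).fit(ci_level=ci_level, **options)
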