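"""Bayesian inference for the OLINH distribution.

Independent gamma priors on the four parameters; posterior sampling by
Metropolis-Hastings within a systematic-scan Gibbs sweep.  The full
conditional of the tail index alpha is an exact gamma law,

    alpha | beta, delta, theta, x ~ Gamma(n + mu1, nu1 + sum_i log(B_i/beta)),
    B_i = beta + G_i/(1 - G_i),

(the rate follows from the joint posterior, which carries the beta**(n*alpha)
likelihood factor; note sum log(B_i/beta) > 0 always).  beta, delta and theta
are updated by Gaussian random walks on the log scale with the log-normal
proposal's Jacobian correction, so each accepts with probability

    min(1, pi(p')/pi(p) * p'/p).

Point estimates are posterior means of the retained draws (squared-error
loss); interval estimates are highest-posterior-density intervals found by
the shortest-window scan over the sorted draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distribution import ObservationSet, OlinhParams
from .mle import log_likelihood

__all__ = ["GammaPriors", "PosteriorSample", "OlinhBayes", "log_posterior",
           "draw_alpha_conditional", "mh_update", "run_mcmc", "hpd_interval"]

_PARAMS = ("alpha", "beta", "delta", "theta")


@dataclass(frozen=True)
class GammaPriors:
    """Gamma(mu_p, nu_p) shape/rate hyperparameters for alpha, beta, delta, theta."""

    mu: tuple = (0.1, 0.1, 0.1, 0.1)
    nu: tuple = (0.1, 0.1, 0.1, 0.1)

    def __post_init__(self):
        mu = tuple(float(v) for v in self.mu)
        nu = tuple(float(v) for v in self.nu)
        if len(mu) != 4 or len(nu) != 4:
            raise ValueError("mu and nu must each have four components")
        if any(v <= 0 for v in mu + nu):
            raise ValueError("all gamma hyperparameters must be > 0")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "nu", nu)

    def log_prior(self, w: OlinhParams) -> float:
        p = w.as_array()
        mu = np.asarray(self.mu)
        nu = np.asarray(self.nu)
        return float(np.sum((mu - 1.0) * np.log(p) - nu * p))


def log_posterior(data, w: OlinhParams, priors: GammaPriors) -> float:
    """Unnormalised log posterior: log-likelihood plus log prior.

    `data` may be None or empty-like, in which case this is the log prior.
    """
    lp = priors.log_prior(w)
    if data is None:
        return lp
    return log_likelihood(data, w) + lp


def _log_odds_sum(data, beta: float, delta: float, theta: float) -> float:
    """sum_i log(B_i / beta) = sum_i log1p(odds_i / beta) — the data part of
    the alpha-conditional's gamma rate."""
    x = np.asarray(data)
    with np.errstate(over="ignore", divide="ignore"):
        t = np.exp(theta * np.log1p(delta / x))
        s = 1.0 - t
        log1mG = np.log(-np.expm1(s))
    lr = s - log1mG
    return float(np.logaddexp(0.0, lr - np.log(beta)).sum())


def draw_alpha_conditional(data, beta, delta, theta, priors: GammaPriors, rng) -> float:
    """One exact draw from alpha's gamma full conditional."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if data is None or (hasattr(data, "__len__") and len(data) == 0):
        n, rate_data = 0, 0.0
    else:
        n, rate_data = len(data), _log_odds_sum(data, beta, delta, theta)
    shape = n + priors.mu[0]
    rate = priors.nu[0] + rate_data
    return float(rng.gamma(shape) / rate)


def _conditional_logdens(name: str, value: float, data, state: dict,
                         priors: GammaPriors) -> float:
    """Log full-conditional density of one parameter (up to a constant)."""
    trial = dict(state)
    trial[name] = value
    w = OlinhParams(**trial)
    return log_posterior(data if data is not None and len(data) else None, w, priors)


def mh_update(name: str, current: float, data, state: dict, priors: GammaPriors,
              proposal_scale: float, rng) -> tuple[float, bool]:
    """One log-scale Gaussian random-walk MH step for beta, delta or theta.

    Targets the parameter's full conditional; the log-scale walk needs the
    Jacobian factor proposed/current in the acceptance ratio.
    """
    if name not in ("beta", "delta", "theta"):
        raise ValueError(f"mh_update handles beta/delta/theta, not {name!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    proposed = float(current * np.exp(proposal_scale * rng.standard_normal()))
    try:
        log_ratio = (_conditional_logdens(name, proposed, data, state, priors)
                     - _conditional_logdens(name, current, data, state, priors)
                     + np.log(proposed / current))
    except (ValueError, FloatingPointError, OverflowError):
        return current, False
    if np.log(rng.uniform()) < log_ratio:
        return proposed, True
    return current, False


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing `level` of the sorted draws."""
    srt = np.sort(np.asarray(draws, dtype=float))
    m = srt.size
    keep = max(int(np.ceil(level * m)), 2)
    if keep >= m:
        return float(srt[0]), float(srt[-1])
    widths = srt[keep - 1:] - srt[: m - keep + 1]
    i = int(np.argmin(widths))
    return float(srt[i]), float(srt[i + keep - 1])


@dataclass
class PosteriorSample:
    """MCMC output: chains, posterior-mean point estimates and HPD intervals."""

    chains: dict
    burn_in: int
    thin: int
    point_estimates: dict
    hpd_intervals: dict
    hpd_level: float
    acceptance_rates: dict
    priors: GammaPriors
    diagnostics: dict = field(default_factory=dict)

    @property
    def retained(self) -> dict:
        return {k: v[self.burn_in:][:: self.thin] for k, v in self.chains.items()}

    def summary(self) -> str:
        lines = [
            f"OLINH posterior sample ({len(self.chains['alpha'])} iterations, "
            f"burn-in {self.burn_in}, thin {self.thin})",
            f"{'param':>8} {'post. mean':>12} {'post. sd':>10} "
            f"{f'[{self.hpd_level:.0%} HPD]':>24} {'accept':>8}",
        ]
        for name in _PARAMS:
            dr = self.retained[name]
            lo, hi = self.hpd_intervals[name]
            acc = self.acceptance_rates.get(name)
            acc_s = f"{acc:.2f}" if acc is not None else "exact"
            lines.append(
                f"{name:>8} {self.point_estimates[name]:>12.4f} {dr.std():>10.4f} "
                f"  [{lo:>9.4f}, {hi:>9.4f}] {acc_s:>8}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "point_estimates": self.point_estimates,
            "hpd_intervals": {k: list(v) for k, v in self.hpd_intervals.items()},
            "hpd_level": self.hpd_level,
            "acceptance_rates": self.acceptance_rates,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "n_iter": len(self.chains["alpha"]),
        }


def run_mcmc(data, priors: GammaPriors = GammaPriors(), n_iter: int = 5000,
             burn_in: int = 1000, thin: int = 1, proposal_scales=None,
             hpd_level: float = 0.95, seed=None,
             init: OlinhParams | None = None) -> PosteriorSample:
    """MH-within-Gibbs sampler: exact alpha draw, then log-scale random-walk
    MH for beta, delta, theta, each sweep.

    Proposal scales adapt toward a 0.2-0.5 acceptance window during burn-in
    only, then stay frozen so the post-burn-in chain targets the exact
    posterior.
    """
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    if data is not None and not isinstance(data, ObservationSet) and len(data):
        data = ObservationSet(data)
    empty = data is None or len(data) == 0
    data = None if empty else data
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    scales = dict(proposal_scales or {})
    for nm in ("beta", "delta", "theta"):
        scales.setdefault(nm, 0.3)
    adapt_every = 100

    if init is None:
        mu, nu = np.asarray(priors.mu), np.asarray(priors.nu)
        start = mu / nu  # prior means
        init = OlinhParams(*np.maximum(start, 0.1))
    state = {"alpha": init.alpha, "beta": init.beta,
             "delta": init.delta, "theta": init.theta}

    chains = {k: np.empty(n_iter) for k in _PARAMS}
    accepted = {k: 0 for k in ("beta", "delta", "theta")}
    window = {k: 0 for k in accepted}

    for it in range(n_iter):
        state["alpha"] = draw_alpha_conditional(
            data, state["beta"], state["delta"], state["theta"], priors, rng)
        for nm in ("beta", "delta", "theta"):
            new, ok = mh_update(nm, state[nm], data, state, priors, scales[nm], rng)
            state[nm] = new
            accepted[nm] += ok
            window[nm] += ok
        if it < burn_in and (it + 1) % adapt_every == 0:
            for nm in window:
                rate = window[nm] / adapt_every
                if rate < 0.2:
                    scales[nm] *= 0.7
                elif rate > 0.5:
                    scales[nm] *= 1.4
                window[nm] = 0
        for k in _PARAMS:
            chains[k][it] = state[k]

    retained = {k: chains[k][burn_in:][::thin] for k in _PARAMS}
    point = {k: float(v.mean()) for k, v in retained.items()}
    hpd = {k: hpd_interval(v, hpd_level) for k, v in retained.items()}
    rates = {k: accepted[k] / n_iter for k in accepted}
    diag = {"proposal_scales": scales}
    if min(rates.values()) < 0.01:
        diag["warning"] = "MH acceptance below 1% for some parameter"
    return PosteriorSample(chains=chains, burn_in=burn_in, thin=thin,
                           point_estimates=point, hpd_intervals=hpd,
                           hpd_level=hpd_level, acceptance_rates=rates,
                           priors=priors, diagnostics=diag)


class OlinhBayes:
    """Model object wrapping the MH-within-Gibbs sampler."""

    def __init__(self, data, priors: GammaPriors = GammaPriors()):
        self.data = data if isinstance(data, ObservationSet) or data is None \
            else (ObservationSet(data) if len(data) else None)
        self.priors = priors

    def log_posterior(self, w: OlinhParams) -> float:
        return log_posterior(self.data, w, self.priors)

    def fit(self, **kwargs) -> PosteriorSample:
        return run_mcmc(self.data, self.priors, **kwargs)
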