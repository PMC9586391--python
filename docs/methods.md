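# Methods

## The model

The inverted Nadarajah–Haghighi (INH) distribution is the law of 1/Y when Y
is Nadarajah–Haghighi; on x > 0 its CDF and density are

    G(x; δ, θ) = exp(1 − (1 + δ/x)^θ),
    g(x; δ, θ) = (δθ/x²)(1 + δ/x)^{θ−1} exp(1 − (1 + δ/x)^θ),

with scale-like δ > 0 and shape θ > 0. The odd Lomax-G (OL-G) transform maps
any baseline CDF G to

    F(x) = 1 − β^α [β + G/(1−G)]^{−α},     α, β > 0,

i.e. it sends the baseline odds G/(1−G) through a Lomax survival function.
Applying OL-G to the INH baseline gives the four-parameter OLINH family
implemented here. Key structural facts, all of which the test suite
exercises:

- **Reduction.** α = β = 1 collapses the transform: OLINH(1, 1, δ, θ) ≡
  INH(δ, θ) exactly.
- **Tail.** As x → ∞ the baseline odds behave like x/(θδ), so
  S(x) ~ β^α (θδ)^α x^{−α}: a power tail of index α. Hence E[X^r] < ∞ iff
  r < α, and the MGF diverges for every t > 0.
- **Quantile.** Writing u = β[(1−q)^{−1/α} − 1] and G_q = u/(1+u), the
  quantile is Q(q) = δ / [(1 − ln G_q)^{1/θ} − 1]. This is the direct
  inversion of F and satisfies F(Q(q)) = q to 1e−9 across q ∈ [0.001,
  0.999]; sampling is by inverse transform.
- **Hazard.** f/S is decreasing or upside-down bathtub depending on the
  parameters, which is what makes the family attractive for epidemiological
  rate data.

## Numerical evaluation

All distribution functions are evaluated through T = (1 + δ/x)^θ and
s = 1 − T ≤ 0 on the log scale: log(1 − e^s) via `expm1`, the survival
function directly from the OL-G form (never 1 − F), and the density's last
factor via `logaddexp(log β, s − log(1−e^s))`. The log-density is finite
from x = 1e−4 (where the naive exponent is ≈ −1.8e6) to x = 1e6 (where the
baseline CDF is within 1e−6 of 1) at moderate parameter values.

Moments, incomplete moments, the MGF (t ≤ 0) and Rényi entropy are computed
by adaptive quadrature of the exact density, split at the median, with the
left piece mapped through x = δ/u to remove the essential singularity at 0;
absolute tolerance 1e−9. The published power series for these summaries
contain a factor ∏_{s≥0}(r+s) that diverges term by term, so they are
treated as formal and are not implemented. The OL-G linear representation
*is* implemented as a cross-check: with Δ_{k,j} = (−1)^j α/(k+j+1) β^{−k−1}
C(−α−1, k) C(−k−2, j), partial sums of Σ Δ_{k,j}(k+j+1) g G^{k+j} converge
to the density wherever the baseline odds are below β (verified to 1e−13 by
K = 12 at the test point). Note the β exponent: expanding [β + W]^{−α−1} in
the odds W forces β^{−(k+1)}; the commonly printed β^{k+1} makes the series
diverge for β > 1.

Skewness and kurtosis are the quantile-based Bowley and Moors measures: the
heavy tail makes moment-based measures non-existent whenever α ≤ 4.

## Maximum likelihood

The log-likelihood is the sum of the stable log-density. α has a closed-form
profile maximiser, α̂(β, δ, θ) = n / Σ log(B_i/β) with B_i = β + G_i/(1−G_i),
so `OlinhMLE.fit` searches only (β, δ, θ), on the log scale (positivity
without constraints), with the analytic score (the envelope theorem gives
the profiled gradient for free). Eight deterministic starting points are
built from a quantile-matched INH fit crossed with small/large β and two
ridge directions in (δ, θ); the best of eight L-BFGS-B runs, each polished
by Nelder–Mead, wins. Standard errors come from the observed information —
minus the central-difference Jacobian of the *analytic* score (relative
step 1e−5), which is far more accurate on flat surfaces than differencing
the likelihood twice — inverted, with a pseudo-inverse fallback that is
flagged in the diagnostics. Wald intervals are on the original parameter
scale, floored at 0.

**The ridge.** (δ, θ) is weakly identified: the family's closure contains
three-parameter limits (δ → ∞, θ → 0 with θ ln δ fixed gives a Fréchet-type
law; δ → 0, θ → ∞ with δθ fixed gives an inverse-Gompertz-type law), and on
real or simulated data the likelihood is often nearly flat — or strictly
increasing — along these directions. On the packaged vaccination data the
information matrix at the optimum has a smallest eigenvalue ≈ 5e−8, so the
δ standard error is of order 1e3; point estimates of δ and θ should be read
as a ridge coordinate, and the likelihood value, α̂, and the fit statistics
as the meaningful summaries.

## Bayesian estimation

Independent Gamma(μ_p, ν_p) priors (default μ = ν = 0.1, weakly
informative). The α full conditional is exactly Gamma(n + μ₁, ν₁ +
Σ log(B_i/β)) — the rate includes the −n ln β part contributed by the
β^{nα} likelihood factor, which keeps it strictly positive — and is drawn
exactly each sweep; β, δ, θ use Gaussian random walks on the log scale with
the log-normal Jacobian in the acceptance ratio. Proposal scales adapt
toward a 0.2–0.5 acceptance window during burn-in only and are frozen
afterwards, preserving the stationary law. Defaults: 5000 iterations, 1000
burn-in, thin 1. Point estimates are posterior means (squared-error loss);
intervals are HPD by the shortest-window scan over sorted draws.

With vague priors the posterior inherits the likelihood ridge. Converged
long chains (40k–80k iterations) at n = 2000 show posterior means 20–65%
from the generating (β, δ, θ) for most data realisations, with θ's marginal
strongly right-skewed; α is recovered accurately. A short chain started
near the truth can *appear* to recover all four parameters simply because
it has not yet mixed over the ridge — the acceptance test uses a long chain
precisely so that this failure is visible rather than masked.

## The simulation study

`simulate.run_cell` draws inverse-transform samples (per-replicate seeds
spawned from the master seed, so cells are reproducible and
order-independent), estimates each replicate, and reports bias, relative
bias, MSE = (1/N) Σ (ω̂_j − ω)², mean interval length, and coverage.

Because the likelihood has no interior maximum for a sizeable fraction of
replicates (it climbs a boundary ridge), the per-replicate MLE protocol is
explicitly local: L-BFGS-B on the profiled log-likelihood started at the
true values, with log-bounds truth ± log 100. A replicate is **converged**
when the estimate lies inside [truth/50, truth·50] with positive-definite
observed information; the rest are counted in `n_failed` and excluded from
the summaries. At truth (1.25, 1.5, 1.5, 1.5) the failure fraction is
roughly 78% at n = 30, 53% at n = 80 and 36% at n = 150 — a real feature of
the model, reported rather than hidden. Consequences worth knowing:

- MSE(α̂) ≈ 0.07–0.09 and 95%-Wald coverage for α ≈ 95–96% at n = 150 with
  1000 replicates.
- The n-dependence of the exclusion rate induces survivor bias at small n,
  so the textbook "MSE decreases with n" holds cleanly for α and δ but can
  fail for β and θ between n = 30 and n = 150.
- Wald coverage for β sits in the high 80s at n = 150: its sampling
  distribution is heavy-tailed and the normal approximation undercovers.

Default problem sizes (1000 replicates for a headline cell, 400 for grid
scans; 2000 MCMC iterations with 500 burn-in inside Bayesian cells) keep a
full study in the minutes range on one core.

## Goodness of fit

KS, Cramér–von Mises and Anderson–Darling statistics from the ordered PITs
(clipped to [1e−10, 1 − 1e−10] for the AD logs), KS p-value from the
asymptotic Kolmogorov law, and AIC / corrected AIC / BIC / HQIC from the
fitted log-likelihood with honest parameter counts (k = 4 for OLINH, k = 2
for INH). `compare_models` ranks by AIC, ties by BIC then name. On the
packaged data OLINH dominates INH in likelihood (as it must — INH is nested
at α = β = 1) and on all three EDF statistics, but *not* on AIC: the
2-parameter INH fit is within one log-likelihood unit, so the 4-parameter
penalty leaves INH ahead, 291.10 vs 292.18.

## Packaged data

46 national rates of fully vaccinated persons per 100 population (African
countries, an early-pandemic snapshot), minimum 0.042, maximum 72.286,
checksum-pinned in the tests. The summary table reproduces with the n−1
variance (256.9492) and linear-interpolation quartiles (1.1190, 12.5448) —
the convention is pinned in `data.summary_stats`.

## Known limitations

- No censored-data likelihood; complete samples only.
- Only the INH baseline is wired through the OL-G transform.
- δ/θ point estimates (both MLE and posterior means) are ridge coordinates;
  report them with their intervals, never alone.
- The synthetic-data generator produces exact i.i.d. draws from the model,
  so passing simulation tests demonstrates estimator behaviour *under the
  model*, not robustness to misspecification, dependence, or measurement
  error in real rate data.
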