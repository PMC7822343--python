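# Methods

## The distribution

The log-Bilal law on (0, 1) arises as `Y = exp(−X)` with `X` Bilal-distributed
(`X` is the median of three i.i.d. exponentials with scale θ; its density is
`(6/θ)e^(−2x/θ)(1 − e^(−x/θ))`). Equivalently `Y = B^θ` with `B ~ Beta(2, 2)`
— the representation the test suite uses as an independent oracle, since it
reduces every closed form to scipy's beta distribution. The shape parameter
θ > 0 moves the mass from the right end of the interval (θ small) to the left
end (θ large): the mean `6/((θ+2)(θ+3))` decreases strictly in θ. The
variance does not: the printed rational form
`3θ²(θ²+10θ+13)/((θ²+5θ+6)²(2θ²+5θ+3))` is unimodal in θ, rising from 0 to a
maximum near θ ≈ 1.554 before decaying like `3/(2θ²)`. The package treats the
unimodal behaviour as the property to test; a blanket "variance decreases in
θ" claim holds only beyond the mode.

The hazard rate is either increasing or bathtub-shaped. No closed-form
boundary between the regimes is known to us, so `hrf_shape_diagnostic`
classifies numerically (sign changes of a finite-difference derivative on a
2001-point interior grid) rather than pretending to a formula.

### Numerical choices

- All powers `y^a` are computed as `exp(a·log y)` on the open interval, so
  extreme shapes (θ down to 0.05 and up to 50 are exercised in tests)
  underflow gracefully instead of overflowing.
- The quantile function inverts the cubic `3t² − 2t³ = u` with the
  trigonometric root `t = 1/2 − sin(arcsin(1 − 2u)/3)`, which is real-valued
  and stable on the whole of (0, 1); a Cardano cube-root form would pass
  through complex intermediates. Verified against bisection on the cdf at
  1e-10.
- Boundary policy: the cdf accepts the closed endpoints (F(0) = 0, F(1) = 1);
  the density and quantile reject them; samples containing exact 0 or 1 raise
  with the offending row named — never a silent clamp, which would bias every
  likelihood downstream.
- Sampling is inverse-transform of `numpy` Generator uniforms; the uniform
  stream defines reproducibility, so a fixed seed gives the same draws for
  every θ. A uniform of exactly 0.0 (possible with `random()`) is nudged to
  the next float.

## Estimation of θ

- **MLE**: the log-likelihood `n·ln(6/θ) + (2/θ − 1)Σln yᵢ + Σln(1 − yᵢ^(1/θ))`
  is maximized over log θ (unconstrained BFGS with the analytic score as
  gradient), started at the moment estimate. The data-dependent term is the
  mean of **ln yᵢ** — only that reading is consistent with the density and
  with the sufficient statistic `Σ ln yᵢ`; the arithmetic mean of the yᵢ
  belongs to the method of moments instead. The standard error is the
  observed information (central difference of the analytic score) inverted at
  the optimum.
- **Method of moments**: closed form `θ̂ = ½(√((ȳ+24)/ȳ) − 5)` from equating
  the first moment to the sample mean; exact identity
  `mu_from_theta(θ̂) = ȳ` is property-tested. Degenerate samples whose mean
  maps to θ ≤ 0 raise.
- **LSE / WLSE**: minimize `Σ wᵢ [F(y₍ᵢ₎; θ) − i/(n+1)]²` over bounded log θ
  (Brent on [1e−4, 1e4]), with wᵢ = 1 or the inverse-variance weights
  `(n+1)²(n+2)/(i(n−i+1))`. Ties are ordered by a stable sort, so equal
  observations keep input order (any assignment gives the same objective).

## The regression model

`logit(μᵢ) = xᵢᵀβ` with a leading intercept column; the likelihood is
`Σ log f(yᵢ; θ(μᵢ))`. The code evaluates it on that composed route (density ∘
reparametrization ∘ link) — the expanded mean-parametrized expression is kept
in the test suite as the second route of a two-routes-one-truth check. The
linear predictor is clipped at |η| = 35 (expit is flat to machine precision
beyond that), which keeps μ, and hence θ(μ), finite.

Fitting is BFGS on the negative log-likelihood with finite-difference
gradients (statsmodels `numdiff`), started at `β₀ = logit(ȳ)` and zero
slopes; a Nelder-Mead polish is applied when BFGS reports precision loss, and
the fit is accepted only if the final gradient is small. Standard errors are
the inverse numerical Hessian's diagonal; Wald z statistics are referred to
the standard normal, the convention of the models this one is compared with.
Rank deficiency, non-convergence and a non-positive-definite Hessian raise
distinct exceptions.

Quantile residuals are `Φ⁻¹(F(yᵢ; θ(μ̂ᵢ)))`. The response is continuous, so
no randomization is involved — the probability-integral transform is
deterministic; values of exactly 0 or 1 (possible only by numerical
underflow) are clipped with a warning. An intercept-only fit is exactly the
univariate MLE through the μ ↔ θ bijection, which the tests assert.

## Goodness of fit

The battery computes, at the fitted parameters and without
parameter-uncertainty correction: the classical K-S sup statistic with the
asymptotic Kolmogorov p-value; the Cramér–von Mises statistic
`W² = Σ(u₍ᵢ₎ − (2i−1)/(2n))² + 1/(12n)`; the Anderson–Darling statistic
`A² = −n − (1/n)Σ(2i−1)[ln u₍ᵢ₎ + ln(1 − u₍ₙ₊₁₋ᵢ₎)]`; and AIC/BIC. The
unmodified statistics are used; published tables computed with
small-sample-adjusted variants (factors `1 + 0.5/n` for W², `1 + 0.75/n +
2.25/n²` for A²) differ by about 1–2% at n ≈ 40, which is why comparisons to
such tables carry a 2% relative tolerance on A² and W².

## Baseline families

Beta (via scipy's density), Kumaraswamy, Topp-Leone and unit-Lindley, each
with MLE and numerical-Hessian standard errors. Two-parameter families are
optimized in log-parameter space from beta-moment starts; the one-parameter
families have unimodal likelihoods and use bounded scalar optimization —
their closed-form MLEs (Topp-Leone: `−n/Σln(2y − y²)`; unit-Lindley via the
underlying Lindley variable `y/(1−y)`) serve as test oracles for the
optimizer rather than as the implementation.

## The Monte-Carlo engine

For each sample size, N samples are drawn at the true θ and **all methods
see the same samples** (paired design; method contrasts are then free of
between-sample Monte-Carlo noise — pairing is a design choice of this
package). Metrics per (method, n): bias `mean(θ̂ − θ)`, MSE
`mean((θ̂ − θ)²)`, MRE `mean(θ̂/θ)`. Replicates whose fit raises or fails to
converge are excluded and counted; a method failing in over half the
replicates at some n aborts the study, since that signals an estimator
defect rather than hard data. One master `SeedSequence` spawns a substream
per sample size, so results are reproducible and insensitive to the order
of grid evaluation.

Reference design: θ = 1.7, n from 20 to 300 in steps of 5, N replications.
The package default is N = 1000 — at that scale the study conclusions
(bias and MSE shrinking in n, MRE within (0.97, 1.03) at n = 300, MLE with
the smallest MSE of the four methods) are stable across seeds, while a full
N = 10 000 study remains one flag away (`--reps 10000`). The acceptance test
evaluates the endpoints n = 20 and n = 300 only, which is what the tested
conclusions constrain; the CLI runs the full grid.

## Synthetic data and what tests show

The fixture generator draws covariates i.i.d. U(0, 1) (or standard normal),
forms μ through the logit link at user-chosen coefficients, and draws the
response by inverse transform at θ(μ). Default study conditions are the
reference ones: θ = 1.7 for univariate work, β = (1.0, −0.5) with a uniform
covariate for regression calibration (chosen to keep μ in a moderate range
(0.62, 0.73), a regime comparable to real index data). What this emulates is
a *correctly specified* model with clean covariates; it does not emulate
measurement error, covariate outliers, responses piling up near 0 or 1, or
model misspecification — passing calibration tests therefore demonstrates
internal correctness of the likelihood/residual machinery, not robustness on
messy field data.

The two real-data analyses (OECD Better Life Index 2017: dwellings without
basic facilities; educational attainment with three covariates) require the
user-supplied extract described in `datasets.load_bli_table` — the package
does not redistribute or auto-download OECD data. Their tests run the full
pipeline when `data/oecd_bli_2017.csv` is present and fail with guidance
when it is not.

## Known limitations

- A single shape parameter ties the variance to the mean; over- or
  under-dispersion relative to that relationship is not modelled
  (beta regression's φ has no analogue here).
- The K-S p-value is asymptotic; exact small-n p-values are a possible
  extension.
- GOF statistics are computed at fitted parameters without the
  estimation-uncertainty correction, the standard convention in the
  comparison literature but anti-conservative for formal testing.
- Covariates are used on their raw scale; responses given as percentages
  must be rescaled explicitly (`percent_rescale` / `--percent-rescale`).
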