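# Methods

## The family and its sub-models

PoiGHL(α, λ, a) is the law of the minimum of a zero-truncated-Poisson(λ)
number of iid generalized half logistic (GHL) variates with cdf
`G(x) = tanh(αx/2)^a`.  Its cdf, density, survival and hazard are closed
forms; so is the quantile function

    ξ(p) = (2/α) · atanh( W^{1/a} ),   W = −log(1 − p(1 − e^{−λ})) / λ,

which drives exact inverse-transform sampling and the quantile-based shape
measures (Bowley skewness, Moors kurtosis).  Sub-models: `a = 1` is the half
logistic Poisson (HLP); λ→0 is GHL, represented by its own restricted
parameter object rather than a tiny λ, which would lose precision in
`1 − e^{−λ}`; both restrictions give the half logistic.  Parameters are
strictly positive; `α` carries inverse time units, `λ` and `a` are
dimensionless.

Density behaviour at the origin is a-dependent (divergent for a < 1, the
finite limit αλ/(2(1−e^{−λ})) at a = 1, zero for a > 1); `pdf`/`logpdf`
return the limit values there rather than raising.  All exponentials are
computed through `expm1`/`log1p` forms, so λ and αx up to ≈700 are safe.

## The substitution backbone

If `V = G(X)` then V is truncated-exponential(λ) on (0, 1).  Every
expectation in the package — moments, incomplete moments, residual-life
moments, probability-weighted moments, entropies, the KL divergence, and
the stress-strength integral — is computed as a one-dimensional adaptive
quadrature over v ∈ (0, 1) with `x(v) = (2/α) atanh(v^{1/a})`
(default tolerances 1e-10 absolute and relative).  This removes both the
infinite domain and the x→0 integrable singularity of the density for
a < 1.  The test-suite cross-checks this route against direct x-domain
quadrature and against seeded Monte Carlo.

Series rearrangements of these quantities (moment series with iterated beta
derivatives, quantile power series, order-statistic moment series) are not
used: they are numerically fragile, and quadrature of the defining integral
is normative.  Two series are retained because they are cheap and provide a
genuinely independent route:

* the A-function
  `A(β1, β2, β3) = ∫ e^{−αx}(1−e^{−αx})^{β1}(1+e^{−αx})^{−β2} e^{−λT^{β3}} dx`,
  and
* the triple series for the stress-strength reliability R.

In both, the literature's inner expansion in powers of `(1 − u)` sits on the
boundary of the binomial series' convergence disc and, term-integrated,
diverges for the exponent combinations that actually occur.  We expand
`(2 − u)^{−c} = 2^{−c} Σ_j (c)_j/j! (u/2)^j` instead, which converges
geometrically; the series evaluators agree with the quadrature values to
≈1e−12 and report their last-term magnitude as a truncation diagnostic.
Truncation is controlled by a `SeriesSpec` (default: 200 terms max,
tail tolerance 1e−10).

## Entropies

Shannon entropy is `E[−log f(X)]`, evaluated in the v-domain where
`log f(x(v))` has a stable closed form; an additive decomposition into
elementary expectations is implemented separately as a cross-check, and the
two agree to 1e−8 across the tested grid.  The exact scale identity
`H(α, λ, a) = H(1, λ, a) − log α` holds to ≈1e−14.  Published entropy
tables for this family do not agree with direct evaluation of the defining
integral (e.g. direct quadrature at (1, 1, 1) gives 1.0898 where 0.9930 has
been reported, while our two independent routes and Monte Carlo agree with
each other and the scale identity is exact); such tables are therefore used
only as qualitative trend references, never as numeric ground truth.

Rényi entropy `(1−ρ)^{−1} log ∫ f^ρ` is finite for a < 1 only when
`ρ(a−1) + 1 > 0`; violations raise an explicit error.  The KL divergence is
implemented for a common α (the two-parameter comparison the family's
theory develops) and validated against Monte Carlo and the Gibbs
inequality.

## Maximum likelihood

Fitting maximizes the closed-form log-likelihood in log-parameter space
(unconstrained, bounds |log θ| ≤ 20) with the analytic score, L-BFGS-B from
a deterministic multi-start grid — α₀ ∈ {1/mean, 1/median},
λ₀ ∈ {0.5, 2, 8}, a₀ ∈ {0.5, 1, 2}, restricted per sub-model — followed by
a Nelder-Mead polish; the best final log-likelihood wins, ties broken by
the smaller parameter norm.  Standard errors come from the pseudo-inverse
of a symmetrized central-difference observed information (step
max(1e−4, 1e−4|θ_i|)); condition numbers above 1e10 or negative variances
flag the covariance as unreliable.  A fit whose optimum sits on the log
bound (in practice: HLP likelihoods whose supremum is the λ→0 half logistic
boundary, which happens when the sample mean of G(x) is ≥ 1/2) is reported
with `converged = False`, and its log-likelihood is the attained supremum.

Information criteria: AIC = 2k − 2ℓ, BIC = k log n − 2ℓ, and CAIC is the
small-sample corrected AIC, AIC + 2k(k+1)/(n−k−1) — the convention verified
against the published application tables.  The likelihood-ratio test
`w = −2(ℓ_null − ℓ_alt)` uses the χ² reference with df equal to the
parameter-count difference; the GHL null lies on the λ→0 boundary of the
alternative, where the χ² reference is conservative (noted, not corrected).

A caution for users comparing against the original application tables: the
published restricted (a = 1) fits of the three example datasets are not
global maxima — evaluating their printed parameters reproduces their
printed log-likelihoods, but better optima exist (for the
mechanical-components data the restricted likelihood has no interior
maximum at all and its supremum is the half logistic boundary value).  This
package reports the correctly maximized restricted likelihoods, so its LR
statistics (4.91, 22.14, 6.59) are smaller than the published ones (5.22,
26.56, 7.96); the full-model fits agree with the published ones to print
precision.

Goodness of fit uses the probability integral transform: the standard KS
sup-distance (p-value from the asymptotic Kolmogorov distribution — the
large-n convention), Anderson-Darling, and Cramér-von Mises.  AD/CvM
printed in the original applications came from a normality-testing package
whose post-transform null is not documented; our KS reproduces the
published values, AD/CvM are computed by the standard uniform-PIT formulas
and are not expected to match that source numerically.

Wald confidence intervals θ̂ ± z·se are asymptotically exact but
conservative in finite samples for (α, λ): at n = 500 from (1, 1, 1) the
measured coverages are ≈0.98/0.99/0.96 for (α, λ, a) — λ̂'s sampling
distribution is strongly right-skewed and tightly correlated with α̂.  The
test-suite asserts interval validity for all three and the nominal two-sided
band for the shape only.

## Stress-strength reliability

Convention: R = P(X1 > X2) = ∫ f1 F2 with X1 the strength.  (Parts of the
literature write P(X1 < X2) in prose while computing ∫ f1 F2; the numeric
values fix the convention adopted here.)  In the v-domain R is a
one-dimensional integral manifestly independent of α, and
R(a1, a2, λ) + R(a2, a1, λ) = 1.

Joint inference fixes α = 1 and shares λ across the two samples (the model
under which identifiability is clean); a warning suggests rescaling when
the pooled sample mean is far from unit scale.  The covariance of
(â1, â2, λ̂) is the inverse *expected* Fisher information, whose entries
reduce exactly to truncated-exponential expectations `E[V log V]` and
`E[V (log V)²]` (the a1–a2 cross entry is identically zero); this is the
procedure that reproduces the published variance matrix of the carbon-fiber
application to all printed digits, and it is exact rather than
finite-differenced.  `Var(R̂)` follows by the delta method with a
central-difference gradient of the quadrature R (relative step 1e−5), and
the 95% interval `R̂ ± 1.96 √Var(R̂)` is clipped to [0, 1].

The published fiber interval (0.4918, 0.7426) implies a delta variance of
0.0041, nearly double the 0.0022 obtained from the verified numeric
gradient; the same source's simulation table reports average `Var(R̂)`
values 2–6× its own MSE values (one exceeds 1 for an estimator bounded in
[0, 1]), indicating an inflated series gradient there.  We keep the numeric
gradient: our interval (0.5249, 0.7095) is the internally consistent one,
and our simulated ALCI values track the simulated MSE as they should.

## Synthetic data and the recovery studies

Sampling is inverse-transform through the closed-form quantile, driven by
numpy's counter-based Philox generator keyed by the user seed, so one seed
and size determine the stream on every platform.  Study replicates spawn
substreams by mixing the replicate index into the seed sequence (replicate
0 reproduces the plain `sample()` stream), so partial reruns are stable.

The recovery studies emulate the published designs: one-sample MLE
recovery over n ∈ {30, …, 300} and two-sample R̂ recovery over
(n, m) ∈ {(20,20), (30,20), (30,40), (50,50)}, reporting mean, sd, bias,
MSE (and for R̂: mean delta variance and the average 95% CI length, ALCI).
Default replication is 1000 — the package's standard study size, chosen so
the full trend contracts run as part of the routine suite; the original
10,000-replicate scale is available by passing `reps` (or `--reps`).
Replicate fits are warm-started at the generating truth, a standard
variance-reduction-free shortcut that does not change the estimator, only
the search path.  Per-replicate fit failures are counted and tolerated up
to 2%.

What the generator does *not* emulate: censoring, covariates,
measurement rounding, or model misspecification — passing recovery tests
show the estimator works when the model is true, nothing more.

## Degenerate inputs and edge policies

Nonpositive observations are rejected with their indices listed; PIT values
at exactly 0/1 are clipped to [1e−12, 1−1e−12] with a warning; quantile
probabilities must lie strictly inside (0, 1); the empty-sample and
too-small-sample cases raise before optimization; `reliability_series`
warns and returns its partial value when the anti-diagonal sum has not met
the tail tolerance within `max_terms`.

## Known limitations

* No censored-data likelihoods, no location-scale (log-)regression on
  covariates; the log-PoiGHL law itself is implemented and tested.
* The transformed-family mappings (exponentiated Weibull Poisson,
  Poisson generalized Gompertz, …) are documented relationships only.
* Unequal-λ stress-strength R is available through
  `reliability_integral(lam2=...)` but has no fitting routine.
* Hazard-shape *classification* is not implemented; the hazard is evaluated
  pointwise.
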