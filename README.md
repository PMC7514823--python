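# poighl

Lifetime modelling with the **Poisson generalized half logistic (PoiGHL)
distribution**: a three-parameter family for survival and reliability data
whose hazard can be increasing, decreasing, bathtub-shaped or unimodal —
shapes the classical half logistic cannot accommodate.

The package is aimed at biostatisticians and reliability engineers who need
a flexible parametric lifetime model with full maximum-likelihood machinery:
distribution functions and random generation, moments and entropy measures,
model fitting with standard errors and goodness-of-fit, nested-model tests,
and stress-strength reliability `R = P(X1 > X2)` with delta-method
confidence intervals.

## The model

Let `Y_1, …, Y_M` be iid generalized half logistic (GHL) variates with cdf

    G(y) = ((1 − e^{−αy}) / (1 + e^{−αy}))^a = tanh(αy/2)^a,     α, a > 0,

and let `M` be zero-truncated Poisson(λ), independent of the `Y_i`.  Then
`X = min{Y_1, …, Y_M}` follows PoiGHL(α, λ, a) with

    F(x) = (1 − e^{−λ G(x)}) / (1 − e^{−λ}),      x, α, λ, a > 0.

`α` is a scale-rate, `a` the GHL shape, and `λ` controls how many latent
components compete for the minimum.  The λ→0 limit recovers GHL; fixing
`a = 1` gives the half logistic Poisson (HLP); both together give the plain
half logistic (HL).  A key computational identity used throughout:
`V = G(X)` is truncated-exponential(λ) on (0, 1), so every expectation over
X becomes a well-behaved integral on the unit interval.

For two independent variates sharing α and λ — strength `X1 ~ PoiGHL(a1, λ)`
and stress `X2 ~ PoiGHL(a2, λ)` on the unit scale — the reliability

    R = P(X1 > X2) = ∫ f1(x) F2(x) dx

is independent of α; the package estimates it jointly by maximum likelihood
with an expected-information covariance matrix and delta-method variance.

## Worked example

```python
>>> import poighl as pg
>>> p = pg.PoiGHLParams(alpha=1.0, lam=1.2, a=1.3)
>>> round(pg.quantile(0.5, p), 4)          # closed-form median
0.9794
>>> round(pg.raw_moment(1, p), 4)          # E[X] by quadrature
1.2504

>>> data = pg.load_dataset("mechanical_20")    # 20 component failure times
>>> fit = pg.fit_mle(data.values, "poighl")
>>> [round(v, 4) for v in fit.theta()], round(fit.loglik, 2), round(fit.aic, 2)
([19.0226, 4.4492, 6.6817], 35.41, -64.82)

>>> x = pg.load_dataset("fibers_20mm").values  # carbon-fiber strengths, GPa
>>> y = pg.load_dataset("fibers_50mm").values
>>> ss = pg.fit_ss(x, y)
>>> round(ss.R_hat, 4), (round(ss.ci_low, 4), round(ss.ci_high, 4))
(0.6172, (0.5249, 0.7095))
```

The mechanical-components fit says the data are best described by a very
steep shape (`a ≈ 6.7`) with a substantial Poisson thinning rate — the
three-parameter model improves markedly on its HLP and HL restrictions (try
`pg.lr_test(data.values, "hlp")`).  The fiber result reads: a 20 mm fiber
survives the stress imposed by the 50 mm regime with estimated probability
0.617, with a 95% asymptotic interval of roughly ±0.09.

The same operations are available from the shell:

```bash
poighl fit mechanical_20 --model poighl
poighl compare mechanical_20 poighl hlp ghl hl
poighl sample -n 5 --alpha 1 --lam 1.2 -a 1.3 --seed 7
poighl simulate --preset ss --reps 1000 --seed 0
```

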