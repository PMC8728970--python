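# Methods

## Generative model

Each biological sample *j* in arm *i* carries a true cell-type
proportion *p<sub>ij</sub> ~ Beta(a<sub>i</sub>, b<sub>i</sub>)*; the
assay observes *A<sub>ij</sub> | p<sub>ij</sub> ~ Binomial(n<sub>i</sub>,
p<sub>ij</sub>)* cells of that type among *n<sub>i</sub>* cells, and the
analysis works with *p̂<sub>ij</sub> = A<sub>ij</sub>/n<sub>i</sub>*.
Samples are independent within and across arms (paired designs couple
the latent proportions only).  The beta shapes are moment-matched to a
user-supplied mean μ and SD σ:

    a = μ (μ(1−μ)/σ² − 1),    b = a (1/μ − 1),

valid when σ² < μ(1−μ); we additionally require a > 1 and b > 1 so the
prior is unimodal, and reject parameters violating either bound with the
bound named in the error.  Moment matching divides by σ²; a variant of
this identity sometimes circulates with σ in the denominator, which does
not satisfy the beta moment equations (μ = 0.5, σ = 0.1 must give the
symmetric Beta(12, 12)), so σ² is used throughout.

The observed proportion is scaled beta-binomial with

    E[p̂] = a/(a+b),
    V[p̂] = a b (a+b+n) / (n (a+b)² (a+b+1)) = σ² (a+b+n)/n,

strictly above σ² for finite n with limit σ².  This finite-cell
inflation is the entire difference between this package and a classical
("legacy") t-test power calculation, which this package also provides as
the infinite-cell reference.

## False-negative rate

For the unpaired design the Welch t statistic on m₀ + m₁ observed
proportions is treated as a central t with Satterthwaite degrees of
freedom computed from the *model* variances V[p̂ᵢ], shifted by the
noncentrality

    ncp = (E[p̂₁] − E[p̂₀]) / sqrt(V[p̂₁]/m₁ + V[p̂₀]/m₀),

so β = 𝒯ν(t* − ncp) with t* the upper-α (one-sided) or upper-α/2
(two-sided) central-t quantile.  Two conventions for the alternative
distribution are exposed:

- `shifted_central_t` (default): the central-t CDF evaluated at
  t* − ncp, the literal reading of the shifted approximation above;
- `noncentral_t`: the exact noncentral-t CDF at t*, the convention of
  classical power software.

They differ by well under 0.01 in β for typical designs (e.g. 0.078 vs
0.071 for the worked trial design at 6 + 6 samples); both are tested.
The two-sided β deliberately ignores the (astronomically small)
probability of rejecting in the wrong tail.  A one-sided test whose
declared direction (case > control) opposes the supplied means emits a
warning rather than an error, since β > 1 − α is a legitimate, if
alarming, answer.

Paired designs require equal arm sizes M and a correlation ρ of the
*true* proportions between conditions.  By the law of total covariance
the binomial layers drop out and cov(p̂₀, p̂₁) = ρσ₀σ₁; the observed
correlation is attenuated by n/sqrt(n(a+b+n)) per arm and approaches ρ
only as cell counts grow.  The paired difference has variance
V[p̂₁] + V[p̂₀] − 2ρσ₀σ₁, the noncentrality divides the mean difference
by sqrt(variance/M) (the standard error of a mean difference — the only
dimensionally consistent reading), and ν = M − 1.  At ρ = 0 the paired
ncp coincides with the unpaired one exactly; negative ρ is allowed with
a warning, since it only destroys power.

SESOI testing translates the control mean by the margin before the beta
reparametrization (SD unchanged), so only differences beyond the margin
count as effects.  TOST equivalence power combines the two one-sided
SESOI-shifted tests through the conservative intersection bound
max(0, power_lower + power_upper − 1); the bound is essentially tight
because the two rejection events overlap almost completely for any
margin of practical interest.

### Monotonicity caveat

β is strictly decreasing when both arms grow together or when cells per
sample increase.  Growing *one* arm while the other stays very small is
not exactly monotone: the Satterthwaite df is dragged toward the small
arm's m − 1, and the larger critical value can outweigh the
noncentrality gain.  The effect is ≤ 0.011 in β for 3-sample arms with
a 1.1× effect and ≤ 0.002 for arms of ≥ 4 samples with ≥ 1.3× effects;
the test suite asserts monotonicity accordingly (strict on the
equal-size diagonal, within 0.005 per axis).

## Normal-approximation diagnostics

The t approximation trusts the sample mean of m beta-binomial
proportions to be near-normal.  Averaging shrinks skewness by √m and
excess kurtosis by m; both shrunk magnitudes below 0.5 is reported as
sufficient normality.  Skewness and excess kurtosis use the standard
beta-binomial closed forms (exact pmf enumeration as a fallback below
n = 100 if the closed forms ever go non-finite, and as the independent
oracle in tests).  As a rule of thumb the diagnostic passes for
abundances of 0.1–50% with coefficients of variation up to 0.3 whenever
m ≥ 3 and the cell count is reasonable (n ≥ 300 for a 1% cell type).
Accuracy degrades outside this domain: for a rare type with CV 0.5
(μ = 0.03, σ = 0.015) the analytic β deviates from a 50,000-replicate
simulation by ≈ 0.02 absolute, against ≤ 0.013 everywhere on a
ten-design grid inside the domain.

## Pilot-data priors

Group summaries use the textbook estimators: t-based CI for the mean
(limits clipped to [0, 1], since a proportion cannot leave the unit
interval), χ²-based CI for the SD, Fisher-z CI for the correlation of
matched pairs (plain standard-normal quantile; ≥ 4 pairs required).
A degenerate pilot (all values equal) yields a point interval rather
than an error — downstream GroupSpec construction rejects σ = 0 with its
own message.  Complementary log-log or bootstrap intervals are not
implemented: they trade the transparent clipping rule for skewed limits.
Correlation estimation from unmatched samples is out of scope; paired
designs accept a user-supplied ρ instead.

## Monte-Carlo validation

`simulate` draws from the exact generative model: per sample a beta
draw, then a binomial count.  Paired draws couple the two beta marginals
through a Gaussian copula whose normal correlation is calibrated
(Gauss–Hermite quadrature of the induced product-moment correlation,
then Brent root-finding) so the latent pair correlates at exactly the
requested ρ — the marginals stay exactly beta, which a bivariate-normal
shortcut would not preserve.  The test applied inside replicates is the
same family the engine models: Welch (not pooled-Student) for unpaired,
the ordinary paired t otherwise; replicate-level rejections were
verified identical to `scipy.stats.ttest_ind`.  All randomness descends
from one root seed via `SeedSequence.spawn` (one substream per grid
cell), making every run bit-reproducible.  Cells whose empirical
false-negative rate is exactly zero have no defined relative error; they
are excluded from grid means and counted in the table's
`excluded_zero_cells` attribute.

The empirical-resampling validator (`empirical_resample_fnr`) follows
the pilot-bootstrap design: draw m samples per group with replacement
from observed pilot proportions, thin each through Binomial(n, p), test
one-sided Welch, tally non-rejections.  The test suite exercises it on
synthetic pilot cohorts (144 and 46 beta draws with means 0.56/0.42,
SD 0.15 — sizes and means emulating a tumor/juxtatumoral T-cell
contrast) and checks agreement with the analytic prediction at matching
moments to ±0.04.

## Problem sizes and numerical choices

- The validation-grid statistic (mean |analytic − empirical|/empirical
  over sample sizes 5..12 per arm, 10,000 replicates per cell, μ 0.03 vs
  0.05, σ 0.015/0.01, n = 1000) is stochastic with a seed-to-seed SD of
  ≈ 0.25 percentage points; the acceptance script and tests report its
  expectation as the mean of five independent simulation rounds
  (≈ 20 s total).  Typical values: ≈ 10.7% for the finite-cell engine,
  ≈ 42.6% for the legacy calculation, with the legacy prediction below
  the empirical rate in every cell — ignoring finite cells is not just
  noisier, it is biased optimistic.  The engine's largest relative
  errors concentrate where β < 0.1 (large equal arms): the shifted
  central-t tail underestimates β for strongly skewed rare-type
  configurations.
- Sample-size searches scan linearly up to m_max = 200 (the default
  feasibility horizon); bisection would be valid on the diagonal but
  buys nothing at this scale and is fragile on floating-point plateaus.
- Critical values and CDFs use real-valued df throughout; invariant
  checks use relative tolerance 1e-9.
- Design tables serialize to CSV at 3 decimals (design-report precision)
  and to JSON at full precision with complete parameter metadata.

## Limitations

- One cell type at a time: no Dirichlet-multinomial joint modeling of
  the full composition, and no multiple-testing correction across cell
  types.
- The beta shapes come from user-supplied (or pilot-estimated) moments,
  not from maximum likelihood on raw counts.
- Synthetic validation draws from the model's own generative law plus
  pilot resampling; real data add batch effects, dependent samples
  (e.g. multicenter structure) and classification noise in cell-type
  labels, none of which the diagnostics here can see.
- Rank-based (Wilcoxon) power is not estimated.
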