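# Methods

## The model

`nrsem` analyses multi-instrument adolescent mental-health surveys with a
non-recursive (feedback) structural equation model.  Three endogenous
constructs — depression, anxiety, somatic symptom burden — are measured by
the PHQ-9A, GAS-7 and SSS-8; perceived stress (PSS-10) and social support
(OSSS-3) enter as latent exogenous constructs alongside binary covariates
(sex, school type, alcohol use, chronic illness, physical trauma, death of
a loved one, family academic pressure, self-rated academic ability, study
time, extra tutoring, physical activity).  In LISREL notation:

    eta = B eta + Gamma xi + zeta          (structural part)
    v   = Lambda (eta, xi) + eps           (measurement part)

with `Cov(zeta) = Psi` (off-diagonals free: complete correlation of the
disturbances), `Cov(xi) = Phi`, `Cov(eps) = Theta` (diagonal).  `B` carries
the reciprocal depression <-> anxiety entries, so `(I - B)` must be
invertible and the implied covariance is

    Sigma_eta,eta = A (Gamma Phi Gamma' + Psi) A',   A = (I - B)^{-1}.

Observed variables entering the structural part directly (binary
covariates, composite scores) are single-indicator constructs with loading
1 and zero measurement error; multi-indicator constructs fix their first
loading at 1 for scale-setting.

## Identification

A feedback loop is identified only through exclusion restrictions.  Three
checks are implemented on the 0/1 system matrix (loop equations x all
variables): unique instruments per loop variable (necessary), the order
condition `excluded >= m - 1` (necessary), and the rank condition — delete
row i and every column with a 1 in row i; the remainder must have rank
`>= m_loop - 1` (sufficient).  The rank is computed numerically (tolerance
1e-8, exact for 0/1 entries); deleting duplicate/linearly dependent rows by
hand is equivalent to taking the matrix rank directly.

Instrument quality is screened pairwise per directed loop edge with 2SLS on
scale-mean composites: the Cragg-Donald minimum-eigenvalue F (strong if
> 10) and the Sargan J overidentification test (suspect if p <= 0.05,
homoskedastic form; df = #instruments - #endogenous regressors, undefined
when just-identified).  Other loop regressors are *omitted* from the probe
equation rather than controlled for — conditioning on an endogenous
variable would inject its endogeneity into the test.  An edge that fails
the screen is deleted (the standard remediation for a weak/faulty
instrument), after which identification is re-checked.

## Estimation

The Wishart ML discrepancy `F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p` is
minimised by L-BFGS with an analytic gradient (assembled blockwise through
`Lambda`, `B`, `Gamma`, `Phi`, `Psi`, `Theta`), followed by a damped-Newton
polish using a finite-difference Hessian of the analytic gradient — the
polish rescues the flat, ill-conditioned surfaces that large free `Phi`
blocks produce.  Non-PD `Sigma` or near-singular `I - B` return a large
penalty value, so the line search backtracks into the feasible region;
persistent infeasibility triggers jittered restarts from the moment-based
start values (free loadings 0.7, `B` and `Gamma` zero, variances at half
the sample values, `Phi`/`Psi` from composite-proxy covariances).
Convergence requires a gradient infinity-norm below 1e-3; `chi2 = (n-1) F`.
Standard errors come from the observed information (`acov = 2/(n-1) H^-1`).
The baseline model for incremental indices is the independence model with
free variances, whose ML solution is closed-form.  AIC is reported on the
`chi2 + 2q` scale so that magnitudes are comparable with common SEM
software output.

Estimation is complete-case: records with any missing analysis variable
are removed by listwise deletion, which refuses to act when more than 5%
(configurable) of records are incomplete.  Because Likert items are
non-normal, inference uses case-resampling bootstrap percentile intervals
(default 3000 replicates at library level) rather than normal-theory SEs;
ML point estimates are kept.

## Item parceling

Item-level models of 37 Likert indicators rarely fit well; factorial
(item-to-construct balance) parceling averages subsets of a construct's
items into composite indicators.  Items are sorted by the magnitude of
their single-factor loadings (first principal axis) and dealt to parcels in
serpentine order (1..k, k..1, ...), ties broken by item index; a parcel
score is the mean of its items.  Serpentine dealing is a balance
*heuristic*: it lands well below the spread of a random partition but is
not guaranteed to minimise the spread of parcel loading sums (enumeration
shows cases where an exhaustive search does strictly better).  Defaults: 3
parcels per construct, 2 for constructs with fewer than 6 items.

## Effects

With `A = (I - B)^-1`, total effects are `T_endo = A - I` and
`T_exo = A Gamma`, equal to the geometric path series when the spectral
radius of `B` is below 1; indirect = total - direct, so a loop member
exerts an "indirect" effect even on its own partner through loop
amplification.  CIs come from applying the decomposition to every
bootstrap replicate (percentile method).  Standardisation multiplies each
effect by `SD(predictor)/SD(outcome)` using model-implied variances, which
preserves additivity and the reciprocal product `b12 * b21`.

## Screening diagnostics

Mardia's multivariate kurtosis `b2p = mean[(x - xbar)' S^-1 (x - xbar)]^2`
with expectation `p(p+2)` and critical ratio
`(b2p - p(p+2)) / sqrt(8 p (p+2) / n)`; the non-normality verdict uses the
convention of reporting the kurtosis *excess* (`b2p - p(p+2) > 7` and
CR > 5), matching how common SEM software prints "multivariate kurtosis".
Mahalanobis outliers use the chi-square(p) upper tail at alpha = 0.001.
KMO uses the anti-image formula with partial correlations from the
inverted correlation matrix (exactly 0.5 for p = 2, a useful invariant);
Bartlett's sphericity is `-(n - 1 - (2p+5)/6) ln|R|`.  ICC(1) comes from
one-way ANOVA with the unbalanced-design average cluster size.  Harman's
one-factor test uses the first principal component's variance share by
default (principal-axis extraction behind a flag).  Sample covariances use
the n-1 denominator throughout.

## The synthetic population

The generator draws `eta = (I-B)^-1 (Gamma xi + zeta)` exactly, then cuts
continuous indicators `loading * latent + N(0, 0.6^2)` at fixed thresholds
into each item's Likert range (graded-response style).  Default structural
coefficients are the published unstandardized direct effects of the study
this battery emulates (loop 0.74 both ways; stress 0.54/0.53/-0.06; etc.);
loadings default to 0.7 with the per-construct marker at 1.0; thresholds
are right-skewed so symptom endorsement is realistic for a school
population; covariate prevalences match the study's sample composition;
missingness is MCAR on predictor columns only at a rate that leaves a
handful of incomplete records per 1379.

Two deliberate deviations from the printed coefficients, both load-bearing:

* **Instrument relevance.**  The published instrument coefficients
  (|gamma| 0.02-0.13 on mostly binary covariates) cap the first-stage R^2
  so low that no estimator could identify the loop — incompatible with the
  study's own claim of strong instruments (F > 10) for the retained
  depression <-> anxiety loop.  The defaults therefore enlarge the five
  instrument coefficients until that diagnostic regime holds, and keep the
  somatic instruments (study time, tutoring) weak so the somatic feedback
  paths fail the screen and are pruned, as in the study.
* **Recovery mode.**  Thresholded ordinal items analysed as continuous
  attenuate `Gamma` by a roughly constant factor (the loop entries of `B`,
  being scale ratios, survive).  Recovery and coverage studies therefore
  use the generator's continuous-indicator mode, where the analysis model
  is correctly specified; the ordinal default exercises the full pipeline,
  asserting only the scale-free loop coefficient (within 0.15).

What passing tests show, and do not show: the estimator recovers the truth
under its own assumptions (linear latent structure, MCAR missingness,
graded-response items); nothing here validates the model against real
adolescents, MNAR mechanisms, DIF, or longitudinal dynamics.

## Study sizes used by the tests and the acceptance script

Chosen as this package's own simulation design: parameter recovery uses 30
replications of n = 2000 continuous-indicator surveys (mean bias per free
structural coefficient); bootstrap coverage uses 60-100 replications of
the observed-variable loop scenario at n = 800-1000 with 150-200 bootstrap
replicates each; size calibrations (Bartlett, Sargan) use 300-500
replications; the pipeline demonstration uses one n = 1379 survey with
200-300 bootstrap replicates.  The library default of 3000 bootstrap
replicates applies when no explicit value is passed.

## Known limitations

* No FIML for missing data (complete-case only) and no MAR/MNAR handling.
* No ordinal-specific estimation (WLSMV/polychoric); items are treated as
  continuous after parceling, as is common practice for these instruments.
* The Sargan screen inherits weak-instrument size distortion: with
  marginal instruments a valid loop edge is occasionally pruned (a ~5%
  event per edge under the default population).
* Percentile bootstrap CIs can be asymmetric around the ML point estimate;
  the point estimate is not guaranteed to lie inside its own CI for every
  parameter.
* `compare_models` ranks by AIC and only flags disagreement among the
  other criteria; it does not adjudicate it.
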