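# Methods

`nfltraj` re-creates, on synthetic cohorts, the statistical pipeline used to
compare cerebrospinal-fluid (CSF) and plasma neurofilament light chain (NfL)
trajectories across the autosomal dominant Alzheimer's disease (ADAD)
continuum: disease-time (EYO) staging from longitudinal Clinical Dementia
Rating (CDR) scores, duplicate-assay QC, Bayesian restricted-cubic-spline
mixed models with divergence-point detection, empirical-Bayes extraction of
within-person rates of change, segmented-regression bifurcation analysis,
plasma/CSF ratio comparisons, and NfL-imaging coupling models. This note
records the models, the generator that stands in for the (non-public) cohort
data, the numerical choices, and what the synthetic experiments do and do
not establish.

## Disease-time staging

Each pathogenic variant has an expected symptom-onset age; a participant's
EYO at a visit is `age − expected onset`, computed identically for mutation
carriers (MC) and non-carrier family controls (NC). Expected onset is the
mean of the onsets reported for carriers of the same variant, falling back
to the parental onset age. Exclusion rules are applied in a fixed order:
non-pathogenic/Dutch-type-like variants (participant level), competing
neurological disorders (participant level), CDR reverters (participant
level), and NC *visits* with EYO strictly greater than 15 years (visit
level: data, not people, are dropped; a participant with no remaining visits
leaves the table). Stages from longitudinal CDR: all-zero → presymptomatic
MC; zero at baseline then positive at every later visit → converter; positive
throughout → symptomatic; any positive-then-zero sequence → reverter
(excluded). A carrier with a single CDR-0 visit is presymptomatic and with a
single positive visit symptomatic, since conversion needs two visits.

## Assay QC

NfL is measured in duplicate. The duplicate CV is `100·SD/mean` with the
n−1 (two-point) SD, so CV(a,b) = 100·|a−b|/(√2·mean). Pairs with CV > 20% or
a missing replicate are flagged; flagged CSF pairs use the remeasured pair
when one exists, flagged plasma pairs keep the initial values (no fluid
remains for remeasurement) and carry their flags. The reported value is the
mean of the replicates used; rows are never dropped by QC. All analyses use
log10 concentrations.

## Trajectory model and divergence point

For baseline log10 NfL (or an extracted rate of change) `y`:

    y = b0 + b_mc·MC + b_lin·e + b_cub·c(e) + b_lin:mc·MC·e + b_cub:mc·MC·c(e)
        + b_age·age + b_sex·sex + b_bmi·BMI + u_family + ε,
    u_family ~ N(0, σ_f²),  ε ~ N(0, σ_e²),

where `e` is EYO and `c(e)` is the nonlinear term of a 3-knot restricted
cubic spline (Harrell normalization, knots at the 0.10/0.50/0.90 empirical
quantiles of the pooled analysis sample), so the EYO effect contributes
exactly two design columns and is linear beyond the boundary knots.

Priors are weakly informative: Normal(0, 10²) on fixed effects of the
standardized design, half-Normal(0, 5) on both SDs. Sampling exploits the
Gaussian structure twice. Family intercepts are marginalized in closed form
(compound-symmetric blocks, Sherman–Morrison), and, conditional on
(σ_f, σ_e), the fixed-effect posterior is an exact multivariate normal whose
normalizing constant is also available in closed form. An ensemble MCMC
sampler (emcee with differential-evolution moves; 16 walkers, 2500 steps,
1000 burn-in, thin 3 by default, ≥ 4000 retained draws) therefore only
explores the two-dimensional marginal posterior of (log σ_f, log σ_e); a
fixed-effect vector is then drawn exactly from its conditional normal at
every retained variance draw, so coefficient draws carry no ensemble
autocorrelation. Walkers are treated as chains for split-R̂ and bulk ESS; a
fit with any R̂ ≥ 1.01 is flagged non-converged and downstream operations
refuse it unless forced. Identical seed and settings reproduce the draws
bit-for-bit.

The MC−NC difference curve is evaluated on an EYO grid (−30 to +15 in
0.1-year steps, truncated to the observed range) at reference covariates
(sample means; sex at its sample proportion); covariates cancel in the
difference, which depends only on the status main effect and its two spline
interactions. Two divergence summaries are reported:

* the **literal first crossing** — the first grid point whose equal-tailed
  95% credible interval excludes 0 — together with a persistence flag, and
* the **first persistent crossing** — the first grid point from which the
  interval excludes 0 with a consistent sign through the end of the grid.

The literal scan is fragile: under a null (identical groups) the pointwise
band excludes zero somewhere on the grid in a substantial fraction of
replicates, mostly isolated crossings at the sparse EYO extremes where the
spline extrapolates (in a 20-replicate null study, 8 literal crossings but
only 2 persistent ones). Detection-style conclusions therefore use the
persistent estimate; both are always reported.

A penalized cubic regression spline smoother (statsmodels GLMGam/BSplines,
GCV-selected penalty) is the conservative cross-check: groups are smoothed
separately, approximate 95% mean bands are formed from the penalized
covariance, and the alternative divergence is the first grid point from
which the two bands stay disjoint through the end of the common EYO support.
On zero-residual degenerate inputs (where the PIRLS loop refuses to fit) an
equivalent penalized least-squares path with a descending GCV grid is used;
ties in GCV resolve toward the smoothest fit, so an exactly linear truth is
reproduced with effective degrees of freedom ≈ 2.

## Within-person rates of change

Per analyte, an LMM with fixed time-from-baseline effect, a family random
intercept and per-participant random intercept and slope (independent
variance components, fit with statsmodels MixedLM) yields each participant's
annualized slope as fixed effect + empirical-Bayes (BLUP) random slope. The
same operation serves precuneus volume and PiB SUVR. When every
participant's data are exactly linear (zero residual variance) the MLE sits
on the variance boundary and the BLUPs converge to the per-subject OLS
slopes; that exact limit is returned directly. Note that BLUPs shrink
toward the *global* mean slope, which flattens slope-versus-EYO patterns;
recovery experiments that target the shape of the rate curve therefore work
with rate values carrying the generator's between-subject scatter rather
than doubly-shrunken pipeline output.

Cross-sectional and longitudinal CSF–plasma associations use Pearson
correlation plus covariate-adjusted OLS (age, sex, BMI), fit per group, and
report unadjusted r², full-model r² and the partial r² of the plasma term.
Candidate covariate sets (all 8 subsets of {age, sex, BMI}) are ranked by
AIC with Akaike weights and cumulative weight on common complete cases.

Clinical groups are compared with a family-clustered LMM (`slope ~ group +
age + sex + BMI`, family random intercept); all pairwise contrasts are Wald
tests with residual-df t p-values and Holm adjustment over the 6-contrast
family. Satterthwaite-type degrees of freedom are not exposed by the
backend; the residual-df approximation is documented and calibrates the
family-wise error below 0.05 in a 200-replicate null study at the published
group sizes (88/79/13/48). The plasma/CSF ratio uses absolute pg/ml values.

## Segmented (bifurcation) analysis

A single-breakpoint model is fit by the standard iterative linearization:
given ψ, regress `y ~ x + (x−ψ)₊ + gap-indicator`, update ψ by
gap/slope-change, iterate to |Δψ| < 1e-6 (≤ 100 iterations), multi-start at
seven interior quantiles with best-RSS selection, and refit without the gap
term at the converged ψ. SE(ψ) follows the delta method. Because the
breakpoint vanishes under the linear null, significance uses a Davies-type
supremum bound over 10 candidate breakpoints: p ≤ 2[Φ(−M) + V·e^(−M²/2)/√(8π)]
with M the largest |t| of the hinge term and V the total variation of the t
path. `detect_bifurcation` reports "no bifurcation" when the Davies test
exceeds α = 0.05, when SE(ψ) spans more than 25% of the x range, or when the
segmented fit fails to improve on the straight line. The slope-change
estimate at the converged ψ is a post-selection quantity (the iteration
settles where the apparent change is largest) and is not compared to its
naive SE; the Davies test is the calibrated rule (19–20/20 null retention in
20-replicate studies). On every test dataset the converged ψ matches an
exhaustive profile-RSS grid search (0.01-year scan with 0.001-year local
refinement) to well under 0.01 years.

## Imaging coupling

Precuneus volumes are ICV-adjusted by the residual method with NC as the
reference group (adjusted volume is uncorrelated with ICV among NC). Per
group and analyte, the model `imaging ~ time · (age + sex + BMI + NfL
slope)` with family random intercept and participant random intercept+slope
tests the NfL-slope-by-time interaction (imaging units per year per unit
log10-NfL slope). Groups too small for random slopes fall back to random
intercepts with a warning. In the zero-noise limit the fixed-effect solution
is weighting-invariant, and the exact OLS interpolant is returned.

## Synthetic cohort generator

The generator is the package's study population. Defaults emulate the DIAN
structure: 355 carriers and 212 non-carriers in 140 families; visits every
2 years (annual once symptomatic), 2–5 scheduled visits with 5% random
(MCAR) visit dropout; baseline EYO uniform on (−30, +10); conversion age =
expected onset + Normal(0, 2 yr); a 2% reverter fraction and 3 extreme-NfL
"competing disorder" outliers to exercise the exclusion rules; duplicate
replicates with 5% lognormal CV (2% of pairs drawn at 22–35% CV, CSF
remeasurements generated for flagged pairs); family, subject-intercept,
subject-slope and residual SDs of 0.05, 0.08, 0.010 and 0.05 log10 units;
age/sex/BMI effects of realistic sign and size per fluid (higher age → both
fluids up; male → CSF up; higher BMI → plasma down).

The carrier disease signal is defined through its *rate*: d(log10 NfL)/dEYO
is 0 before the true divergence EYO d (−20 by default), rises linearly with
slope k = 0.0025 log10/yr² after d (the same ramp in both fluids, matching
their near-identical presymptomatic behaviour), and, for plasma only, stays
constant after the true plateau EYO (+3.6). The mean level is the exact
integral of this ramp (piecewise quadratic, C1), so divergence and plateau
truths and per-subject window-averaged true slopes are closed-form; a
smoothed (softplus) ramp was considered and rejected because its integral
has no elementary closed form, which would have made the truth values
quadrature-dependent. Imaging: precuneus volume depends linearly on ICV,
shows a cumulative carrier deficit, and its annual slope gains
`imaging_coupling × (true CSF-NfL slope)` (default −2000 mm³/yr per
log10/yr) once a carrier is ever symptomatic; PiB SUVR follows a sigmoid
level in EYO with subject slopes independent of NfL, encoding the amyloid–
neurodegeneration decoupling. The truth object (random effects, conversion
ages, true slopes) is serialized separately and never read by inference
code.

## Replication experiments and their sizes

The acceptance experiments (`nfltraj.experiments`) fix the study conditions:

* **Divergence recovery** — 400 participants (235/165, 100 families), truth
  d = −20, 20 seeds, plus 20 null seeds. "Low noise" (residual 0.015, family
  0.010, subject 0.015) comes from a power analysis: with a quadratic-onset
  signal the band first excludes zero ≈ √(4·SE/k) years late, so a ≤ 3-year
  median lag at n = 400 needs total SD ≤ ~0.024 log10. Observed: median
  |error| ≈ 2.8–3.1 years, 0–2/20 persistent false divergences under the
  null. At the realistic default noise the same estimator detects ~4–5 years
  late — a statement about information, not implementation.
* **Plateau recovery** — 150 rate values over EYO (−5, +12) with the default
  subject-slope scatter; 20 seeds per fluid. Detection (Davies α = 0.05 +
  precision guard): 17–19/20 for plasma-like data, 19–20/20 "none" for
  CSF-like data. Localization to ±2 years succeeds in ~14/20: the asymptotic
  SD(ψ) is 1.3 years but the finite-sample distribution is heavier-tailed
  (~1.8 years), so the ±2-year bar sits near the 70–75% quantile under these
  committed conditions. The corresponding acceptance test is left failing
  rather than quietly changing the generator's heterogeneity.
* **Segmented-vs-oracle** — 20 seeds, n = 200, strong break; max |ψ
  difference| < 0.005 years.
* **Family-wise error** — 200 null replicates at group sizes 88/79/13/48;
  observed FWER 0.03–0.045.
* **Imaging coupling** — 20 symptomatic-heavy cohorts (~60 symptomatic
  carriers with imaging); the −2000 coupling is recovered within 2 SE with
  the correct sign in ~16/20 (estimates attenuate toward zero because
  extracted slopes are shrunken, error-carrying predictors — covered by the
  2-SE band), and the PiB null is retained in ~19/20 (p-values calibrated,
  2/40 rejections in a null study).

## What passing these tests does and does not show

The generator draws from the same model families the pipeline fits (linear
mixed structure, Gaussian noise, MCAR dropout), so the experiments verify
correctness and calibration of the machinery, not robustness to the
misspecifications real cohorts carry: informative dropout, assay batch and
site effects, non-Gaussian heterogeneity, variant-level onset heterogeneity,
imaging partial-volume effects and measurement-error structure are all
absent by design. Real-data headline quantities (divergence near −25 to −19
EYO, plasma bifurcation near +3.6 EYO, cross-sectional r² ≈ 0.7) depend on
access-controlled cohort data and are treated as qualitative recovery
patterns only.

## Numerical conventions

Quantiles use linear interpolation of order statistics. Percentages in
descriptive tables are recomputed from counts and printed to the nearest
integer at ≥ 10% and one decimal below 10%. Wilcoxon rank-sum (two-sided)
and Pearson χ² without continuity correction compare groups in the
descriptive table. Design matrices are standardized internally for
sampling; condition numbers above 1e6 (age and EYO are strongly collinear by
construction) raise a warning but do not stop the fit. All randomness flows
from explicit integer seeds; derived seeds stay below 2³¹.
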