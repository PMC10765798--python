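# Methods

## The problem

Cross-sectional interview surveys record a participant's chronic-disease
status once. When survey records are later linked to death registries, a
participant who was disease-free at interview but diagnosed afterwards is
counted as disease-free at death — *misclassification of disease status at
death* (MicDaD). Mortality rate ratios (MRR) comparing diseased with
non-diseased individuals computed from such data are therefore biased:
person-time and deaths that belong to the diseased group are booked to the
non-diseased group. This package implements a simulation experiment that
quantifies the size and direction of that bias in a high-incidence setting
(a common late-onset chronic disease such as type 2 diabetes) and a
low-incidence setting (a rare early-onset disease such as lupus
erythematosus).

## Model

Lives move through a three-state illness-death model (IDM): Healthy →
Diseased (incidence rate *i(a)*), Healthy → Dead (non-diseased mortality
*m₀(a)*), Diseased → Dead (diseased mortality *m₁(a)*). The disease is
chronic (no remission), death is absorbing, and the cohort is a birth cohort
so age is the only timescale. All rates live on ages [0, 110].

Parametric forms:

* *m₀(a) = exp(β₀ + β₁ a)* — Gompertz. Log-linearity means the downstream
  Poisson rate model is correctly specified, so estimation error is pure
  sampling noise plus the masking effect under study. The slope is fixed at
  β₁ = 0.1 /year, a typical adult value; only the level is calibrated.
* *MRR(a) = m₁(a)/m₀(a) = exp(c₀ − c₁ a)* — log-linear and decreasing with
  age. High setting: (c₀, c₁) = (2, 0.02), giving 3.32 / 2.23 / 1.49 at ages
  40 / 60 / 80. Low setting: the log-linear curve through (40, 3.79) and
  (80, 1.51), which gives 2.39 at 60. *m₁ = m₀·MRR* is then Gompertz too.
* *i(a)* is zero below an onset age (30 y high, 18 y low — assumptions, see
  limitations) and log-linear above it, with two free parameters.

### Calibration

The original rate formulas behind the study settings are not available, so
the defaults are surrogates pinned to published summary quantities. Per
setting, the three free parameters (m₀ level; incidence level and slope) are
solved jointly (`calibrate_rates`, Powell-hybrid root-find on adaptive
quadratures, residual tolerance 1e−6) so that:

* the competing-risk lifetime probability of diagnosis,
  ∫ i(a)·exp(−Λ_i(0,a) − Λ_{m₀}(0,a)) da, equals 0.40019 (high) / 0.00196
  (low);
* the median onset age among the diagnosed equals 60.75 y / 32.55 y;
* the median death age among those dying non-diseased equals 74.00 y /
  70.53 y.

The last target is deliberately the *conditional* median. A simpler
calibration that treats the printed median as the unconditional median of
the m₀-only process was tried first (`calibrate_m0`, closed form, still the
solver's starting point): in the high-incidence setting competing diagnosis
selects earlier deaths into the non-diseased group strongly enough to shift
the cohort's overall median death age ~2.6 y below the intended value, so
the joint conditional calibration was adopted. With it, a simulated
100 000-life high cohort lands at 74.1 (non-diseased), 77.0 (diseased) and
75.3 (overall) against intended 74.00 / 75.85 / 74.84 — the diseased median
is not itself a calibration target and inherits a ~1 y surplus from the
surrogate incidence shape.

## Simulation

Discrete-event microsimulation. For each life, the first event age solves
Λ_{m₀+i}(0, a*) = −ln U by vectorized bisection (60 iterations, i.e. to
machine precision); the event is a diagnosis with probability
i(a*)/(i(a*)+m₀(a*)), the thinning rule for competing risks. Diagnosed lives
draw the death age from m₁ starting at diagnosis via the Gompertz
closed-form inverse cumulative hazard. Lives with no event by 110 are
assigned death at exactly 110 (< 10⁻⁴ of lives under the defaults).
Populations are stored as one row per individual and round-trip through a
Lexis-style long format (one row per state episode).

Survey ages are Uniform(18, 110), drawn once on the parent population and
inherited by sub-samples. A diagnosis strictly after the survey is masked;
a tie (survey age equal to diagnosis age) counts as observed, and surveys
falling after death follow the same literal rule.

## Estimation

Person-time is split on the window [40, 80) into 1-year bands: non-diseased
time from 40 to min(diagnosis, death, 80), diseased time from
max(diagnosis, 40) to min(death, 80), with the death event booked to the
band containing the death age and the state occupied at death; deaths at or
after 80 are censored. Under MicDaD the *observed* diagnosis is used, so a
masked life's diseased time and death are wrongly non-diseased — masking
reallocates person-time and events between groups but conserves their
totals, which is tested as an invariant. A diagnosed person still
contributes healthy person-time before diagnosis (time-split
classification), matching episode-based storage and avoiding immortal-time
artifacts beyond the masking itself.

Each group's death rate is modelled as λ(a) = exp(β₀ + β₁a) with band
person-years as exposure and the band midpoint as the age covariate, fitted
by Newton–Raphson from an intercept-only start (parameter-change tolerance
1e−10; the fit is flagged unconverged otherwise). The estimated MRR at age a
is exp(Δβ₀ + Δβ₁·a) from the diseased and non-diseased fits. The ratio is
diseased over non-diseased mortality — the orientation under which all
reported values exceed one.

## Resampling study

200 sub-populations of 5 000 are simple random samples without replacement
within a draw, independent across draws. Each is analysed twice (true vs
observed status) — a paired design. Bias at an evaluation age (40, 60, 80)
is the median over sub-populations of (MRR with MicDaD − MRR without);
summaries add 2.5%/97.5% quantiles (linear-interpolation convention) and
over/under/tie counts. Sub-populations where a fit fails — possible in the
low setting, where a sample may contain no diseased deaths inside the
window — are excluded from summaries and counted. Kernel densities of the
MRR distributions use a Gaussian kernel with Silverman bandwidth; an
all-equal sample falls back to a narrow fixed-bandwidth peak.

Randomness: one top-level seed expands into named substreams (simulation,
survey, sampling) via `SeedSequence.spawn`, so stages can be re-run
independently and every output is reproducible bit-for-bit from the run
manifest. CSVs are written at 10 significant digits.

## What the generator does and does not emulate

The generator reproduces the study conditions: a closed 100 000-individual
birth cohort, age-only rate dependence, chronic disease without remission,
one-time surveys uniform on [18, 110], and the two incidence settings. It
does not emulate calendar-time trends, duration-in-state effects on
mortality, covariates (sex, socioeconomic position), repeated surveys,
migration, or birth-year heterogeneity. Passing tests therefore show the
estimation machinery behaves correctly under the model's assumptions, not
that real survey–registry linkages carry bias of exactly this size; in
practice the amount of missing diagnosis information is unknown and can
exceed what uniform survey ages produce.

## Numerical choices

* Cumulative hazards: closed forms for Gompertz and the log-linear
  incidence; adaptive quadrature (relative tolerance 1e−10) for arbitrary
  rate objects.
* Event-time inversion: bisection to ~1e−16 years; exact closed-form
  inverse for Gompertz second events.
* Calibration: residual tolerance 1e−6 (relative); failures raise with the
  residuals attached.
* Poisson fits: Newton–Raphson, tolerance 1e−10, at most 100 iterations;
  zero-event tables raise; single-band tables are fittable only with a
  fixed slope.
* Degenerate inputs: zero-length hazard intervals return 0; zero incidence
  yields populations with no diagnoses and a study where every diseased fit
  fails (reported, not fatal); empty populations yield empty tables.

## Known limitations

* The surrogate rates match the published summary targets, not the original
  formulas; stochastic results (medians over sub-populations, bias values)
  agree to within the stated tolerances rather than exactly.
* Onset ages (30 y / 18 y) below which incidence vanishes are assumptions.
* The low-incidence setting yields ~10 diagnosed individuals per 5 000-life
  sub-sample, so its per-sub-population MRR estimates — and hence the median
  bias — are intrinsically noisy; its published-style summary is "no
  systematic bias" rather than a precise number.
* The Gompertz slope 0.1/year is fixed, not estimated from any data source.
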