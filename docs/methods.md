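# Methods

This note documents the models, the numerical choices, the synthetic
data generator, and the design decisions taken where the design was
genuinely open. Units throughout: grams, kcal, days, mg/kg.

## The two-compartment model

Body mass is split into fat mass (FM) and fat-free mass (FFM), each with
a fixed energy density (ρ_FM, ρ_FFM). The single driver is the
imbalance between measured food-intake energy *I* and expenditure *E*;
a constant partition slope α = dFFM/dFM allocates the imbalance between
the compartments, so every trajectory is confined to the line
FFM = FFM₀ + α·(FM − FM₀). Expenditure is

E = K + β(I − I₀) + (λ + γ_FM)·FM + (λ + γ_FFM)·FFM
  + η_FM·dFM/dt + η_FFM·dFFM/dt + d(X),

the sum of a basal offset, diet-induced thermogenesis above the baseline
intake I₀, mass-dependent maintenance and activity, tissue-deposition
costs, and (in drug studies) a Hill-type drug effect
d(X) = D₀ + D_max·X/(ED₅₀ + X) applied during the half-open dosing
window [0, 23) days. D₀ is handling stress and applies to the vehicle
arm too; the caloric-restriction configuration carries no drug term at
all, so setting the drug machinery aside reproduces the restriction
model exactly (asserted by test).

**Implicit expenditure, resolved in closed form.** The deposition terms
contain dFM/dt and dFFM/dt, which via the partition equations contain E.
The equation is linear in E: with E₀ the explicit part and
c = (η_FM + α·η_FFM)/(ρ_FM + α·ρ_FFM),

E = (E₀ + c·I)/(1 + c).

We resolve algebraically rather than iterating inside the ODE
right-hand side; a damped fixed-point iteration is kept in the test
suite as an independent oracle (agreement < 1e-10 kcal/day).

**Integration.** Fixed-step classical RK4 with 10 substeps/day,
restarted at each day boundary. Intake, the drug effect and (in the
profile generator) the partition slope are frozen per day interval
(left endpoint), so the piecewise-constant inputs never straddle a step
and results are bit-reproducible across platforms; adaptive solvers
would smooth over the intake discontinuities. Fat mass is clipped at
0 g with a logged warning — a regime the studied designs never enter.

**Closed-form day map for calibration.** Within one day the model is
affine in its state (E₀ is linear in FM along the partition line), so
the ten RK4 substeps compose into a single affine map whose coefficients
are computed exactly; the same holds for the α-free model at a fixed
body-weight input, with time-varying forcing entering through the RK4
stage weights. Calibration evaluates these compositions (~0.1 ms per
study objective) instead of stepping the integrator; a test asserts
equality with the general integrator at every integer day to < 1e-9
relative. The fast path ignores the FM ≥ 0 clip, which is irrelevant in
the fitted regimes.

## The α-free model

Differentiating mass balance BW = FM + FFM and substituting into energy
balance I − E = ρ_FM·dFM/dt + ρ_FFM·dFFM/dt gives

(ρ_FM − ρ_FFM)·dFM/dt = I − E − ρ_FFM·dBW/dt,

with FFM = BW − FM. Body weight is an input: a cubic smoothing spline
of the arm-mean daily BW supplies BW(t) and its derivative. The
expenditure equation is again linear in E (with
c′ = (η_FM − η_FFM)/(ρ_FM − ρ_FFM)) and resolved in closed form. The
instantaneous composition ratio
dFFM/dFM = −(I − E − ρ_FM·Ḃ)/(I − E − ρ_FFM·Ḃ) is reported along the
trajectory; points where fat mass is stationary (denominator < 1e-8)
are emitted as NaN rather than infinities.

**Smoothing-spline dialect.** The classical objective
p·Σ(y − f)² + (1 − p)·∫f″² is used with fidelity p; p = 0 is the
least-squares line and p = 1 the natural cubic interpolant
(implemented via the penalised-spline solver with penalty
λ = (1 − p)/p). The default p = 0.2 refers to *this* convention;
"smoothing factor" parameters of other spline toolboxes are not
numerically interchangeable — when matching a fit produced elsewhere,
calibrate by effective degrees of freedom rather than copying the
number. At p = 0.2, daily observations with 2 g noise track a
noise-free 45-day weight curve to better than 5 g on interior days
(seeded test).

**Exact model input.** For equivalence checks the α-free model can be
driven by `model_bw_input`, which evaluates a partition-model run's BW
and Ḃ in closed form within each day (the within-day dynamics are a
scalar linear ODE), including the correct one-sided branch at day
boundaries. Fed this input with shared parameters, the α-free model
reproduces the partition model's fat mass to ≪ 0.1 g over 45 days —
the module's primary oracle, checked over 20 random parameter draws.

## Calibration

* **Partition slope α:** total least squares on pooled individual
  (FM, BW − FM) points — orthogonal distances, via the principal
  eigenvector of the centred second-moment matrix. Orthogonal
  regression is appropriate because both coordinates carry measurement
  error; it is symmetric under axis exchange (slope inverts), unlike
  ordinary least squares. Isotropic scatter and vertical principal
  directions are reported as errors, not numbers.
* **Objective:** Σ(BW − BŴ)²/N_BW + Σ(FM − F̂M)²/N_FM per arm, summed
  over arms with equal weight (the studies are fitted jointly). FFM is
  never compared directly: it is not measured, only derived as
  BŴ − F̂M. Simulations run from the first to the last
  body-composition day, initialised at the arm-mean first BC
  measurement; missing intake before the intervention is imputed with
  the baseline intake, a missing tail carries the last measurement
  forward, and interior gaps (not covered by the two study rules) use
  last-observation-carried-forward with a logged warning.
* **Baseline intake I₀:** for the CR design, the mean of the four
  pre-study baseline days; for the drug design, the day-0 measurement
  (the first dosing day) — the convention of the original study
  protocols.
* **λ (activity) with K pinned:** λ and K trade off along a ridge
  (quantified by `lambda_k_surface`; nodes near the minimum have
  |corr(λ, K)| > 0.9, and re-fitting λ at different fixed K moves the
  estimate monotonically). K is therefore fixed at 0 for the CR study
  and λ found by bounded Brent minimisation on [0, 0.5] kcal/g/day,
  xatol 1e-10. On noise-free synthetic data λ is recovered to < 1e-4.
* **Drug quartet (K, D₀, D_max, ED₅₀):** λ is carried over; the four
  expenditure parameters are fitted by simulated annealing — geometric
  cooling T_k = 0.95^k·T₀ over 120 temperature levels, 200 iterations
  per temperature, Gaussian proposals scaled to 5% of the box width,
  box K ∈ [−100, 100], D₀ ∈ [0, 100], D_max ∈ [0, 200] kcal/day,
  ED₅₀ ∈ [0.5, 100] mg/kg, T₀ from the spread of 50 random probes —
  followed by a bounded Nelder–Mead polish that makes the optimum
  solver-independent. All randomness flows from one integer seed; two
  runs with the same seed return identical results. Any reasonable
  annealer reaches the same basin on this smooth 4-parameter surface;
  the budget above is the package default. The α-free refit uses the
  same protocol with the α-free simulator (λ is not re-estimated).
  ED₅₀ is the least identifiable of the four, with wide
  study-to-study scatter at realistic noise.
* **Kleiber translation:** per-gram metabolic rates transfer between
  body sizes as (m_target/m_ref)^(−1/4) (whole-body rate ∝ mass^(3/4)),
  e.g. from a 25 g mouse to a 350 g lean rat.

## Synthetic studies

The generator emulates the two study designs the analysis targets:

* **CR:** baseline BW ~ Normal(640, 62) g; arms ad-lib and 10/20/30/40%
  restriction of each animal's measured baseline intake; 26 restriction
  days; DXA days −3/12/22; n = 10/arm; baseline intake established over
  4 pre-study days.
* **Drug (CB1Ra):** baseline BW ~ Normal(695, 75) g; vehicle and
  3/10/30 mg/kg for 23 days plus a 15-day washout; DXA days −3/24/42;
  n = 9–10/arm; baseline intake = day-0 measurement (so each animal's
  I₀ is its own day-0 intake, keeping the synthetic world
  self-consistent with the fitting convention).

Per animal: baseline body composition is drawn *along the population
FFM–FM line* (slope 0.92, intercept 357 g, vertical scatter 8 g) at the
drawn body weight. This is deliberate: drawing FM as an independent
fraction of BW would give the pooled baseline cloud a principal axis
set by the baseline covariance (slope ≈ 3) rather than by the
composition relation, and the pooled TLS step would not estimate the
partition slope. Biologically, heavier diet-induced-obese rats are
heavier mostly through fat, which is exactly a line of this kind.
Between-animal variability: basal offset K ~ Normal(0, 3) kcal/day and
baseline intake with 5% coefficient of variation; ad-lib intake gets 5%
lognormal day-to-day jitter. Measurement noise: BW σ = 5 g daily,
FM σ = 8 g on DXA days; intake is recorded exactly (it is weighed, not
assayed). The noise and variability magnitudes are generator choices on
the scale of typical colony data, not measured quantities.

Drug-arm intake suppression is a modelling choice (in the real design it
is a measured outcome): a dose-dependent dip
s = 0.30·X/(X + 10 mg/kg), full in week 1, relaxing to half with a
4-day time constant thereafter (partial tolerance), and recovery to
baseline after dosing stops.

A second entry point integrates the partition equations with a
time/dose-dependent slope profile (default: α falling with dose during
treatment, i.e. loss shifted toward fat at high dose). These
partition-violating worlds reproduce the qualitative failure mode the
α-free model exists for: the fitted constant-α model still matches body
weight (residuals at the noise scale) but misfits fat mass at the DXA
days, with a fat-mass objective more than 3× (typically 10–35×) the
α-free model's.

**What passing tests do and do not show.** The generator's animals obey
the model family exactly (up to the injected partition violation), have
Gaussian noise, and no dropout, no within-day intake patterning, no
water-compartment shifts. Parameter recovery here demonstrates the
correctness and identifiability of the estimation machinery under the
stated designs — not that the model is adequate for any particular real
colony.

## Default parameters

ρ_FM = 9.4, ρ_FFM = 1.8, η_FM = 0.18, η_FFM = 0.23 kcal/g and β = 0.24
are literature placeholders for rodent tissue energetics and
Sprague-Dawley diet-induced thermogenesis; γ_FM = 0.01 and
γ_FFM = 0.10 kcal/g/day are Kleiber-scaled placeholders chosen so that
a 640 g DIO rat is near energy balance at ~107 kcal/day intake.
λ = 0.087 kcal/g/day, K_CR = 0, and the drug quartet
(K = −16.6, D₀ = 13, D_max = 37 kcal/day, ED₅₀ = 10 mg/kg) are the
calibrated values the synthetic worlds are built around and that the
recovery tests re-estimate. All are config-file overridable; nothing in
the pipeline hard-codes them.

## Problem sizes and numerical tolerances

Equivalence and conservation checks run 20 random 45-day draws with
intake jitter ±10% around the draw's equilibrium (wilder draws starve
the fat compartment — a valid regime, but not the one under test).
Noisy-recovery checks use 25 replicate studies per statistic; the
partition-violation comparison uses 10 replicate worlds and reports the
median objective ratio; the acceptance script reports medians over 5
(λ) and 15 (drug quartet) replicate studies, the larger count because
of ED₅₀'s scatter. Energy conservation is verified to 1e-6 relative
with an independent per-day Simpson quadrature of I − E over the stored
states; partition-line confinement to 1e-6 relative; the closed-form
day map to 1e-9 relative against the stepped integrator.

## Known limitations

* No extracellular-water compartment: short-term fluid shifts are
  absorbed into apparent expenditure.
* Dose acts directly through the Hill term; no pharmacokinetic link
  from plasma concentration to effect, and ED₅₀ is interpreted in
  mg/kg.
* No uncertainty propagation from the body-weight spline into the
  α-free fat-mass estimates, and point estimates only (no bootstrap).
* Arm-level mean intake drives the fits; individual-animal fitting is
  not implemented.
* Pipeline stages are recomputed on each run (simulations cost
  milliseconds; no result caching).
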