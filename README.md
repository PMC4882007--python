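# ratabolic

Energy-balance modelling of body weight and body composition in the rat,
built for short-term pre-clinical intervention studies: caloric
restriction (CR) and pharmacotherapy (a CB1-receptor antagonist serving
as the reference drug design).

## Who this is for

Quantitative pharmacologists and systems biologists who have daily food
intake (FI) and body weight (BW) measurements plus sparse DXA fat-mass
(FM) measurements from rodent studies, and who want to (i) calibrate a
mechanistic energy-balance model to those data, (ii) estimate drug
effects on energy expenditure, and (iii) infer body-composition dynamics
on days where no DXA scan exists.

## The models

**Two-compartment (partition) model.** Fat mass and fat-free mass
(FFM) change with the imbalance between intake *I* and expenditure *E*:

```
ρ_FM  dFM/dt  = ρ_FM          / (ρ_FM + ρ_FFM·α) · (I − E)
ρ_FFM dFFM/dt = ρ_FFM·α       / (ρ_FM + ρ_FFM·α) · (I − E)

E = K + β(I − I₀) + (λ + γ_FM)·FM + (λ + γ_FFM)·FFM
      + η_FM·dFM/dt + η_FFM·dFFM/dt + d(X)
```

with ρ the tissue energy densities (kcal/g), η the deposition costs,
β the diet-induced thermogenesis fraction, γ the mass-specific metabolic
rates, λ physical activity per gram of body weight, K a basal
thermogenesis offset, and α = dFFM/dFM the constant energy-partition
slope. Drug treatment adds a Hill effect
`d(X) = D₀ + D_max·X/(ED₅₀ + X)` during the dosing window.
Because *E* contains the mass derivatives, the expenditure equation is
implicit; it is linear in *E* and resolved in closed form.

**α-free model.** Combining mass balance `BW = FM + FFM` with energy
balance eliminates the partition assumption:

```
(ρ_FM − ρ_FFM) dFM/dt = I − E − ρ_FFM·dBW/dt
```

Body weight enters as an input (a cubic smoothing spline of the measured
series supplies `BW(t)` and its derivative) and FFM is recovered by mass
balance. The instantaneous ratio
`dFFM/dFM = −(I − E − ρ_FM·Ḃ)/(I − E − ρ_FFM·Ḃ)` is exposed as a
diagnostic — unlike α it may change over time.

**Calibration.** α is a total-least-squares line through pooled
(FM, FFM) points; λ is fitted to the CR study by bounded scalar
minimisation with K pinned at 0 (the two are non-identifiable — see the
λ–K error surface); the drug quartet (K, D₀, D_max, ED₅₀) is fitted to
the drug study by seeded simulated annealing with a Nelder–Mead polish.
The objective is the sum of mean squared BW (daily) and FM (DXA-day)
errors against arm means.

A synthetic-study generator emulates both study designs with known
ground truth, so every stage of the pipeline is testable end to end by
parameter recovery.

## Worked example

```python
import ratabolic as rb

# a synthetic caloric-restriction study: 5 arms x 10 rats, daily BW/FI,
# DXA fat mass on days -3/12/22, known ground truth
records, truth = rb.generate_study(rb.GeneratorConfig.cr_default(), seed=7)
arms = rb.aggregate_arms(records)

# constant partition slope from pooled individual body-composition points
fm, ffm = rb.pooled_bc_points(records)
line = rb.fit_alpha_tls(fm, ffm)
print(f"partition slope alpha = {line.slope:.3f} (intercept {line.intercept:.1f} g)")

# physical-activity coefficient, basal thermogenesis pinned at zero
fit = rb.fit_lambda_cr(arms, rb.ModelParams(alpha=line.slope))
print(f"lambda = {fit.params['lam']:.4f} kcal/g/day")

# simulate the 40%-restricted arm at the fitted parameters
sched = rb.impute_intake(arms[-1], (-3, 22))
fm0 = arms[-1].fm_mean[0]
init = rb.BodyState(-3.0, fm0, arms[-1].bw_on(-3) - fm0)
p = rb.ModelParams(alpha=line.slope, lam=fit.params["lam"], i0=arms[-1].i0)
traj = rb.simulate(init, sched, p, t_end=22)
print(f"day 22: model BW {traj.at_days(22, 'bw')[0]:.1f} g "
      f"vs observed {arms[-1].bw_on(22):.1f} g")
```

prints

```
partition slope alpha = 0.960 (intercept 350.8 g)
lambda = 0.0868 kcal/g/day
day 22: model BW 551.4 g vs observed 556.5 g
```

i.e. the pooled body-composition relation is recovered near the
generating line (FFM ≈ 0.92·FM + 357), the physical-activity coefficient
lands near its generating value of 0.087 kcal/g/day, and the calibrated
model tracks the most severely restricted arm's weight loss to within a
few grams.

The same workflow is available from the shell:

```
ratabolic generate --kind cr --seed 7 --out cr.csv
ratabolic fit-alpha --study cr.csv
ratabolic fit-cr --study cr.csv
ratabolic report --out report/ --seed 7     # full two-study pipeline
```

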