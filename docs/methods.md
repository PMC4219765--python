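# Methods

## Model

One individual is advanced with an explicit Euler step of one day. The
state is the pair (F, L) of fat and lean mass in kg; total mass is
m = F + L and BMI is m/h². Each day, in order:

1. draw the social term s (if enabled);
2. update intake I = I₀ (m/m₀)^γ from the current mass;
3. recompute expenditure E = B(sex, age, m) + βI + A(m);
4. form the effective imbalance φ = I − E + s;
5. choose the partition fraction p (Forbes or Hall);
6. step ΔL = pφΔt/ρ_L, ΔF = (1−p)φΔt/ρ_F.

The scheme conserves energy identically per step
(ρ_F ΔF + ρ_L ΔL = φΔt), and a suite test confirms closure to 1e−9
relative over 10⁵ random steps and 1e−8 cumulatively over whole runs.

### Assumptions

- Two compartments only; glycogen and fluid shifts are out of scope, so
  the first days of a diet change are smoother than in reality.
- The basal rate is linear in current mass within fixed sex/age
  brackets; no metabolic adaptation beyond that linearity.
- Intake responds to mass only through the power law; appetite,
  palatability and deliberate dieting strategies are not modelled.
- The social term is exogenous white noise (or a constant offset in the
  sweep cases); there is no network structure and no feedback from the
  individual onto their environment.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| ρ_F | energy density of fat | 9400 kcal/kg | standard two-compartment value |
| ρ_L | energy density of lean tissue | 1800 kcal/kg | standard two-compartment value |
| C | Forbes constant (energy-share scale) | 10.4·ρ_L/ρ_F ≈ 1.99 kg | equivalent to the Forbes companionship slope dL/dM = 10.4/(10.4+F) |
| γ | intake responsiveness | drawn U(0.1, 0.5); 0.3 in social scenarios | 0.3 is the mean of the sampling interval |
| β | thermogenesis fraction of intake | 0.10 | diet-induced thermogenesis convention |
| BMR | basal rate, kcal/day | FAO/WHO/UNU (Schofield) adult weight equations, brackets 18–30 / 30–60 / 60+ by sex | configurable table |
| δ | activity cost, kcal/kg/day | calibrated: (E₀ − B₀ − βI₀)/m₀ | E(t₀) must reproduce the stated E₀ exactly |
| α_s | social proximity | 0.5 in case i | midpoint of [0, 1] |
| ε | social influence | ≤ 300 kcal/day; 50 in case ii; U(0, 300) in case iii | the ±300 cap is 10–20 % of a typical daily intake |
| horizon | run length | 1500 days (sweeps: 5000) | long enough for the slowest γ to settle within 0.5 kcal/day of balance |

Activity can alternatively be held constant at its t₀ value
(`activity_mode="constant"`); the default scales with mass, which keeps
expenditure strictly increasing in mass and guarantees a unique stable
mass whenever one exists.

## The two partition rules

The Forbes rule p = C/(C+F) routes a growing share of any deficit to
lean tissue as the fat store empties; fat mass therefore decays toward
zero but cannot cross it. If lean mass itself would be exhausted (no
positive-mass equilibrium exists), the run clamps both compartments at
zero, sets a `clamped` flag and stops.

The Hall rule defines p through the realized lean fraction of the
previous day's mass change, ΔL/ΔM. Interpreted self-consistently — the
ratio is a mass fraction, so the engine converts it to the lean *energy*
share q·ρ_L/(q·ρ_L + (1−q)·ρ_F) before partitioning — this recursion
reproduces whatever split seeded it (here the Forbes split at the
initial composition) and never reacts to the fat level. Under a
sustained deficit whose cumulative fat share exceeds the initial fat
store, fat mass crosses zero; the engine flags the day (`negative_fat`)
and keeps integrating, because the pathology is itself a result of the
model comparison. A naive alternative reading — feeding the raw mass
ratio back in as the energy share — converges monotonically to p = 1
(all change in lean, fat frozen) and makes the two rules
indistinguishable in fat behaviour; it was rejected for that reason.

The first Hall step, and any step whose |ΔM| falls below 1e−9 kg, is
seeded from the Forbes split at the current fat mass (or the last used
split if the fat store is non-positive).

## Dynamic intake and the stable mass

I(t) = I₀ (m/m₀)^γ has its fixed point at m₀ and satisfies: γ = 0
decouples intake from mass, and larger γ weakens the net restoring
force (1−β)I(m) − B(m) − δm near equilibrium, so the time to reach the
stable mass grows with γ — confirmed to be monotone over the grid
0.10…0.50 (step 0.05). The stable mass itself also shifts slightly with
γ (≈ 98.5 kg at γ = 0.1 versus ≈ 96.6 kg at γ = 0.5 for the 99.52 kg
preset male): γ changes both the path and, mildly, the destination,
because the balance condition contains I(m). Tests therefore compare
each run against the root of its own balance equation (an independent
Brent-solver oracle) rather than across γ.

Stability is reported two ways: the first day within 0.1 kg of the
run's final mass (`time_to_stability`), and the final intake–expenditure
gap, with 0.5 kcal/day used as the "settled" threshold.

## Social term

The net social energetic difference enters the daily balance once, as
sign·α_s·ε. The trajectory records the term in its own column rather
than folding it into the individual intake and expenditure series; this
keeps the individual's routine and the social perturbation separately
auditable and avoids double-counting in the thermogenesis term (which by
construction is a fraction of the *individual* intake). In case iii,
proximity, influence and sign are redrawn independently every day; per-
individual fixed draws were the alternative, but daily redraw is the
natural reading of noise that "varies with daily circumstances".

## Synthetic population

The generator emulates survey-style energy distributions without
shipping any data: height ~ Normal by sex (1.76 ± 0.07 m male,
1.62 ± 0.07 m female), BMI ~ truncated Normal (26 ± 4, bounds 16–45),
mass = BMI·h², fat fraction ~ truncated Normal by sex (0.22/0.32 ± 0.06,
bounds 0.05–0.55), age ~ U(18, 60), PAL ~ U(1.4, 2.0),
E₀ = BMR·PAL, I₀ = E₀ + U(−300, 300), γ ~ U(0.1, 0.5). The
anthropometric defaults are generic-adult placeholders, deliberately
overridable; no country's demography is claimed. With PAL ≥ 1.4 and
β = 0.10 the calibrated activity cost is positive for every profile
(worst case PAL bound (1 + β·gap/B₀)/(1−β) < 1.4), which generation
verifies per profile.

What passing tests on this population do **not** show: realism of the
joint age–BMI–activity distribution, children and adolescents, secular
trends, or measurement error in intake reporting.

## Numerical choices

- Explicit Euler, Δt = 1 day, no adaptive stepping; a 10×-finer step
  changes a one-year final mass by well under 1 % (regression-tested).
- Hall ΔM tolerance 1e−9 kg; Forbes requires F > 0 strictly.
- Trajectories are written with `%.10g` formatting, so identical seeds
  give byte-identical CSVs.
- Degenerate inputs raise `ValueError` with the offending quantity; the
  engine attaches the day index.

## Known limitations

- The Hall-rule reading is one defensible interpretation of an
  increment-ratio partition; its defining property here is the absence
  of fat-level feedback.
- Constant-offset social cases shift the stable mass monotonically but
  the magnitude of the shift inherits all the simplifications above.
- The estimator for γ is a grid search (0.10…0.50, step 0.05) by least
  squares on the mass trajectory; it resolves γ to one grid step and is
  intended as a consistency check, not an inference tool with
  uncertainty quantification.
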