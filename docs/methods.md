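# Methods

`pulsetwin` builds a virtual-patient database of arterial pressure
waveforms with a nonlinear 1-D pulse-wave model, learns to reconstruct
waveforms at inaccessible sites from three peripheral measurements, and
grades abdominal aortic aneurysm (AAA) severity from the reconstructed
abdominal waveform.  This note records the model, the numerical
choices, the defaults and why, and what the synthetic cohort does and
does not represent.

## 1-D haemodynamic model

Each vessel segment solves mass and momentum balance for lumen area
`A(x,t)` and flow `Q(x,t)`:

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dP/dx = -2*pi*gamma*nu*Q/A

with a flat velocity profile in the convective term and a boundary-layer
friction profile parameter `gamma = 9` (dimensionless, overridable per
segment).  The wall is a power-law elastic tube with a Voigt viscous
term:

    P - P0 - Pext = (2*rho*c0^2/b) * ((A/A0)^(b/2) - 1)
                    + Gamma/(A0*sqrt(A)) * dA/dt

* `c0` — intrinsic wave speed at the reference state (m/s); tapers
  linearly along a segment.
* `b = 2` by default: the elastic slope at `A0` is `rho*c0^2/A0`
  for every `b`, and `b=2` makes the local wave speed
  `c = c0*sqrt(A/A0)`.
* `P0 = 80 mmHg` is the reference (stress-free) pressure, `Pext = 0`.
* `Gamma` (Pa·s·m) sets wall viscosity.  We parametrize it through the
  equivalent diffusivity `D = Gamma/(rho*sqrt(A0))` and ship the tree
  with `D = 0.18 m^2/s` for every segment, i.e.
  `Gamma = 0.18*rho*sqrt(A0)`.  This gives frequency-squared damping
  that attenuates the ~10 Hz ringing of junction reflections over a
  metre scale while leaving the principal harmonics intact.

Terminal segments couple to three-element Windkessels
(`Zc` in series with parallel `R`–`C`, outflow pressure
`Pout = 10 mmHg`); `Zc = rho*c0/A0` at the terminal cross-section, so
outgoing waves see a matched termination at high frequency.  Junctions
conserve mass and total pressure `P + rho*u^2/2`.  The inlet couples to
a lumped two-chamber heart (left atrium and ventricle, time-varying
elastance with a two-cosine activation, pressure-gated linear valve
resistances, constant-pressure venous return), connected to the 1-D
root by conservation of mass and static pressure.

## Numerics

* Scheme: two-step (predictor/corrector) MacCormack on the interior
  nodes; formally second order in the smooth interior.  Scheme identity
  is recorded in `SolverConfig.scheme`.
* Boundaries: characteristic closures, first order.  Riemann
  invariants `u ± (4/b)(c - c0)` are extrapolated from the neighbouring
  node; the inlet solves the valve law and the incoming invariant
  implicitly (Newton), outlets solve the Windkessel relation against
  the outgoing invariant, and each junction runs a damped Newton on the
  coupled mass/total-pressure system to a relative residual of 1e-12
  (contract: 1e-10).
* Wall viscosity: the Voigt term is split off and integrated implicitly
  (backward Euler diffusion solve, Thomas algorithm per segment), so it
  imposes no time-step restriction and physiological damping is
  affordable.
* Time step: CFL bound `dt = CFL*min(dx/(1.45*c0_max + 3 m/s))` with
  `CFL = 0.8` by default; critical AAA patients (locally floppy wall,
  large area excursions) run at `CFL <= 0.45`.
* Convergence to a periodic state: cycles repeat until the maximum
  node-wise pressure difference between consecutive cycles falls below
  0.1 mmHg (0.2 mmHg in the desk preset), typically 6–12 cycles.
* Grid sensitivity: halving `dx` and `dt` moves the converged aortic
  cycle by up to ~1.6 mmHg (mean ~0.7 mmHg, about 2% of pulse
  pressure), dominated by the first-order boundary closures.  The test
  suite asserts max < 3 mmHg / mean < 1 mmHg as the documented bound.
* Equilibrium, linear wave speed (0.1% error), closed-end reflection
  (0.4% from doubling), Windkessel steady state (<1e-3 relative) and
  the steady friction balance are verified against analytic oracles in
  the tests.

## The shipped arterial tree

The full 123-vessel anatomy the haemodynamic literature uses is not
tabulated anywhere we can ship from, so the package provides a reduced
25-segment systemic tree (CSV + YAML sidecar, clinical units on disk:
cm, mmHg, mL) containing every vessel the pipeline addresses by name:
aortic root, arch, thoracic (descending) and abdominal aorta, celiac
trunk (standing in for the abdominal side branches), common carotids
with cerebral and external branches, subclavian/brachial arteries with
radial and ulnar branches, common/internal iliacs and femorals.  Any
tree with those names can be substituted through the same schema; the
pipeline is topology-agnostic.

Baseline wave speeds (aorta ~6.2–7.8 m/s, periphery 8–12 m/s at the
50-year anchor) were calibrated once so that the simulated cohort's
heart–femoral pulse wave velocity spans roughly 6.8–12 m/s across ages
30–89 (see ageing below).  Measurement sites: carotid, brachial and
femoral cycles are sampled midway along their vessels; the abdominal
target 3 cm upstream of the distal end of the abdominal aorta; model
outputs are the aortic root, that abdominal site, the left cerebral and
the left iliac artery.

## Virtual patients

Profiles are drawn independently and uniformly within cohort bounds:
age 30–89 y, weight 40–120 kg, height 150–200 cm, gender ~ Bernoulli(½),
ejection fraction 57–66.99%, cardiac output 4.5–7.0 L/min, and — where
the study leaves the marginal unstated — heart rate 55–90 bpm and mean
arterial pressure (MAP) 75–105 mmHg.  Body surface area is computed,
never sampled, with the Du Bois formula
`BSA = 0.007184 * W^0.425 * H^0.725` (W kg, H cm).

Anthropometric scaling of the tree:

* femoral length `L = 0.245*H` (cm),
* descending (thoracic) aorta length `L = -2.6235 + 0.1507*H` (cm),
* proximal abdominal-aorta diameter
  `D = 14.10 + 0.13*A + (-1.09 + 0.04*A)*G + 5.8*BSA`, read in **mm**
  (the 14.10 base value is anatomically plausible only in mm); the
  distal diameter keeps the base taper ratio,
* every other segment scales isometrically — lengths with `H/175`,
  diameters with `sqrt(BSA/BSA_ref)` (reference subject 75 kg, 175 cm).

Note the diameter regression yields healthy abdominal aortas of
2.4–4.2 cm across the sampled ranges, which overlaps the AAA diameter
classes; healthy labels are nevertheless assigned by the absence of a
focal aneurysm, so the classifier must separate diffuse large baselines
from focal dilations.  This overlap is inherited from the scaling
relation and is one reason desk-scale classification is hard.

Ageing: all intrinsic wave speeds are multiplied by
`m(age) = 1 + 0.0105*(age - 50)`, anchored at 50 y.  The slope was
calibrated once against the target cohort PWV span and is not revisited;
the cohort test checks that ≥95% of retained patients fall in
5–13 m/s.

Windkessel assignment: the total effective resistance meets the target
MAP at the target cardiac output (`R_eff = (MAP - Pout)/CO`);
conductances and compliances are apportioned in proportion to terminal
area, with total compliance set by a 1.8 s decay time constant.  Heart
calibration tunes venous pressure (preload, hence end-diastolic
volume) and peak ventricular elastance (hence end-systolic volume)
by bounded multiplicative iteration until the converged simulation
reproduces the sampled EF and CO within 5%; failures reject the
profile.  Retained patients must have simulated MAP in 50–150 mmHg;
rejected profiles are redrawn (rejection sampling preserves the uniform
marginals within bounds) and logged in the manifest.

## Aneurysms

Fusiform AAAs are written into the abdominal aorta's nodewise reference
area with a sinusoidal axial profile
`D(xi) = D_base + (D_max - D_base)*sin(pi*xi/L)`, widest at mid-length
and continuous with the baseline at both ends.  Severity bins are
half-open and decimal-aligned: healthy < 3.0, small [3.0, 4.5),
medium [4.5, 5.5), large ≥ 5.5 cm, with generated diameters capped at
6.9 cm.  Diameters are uniform within class; lengths uniform in
class-specific sub-ranges (small 4–6.6, medium 4.5–7.1,
large 5.5–10 cm) whose means increase with class; axial placement is
uniform over feasible offsets.  A configurable fraction (default 0.25)
of large aneurysms is "critical": five contiguous grid elements inside
the aneurysm have their wave speed multiplied by independent uniform
draws from [0.14, 0.30], mimicking near-rupture wall weakening; small
and medium aneurysms keep their original stiffness.  A sampled
aneurysm whose `D_max` does not exceed the local baseline (possible
because of the diameter regression above) rejects the profile.

## Waveform toolkit

One cycle per patient per site, resampled by periodic linear
interpolation to N = 200 uniform samples (resolves the dicrotic notch
at T ≈ 1 s without inflating the learned sequence length).  Harmonic
energy fractions are ratios of squared Fourier magnitudes with the mean
excluded (Parseval-consistent).  A reconstruction is "accurate" when
its cycle-averaged absolute error is below 0.5 mmHg.  The dicrotic
notch is the first local minimum after the systolic peak (within 0.4 T)
followed by a rise of ≥ 0.5 mmHg; absence is flagged, not fatal.  Pulse
wave velocity uses intersecting-tangent feet (max-upstroke tangent vs
the cycle minimum) over the anatomical root→mid-femoral path length.

## Inverse model

A stacked LSTM (2 layers × 32 cells, forget-bias 1) maps the
per-timestep (carotid, brachial, femoral) pressures to M = 4 output
channels through a single dense layer applied at every timestep; loss
is MSE under Adam.  One multi-output model is trained, not M models.
Channels are z-scored with statistics from the training split only.
Patients split 80/20 into training/testing; the training split is
further split 80/20 into fitting/validation for the loss history.  The
full-scale schedule is 1400 epochs with batch 300; the desk preset
keeps the architecture and uses 600 epochs, batch 32, learning rate
6e-3 with step decay (×0.3 at 70% and 90% of the run).  Cycles are fed
once per pass (no repetition).  The networks are implemented directly
in NumPy (full backpropagation through time; finite-difference
verified) so the package has no deep-learning framework dependency.

## Severity classifier

A 1-D CNN consumes one N-sample pressure cycle: conv(128, k=10) →
conv(128, k=10) → max-pool (window 2, stride 2) → conv(256, k=10) →
conv(256, k=10) → global average pooling → dense 16 → 8 → 4, softmax
with categorical cross-entropy (log clipped at 1e-12); hidden
activations are leaky rectifiers (slope 0.01 — a plain rectifier can
kill an entire small-batch training run when every hidden unit goes
dead, which we observed on desk-scale folds); convolutions are
un-padded.  Training uses
stratified 10-fold cross-validation inside the training split (fold
accuracies reported), then a refit on the full training split that is
evaluated once on the held-out test set.  In the end-to-end pipeline
the classifier input is the *inverse model's* reconstructed distal
abdominal cycle, never the simulator's ground truth (a ground-truth
ablation flag exists and labels its report).  Desk preset: 120 refit
epochs, 30 epochs per CV fold, batch 8, learning rate 3e-3 — roughly
100 epochs are needed before the loss escapes its initial plateau on
small cohorts.

## Problem sizes and determinism

The package's desk-scale study conditions are: 60 virtual patients
(18 healthy, 14 per AAA class), N = 200 samples/cycle, the desk
training schedules above, and a 0.2 mmHg periodicity tolerance.  Full
runs with the study-scale cohort (4137 healthy, 1958/1164/1400 AAA) and
schedules are available through the `full` preset.  At desk scale the
inverse model reconstructs held-out waveforms to ~1 mmHg mean error —
informative, but mostly above the strict 0.5 mmHg accuracy flag — and
the classifier learns in-sample structure but generalizes weakly from
~48 training patients; both experiments therefore report their gap to
the full-scale figures rather than matching them.  Every stage seeds
all randomness from a master seed through a fixed counter scheme;
(seed, configuration) determines database numerics and trained weights
exactly.

## What the synthetic cohort does not capture

The generator emulates anthropometric geometry scaling, ageing
stiffening, cohort haemodynamic ranges and focal aneurysmal dilation
with optional wall weakening.  It does not include venous or pulmonary
circulations, autonomic regulation, special liver/myocardial beds,
non-Newtonian rheology, measurement noise, sensor placement error, or
inter-patient variability beyond the sampled profile fields —
conditional dependencies between cardiac parameters and demographics
are deliberately absent (parameters are sampled independently within
bounds).  Passing tests therefore demonstrate correctness of the
pipeline on this model class, not clinical performance; any transfer to
measured human data would require retraining or transfer learning on
real recordings.
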