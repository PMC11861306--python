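# Methods

## The model

`fourccr` implements a four-compartment controller model of localized
muscular fatigue with enhanced recovery (4CCr) at the level of one functional
muscle group (FMG — the flexors or extensors of one joint, treated as a
single agonist pool).  The motor-unit pool is partitioned into fractions

- `MA` — active,
- `MR` — resting (recruitable),
- `MFP` — peripherally fatigued (impairment at or distal to the neuromuscular
  junction),
- `MFC` — centrally fatigued (impaired voluntary activation),

with `MA + MR + MFP + MFC = 1`.  The governing equations are

```
dMA/dt  = -(FP + FC)·MA + C(t)
dMR/dt  =  RP·MFP + RC·MFC - C(t)
dMFP/dt = -RP·MFP + FP·MA
dMFC/dt = -RC·MFC + FC·MA
C(t)    =  L·min(TL - MA, MR)
```

`TL(t)` is the target load — the torque demanded of the muscle group as a
fraction of its current maximal capacity — and `C(t)` a bidirectional
proportional drive that recruits rested units when demand is unmet and
de-activates surplus units otherwise.  Joint angular velocity `V` (degree/s,
concentric agonist convention, `V ≥ 0`) splits the fatigue flow between the
two fatigued pools:

```
FP = FP0·(1 - e^(-k·V))        RC = r·RC0  if TL = 0, else RC0
FC = FC0·e^(-k·V)              RP = RP0
```

Isometric work (`V = 0`) is therefore purely central and fast dynamic work
increasingly peripheral.  At `V = 0` the peripheral pool never fills and the
model reduces algebraically to the three-compartment controller model with
enhanced recovery (3CCr), with `MFC` playing the role of its single fatigued
pool — the package verifies this against a separately coded 3CCr integrator.

The model's observable is the **residual capacity** `MA + MR = 1 - MFP -
MFC`: the fraction of baseline strength still available, which maps directly
onto normalized MVIC (maximal voluntary isometric contraction) torque.

## Parameters

| symbol | meaning | units | default |
|---|---|---|---|
| `FC0` | central fatigue rate at `V = 0` | 1/s | required input |
| `FP0` | peripheral fatigue rate at `V → ∞` | 1/s | required input (or `FP0_over_RP0 × RP0`) |
| `RC0` | central recovery rate under load | 1/s | required input |
| `RP0` | peripheral recovery rate (constant) | 1/s | required input |
| `r` | central recovery multiplier at rest, `≥ 1` | — | 1 |
| `k` | velocity coefficient (stored as magnitude) | s/degree | 0 |
| `L` | controller gain | — | 20 |

`FC0`, `RC0` and `r` are joint-level three-compartment quantities; the
library deliberately ships no defaults for them — they are config inputs
with provenance kept in the parameter file.  Fitted velocity-split values
(`k`, `RP0`, `FP0/RP0`) for six muscle groups (shoulder, hip, knee × flexors
/extensors) are bundled in `core_model.VELOCITY_PARAMETER_TABLE`; no fitted
elbow values exist.  Two reading conventions are resolved in the types
themselves:

- fitted tables report the signed exponent coefficient, so `k` is stored as
  a magnitude — the model's stated monotonicity (peripheral share grows with
  velocity) is authoritative;
- the published `FP/RP` column is a **ratio**, so `FP0 = ratio × RP0` (the
  product reading gives rates ~1e8 1/s, physically absurd);
- the rest multiplier `r` applies on the **unloaded** branch (`TL = 0`),
  matching its definition as a rest-recovery multiplier and the 3CCr
  lineage; `rest_multiplier_at_rest=False` flips the branch for sensitivity
  analysis.

`L` only needs to be large enough for the developed force to track `TL`
closely (anything above ~10; a warning fires below that), and predictions
are insensitive to it; 20 is the working default.

## Task protocols

Tasks are phases coded `(TL, DC, CT)`: each cycle is active (`TL`, `V`) for
`DC·CT` seconds, then at rest (`TL = 0`) for the remainder.  The active
portion leads the cycle, so MVIC sample times (the active onsets of
isometric phases) are well defined.  The standard fatiguing protocol
alternates five isometric measurement phases — one `(1, 0.2, 15 s)` cycle
per ROM stop — with four 60 s isokinetic phases coded
`(1, 0.5, 2·ROM/V)`, the cycle time being one full flexion–extension sweep.
Six-stop joints (elbow, hip, knee) give 5×90 + 4×60 = 690 s; the five-stop
shoulder gives 615 s.  When 60 s is not a whole number of isokinetic cycles,
complete cycles are laid down and the final partial cycle is truncated at
60 s, active-first (the dynamometer enforces the fixed phase length).  The
nominal velocity is a phase property and is held through both half-cycles;
the agonist/antagonist alternation is expressed by `DC = 0.5` on `TL`.

## Numerics

- Fixed-step classical RK4; default `dt = 0.01 s` resolves the fastest time
  constant `1/L = 0.05 s`.  The grid is split at every profile breakpoint so
  steps never straddle a `(TL, V)` discontinuity.
- States are clipped to `[0, 1]` and renormalized when the pool sum drifts
  beyond 1e-12; an excursion beyond `[-1e-6, 1 + 1e-6]` before clipping
  aborts with a step-size diagnostic rather than silently clamping.
- The simulation starts fully rested (`MR = 1`), reflecting the ≥ 48 h
  washout between test sessions.
- Two independent checks guard the integrator: an explicit first-order
  (Euler) mode run at a 100× finer step, and the separately coded 3CCr
  reference at `V = 0`.  Over the full 690 s protocol, Euler at `dt = 1e-4`
  and RK4 at `dt = 1e-2` agree on final residual capacity to ~2e-7.
- Kernels are numba-jitted; the Python surface validates inputs and carries
  the domain types.

## Torque processing

For each session (participant × muscle group × velocity): per-phase
normalization by the phase maximum; the five normalized torque–angle curves
are averaged into one subject curve; each phase's representative strength is
the closed-form least-squares scale `s = Σyc / Σc²` of the subject curve
onto the best simple-majority subset of `⌈(n+1)/2⌉` stops (all `C(n, m)`
subsets evaluated; lowest summed **squared** residuals wins; exact ties go
to the lexicographically lowest stop-index subset, making the choice
deterministic).  The majority-subset fit tolerates a minority of corrupted
stops.  Consecutive scale drops, relative to the phase-1 scale, are fatigue
rates in %MVC per minute of intervening isokinetic work; within each muscle
group × iteration cell, the rate is regressed on velocity by OLS
(statsmodels) with t-based 95% CI and two-sided p-value.  Rates are
normalized per session (phase-1 base); recovery within an isometric phase is
treated as negligible, consistent with attributing strength decline to the
isokinetic work alone.

## Synthetic data and the measurement model

The generator emulates the dynamometer's data shape: 5 isometric phases × n
ROM stops per muscle group and session velocity, with

```
torque = amplitude · shape(angle) · residual_capacity · (1 + ε),   ε ~ N(0, σ)
```

a Gaussian-bell torque–angle `shape` (peak angle defaulting to mid-ROM,
width 40°), and multiplicative noise because MVIC variability scales with
torque.  Flexors and extensors are independent muscle groups with their own
parameters and shapes.

**Measurement model.**  By default the residual capacity entering a phase's
torques is sampled once, at the phase's first MVIC onset, and applied to all
stops of that phase.  This is the package's own idealization, chosen for
self-consistency with the processing pipeline: a phase is summarized by one
scale factor under the assumption of negligible within-phase recovery, so
the generator asserts the same assumption.  The model itself predicts ~1–2%
capacity recovery within the rest-heavy later isometric phases;
`sample_within_phase=True` samples capacity at each stop's own MVIC time for
realism experiments, at the cost of exact closure.  Consequently, on
noiseless default data the pipeline recovers normalized strengths equal to
the sampled capacities to machine precision, and the generate → process →
fit loop has its optimum exactly at the generating truth.

What the synthetic data do **not** emulate: torque waveforms (only peaks),
angle-dependent fatigue, day-to-day baseline drift, co-contraction,
participant anthropometry, and within-phase recovery (by default).  Passing
tests therefore demonstrate internal consistency of model + pipeline +
estimator, not fidelity to any particular muscle.

Default ground truth: the six fitted muscle-group rows plus synthetic elbow
entries of comparable magnitude, with synthetic central-side constants
`FC0 = 0.01 1/s`, `RC0 = 0.002 1/s`, `r = 15` — magnitudes in line with
published joint-level three-compartment constants.

## Parameter estimation

The three velocity-split parameters `(k, RP0, FP0)` are estimated with the
central-side constants held fixed.  The misfit is least squares between the
model's residual capacity at each isometric phase's first MVIC onset and the
measured per-phase normalized strength, weighted by the phase's MVIC count;
sessions sharing a protocol reuse one simulation per candidate.  The search
is seeded differential evolution over `(k, log10 RP0, log10 FP0)` — the two
rates are positive and span decades — inside default bounds `k ∈ [0, 0.1]
s/°`, `RP0 ∈ [1e-7, 1e-3] 1/s`, `FP0 ∈ [1e-4, 1] 1/s` (bracketing the fitted
table by ≥ 3× each side), stopping early once the average change of the best
objective over 15 consecutive generations falls below 1e-10 (a scaled-down
stall window; the search budget defaults to population multiplier 12 and 60
generations to keep a fit under ~20 s), followed by a bounded L-BFGS-B
polish.  Results are deterministic given the seed.

**Identifiability.**  `FP0` and `k` enter only through `FP0·(1 - e^(-kV))`,
so all-isometric data leave them unidentifiable (the estimator refuses such
input); two or more distinct nonzero velocities separate them.  `RP0` is
structurally identified but weakly so on the 690 s protocol: peripheral
recovery contributes only `∫RP·MFP dt ≈ 5e-3` to strength, so on noiseless
data it is recovered to ~1%, while 2% measurement noise leaves the objective
nearly flat in `RP0` across decades and estimates scatter far from truth.
This is a property of the protocol (no long post-task recovery window), not
of the optimizer — lengthened rest phases or follow-up strength measurements
would be needed to pin `RP0` from noisy data.

**Validation.**  Model predictions at every MVIC sample time are correlated
(Pearson) against the measured per-phase strength repeated once per sample
time in that phase (6 repeats for hip/knee, 5 for shoulder).  Because
predictions recover slightly within a phase while the measured value is
constant, even a noiseless self-comparison sits just below `r = 1` (~0.988);
constant series make `r` undefined and are reported as missing.

## Problem sizes used by tests and the acceptance script

Simulations run the full 690 s (or 615 s) protocols at `dt = 0.01 s`; the
first-order oracle uses `dt = 1e-4 s`.  The randomized conservation check
draws 100 parameter sets; the synthetic study uses one participant per cell
for design cardinality and 14 participants × 5 velocities × 5 seeds for the
noisy recovery experiment, with a reduced search budget (population 8, 40
generations) for the noisy fits.  These sizes are the package's default
experiment configuration and are stated in the test/docstrings where used.

## Known limitations

- Joint angle affects neither fatigue rates nor the controller; only its
  rate of change (velocity) enters the model.
- Antagonist co-contraction is not modelled (`TL = 0` for the antagonist).
- Submaximal isokinetic effort and continuously varying velocity profiles
  are expressible through `TaskProfile` but have no fitted parameters here.
- The velocity split is phenomenological; `F`/`R` laws can be swapped as the
  physiology firms up without touching the compartment structure.
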