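# Methods

This note documents the model, the numerical choices, the defaults and the
limitations of `afterfit`, in the package's own terms.

## Model and assumptions

Aortic pressure over one cardiac cycle obeys the three-element Windkessel
equation

    dp/dt = (1/C + Z/(RC)) q + Z dq/dt − p/(RC)

in the fixed internal unit system kPa / ms / ml (mmHg and seconds are
converted at the I/O boundary only, with 1 mmHg = 0.133322 kPa).  The flow
q(t) across the aortic valve is treated as known data; the valve is a
one-way resistive diode, so q ≥ 0 and diastolic flow is zero.  The model
assumes a single lumped arterial compartment: no wave transmission, no
pressure augmentation, and a single exponential diastolic decay with time
constant τ = RC.

## Forward solver

The equation is linear in p with one slow time constant (τ of hundreds to
thousands of ms), so stiffness is absent.  It is integrated with classical
fixed-step 4th-order Runge–Kutta at a default step of 1 ms.  Because the
right-hand side is linear in p, one RK4 step reduces exactly to the scalar
recurrence p[n+1] = A·p[n] + B[n] with A the 4th-order Taylor polynomial of
exp(−h/τ); the recurrence is evaluated as a first-order IIR filter, which
is bit-identical to explicit RK4 stepping but runs at C speed.  This makes
a full-cycle solve cheap enough (~tens of µs) that the optimizer and the
sensitivity analyses can afford thousands of refits.  dq/dt is formed by
central finite differences on the flow samples (one-sided at the
endpoints), optionally moving-average smoothed (off by default), and
linearly interpolated onto the solver grid and its RK4 midpoints.
Validation: with q ≡ 0 the solution matches p₀·exp(−t/τ) to better than
1e−6 relative; with constant flow it converges to the fixed point
(R + Z)·q₀; halving the step changes the trace by less than 1e−6 relative.

## Event times and feature extraction

The fit uses only three characteristic pressures.  Ejection onset and valve
closure are located on the flow trace: a threshold of 2% of peak flow finds
the rising and falling crossing segments robustly, and the reported event
times are the linear extrapolations of those segments to the zero-flow
baseline.  The extrapolation step matters: the raw threshold-crossing time
lags true valve opening by a few ms on smooth pulses, which would bias the
extracted opening pressure upward on steep upstrokes and break the
consistency between measured features and the model's periodicity residual.
With zero-baseline extrapolation the event times are also independent of
the sampling grid.  Extracted quantities: p_op = p at onset, p̂ = trace
maximum, p_cl = p at closure, p_ed = p at cycle end, MAP = cycle mean of p,
SV = ∫q dt, T_dias = T_cycle − (t_cl − t_onset).

When only cuff measurements exist, p_op is taken as diastolic cuff
pressure, aortic p̂ as systolic cuff pressure (the LV peak estimate adds
the echo trans-valvular drop), and p_cl is placed a configurable fraction
(default 0.7) of the pulse pressure above diastolic.  That fraction is a
dicrotic-notch heuristic, not an empirically fitted value.

Pre-processing of measured trace pairs synchronizes ejection onset (from
flow) with the pressure-upstroke foot (the pressure minimum), by circular
shifting with a periodic extension; sub-sample shifts are snapped to zero.
Heart-rate adjustment is a uniform time scaling to the target cycle length
with flow amplitude divided by the same factor, the simplest choice that
preserves stroke volume exactly.

## Objective and constraints

The cost is the three-term weighted sum of squared residuals between
measured and simulated features; the second term compares the measured
opening pressure with the simulated end-of-cycle pressure and therefore
acts as a periodicity residual.  Default weights ω_i = 1/m_i² with m_i the
measured values make each term a squared relative error, so all three
contribute on the same scale; both the γ_i and the reference means are
configurable.

The simulated pressure is anchored so that it equals the measured p_op at
the detected onset time: the linear step recurrence is inverted over the
(few) pre-onset samples to find the consistent p(0).  When onset is at
t = 0 this reduces to the plain initial condition p(0) = p_op.

Five physiological inequality groups — 1 ≤ Z, 1 ≤ C ≤ R,
b₀ ≤ RC/T_dias ≤ b₁, b₂ ≤ p_cl/MAP, b₃ ≤ p_cl — are folded in as
κ·Σ max(0, g)² with a single scale κ = 1e4, large enough that a ~1%
relative violation dominates typical cost magnitudes while keeping the
penalty C¹-continuous.  Default bounds b₀ = 0.5, b₁ = 6 (decay constant
relative to diastole), b₂ = 0.7 (closing pressure relative to MAP),
b₃ = 4 kPa are deliberately generous stand-ins spanning physiological
ranges; all are configurable and should be tightened when cohort
statistics are available.

## Optimizer

The objective is non-convex, so identification is global–local: 256
scrambled Sobol' points of the search box (plus a physiology-based initial
guess R₀ = MAP/CO, τ₀ from the diastolic decay, Z₀ = 0.05·R₀) are
evaluated, the best 8 are refined with bounded Nelder–Mead, and refined
minima are clustered at 1e−3 relative tolerance to detect multimodality.
Local refinement runs in log10 parameter space, which equalizes the scales
of Z (~10), R (~100) and C (~10), keeps parameters positive, and maps the
box to a box; each refinement is restarted once from its own solution to
re-inflate the simplex and guard against premature collapse.  Near-ties in
objective value are broken deterministically by smallest Z, then R, then C.
All randomness flows through one explicitly passed seed; a given seed
yields a bit-identical result.  The default box Z ∈ [1, 50],
R ∈ [10, 300] kPa ms/ml, C ∈ [1, 100] ml/kPa brackets reported clinical
fits with margin.

Uniqueness is verified operationally: the local stage is repeated from 100
uniform random feasible starts and the count of starts agreeing with the
consensus minimizer within 1% relative per parameter is reported.  On the
default synthetic fixture this count is 100/100 across seeds.

## Synthetic data generator

The generator emulates one cardiac cycle: a half-sine ejection pulse
q(t) = πSV/(2T_ej)·sin(πt/T_ej) (closed-form stroke volume and peak; a
trapezoid variant is available), the corresponding Wk3 pressure response,
and an LV volume trace integrating −q from EDV = 150 ml.  Defaults — cycle
800 ms, ejection 300 ms, SV 80 ml, the published AS operating point
Z = 9.26, R = 97.46, C = 8.42 with p_op = 10 kPa — define the standard
fixture.  Gaussian noise can be added to the measured pressure triple
(absolute and/or relative) and to the traces.

With the prescribed p_op the fixture is not exactly periodic (p_ed ≠ p_op
at the truth parameters), as in real fits; for parameter-recovery
experiments the generator can instead solve for the periodic initial
pressure (`periodic=True`), making the measured triple exactly consistent
with the truth.  `random_cases` draws log-uniform triples inside the box
interior with randomized SV, ejection and cycle times, and rejects any case
violating the physiological constraints, so every ground truth is
attainable by a feasible fit.

What the generator does *not* emulate: beat-to-beat variability,
respiration, measurement drift, reflected-wave shapes, or the systematic
(non-Gaussian) errors of cuff-to-central pressure estimation.  Passing
recovery tests on these fixtures therefore demonstrates correctness of the
identification machinery, not clinical accuracy on real traces.

## Sensitivity analyses

Independent variation: each input pressure is swept over an even grid of
±10% (endpoints and base point included; grid size 100 by default, smaller
in the test suite), refitting per point and reporting extreme signed
relative deviations of Z, R, C in percent.  Global analysis: Saltelli
paired-matrix sampling over the ±10% hypercube with first-order Sobol'
indices per output, estimated as S_i = mean(f_B·(f_AB_i − f_A))/Var, with
bootstrap (200 resamples) 95% confidence half-widths.  The sampler and
estimator are implemented in-package on scipy's Sobol' sequence and are
validated against the closed-form indices of the Ishigami benchmark
(agreement within 0.02 at n = 2^14).  An independent normal density
(σ² = 0.2 kPa² per component, centred on the measured triple) is attached
to every sample as a plausibility weight; sampling itself is uniform over
the stated range.

Refits inside the sensitivity loops default to warm-started local
refinement from the reference optimum (`refit="warm"`); the input→parameter
mapping is continuous, and warm starts reproduce full refits while keeping
the Saltelli loop (n·5 refits) tractable.  `refit="full"` restores complete
global–local refits.  The base sample count defaults to a desk-scale 256
(`FULL_SCALE_N_SOBOL = 5000` restores the full-scale setting).  The second
propagation stage — from Wk3 parameter uncertainty into outputs of a
coupled ventricular model — is out of scope; the report schema notes the
extension point.

## Problem sizes and determinism

Default problem sizes were chosen so that a complete fit takes well under a
second and the full test suite about a minute on a single core: solver step
1 ms over one 800 ms cycle, 256 global candidates, 8 local refinements, 100
multistart repetitions, 20-case recovery experiments, Sobol' base samples
256 (sensitivity) and 2^14 (estimator oracle).  Every stochastic component
consumes an explicit integer seed and no global random state is touched.

## Known limitations

- The penalty bounds b_i and the cost reference means are stand-in
  defaults, not cohort-calibrated values.
- p_cl estimation from cuff data uses a fixed pulse-pressure fraction; real
  dicrotic-notch pressures vary with pathology.
- Only first-order Sobol' indices are computed (no total-effect indices).
- The Wk3 model itself cannot represent wave-transmission phenomena, so
  brachial-to-central pressure transfer errors propagate directly into the
  identified parameters; with noisy inputs the impedance Z is the least
  robust parameter by a wide margin.
- Non-uniformly sampled traces are accepted, but event detection assumes a
  reasonably dense sampling of the ejection upstroke.
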