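# Methods

## The action-potential model

The membrane potential obeys `dv/dt = −Σ_x I_x + I_stim` with thirteen
currents (A/F, outward positive): fast and late sodium (I_Na, I_NaL),
L-type and T-type calcium (I_CaL, I_CaT), transient outward (I_to), rapid
and slow delayed rectifier (I_Kr, I_Ks), inward rectifier (I_KL), the
Na⁺/Ca²⁺ exchanger (I_NaCa), the Na⁺/K⁺ pump (I_NaK), the sarcolemmal
calcium pump (I_pCa) and chloride/calcium backgrounds (I_bCl, I_bCa).  Every
gated current is `b_x · g_x · o_x · (v − E_x)` with open probability `o_x` a
product of Hodgkin–Huxley gates `dx/dt = (x_∞(v) − x)/τ_x(v)` and `b_x` the
drug block factor; I_CaL replaces the ohmic driving force with a GHK flux
factor (inward-rectifying in v, scaled by a dimensionless constant absorbed
into the calibration); I_NaK and I_NaCa use standard voltage-dependent
saturation forms, I_pCa is a constant saturation fraction of its maximal
magnitude.

A single set of kinetics serves all species.  What distinguishes the five
shipped parameterizations (`src/aptrans/data/*.yaml`) is the vector of
effective maximal conductances/magnitudes — the quantity `ρ_x g⁰_x` that
absorbs channel count, membrane area, capacitance and single-channel
conductance — plus the dog's raised intracellular potassium (145 mM vs
120 mM, matching its more negative resting potential).  The T-type current
(nonzero only in zebrafish) uses the published closed-form gating with
activation midpoint −26.3 mV and inactivation midpoint −61.7 mV, exactly as
printed; τ_d is symmetric about the activation midpoint.

**Why calibrated stand-in kinetics.**  The conductance table this package
ships is published, but the full rate equations of the underlying "Base
model" are not; they live in a separate reference.  The kinetics here were
therefore designed fresh (standard sigmoidal steady states, Gaussian/bell
time-constant profiles) and then calibrated so that the *human*
parameterization paced at 1 Hz reproduces the published human control-model
biomarkers, APD50 = 221 ms and APD90 = 317 ms (the shipped model gives
222.9 and 316.5 ms), while all five species show physiological morphology:
resting potential in [−92, −78] mV, peak above 0 mV, beat-to-beat APD90
change below 0.5 ms at the recorded beat.  Two published control values for
human APD50 exist (221 and 214 ms in different tables); calibration targets
the 221/317 pair.  Every downstream validation (inversion, translation) is
self-consistent — the same model generates and fits the data — so the
method is exercised faithfully even though the kinetics are not a verbatim
reproduction.

Calibration was a manual loop over a handful of constants (L-type
inactivation τ_f, I_Kr activation/deactivation τ_xr and rectification,
inward-rectifier activation curve, the GHK scale), with two structural
choices worth recording: the L-type window current was narrowed (activation
midpoint −9 mV/slope 6, inactivation −33 mV/slope 4.5) so that strong I_Kr
block prolongs the AP without early-afterdepolarization-like repolarization
failure, and I_Kr deactivates quickly below −30 mV so that terminal
repolarization is slow enough to give the human APD50→APD90 spread of
~95 ms.

Fixed concentrations (mM): Na 10/140, K 120/5.4 (dog 145/5.4), Ca
10⁻⁴/1.8, Cl 24/150, at 310 K; equilibrium potentials are Nernst at these
values.  Dynamic ion bookkeeping is deliberately omitted: the translation
method operates entirely through conductance scaling and voltage
biomarkers, and fixed concentrations keep the state small (v plus twelve
gates) and the model exactly periodic under pacing.

## Pacing and numerics

The stimulus is a 5 ms depolarizing current pulse at 1 Hz.  Its amplitude
is a per-species constant frozen in the species files at 1.5× the diastolic
threshold found once by bisection (10.7–17.7 A/F across species).
Simulations start from the quiescent state (gates at steady state for
v = −85 mV) and pace 100 beats by default; biomarkers come from the final
beat, and `|APD90(last) − APD90(last−1)|` is recorded as a convergence
metric (a warning, never an error, if above 0.5 ms).

Integration uses an adaptive Rush–Larsen/Heun scheme implemented in numba:
gates advance by the exact exponential update (unconditionally stable and
bounded in [0,1] for any step), the voltage by Heun's method with the step
chosen so one step changes v by at most 0.2 mV, capped at 0.25 ms (0.05 ms
in the first 20 ms of each beat, so the upstroke is sampled at well under
0.1 ms).  This choice is deliberate: the inversion evaluates thousands of
paced simulations, and a compiled fixed-algorithm integrator is two orders
of magnitude faster than a generic stiff solver called through Python.
Halving all step controls changes APD50 by ~0.05 ms and every APDp by under
0.2 ms (asserted in the tests), well below any tolerance used downstream.

## Drug model

Block is conductance-only with Hill coefficient fixed at 1:
`b_x(D) = 1/(1 + ε_x D)`, `ε_x = 1/IC50_x`.  At D = IC50 the factor is
exactly ½.  The factor map depends only on the drug and dose — never on the
species — which is the computational expression of the invariance that
makes translation possible.  Dose units are carried as labels and must
match between drug and dataset; an explicit converter is provided, nothing
converts silently.

## Inversion

Data are per-dose biomarker sets (control included): APD20…APD90 in 10%
steps, v_min, v_max, and optionally dv/dt_max (needed to see sodium-current
block).  The cost is `H = Σ_d Σ_j w_{d,j} H_j²` with relative absolute
residuals and weights 2 (v_max, v_min, APD50), 5 (APD90), 1 (everything
else, including dv/dt_max whose weight is configurable); control-case
weights are multiplied by the number of doses.  Failed simulations inside
the optimizer return a 10⁶ penalty instead of raising, keeping simplices
alive.

Minimization is continuation with randomized Nelder–Mead restarts, in
log-space for both λ and ε (positivity by construction).  Defaults follow
the reference procedure: 10 rounds × 100 starts × 15 NM iterations, λ
starts uniform within ±10% of the incumbent, ε starts log-uniform within a
factor 5.  Three surrogate decisions fill gaps the procedure leaves open:

* **First incumbent.**  λ = 1 for all free currents; each free ε from a
  coarse scan over {0.01, 0.1, 0.3, 1, 3, 10}/D_max, one channel at a time
  with the others held at 1/D_max (a reproducible stand-in for hand-tuned
  starting points; the 0.01 point means "essentially no block").
* **Explicit initial simplex.**  scipy's default simplex collapses when a
  log-parameter is 0 (λ = 1 exactly); each NM start uses steps of
  `jitter/2` in λ dimensions and `ln(5)/3` in ε dimensions.
* **No-block probes.**  Each round prepends one deterministic start per
  free ε with that ε set to 0.01/D_max and everything else at the
  incumbent.  Rationale: when a free channel has little leverage on the
  source AP (e.g. I_Kr in the zebrafish parameterization), the fit can
  settle in a compensation valley — a large spurious block on that channel
  traded against extra block elsewhere — that random factor-5 perturbations
  cannot escape in a scaled-down schedule.  The probe explicitly asks
  whether the data support dropping each block, which is also the
  scientifically meaningful null hypothesis for an untargeted channel.

Cost evaluations pace a warm-started model: the unmodified species is paced
50 beats once and cached; each candidate then paces 30 further beats from
that state.  The synthetic generator uses the *same* evaluator, so the cost
at the generating parameters is exactly zero and steady-state truncation
bias cancels between data and fit.  The full schedule with all currents
free is an overnight-scale computation; the scaled profile used in the
end-to-end tests (4 rounds × 20 starts × 15 NM iterations, free parameters
restricted to the generated-data design's {I_Na, I_CaL, I_Kr}) runs in
minutes and recovers per-channel block fractions to a few percentage
points.  All randomness flows from a single recorded seed; a repeated run
is bitwise identical.

## Translation

From a source-species fit, only ε̂ transfers: the target species is
simulated with its own shipped conductances and block factors
`1/(1 + ε̂_x D)`, and percent changes are taken against the target's own
control simulation.  λ̂ is deliberately left behind — it captures the
individual source cell's conductance densities, which are exactly what
differs between species.  If a targeted channel has zero conductance in the
target (or source), the code warns: no information can flow through a
current a species does not have.  Any ordered species pair works through
the same code path (animal→human, animal→animal, self-translation; the
latter reproduces direct simulation exactly and is asserted in tests).

## Synthetic data

A design names a base species, hidden per-current factors λ*, a true drug
(ε* per channel; a convenience constructor expresses "X% block at dose D"),
doses including control, and optional per-biomarker relative noise s.d.
Generation simulates each dose and records biomarkers; the ground truth
(λ*, ε*, noiseless biomarkers) is stored alongside.  Noise is multiplicative
Gaussian, truncated at ±4 s.d. and floored so APDs stay positive and
v_max > v_min; zero s.d. reproduces the noiseless path bitwise.  The
default (and the generated-data study's condition) is noiseless.  What the
generator does *not* emulate: raw-trace noise, electrode artifacts,
beat-to-beat variability, cell populations — so passing recovery tests
demonstrate correctness of the estimator under the model's own assumptions,
not robustness to real measurement error.

## Known limitations

* Kinetics are calibrated stand-ins; absolute drug-response magnitudes for
  non-human species are model-dependent and only signs/orders are
  meaningful against published tables.
* Fixed concentrations exclude rate-dependent APD accumulation and calcium
  handling; 1 Hz pacing only is validated.
* Conductance-only Hill-1 block; no state-dependent or kinetic drug
  binding.
* Identifiability degrades for channels with weak effect on the source AP;
  the estimator recovers "no block" for such channels but cannot quantify a
  real block carried by them.
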