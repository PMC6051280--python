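# Methods

## Forward model

Each vocal fold is reduced to two lumped masses (a lower mass m₁ carrying
the aerodynamic load and an upper mass m₂ shaping the upper glottal slit),
linear springs k₁, k₂ anchoring them to the larynx wall, a coupling spring
k_c between them, and viscous dampers r₁, r₂.  The state is the eight
displacements/velocities of the four masses.  Assumptions inherited from
the classical simplified two-mass formulation:

- Bernoulli flow exists only below the narrowest part of the glottis; a
  jet with constant (zero) supraglottal pressure forms above it, so only
  the lower masses are driven: F₁ = L·d·P₁/m₁ as an acceleration.
- Pressure losses at the glottal entrance and viscosity in the glottis are
  neglected; channel (vocal-tract) coupling is ignored, P₀ = 0.
- Fold collision is a one-sided spring: while slit i has negative area,
  an extra restoring spring cᵢ = 3 kᵢ acts.  The collision constants are
  always derived from the current kᵢ, never stored.
- Unilateral pathology enters through a single scalar β ∈ (0.4, 1]:
  right-side masses are divided by β and right-side stiffnesses
  (k, k_c, and hence c) multiplied by β.  Damping is not scaled.  The
  right fold's small-signal natural frequencies are then exactly β times
  the left's.
- The contact force is distributed over the two folds with weights
  β/(β+1) (left) and 1/(β+1) (right).  With the β-scaled constants this
  makes the contact forces on the two folds equal and opposite — the
  momentum-consistent (Newton's third law) form of the asymmetric
  collision term.  At β = 1 it reduces to the classical symmetric
  expression −Θ(−a)(c/m)·a/(2L).

### Units and parameters

Internal units are centimetres, grams, milliseconds; pressures are then in
units of 100 kPa (P_s = 0.008 ⇔ 0.8 kPa) and internal frequencies in kHz
(reported in Hz).  Defaults (the standard set of this model family):

| parameter | default | units | meaning |
|---|---|---|---|
| m₁, m₂ | 0.125, 0.025 | g | lower/upper mass |
| k₁, k₂ | 0.08, 0.008 | g/ms² | anchor springs |
| k_c | 0.025 | g/ms² | mass-coupling spring |
| r₁ = r₂ | 0.02 | g/ms | damping |
| a₀₁ = a₀₂ | 0.05 | cm² | rest areas |
| L, d | 1.4, 0.25 | cm | fold length, lower-mass thickness |
| P_s | 0.008 | 100 kPa | subglottal pressure |
| ρ | 0.00113 | g/cm³ | air density (standard literature value) |
| x₀ | 0.05 | cm² | scale of the smoothed switch Ω |
| β | 1.0 | — | asymmetry; healthy symmetry at 1 |

The aperture switch Ω(x) = tanh(50·x/x₀) (zero for x ≤ 0) smooths the
on/off gating of the Bernoulli pressure on the area scale of the rest
aperture; x₀ defaults to a₀₁ and a hard-step variant is available
(`SimulationConfig(hard_switch=True)`).  At these parameters the two
variants differ negligibly (phonation frequency shifts < 0.1 Hz).

### Integration

Fixed-step classical RK4 with dt = 0.04 ms (25 kHz), duration 500 ms,
initial condition x = 0.01 cm, v = 0 on all masses, first 100 ms flagged
as transient (retained in the result, skipped by analyses).  The 25 kHz
step aligns simulated flow sampling with the sampling rate used for
sustained-vowel recordings so objective comparisons need no resampling.
A divergence guard aborts when any |x| exceeds 10 cm — during parameter
searches this flags unphysical candidates cheaply.  The inner loop is
compiled with numba; the NumPy implementation of the same vector field is
kept as the readable reference and the test suite checks the two against
each other pointwise and against an adaptive high-accuracy integrator.

Numerical accuracy: the contact force makes the vector field nonsmooth,
so fixed-step RK4 loses formal order at collision onsets.  Against a
`solve_ivp` reference (rtol 1e-10) the relative RMS displacement error
over 200 ms is ≈1.7·10⁻³ at dt = 0.04 ms, contracting to ≈4·10⁻⁵ at
dt = 0.005 ms.  The default step is kept at 0.04 ms because the flow
statistics used for fitting are insensitive at that level (F0 shifts
< 0.01 Hz when dt is halved) and the optimiser runs thousands of
simulations.

### Behaviour at the standard parameters

At β = 1 the model phonates at 135.8 Hz (dt-converged; confirmed
independently with an adaptive integrator), strictly between the fold's
small-signal eigenfrequencies of 120.4 and 200.5 Hz.  As β decreases the
oscillation entrains toward the softened fold: F0 ≈ 117 Hz at β = 0.8,
≈82.5 Hz at β = 0.6 (with the first overtone, 164.9 Hz, landing between
the healthy fold's eigenfrequencies), ≈70 Hz at β = 0.53.  Scanning
β ∈ [0.45, 0.60] in 0.01 steps, the per-period extrema counts of the two
lower-mass displacements pass through 2:1 and, for β ≈ 0.47–0.50, 3:1 —
the healthy (stiffer) fold completes three oscillations per glottal
period.  Reports of this model family place the symmetric phonation
frequency somewhat higher (≈145 Hz) and the β = 0.6 / 0.53 overtones at
≈190 / ≈110 Hz; we could not reproduce those numbers from the published
equations and parameter values under any of the formula variants we
tested (pressure gating, contact-force form, coupling-spring placement,
force signs, step sizes), while all the structural claims — bracketing by
the eigenfrequencies, the overtone between the healthy fold's
eigenfrequencies, and the 1:3 entrainment regime — hold as described.
The acceptance script reports the values this implementation actually
computes.

## Dynamics analysis

- **F0**: autocorrelation peak in the 50–500 Hz band with parabolic lag
  refinement; a frame is "unvoiced" when no normalised peak reaches 0.3.
- **Spectra**: Hann window over the full post-transient segment,
  zero-padded to ≥ 2²⁰ points (≤ 0.03 Hz grid) — needed to separate
  overtone lines from nearby eigenfrequency markers.  Each trace is
  normalised to its own maximum.
- **Overtone location**: spectral peaks (height ≥ 0.5 % of the spectrum
  maximum) sorted by height; peaks within 10 Hz of a stronger line are
  discarded as window-leakage sidelobes; the strongest remaining line
  that is not the fundamental is the overtone.
- **Extrema ratio**: the repeat period of the joint (x1l, x1r) trajectory
  is the smallest autocorrelation lag recovering 95 % of lag-0; strict
  local maxima are counted on a 3-sample-smoothed signal over up to eight
  whole repeats and the reduced integer ratio returned.
- **Bifurcation scans**: per β, the set of distinct post-transient local
  maxima (clustered with 1e-4 cm tolerance); divergent runs appear as
  gaps.

## Glottal inverse filtering

Adaptive iterative inverse filtering: high-pass at 30 Hz (integration
amplifies drift), then alternating low-order glottal pre-models and
linear-prediction vocal-tract models, all fitted in the speech domain
where the formants are well conditioned; the flow estimate is the
radiation-compensated (leaky integrator, pole 0.99) inverse-filtered
signal.  Two passes by default ("2 or 3" is conventional); LP uses the
autocorrelation method (Hann pre-window, Toeplitz solve), glottal order
2, tract order fs/1000 + 2.  All fitted filters are checked for minimum
phase; instability raises rather than silently diverging.  Polarity is
preserved by default (the chain is polarity-preserving); an optional
`polarity="auto"` applies the conventional skewness cue on a
300 Hz-lowpassed copy, which we found unreliable on vowels whose first
formant leaves strong ripple in the closed phase.

On the synthetic-vowel grid (F0 ∈ {100, 145, 200} Hz × three formant
configurations with F1 from 450 to 700 Hz) the extracted flow's peak
cross-correlation with the true source is ≥ 0.95.  Time-quotient accuracy
degrades with pitch: |ΔOQ| ≤ 0.1 holds for F0 ≤ 145 Hz but OQ is
overestimated by up to ≈0.25 at 200 Hz, where only a handful of harmonics
sample the tract — the classical failure mode of threshold-based timing
measures, and the reason the amplitude-based NAQ (|ΔNAQ| ≤ 0.05
everywhere on the grid) is preferred for high-pitched voices.

## Glottal features

Cycles are anchored on the major flow peaks; the opening is the last
upward crossing of the threshold before each peak and the closing the
first downward crossing after it, so residual formant ripple in the
closed phase cannot fake landmarks.  The threshold is 5 % of the robust
(1st–99th percentile) peak-to-peak amplitude; flows with an exactly-zero
closed phase (model output) instead use the zero floor, with opening and
closing instants refined to subsample precision by extrapolating the
local slope to the true zero crossing, and the peak refined parabolically.
Without subsample refinement the 25 kHz sampling grid alone injects
cycle-to-cycle jitter of ~2·10⁻³ into SQ; with it, all perturbation
measures of a noiseless periodic simulation are below 10⁻³.

Quotients per cycle (averaged over cycles): OQ = open time / period,
SQ = rise/fall time ratio, ClQ = fall time / period, NAQ = (peak
amplitude / |steepest negative slope|) / period; F0 is the reciprocal
mean period.  Perturbations are jitter-style mean absolute successive
differences relative to the mean — zero for any constant-per-cycle
sequence, 2|a−b|/(a+b) for an alternating one.  The matching objectives
place the target statistic in every denominator; a perturbation term
whose target value is exactly zero is dropped with a warning (its
relative error is undefined).  Both objectives are invariant to flow
amplitude scaling, which the optimiser exploits: no amplitude calibration
of the target is needed.

## Parameter inversion

The fit vector is Φ ⊕ β = [m₁, m₂, k₁, k₂, k_c, r₁, r₂, P_s, β], the
left (healthy) fold's constants plus the shared pressure, with the right
fold derived through β — the natural encoding of a unilateral lesion.
Search intervals: masses/stiffnesses/damping ∈ [0.001, 0.5], P_s ∈
[0.001, 0.05], β ∈ [0.4, 1].  An `independent_sides=True` flag widens the
search to fully independent folds (16 dimensions) for exploration.

GPSO: 30 particles, inertia annealed 0.9 → 0.5, c₁ = c₂ = 2, velocities
clamped to 20 % of each interval, positions clipped to the bounds; each
generation a roulette-wheel (fitness 1/(score+1e-9)) selection of M = 30
individuals is followed by arithmetic crossover with probability 0.7, the
offspring replacing all particles except the incumbent best (elitism, so
the best-score trace is non-increasing).  Termination at objective ≤ 1e-3
or the generation budget (400 by default; the recovery experiments in the
test suite run 60–100 generations, which the convergence traces show is
past the plateau for these targets).  Candidates whose simulation
diverges or fails to produce three cycles score +∞.  The swarm's best
point is polished by L-BFGS-B within the bounds using central-difference
gradients (relative step 1e-4, balancing integration ripple against
curvature); the refiner returns the better of its start and end points.
All randomness flows from one seeded generator recorded in the result.

### Identifiability

The objective compares five statistics while the search space has nine
dimensions, so the minimiser's level sets are (generically)
four-dimensional manifolds: many parameter vectors reproduce a target's
quotients essentially exactly.  Empirically, fits of model-generated
targets reach median FY ≈ 0.01, but the fitted β can sit far from the
generating β at equally good objective values (we observed a β = 1.0
target matched to FY = 0.0037 by a candidate with β = 0.55), and the
fitted coupling stiffness often rests on a search bound.  Recovered
individual parameters should therefore be read as representatives of an
equivalence class, not point estimates; distinguishing voice groups by a
single fitted parameter requires either constraining the other
dimensions or enriching the objective (e.g. waveform-level error), both
outside the present scope.  The perturbation-augmented objective (FYp)
adds five more statistics and is preferred for unstable, pathological
voices, but for noiseless periodic targets the added terms are
uninformative.

## Synthetic data

The generators define the test conditions for the whole pipeline:

- `lf_pulse_train` — Rosenberg-style raised-cosine pulses with exact
  closed-form quotients (ClQ = OQ/(1+SQ), NAQ = (2/π)·ClQ), defaults
  F0 = 145 Hz, OQ = 0.6, SQ = 2; optional seeded uniform period jitter
  with the realised period sequence retained as ground truth.  A smooth
  pulse is used because a triangle's spectral nulls defeat LP-based tract
  estimation; the feature extractors are separately validated against
  triangle closed forms.
- `synth_vowel` — pulse train → all-pole tract (formant poles with
  80–120 Hz bandwidths; default /a/-like 700/1200/2600 Hz) → radiation
  zero (1 − 0.99 z⁻¹) → optional seeded white noise; the true flow is
  retained for round-trip validation.  25 kHz, 16-bit PCM when written.
- `model_target` — forward-simulated flows with the generating Φ, β and
  quotients attached; non-oscillating parameter sets are rejected.
- `make_fixture_set` — a small corpus of 4 normal-like (β ∈ [0.9, 1],
  default k_c) and 4 pathological-like (β ∈ [0.45, 0.6], raised k_c)
  voices, byte-reproducible from its seed manifest.

What the synthetic conditions do **not** emulate: real recordings' room
acoustics and microphone response, aspiration noise correlated with the
open phase, vocal-tract nonlinearity and source–tract interaction, and
natural F0 drift.  Passing the round-trip tests therefore demonstrates
the pipeline's internal consistency, not field accuracy on clinical
recordings.

## Known limitations

- The model omits vocal-tract loading (P₀ = 0), three-dimensional and
  body-cover fold structure, and turbulence; it is a minimal model of
  asymmetry-induced bifurcations, not a full larynx simulator.
- Inverse filtering assumes an all-pole tract and breaks down gracefully
  but measurably as F0 approaches F1 (see the quotient-accuracy numbers
  above).
- Fitted parameters are identifiable only up to the objective's level
  sets (see Identifiability).
- Fixed-step integration across contact events limits trajectory accuracy
  at the default step to ~10⁻³ relative; analyses that need tighter
  trajectories should lower `SimulationConfig.dt`.
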