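# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `stridepower`, and what the synthetic test bench can and cannot show
about real laboratory data.

## The validation problem

Foot-mounted running power meters report power output (PO, W), ground
contact time (GCT, s) and leg-spring stiffness (LSS, kN/m) at 1 Hz from
proprietary inertial algorithms. Assessing their validity requires
reference instruments — track-embedded force platforms, optical motion
capture, and a breath-by-breath metabolic analyser — and a statistical
framework that can say, from a handful of runners, whether the device
measures the same quantity as the reference. `stridepower` implements the
complete reference chain and the Bayesian agreement analysis, and pairs
them with a spring-mass simulator that produces sessions whose true
mechanics are known exactly, so every stage is testable end to end.

## Reference mechanics (force platform)

**Contact detection.** A contact opens at the first sample with
`Fz >= threshold` (default 20 N, a standard noise floor for 500 Hz
platforms) and closes at the first subsequent sample below it; contacts
shorter than 10 ms are discarded. Reported strike/toe-off times refine the
sample instants by linear interpolation of the threshold crossing, which
removes the ±1-sample quantisation of the contact duration. The remaining
GCT error is the deterministic threshold bias (the half-sine spends
~1 ms per side below 20 N), about −2 to −3 ms in our regime.

**External power.** Centre-of-mass accelerations are
`Az = (Fz − m g)/m`, `Ax = Fx/m` with `g = 9.80665` m/s². Velocities and
displacements follow by cumulative trapezoidal integration over one stride
window (ipsilateral strike to ipsilateral strike, i.e. two alternating
contacts plus flight). Two integration constants are unavoidable and the
data do not fix them: the horizontal velocity is anchored at the prescribed
stage speed (pacing is cone-enforced in the protocol being emulated) and
the vertical constant is chosen to zero the stride-mean vertical velocity
(steady running has no net vertical drift). Works are
`Wp = m g (max Dz − min Dz)`, `Wk = ½ m (max Sx² − min Sx²)`,
`Wt = Wp + Wk` — an external summation with no energy-transfer term — and
external power is `W_ext = Wt · ω` with `ω = 1/Ts`,
`Ts = (C2 − C1)/2` from consecutive ipsilateral strikes. Note that this
`ω` is numerically a step rate; the convention is kept as the reference
method defines it. The mechanical cost of running is
`Cm = W_ext/(S̄x · m)` (J·kg⁻¹·m⁻¹). The work extrema are taken over the
full stride window, not stance only; the alternative is a one-line change
but is not exposed because no reference definition demands it.

**Per-lap aggregation.** All per-stride metrics are averaged without
weights across the valid strides of one platform passage.

## Leg stiffness (spring-mass reference)

During stance the runner is a point mass on a linear leg spring of resting
length `L = 0.53 · height`. The spring sweeps a half-angle `θ` with
`sin θ = v·Tc/(2L)` and compresses by `ΔL = Δy + L(1 − cos θ)`, where `Δy`
is the downward excursion of the centre of mass obtained by double
integration of `Az` over the contact, with the touchdown vertical velocity
taken from the stride-level integration. Stiffness is
`kleg = F̂z/ΔL` (kN/m), `F̂z` the peak vertical force of the contact. The
forward velocity `v` entering `θ` is the stride-mean horizontal speed —
the same quantity the estimator has access to — and the simulator defines
its ground-truth stiffness with the identical convention so the recovery
contract is exact. Some texts print the sweep relation as
`θ = sin(v·Tc/2L)`, which is dimensionally a different statement;
`literal_theta=True` reproduces it for comparison, the default uses the
arcsine geometry. In the `θ → 0` limit the estimator reduces exactly to
the vertical-spring form `F̂z/Δy`.

**Heel-marker timing.** Strikes are flat-plateau left edges of the heel
height signal (minima below the 10th percentile + 5 mm, separated by at
least 0.4 stride periods). Using the left edge rather than the plateau
centre dates the strike to within one 400 Hz sample on flat-bottomed
stance signals. The foot's airborne interval is read from
threshold crossings of the same signal.

## Metabolic chain

Breath-by-breath VO2 is linearly interpolated to integer seconds (no
extrapolation), smoothed with a five-sample centred moving average
("5 s bins"; shrinking windows at the edges so no data are discarded;
centred rather than trailing to avoid phase lag against power), truncated
for the first 60 s of exercise (VO2 lags the instantaneous power step at
onset), and converted to metabolic power with `W_met = VO2 · m/60 · 21.1`
(21.1 J per ml O2). Net mechanical efficiency is
`ME = W_ext/ΔW_met · 100` with `ΔW_met` net of a resting baseline
(default 5 ml·kg⁻¹·min⁻¹, configurable; a measured pre-test window can
replace it). Stage-level ME uses stage means, by default over the final
30 s of each stage where first-order kinetics have most nearly
equilibrated. With a physiological time constant (τ ≈ 25 s) a 60 s stage
never fully equilibrates and stage ME carries a transient positive bias of
order 10%; chain-accuracy tests therefore use a short τ to isolate the
arithmetic from the kinetics, and the default τ stays physiological.

## Device alignment

The platform section spans the first `platform_span` metres (default 9) of
each `lap_length` = 200 m lap. Device records are matched by cumulative
distance into the half-open window `[k·200, k·200 + 9)` and averaged to
one value per lap per channel; the window start convention is
configurable. Laps without device samples are flagged missing, not
errors — the downstream mixed model tolerates unbalanced designs.

## Synthetic sessions

Each step is one contact cycle: a half-sine vertical GRF over the contact
`Tc`, zero in flight, with peak from whole-cycle impulse balance
`F̂z = m g (π/2)(T/Tc)`; a full stride holds two cycles on alternating
feet. The half-sine was chosen deliberately: it admits closed forms for
every quantity the pipeline estimates, and it omits the passive impact
peak — which the device class under study also does not model. The
horizontal force is a full sine (braking then propulsion, zero net
impulse) whose amplitude makes the per-step speed fluctuation a fixed
fraction of running speed (default 0.17, putting `Cm` near
2.3 J·kg⁻¹·m⁻¹ at 4 m/s, the magnitude external-work summation yields on
a track). The stride duty factor falls linearly from 0.38 at 2.2 m/s to
0.28 at 5.5 m/s, which produces the expected negative GCT–speed trend.
Given a target leg stiffness, speed and duty factor, the contact time is
solved by root finding (the implied stiffness is strictly decreasing in
`Tc`, so the root is unique); typical solutions are 0.19–0.31 s over the
protocol speeds, with peak forces of 1.4–1.7 kN at 70 kg.

The protocol is the incremental track test: stages of 60 s rising 0.5 km/h
from the subject's initial speed until a configured maximum (default
19 km/h) — the behavioural stop rule of a paced test is abstracted to this
speed cap. VO2 follows first-order kinetics toward an affine steady state
`vo2_rest + slope · P` (default slope 0.08 ml·kg⁻¹·min⁻¹ per W, saturating
at vo2max), with breaths emitted by a gamma renewal process whose mean
interval shrinks from 4 s at rest to 1.5 s at maximal intensity. The
device stream applies an additive bias
`po_offset + po_slope · speed` plus Gaussian noise per channel. The
study-condition preset (`DeviceBiasModel.underreading()`) uses −300 W
constant plus −20 W per m/s — a large underestimation growing with
speed — with 10 W power noise. The bias is linear and unclipped: at the
lowest stage speeds the biased stream can go slightly negative, which the
statistics handle and which keeps the bias model exactly invertible. No
instrument noise model is claimed to be realistic; all noise parameters
are configuration.

All randomness derives from one master seed through independent
per-channel streams, so enabling noise on one channel never perturbs
another and identical seeds give bit-identical sessions.

**What the simulator does not emulate:** impact transients, within-stage
speed variability and pacing error, curved-track centripetal forces,
surface compliance, breath-by-breath physiological drift, device distance
drift (available as an injection but off by default), or asymmetry between
limbs. Passing recovery tests therefore demonstrates the correctness of
the estimators under the spring-mass model, not robustness to every
artefact of real recordings.

## Bayesian agreement framework

**Model.** For each metric,

    y_ijk = β0 + S0_i + β1·device_k + (β2 + S1_i)·speed_j
            + β3·(speed_j · device_k) + ε_ijk,

subject i, lap/speed j, device k (0 = reference, 1 = pod). Speed is
z-scored; the device indicator is left 0/1 so β1 reads directly as the
pod-minus-reference offset. `(S0_i, S1_i)` are bivariate normal with
standard deviations `(τ0, τ1)` and correlation ρ.

**Priors.** Device offset: N(0, 1000) for power (the offset scale was
genuinely unknown a priori), N(0, 1) for GCT in seconds, N(0, 10) for LSS.
Speed slope: N(0, 200) for power, N(0, 1) for GCT and LSS, on the
standardised-speed scale. The interaction, for which no scale was
prescribed anywhere, inherits its metric's speed prior. Scales
(σ, τ0, τ1): half-Student-t(3, 0, 2.5·sd(y)); correlation: LKJ(2)
marginal. The intercept prior is the data-anchored default of the Stan
regression front ends, student-t(3, median(y), max(2.5, mad(y))): a
fixed-location narrow intercept prior hundreds of scales below the
response level would push the intercept into the random effects and leave
a spurious ridge along (β0, τ0); the data-anchored form is what a
design-matrix-centring stack effectively uses, and is the only reading
consistent with raw-scale intercepts near 570 W coexisting with
τ0 ≈ 86 W.

**Computation.** The random effects are integrated out analytically —
per subject the marginal covariance is `σ²I + Z Σ_b Z'`, handled by the
Woodbury identity on 2×2 blocks — leaving an 8-parameter posterior
(β, log τ0, log τ1, atanh-scaled ρ, log σ) sampled with an
affine-invariant ensemble (differential-evolution moves, 32 walkers,
700 warm-up + 800 retained steps by default). The initial cloud is
overdispersed to the posterior's estimated width because DE proposals
scale with ensemble spread. For asserted summaries the fit runs four
independent ensembles: split-R̂ is computed across the independent runs
(walker-level R̂ is biased upward for interacting walkers and converges
slowly even after equilibration), effective sample sizes from individual
walker trajectories. Fits with max R̂ > 1.01 are flagged non-converged.

**Bayes factors.** Marginal likelihoods by the iterative optimal-bridge
estimator (moment-matched Gaussian proposal fitted to half the posterior
draws, overflow-safe iteration anchored at the median log-ratio),
bootstrap standard errors over both draw sets, flagged unstable above 10%
relative SE. Term-wise BF10s compare models with and without the term:
device and speed are tested within the no-interaction model, the
interaction by full versus no-interaction. The estimator reproduces the
closed-form marginal likelihood of a conjugate normal model to three
decimals and returns BF = 1 for a model against itself within bootstrap
error. Evidence labels follow the Jeffreys scale
(≥100 extreme, 30–100 very strong, 10–30 strong, 3–10 moderate, 1–3
anecdotal; the inverse scale below 1).

**ICC.** Per posterior draw, `τ0²/(τ0² + σ²)`, evaluated at standardised
speed 0 where the random-slope variance vanishes (the model has no single
ICC once slopes vary by subject; the reference point makes the reported
fraction well-defined). Median and central 95% interval are reported.

**Correlation.** The Bayesian Pearson test uses the exact reduced
likelihood of r given ρ (hypergeometric form) with a uniform prior on
(−1, 1), integrated on a 4001-point grid in log space — deterministic, no
sampling. The Bayes factor agrees with an independent exact
implementation (pingouin) to <1%.

**Bland–Altman.** Differences are device − reference; limits of agreement
are bias ± 1.96·sd with t-based confidence intervals for the bias and the
standard `sd·sqrt(1/n + z²/(2(n−1)))` error for each limit; the slope of
differences on pair means is reported as the proportional-error
diagnostic.

**Correction function.** An ordinary least-squares line mapping per-speed
averaged device power to reference power. Its coefficients are
cohort-specific descriptions of one device population, not constants of
nature; the residual RMS says how affine the device error actually is.

## Problem sizes and tolerances

The test bench uses five-stage sessions (10→12 km/h) for recovery checks
and six simulated runners over nine to thirteen stages for the end-to-end
analysis; mixed-model recovery runs 6 subjects × 20 laps × 2 devices
(240 observations), 20 replicates for interval coverage and null-regime
Bayes factors. Tolerances asserted by the tests: contact time within 4 ms
(two 500 Hz samples), trapezoidal integration within 0.1% of closed
forms, stiffness within 5%, external power within 2%, stage efficiency
within 3% under fast kinetics, ICC within ±0.2 at the six-subject design,
Bland–Altman moments within Monte-Carlo sampling error. These reflect the
discretisation and sampling error budgets of each estimator, not device
specifications.

## Known limitations

- The sampler is an ensemble method on a marginalised posterior; it is
  accurate for this model family but does not scale to crossed random
  effects or non-Gaussian responses.
- Walker-level ESS is reported from interacting walkers and should be
  read as an estimate, not an exact count.
- The ICC of a random-slope model is reported at one covariate point;
  other conventions (integrating over the speed distribution) would give
  different values.
- Stage-mean efficiency under physiological VO2 kinetics carries the
  documented transient bias; the package reports it as measured and does
  not deconvolve the kinetics.
- The simulator's hop-free, impact-free waveform makes contact detection
  easier than on real platform data with impact transients and noise;
  the 20 N default threshold is standard but untested here against real
  noise floors.
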