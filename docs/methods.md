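# Methods

This note records the models implemented, the parameter choices that
matter, what the synthetic stages do and do not emulate, and the numerical
decisions taken where the design was genuinely open.

## Stimulus generators

All drives are pure functions of `(params, seed)`.

**Logistic map.** `x(n+1) = μ x(n)(1 − x(n))` with μ = 3.8 (fully developed
chaos on the unit interval), 10,000 iterates, start drawn uniformly on
(0.01, 0.99) — the open interval avoids the absorbing endpoints — and a
linear rescale to [−0.5, +0.5] V. Discrete maps have no intrinsic timescale,
so one iterate is one sample and the playback interval `dt` (default
0.01 s) is an explicit parameter; spectral quantities are therefore
well-defined but their Hz values scale with the chosen `dt`. Domain checks:
μ ∈ (0, 4] (iterates can escape [0, 1] for μ > 4), x₀ ∈ (0, 1). The fixed
point x* = 1 − 1/μ is invariant but unstable for μ > 3 (|f′(x*)| = μ − 2);
in floats an orbit started there escapes after ≈ 60 iterates at μ = 3.8 —
constancy holds only over short horizons.

**Baker transformation.** The generalized area-preserving form with fold
parameter α: the square is cut at x = α, each strip stretched to full width
and compressed in height, the right strip stacked on top. At α = 1/2 the
x-dynamics is exactly the binary doubling map `2x mod 1`, which is *not*
chaotic in IEEE-754 arithmetic: each iterate shifts the mantissa left one
bit, so every orbit lands exactly on 0 after at most ~52 iterates and stays
there (the emitted voltage pins to `v_lo`). This is retained as the default
because published baker-drive statistics (input mean ≈ median ≈ the lower
rail with a small transient sd) carry exactly this signature, and
recognizing it matters more than hiding it. A sustained chaotic baker drive
is available with any α not equal to 1/2 (e.g. 0.49), where the stretch
factor is not a power of two.

**Lorenz / Rössler.** Standard vector fields at the classic chaotic
parameter sets (σ = 10, ρ = 28, β = 8/3; a = b = 0.2, c = 5.7), integrated
with fixed-step classical RK4 at dt = 0.01 s over 100 s, no adaptive
control. The selected component is multiplied by `scale` (volts per
state-unit, default 1.0); reported voltage tables in source experiments
imply a hardware scale that is not recoverable, so state-units-as-volts is
the documented default. Verification: RK4 reproduces `exp(−t)` to < 1e−8
relative error per unit time at dt = 0.01, and dt = 0.01 trajectories stay
within 1e−2 state-units of a dt = 0.001 reference over 10 s.

**FitzHugh–Nagumo.** Implemented as

    dv/dt = v − v³/3 − w + c
    dw/dt = ε (v + a) − γ w + b

with fast activation v, slow recovery w, drive current c, and defaults
a = ε = γ = 0.1. The recovery bias b (default 0.2) is this implementation's
explicit excitability offset: it fixes the w-nullcline intercept and hence
the Hopf window of the drive. With b = 0.2 the window is c ∈ (1.8, 2.4)
approximately, i.e. the rheobase lies between the two canonical drive
levels: at c = 1 the trajectory from (0, 0) makes a transient excursion and
settles to the stable rest state (quiescence); at c = 2 it settles into a
sustained relaxation limit cycle (period ≈ 33 time-units at these
parameters, converged to < 0.01% between dt = 0.01 and dt = 0.001). The
bias is needed because at a = ε = γ = 0.1 *no* placement of a constant
drive in the standard bias-free variants separates c = 1 from c = 2: those
forms either oscillate at both drives or place the window below c = 1
(verified by a systematic scan); b is therefore the one free constant fitted
to the qualitative quiescent-to-spiking transition, chosen once and not
revisited.

**Pulse trains.** Seeded uniform bits at 1 ms resolution; a 1-bit holds
+500 mV for 100 ms from its onset, a 0-bit −500 mV; overlapping pulses
resolve to the most recent onset. Identical seeds give byte-identical
traces.

## Response surrogate

The composite's transfer is modeled phenomenologically — no electrochemical
or mechanochemical state, only the measured signatures:

    output = clamp(gain · lowpass(input) + offset, v_min, v_max) + noise

* `gain` — attenuation (the observed 5–30-fold variance suppression
  corresponds to gains of roughly 1/30–1/5);
* `lowpass` — zero-phase moving average with cutoff `lp_cutoff` (Hz); being
  symmetric it commutes with time reversal, so the noise-free surrogate
  does too;
* `v_min/v_max` — the hard output clamp (bounded response range);
* `freq_shift` — optional dominant-mode shift by uniform resampling,
  default off: the small (~0.05 Hz) shifts and the ~2.16× frequency
  multiplication seen under some drives are observations, not mechanisms,
  and are left configurable rather than baked in;
* `noise` — seeded additive Gaussian, sd `noise_sd`.

Sigmoid coupling: `V_out = 1/(1 + exp(−m (V_in − c)))` with midpoint
c = 0.5 V; large m approaches the all-or-none step. Implemented via tanh
for numerical stability; exact at the midpoint.

**Parameter recovery.** `recover_surrogate_params` is a closed-form moment
estimator: gain = |cov(x, y)|/var(x) over samples away from the clamp
rails, offset = mean(y − gain·x), clamp bounds = output extrema. The
covariance slope is used rather than the std ratio because the ratio is
biased upward by σ²/(2 g² var(x)) under additive noise — at gain 0.04 and
noise sd 5 mV on a ±0.5 V drive that bias alone exceeds 10%. The estimator
is consistent when smoothing is mild and clamping spares most samples; under
heavy clamping only the clamp bounds remain exact.

**Presets.** `presets/{system}.json` are tuned once so each drive's
surrogate output approximates the corresponding published output-statistics
row within about a factor of two under *this package's* drive conventions
(the source input conventions are not recoverable — e.g. a ±0.5 V logistic
encoding cannot produce a 1.44 V input mean). They are presets, not ground
truth. The Rössler preset keeps its clamp inactive so that its design gain
0.045 ≈ 1/22 is directly visible as the output/input sd ratio.

## Analysis suite

* **Peaks per second** (the tables' "frequency"): count of local maxima
  with prominence ≥ 0.5 × sd of the linearly detrended signal, divided by
  `dt·(n−1)`. Robust to small noise; reduces to cycle counting on clean
  periodic signals; 0 on zero-variance traces. Whether published table
  frequencies are peak rates or FFT modes is ambiguous, so reports carry
  both this and the spectral dominant mode.
* **Spectrum**: `20 log₁₀(|rfft(v)|/n)`, floor −200 dB; mean/sd over
  positive-frequency bins; dominant mode over all bins including DC (a
  mean-dominated signal legitimately peaks at 0 Hz). dB levels depend on
  this normalization convention; cross-study comparison requires matching
  conventions, which published figures do not pin down.
* **Cross-correlation**: mean-removed, normalized so a self-pair is exactly
  1 at lag 0; positive lag means the second trace trails the first; ties
  break toward the smallest |lag|.
* **PCA**: sklearn decomposition of the n×2 (input, output) sample cloud;
  covariance by default, correlation under `standardize=True`. Fractions
  sum to 1; a numerically constant channel (sd at rounding level) returns
  {1, 0} with a warning and a `degenerate` flag.
* **Savitzky–Golay**: scipy filter, order 2 / frame 15 defaults; exact on
  polynomials up to the order.
* **Lyapunov (Wolf-style)**: after optional Savitzky–Golay pre-smoothing,
  repeatedly select the nearest neighbor in value of the current fiducial
  point subject to (i) separation ≥ 0.001 V (noise floor) and (ii) temporal
  index distance ≥ 50 samples (decorrelation); track the pair step by step
  until the separation exceeds 10% of the data range, accumulate
  ln((d_end + ε)/(d_start + ε)) with ε = 1e−5, renormalize, and divide by
  the total tracked steps. λ is per sample step; negative = convergence.
  On the μ = 4 logistic map this lands within a few percent of the analytic
  ln 2. The *literal* fixed-offset pairing rule (mean one-step log-ratio
  over all (i, i+50) pairs above the noise floor) is retained as
  `mode="fixed_offset"`; on a bounded stationary series the separation
  statistics are time-invariant, making that rule a null statistic whose
  output hovers near 0 — which is exactly the magnitude regime of published
  exponents of order 1e−4, a useful diagnostic when comparing conventions.
  Raises a diagnostic error when no pair clears the noise floor (e.g.
  constant traces).

## Oscillatory threshold logic

Thresholding is strict (`v > θ`; equality is LOW, matching "surpass") with
a minimum-duration constraint: a run of suprathreshold samples registers
only if it spans ≥ ⌈τ_min/dt⌉ samples. θ defaults to the stated 0.5 V;
the alternative derivation (resting 0.0212 V + 2 × 0.0176 V = 0.0564 V)
ships as `THETA_REST_DERIVED` because the two printed derivations disagree
and only one can have been used on the recordings. Channel gate streams
are the duration-constrained bits ANDed with the plain comparison bits of
the same channel — the conjunction of a bit with an analog value being
undefined, this is the documented reading; since the duration rule implies
the comparison, the AND is an identity recorded for structural fidelity.
The OTL column is the OR of the two output gate streams, so it is
internally always equal to `V1_out ∨ W1_out` (asserted as an invariant).
The half-adder sum is an OR gate as printed in the source truth table
(nonstandard; a = b = 1 gives sum 1), with the conventional XOR behind
`sum_mode="xor"`. Note the source's own sampled truth table lists OTL = 0
at steps where V1_out = 1, which contradicts OR semantics; this package
implements the stated equations and will disagree with that column.

## Morphometry

Otsu (default) or fixed-level binarization; 8-connectivity default for
labeling; areas = pixel counts × pixel_size², lengths = region major-axis
extent × pixel_size, so pixel-size equivariance (lengths ×k, areas ×k²) is
exact by construction. Standard deviations are population (ddof = 0) by
default, sample by flag. The published mean 14,732.6 nm / sd 6,150.47 nm is
treated as a *length* statistic (the figure's units and quantity labels are
contradictory) and seeds the phantom's lognormal length distribution.

The phantom renders non-touching thick random-walk strokes (fibers) and
discs (microspheres, ~10 µm radius, echoing the imaged ~20 µm spheres) on
a 1024² field at 100 nm/pixel, levels 0.2/0.8, optional Gaussian noise,
with rejection-sampled placement (clearance 3 px) and exact ground-truth
labels. What it does emulate: two-phase contrast, object crowding, additive
noise, realistic size dispersion. What it does not: SEM texture,
charging/shading gradients, touching or overlapping fibers, out-of-focus
blur. Passing tests therefore certify the measurement chain, not
performance on contacting-fiber imagery, where component counting is known
to under-segment.

## Orchestration

Experiments are JSON-configurable (`ExperimentConfig`): drive family and
parameters, surrogate (preset name or explicit parameters) or a recorded
response path, Lyapunov/OTL settings, and one integer seed from which every
stochastic stage derives. Reports carry a config hash and every stated
generator parameter for auditability; re-running a config is bit-identical.
Stage failures propagate with the stage name and config hash. Figure
generation is optional so headless runs stay headless.

## Problem sizes

Default study sizes: 10,000 iterates (maps), 100 s at dt = 0.01 (flows),
10,000-step OTL fixtures, 1024² phantoms with 50 fibers, 20-seed batteries
for sign/period properties, 100-seed batteries for recovery Monte-Carlo.
Oracle cross-checks (fine-step integrations, exhaustive gate tables,
hand-iterated maps) use the smallest sizes that exercise the property.

## Known limitations

* The surrogate is a transfer-signature model; it cannot answer mechanistic
  questions (conduction pathways, reconfiguration dynamics).
* Voltage scales of the continuous drives are in state-units; matching
  recorded input tables requires fitting the hardware scale.
* The Lyapunov estimator is scalar and pairwise (no embedding, no spectrum
  of exponents); smoothing before estimation biases |λ| downward.
* Frequency multiplication under strong drives is available only as an
  explicit `freq_shift`/resampling choice, not an emergent property.
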