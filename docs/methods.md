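# Methods

## Model

The simulator describes auditory cortex (AC) as 240 cortical-column units
arranged in 15 tonotopic fields of 16 columns: inferior colliculus (IC),
thalamus, three core, eight belt and two parabelt fields (32 subcortical and
208 cortical columns).  Each column contains one excitatory and
one inhibitory mean-field population governed by leaky-integrator equations
with membrane time constant τ_m = 40 ms and a spiking-rate function g.  The
analytic machinery assumes the linear regime g(x) = αx with α = 1,
interpreted as deviations from a spontaneously active resting state; a
saturating-rate variant is available in the numerical integrator for
comparison, and at the default stimulus amplitude (0.01) the two agree to a
few percent.

### Canonical form and normal modes

Absorbing the leak terms into the couplings gives the canonical first-order
pair

    u' = W̃_AC u − w_ei v + I_e(t),     v' = w_ie u − w̃_ii v + I_i(t)

in units of τ_m, with W̃_AC = α·W_AC − I and w̃_ii = α·W_ii + 1 (the
within-column scalars are W_ei = 1, W_ii = 0.2, W_ie,d = 1, so the canonical
scalars are (1, 1.2, 1)).  `canonicalize` is the only function that encodes
this transformation.  With W̃_AC symmetric and the within-column matrices
scalar, the orthogonal eigenbasis Υ of W̃_AC decouples both equations
simultaneously into damped harmonic oscillators with per-mode decay constant
γ_d = (w̃_ii − w_d)/2, squared angular frequency ω²₀,d = w_ei·w_ie,d −
w̃_ii·w_d, and damping frequency δ_d = √(ω²₀,d − γ²_d).  A mode is unstable
when γ_d ≤ 0, or when δ_d is imaginary with γ_d − |δ_d| ≤ 0 (equivalently
ω²₀,d ≤ 0); δ_d = 0 (tolerance 1e−9) is critical damping.

Stimuli are piecewise constant (a boxcar with a 10-ms subcortical conduction
delay), so the closed-form constant-drive solution is applied per segment,
with the exact state carried across segment boundaries; the input's delta
derivatives never need to be represented.  Modal drives are obtained with Υᵀ
when the basis is orthonormal to 1e−8 and by an explicit solve otherwise.
Overdamped modes are evaluated as sums of pure decaying exponentials so that
nothing overflows; critically damped modes use the (a·t + b)·e^(−γt) limit
form.  Eigenvalues are sorted descending and eigenvectors are normalized with
their first appreciable entry positive, so mode indexing is reproducible.

An adaptive Dormand–Prince integration of the same equations (rtol 1e−10)
serves as an independent oracle; the analytic solution matches it to better
than 1e−6 max-abs on the full model and on randomized miniature anatomies
(observed ~1e−11).

### Connectivity

Subcortical wiring follows the fixed values: IC and thalamic recurrent
self-weights 0.09, IC→thalamus and thalamus→core one-to-one tonotopic
afferents of 0.015.  Afferents are entered symmetrically into W_AC (the
analytic approach requires a symmetric matrix); their functional direction
survives only in the connection-class labels used by the MEG topography.

Cortical connections spread from each column to its tonotopic counterpart
and neighbours with a Gaussian profile perturbed multiplicatively by
log-uniform factors exp(s·U(−1,1)); every field-pair block draws from its own
seeded stream, so any block can be regenerated independently, and the
cortical block is symmetrized ((W + Wᵀ)/2) after generation.  The 13 fields
are connected by 36 bidirectional between-field pathways (core–core chain,
core to flanking belt, a belt ring, belt to parabelt, parabelt–parabelt) in
two density classes.

The within-field kernel combines recurrent excitation (peak r, width σ, the
self-weight spared by the surround), a lateral-inhibition Gaussian, and — in
the belt and parabelt — interleaved sign-alternating side bands (nearest
neighbours inhibited, next-nearest facilitated) that give the secondary
fields multi-peaked tuning.

### Calibration of the connectivity defaults

The within- and between-field strengths are free parameters of the model
(the subcortical values and all within-column scalars are fixed).  They were
calibrated once, jointly, against the model's published operating point —
a three-deflection ERF with N1m near 115 ms, dominant frequency 3–4 Hz,
envelope decay near 60–70 ms, and roughly a fifth of dynamical-parameter
randomizations unstable — and then frozen:

| parameter | value | role |
|---|---|---|
| r | 0.102 | within-field excitatory peak |
| σ | 1.391 | tonotopic spread (channels) |
| s | 0.353 | multiplicative stochasticity |
| lateral inhibition | 0.667 (width 1.5) | within-field surround, all cortex |
| alternating bands | 0.292 (width 1.23) | belt/parabelt side bands |
| between-field | 0.156 / 0.044 | high / low density classes |
| subcortical surround | 0.308 (width 0.8·1.339) | IC/thalamus sharpening |

Two structural choices matter.  First, the top of the W̃_AC spectrum sits at
w_d ≈ 0.46: under the ensemble's multiplier law this reproduces an ~19%
unstable fraction through the sign of ω²₀,d.  Second, the marginal modes are
alternating (high tonotopic frequency) belt/parabelt patterns.  These are
nearly orthogonal both to the smooth Gaussian spread through which the
afferent drive reaches the secondary fields and to the field-level (block
constant) MEG readout, so the near-boundary modes set the stability margin
without dominating the simulated signal, and stable runs decay cleanly.

### MEG forward model

R(t) sums the synaptic inputs to cortical excitatory populations weighted by
field-level topography matrices: K₁ (feedforward −4, feedback +20,
within-field −5) on the excitatory part of W_AC, K₂ (+2) on within-column
inhibition, K₃ (+2) on lateral inhibition.  The K₁ field matrix has 88
nonzero entries: 13 within-field, 72 for the 36 bidirectional cortical
pathways, and 3 thalamocortical afferent (feedforward) entries onto the core
— thalamic afferent synapses are excitatory synapses on cortical pyramidal
cells and are therefore weighted like other feedforward inputs.  Subcortical
populations never appear as post-synaptic rows.  Both the connection-type
and the per-field decompositions of R(t) are exact partitions of the sum.

### Waveform descriptors

* **Peaks.**  The N1m is the global extremum of largest magnitude after
  stimulus onset; its sign defines the negative polarity.  The P1m (P2m) is
  the last (first) opposite-polarity local extremum before (after) it,
  flagged absent below 1% of the N1m magnitude.  For topography sweeps, in
  which the feedforward-polarity deflection can grow from ripple to dominant
  lobe, `polarity_peak` tracks a deflection by polarity instead of
  relabelling within each waveform.
* **Dominant frequency.**  FFT magnitude argmax (zero bin excluded) after
  removing the DC offset, zero-padded to ≥4096 samples.  The offset is
  estimated by the global median: subtracting the time-average would inject
  a boxcar into a one-sided transient.  For a damped sinusoid the true
  spectral argmax is the damped frequency √(f₀² − (1/2πτ)²), which the
  estimator recovers to within one padded FFT bin; once the oscillation
  decays within a single cycle the peak merges into the origin and no
  estimator can report f₀.
* **Decay constant.**  The envelope is the magnitude of the zero-padded
  analytic signal; A·e^(−t/τ) is fitted by least squares in linear space
  (initialized from a log-space line) from the envelope peak to 600 ms,
  restricted to samples above 5% of the envelope peak.  The restriction
  matters: the Hilbert transform of a time-limited pulse carries an
  algebraic (area/πt) tail, and a log-space or full-window fit is dragged by
  that tail and by faint long-lived modes.  Fits are invalid when the
  envelope peaks after 500 ms or τ exceeds twice the window.  On damped
  sinusoids the estimator is within 5% wherever the envelope is well posed
  (≥ ~1.5 rad of oscillation per decay time, envelope not spanning the whole
  window); for sub-cycle pulses the bias can reach ~35% — an inherent limit
  of envelope-based estimation, shared by anything built on the same
  transform.  On the default model the decay constant is 60–74 ms across
  connectivity seeds; occasional seeds whose envelope plateaus just above
  the 5% threshold fit to ~107 ms instead (a knife-edge of the windowing,
  documented rather than smoothed away).

### Randomization ensembles

Multipliers are drawn from the equiprobable mixture of U[0.5, 1] and
U[1, 2].  Topographical mode randomizes each nonzero field-level entry of K₁
(88), K₂ (13) and K₃ (13) with the dynamics frozen, so only the forward model
is recomputed per run.  Dynamical mode draws one multiplier for each of the
three canonical scalar weights (w_ie,d, w_ei, w̃_ii) and a fresh stochastic
W_AC per run, with the K values frozen; runs with any unstable mode are
counted and excluded from waveform statistics.  Per-run streams derive from
(base_seed, run_index), so individual runs are independently reproducible.
Randomizing the scalars per matrix (rather than per column) keeps the exact
simultaneous diagonalization — per-column diagonals would break the
commutation condition the closed-form solution rests on.

The N1m amplitude floor used when summarizing latency ranges is defined
relative to the default-run N1m amplitude (default 0.35×), because R(t) has
arbitrary units: the subcortical relay weights bound the cortical state
amplitudes near 1e−5 regardless of the cortical strengths, so an absolute
floor would be meaningless across unit conventions.  An absolute override is
config-exposed.

## Problem sizes

The default time grid is 0–600 ms at 1 ms; ensembles run 1000 simulations
(~30 s for both on one CPU); unit tests use miniature anatomies
(3 fields × 4 columns) and 60-run ensembles.

## What the synthetic protocol does and does not cover

All inputs are generated internally; the stimulus is a 50-ms boxcar of
amplitude 0.01 on the central IC channel.  The generator emulates tonotopic
Gaussian connectivity with multiplicative disorder, not measured anatomy; the
forward model abstracts all head geometry into field-level weights (no lead
fields or sensor arrays); there is no synaptic plasticity, no ongoing
background activity, and no measurement noise.  Passing tests therefore
certify the analytic machinery and the in-silico comparisons — not agreement
with any particular subject's recordings.

## Known limitations

* The P1m-type deflection at strong feedforward weighting is the
  core-response maximum, which cannot precede the stimulus offset (60 ms) in
  a cascade of monotonically rising stages; its latency saturates near
  ~69 ms in the sweep.
* The default P2m falls at 205–245 ms depending on the connectivity seed;
  configurations that delay it further also push the ensemble instability
  fraction and decay constants away from their operating points (the three
  quantities co-vary through the stability margin).
* Dynamical-mode runs whose multipliers push the visible band close to the
  ω²₀ = 0 boundary produce amplified slow responses whose largest deflection
  can fall after 160 ms; they are stable and are retained.
* The across-field structure of a mode's field map is greatest for
  between-field (graph) patterns, which here carry low damping frequencies;
  δ_d is non-monotone along the spectrum, so "high structure" does not imply
  "high frequency" in this parameterization.
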