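# Methods

## The model

Each cortical network is a two-population rate model with adapting
excitation.  The average excitatory activity `E(t)`, inhibitory activity
`I(t)` and adaptation `A(t)` evolve as

    tau_E dE/dt = -E + Omega_E(W_EE*E - W_EI*I - W_EA*A + xi + i_E)
    tau_I dI/dt = -I + Omega_I(W_IE*E - W_II*I + xi_I)
    tau_A dA/dt = -A + W_AE*E

with threshold-linear response functions `Omega(x) = g*(x - theta)` clipped
below at 0, time constants `tau_E = 10 ms`, `tau_I = 5 ms`, `tau_A = 300 ms`,
gains `g_E = 6`, `g_I = 30`, thresholds `theta_E = 0.0517`,
`theta_I = 0.2778` and weights `W_EE = 1`, `W_EI = 0.166`, `W_IE = 1.66`,
`W_II = 0.083`, `W_EA = 0.166`, `W_AE = 1.1`.  The quiescent Down state
(E = I = 0) is always a fixed point; with these constants a second, active
Up fixed point exists at (E, I) ≈ (0.2006, 0.4751) (adaptation slaved to
activity), separated from Down by a saddle.  Slow adaptation shifts the
excitatory nullcline as the network dwells in either state, modulating the
two basins, and the background noise current `xi` triggers the transitions:
the Up-Down state (UDS) oscillation.

Two such networks are coupled strictly feed-forward: the afferent
("neocortical") network drives the efferent ("entorhinal") excitatory
population with `i_E(t) = W_EXT * E_A(t)`.  All internal parameters are
shared except the efferent recurrent excitation, called `W_INT`.  Strong
drive phase-locks the efferent UDS to the afferent rhythm; a more stable
efferent Up attractor (larger `W_INT`) lets the efferent ignore afferent
Down transitions (spontaneous persistent activity, SPA), and weaker drive
(smaller `W_EXT`) lets it ignore afferent Up transitions (spontaneous
persistent inactivity, SPI).

### Response-function ceiling

The upper saturation of the response function is retained for the
excitatory population (whose activity never exceeds ~0.5 in practice) but
**not** for the inhibitory population.  With a hard inhibitory ceiling at 1
the default weights admit a deeply stable fixed point at (E, I) = (1, 1)
(its excitatory input exceeds the saturation knee by 0.43): every
Down-to-Up transition overshoots into it and no Up-to-Down transition can
ever occur, which contradicts the bistable Up/Down phenomenology the model
exists to produce.  All the closed-form analysis (nullclines, fixed
points, stability conditions) lives on the linear branch and never invokes
saturation; letting the steep inhibitory response (gain 30, linear range
only 0.033 wide) continue past its knee keeps inhibition globally
stabilizing and removes the spurious absorbing state.  During transitions
`I` transiently overshoots 1 by up to ~2.

### Noise model

The noise current is an Ornstein-Uhlenbeck process updated once per
integration step with the exact discrete transition, held constant across
the RK4 substeps.  Defaults: stationary SD `sigma_noise = 0.02`,
correlation time `noise_tau = 100 ms`, injected into the **excitatory**
response argument only (`sigma_noise_I = 0`); `sigma_noise_I` and a
correlation `noise_rho` expose shared or independent two-channel variants.
Three considerations fixed this choice:

* White per-step noise is averaged by the membrane time constants down to
  a ~7x smaller effective amplitude; at any plausible SD it produces state
  dwell times of minutes, not the ~1 Hz UDS alternation the model is meant
  to show.  A correlation time comparable to or longer than the intrinsic
  E/I spiral period (~8 ms) lets the state track the noise
  quasi-statically, so escape thresholds are set by the fixed-point
  annihilation margins.
* Noise in the inhibitory argument is amplified five-fold relative to the
  excitatory channel (gain 30 vs 6) and dominates Up-state escape with a
  margin that barely depends on the recurrent excitation; it erases the
  exponential sensitivity of SPA to `W_INT` that is the model's central
  prediction.  Routing the noise through the excitatory argument preserves
  it.
* At SD 0.02 the adapted Up-state annihilation margin and the Down-state
  escape threshold (`theta_E`) are both ~2.5-3 SD: both transitions are
  rare noise-limited events, dwell times are ~1-6 s (UDS at ~0.15 Hz, duty
  ~0.18), and the four coupling regimes (locked / SPA / SPI / both) appear
  in the corners of the default coupling plane.

The integration step is 0.2 ms (classical RK4; Euler available for
comparison).  The exact OU update makes the trajectory statistics
insensitive to the step: halving it changes state occupancies by a few
percent.  Simulations start in the Down state with a 5 s burn-in
discarded.

## Detection pipeline

Surrogate (or real) paired recordings are processed as:

1. **Spike removal** (V_m only): onsets where the derivative of the
   100 Hz-8 kHz band-passed signal exceeds 10 SD above its mean; 3 ms
   after each onset (plus a 1 ms pre-onset guard, since the threshold
   crossing sits inside the rising edge) replaced by linear interpolation;
   overlapping windows merge.
2. **Mains removal**: cascade of zero-phase 8-pole bandstops at 45-55 up
   to 295-305 Hz (4th-order Butterworth, forward-backward).
3. **Desynchronized-epoch rejection**: multitaper spectrogram (15 s
   windows, 50% overlap, time-bandwidth 4, 7 tapers) of the broadband
   signal; each unit-variance window yields the maximum log power in
   0.05-2 Hz and the integrated log power in 4-40 Hz.  A window is
   desynchronized when the first minus the second falls below 0 (measured
   separation on surrogates: UDS >= +25, 1/f activity <= -40); flagged
   runs shorter than 25 s are discarded (a single transition-free window
   is a long Down state, not a desynchronized epoch).  A relative z-score
   rule is available but off by default: it flags a fixed quantile of
   windows on perfectly stationary recordings.
4. **Slow band**: zero-phase 0.05-2 Hz band-pass.
5. **EDHMM segmentation** at 50 Hz: two states, Gaussian emissions with
   sliding-window (50 s) state means, inverse-Gaussian dwell
   distributions discretized over a 40 s support, transition structure
   forced (two states must alternate).  Fitting is segmental (hard) EM:
   a two-component Gaussian mixture initializes the labels (a
   single-component fit must lose on BIC, otherwise "no UDS detected"),
   then sliding means / SDs / duration MLEs and Viterbi re-decoding
   alternate until the path log-joint converges (rel. 1e-4, cap 30); the
   iteration stops rather than accept a decrease, so the recorded history
   is non-decreasing.  Decoded fragments shorter than 0.1 s (forced by
   the finite duration support) are absorbed into their neighbours.

## Persistence statistics

Efferent state initiations are matched greedily to the closest same-type
afferent initiation (ties toward the earlier one; matching a sorted list
keeps each label's matches monotone).  The trigger set of an efferent
state spans the afferent states from its own match up to the next state's
match; alternation makes the count odd, so quantized durations
(0.5 per afferent state) fall on half-integers with minimum 0.5.  States
whose span is non-positive — transitions not locked to the afferent
rhythm — are excluded, as are recording-boundary states.  `phi_SPA` is
the fraction of efferent Up states that contain at least one complete
afferent Down interval (the state "outlasted an entire afferent Down");
`phi_SPI` symmetrically for Down states.  On tightly locked data this
coincides with a trigger count >= 3 (quantized duration >= 1.5); on
loosely coupled simulations the interval criterion is stricter, because a
premature efferent transition can collect three trigger states without
fully spanning any of them, and it is the interval criterion that defines
the rates.  Transition delays
are summarized per cell by their **median** (the mean is dominated by the
heavy tail of unlocked transitions; measured on a 5x5 grid the median
Down-Up delay tracks `W_EXT` at Spearman -0.96 where the mean scrambles to
-0.4).  History dependence uses the first two quantized modes:
`p1 = 1 - m1`, `p2 = 1 - m2/p1`.

## Connectivity inference

A library of coupled simulations covers `W_EXT in [0.08, 0.32]`,
`W_INT in [1.00, 1.16]` (12x12 by default; the reproduction experiments
use 3 seeds x 600 s per point, and the full-scale 100x100 x 5 x 1000 s
is a configuration change).  The grid
bounds bracket the four regimes: locking needs the afferent drive
`W_EXT * E_up` to exceed roughly twice the noise SD, i.e. `W_EXT >~ 0.2`
with `E_up ~= 0.2`.  Each observed cell is matched to the grid point
minimizing `d = sqrt((phi_SPA - xi_SPA)^2 + (phi_SPI - xi_SPI)^2)` (ties
toward smaller `W_INT`, then smaller `W_EXT`); the alternate metric uses
the afferent-side skipped-state fractions.  The matched entry also
predicts the two transition delays; observed-minus-predicted residuals
estimate propagation offsets outside the model.

## Surrogate recordings

V_m is an affine map of efferent activity (Down -> -74.2 mV, Up fixed
point -> -52.4 mV, the MEC-like anchors), plus 1 mV Gaussian observation
noise, 1 ms triangular +40 mV spikes at an inhomogeneous Poisson rate
(30 Hz per unit supra-threshold activity, ~4 Hz in Up states), and a
0.3 mV 50 Hz mains tone, sampled at 2 kHz.  The LFP is the z-scored
afferent activity with 15% pink background and the same mains tone.
Desynchronized epochs replace both channels with pink noise at 20% of the
UDS amplitude, crossfaded over 0.5 s.  The generator does not emulate
spike afterpotentials or bursting, electrode drift, depth-dependent LFP
polarity, or non-Gaussian V_m noise; passing tests therefore validate the
pipeline's logic and calibration on this statistical family, not its
robustness to every artifact of in vivo data.

## Known limitations

* The reference noise constant for this model family (SD 0.03 with
  per-step draws at 0.2 ms) could not be mapped onto any convention that
  reproduces the intended UDS dynamics; the OU calibration above is the package's own operating
  point, chosen once from isolated-network and regime-corner behavior.
* The exponential sensitivity of SPA to `W_INT` and of SPI to `W_EXT`
  reproduces in sign and monotonicity, but the fitted e-folding scales
  are ~5-20x larger (flatter) than the reference values 0.015 and 0.004
  the package aims to reproduce: at any
  noise scale that still allows the afferent network to leave its Down
  state, the escape-margin arithmetic of the default weights caps the
  achievable steepness.  The acceptance suite reports this honestly.
* At the desk-scale UDS frequency (~0.15 Hz) a 600 s recording holds only
  ~90 efferent states, so per-cell rate estimates carry binomial noise of
  a few percentage points; recovery statistics are correspondingly noisy.
* Up-state occupancy (duty ~0.18) is lower than typical urethane UDS
  (~0.4-0.6); the default weights make the Down basin deeper than the
  adapted Up basin under every noise routing we examined.
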