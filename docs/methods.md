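# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. Units throughout: forces
in pN, lengths in nm, energies in pN·nm, rates in 1/s. Thermal energy
k_BT = 0.0138065 pN·nm/K × 295.95 K = 4.086 pN·nm at the 22.8 °C operating
temperature.

## Mechanical model of the tether

A construct is a series of duplex/single-strand segments plus a
single-stranded handle, pulled by an optical trap of stiffness
k = 0.156 pN/nm moving at 50 nm/s, so the nominal loading rate is
k·v = 7.8 pN/s. At every sample the force solves the series balance
F = k (x_trap − x_c(F)) with x_c the construct extension; because the trap
dominates the series compliance, the effective loading rate stays within
about 5% of nominal (the package checks it lies in 7.8 ± 1.5 pN/s).

Elasticity laws:

* B-form and S-form duplex: extensible worm-like chain (Marko–Siggia
  interpolation plus an enthalpic term), inverted numerically.
  B-form: rise 0.34 nm/bp, persistence length 45 nm, stretch modulus
  1200 pN. S-form: persistence length 10 nm, stretch modulus 1000 pN.
* single strands (peeled strand, handles): extensible freely-jointed chain
  (Langevin function), Kuhn length 1.5 nm, stretch modulus 800 pN.
* a segment melted with both strands sharing tension extends as two
  identical single strands in parallel: x(F) = x_ss(F/2).

**Calibration instead of ab-initio contours.** The per-unit contour lengths
of the peeled, shared-melt and S-form conformations are solved at scenario
build time so that the state-to-state extension differences at the measured
transition forces equal the measured values: 14.7 nm between peeled and
B-form 5′AT at 61.5 pN; 10.6 nm between internally melted and B-form 3′5′AT
at 67.8 pN; 8.0 nm for the AT-part peel of ATGC at 62.1 pN and 24.7 nm
total (AT peeled + GC S-form vs all-B) at 64.3 pN. Only relative extensions
are observable in this geometry, so these differences are the physically
meaningful anchors. The resulting contours (≈0.56 nm/nt peeled ssDNA,
≈0.61 nm/bp S-form) fall in the range expected for these conformations.

The handle is a single effective single-stranded compliance of 50 nm
contour. Its length is not experimentally constrained; 50 nm keeps the
series stiff enough that branch fits stay close to linear and the loading
rate stays near nominal. The modelled force range is capped at 120 pN; the
elasticity laws and state machines are not meant to extrapolate beyond the
overstretching regime.

## Kinetics and calibration

Abrupt transitions follow Bell rates k(F) = k₀ exp(F x‡ / k_BT), with x‡
signed (negative for transitions accelerated by *lowering* force, i.e.
rezipping on the down-ramp). Under a linear ramp the mean first-passage
force has closed forms in the exponential integral E1 (up-ramp:
(k_BT/x‡) e^a E1(a) with a = k₀k_BT/(x‡ r); down-ramp:
(k_BT/|x‡|)(ln a + γ + E1(a))). Zero-force rates are obtained by inverting
these closed forms against the measured mean transition forces at the
7.8 pN/s nominal ramp; transition distances are set so the Bell–Evans
rupture-force spread π/√6·k_BT/x‡ matches the measured ±1 s.d. (e.g.
x‡ = 2.0 nm for the 5′AT melt, 2.62 pN spread). The closed forms are
cross-checked in the tests against hazard-inversion Monte-Carlo sampling.

## The simulator (synthetic-data generator)

Each construct × salt condition is a small state machine over mechanical
states, advanced by a Gillespie loop inside every 1 kHz sampling interval
(rates refreshed after each switch, since a state change at fixed trap
position changes the force). Per-state extension grids are precomputed and
inverted by interpolation; states without outgoing transitions are advanced
vectorised. Gaussian noise of σ = 0.3 pN is added to the force channel
(chosen so rips of ≥1.5 pN are ≥5σ; the paper-scale instrument noise is not
published). Every state change is logged with time, name, pre-event force
and trap position, and per-sample state labels are kept, so detectors and
fits can be scored against exact ground truth.

Scenario defaults (all transition forces are the measured ensemble means):

* **5′AT** (64 bp, one end sealed): melt 61.5/43.6 pN (1 M / 5 mM),
  rezip 21.7/17.3 pN; plus a reversible partial-peel intermediate (12 bp
  peeled, crossing ~2.5 pN below the mean melt force, attempt rate 25/s).
  The experiments resolve this bistable hopping but not its rate constants
  or size; the defaults are order-of-magnitude choices, kept small enough
  that a melting rip out of either branch remains detectable. The melt
  hazard is identical from the B and intermediate states, so the
  rupture-force distribution stays exactly Evans–Ritchie.
* **3′5′AT high salt**: internal melting is an equilibrium two-state
  mixture — the extension is the Boltzmann-weighted average of B and
  shared-melt extensions with midpoint 67.8 pN and cooperative length
  2.6 nm — emulating the continuous, non-hysteretic transition. With
  probability 34/155 per relax phase (the measured pathway fraction) the
  molecule instead freezes fully molten and rezips abruptly via a Bell
  channel near 55 pN (the 1 M hysteretic rezip force is not quantified
  experimentally; 55 pN is an order-of-magnitude choice producing a clear
  loop). Low salt: single abrupt melt at 61.0 pN, hysteretic rezip at
  41.1 pN.
* **ATGC high salt**: a three-state Boltzmann ladder (B ⇌ intermediate ⇌
  stretched) with transition distances x_I = 8.0 nm and x_S = 19.9 nm (the
  measured extension steps), B/I crossing at 62.1 pN and I/S crossing at
  65.924 pN — derived so the intermediate population peaks at the measured
  64.3 pN. Hopping at the crossings uses a 40/s attempt rate with detailed
  balance. The intermediate branch carries an excess compliance, active
  only between the crossings and sized so the stretched-minus-intermediate
  separation at the upper crossing equals the measured 11.9 nm: this
  realises the split-intermediate picture (an internal sub-transition gives
  the intermediate its smaller force–position gradient) and reproduces the
  measured decomposition 8.0 + 4.8 + 11.9 = 24.7 nm. Low salt: the AT peel
  splits into two sub-steps (45 and 49 pN), B-to-S at 59 pN, then an
  irreversible full melt (67 pN, not experimentally quantified) with rezip
  near 20 pN.
* Salt enters only through the kinetic parameter sets; no explicit
  electrostatic model is attempted.

What the generator does **not** emulate: instrument drift and 1/f noise,
bead rotation and hydrodynamics, multiple tethers, attachment rupture,
glyoxal chemistry, and sequence-level base-pairing energetics. Passing
tests therefore demonstrate that the analysis recovers known transition
parameters under idealised recording conditions, not robustness to every
artefact of real recordings.

## Detection

Rips/zips: at each window boundary the leading-window mean force is
compared with the trailing-window mean plus a ramp correction taken from
the phase-wide *median* force increment. A windowed linear fit was
deliberately not used for the baseline: when the jump sits inside the
trailing window it corrupts the fitted slope and produces a mirror response
of opposite sign that can flip the rip/zip call; the median ramp is immune
to the events themselves. Default threshold 1.5 pN (5σ of the force noise,
≈15σ of the windowed statistic), window 30 ms; the event force is the
trailing-window estimate at the last pre-event sample, matching the
convention of reading the transition force just before the jump.

Hysteresis: pull and relax are compared at matched trap positions (1 nm
binned means); a cycle is hysteretic when the maximum gap exceeds 1.0 pN.
The threshold sits between the binned-noise scatter of reversible cycles
(≲0.4 pN) and the smallest genuine loop among these constructs (the 3′5′AT
internal melt, ≳1.6 pN). Constructs with heavy bistable hopping near a
crossing may need a higher threshold.

Branch fits around an abrupt event use two robustness devices: one-sided
sigma-clipping on boxcar-smoothed force (hop dwells sit at lower force for
the same position and would tilt the B-branch), and a data-driven cap of
the window top at the hopping onset, so the extrapolation to the event
force stays short.

## Equilibrium fits

Reaction extent is computed per sample as the relative trap-position
distance to the two branch lines at the sample's force, clamped to [0,1].
The pipeline boxcar-smooths the force (25 ms) before computing extent: the
raw 0.3 pN noise maps through the branch slopes to ≈0.2 extent noise whose
clamp would otherwise bias the logistic tails. Points are binned (0.25 pN)
and fitted by weighted least squares (lmfit); initial values come from the
empirical 25/50/75% crossing forces. Relax phases classified hysteretic are
excluded — a frozen molten molecule does not sample the equilibrium
populations.

Three-state analysis: outer branches are fitted with two-sided sigma
clipping; the intermediate branch — whose force window is never free of
excursions to the flanking states — is refined by three rounds of
assign-then-refit. Samples between the outer windows (2 pN clearance) are
assigned to the nearest branch (ties toward the lower-extension state) and
binned at 0.5 pN (bins with <5 samples dropped); the three-state fit is
weighted by per-bin binomial variance (floored at p(1−p) = 0.0025). The
crossing forces and the intermediate-population maximum have closed forms
under the force-linear Boltzmann weights; numerical crossing location is
retained as an internal consistency check (agreement to 1e−6 pN).

Operational biases, quantified on noise-free synthetic data: the
linear-branch extent procedure sharpens the transition slightly
(δ reported ≈ +3–7% of the generating value) and the branch-line
extrapolation under-reports the midpoint extension by ≈3–5%; per-sample
label noise in the three-state assignment flattens the population curves,
attenuating the fitted transition distances while leaving the crossing
forces accurate to a few tenths of a pN. Extension-type quantities are
measured on smoothed force because window selection on raw noisy force
truncates the branch windows and visibly tilts the fits.

## Reported sizes

The acceptance script runs 16 molecules × 2 cycles (5′AT 1 M), 12 cycles
(5′AT 5 mM), 10 molecules × 3 cycles (3′5′AT), 400 relax curves for the
pathway fraction, 16 cycles (3′5′AT 5 mM) and 8 molecules × 4 cycles
(ATGC) — at or below the experimental ensemble sizes, which keeps the whole
reproduction to a few minutes on one CPU while the ensemble means remain
well inside the measured dispersions.

## Known limitations

* The two-state and three-state functional forms are the standard
  equilibrium force laws (logistic in force; force-linear Boltzmann
  exponents without a quadratic compliance term). Compliance differences
  are absorbed by the branch fits.
* The cooperative-length→bp conversion divides by the measured per-bp
  midpoint extension (0.166 nm/bp); it inherits that measurement's bias.
* Hidden-Markov dwell-time analysis of the hopping kinetics, force-clamp
  protocols, fluctuation-theorem free-energy estimators and glyoxal
  exposure kinetics are out of scope.
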