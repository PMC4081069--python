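# forcemelt

Analysis of force-induced DNA melting and B-to-S overstretching in short
designed duplexes from optical-tweezers pull–relax experiments, together
with a kinetic Monte-Carlo simulator that generates matched synthetic
trajectories with known ground truth.

## The scientific problem

When torsionally unconstrained double-stranded DNA is stretched to 60–70 pN
it overstretches by up to ~70% of its contour length. Three mechanisms can
account for the lengthening:

1. **peeling** — strand separation from a free duplex end; one strand
   carries the full tension while its complement relaxes;
2. **internal melting** — denaturation bubbles nucleate inside the duplex
   and both strands share the tension;
3. **B-to-S transition** — a longer, still base-paired "S-form".

Short designed duplexes isolate these mechanisms: a 64 bp AT-rich duplex
sealed at one end by an inter-strand cross-link (5′AT) can only peel; the
same duplex sealed at both ends (3′5′AT) can only melt internally; a 122 bp
composite of the AT core plus a GC-rich sequence (ATGC) peels in the AT part
and then forms S-DNA in the GC part. The package is aimed at single-molecule
biophysicists who need to quantify these transitions from force versus trap
position trajectories: rip/zip detection, hysteresis classification, linear
branch fits, and equilibrium population models.

## Models

For a continuous two-state transition the extent of reaction
φ(F) — the relative distance of each sample to linear force–position fits
below and above the transition region — follows the equilibrium force law

    φ(F) = 1 / (1 + exp(−δ (F − F_tr) / k_B T))

with midpoint force `F_tr` and cooperative length `δ` (the transition
distance in the Boltzmann exponent; it sets the force width of the
transition). `TwoStateModel(force, extent, kbt).fit()` returns a results
object with both parameters, standard errors and a `summary()` table.

For a construct with an intermediate (ATGC), per-sample state labels are
assigned by proximity to three branch fits and binned into occupation
probabilities, which follow Boltzmann populations

    P_i(F) ∝ exp(−(G_i − F x_i) / k_B T),   i ∈ {B, I, S},  G_B = x_B = 0.

`ThreeStateModel(populations, kbt).fit()` estimates `(G_I, x_I, G_S, x_S)`
and derives `F_tr^I` (B/I crossing, `G_I/x_I`), `F_tr^II` (I/S crossing,
`(G_S−G_I)/(x_S−x_I)`) and `F_tr` (maximum of the intermediate population).

Abrupt transitions are governed by Bell–Evans kinetics,
`k(F) = k_0 exp(F x‡ / k_B T)`; under a constant loading rate the mean
rupture force has a closed form used both to calibrate the simulator's
zero-force rates against measured mean transition forces and as an
independent oracle in the tests.

## Worked example

```
$ forcemelt demo --seed 1
== 5'AT, 1 M NaCl: peeling with hysteresis ==
  cycle 0: F_m = 65.1 pN, F_r = 22.7 pN, extension = 14.6 nm, HYSTERETIC
  cycle 1: F_m = 61.8 pN, F_r = 21.4 pN, extension = 14.2 nm, HYSTERETIC
  cycle 2: F_m = 56.6 pN, F_r = 21.4 pN, extension = 14.2 nm, HYSTERETIC
== 3'5'AT, 1 M NaCl: continuous internal melting ==
  F_tr = 68.0 pN, delta = 2.60 nm
== ATGC, 1 M NaCl: peel + B-to-S, three-state fit ==
  F_tr^I = 61.8 pN, F_tr = 64.0 pN, F_tr^II = 66.0 pN
```

Each 5′AT cycle shows one abrupt melting rip near 61.5 pN (cycle-to-cycle
spread is the Bell–Evans rupture-force distribution), rezipping near 22 pN
on relaxation — the hysteresis that identifies peeling — and a ~14.7 nm
(0.230 nm/bp) extension at the melting force. The double-sealed 3′5′AT
construct instead melts continuously; the two-state fit recovers the
midpoint near 67.8 pN and a cooperative length of 2.6 nm (≈16 bp at the
0.166 nm/bp midpoint extension). For ATGC the three-state fit places the
B/intermediate crossing near 62.1 pN (AT peel), the intermediate-population
maximum near 64.3 pN, and the intermediate/stretched crossing (GC B-to-S)
above it.

The same steps are available programmatically:

```python
import forcemelt as fm

scenario = fm.load_scenario("FIVE_PRIME_AT", "HIGH_1M")
trajs, log = fm.simulate_molecule(scenario, n_cycles=3, seed=1)
pull, relax = fm.segment_cycles(trajs[0])[0]
events = fm.detect_rips(pull)          # melting rip with F_m, force drop
call = fm.classify_hysteresis(pull, relax)
```

and as CLI subcommands `simulate`, `detect`, `fit2`, `fit3`, `report` over
the plain-text TSV trajectory format.

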