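# Model and methods

`achnet` simulates two excitatory–inhibitory (E–I) cortical modules coupled
by plastic excitatory synapses, to study how spatially structured
acetylcholine (ACh) signaling steers spike-timing-dependent plasticity
(STDP) between network regions.  This note documents the model equations,
the package's defaults and the reasoning behind the choices that the
published description leaves open, the numerical scheme, what the synthetic
fixtures do and do not cover, and known limitations.

## Single-cell model

Each cell is a single-compartment conductance-based neuron with a fast
sodium current (instantaneous activation `m∞(V)`, inactivation `h`), a
delayed-rectifier potassium current (`n`), a slow low-threshold M-type
potassium current (`z`) and a leak:

    C dV/dt = − gNa·m∞(V)³·h·(V−VNa) − gKdr·n⁴·(V−VK) − gKs·z·(V−VK)
              − gL·(V−VL) + I_drive − I_syn + I_noise

with C = 1 µF/cm², gNa = 24, gKdr = 3, gL = 0.02 mS/cm², VNa = 55,
VK = −90, VL = −60 mV.  Gating variables relax as
`dx/dt = (x∞(V) − x)/τx(V)`; all steady states are logistic in V with
midpoints/slopes m(−30, 9.5), h(−53, −7), n(−30, 10), z(−39, 5) mV, and
`τh = 0.37 + 2.78/(1+exp((V+40.5)/6))`,
`τn = 0.37 + 1.85/(1+exp((V+27)/15))`, `τz = 75 ms`.

`gKs ∈ [0, 1.5] mS/cm²` encodes the ACh level: muscarinic (M1) signaling
blocks the M-current, so `gKs = 0` means saturating ACh and `gKs = 1.5`
none.  Lowering `gKs` moves the cell from Type 2 excitability
(discontinuous f–I onset — here ≈ 7.6 Hz at a rheobase of ≈ 1.2 µA/cm² for
gKs = 1.5) to Type 1 (continuous onset; the gKs = 0 cell is spontaneously
active, its rheobase sits near −0.1 µA/cm²), raises the gain, and removes
spike-frequency adaptation.  These f–I facts are computed by
`neuron.fi_curve` and pinned in the test suite, not assumed.

## Network architecture

A module holds 400 E cells on a periodic 20×20 lattice and 100 I cells on
a periodic 10×10 lattice (20 % inhibition).  Wiring is local excitation /
global inhibition:

* E → 40 nearest E neighbours (wrapped Euclidean distance, distance ties
  broken uniformly at random), weight 0.01 mS/cm²;
* E → 10 nearest I cells, with the E cell overlaid on the I lattice at
  half coordinates, weight 0.05;
* I → all 400 E cells (0.04) and all 99 other I cells (0.04); self-inhibition
  is excluded by default (`include_ii_self` restores it).

Every synapse has exponential kinetics with τ = 3 ms and reversal 0 mV
(excitatory) or −75 mV (inhibitory); a presynaptic spike increments the
target conductance by the synaptic weight.

The two modules are connected E→E either randomly (each target draws 40
distinct sources; 5 in the sparse variant) or topographically (each cell
contacts the nearest cells of the other module with the grids stacked; the
aligned cell at distance 0 is included).  These synapses start at
0.005 mS/cm² — half the permitted maximum — and are the only plastic ones.

## STDP rule

Pair-based, additive, asymmetric: a post-minus-pre interval Δt ≥ 0 adds
`A₊·exp(−Δt/τ₊)` and Δt < 0 adds `−A₋·exp(Δt/τ₋)`, with A₊ = 0.0025,
A₋ = 0.00125 mS/cm², τ₊ = 14 ms, τ₋ = 34 ms; weights hard-clip to
[0, 0.01] mS/cm².  The default pairing is all-pairs, realized online with
eligibility traces that increment by one per spike; the trace update is
exactly the explicit double sum over pairs (verified to 1e−12 in the
tests).  Nearest-neighbour pairing (traces reset to one) is available via
`STDPParams(pairing="nearest")`.  Simultaneous pre/post events in one time
step are processed pre-then-post so the pair lands on the Δt = 0
potentiation branch.  Note the practical consequence of additive updates
with these amplitudes: two favourable coincidences move a synapse from its
initial value to the upper bound, so weights saturate within a few volleys
and the reported percentage changes reflect the ongoing balance of volley
timing, not a slow drift.

## Spatial ACh maps

A map assigns one scalar per cell over both lattices.  Hotspot maps are
radial sigmoids around one or more centers:
`value(d) = min + (max − min)·S((d − r)/w)` with S the logistic function,
`d` the wrapped distance to the nearest center on the shared 20×20 frame
(I cells evaluated at doubled coordinates).  The published formula spans
exactly one unit of conductance (`min + S(d − r)`); the package scales the
amplitude so that stated hotspot/surround pairs (e.g. 0.6 inside / 1.5
outside) are actually attained, and keeps the literal unit-amplitude form
behind `unit_amplitude=True`.  The radius (default r = 5 lattice units)
and steepness (default w = 1 lattice unit) are not constrained by any
published value; sweeps over them change the hotspot area but none of the
qualitative results reported by the tests.  DC-drive maps reuse the same
profile so that excitability fields stay spatially registered with the
ACh field.

## Who receives what (a deliberately documented choice)

The published description is ambiguous about whether the constant drive
(DC), the noise pulses, and the gKs maps apply to inhibitory cells.  The
package's defaults, chosen by explicit comparison of the candidate
configurations against the qualitative results the model must reproduce:

* **gKs maps modulate both populations** (the map construction explicitly
  covers the I lattice).
* **DC drive targets E cells** (`dc_to_i_cells=False` by default).  When I
  cells are also driven they fire tonically and asynchronously; this both
  degrades volley synchrony and — because a high-gKs map then weakens a
  module's inhibition — can invert the excitability ordering of two
  modules, contradicting the diagonal potentiation/depression boundary
  that defines the model's central phase diagram.
* **Noise pulses target E cells** (`NoiseParams(e_cells_only=True)` by
  default), consistent with the treatment of DC; a flag widens either to
  the I population.

With these defaults the model reproduces: the four canonical
mismatched-excitability cases (leader module's outgoing synapses
potentiate, ±~100 % without noise), the attenuation of net weight change
with increasing noise rate, and the hotspot results — a strongly modulated
hotspot (gKs 0.2, DC 3.0) fires high-frequency multi-spike volleys that
potentiate its incoming synapses and localize plasticity to the hotspot
even under random coupling.

Two published behaviours are **not** reproduced at the printed parameters,
and are documented rather than tuned for:

1. *Per-volley participation.*  At gKs = 0.6, DC = 2.0 a module settles
   into a stable ~44 Hz gamma rhythm, but single cells sustain only
   ~32 Hz under the M-current at that drive, so each volley recruits
   ~1/3 of the E cells and cells rotate through successive volleys
   (every cell participates within a few cycles).  The test suite asserts
   periodicity, gamma frequency and >90 % recruitment over any 150 ms
   stretch instead of near-total recruitment per volley.
2. *Noise-induced sign reversal.*  Strong per-cell Poisson noise scales
   the net inter-module weight change down substantially (e.g. +42 % →
   +9…18 % into the less excitable module as the rate goes 0 → 10 Hz) but
   does not flip the sign pattern here.  The reversal mechanism requires
   the more excitable module's noise-seeded initiating burst to remain
   small while its main volley is postponed past the partner's volley; in
   this implementation the initiating burst recruits the bulk of the
   module within ~5 ms, so the tight leader pairs keep net potentiation in
   the leader→follower direction.  Pair-time-difference histograms show
   the "secondary volley" mass at +10–15 ms does build up — the regime
   boundary is near (doubling the pulse amplitude, an unprinted value,
   flips one of the two signs) — but at the printed 6 µA/cm² amplitude the
   reversal does not occur.  The corresponding acceptance test is left
   failing on purpose.

## Numerics

* **Integrator:** classical RK4 on the full 1,000-cell state at a fixed
  dt = 0.05 ms.  Synaptic conductances decay analytically across RK4
  substeps.  An exponential-Euler variant (`method="exp_euler"`) exists
  but accumulates ~7 ms of spike-time drift over 5 s at this dt (RK4:
  0.05 ms when dt is halved), so RK4 is the default everywhere.
* **Spike detection:** upward crossing of −20 mV with a 2 ms lockout.
  Spikes in this model overshoot 0 mV, so any threshold in [−20, 0] marks
  the same events; −20 mV is robust to the 6 µA noise pulses.
* **Event ordering per step:** integrate → detect crossings → record →
  deliver conductance jumps (using the weights as of that step) → STDP
  (depression at pre spikes, then trace increment, then potentiation at
  post spikes, clip after every update).
* **Randomness:** one master seed expands through named `SeedSequence`
  substreams (wiring; per-trial initial conditions; per-trial noise), so
  identical configs are bitwise reproducible and components can be
  re-drawn independently.  Trials redraw wiring by default
  (`share_wiring_across_trials` shares it).
* **Initial conditions:** V ~ U(−70, −50) mV per cell, gates at steady
  state for that voltage.
* **Stability guard:** the run aborts with time and cell index if any |V|
  exceeds 200 mV or turns non-finite.
* **Burst statistics:** spike trains are binned at 0.1 ms, convolved with
  a σ = 1 ms Gaussian, and volley times are trace peaks above 10 % of the
  module's E count with a 5 ms merge radius.  Mean phase coherence pairs
  each reference inter-burst interval with the first partner burst inside
  it and averages the two directional phasor-mean magnitudes.  Percentage
  weight changes use `100·(Wf − Wi)/Wi` per wired edge, averaged over
  incoming edges per cell and over cells per module; displays use a
  linear scale within ±2 % and one unit per decade beyond.

## Problem sizes

Default protocol statistics use 5,000 ms trials; the package's own test
battery runs shorter horizons (0.4–5 s) and 1–2 trials per configuration,
and the default sweep grid is a coarse 5×5 (gKs 0–1.5 × DC 0–4) with 2
trials per point.  Denser grids and more trials are plain configuration
changes.

## Synthetic fixtures

`experiments.generate_volley_fixture` draws idealized rasters — volleys at
known times, Bernoulli participation, Gaussian jitter, a fixed
inter-module lag — to validate the analysis stack (trace, peak detection,
MPC, volley frequency) against exact ground truth.  The fixtures contain
no refractoriness, no rate heterogeneity and no within-volley structure,
so passing them certifies the statistics, not the simulator; simulator
behaviour is covered by the dynamical tests above.

## Limitations

* Exactly two modules; no distance-dependent intra-module weights; no
  synaptic delays; no short-term plasticity or NMDA voltage dependence.
* ACh acts only through gKs (tonic, fixed in time); no phasic release, no
  nicotinic pathway, no direct modulation of the STDP kernel.
* The plasticity rule is the canonical pair-based additive kernel;
  triplet and calcium-based variants are out of scope.
* Phase-response-curve analysis is not implemented.
* The two documented regime differences above (per-volley participation,
  noise-driven sign reversal) are open questions of this implementation.
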