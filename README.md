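# achnet

Conductance-based simulation of two coupled excitatory–inhibitory (E–I)
cortical modules, for studying how acetylcholine (ACh) — acting through
the M-type potassium current — steers spike-timing-dependent plasticity
(STDP) between network regions.

## The scientific problem

Cholinergic neuromodulation is spatially structured: ACh release can be
high in one patch of cortex and low nearby.  Through muscarinic M1
receptors, ACh blocks the slow M-current, so local ACh level maps onto
the maximal conductance `gKs` of that current (`gKs = 0` ↔ high ACh,
`gKs = 1.5 mS/cm²` ↔ none).  Lowering `gKs` switches neurons from Type 2
to Type 1 excitability, raises their gain, and removes spike-frequency
adaptation — which changes when cells fire relative to one another.
Since pair-based STDP converts relative spike timing into synaptic
change, spatially heterogeneous ACh can decide *which* connections
between two brain regions strengthen and which weaken.

`achnet` is a desk-scale simulator for this question, intended for
computational neuroscientists who want to reproduce, probe or extend the
model: two E–I modules (400 excitatory cells on a periodic 20×20 lattice,
100 inhibitory cells on 10×10, local excitation / global inhibition)
generate pyramidal–interneuron gamma (PING) volleys; plastic excitatory
synapses between the modules evolve under an asymmetric pair STDP rule;
`gKs` and the constant drive can vary in space as sigmoid "hotspot" maps.

## Model core

Membrane dynamics per cell (Hodgkin–Huxley type, voltages in mV, time in
ms, conductances in mS/cm²):

    C dV/dt = − gNa·m∞³·h·(V−VNa) − gKdr·n⁴·(V−VK) − gKs·z·(V−VK)
              − gL·(V−VL) + I_drive − I_syn + I_noise

Synapses are conductance jumps with a 3 ms exponential decay.  The STDP
kernel, applied only to inter-module E→E synapses with hard bounds
[0, 0.01] mS/cm²:

    Δw(Δt) =  A₊·e^(−Δt/τ₊)   for Δt ≥ 0      A₊ = 0.0025,  τ₊ = 14 ms
              −A₋·e^(Δt/τ₋)   for Δt < 0      A₋ = 0.00125, τ₋ = 34 ms

where Δt is post-minus-pre spike time.  Plasticity outcomes are
summarized by ΔW = 100 % × (W_final − W_initial)/W_initial per synapse,
averaged over each cell's incoming inter-module edges and over modules,
and by the mean phase coherence (MPC) of the two modules' volley trains.

See `docs/methods.md` for the full equations, parameter tables, numerical
scheme and the design choices taken where the published description is
ambiguous.

## Worked example

Case "F" is the canonical excitability mismatch: both modules at
`gKs = 0.6`, module 1 driven harder (DC 3.0 vs 2.0 µA/cm²), random
inter-module wiring, no noise:

```python
from achnet.experiments import run_example

res = run_example("F", n_trials=1, duration=5000.0, seed=1)
print(f"mean dW into module 2 (1->2): {res.summary.mean_dw_into_module2:+.1f} %")
print(f"mean dW into module 1 (2->1): {res.summary.mean_dw_into_module1:+.1f} %")
print(f"mean phase coherence:          {res.mpc:.3f}")
print(f"volley frequency module 1:     {res.burst_frequency[1]:.1f} Hz")
print(f"volley frequency module 2:     {res.burst_frequency[2]:.1f} Hz")
```

prints

    mean dW into module 2 (1->2): +23.8 %
    mean dW into module 1 (2->1): -84.9 %
    mean phase coherence:          0.892
    volley frequency module 1:     56.0 Hz
    volley frequency module 2:     55.4 Hz

The more excitable module 1 leads each locked gamma volley (MPC ≈ 0.9),
so synapses from module 1 onto module 2 potentiate (+24 % on average,
many saturating at the bound) while the reciprocal synapses depress
(−85 %): the leader wires into the follower.  `res.per_cell_dw` holds the
20×20 per-cell incoming-ΔW maps used for hotspot-localization figures.

The same machinery is scriptable from the shell:

    achnet example F --out out/F --trials 4 --seed 1
    achnet sweep --gks 0.0,0.375,0.75,1.125,1.5 --dc 0.0,1.0,2.0,3.0,4.0 \
                 --noise 0.0,5.0 --out out/sweep.csv
    achnet simulate --config config.yaml --out out/run --no-stdp
    achnet fi --gks 1.5 --out out/fi.tsv

Outputs are plain text: spikes as TSV (display id, time), weights as
MatrixMarket, maps as CSV grids with JSON sidecars, summaries as JSON.

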