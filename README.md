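# kernelfield

Extracellular brain signals — laminar local field potentials (LFPs) and
current dipole moments — from population spike rates, without simulating a
biophysically detailed recurrent network.

Point-neuron and rate-based network models predict spiking activity
efficiently but carry no spatial distribution of transmembrane currents,
so they cannot produce extracellular signals by themselves. `kernelfield`
closes that gap for computational neuroscientists: it computes, for every
connection pathway X→Y of a network described only *statistically*
(population sizes, cell geometries, connection probabilities, synapse
depth profiles, weight/delay distributions), a causal spatiotemporal
impulse response — a *kernel* H_YX(**R**, τ) — giving the expected signal
per presynaptic spike. Signals then follow by convolution,

&nbsp;&nbsp;&nbsp;&nbsp;ψ̂(**R**, t) = Σ_X Σ_Y (ν_X ∗ H_YX)(**R**, t),

either offline or through a streaming FIR node fed binned spike counts.
Kernels are computed deterministically from linearized neuron models:
current-based synapses Ī·f(t) about a working voltage V̄m, quasi-active or
passive-frozen ion-channel linearization (γ_R, η), an effective membrane
conductance g_eff absorbing the time-averaged synaptic bombardment, the
expected synaptic in-degree per compartment, volume-conductor forward
models (line source, population current disk, current dipole), and the
conduction-delay density. A seedable Monte-Carlo population oracle — the
same quantity computed by explicit sampling of cells, synapses, weights
and delays — validates the deterministic predictor, and a fitted
two-population leaky integrate-and-fire (LIF) surrogate network supplies
realistic spike trains to drive predictions end to end.

See `docs/methods.md` for the model, assumptions, numerics and
limitations.

## Worked example

Build the deterministic kernel set for the built-in two-population
reference network (8192 excitatory + 1024 inhibitory ball-and-sticks
cells, 13-contact laminar probe):

```python
import numpy as np
from kernelfield import build_kernel_set, reference_network

net = reference_network()          # tabulated populations, pathways, rates
ks = build_kernel_set(net, mode="frozen", g_eff=True)
for pathway in ks.pathways():
    H = ks.get(pathway, "potential")           # (13 channels, 1601 lags) mV
    ch = int(np.argmax(np.abs(H).max(axis=1)))
    peak = H[ch].flat[np.argmax(np.abs(H[ch]))]
    print(pathway, f"{peak * 1e3:+.3f} uV at channel {ch}")
```

prints

```
E->E +5.068 uV at channel 5
E->I +0.260 uV at channel 9
I->E -35.168 uV at channel 10
I->I -1.416 uV at channel 11
```

Each number is the extracellular-potential contribution of one average
presynaptic spike at the kernel's strongest probe channel: excitatory
spikes produce a positive deflection near their apical synapse zone
(channel 5, depth 500 µm), inhibitory spikes a ~7× larger negative
deflection peri-somatically (channel 10) — outward versus inward synaptic
currents, amplified by the larger inhibitory conductances, multapse counts
and slower kinetics. Convolving these kernels with LIF-network spike
rates and analyzing the result is shown step by step in `examples/`
(`01` linearized cell dynamics, `02` kernels, `03` Monte-Carlo
validation, `04` spikes→signals, `05` streaming FIR + spectra). A thin
CLI wraps the same calls:

```bash
kernelfield kernels-build --out kernels.h5
kernelfield lif-simulate --duration 12000 --seed 1 --out spikes.tsv --index-out index.tsv
kernelfield signals-predict --kernels kernels.h5 --spikes spikes.tsv \
    --index index.tsv --duration 12000 --out signals.h5
kernelfield signals-analyze --signals signals.h5 --signal dipole --out metrics.json
```

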