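"""Deterministic spike-to-signal kernels for the reference network.

Builds the causal impulse-response kernels H_YX(R, tau) mapping one
presynaptic spike in population X to the extracellular potential (13
laminar channels) and current dipole moment contributed by postsynaptic
population Y, for all four pathways of the built-in two-population
network.
"""

import numpy as np

from kernelfield import build_kernel_set, reference_network

net = reference_network()  # tabulated populations, pathways, drives, rates
ks = build_kernel_set(net, mode="frozen", g_eff=True)

print(f"lag grid: {ks.n_lags} samples, 0..{ks.tau[-1]:.0f} ms at {ks.dt} ms")
for pathway in ks.pathways():
    H = ks.get(pathway, "potential")
    ch = int(np.argmax(np.abs(H).max(axis=1)))
    peak = H[ch].flat[np.argmax(np.abs(H[ch]))]
    lag = ks.tau[np.argmax(np.abs(H[ch]))]
    pz = ks.get(pathway, "dipole")[2]
    print(f"{pathway}: potential peak {peak * 1e3:+.3f} uV "
          f"(channel {ch}, lag {lag:.1f} ms); "
          f"|P_z| peak {np.abs(pz).max():.1f} nA*um per spike")

# Peaks are per presynaptic spike: a single inhibitory spike contributes
# roughly an order of magnitude more extracellular signal than a single
# excitatory spike (stronger synapses, larger multapse count, slower
# kinetics), even though the E population is 8x larger.
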