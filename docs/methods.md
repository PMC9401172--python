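# Methods

`kernelfield` predicts extracellular signals — laminar extracellular
potentials and the current dipole moment — from population spike rates, by
convolving the rates with deterministic, causal spike-to-signal kernels
computed from a statistical description of a neuronal network and
linearized multicompartment (MC) cell models. This note documents the
models, the numerics, the parameter conventions, and the limits of what
the synthetic test conditions can show.

## Model overview

The predicted signal is a sum of causal convolutions,

ψ̂(**R**, t) = Σ_X Σ_Y (ν_X ∗ H_YX)(**R**, t),

where ν_X is the binned spike rate of presynaptic population X and
H_YX(**R**, τ) the expected signal contributed by postsynaptic population Y
per presynaptic spike in X, on the lag grid τ = 0, Δt, …, τ_max. Kernels
are stored in signal units per presynaptic *spike* (mV, nA·µm), so FIR
coefficients apply directly to spike counts per bin (ν·Δt).

A kernel is built from five ingredients:

1. **Linearized membranes.** Conductance synapses are replaced by
   current-based synapses Ī_syn·f(t) with Ī_syn = Ḡ_syn(V̄m − E_syn)
   evaluated at a fixed linearization voltage V̄m (default −70 mV).
   Voltage-gated channels with one gating variable are linearized about V̄m
   into the quasi-active form: a constant open conductance
   ḡ_w·ω_∞(V̄m) plus a feedback term b·ε with
   b = ḡ_w(V̄m − E_w)·∂ω_∞/∂V and auxiliary state
   τ_w(V̄m)·dε/dt = V − V̄m − ε. The derived diagnostics γ_R (total/leak
   conductance ratio) and η = b/ḡ_L (feedback sign and strength) are
   exposed; "frozen" mode drops the feedback (η = 0), leaving a passive
   membrane with the extra open conductance. The leak reversal is shifted to
   E_L′ = V̄m + Σ_w ḡ_w ω_∞(V̄m)(V̄m − E_w)/ḡ_L so the linearized cell
   rests exactly at V̄m; the ω_∞ factor is required for that property to
   hold (an input-free simulation settles at V̄m to < 1e-6 mV, which the
   tests check by steady-state simulation).
2. **Effective membrane conductance.** Persistent synaptic bombardment at
   mean rates ⟨ν_X'⟩ adds a time-averaged conductance per compartment,
   g_eff,m = ḡ_L + (1/A_m)·Σ_X' ⟨ν_X'⟩⟨k_syn,m⟩Ḡ_syn ∫f dt, summed over
   recurrent pathways *and* the external drive. For the reference
   parameters this raises the dendritic leak by roughly an order of
   magnitude (inhibition-dominated), shortening the effective membrane time
   constant; ignoring it overestimates predicted signal amplitudes by about
   a factor two.
3. **Expected synaptic input per spike.** One presynaptic spike activates,
   in expectation, ⟨k̃⟩·K_YX/N_X synapses across the postsynaptic
   population, where K_YX = C·N_Y·(N_X − 1[X=Y]) is the pairwise-Bernoulli
   connection count and ⟨k̃⟩ the mean of the discretized multapse
   distribution. They are distributed over compartments proportionally to
   the depth profile L_YX(z) times membrane area, restricted to the
   pathway's allowed sections.
4. **Population forward models.** Potentials use the analytic solution for
   a homogeneous planar current disk of the population radius at each
   compartment depth (in the package units — nA, µm, S/m, mV — the
   point-source solution is exactly I/(4πσr), so no conversion constant
   appears); the dipole uses f_m = [0, 0, z_m] (lateral components cancel
   by radial symmetry). Explicit single cells use the line-source solution
   with disk-electrode averaging (100 fixed-seed points on each 5-µm
   contact), the perpendicular distance floored at the compartment radius.
5. **Conduction delays.** The truncated-Gaussian delay density is evaluated
   on the lag grid, renormalized to unit sum, and convolved with the
   intermediate kernel, preserving causality (kernels vanish below the
   0.3 ms minimum delay).

### Depth averaging: joint quadrature vs factorization

The soma depths of a population scatter as N(0, 75 µm). Two treatments are
implemented (`depth_average=`):

* `"quadrature"` (default): the expectation over soma depth is taken
  jointly. At each Gauss–Hermite node z_v the in-degree map uses the
  depth-shifted profile L(z_m + z_v) (renormalized per cell, as in a
  sampled network) and the disk forward model is evaluated at the shifted
  compartment depths; one batched Crank–Nicolson simulation covers all
  nodes. This preserves the covariance between a cell's depth and where its
  synapses land, and agrees with the Monte-Carlo population oracle to a few
  percent per channel.
* `"factorized"`: the in-degree profile is convolved with the depth density
  (Gaussian-convolution closed form) and, independently, the disk forward
  solution is convolved with the same density (adaptive quadrature). This
  product-of-expectations variant is the cheaper classical formulation; it
  visibly smooths the potential kernels near amplitude extrema and sign
  flips (up to tens of percent on individual channels) while leaving the
  dipole kernel essentially unchanged. The Monte-Carlo oracle arbitrates
  between the two, which is why quadrature is the default.

### Monte-Carlo oracle

`hybrid_kernel_oracle` samples a discrete realization — soma positions
(uniform areal density within the 150 µm radius, Gaussian depth),
Bernoulli connectivity without autapses, discretized-Gaussian multapse
counts, placements ∝ L(z_m + z_v)A_m, zero-truncated weights,
0.3-ms-truncated delays — fires every presynaptic neuron once,
synchronously, simulates every postsynaptic cell (batched, one matrix
factorization), maps currents through per-cell line-source/dipole
matrices, sums, and divides by N_X. The external drive enters only through
g_eff (its steady-state effect), keeping the oracle linear and exactly
seedable; the same g_eff map is used for every sampled cell so all cells
share one propagator.

## Cable solver

Compartments are cylinders; axial conductances combine half-compartment
cytoplasmic resistances (R_a·(L/2)/(π r²)), pairwise at branch points.
Linear mode assembles voltages plus auxiliary gating states into one
affine system integrated by Crank–Nicolson with a single LU factorization
(unconditionally stable at the 0.0625 ms grid; halving Δt changes peaks by
< 1%; a matrix-exponential oracle with matched piecewise-linear input
agrees at the somatic peak to < 1e-6 mV). The per-compartment
transmembrane current is computed as the net axial current into each
compartment — by charge conservation identical to capacitive + ionic +
point currents booked to their host compartment — so ΣI_m = 0 holds to
machine precision at every step, which volume-conductor models require.
Nonlinear mode (gated channels retained) integrates the full ODE system
with LSODA and exists for small validation experiments only.

## Parameter conventions and defaults

* Units: lengths µm, areas µm² (converted internally to cm² for specific
  quantities), conductances S/cm² (specific) / nS (synaptic), currents nA,
  voltages mV, times ms, conductivity S/m.
* Reference network: two populations (8192 excitatory ball-and-sticks
  cells with a 1 mm apical dendrite; 1024 inhibitory cells symmetric about
  the soma), pairwise connection probability 0.05, tabulated multapse /
  weight / delay distributions, pathway-specific Gaussian(-mixture) synapse
  depth profiles (excitatory axons avoid somata), fixed-rate Poisson
  external drive (465/160 synapses per neuron at 40 s⁻¹), stationary rates
  {E: 2.6, I: 5.1, ext: 40} s⁻¹, V̄m = −70 mV, probe of 13 contacts at
  z = 1000…−200 µm, σ = 0.3 S/m.
* τ_max = 100 ms (kernels decay to < 1% of peak well before that), Δt =
  0.0625 ms everywhere; mixing grids raises an error rather than
  resampling.
* The weight-perturbation factor J rescales each pathway mean as
  Ḡ′ = Ḡ·J^(Ḡ_partner/Ḡ) (dimensionless exponent form; identity at J = 1;
  J > 1 shifts the balance toward excitation).

### Channel kinetics

The built-in presets are passive by default; the tabulated cells carry
their leak parameters per section. A generic, synthetic I_h-style channel
(`generic_ih`) is bundled for quasi-active demonstrations: sigmoidal
activation opening with hyperpolarization (half-activation −107 mV, slope
12 mV — the range published for neocortical HCN channels), a bell-shaped
time constant of a few tens of ms, reversal −45 mV. It is a stand-in, not
the kinetics of any specific published model; spike-generating channels
(fast Na⁺/K⁺) are out of scope — users can register their own
`GatedChannel` definitions, which the linearizer accepts unchanged (one
gating variable per channel instance; frozen mode always available).

## LIF surrogate network

The point-neuron surrogate is a two-population current-based LIF network
(exponential PSCs, τ_syn = 0.5 ms, τ_m = 10 ms, threshold −55 mV, reset
= E_L = −65 mV, refractory 2 ms) advanced with the exact-integration
propagator of the coupled linear system per 0.0625 ms step (single-neuron
interspike intervals match the closed form to within one step; the
subthreshold mean matches Campbell's theorem). Connectivity is pairwise
Bernoulli (0.05) with zero-truncated signed PSC amplitudes and truncated
Gaussian delays rounded to the grid; the external drive collapses the
per-neuron Poisson sources into one Poisson process per neuron, drawn in
batches around a compiled stepping loop.

**Current scale.** The tabulated synaptic amplitudes carry an ambiguous
unit; the package treats the scale as a single constant
(`current_scale`, multiplying the tabulated figures). A nA reading is
dynamically impossible (a single external event would depolarize by
~50 mV); on a pA-like scale the network is fluctuation-driven with the
mean membrane potential a fraction of a millivolt below threshold, making
the stationary rates hypersensitive to the constant. The default
9.275e-4 was calibrated once, by simulation, so the excitatory population
reproduces the reference stationary rate (≈2.6 spikes/s, stable across
seeds at 7–12 s durations), and is not adjusted thereafter.

**Structural limits of the tabulated parameter set.** With these parameters
both populations are dominated by their external drive and the excitatory
membrane sits closer to threshold than the inhibitory one, while recurrent
coupling contributes ≲0.1 mV per Hz of presynaptic rate. Two consequences
follow for *any* single current scale, and simulations confirm both: the
inhibitory population cannot fire faster than the excitatory one (it
settles near 1.3 spikes/s when E is at 2.6, versus the reference 5.1), and
the network sustains no gamma-band resonance, so the excitatory-rate power
spectrum is broadband with no peak near the reference's ~55 Hz. These two
quantities are therefore reported as measured rather than reproduced; the
acceptance suite leaves them red deliberately.

## Signal prediction and analysis

Offline prediction zero-pads the spike-count series and uses valid-mode
direct convolution so that every output sample is a full-length window
dot product — bit-for-bit identical to the streaming FIR node, which keeps
a circular buffer of the last L counts and emits one windowed product per
step. Causality is exact: a rate impulse at t₀ produces the kernel
starting at t₀ and nothing earlier.

Analysis follows the conventions used for laminar data: startup transient
(default 2000 ms) dropped and channel means removed before any metric;
amplitude agreement as r_STD = STD(x)/STD(y); temporal agreement as the
squared Pearson correlation at zero lag; aggregation by median and
10th/90th percentiles; low-pass filtering with a 2nd-order elliptic design
(0.1 dB ripple, 40 dB stopband, 100 Hz critical frequency) applied
forward-backward — note the zero-phase double pass doubles the decibel
figures, and a 2nd-order elliptic reaches its 40 dB floor only around
550 Hz, not immediately above the cutoff; spectra and coherence via
Welch's method (segment 2048, overlap 1536, detrending off by default).

## What the synthetic conditions do and do not show

All validation runs on synthetic networks whose statistics are the
generator's defaults above. Passing tests show internal consistency of the
framework — the deterministic predictor equals the explicit population
average, linearization is faithful for small signals, the signal path is
exactly linear and causal — at desk scale (oracle runs use 64 postsynaptic
cells × 32 realizations with the connection probability raised to 0.2 to
keep per-cell synapse counts realistic; predictor and oracle always see
the same scaled description). They do not show that the linearization is
adequate for strongly synchronized network states, for voltage excursions
beyond a few mV, for cells whose local membrane potential deviates far
from the single V̄m, or for real recorded data. The ground-truth recurrent
conductance-based network that would anchor absolute accuracy is outside
the package's scope, so amplitude-level statements are relative
(g_eff off/on, pathway ratios), not absolute comparisons to a reference
signal.

## Known limitations

* One gating variable per channel instance; m^a·h^b structures must be
  composed by the user or frozen.
* No lateral (distance-dependent) connectivity; populations are radially
  homogeneous columns.
* Static weights (no plasticity); stationary rates enter g_eff only.
* Presynaptic action-potential signatures are not part of kernels (they
  would be non-causal contributions); predictions target the ≲300 Hz band
  where synaptic currents dominate.
* The dipole supports EEG/MEG-style far-field models downstream but no
  head model is included.
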