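"""Signal prediction: population rates x kernels -> signal time series.

The predicted signal is the sum over pathways of causal discrete
convolutions of presynaptic population rates with the pathway kernels,

``psi(R, t) = sum_X sum_Y (nu_X * H_YX)(R, t)``,

available offline (:func:`convolve_predict`) or as a streaming
finite-impulse-response node fed binned spike counts (:class:`FIRNode`,
:func:`fir_stream`).  Both routes are the same linear map and agree
bit-for-bit: kernels are sampled in signal units per presynaptic *spike*,
so FIR coefficients apply directly to spike counts per bin
(``nu * dt = counts``), and the offline path convolves counts with the
same coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .kernels import KernelSet
from .lifnet import RateSeries

__all__ = ["SignalSet", "FIRNode", "convolve_predict", "fir_stream"]


@dataclass
class SignalSet:
    """Predicted signals per signal type.

    ``signals[signal]`` is (n_channels, n_steps); ``t`` the time grid (ms).
    ``provenance`` records kernel metadata and the rate source.
    """

    t: np.ndarray
    dt: float
    signals: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.t, track_times=False)
            f.attrs["dt"] = self.dt
            for k, v in self.provenance.items():
                f.attrs[f"prov_{k}"] = v
            for signal, values in self.signals.items():
                f.create_dataset(signal, data=values, track_times=False)

    def to_csv(self, path, signal: str) -> None:
        import pandas as pd

        vals = self.signals[signal]
        df = pd.DataFrame(vals.T, index=self.t)
        df.index.name = "t_ms"
        df.to_csv(path)


def convolve_predict(
    rates: RateSeries,
    kernels: KernelSet,
    signals: Optional[Sequence[str]] = None,
    per_pathway: bool = False,
):
    """Offline kernel prediction by causal convolution.

    For each pathway X->Y, the presynaptic spike *counts* per bin
    (``nu_X * dt``) are convolved with the kernel rows and the result is
    truncated to the input window, so a rate impulse at t0 produces the
    kernel starting exactly at t0 and nothing before it.  Contributions
    are summed over pathways (superposition).

    Raises ``ValueError`` on a time-step mismatch (no silent resampling).

    With ``per_pathway=True`` returns ``{pathway: SignalSet}`` instead of
    the summed :class:`SignalSet`.
    """
    if not np.isclose(rates.dt, kernels.dt):
        raise ValueError(
            f"rate bin width {rates.dt} ms != kernel step {kernels.dt} ms"
        )
    n = len(rates.t)
    if signals is None:
        signals = sorted({s for sigs in kernels.kernels.values() for s in sigs})
    per = {}
    total = {}
    for pathway in kernels.pathways():
        pre = pathway.split("->")[0]
        if pre not in rates.rates:
            raise ValueError(f"no rate series for presynaptic population {pre!r}")
        counts = rates.counts(pre)
        entry = {}
        for signal in signals:
            H = kernels.get(pathway, signal)
            L = H.shape[1]
            # zero-pad so every output is a full L-term window: identical
            # arithmetic to the streaming FIR node (bit-for-bit)
            padded = np.concatenate([np.zeros(L - 1), counts])
            out = np.empty((H.shape[0], n))
            for ch in range(H.shape[0]):
                out[ch] = np.convolve(padded, H[ch], mode="valid")[:n]
            entry[signal] = out
            total[signal] = total.get(signal, 0.0) + out
        per[pathway] = SignalSet(t=rates.t, dt=rates.dt, signals=entry,
                                 provenance={"pathway": pathway})
    if per_pathway:
        return per
    return SignalSet(t=rates.t, dt=rates.dt, signals=total,
                     provenance={"pathways": ",".join(kernels.pathways()),
                                 **{str(k): v for k, v in kernels.meta.items()}})


class FIRNode:
    """Streaming finite-impulse-response filter over binned spike counts.

    ``coefficients`` has shape (n_channels, L): per output channel, one
    coefficient per lag, ``h[l] = H(tau = l*dt)`` in signal units per
    spike.  The node keeps a circular buffer of the last L input counts;
    output at step k depends only on inputs at steps <= k (causal).
    """

    def __init__(self, coefficients: np.ndarray):
        h = np.atleast_2d(np.asarray(coefficients, float))
        self.h = h
        self.L = h.shape[1]
        self.reset()

    @classmethod
    def from_kernel(cls, kernels: KernelSet, pathway: str, signal: str) -> "FIRNode":
        return cls(kernels.get(pathway, signal))

    def reset(self) -> None:
        self._window = np.zeros(self.L)  # window[l] = x[k - L + 1 + l]

    def step(self, count: float) -> np.ndarray:
        """Advance one time step with the spike count of that step; returns
        the per-channel output sample."""
        self._window[:-1] = self._window[1:]
        self._window[-1] = count
        # y[k] = sum_l h[l] x[k-l]; 'valid' convolution of the window with
        # each coefficient row is exactly that sum, in the same multiply-
        # accumulate order as the offline numpy convolution
        return np.array([
            np.convolve(self._window, self.h[c], mode="valid")[-1]
            for c in range(self.h.shape[0])
        ])


def fir_stream(node: FIRNode, counts: np.ndarray) -> np.ndarray:
    """Run a spike-count sequence through a FIR node step by step.

    Returns (n_channels, n_steps).  The result is bit-identical to
    convolving the counts with the node's coefficients offline.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 1:
        raise ValueError("counts must be a 1-D per-step sequence")
    out = np.empty((node.h.shape[0], len(counts)))
    for k, c in enumerate(counts):
        out[:, k] = node.step(c)
    return out
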