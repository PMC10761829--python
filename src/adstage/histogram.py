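"""Intensity histograms and zero-phase lowpass smoothing of their envelope.

The raw 256-bin histogram of a brain slice is too jagged for valley
picking, so its envelope is smoothed with a minimum-order linear-phase
FIR lowpass (Kaiser-window design).  The filter is applied zero-phase —
forward convolution with the symmetric kernel after symmetric edge
padding — so peak and valley *locations* are unbiased, which the
downstream threshold selection depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class FilterSpec:
    """Lowpass design parameters on the normalized frequency axis (1 = Nyquist).

    Parameters
    ----------
    passband_edge : float
        End of the passband as a fraction of Nyquist.  The default 0.005
        keeps only the slow envelope of a 256-bin histogram.
    stopband_attenuation : float
        Minimum stopband rejection in dB.
    transition_width : float
        Width of the transition band as a fraction of Nyquist.  The
        default 0.15 matches the conventional minimum-order lowpass
        design (~85% steepness); the filter order grows as 1/width, and
        very narrow transitions produce kernels longer than the
        histogram itself, erasing the multimodal structure the
        thresholding needs.
    """

    passband_edge: float = 0.005
    stopband_attenuation: float = 60.0
    transition_width: float = 0.15
    taps: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not 0.0 < self.passband_edge < 1.0:
            raise ValueError("passband_edge must lie in (0, 1)")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")
        if self.passband_edge + self.transition_width >= 1.0:
            raise ValueError("stopband edge must stay below Nyquist")
        if self.stopband_attenuation <= 0:
            raise ValueError("stopband_attenuation must be positive")


def compute_histogram(image: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """256-bin (``2**bit_depth``) intensity histogram; counts sum to M*N."""
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    n_bins = 1 << bit_depth
    return np.bincount(image.reshape(-1).astype(np.int64), minlength=n_bins)


def design_lowpass(spec: FilterSpec | None = None) -> FilterSpec:
    """Populate ``spec.taps`` with a minimum-order Kaiser-window FIR lowpass.

    The order starts from the Kaiser estimate for the requested
    attenuation and transition width (forced odd, so the kernel is
    symmetric about an integer delay) and is grown until the realised
    response actually rejects >= the requested dB everywhere beyond the
    stopband edge — the closed-form estimate can fall a couple of dB
    short.  ``firwin`` normalises the taps to unity DC gain, so a
    constant input passes through unchanged.
    """
    if spec is None:
        spec = FilterSpec()
    elif spec.taps is not None:
        return spec
    numtaps, beta = signal.kaiserord(spec.stopband_attenuation, spec.transition_width)
    numtaps |= 1
    cutoff = spec.passband_edge + spec.transition_width / 2.0
    floor = 10 ** (-spec.stopband_attenuation / 20.0)
    for _ in range(50):
        taps = signal.firwin(numtaps, cutoff, window=("kaiser", beta), scale=True)
        w, h = signal.freqz(taps, worN=4096)
        stop = np.abs(h[w / np.pi >= spec.passband_edge + spec.transition_width])
        if stop.size == 0 or stop.max() <= floor:
            break
        numtaps += 2
    return FilterSpec(spec.passband_edge, spec.stopband_attenuation,
                      spec.transition_width, taps)


def smooth_histogram(counts: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase lowpass smoothing of a histogram envelope.

    The counts are padded symmetrically by half the kernel length at
    both ends, convolved with the symmetric taps, and cropped back —
    equivalent to forward filtering followed by exact group-delay
    compensation.  Negative ringing is clamped to zero since the result
    represents counts.
    """
    spec = design_lowpass(spec)
    counts = np.asarray(counts, dtype=np.float64)
    pad = len(spec.taps) // 2
    padded = np.pad(counts, pad, mode="symmetric")
    out = np.convolve(padded, spec.taps, mode="valid")
    return np.clip(out, 0.0, None)
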