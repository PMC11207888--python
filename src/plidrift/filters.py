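"""Zero-phase FIR band-pass and IIR notch filtering.

Band-pass filters are windowed-sinc (Hamming) designs applied as a
single linear-phase pass with group-delay compensation (odd tap count,
``same``-mode FFT convolution), which is exactly zero-phase for the
symmetric impulse response.  The Hamming window gives > 50 dB stop-band
attenuation.

Transition bandwidths follow the usual heuristic for physiological
bands: 25 % of the band edge, at least 2 Hz, and never wider than the
distance to DC (low edge) or to Nyquist (high edge).
"""

from __future__ import annotations

import numpy as np
from scipy import signal


#: Upper-edge transitions are capped so the roll-off always completes
#: inside the 45 -> 50 Hz gap between the analysis band and mains.
MAX_HIGH_TRANSITION = 5.0


def transition_bandwidth(edge: float, sampling_rate: float, side: str) -> float:
    """Transition width in Hz for a filter edge: a quarter of the edge
    frequency, raised to at least 2 Hz but never above half the edge.

    ``side`` is ``"low"`` for the high-pass edge (bounded by DC) or
    ``"high"`` for the low-pass edge (additionally bounded by Nyquist and
    by :data:`MAX_HIGH_TRANSITION`).
    """
    trans = min(max(0.25 * edge, 2.0), edge / 2.0)
    if side == "low":
        return trans
    nyq = sampling_rate / 2.0
    return min(trans, MAX_HIGH_TRANSITION, max(nyq - edge, 1e-3))


def design_bandpass(low: float, high: float, sampling_rate: float) -> np.ndarray:
    """Hamming windowed-sinc band-pass taps (odd length, linear phase)."""
    nyq = sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    trans_lo = transition_bandwidth(low, sampling_rate, "low")
    trans_hi = transition_bandwidth(high, sampling_rate, "high")
    # Hamming window: ~3.3 normalized-frequency units per transition width;
    # the sharper of the two edges sets the tap count.
    n_taps = int(np.ceil(3.3 * sampling_rate / min(trans_lo, trans_hi)))
    n_taps += 1 - n_taps % 2  # odd length -> integer group delay
    # -6 dB cutoffs half a transition band outside the passband edges, so
    # the passband itself keeps ~unit gain up to the nominal edges
    f_lo = max(low - trans_lo / 2.0, trans_lo / 4.0)
    f_hi = min(high + trans_hi / 2.0, nyq * 0.999)
    return signal.firwin(
        n_taps, [f_lo, f_hi], pass_zero=False, fs=sampling_rate, window="hamming"
    )


def apply_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR along the last axis with delay compensation.

    ``same``-mode convolution with an odd-length symmetric kernel centres
    the impulse response, so in-band sinusoids come out with zero lag.
    """
    if taps.ndim != 1 or taps.size % 2 == 0:
        raise ValueError("taps must be a 1-D odd-length array")
    return signal.fftconvolve(data, taps[np.newaxis, :] if data.ndim == 2 else taps,
                              mode="same", axes=-1)


def bandpass(data: np.ndarray, low: float, high: float, sampling_rate: float) -> np.ndarray:
    """Zero-phase band-pass of ``channels x samples`` (or 1-D) data."""
    return apply_zero_phase(np.asarray(data, dtype=np.float64),
                            design_bandpass(low, high, sampling_rate))


def notch(data: np.ndarray, freq: float, sampling_rate: float, q: float = 30.0) -> np.ndarray:
    """Zero-phase narrow-band rejection at ``freq`` Hz (IIR notch, filtfilt).

    With the default quality factor the -3 dB width is ``freq / 30``
    (~1.7 Hz at 50 Hz), so neighbours 5 Hz away are attenuated well
    under 3 dB.
    """
    nyq = sampling_rate / 2.0
    if not 0 < freq < nyq:
        raise ValueError(f"notch frequency {freq} Hz must lie below Nyquist ({nyq} Hz)")
    b, a = signal.iirnotch(freq, q, fs=sampling_rate)
    return signal.filtfilt(b, a, np.asarray(data, dtype=np.float64), axis=-1)
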