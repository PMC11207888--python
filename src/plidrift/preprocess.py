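"""Preprocessing: resampling, re-referencing, filtering, epoching and QC.

The chain mirrors a standard long-session EEG pipeline: polyphase
down-sampling, linked-mastoid re-referencing (dropping the reference
channels from the network space), zero-phase FIR band-pass, optional
mains notch, fixed-length overlapping epochs with session-margin
trimming, whole-epoch baseline removal, and a high-frequency power
criterion that flags noisy epochs.

Input is assumed artifact-cleaned (no ocular-component removal is
performed here); the synthetic path contains no such artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from . import filters
from .bands import BandDefinition
from .montage import MontageSpec


@dataclass
class Recording:
    """A continuous multi-channel recording.

    ``data`` is ``channels x samples`` (microvolts) in ``montage.all_labels``
    order when reference channels are present, or ``montage.labels`` order
    after re-referencing.
    """

    data: np.ndarray
    sampling_rate: float
    montage: MontageSpec
    has_references: bool = True
    annotations: list | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        expected = len(self.montage.all_labels) if self.has_references else self.montage.n_channels
        if self.data.shape[0] != expected:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but the montage "
                f"defines {expected}"
            )

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return self.montage.all_labels if self.has_references else self.montage.labels

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate


@dataclass
class EpochSet:
    """Ordered fixed-length segments of a recording.

    ``epochs`` has shape ``n_epochs x channels x samples``; ``retained_mask``
    marks epochs that survived quality control.  ``start_times`` records the
    window grid in seconds relative to the recording start.
    """

    epochs: np.ndarray
    sampling_rate: float
    montage: MontageSpec
    epoch_duration: float
    step: float
    subject_id: str = "subject-0"
    start_times: np.ndarray | None = None
    retained_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a 3-D array (epochs x channels x samples)")
        if self.retained_mask is None:
            self.retained_mask = np.ones(self.epochs.shape[0], dtype=bool)
        else:
            self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
        if self.start_times is None:
            self.start_times = np.arange(self.epochs.shape[0]) * self.step
        else:
            self.start_times = np.asarray(self.start_times, dtype=np.float64)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())


def resample(recording: Recording, target_rate: float) -> Recording:
    """Anti-aliased polyphase resampling to ``target_rate`` (down only)."""
    if target_rate > recording.sampling_rate:
        raise ValueError(
            f"upsampling ({recording.sampling_rate} -> {target_rate} Hz) is not supported"
        )
    if target_rate == recording.sampling_rate:
        return recording
    ratio = Fraction(target_rate / recording.sampling_rate).limit_denominator(1000)
    data = signal.resample_poly(recording.data, ratio.numerator, ratio.denominator, axis=-1)
    return replace(recording, data=data, sampling_rate=target_rate)


def rereference(recording: Recording, reference_labels: tuple[str, str] | None = None) -> Recording:
    """Subtract the linked-mastoid mean and drop the reference channels."""
    refs = tuple(reference_labels or recording.montage.reference_labels)
    if not recording.has_references:
        return recording  # idempotent: no reference channels remain
    labels = recording.montage.all_labels
    missing = [r for r in refs if r not in labels]
    if missing:
        raise ValueError(f"reference channel(s) {missing} not present in {labels}")
    ref_idx = [labels.index(r) for r in refs]
    net_idx = [labels.index(lab) for lab in recording.montage.labels]
    ref_mean = recording.data[ref_idx].mean(axis=0)
    data = recording.data[net_idx] - ref_mean
    return replace(recording, data=data, has_references=False)


def bandpass_fir(recording: Recording, low: float, high: float) -> Recording:
    """Zero-phase Hamming-window FIR band-pass."""
    data = filters.bandpass(recording.data, low, high, recording.sampling_rate)
    return replace(recording, data=data)


def notch(recording: Recording, freq: float = 50.0) -> Recording:
    """Zero-phase mains notch (real-data path only; synthetic data carry no mains)."""
    return replace(recording, data=filters.notch(recording.data, freq, recording.sampling_rate))


def epoch(
    recording: Recording,
    window: float = 300.0,
    step: float = 150.0,
    trim: float = 300.0,
    subject_id: str = "subject-0",
) -> EpochSet:
    """Cut the recording into fixed-length windows on a regular grid.

    Windows start every ``step`` seconds from time 0; any window that
    overlaps the first or last ``trim`` seconds of the recording is
    excluded (containment rule).  The epoch count is data-derived, never
    assumed.
    """
    fs = recording.sampling_rate
    n_samples = recording.data.shape[1]
    duration = n_samples / fs
    required = 2 * trim + window
    if duration < required:
        raise ValueError(
            f"recording of {duration:.1f} s is too short: epoching with "
            f"window={window} s and trim={trim} s requires at least {required:.1f} s"
        )
    win_n = int(round(window * fs))
    step_n = int(round(step * fs))
    trim_n = int(round(trim * fs))
    starts = [
        s for s in range(0, n_samples - win_n + 1, step_n)
        if s >= trim_n and s + win_n <= n_samples - trim_n
    ]
    if not starts:
        raise ValueError("no epoch window fits inside the trimmed recording")
    epochs = np.stack([recording.data[:, s:s + win_n] for s in starts])
    return EpochSet(
        epochs=epochs,
        sampling_rate=fs,
        montage=recording.montage,
        epoch_duration=window,
        step=step,
        subject_id=subject_id,
        start_times=np.asarray(starts, dtype=np.float64) / fs,
    )


def baseline_correct(epoch_set: EpochSet) -> EpochSet:
    """Remove the whole-epoch mean from every channel of every epoch."""
    data = epoch_set.epochs - epoch_set.epochs.mean(axis=-1, keepdims=True)
    return replace(epoch_set, epochs=data)


def highband_power(epoch_set: EpochSet, band_low: float = 20.0, band_high: float = 40.0) -> np.ndarray:
    """Per-epoch mean power (across channels) in ``band_low``-``band_high`` Hz."""
    fs = epoch_set.sampling_rate
    powers = np.empty(epoch_set.n_epochs)
    for i in range(epoch_set.n_epochs):
        freqs, psd = signal.periodogram(epoch_set.epochs[i], fs=fs, axis=-1)
        mask = (freqs >= band_low) & (freqs <= band_high)
        powers[i] = np.trapezoid(psd[:, mask], freqs[mask], axis=-1).mean()
    return powers


def qc_reject(
    epoch_set: EpochSet,
    band_low: float = 20.0,
    band_high: float = 40.0,
    threshold_db: float = 6.0,
) -> EpochSet:
    """Flag epochs whose 20-40 Hz power exceeds the recording median by > ``threshold_db``.

    The reference level is the per-recording median of epoch-level band
    power, a robust self-contained baseline.  Retained epochs are
    unchanged; rejected epochs stay in the array but are masked out.
    """
    if epoch_set.n_epochs < 3:
        raise ValueError("qc_reject needs at least 3 epochs to estimate a reference level")
    powers = highband_power(epoch_set, band_low, band_high)
    ref = np.median(powers)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_db = 10.0 * np.log10(powers / ref)
    rejected = rel_db > threshold_db
    if rejected.any():
        warnings.warn(
            f"qc_reject: excluding {int(rejected.sum())} of {epoch_set.n_epochs} epochs "
            f"(> {threshold_db} dB above median {band_low}-{band_high} Hz power)",
            stacklevel=2,
        )
    mask = epoch_set.retained_mask & ~rejected
    return replace(epoch_set, retained_mask=mask)


def band_decompose(
    epoch_set: EpochSet, bands: tuple[BandDefinition, ...]
) -> dict[str, EpochSet]:
    """Band-filter every epoch once per band (retained and masked alike)."""
    fs = epoch_set.sampling_rate
    out: dict[str, EpochSet] = {}
    for band in bands:
        band.check_nyquist(fs)
        taps = filters.design_bandpass(band.low, band.high, fs)
        filtered = filters.apply_zero_phase(
            epoch_set.epochs.reshape(-1, epoch_set.epochs.shape[-1]), taps
        ).reshape(epoch_set.epochs.shape)
        out[band.name] = replace(epoch_set, epochs=filtered)
    return out
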