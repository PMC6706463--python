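"""Filtering, segmentation and band isolation of multichannel recordings.

The analysis pipeline works on 3-second epochs of narrowband (alpha,
8-13 Hz) signal. Filtering is zero-phase (forward-backward Butterworth)
so that downstream instantaneous-phase estimates carry no filter delay;
each epoch is filtered independently and its first and last 75 ms are
trimmed to discard filter edge transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from . import io as _io

DEFAULT_FILTER_ORDER = 4  # Butterworth sections; effective rolloff doubles under filtfilt


@dataclass(frozen=True)
class Recording:
    """One subject's continuous multichannel recording.

    data is (channels, samples), in microvolt-like units; channel labels
    are unique and ordered; the reference electrode is recorded but no
    re-referencing is applied anywhere in the pipeline.
    """

    subject_id: str
    sampling_rate: float
    channel_labels: tuple
    data: np.ndarray
    reference_label: str = "Cz"

    def __post_init__(self):
        data = np.asarray(self.data, float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def to_container(self, stem) -> None:
        _io.write_array_container(
            stem,
            self.data,
            {
                "subject_id": self.subject_id,
                "sampling_rate": self.sampling_rate,
                "channel_labels": list(self.channel_labels),
                "reference_label": self.reference_label,
                "kind": "recording",
            },
        )

    @classmethod
    def from_container(cls, stem) -> "Recording":
        data, meta = _io.read_array_container(stem)
        return cls(
            subject_id=meta["subject_id"],
            sampling_rate=meta["sampling_rate"],
            channel_labels=tuple(meta["channel_labels"]),
            data=data,
            reference_label=meta.get("reference_label", "Cz"),
        )

    def to_edf(self, path) -> None:
        _io.write_edf(
            path,
            self.data,
            self.sampling_rate,
            self.channel_labels,
            subject_id=self.subject_id,
        )

    @classmethod
    def from_edf(cls, path) -> "Recording":
        data, fs, labels, subject = _io.read_edf(path)
        return cls(
            subject_id=subject,
            sampling_rate=fs,
            channel_labels=tuple(labels),
            data=data,
        )


@dataclass(frozen=True)
class EpochSet:
    """Segmented (and possibly band-limited) data: (epochs, channels, samples)."""

    subject_id: str
    sampling_rate: float
    channel_labels: tuple
    data: np.ndarray
    epoch_length: float
    trim: float = 0.0
    band: tuple | None = None

    def __post_init__(self):
        data = np.asarray(self.data, float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError("epoch data must be (epochs, channels, samples)")
        expected = int(round((self.epoch_length - 2 * self.trim) * self.sampling_rate))
        if data.shape[2] != expected:
            raise ValueError(
                f"samples per epoch is {data.shape[2]}, expected {expected} "
                f"({self.epoch_length} s minus 2 x {self.trim} s at "
                f"{self.sampling_rate} Hz)"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def _design_bandpass(low: float, high: float, fs: float, order: int):
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist "
            f"({nyq} Hz); got ({low}, {high})"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(recording: Recording, low: float, high: float,
             order: int = DEFAULT_FILTER_ORDER) -> Recording:
    """Zero-phase Butterworth band-pass of a continuous recording.

    Forward-backward application squares the magnitude response, so an
    order-4 design gives > 40 dB attenuation one octave outside the band
    with a maximally flat (sub-dB ripple) passband.
    """
    sos = _design_bandpass(low, high, recording.sampling_rate, order)
    filtered = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return replace(recording, data=filtered)


def segment(recording: Recording, epoch_length: float = 3.0,
            n_epochs: int = 50) -> EpochSet:
    """Cut consecutive non-overlapping epochs from the start of a recording."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be at least 1")
    spe = int(round(epoch_length * recording.sampling_rate))
    needed = spe * n_epochs
    if needed > recording.n_samples:
        raise ValueError(
            f"recording too short: {n_epochs} epochs of {epoch_length} s need "
            f"{needed} samples, only {recording.n_samples} available"
        )
    data = recording.data[:, :needed]
    epochs = data.reshape(recording.n_channels, n_epochs, spe).transpose(1, 0, 2)
    return EpochSet(
        subject_id=recording.subject_id,
        sampling_rate=recording.sampling_rate,
        channel_labels=recording.channel_labels,
        data=epochs.copy(),
        epoch_length=epoch_length,
        trim=0.0,
        band=None,
    )


def isolate_band(epochset: EpochSet, low: float = 8.0, high: float = 13.0,
                 trim: float = 0.075, order: int = DEFAULT_FILTER_ORDER) -> EpochSet:
    """Band-pass each epoch independently, then trim both ends.

    The trim (default 75 ms) discards the filter's edge transients; with
    3 s epochs at 1000 Hz this leaves 2850 samples per epoch.
    """
    if trim < 0:
        raise ValueError("trim must be non-negative")
    if trim >= epochset.epoch_length / 2:
        raise ValueError(
            f"trim {trim} s must be below half the epoch length "
            f"({epochset.epoch_length / 2} s)"
        )
    sos = _design_bandpass(low, high, epochset.sampling_rate, order)
    filtered = signal.sosfiltfilt(sos, epochset.data, axis=-1)
    k = int(round(trim * epochset.sampling_rate))
    if k:
        filtered = filtered[:, :, k:-k]
    return EpochSet(
        subject_id=epochset.subject_id,
        sampling_rate=epochset.sampling_rate,
        channel_labels=epochset.channel_labels,
        data=filtered,
        epoch_length=epochset.epoch_length,
        trim=epochset.trim + trim,
        band=(low, high),
    )


def reject_epochs(epochset: EpochSet, amplitude_limit: float) -> tuple:
    """Drop epochs whose absolute peak in any channel exceeds the limit.

    Returns (surviving EpochSet, number rejected). Survivor order is
    preserved. Stands in for manual/ICA artifact screening on real data.
    """
    if not amplitude_limit > 0:
        raise ValueError("amplitude_limit must be positive")
    peaks = np.abs(epochset.data).max(axis=(1, 2))
    keep = peaks <= amplitude_limit
    n_rejected = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"all {epochset.n_epochs} epochs exceed the amplitude limit "
            f"{amplitude_limit}"
        )
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} epoch(s) above {amplitude_limit}")
    out = replace(epochset, data=epochset.data[keep])
    return out, n_rejected
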