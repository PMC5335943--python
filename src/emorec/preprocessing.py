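"""Epoch segmentation and the 0.5-30 Hz clinical band filter bank.

The recogniser operates on fixed-length epochs of 192 samples (1.5 s at
128 Hz).  That length makes a full 14-channel epoch carry 14 x 192 = 2688
samples — the flattened filtered-signal feature — and lets exactly ten
non-overlapping epochs tile a 15 s decision window.

Each epoch is decomposed into the four clinical bands (delta 0.5-4, theta
4-8, alpha 8-13, beta 13-30 Hz) with 4th-order Butterworth filters applied
forward-backward, so filtering is zero-phase and preserves epoch shape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from ._errors import InvalidArgumentError
from .synth import DEFAULT_MONTAGE, DEFAULT_SAMPLING_RATE, EEGRecording, EmotionLabel, Montage

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "BROADBAND",
    "Epoch",
    "BandFilteredEpoch",
    "DEFAULT_EPOCH_LENGTH",
    "segment",
    "bandpass",
    "broadband",
    "decompose",
]

#: Default epoch length in samples: 1.5 s at 128 Hz.
DEFAULT_EPOCH_LENGTH = 192


@dataclass(frozen=True)
class Band:
    """A named frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise InvalidArgumentError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )


#: Conventional clinical bands partitioning the 0.5-30 Hz envelope.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0),
)

#: The full analysis envelope, used for the filtered-signal feature family.
BROADBAND = Band("broadband", 0.5, 30.0)


def validate_band_partition(bands: tuple[Band, ...]) -> None:
    """Check that bands are ordered, non-overlapping and contiguous."""
    if len(bands) != 4:
        raise InvalidArgumentError(f"expected exactly 4 bands, got {len(bands)}")
    for lo, hi in zip(bands, bands[1:]):
        if lo.high_hz > hi.low_hz + 1e-12:
            raise InvalidArgumentError(f"bands {lo.name!r} and {hi.name!r} overlap")
        if lo.high_hz < hi.low_hz - 1e-12:
            raise InvalidArgumentError(f"gap between bands {lo.name!r} and {hi.name!r}")


validate_band_partition(DEFAULT_BANDS)


@dataclass
class Epoch:
    """One fixed-length classification window of multichannel EEG."""

    data: np.ndarray
    montage: Montage = DEFAULT_MONTAGE
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    label: EmotionLabel | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("epoch data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise InvalidArgumentError(
                f"epoch has {self.data.shape[0]} rows for a "
                f"{self.montage.n_channels}-channel montage"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class BandFilteredEpoch:
    """An epoch's content restricted to one frequency band."""

    band: Band
    data: np.ndarray
    parent: Epoch

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.parent.data.shape:
            raise InvalidArgumentError("band-filtered data must match parent epoch shape")


def segment(
    recording: EEGRecording,
    epoch_length: int = DEFAULT_EPOCH_LENGTH,
    step: int | None = None,
) -> list[Epoch]:
    """Cut a recording into fixed-length windows at the given stride.

    Windows start at sample 0 and advance by ``step`` (default: the epoch
    length, i.e. non-overlapping).  A trailing partial window is dropped; a
    recording shorter than one epoch yields an empty list.
    """
    if step is None:
        step = epoch_length
    if epoch_length <= 0:
        raise InvalidArgumentError(f"epoch_length must be positive, got {epoch_length}")
    if step <= 0:
        raise InvalidArgumentError(f"step must be positive, got {step}")
    epochs = []
    for start in range(0, recording.n_samples - epoch_length + 1, step):
        epochs.append(
            Epoch(
                data=recording.data[:, start : start + epoch_length].copy(),
                montage=recording.montage,
                sampling_rate=recording.sampling_rate,
                label=recording.label,
            )
        )
    return epochs


def _sos(band: Band, sampling_rate: float) -> np.ndarray:
    nyq = sampling_rate / 2.0
    if not band.high_hz < nyq:
        raise InvalidArgumentError(
            f"band {band.name!r} upper edge {band.high_hz} Hz is not below the "
            f"Nyquist frequency {nyq} Hz"
        )
    return sps.butter(
        4, [band.low_hz / nyq, band.high_hz / nyq], btype="bandpass", output="sos"
    )


def bandpass(epoch: Epoch, band: Band) -> BandFilteredEpoch:
    """Zero-phase 4th-order Butterworth band-pass of every channel.

    Forward-backward application cancels group delay, so in-band
    oscillations keep their phase; reflective padding limits edge
    transients.  Output shape equals input shape.
    """
    sos = _sos(band, epoch.sampling_rate)
    filtered = sps.sosfiltfilt(sos, epoch.data, axis=-1)
    return BandFilteredEpoch(band=band, data=filtered, parent=epoch)


def broadband(epoch: Epoch, band: Band = BROADBAND) -> Epoch:
    """Return the epoch filtered to the full 0.5-30 Hz analysis envelope."""
    sos = _sos(band, epoch.sampling_rate)
    return replace(epoch, data=sps.sosfiltfilt(sos, epoch.data, axis=-1))


def decompose(
    epoch: Epoch, bands: tuple[Band, ...] = DEFAULT_BANDS
) -> dict[str, BandFilteredEpoch]:
    """Apply every band filter to the epoch; one entry per configured band."""
    return {band.name: bandpass(epoch, band) for band in bands}
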