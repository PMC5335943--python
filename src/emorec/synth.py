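"""Synthetic consumer-headset EEG with emotion-dependent spectral structure.

The generator emulates a 14-channel, 128 Hz headset stream so the rest of
the pipeline (epoching, band filtering, Hjorth features, classification,
majority-vote feedback) can be exercised without hardware.  Each emotion
class is given a fixed spectral profile: per-band, per-channel gains applied
to band-limited Gaussian noise, summed with a pink (1/f) background.  The
profiles are fixtures that make the four classes statistically separable;
they are not claims about human physiology.

Amplitudes are on a microvolt-like scale (background plus band components
peak around +/-50 uV), which is cosmetic: every downstream feature is either
scale-aware (Hjorth activity) or scale-free (mobility, complexity), and
classifiers standardise features anyway.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from ._errors import InvalidArgumentError, ParseError

__all__ = [
    "EmotionLabel",
    "Montage",
    "DEFAULT_MONTAGE",
    "EEGRecording",
    "ClassSpectralProfile",
    "DEFAULT_PROFILES",
    "DEFAULT_SAMPLING_RATE",
    "generate_recording",
    "write_csv",
    "read_csv",
]

DEFAULT_SAMPLING_RATE = 128.0

#: The 14 data electrodes of the consumer headset montage, in stream order.
#: The CMS/DRL reference electrodes carry no signal and are metadata only.
DEFAULT_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

FRONTAL_CHANNELS = ("AF3", "F7", "F3", "FC5", "FC6", "F4", "F8", "AF4")
TEMPORAL_CHANNELS = ("T7", "T8")


class EmotionLabel(str, enum.Enum):
    """The four academic-emotion classes, one per valence-arousal quadrant."""

    HAPPY = "happy"    # +valence, +arousal
    CALM = "calm"      # +valence, -arousal
    SAD = "sad"        # -valence, -arousal
    SCARED = "scared"  # -valence, +arousal

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Montage:
    """Ordered electrode layout (10/20-derived labels)."""

    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    reference_note: str = "CMS/DRL average references at P3/P4; no data channels"

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InvalidArgumentError("montage channel names must be unique")
        if not self.channel_names:
            raise InvalidArgumentError("montage needs at least one channel")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise InvalidArgumentError(
                f"channel {name!r} not in montage {self.channel_names}"
            ) from None


DEFAULT_MONTAGE = Montage()


@dataclass
class EEGRecording:
    """Multichannel EEG time series: ``data`` is channels x samples."""

    data: np.ndarray
    montage: Montage = DEFAULT_MONTAGE
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    label: EmotionLabel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise InvalidArgumentError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not self.sampling_rate > 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class ClassSpectralProfile:
    """Per-band, per-channel amplitude gains plus background noise level.

    ``band_gains`` maps a band name to a length-``n_channels`` vector of
    non-negative multipliers applied to that band's unit-variance noise
    component.  ``background_amplitude`` is the rms of the pink-noise floor.
    """

    band_gains: dict[str, np.ndarray]
    background_amplitude: float = 10.0
    component_amplitude: float = 5.0

    def __post_init__(self) -> None:
        coerced = {b: np.asarray(g, dtype=float) for b, g in self.band_gains.items()}
        for band, g in coerced.items():
            if not np.all(np.isfinite(g)) or np.any(g < 0):
                raise InvalidArgumentError(f"gains for band {band!r} must be finite and >= 0")
        object.__setattr__(self, "band_gains", coerced)
        if self.background_amplitude < 0:
            raise InvalidArgumentError("background_amplitude must be >= 0")


def _make_default_profiles() -> dict[EmotionLabel, ClassSpectralProfile]:
    n = len(DEFAULT_CHANNELS)
    frontal = np.array([c in FRONTAL_CHANNELS for c in DEFAULT_CHANNELS])
    temporal = np.array([c in TEMPORAL_CHANNELS for c in DEFAULT_CHANNELS])

    def gains(**boost: tuple[np.ndarray, float]) -> dict[str, np.ndarray]:
        out = {b: np.ones(n) for b in ("delta", "theta", "alpha", "beta")}
        for band, (mask, factor) in boost.items():
            out[band] = np.where(mask, factor, 1.0)
        return out

    everywhere = np.ones(n, dtype=bool)
    return {
        EmotionLabel.CALM: ClassSpectralProfile(gains(alpha=(everywhere, 3.0))),
        EmotionLabel.HAPPY: ClassSpectralProfile(gains(beta=(frontal, 3.0))),
        EmotionLabel.SAD: ClassSpectralProfile(
            gains(delta=(frontal, 3.0), theta=(frontal, 3.0))
        ),
        EmotionLabel.SCARED: ClassSpectralProfile(
            gains(beta=(frontal | temporal, 2.5), theta=(frontal | temporal, 2.5))
        ),
    }


#: Fixed class-conditional spectral fixtures (see module docstring).
DEFAULT_PROFILES = _make_default_profiles()

# Band edges used by the generator; must agree with preprocessing defaults.
_GENERATOR_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

_LABEL_INDEX = {lab: i for i, lab in enumerate(EmotionLabel)}


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-rms 1/f-shaped Gaussian noise along the last axis."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0  # no DC offset
    pink = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    rms = pink.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return pink / rms


def generate_recording(
    label: EmotionLabel | str,
    duration: float,
    seed: int,
    profiles: dict[EmotionLabel, ClassSpectralProfile] | None = None,
    montage: Montage = DEFAULT_MONTAGE,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> EEGRecording:
    """Synthesise one labelled EEG recording.

    The signal is a sum over the four clinical bands of 4th-order
    Butterworth band-limited Gaussian noise (normalised to unit rms per
    channel, then scaled by the class profile's gain and the component
    amplitude) plus a pink background.  Identical ``(label, duration,
    seed)`` give bit-identical output; the label participates in the seed
    stream so different classes never share noise.
    """
    label = EmotionLabel(label)
    if not duration > 0:
        raise InvalidArgumentError(f"duration must be positive, got {duration}")
    profiles = DEFAULT_PROFILES if profiles is None else profiles
    profile = profiles[label]
    n_samples = int(round(duration * sampling_rate))
    n_ch = montage.n_channels

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_LABEL_INDEX[label],))
    )
    data = profile.background_amplitude * _pink_noise(rng, (n_ch, n_samples))
    nyq = sampling_rate / 2.0
    for band, (low, high) in _GENERATOR_BANDS.items():
        gains = profile.band_gains.get(band)
        if gains is None:
            continue
        sos = sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
        component = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n_samples)), axis=-1)
        rms = component.std(axis=-1, keepdims=True)
        rms[rms == 0] = 1.0
        data += profile.component_amplitude * gains[:, None] * component / rms
    return EEGRecording(
        data=data, montage=montage, sampling_rate=sampling_rate, label=label, seed=seed
    )


# ---------------------------------------------------------------------------
# CSV round-trip
#
# Dialect: UTF-8, '.' decimal; comment lines '# key=value' (fs mandatory,
# label/seed optional), then a channel-name header row, then one row per
# sample instant with one column per channel.


def write_csv(recording: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        rate = recording.sampling_rate
        fh.write(f"# fs={rate:g}\n")
        if recording.label is not None:
            fh.write(f"# label={recording.label.value}\n")
        if recording.seed is not None:
            fh.write(f"# seed={recording.seed}\n")
        fh.write(",".join(recording.montage.channel_names) + "\n")
        np.savetxt(fh, recording.data.T, fmt="%.10g", delimiter=",")


def read_csv(path: str | Path, montage: Montage | None = DEFAULT_MONTAGE) -> EEGRecording:
    """Parse a recording written by :func:`write_csv`.

    ``montage`` declares the expected layout; a header that does not match
    it is a :class:`ParseError`.  Pass ``montage=None`` to accept whatever
    channel set the file declares.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ParseError(f"malformed metadata comment {line!r}", lineno)
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                continue
            cells = line.split(",")
            if len(cells) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, found {len(cells)}", lineno
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ParseError(f"non-numeric cell: {exc}", lineno) from None

    if "fs" not in meta:
        raise ParseError("missing '# fs=<rate>' header")
    try:
        rate = float(meta["fs"])
    except ValueError:
        raise ParseError(f"invalid sampling rate {meta['fs']!r}") from None
    if header is None:
        raise ParseError("missing channel-name header row")
    if montage is not None and list(header) != list(montage.channel_names):
        raise ParseError(
            f"file lists {len(header)} channels {header!r}; expected montage "
            f"{list(montage.channel_names)!r}"
        )
    if not rows:
        raise ParseError("empty data section")

    label = EmotionLabel(meta["label"]) if "label" in meta else None
    seed = int(meta["seed"]) if "seed" in meta else None
    file_montage = montage if montage is not None else Montage(tuple(header), "from file")
    return EEGRecording(
        data=np.asarray(rows, dtype=float).T,
        montage=file_montage,
        sampling_rate=rate,
        label=label,
        seed=seed,
    )


def write_sidecar(recording: EEGRecording, path: str | Path) -> None:
    """Optional JSON sidecar carrying label/seed metadata."""
    payload = {
        "label": recording.label.value if recording.label else None,
        "seed": recording.seed,
        "sampling_rate": recording.sampling_rate,
        "channels": list(recording.montage.channel_names),
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
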