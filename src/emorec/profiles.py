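"""Training-session stimuli and per-user profile/treatment persistence.

Training sessions follow an affective-picture protocol: a manifest of 180
stimuli (45 per emotion), each tagged with its valence-arousal quadrant
(happy +v/+a, scared -v/+a, calm +v/-a, sad -v/-a).  Actual picture
content is out of scope — the manifest holds synthetic stimulus ids, which
is all the signal pipeline needs, and each entry drives the synthesis of a
stimulus-locked labelled recording.

A user profile accumulates labelled training epochs across sessions,
references the trained model, and stores an append-only, timestamped list
of treatment instructions per emotion.  Profiles persist as one versioned
JSON file per user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from ._errors import InvalidArgumentError, PersistenceError
from .preprocessing import DEFAULT_EPOCH_LENGTH, Epoch, segment
from .synth import (
    DEFAULT_MONTAGE,
    DEFAULT_SAMPLING_RATE,
    ClassSpectralProfile,
    EmotionLabel,
    Montage,
    generate_recording,
)

__all__ = [
    "QUADRANTS",
    "StimulusEntry",
    "StimulusManifest",
    "build_manifest",
    "record_training_session",
    "Treatment",
    "UserProfile",
    "add_or_update_treatment",
    "save_profile",
    "load_profile",
]

_PROFILE_FORMAT_VERSION = 1

#: Valence/arousal signs per emotion (+1 positive, -1 negative axis half).
QUADRANTS: dict[EmotionLabel, tuple[int, int]] = {
    EmotionLabel.HAPPY: (+1, +1),
    EmotionLabel.SCARED: (-1, +1),
    EmotionLabel.CALM: (+1, -1),
    EmotionLabel.SAD: (-1, -1),
}


@dataclass(frozen=True)
class StimulusEntry:
    stimulus_id: str
    label: EmotionLabel
    valence: int
    arousal: int
    duration_s: float

    def __post_init__(self) -> None:
        if (self.valence, self.arousal) != QUADRANTS[self.label]:
            raise InvalidArgumentError(
                f"stimulus {self.stimulus_id}: quadrant ({self.valence}, "
                f"{self.arousal}) inconsistent with label {self.label.value}"
            )


@dataclass
class StimulusManifest:
    entries: list[StimulusEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def per_class_counts(self) -> dict[EmotionLabel, int]:
        out = {lab: 0 for lab in EmotionLabel}
        for e in self.entries:
            out[e.label] += 1
        return out

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "stimulus_id": e.stimulus_id,
                "label": e.label.value,
                "valence": e.valence,
                "arousal": e.arousal,
                "duration_s": e.duration_s,
            }
            for e in self.entries
        ]
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusManifest":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            entries=[
                StimulusEntry(
                    stimulus_id=e["stimulus_id"],
                    label=EmotionLabel(e["label"]),
                    valence=e["valence"],
                    arousal=e["arousal"],
                    duration_s=e["duration_s"],
                )
                for e in raw
            ]
        )


def build_manifest(
    per_class: int = 45, seed: int = 0, display_duration: float = 3.0
) -> StimulusManifest:
    """Build a quadrant-consistent stimulus manifest, shuffled by seed.

    The default reproduces the study protocol: 45 stimuli per emotion,
    180 in total.  Display duration defaults to 3 s per stimulus.
    """
    if per_class < 1:
        raise InvalidArgumentError(f"per_class must be >= 1, got {per_class}")
    entries = [
        StimulusEntry(
            stimulus_id=f"stim_{label.value}_{i:03d}",
            label=label,
            valence=QUADRANTS[label][0],
            arousal=QUADRANTS[label][1],
            duration_s=display_duration,
        )
        for label in EmotionLabel
        for i in range(per_class)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    return StimulusManifest(entries=[entries[i] for i in order])


def record_training_session(
    manifest: StimulusManifest,
    seed: int = 0,
    epoch_length: int = DEFAULT_EPOCH_LENGTH,
    profiles: dict[EmotionLabel, ClassSpectralProfile] | None = None,
    montage: Montage = DEFAULT_MONTAGE,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> list[Epoch]:
    """Simulate one stimulus-locked recording session.

    For each manifest entry a recording of the entry's display duration is
    synthesised under that entry's emotion profile, segmented into
    non-overlapping epochs, and the epochs are labelled with the stimulus
    emotion.  Per-entry seeds are derived deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    entry_seeds = rng.integers(0, 2**31 - 1, size=len(manifest.entries))
    epochs: list[Epoch] = []
    for entry, entry_seed in zip(manifest.entries, entry_seeds):
        rec = generate_recording(
            entry.label,
            entry.duration_s,
            seed=int(entry_seed),
            profiles=profiles,
            montage=montage,
            sampling_rate=sampling_rate,
        )
        epochs.extend(segment(rec, epoch_length=epoch_length))
    return epochs


@dataclass(frozen=True)
class Treatment:
    emotion: EmotionLabel
    text: str
    author: str
    timestamp: str  # ISO-8601 UTC

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise InvalidArgumentError("treatment text must be non-empty")


@dataclass
class UserProfile:
    """Per-user store: labelled epochs, model reference, treatments."""

    user_id: str
    name: str = ""
    epochs: list[Epoch] = field(default_factory=list)
    model_ref: str | None = None
    treatments: dict[EmotionLabel, list[Treatment]] = field(default_factory=dict)

    def add_epochs(self, new_epochs: list[Epoch]) -> None:
        unlabeled = [i for i, e in enumerate(new_epochs) if e.label is None]
        if unlabeled:
            raise InvalidArgumentError(
                f"stored epochs must be labelled; epochs {unlabeled[:5]} are not"
            )
        self.epochs.extend(new_epochs)

    def treatments_for(self, emotion: EmotionLabel) -> list[Treatment]:
        return list(self.treatments.get(EmotionLabel(emotion), []))


def add_or_update_treatment(
    profile: UserProfile, emotion: EmotionLabel | str, text: str, author: str = ""
) -> UserProfile:
    """Append a treatment instruction under the emotion key.

    Treatment history is append-only with non-decreasing timestamps; the
    instructor "updates" a plan by appending a newer entry.
    """
    emotion = EmotionLabel(emotion)
    if not text or not text.strip():
        raise InvalidArgumentError("treatment text must be non-empty")
    now = datetime.now(timezone.utc).isoformat()
    existing = profile.treatments.setdefault(emotion, [])
    if existing and existing[-1].timestamp > now:
        now = existing[-1].timestamp  # clock skew guard: keep monotone
    existing.append(Treatment(emotion=emotion, text=text, author=author, timestamp=now))
    return profile


# ---------------------------------------------------------------------------
# Profile persistence (versioned JSON, one file per user)


def save_profile(profile: UserProfile, path: str | Path) -> None:
    payload = {
        "format_version": _PROFILE_FORMAT_VERSION,
        "user_id": profile.user_id,
        "name": profile.name,
        "model_ref": profile.model_ref,
        "epochs": [
            {
                "label": e.label.value,
                "sampling_rate": e.sampling_rate,
                "channels": list(e.montage.channel_names),
                "data": e.data.tolist(),
            }
            for e in profile.epochs
        ],
        "treatments": {
            emotion.value: [
                {"text": t.text, "author": t.author, "timestamp": t.timestamp}
                for t in items
            ]
            for emotion, items in profile.treatments.items()
        },
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_profile(path: str | Path) -> UserProfile:
    try:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise PersistenceError(f"cannot read profile {path}: {exc}") from exc
    version = raw.get("format_version")
    if version != _PROFILE_FORMAT_VERSION:
        raise PersistenceError(
            f"profile format version {version!r} not supported "
            f"(expected {_PROFILE_FORMAT_VERSION})"
        )
    epochs = [
        Epoch(
            data=np.asarray(e["data"], dtype=float),
            montage=Montage(tuple(e["channels"]), "restored from profile"),
            sampling_rate=e["sampling_rate"],
            label=EmotionLabel(e["label"]),
        )
        for e in raw["epochs"]
    ]
    treatments = {
        EmotionLabel(emotion): [
            Treatment(
                emotion=EmotionLabel(emotion),
                text=t["text"],
                author=t["author"],
                timestamp=t["timestamp"],
            )
            for t in items
        ]
        for emotion, items in raw["treatments"].items()
    }
    return UserProfile(
        user_id=raw["user_id"],
        name=raw["name"],
        epochs=epochs,
        model_ref=raw["model_ref"],
        treatments=treatments,
    )
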