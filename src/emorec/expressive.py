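"""Expressive mode: per-epoch inference smoothed by majority vote.

A consumer headset's single-epoch decisions are noisy, so the recogniser
does not report every 1.5 s epoch.  Instead it collects ten consecutive
epoch decisions per 15 s window and emits one feedback per window: the
modal emotion, with ties resolved in favour of the tied label seen most
recently (the subject's current state wins in a monitoring context).  If
the winning emotion is unpleasant (sad or scared), the feedback carries
the treatment texts stored for that emotion in the user's profile so the
instructor can act on them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._errors import InvalidArgumentError
from .classification import EmotionModel, predict
from .features import FRONTAL_CENTRAL_6, ChannelSubset, extract_features
from .preprocessing import DEFAULT_BANDS, DEFAULT_EPOCH_LENGTH, Band, segment
from .synth import EEGRecording, EmotionLabel

__all__ = [
    "UNPLEASANT",
    "DEFAULT_DECISIONS_PER_WINDOW",
    "EmotionFeedback",
    "majority_vote",
    "run_expressive",
]

#: Negative-valence half of the four academic emotions.
UNPLEASANT = frozenset({EmotionLabel.SAD, EmotionLabel.SCARED})

#: Ten epoch decisions per window: 10 x 1.5 s epochs = one 15 s window.
DEFAULT_DECISIONS_PER_WINDOW = 10


@dataclass
class EmotionFeedback:
    """One aggregated decision for a complete window."""

    label: EmotionLabel
    window_index: int
    vote_counts: dict[EmotionLabel, int]
    treatments_shown: list[str] = field(default_factory=list)


def majority_vote(decisions: list[EmotionLabel]) -> EmotionLabel:
    """The label with the highest count; ties go to the most recent one.

    "Most recent" means the tied label whose last occurrence is latest in
    the list, so the vote is deterministic and favours current evidence.
    """
    if not decisions:
        raise InvalidArgumentError("majority_vote needs a non-empty decision list")
    decisions = [EmotionLabel(d) for d in decisions]
    counts = Counter(decisions)
    top = max(counts.values())
    tied = {label for label, c in counts.items() if c == top}
    for d in reversed(decisions):
        if d in tied:
            return d
    raise AssertionError("unreachable")  # pragma: no cover


def run_expressive(
    recording: EEGRecording,
    model: EmotionModel,
    profile=None,
    epoch_length: int = DEFAULT_EPOCH_LENGTH,
    decisions_per_window: int = DEFAULT_DECISIONS_PER_WINDOW,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    subset: ChannelSubset = FRONTAL_CENTRAL_6,
) -> list[EmotionFeedback]:
    """Simulate the live loop over a stored recording.

    The recording is cut into non-overlapping epochs aligned to its start;
    each epoch is filtered, featurised with the model's feature family and
    classified; every ``decisions_per_window`` consecutive decisions are
    merged into one :class:`EmotionFeedback`.  A trailing group shorter
    than a full window yields no feedback.  ``profile`` may be a
    :class:`~emorec.profiles.UserProfile` (or None); stored treatments are
    attached for unpleasant outcomes.
    """
    if decisions_per_window < 1:
        raise InvalidArgumentError("decisions_per_window must be >= 1")
    epochs = segment(recording, epoch_length=epoch_length, step=epoch_length)
    if not epochs:
        raise InvalidArgumentError(
            f"recording ({recording.n_samples} samples) is shorter than one "
            f"epoch ({epoch_length} samples)"
        )
    X, _, _ = extract_features(epochs, family=model.feature_family,
                               subset=subset, bands=bands)
    if X.shape[1] != model.n_features:
        raise InvalidArgumentError(
            f"feature family {model.feature_family!r} on this montage yields "
            f"{X.shape[1]} features; model expects {model.n_features}"
        )
    decisions = [predict(model, row) for row in X]

    feedbacks: list[EmotionFeedback] = []
    n_windows = len(decisions) // decisions_per_window
    for w in range(n_windows):
        window = decisions[w * decisions_per_window : (w + 1) * decisions_per_window]
        winner = majority_vote(window)
        counts = Counter(window)
        treatments: list[str] = []
        if winner in UNPLEASANT and profile is not None:
            treatments = [t.text for t in profile.treatments_for(winner)]
        feedbacks.append(
            EmotionFeedback(
                label=winner,
                window_index=w,
                vote_counts={lab: counts.get(lab, 0) for lab in EmotionLabel},
                treatments_shown=treatments,
            )
        )
    return feedbacks
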