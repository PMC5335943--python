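"""Full expressive-mode loop: train, store a treatment, monitor a stream.

Trains a model, stores a treatment instruction for "sad", then simulates a
45 s live stream (calm, then sad, then happy, 15 s each).  One feedback is
emitted per 15 s window: the majority label of its ten 1.5 s epoch
decisions, with the stored treatment attached when the outcome is an
unpleasant state.
"""

import numpy as np

import emorec as er

# training: 15 s per class is 10 epochs per class
epochs = []
for i, label in enumerate(er.EmotionLabel):
    epochs.extend(er.segment(er.generate_recording(label, 15, seed=10 + i)))
X, labels, _ = er.extract_features(epochs, family="hjorth14")
model = er.train(X, labels, method="svm", seed=0)

profile = er.UserProfile(user_id="student-01", name="Student One")
er.add_or_update_treatment(profile, "sad", "offer break time", author="instructor")

stream = er.EEGRecording(
    data=np.hstack([
        er.generate_recording("calm", 15, seed=1).data,
        er.generate_recording("sad", 15, seed=2).data,
        er.generate_recording("happy", 15, seed=3).data,
    ])
)
for fb in er.run_expressive(stream, model, profile=profile):
    votes = {k.value: v for k, v in fb.vote_counts.items() if v}
    print(f"window {fb.window_index}: {fb.label.value:>6}  votes={votes}  "
          f"treatments={fb.treatments_shown}")
print()
print("Three windows, one decision each; the sad window carries the stored")
print("treatment text so the instructor can act on it.")
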