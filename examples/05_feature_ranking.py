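"""Mutual-information feature ranking on a controlled example.

Plants one feature that copies the class code among 50 noise features and
shows that the plug-in MI estimator (8 equal-frequency bins) ranks it
first, with noise features all near zero MI.
"""

import numpy as np

import emorec as er
from emorec.features import mutual_information

rng = np.random.default_rng(0)
y = rng.integers(0, 4, 200)
X = np.column_stack([rng.standard_normal((200, 25)), y.astype(float),
                     rng.standard_normal((200, 25))])

ranking = er.mi_rank(X, y)
print(f"informative feature is column 25; top of ranking: {ranking[:5].tolist()}")
print(f"MI of class-copy feature : {mutual_information(X[:, 25], y):.3f} nats")
print(f"MI of a noise feature    : {mutual_information(X[:, 0], y):.3f} nats")
print()
print("ln(4) = 1.386 nats is the ceiling for a 4-class label; the class-copy")
print("feature sits at it while noise features sit near zero, so the ranking")
print("is unambiguous.")
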