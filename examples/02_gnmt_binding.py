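"""Two-site binding of 5mTHF to GNMT and the half-activity hypothesis.

Titrates 5mTHF against 1 uM of GNMT at equilibrium.  The bound-ligand curve
rises above 1 uM — direct evidence for two binding sites — and the
fractional activity computed with weights (1, 0.5, 0) (free enzyme fully
active, singly bound half active, doubly bound dead) reproduces the
published inhibition summary (15 % inhibition at 0.1 uM, 50 % at 1 uM,
90 % at 10 uM) far better than the all-or-nothing hypothesis (1, 0, 0).
"""

import numpy as np

from onecarbon import ActivityWeights, default_parameters, titration_experiment

p = default_parameters()
grid = np.array([0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0])

half = titration_experiment(grid, 1.0, ActivityWeights(1.0, 0.5, 0.0), p)
dead = titration_experiment(grid, 1.0, ActivityWeights(1.0, 0.0, 0.0), p)

print("total 5mTHF  bound   activity(1,.5,0)  activity(1,0,0)")
for t, b, a1, a2 in zip(grid, half.bound, half.activity, dead.activity):
    print(f"{t:10.1f} {b:7.3f} {a1:15.3f} {a2:16.3f}")

data = [(0.1, 0.85), (1.0, 0.50), (10.0, 0.10)]
for w, curve in (("(1, 0.5, 0)", half), ("(1, 0, 0)", dead)):
    sse = sum(
        (curve.activity[np.argmin(np.abs(grid - t))] - a) ** 2 for t, a in data
    )
    print(f"SSE vs published inhibition points, weights {w}: {sse:.4f}")
print("-> once-bound GNMT retaining half its activity fits the data")
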