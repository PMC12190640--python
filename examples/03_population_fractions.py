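"""Recover conformational populations from a simulated cohort.

Simulates 80 molecules at zero Mg (true populations 59.7 / 21.7 / 18.6 %),
runs the full pipeline (selection, HMM idealization, pooled histogram,
three-Gaussian mixture), and prints the recovered fractions.  At this
cohort size the weights typically land within ~2-3 percentage points of
the truth; the study-scale run (574 molecules) is tighter.
"""

import numpy as np

import ribofret as rf

fixture = rf.get_fixture("noMg_occupancy")
ts, _ = rf.generate_dataset(fixture, n_molecules=80, seed=2)
result = rf.analyze_traceset(ts)

print(f"accepted {result.n_accepted}/{result.n_input} traces")
print("population fractions (truth 0.597 / 0.217 / 0.186):")
for w, m, s in zip(result.mixture.weights, result.mixture.means, result.mixture.sigmas):
    d = rf.efret_to_distance(m)
    print(f"  E ~ {m:.2f}: {100 * w:5.1f} %   (sigma {s:.3f}, "
          f"dye separation ~{d.r:.0f} A at R0 = 55 A)")
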