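"""Constrained warping distance between behavioral series.

Shows the cumulative-cost alignment on small sequences, the effect of the
off-diagonal skip penalty, and the class-medoid template distances used as
behavioral features.
"""

import numpy as np

from neurovibe import feature_extraction as fx

a = [0.0, 1.0, 2.0, 1.0, 0.0]
b = [0.0, 0.0, 1.0, 2.0, 1.0, 0.0]   # same shape, delayed by one step

free = fx.idtw(a, b, w=1.0, alpha=1.0, p=0.0)
print(f"distance with free insertions: {free.distance:.3f}")
print(f"optimal path: {free.path}")

penalized = fx.idtw(a, b, w=1.0, alpha=1.0, p=0.5)
print(f"distance with skip penalty 0.5: {penalized.distance:.3f}")
print("The delayed copy aligns at zero cost when off-diagonal steps are "
      "free; each insertion/deletion then costs alpha*p on top.")

rng = np.random.default_rng(0)
class0 = [np.sin(np.linspace(0, 6, 30)) + 0.2 * rng.normal(size=30)
          for _ in range(5)]
class1 = [np.sin(np.linspace(0, 6, 30) + 1.5) + 0.2 * rng.normal(size=30)
          for _ in range(5)]
templates = {"class0": class0[fx.idtw_medoid(class0)],
             "class1": class1[fx.idtw_medoid(class1)]}
probe = class1[3]
feats = fx.idtw_reference_features(probe, templates)
print({k: round(v, 2) for k, v in feats.items()})
print("A class-1 series should sit closer to the class-1 medoid template.")
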