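"""Enrichment metrics: top-n pose enrichment and compound enrichment factors.

ef(nu) = ap^-1 * a(nu)/n(nu): the active fraction among the top nu-percentile
of a ranked compound list, relative to the overall active fraction ap.
ef(1) = 1 always; the ceiling is 1/ap when every active is ranked on top.
"""

import numpy as np

from poseranker import enrichment_factor, topn_pose_enrichment

# 10 compounds, 2 actives both in the top half -> ef(0.5) = (0.2)^-1 * 2/5 = 2
scores = np.arange(10, 0, -1, dtype=float)
active = np.zeros(10, dtype=bool)
active[[0, 3]] = True
curve = enrichment_factor(scores, active, [0.1, 0.5, 1.0])
for nu, ef, a, n in zip(curve.x, curve.values, curve.info["a"], curve.info["n"]):
    print(f"ef({nu:.1f}) = {ef:.2f}   ({a} actives in top {n}, ap = "
          f"{curve.info['ap']:.2f})")

# pose enrichment: three docking attempts whose first hit sits at rank 1, 2, 16
attempts = [[1.0] + [9.0] * 15,
            [9.0, 2.0] + [9.0] * 14,
            [9.0] * 15 + [1.5]]
pose_curve = topn_pose_enrichment(attempts, n_max=16)
print("\ntop-n pose enrichment (fraction of attempts with a <=2.5 A pose "
      "in the top n):")
for n in (1, 2, 16):
    print(f"  n={n:>2}: {pose_curve.values[n - 1]:.3f}")
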