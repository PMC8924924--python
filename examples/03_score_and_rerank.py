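"""Score poses with the graph network and rerank a docking attempt.

An untrained network already demonstrates the architecture's contracts: the
logit is invariant to rigid motion of the complex (all inputs are pairwise
distances and types) and reranking is a stable permutation of the pose set.
"""

from dataclasses import replace

import numpy as np

from poseranker import GraphiteNet, SyntheticSpec, gen_poses, gen_target
from poseranker.synthetic import _random_rotation, restricted_vocabulary

spec = SyntheticSpec(seed=3, n_poses=16)
target = gen_target(spec, 0)
poses = gen_poses(target, spec)

net = GraphiteNet("l->l->r->l->r->l", vocab=restricted_vocabulary(), seed=0)
logit = net.score(poses[0])
rng = np.random.default_rng(0)
R, t = _random_rotation(rng), rng.normal(0, 10, 3)
moved = replace(poses[0],
                receptor=poses[0].receptor.with_coords(
                    poses[0].receptor.coords @ R.T + t),
                pose=replace(poses[0].pose,
                             coords=poses[0].pose.coords @ R.T + t))
print(f"logit {logit:+.6f}, after rigid motion {net.score(moved):+.6f} "
      "(identical up to numerical noise)")

ranked = net.rescore_attempt(poses)
print("rank  logit     label  docking_rank")
for sp in ranked[:5]:
    print(f"{sp.rank:>4}  {sp.logit:+.4f}  {sp.example.label:<5}"
          f"  {sp.docking_rank}")
print("(untrained weights: the ordering is arbitrary but deterministic)")
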