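"""Cross-docking curation: superposition, binding-site clustering, splits.

Structures of one target are superposed onto a reference (members fitting
worse than 5 A are dropped), binding sites are found by density-clustering
superposed ligand centers of mass at eps = 5 A, and targets are assigned to
train/test so that no pair across the boundary exceeds the sequence-identity
threshold.
"""

import numpy as np

from poseranker import SyntheticSpec, gen_study, make_split, superpose_group
from poseranker.crossdock import cluster_binding_sites, max_boundary_identity

study = gen_study(SyntheticSpec(seed=4, n_targets=8, structures_per_target=3,
                                n_poses=8))
target = study.targets[0]
members = [(f"c{i}", rec) for i, rec in
           enumerate(study.conformations[target.target_id])]
ligands = [(target.ligand, target.native_pose)] * len(members)
group = superpose_group(members, target.target_id, ligands=ligands)
print(f"{target.target_id}: {len(group.members)} conformations superposed, "
      f"CA-equivalent RMSDs {[round(m.ca_rmsd, 2) for m in group.members]} A")
clusters = cluster_binding_sites(group)
print(f"binding-site clusters: {len(clusters)} "
      "(one pocket per synthetic target)")

split = make_split(study.sequences(), "seqsim70", seed=0)
n_train = sum(1 for s in split.assignment.values() if s == "train")
print(f"seqsim70 split: {n_train} train / "
      f"{len(split.assignment) - n_train} test targets")
print(f"max train-test boundary identity: "
      f"{max_boundary_identity(study.sequences(), split):.2f} (< 0.70)")
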