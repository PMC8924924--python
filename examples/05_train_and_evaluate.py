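"""Train the pose classifier on a small synthetic study and evaluate it.

Uses a reduced study (12 targets, two receptor conformations each) so the
script finishes in a few minutes; the full-scale run lives in
scripts/acceptance.py.  Training is binary cross-entropy on the
logit with gap poses dropped from training (but kept in the test set) and
balanced hit/miss sampling per epoch.
"""

from poseranker import SyntheticSpec, gen_study
from poseranker.crossdock import make_split, positive_pose_filter
from poseranker.synthetic import restricted_vocabulary
from poseranker.traineval import (TrainingConfig, evaluate, group_by_attempt,
                                  split_examples, train)

study = gen_study(SyntheticSpec(seed=5, n_targets=12, structures_per_target=2))
examples = study.all_examples()
split = make_split(study.sequences(), "uniprot", seed=5,
                   uniprot_of=study.uniprot_map())
train_ex, test_ex = split_examples(examples, split.assignment)
kept = positive_pose_filter(group_by_attempt(train_ex))
train_ex = [ex for poses in kept.values() for ex in poses]
print(f"{len(train_ex)} training poses (hit-bearing attempts), "
      f"{len(test_ex)} test poses")

config = TrainingConfig(seed=5)
net, history = train(train_ex, "l->l->r->l->r->l", config,
                     vocab=restricted_vocabulary())
print(f"final epoch loss {history['loss'][-1]:.3f}, "
      f"validation ROC AUC {history['val_auc'][-1]:.3f}")

report = evaluate(net, test_ex)
print(f"held-out targets: ROC AUC {report['roc_auc']:.3f}, "
      f"PR AUC {report['pr_auc']:.3f}")
print(f"top-1 hit fraction: model {report['top1_model']:.2f} "
      f"vs docking-score ranking {report['top1_docking']:.2f}")
# ROC AUC near 1 means hit poses outscore misses on unseen targets; the top-1
# numbers compare how often the best-ranked pose is within 2.5 A of native.
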