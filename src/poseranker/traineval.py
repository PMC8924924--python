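"""Training loop for hit-vs-miss pose classification, and evaluation metrics.

Training minimizes binary cross-entropy on the ranking logit (hit = 1,
miss = 0).  Gap poses — RMSD between 2.5 and 4 Å — are discarded from the
training set but retained in test sets, and the heavy class imbalance
(roughly 5% hits) is handled by per-epoch balanced sampling of hits and
misses (a weighted-loss alternative is available).  Validation holds out 10%
of the training targets by target id.  Everything is deterministic given the
config seed.

Evaluation covers the standard virtual-screening summaries: ROC AUC
(probability that a random hit outscores a random miss), PR AUC (average
precision), the top-n pose-enrichment curve (fraction of docking attempts
whose best pose among the n highest-ranked is within 2.5 Å of native), and
the compound enrichment factor ef(ν) = ap⁻¹ · a(ν)/n(ν).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .graphite import GraphiteNet, GraphiteParams
from .io_model import HIT, MISS, ComplexExample
from .poselabel import HIT_THRESHOLD
from .sybyl import SybylVocabulary


class UndefinedMetricError(ValueError):
    """A metric needs both classes (or at least one active) to be defined."""


class SingleClassError(ValueError):
    """The training set lacks hits or misses after gap removal."""


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_schedule: str = "constant"      # "constant" or "cosine" (decay to ~0)
    imbalance: str = "balanced"        # "balanced" or "weighted"
    seed: int = 0
    split_kind: str = "uniprot"
    gap_policy: str = "drop_in_train_keep_in_test"  # fixed; the only policy
    validation_fraction: float = 0.10
    # model hyperparameters
    channels: int = 64
    hidden: int = 128
    n_basis: int = 16
    # mean pooling for training: pooled readouts become size-invariant, which
    # keeps logits calibrated across targets of different ligand/pocket size
    pooling: str = "mean"

    def __post_init__(self) -> None:
        if self.gap_policy != "drop_in_train_keep_in_test":
            raise ValueError("gap policy is fixed: drop in train, keep in test")
        if self.imbalance not in ("balanced", "weighted"):
            raise ValueError(f"unknown imbalance strategy {self.imbalance!r}")


class Adam:
    """Adam optimizer over a :class:`GraphiteParams` map."""

    def __init__(self, params: GraphiteParams, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = params.zeros_like()
        self.v = params.zeros_like()
        self.t = 0

    def step(self, params: GraphiteParams, grads: GraphiteParams) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params.keys():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + exp(-|z|)) form
    return np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))


def train(examples: list[ComplexExample], layer_spec: str,
          config: TrainingConfig | None = None,
          vocab: SybylVocabulary | None = None,
          cutoffs=None) -> tuple[GraphiteNet, dict]:
    """Train a GRAPHite pose classifier on labeled complexes.

    ``examples`` is the *training-side* pose set (labels hit/gap/miss); gaps
    are dropped here per the gap policy.  Returns the trained network and a
    history dict with per-epoch mean loss and validation ROC AUC.
    """
    config = config or TrainingConfig()
    rng = np.random.default_rng(config.seed)

    target_ids = sorted({ex.metadata.get("target_id", "?") for ex in examples})
    n_val = max(1, round(config.validation_fraction * len(target_ids))) \
        if len(target_ids) > 1 else 0
    shuffled = list(rng.permutation(target_ids))
    val_targets = set(shuffled[:n_val])

    def side_of(ex: ComplexExample) -> str:
        return "val" if ex.metadata.get("target_id", "?") in val_targets else "train"

    train_ex = [ex for ex in examples
                if side_of(ex) == "train" and ex.label in (HIT, MISS)]
    val_ex = [ex for ex in examples
              if side_of(ex) == "val" and ex.label in (HIT, MISS)]
    hits = [ex for ex in train_ex if ex.label == HIT]
    misses = [ex for ex in train_ex if ex.label == MISS]
    if not hits or not misses:
        raise SingleClassError("training set needs at least one hit and one miss")

    net = GraphiteNet(layer_spec, vocab=vocab, channels=config.channels,
                      hidden=config.hidden, n_basis=config.n_basis,
                      pooling=config.pooling, seed=config.seed, cutoffs=cutoffs)
    prep_hits = [net.prepare(ex) for ex in hits]
    prep_misses = [net.prepare(ex) for ex in misses]
    prep_val = [net.prepare(ex) for ex in val_ex]
    val_labels = np.array([1.0 if ex.label == HIT else 0.0 for ex in val_ex])

    optimizer = Adam(net.params, lr=config.learning_rate)
    pos_weight = len(misses) / len(hits)
    history = {"loss": [], "val_auc": []}
    grads = net.params.zeros_like()
    val_merged = [net.merge_prepared(prep_val[i:i + 512])
                  for i in range(0, len(prep_val), 512)]

    for _epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            optimizer.lr = config.learning_rate * 0.5 * (
                1.0 + math.cos(math.pi * _epoch / max(config.epochs, 1)))
        if config.imbalance == "balanced":
            sel = rng.choice(len(prep_misses), size=len(prep_hits),
                             replace=len(prep_misses) < len(prep_hits))
            batch_pool = [(p, 1.0, 1.0) for p in prep_hits] + \
                         [(prep_misses[i], 0.0, 1.0) for i in sel]
        else:
            batch_pool = [(p, 1.0, pos_weight) for p in prep_hits] + \
                         [(p, 0.0, 1.0) for p in prep_misses]
        order = rng.permutation(len(batch_pool))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            merged = net.merge_prepared([batch_pool[i][0] for i in idx])
            ys = np.array([batch_pool[i][1] for i in idx])
            ws = np.array([batch_pool[i][2] for i in idx])
            logits, cache = net.forward_batch(merged, with_cache=True)
            logits = np.atleast_1d(logits)
            probs = _sigmoid(logits)
            losses.extend(_bce(logits, ys) * ws)
            for k in grads.keys():
                grads[k].fill(0.0)
            net.backward_batch(cache, (probs - ys) * ws / ws.sum(), out=grads)
            optimizer.step(net.params, grads)
        history["loss"].append(float(np.mean(losses)) if losses else float("nan"))
        if val_merged and len(set(val_labels)) == 2:
            val_scores = np.concatenate(
                [np.atleast_1d(net.forward_batch(m)) for m in val_merged])
            history["val_auc"].append(roc_auc(val_scores, val_labels))
        else:
            history["val_auc"].append(float("nan"))
    history["val_targets"] = sorted(val_targets)
    return net, history


# ---------------------------------------------------------------------------
# Metrics


def roc_auc(scores, labels) -> float:
    """ROC AUC: probability a random positive outranks a random negative
    (ties count one half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("ROC AUC needs both classes")
    return float(roc_auc_score(labels, np.asarray(scores)))


def pr_auc(scores, labels) -> float:
    """PR AUC as average precision (step integration, no interpolation)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("PR AUC needs both classes")
    return float(average_precision_score(labels, np.asarray(scores)))


@dataclass(frozen=True)
class EnrichmentCurve:
    """Ranked-list summary: a pose-enrichment curve over rank n, or compound
    enrichment factors over percentile ν."""

    kind: str           # "pose_topn" or "compound_ef"
    x: np.ndarray       # ranks 1..n_max, or ν values
    values: np.ndarray
    info: dict = field(default_factory=dict)


def topn_pose_enrichment(ranked_rmsds: list[list[float]],
                         n_max: int = 16,
                         threshold: float = HIT_THRESHOLD) -> EnrichmentCurve:
    """Fraction of attempts whose best top-n pose is within the hit threshold.

    ``ranked_rmsds[k]`` lists the RMSDs of attempt k's poses in rank order
    (rank 1 first) under the ranking being scored.
    """
    if not ranked_rmsds:
        raise ValueError("no docking attempts")
    values = np.empty(n_max)
    for n in range(1, n_max + 1):
        good = sum(1 for rmsds in ranked_rmsds
                   if len(rmsds) and min(rmsds[:n]) <= threshold)
        values[n - 1] = good / len(ranked_rmsds)
    return EnrichmentCurve(kind="pose_topn", x=np.arange(1, n_max + 1),
                           values=values,
                           info={"threshold": threshold,
                                 "n_attempts": len(ranked_rmsds)})


def enrichment_factor(scores, active, nus) -> EnrichmentCurve:
    """Compound enrichment factors ef(ν) = ap⁻¹ · a(ν)/n(ν).

    ``ap`` is the overall active fraction, ``n(ν) = ⌈ν·N⌉`` the number of
    compounds in the top ν-percentile of the score ranking (ties broken by
    stable input order), and ``a(ν)`` the actives among them.
    """
    scores = np.asarray(scores, dtype=float)
    active = np.asarray(active, dtype=bool)
    n_total = len(scores)
    if n_total == 0 or scores.shape != active.shape:
        raise ValueError("scores and active flags must be matching non-empty arrays")
    n_actives = int(active.sum())
    if n_actives == 0:
        raise UndefinedMetricError("enrichment factor needs at least one active")
    ap = n_actives / n_total
    order = np.argsort(-scores, kind="stable")
    ranked_active = active[order]
    nus = np.asarray(nus, dtype=float)
    if np.any(nus <= 0) or np.any(nus > 1):
        raise ValueError("ν must lie in (0, 1]")
    values = np.empty(len(nus))
    a_list, n_list = [], []
    for i, nu in enumerate(nus):
        n_nu = int(math.ceil(nu * n_total))
        a_nu = int(ranked_active[:n_nu].sum())
        values[i] = (a_nu / n_nu) / ap
        a_list.append(a_nu)
        n_list.append(n_nu)
    return EnrichmentCurve(kind="compound_ef", x=nus, values=values,
                           info={"ap": ap, "a": a_list, "n": n_list,
                                 "tie_break": "stable input order"})


# ---------------------------------------------------------------------------
# Evaluation


def group_by_attempt(examples: list[ComplexExample]) -> dict[str, list[ComplexExample]]:
    attempts: dict[str, list[ComplexExample]] = {}
    for ex in examples:
        attempts.setdefault(ex.metadata.get("attempt_id", "?"), []).append(ex)
    return attempts


def evaluate(net: GraphiteNet, examples: list[ComplexExample],
             n_max: int = 16) -> dict:
    """Full evaluation report on a labeled test set (gaps retained).

    Reports hit-vs-miss ROC/PR AUC of the logits, the top-n pose-enrichment
    curves under the model ranking and the original docking ranking, and the
    top-1 fractions of both.
    """
    attempts = group_by_attempt(examples)
    model_ranked, dock_ranked = [], []
    all_scores, all_labels = [], []
    for poses in attempts.values():
        scored = net.rescore_attempt(poses)
        model_ranked.append([sp.example.metadata["rmsd"] for sp in scored])
        by_dock = sorted(poses, key=lambda ex: ex.pose.rank)
        dock_ranked.append([ex.metadata["rmsd"] for ex in by_dock])
        for sp in scored:
            if sp.example.label in (HIT, MISS):
                all_scores.append(sp.logit)
                all_labels.append(1.0 if sp.example.label == HIT else 0.0)
    model_curve = topn_pose_enrichment(model_ranked, n_max=n_max)
    dock_curve = topn_pose_enrichment(dock_ranked, n_max=n_max)
    report = {
        "n_attempts": len(attempts),
        "n_poses": len(examples),
        "roc_auc": roc_auc(all_scores, all_labels),
        "pr_auc": pr_auc(all_scores, all_labels),
        "pose_enrichment_model": model_curve.values.tolist(),
        "pose_enrichment_docking": dock_curve.values.tolist(),
        "top1_model": float(model_curve.values[0]),
        "top1_docking": float(dock_curve.values[0]),
    }
    return report


def split_examples(examples: list[ComplexExample], assignment: dict[str, str],
                   ) -> tuple[list[ComplexExample], list[ComplexExample]]:
    """Partition examples into (train, test) by their target id."""
    train = [ex for ex in examples
             if assignment.get(ex.metadata.get("target_id")) == "train"]
    test = [ex for ex in examples
            if assignment.get(ex.metadata.get("target_id")) == "test"]
    return train, test
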