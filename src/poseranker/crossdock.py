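"""Cross-docking dataset construction and train/test splitting.

Structures sharing a target (Uniprot-like) identifier are rigidly superposed
onto a reference member (CA atoms, least squares), members fitting worse than
5 Å are dropped, and distinct binding sites within the target are found by
density-clustering the centers of mass of the superposed ligands (DBSCAN,
eps = 5 Å, min_samples = 1 — equivalently single-linkage components at 5 Å).
Clusters with many receptor-compound pairs are capped at five randomly chosen
representatives so that heavily redundant targets do not dominate the set.
Docking attempts whose pose set contains no hit are dropped entirely
(positive-pose filter).  Train/test splits co-locate targets either by
identifier or by connected components of a sequence-similarity graph at a
70% or 50% identity threshold, so no pair straddling the boundary exceeds
the bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from sklearn.cluster import DBSCAN

from .io_model import HIT, ComplexExample, LigandTopology, PoseRecord, ReceptorStructure

SUPERPOSITION_RMSD_CAP = 5.0  # Å
DBSCAN_EPS = 5.0              # Å, on ligand centers of mass
MAX_REPRESENTATIVES = 5


class SuperpositionError(ValueError):
    pass


@dataclass(frozen=True)
class Superposition:
    """Rigid transform x -> R @ x + t."""

    rotation: np.ndarray   # (3, 3)
    translation: np.ndarray  # (3,)

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "Superposition":
        return Superposition(self.rotation.T, -self.rotation.T @ self.translation)


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           ) -> tuple[Superposition, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal :class:`Superposition` and the resulting RMSD.
    Standard SVD solution with a determinant correction to exclude
    reflections.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise SuperpositionError("point sets must be matching (n, 3) arrays")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return Superposition(R, t), rmsd


@dataclass(frozen=True)
class GroupMember:
    """One (structure, ligand) pair inside a target group."""

    structure_id: str
    receptor: ReceptorStructure
    ligand: LigandTopology | None
    native_pose: PoseRecord | None
    transform: Superposition
    ca_rmsd: float


@dataclass(frozen=True)
class TargetGroup:
    target_id: str
    members: tuple[GroupMember, ...]
    dropped: tuple[str, ...] = ()


def _matching_keys(receptor: ReceptorStructure) -> dict:
    """Superposition anchor atoms keyed for cross-structure matching.

    CA atoms keyed by (chain, resseq) when the structure has them; otherwise
    every atom keyed by (chain, resseq, atom name) — synthetic pseudo-atom
    receptors carry no CA atoms.
    """
    ca = {(c, s): i for i, (c, s, name) in
          enumerate(zip(receptor.chain_ids, receptor.res_seqs, receptor.atom_names))
          if name.strip() == "CA"}
    if ca:
        return ca
    return {(c, s, n): i for i, (c, s, n) in
            enumerate(zip(receptor.chain_ids, receptor.res_seqs, receptor.atom_names))}


def superpose_group(structures: list[tuple[str, ReceptorStructure]],
                    target_id: str,
                    ligands: list[tuple[LigandTopology, PoseRecord]] | None = None,
                    rmsd_cap: float = SUPERPOSITION_RMSD_CAP) -> TargetGroup:
    """Superpose all structures of one target onto the first member.

    Anchor atoms are matched by chain/residue identifiers.  Members whose
    optimal fit exceeds ``rmsd_cap`` Å are dropped (and listed in
    ``TargetGroup.dropped``).
    """
    if not structures:
        raise SuperpositionError("empty group")
    ref_id, ref = structures[0]
    ref_keys = _matching_keys(ref)
    members = [GroupMember(ref_id, ref,
                           ligands[0][0] if ligands else None,
                           ligands[0][1] if ligands else None,
                           Superposition.identity(), 0.0)]
    dropped = []
    for k, (sid, struct) in enumerate(structures[1:], start=1):
        keys = _matching_keys(struct)
        shared = sorted(set(ref_keys) & set(keys))
        if not shared:
            raise SuperpositionError(
                f"no matchable anchor atoms between {ref_id} and {sid}")
        mob = struct.coords[[keys[k_] for k_ in shared]]
        tgt = ref.coords[[ref_keys[k_] for k_ in shared]]
        transform, rmsd = kabsch(mob, tgt)
        if rmsd > rmsd_cap:
            dropped.append(sid)
            continue
        members.append(GroupMember(
            sid, struct,
            ligands[k][0] if ligands else None,
            ligands[k][1] if ligands else None,
            transform, rmsd))
    return TargetGroup(target_id=target_id, members=tuple(members),
                       dropped=tuple(dropped))


@dataclass(frozen=True)
class BindingSiteCluster:
    cluster_id: int
    members: tuple[GroupMember, ...]
    centers: np.ndarray  # (n_members, 3) superposed ligand COMs


def ligand_center_of_mass(member: GroupMember) -> np.ndarray:
    """Unweighted mean of the superposed native-ligand heavy-atom coordinates."""
    if member.native_pose is None:
        raise ValueError(f"member {member.structure_id} carries no ligand")
    return member.transform.apply(member.native_pose.coords).mean(axis=0)


def cluster_binding_sites(group: TargetGroup,
                          eps: float = DBSCAN_EPS) -> list[BindingSiteCluster]:
    """Density-cluster superposed ligand COMs (DBSCAN, min_samples=1).

    With min_samples = 1 every point is assigned and no noise points exist;
    the result equals single-linkage connected components at ``eps``.
    """
    members = [m for m in group.members if m.native_pose is not None]
    if not members:
        return []
    coms = np.array([ligand_center_of_mass(m) for m in members])
    labels = DBSCAN(eps=eps, min_samples=1).fit_predict(coms)
    clusters = []
    for cid in sorted(set(labels)):
        idx = np.flatnonzero(labels == cid)
        clusters.append(BindingSiteCluster(
            cluster_id=int(cid),
            members=tuple(members[i] for i in idx),
            centers=coms[idx]))
    return clusters


def cap_representatives(cluster: BindingSiteCluster, max_n: int = MAX_REPRESENTATIVES,
                        seed: int = 0) -> BindingSiteCluster:
    """Uniformly sample at most ``max_n`` receptor-compound pairs, reproducibly."""
    members = cluster.members
    if len(members) <= max_n:
        return cluster
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(members), size=max_n, replace=False))
    return BindingSiteCluster(cluster_id=cluster.cluster_id,
                              members=tuple(members[i] for i in keep),
                              centers=cluster.centers[keep])


def positive_pose_filter(attempts: dict[str, list[ComplexExample]],
                         ) -> dict[str, list[ComplexExample]]:
    """Drop docking attempts whose pose set contains no hit.

    Labels are never altered, only attempt membership.
    """
    return {aid: poses for aid, poses in attempts.items()
            if any(ex.label == HIT for ex in poses)}


# ---------------------------------------------------------------------------
# Train/test splits

SPLIT_KINDS = ("uniprot", "seqsim70", "seqsim50")
_THRESHOLDS = {"seqsim70": 0.70, "seqsim50": 0.50}


@dataclass(frozen=True)
class SplitAssignment:
    assignment: dict[str, str]  # target id -> "train" | "test"
    kind: str
    seed: int
    train_fraction: float
    metadata: dict = field(default_factory=dict)

    def side(self, target_id: str) -> str:
        return self.assignment[target_id]

    def to_rows(self) -> list[tuple[str, str, str, int]]:
        return [(tid, side, self.kind, self.seed)
                for tid, side in sorted(self.assignment.items())]


def sequence_identity(a: str, b: str, match: float = 1.0,
                      mismatch: float = 0.0, gap: float = -0.5) -> float:
    """Global-alignment sequence identity: matches / length of the shorter
    sequence.  Scoring (match +1, mismatch 0, gap -0.5) is fixed here and
    recorded in split metadata."""
    if not a or not b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    alignment = aligner.align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        seg_a, seg_b = a[a0:a1], b[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
    return matches / min(len(a), len(b))


def _components(target_ids: list[str], edges: set[tuple[str, str]]) -> list[list[str]]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(target_ids)
    g.add_edges_from(edges)
    return [sorted(c) for c in nx.connected_components(g)]


def make_split(targets: dict[str, str], kind: str, seed: int = 0,
               train_fraction: float = 0.7,
               uniprot_of: dict[str, str] | None = None) -> SplitAssignment:
    """Assign targets to train/test without similarity leakage.

    ``targets`` maps target id -> amino-acid sequence (sequences may be empty
    for the ``uniprot`` kind).  For the uniprot kind, targets sharing a
    Uniprot identifier (``uniprot_of``, defaulting to the target id itself)
    are co-located.  For seqsim kinds, targets with pairwise identity at or
    above the threshold are connected and whole connected components are
    assigned to one side, greedily packing toward ``train_fraction``.
    """
    if kind not in SPLIT_KINDS:
        raise ValueError(f"unknown split kind {kind!r}")
    ids = sorted(targets)
    if kind == "uniprot":
        uniprot_of = uniprot_of or {t: t for t in ids}
        edges = {(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]
                 if uniprot_of.get(a) == uniprot_of.get(b)}
        threshold = None
    else:
        threshold = _THRESHOLDS[kind]
        edges = set()
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if sequence_identity(targets[a], targets[b]) >= threshold:
                    edges.add((a, b))
    components = _components(ids, edges)
    if len(components) == 1 and len(ids) > 1:
        warnings.warn("all targets fall in one similarity component; "
                      "the requested train fraction cannot be honored")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(components))
    n_total = len(ids)
    target_train = train_fraction * n_total
    assignment: dict[str, str] = {}
    n_train = 0
    for ci in order:
        comp = components[ci]
        side = "train" if n_train < target_train else "test"
        for tid in comp:
            assignment[tid] = side
        if side == "train":
            n_train += len(comp)
    if not any(v == "test" for v in assignment.values()) and len(components) > 1:
        # Ensure a non-empty test side: flip the last-assigned component.
        comp = components[order[-1]]
        for tid in comp:
            assignment[tid] = "test"
    meta = {"identity_measure": "global alignment, match +1, mismatch 0, "
                                "gap -0.5, identity = matches / shorter length",
            "threshold": threshold}
    return SplitAssignment(assignment=assignment, kind=kind, seed=seed,
                           train_fraction=train_fraction, metadata=meta)


def write_groups_json(groups: dict[str, tuple[TargetGroup, list[BindingSiteCluster]]],
                      path) -> None:
    """Serialize target groups and their binding-site clusters.

    Transforms are stored as a 3×3 rotation plus a translation vector.
    """
    import json

    payload = {}
    for target_id, (group, clusters) in groups.items():
        payload[target_id] = {
            "dropped": list(group.dropped),
            "members": [
                {"structure_id": m.structure_id,
                 "ca_rmsd": m.ca_rmsd,
                 "rotation": m.transform.rotation.tolist(),
                 "translation": m.transform.translation.tolist()}
                for m in group.members],
            "clusters": [
                {"cluster_id": c.cluster_id,
                 "structure_ids": [m.structure_id for m in c.members],
                 "ligand_coms": c.centers.tolist()}
                for c in clusters],
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_split_csv(split: SplitAssignment, path) -> None:
    """Write (target_id, side, kind, seed) rows."""
    import pandas as pd

    pd.DataFrame(split.to_rows(),
                 columns=["target_id", "side", "kind", "seed"]
                 ).to_csv(path, index=False)


def max_boundary_identity(targets: dict[str, str],
                          split: SplitAssignment) -> float:
    """Exhaustive max pairwise identity across the train/test boundary."""
    train = [t for t in targets if split.assignment[t] == "train"]
    test = [t for t in targets if split.assignment[t] == "test"]
    best = 0.0
    for a in train:
        for b in test:
            best = max(best, sequence_identity(targets[a], targets[b]))
    return best
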