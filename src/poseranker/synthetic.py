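"""Synthetic receptors, ligands, pose sets and study manifests.

The generator emulates the statistical structure the pose-ranking method
assumes, at desk scale and with no physics: a receptor is a shell of typed
pseudo-atoms lining a roughly spherical pocket with a few designated anchor
atoms; a ligand is a connected random molecular graph placed so that each
anchor pairs with a type-complementary ligand atom within contact range (the
planted interfacial signal).  Pose sets mix hits, gaps and misses at the
class fractions observed in cross-docking data (5.0% / 15.5% / 79.5%), with
every label recomputed through ``poselabel`` rather than trusted from
construction, and with at least 1 Å RMSD between any two poses of one
attempt.  Multi-conformation receptor "ensembles" are produced by smooth
correlated coordinate perturbations calibrated to a requested mean pairwise
RMSD (default 1.6 Å).  Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import poselabel
from .io_model import (AtomRecord, ComplexExample, LIGAND, LigandTopology,
                       PoseRecord, RECEPTOR, ReceptorStructure, write_ligand,
                       write_manifest, write_receptor)
from .sybyl import PSEUDO_RESIDUES, SybylVocabulary

#: Restricted SYBYL subset used by the generator (keeps vocabularies small).
LIGAND_TYPE_POOL = ("C.3", "C.ar", "N.am", "O.2", "O.3", "N.4")
#: Non-contact ligand atoms are carbons: the k designated contact atoms are
#: the only ligand atoms carrying receptor-complementary polar types, so the
#: planted interfacial signal is not diluted by impostor contacts.
LIGAND_SCAFFOLD_TYPES = ("C.3", "C.ar")
RECEPTOR_TYPE_POOL = ("C.3", "C.ar", "N.am", "O.2", "O.3", "N.4")

#: Type-complementary (ligand, receptor) contact pairs; a contact rule is one
#: such pair within `contact_distance` Å.
CONTACT_PAIRS = (("N.4", "O.2"), ("O.3", "N.am"), ("N.am", "O.3"), ("O.2", "N.4"))

_RESNAME_OF_TYPE = {t: name for name, (_el, t) in PSEUDO_RESIDUES.items()}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class GenerationError(RuntimeError):
    """Placement failed within the retry budget; re-seed and retry."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic generator."""

    seed: int = 0
    n_targets: int = 20
    structures_per_target: int = 4
    pocket_radius: float = 8.0
    ligand_size: tuple[int, int] = (8, 30)
    n_poses: int = 64
    mixture: tuple[float, float, float] = (0.05, 0.155, 0.795)  # hit, gap, miss
    contact_k: int = 4
    contact_distance: float = 3.5
    clash_distance: float = 2.2
    min_pose_separation: float = 1.0
    ensemble_size: int = 6
    backbone_scale: float = 1.6
    seq_length: int = 60

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")


@dataclass
class SyntheticTarget:
    target_id: str
    uniprot_id: str
    sequence: str
    receptor: ReceptorStructure
    ligand: LigandTopology
    native_pose: PoseRecord
    contact_ligand_idx: np.ndarray
    contact_anchor_idx: np.ndarray
    shell_radius: float


def restricted_vocabulary() -> SybylVocabulary:
    """Small vocabulary covering everything the generator can emit."""
    return SybylVocabulary(ligand_types=LIGAND_TYPE_POOL,
                           receptor_types=RECEPTOR_TYPE_POOL)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _build_ligand(rng: np.random.Generator, spec: SyntheticSpec,
                  ) -> tuple[np.ndarray, list[tuple[int, int, str]], list[str]]:
    """Random connected molecular graph with ~1.5 Å bonds, clash-free."""
    lo, hi = spec.ligand_size
    n = int(rng.integers(lo, hi + 1))
    coords = np.zeros((n, 3))
    bonds: list[tuple[int, int, str]] = []
    degree = np.zeros(n, dtype=int)
    for i in range(1, n):
        placed = False
        for _ in range(200):
            candidates = [j for j in range(i) if degree[j] < 3]
            parent = int(rng.choice(candidates))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = coords[parent] + 1.5 * direction
            others = np.delete(coords[:i], parent, axis=0)
            if len(others) == 0 or np.min(np.linalg.norm(others - pos, axis=1)) >= 1.2:
                coords[i] = pos
                bonds.append((parent, i, "1"))
                degree[parent] += 1
                degree[i] += 1
                placed = True
                break
        if not placed:
            raise GenerationError("ligand growth failed")
    # occasional ring closure between spatially close, graph-distant atoms
    if rng.random() < 0.3:
        bonded = {frozenset((i, j)) for i, j, _ in bonds}
        for i in range(n):
            close = np.flatnonzero(np.linalg.norm(coords - coords[i], axis=1) < 2.3)
            for j in close:
                if j > i and frozenset((i, int(j))) not in bonded \
                        and degree[i] < 3 and degree[j] < 3:
                    bonds.append((i, int(j), "1"))
                    degree[i] += 1
                    degree[j] += 1
                    break
            else:
                continue
            break
    coords -= coords.mean(axis=0)
    types = [str(rng.choice(LIGAND_SCAFFOLD_TYPES, p=(0.8, 0.2)))
             for _ in range(n)]
    return coords, bonds, types


def _farthest_points(coords: np.ndarray, k: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point subset of size k (spread-out contact atoms)."""
    chosen = [int(rng.integers(len(coords)))]
    while len(chosen) < k:
        d = np.min(np.linalg.norm(
            coords[:, None, :] - coords[chosen][None, :, :], axis=2), axis=1)
        chosen.append(int(np.argmax(d)))
    return np.array(sorted(set(chosen)))


def gen_target(spec: SyntheticSpec, index: int) -> SyntheticTarget:
    """One synthetic target: pocket-shell receptor + ligand + native pose.

    The native pose satisfies all ``contact_k`` planted contact rules and has
    no receptor atom closer than ``clash_distance``.
    """
    rng = np.random.default_rng([spec.seed, index])
    for _attempt in range(20):
        try:
            return _gen_target_once(spec, index, rng)
        except GenerationError:
            continue
    raise GenerationError(f"target {index} generation failed after retries")


def _gen_target_once(spec: SyntheticSpec, index: int,
                     rng: np.random.Generator) -> SyntheticTarget:
    lig_coords, bonds, lig_types = _build_ligand(rng, spec)
    n_lig = len(lig_coords)
    k = min(spec.contact_k, n_lig)
    contact_idx = _farthest_points(lig_coords, k, rng)
    anchor_positions = []
    anchor_types = []
    for c, li in enumerate(contact_idx):
        lt, rt = CONTACT_PAIRS[c % len(CONTACT_PAIRS)]
        lig_types[li] = lt
        base = lig_coords[li]
        norm = np.linalg.norm(base)
        outward = base / norm if norm > 1e-6 else None
        placed = False
        for trial in range(200):
            direction = outward if (trial == 0 and outward is not None) else None
            if direction is None:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                if outward is not None:  # bias outward
                    direction = direction + 1.5 * outward
                    direction /= np.linalg.norm(direction)
            pos = base + 3.0 * direction
            d_all = np.linalg.norm(lig_coords - pos, axis=1)
            if np.min(d_all) >= spec.clash_distance and \
                    (not anchor_positions or np.min(np.linalg.norm(
                        np.array(anchor_positions) - pos, axis=1)) >= 1.8):
                anchor_positions.append(pos)
                anchor_types.append(rt)
                placed = True
                break
        if not placed:
            raise GenerationError("anchor placement failed")
    lig_radius = float(np.max(np.linalg.norm(lig_coords, axis=1)))
    shell_radius = max(spec.pocket_radius, lig_radius + 3.5)
    shell_positions = list(anchor_positions)
    shell_types = list(anchor_types)
    n_shell = 100
    tries = 0
    while len(shell_positions) < len(anchor_positions) + n_shell and tries < 5000:
        tries += 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = shell_radius + abs(rng.normal(0, 0.8))
        pos = direction * r
        if np.min(np.linalg.norm(lig_coords - pos, axis=1)) < spec.clash_distance:
            continue
        if np.min(np.linalg.norm(np.array(shell_positions) - pos, axis=1)) < 1.8:
            continue
        shell_positions.append(pos)
        shell_types.append(str(rng.choice(RECEPTOR_TYPE_POOL)))
    rec_coords = np.array(shell_positions)
    rec_types = shell_types

    lig_atoms = tuple(
        AtomRecord(index=i, element=t.split(".")[0], sybyl_type=t,
                   coords=tuple(c), entity=LIGAND)
        for i, (t, c) in enumerate(zip(lig_types, lig_coords)))
    ligand = LigandTopology(atoms=lig_atoms, bonds=tuple(bonds))
    rec_atoms = tuple(
        AtomRecord(index=i, element=t.split(".")[0], sybyl_type=t,
                   coords=tuple(c), entity=RECEPTOR)
        for i, (t, c) in enumerate(zip(rec_types, rec_coords)))
    receptor = ReceptorStructure(
        atoms=rec_atoms,
        chain_ids=("A",) * len(rec_atoms),
        res_names=tuple(_RESNAME_OF_TYPE[t] for t in rec_types),
        res_seqs=tuple(range(1, len(rec_atoms) + 1)),
        atom_names=tuple(t.split(".")[0] for t in rec_types))
    native = PoseRecord(coords=lig_coords, score=0.0, rank=1, receptor_conf_id="c0")
    target_id = f"T{index:03d}"
    return SyntheticTarget(
        target_id=target_id, uniprot_id="", sequence="",
        receptor=receptor, ligand=ligand, native_pose=native,
        contact_ligand_idx=contact_idx,
        contact_anchor_idx=np.arange(len(anchor_positions)),
        shell_radius=shell_radius)


def contacts_satisfied(target: SyntheticTarget, pose_coords: np.ndarray,
                       receptor: ReceptorStructure | None = None) -> int:
    """Number of planted contact rules satisfied by a pose (of contact_k)."""
    rec = receptor if receptor is not None else target.receptor
    rec_coords = rec.coords
    count = 0
    for li, ai in zip(target.contact_ligand_idx, target.contact_anchor_idx):
        d = np.linalg.norm(pose_coords[li] - rec_coords[ai])
        if d <= 3.5:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Pose generation


def _transform_pose(native: np.ndarray, rot: np.ndarray,
                    trans: np.ndarray) -> np.ndarray:
    com = native.mean(axis=0)
    return (native - com) @ rot.T + com + trans


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _sample_pose(rng: np.random.Generator, native: np.ndarray,
                 target_rmsd: float, max_angle: float) -> np.ndarray:
    """Rigid re-placement whose identity-mapping RMSD is ~``target_rmsd``.

    For a rotation about the centroid plus a translation, squared RMSD is the
    sum of the rotational and translational parts, so the translation length
    can be solved exactly.
    """
    axis = rng.normal(size=3)
    angle = rng.uniform(0, max_angle)
    rot = _rotation_about_axis(axis, angle)
    com = native.mean(axis=0)
    rotated = (native - com) @ rot.T + com
    r_rot = _plain_rmsd(rotated, native)
    if r_rot > target_rmsd:
        return None
    shift = np.sqrt(max(target_rmsd ** 2 - r_rot ** 2, 0.0))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return rotated + shift * direction


def gen_poses(target: SyntheticTarget, spec: SyntheticSpec,
              receptor: ReceptorStructure | None = None,
              conf_id: str = "c0",
              rng: np.random.Generator | None = None,
              counts: tuple[int, int, int] | None = None,
              ) -> list[ComplexExample]:
    """One docking attempt: a labeled pose set at the spec's class mixture.

    Class counts are a multinomial draw at the mixture fractions unless given
    explicitly.  Every label is recomputed through
    ``poselabel.symmetry_rmsd`` + ``label_pose``; construction is never
    trusted.  Poses are mutually at least ``min_pose_separation`` Å apart and
    clash-checked against the receptor.
    """
    if rng is None:
        from zlib import crc32
        rng = np.random.default_rng([spec.seed,
                                     crc32(target.target_id.encode()) % (2**31),
                                     crc32(conf_id.encode()) % (2**31)])
    rec = receptor if receptor is not None else target.receptor
    rec_coords = rec.coords
    native = target.native_pose.coords
    mappings = poselabel.automorphisms(target.ligand)
    if counts is None:
        counts = tuple(rng.multinomial(spec.n_poses, spec.mixture))
    n_hit, n_gap, n_miss = counts
    max_shift = max(2.0, target.shell_radius - 1.0)

    accepted: list[tuple[np.ndarray, float, str]] = []
    accepted_stack = np.zeros((0,) + native.shape)

    def try_accept(pose: np.ndarray, want: str, clash_min: float = 1.5) -> bool:
        nonlocal accepted_stack
        if pose is None:
            return False
        if np.max(np.linalg.norm(pose - native.mean(axis=0), axis=1)) \
                > target.shell_radius + 2.0:
            return False
        dmin = np.min(np.linalg.norm(
            rec_coords[None, :, :] - pose[:, None, :], axis=2))
        if dmin < clash_min:
            return False
        if len(accepted_stack):
            seps = np.sqrt(np.mean(
                np.sum((accepted_stack - pose[None]) ** 2, axis=2), axis=1))
            if seps.min() < spec.min_pose_separation:
                return False
        rmsd, _ = poselabel.symmetry_rmsd(pose, native, target.ligand, mappings)
        if poselabel.label_pose(rmsd) != want:
            return False
        accepted.append((pose, rmsd, want))
        accepted_stack = np.concatenate([accepted_stack, pose[None]], axis=0)
        return True

    budget = 4000
    for want, n_want in (("hit", n_hit), ("gap", n_gap), ("miss", n_miss)):
        got = 0
        tries = 0
        while got < n_want:
            tries += 1
            if tries > budget:
                raise GenerationError(
                    f"could not realize the {want} class within the retry budget")
            if want == "hit":
                u = rng.uniform(0.2, 2.35)
                pose = _sample_pose(rng, native, u, max_angle=0.35)
            elif want == "gap":
                u = rng.uniform(2.6, 3.9)
                pose = _sample_pose(rng, native, u, max_angle=0.6)
            else:
                rot = _random_rotation(rng)
                trans = rng.normal(size=3)
                trans *= rng.uniform(0, max_shift) / np.linalg.norm(trans)
                pose = _transform_pose(native, rot, trans)
                if _plain_rmsd(pose, native) <= 4.2:
                    pose = None
            if try_accept(pose, want):
                got += 1

    scores = np.array([-r for _, r, _ in accepted]) + rng.normal(0, 1.5, len(accepted))
    ranks = np.empty(len(accepted), dtype=int)
    ranks[np.argsort(-scores, kind="stable")] = np.arange(1, len(accepted) + 1)
    examples = []
    order = rng.permutation(len(accepted))
    for pid, k in enumerate(order):
        pose_coords, rmsd, label = accepted[k]
        pose = PoseRecord(coords=pose_coords, score=float(scores[k]),
                          rank=int(ranks[k]), receptor_conf_id=conf_id)
        examples.append(ComplexExample(
            receptor=rec, ligand=target.ligand, pose=pose, label=label,
            metadata={"target_id": target.target_id,
                      "uniprot_id": target.uniprot_id,
                      "attempt_id": f"{target.target_id}:{conf_id}",
                      "pose_id": f"p{pid:03d}",
                      "rmsd": rmsd}))
    return examples


# ---------------------------------------------------------------------------
# Receptor ensembles


def gen_ensemble(receptor: ReceptorStructure, spec: SyntheticSpec,
                 rng: np.random.Generator | None = None,
                 n: int | None = None,
                 scale: float | None = None) -> list[ReceptorStructure]:
    """Conformational ensemble via smooth correlated coordinate perturbations.

    Member 0 is the input structure.  Each other member is displaced by a
    low-frequency random sinusoidal field normalized so that the ensemble's
    mean pairwise all-atom RMSD approximates ``scale`` (default the spec's
    ``backbone_scale``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = n if n is not None else spec.ensemble_size
    scale = spec.backbone_scale if scale is None else scale
    coords = receptor.coords
    members = [receptor]
    if n <= 1:
        return members[:n]
    if scale == 0.0:
        return [receptor] + [receptor.with_coords(coords.copy())
                             for _ in range(n - 1)]
    # Per-member displacement RMS s such that the expected mean pairwise RMSD
    # equals `scale`: pairs with the reference contribute s, pairs between two
    # independently perturbed members contribute s*sqrt(2).
    pairs_ref = n - 1
    pairs_pert = (n - 1) * (n - 2) / 2
    s = scale * (pairs_ref + pairs_pert) / (pairs_ref + pairs_pert * np.sqrt(2))
    for _ in range(n - 1):
        delta = np.zeros_like(coords)
        for _m in range(3):
            amp = rng.normal(size=3)
            kvec = rng.normal(size=3)
            kvec *= rng.uniform(0.05, 0.2) / np.linalg.norm(kvec)
            phase = rng.uniform(0, 2 * np.pi)
            delta += amp[None, :] * np.sin(coords @ kvec + phase)[:, None]
        rms = np.sqrt(np.mean(np.sum(delta ** 2, axis=1)))
        if rms < 1e-12:
            continue
        delta *= s / rms
        members.append(receptor.with_coords(coords + delta))
    return members


def mean_pairwise_rmsd(members: list[ReceptorStructure]) -> float:
    """Mean all-atom RMSD over all member pairs (shared frame, no fitting)."""
    vals = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            vals.append(_plain_rmsd(members[i].coords, members[j].coords))
    return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------------------
# Full studies


@dataclass
class SyntheticStudy:
    spec: SyntheticSpec
    targets: list[SyntheticTarget]
    conformations: dict[str, list[ReceptorStructure]]  # target id -> members
    attempts: dict[str, list[ComplexExample]] = field(default_factory=dict)

    def all_examples(self) -> list[ComplexExample]:
        return [ex for poses in self.attempts.values() for ex in poses]

    def sequences(self) -> dict[str, str]:
        return {t.target_id: t.sequence for t in self.targets}

    def uniprot_map(self) -> dict[str, str]:
        return {t.target_id: t.uniprot_id for t in self.targets}


def _mutate(seq: str, fraction: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    n_mut = int(round(fraction * len(chars)))
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        current = chars[pos]
        choices = [a for a in AMINO_ACIDS if a != current]
        chars[pos] = str(rng.choice(choices))
    return "".join(chars)


def gen_study(spec: SyntheticSpec) -> SyntheticStudy:
    """A full synthetic study: targets, sequence families, receptor
    conformations, and labeled pose sets for every (target, conformation)
    docking attempt.

    Consecutive target pairs may form a sequence family (~88% identity, to
    exercise similarity splits) and may share a Uniprot-like identifier (to
    exercise identifier splits); all other sequence pairs are unrelated.
    """
    rng = np.random.default_rng([spec.seed, 987654321])
    targets = [gen_target(spec, i) for i in range(spec.n_targets)]
    # sequence families over consecutive pairs
    i = 0
    while i < spec.n_targets:
        base = "".join(rng.choice(list(AMINO_ACIDS), size=spec.seq_length))
        paired = (i + 1 < spec.n_targets) and rng.random() < 0.4
        targets[i].sequence = base
        targets[i].uniprot_id = f"U{i:04d}"
        if paired:
            targets[i + 1].sequence = _mutate(base, 0.12, rng)
            share_uniprot = rng.random() < 0.5
            targets[i + 1].uniprot_id = targets[i].uniprot_id if share_uniprot \
                else f"U{i + 1:04d}"
            i += 2
        else:
            i += 1
    conformations = {}
    attempts = {}
    for t_index, target in enumerate(targets):
        ens_rng = np.random.default_rng([spec.seed, 7777, t_index])
        members = gen_ensemble(target.receptor, spec, rng=ens_rng,
                               n=spec.structures_per_target)
        conformations[target.target_id] = members
        for c, rec in enumerate(members):
            conf_id = f"c{c}"
            pose_rng = np.random.default_rng([spec.seed, 31337, t_index, c])
            poses = gen_poses(target, spec, receptor=rec, conf_id=conf_id,
                              rng=pose_rng)
            attempts[f"{target.target_id}:{conf_id}"] = poses
    return SyntheticStudy(spec=spec, targets=targets,
                          conformations=conformations, attempts=attempts)


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write a study as the manifest/PDB/SDF layout the pipeline consumes.

    Returns the manifest path.  Layout: one PDB per receptor conformation,
    one multi-record SDF per docking attempt (plus the native pose as record
    0 of a separate native SDF), a FASTA of target sequences, and a
    JSON-lines manifest with one pose per line.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for target in study.targets:
        tdir = outdir / target.target_id
        tdir.mkdir(exist_ok=True)
        write_ligand(target.ligand, [target.native_pose],
                     tdir / "native.sdf")
        for c, rec in enumerate(study.conformations[target.target_id]):
            rec_file = tdir / f"receptor_c{c}.pdb"
            write_receptor(rec, rec_file)
            attempt_id = f"{target.target_id}:c{c}"
            poses = study.attempts.get(attempt_id, [])
            if not poses:
                continue
            lig_file = tdir / f"poses_c{c}.sdf"
            write_ligand(target.ligand, [ex.pose for ex in poses], lig_file)
            for k, ex in enumerate(poses):
                entries.append({
                    "receptor_file": str(rec_file.relative_to(outdir)),
                    "ligand_file": str(lig_file.relative_to(outdir)),
                    "pose_index": k,
                    "label": ex.label,
                    "target_id": target.target_id,
                    "uniprot_id": target.uniprot_id,
                    "attempt_id": attempt_id,
                    "pose_id": ex.metadata["pose_id"],
                    "rmsd": ex.metadata["rmsd"],
                    "docking_score": ex.pose.score,
                    "docking_rank": ex.pose.rank,
                })
    manifest = outdir / "manifest.jsonl"
    write_manifest(entries, manifest)
    with open(outdir / "sequences.fasta", "w") as fh:
        for target in study.targets:
            fh.write(f">{target.target_id} uniprot={target.uniprot_id}\n")
            fh.write(target.sequence + "\n")
    return manifest
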