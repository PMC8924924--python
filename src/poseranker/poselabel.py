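"""Symmetry-corrected ligand RMSD and hit/gap/miss labeling.

A docked pose is compared to the native (crystal) pose of the same compound
in the same receptor frame — the ligand is never re-superposed, because the
docked placement is exactly what is being judged.  Chemically equivalent atom
orderings (graph automorphisms of the ligand, with elements and bond orders
as colors) are enumerated and the minimum RMSD over all of them is reported.

Labels follow the standard pose-quality rule: RMSD ≤ 2.5 Å is a "hit",
RMSD > 4 Å a "miss", anything in between a "gap".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from networkx.algorithms import isomorphism

from .io_model import HIT, GAP, MISS, LigandTopology

HIT_THRESHOLD = 2.5   # Å, inclusive
MISS_THRESHOLD = 4.0  # Å, exclusive (a miss is strictly greater)

#: Guard against combinatorial blow-up of automorphism enumeration.
MAX_MAPPINGS = 10_000


class MatchingError(ValueError):
    """Pose and native coordinates cannot be matched atom-to-atom."""


@dataclass(frozen=True)
class PoseLabelRecord:
    rmsd: float
    label: str
    mapping_id: int  # index of the automorphism achieving the minimum

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def label_pose(rmsd: float) -> str:
    """hit / gap / miss from an RMSD value (Å)."""
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    if rmsd <= HIT_THRESHOLD:
        return HIT
    if rmsd > MISS_THRESHOLD:
        return MISS
    return GAP


def automorphisms(topology: LigandTopology,
                  cap: int = MAX_MAPPINGS) -> np.ndarray:
    """All element- and bond-order-preserving self-mappings of the ligand.

    Returns an (n_mappings, n_atoms) integer array of permutations; row 0 is
    guaranteed to be a valid mapping (graphs are trivially self-isomorphic).
    Aromatic bonds count as their own bond class.  Enumeration is capped at
    ``cap`` mappings with a warning.
    """
    g = topology.to_networkx()
    matcher = isomorphism.GraphMatcher(
        g, g,
        node_match=isomorphism.categorical_node_match("element", None),
        edge_match=isomorphism.categorical_edge_match("order", None))
    perms = []
    for mapping in matcher.isomorphisms_iter():
        perms.append([mapping[i] for i in range(len(topology.atoms))])
        if len(perms) >= cap:
            warnings.warn(f"automorphism enumeration capped at {cap} mappings")
            break
    return np.array(perms, dtype=np.int64)


def symmetry_rmsd(pose_coords: np.ndarray, native_coords: np.ndarray,
                  topology: LigandTopology,
                  mappings: np.ndarray | None = None,
                  ) -> tuple[float, int]:
    """Minimum heavy-atom RMSD over all ligand automorphisms (no superposition).

    ``mappings`` may carry a precomputed :func:`automorphisms` array to
    amortize enumeration over many poses of the same compound.  Returns
    ``(rmsd, mapping_id)``.
    """
    pose = np.asarray(pose_coords, dtype=float)
    native = np.asarray(native_coords, dtype=float)
    n = len(topology.atoms)
    if pose.shape != (n, 3) or native.shape != (n, 3):
        raise MatchingError("coordinate arrays must both match the topology")
    if mappings is None:
        mappings = automorphisms(topology)
    if mappings.size == 0:
        raise MatchingError("ligand graphs are not isomorphic")
    # (M, n, 3) of native coordinates under each mapping
    diffs = pose[None, :, :] - native[mappings]
    rmsds = np.sqrt(np.mean(np.sum(diffs ** 2, axis=2), axis=1))
    best = int(np.argmin(rmsds))
    return float(rmsds[best]), best


def crossdock_rmsd(pose_coords: np.ndarray, native_coords: np.ndarray,
                   topology: LigandTopology, superposition,
                   mappings: np.ndarray | None = None) -> tuple[float, int]:
    """Symmetry RMSD after mapping the native pose into the pose's receptor frame.

    ``superposition`` is the rigid transform (from ``crossdock``) taking the
    native receptor's frame onto the docked receptor's frame.
    """
    if superposition is None:
        raise MatchingError("cross-docking RMSD requires a receptor superposition")
    native_in_frame = superposition.apply(np.asarray(native_coords, dtype=float))
    return symmetry_rmsd(pose_coords, native_in_frame, topology, mappings)


def write_label_table(rows: list[tuple[str, str, float, str]], path) -> None:
    """CSV label table with columns (attempt_id, pose_id, rmsd, label)."""
    import pandas as pd

    pd.DataFrame(rows, columns=["attempt_id", "pose_id", "rmsd", "label"]
                 ).to_csv(path, index=False)


def label_record(pose_coords: np.ndarray, native_coords: np.ndarray,
                 topology: LigandTopology,
                 mappings: np.ndarray | None = None) -> PoseLabelRecord:
    """Convenience: symmetry RMSD + label in one record."""
    rmsd, mapping_id = symmetry_rmsd(pose_coords, native_coords, topology, mappings)
    return PoseLabelRecord(rmsd=rmsd, label=label_pose(rmsd), mapping_id=mapping_id)
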