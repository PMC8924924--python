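"""Layer routing and directed neighborhood construction.

The network's message-passing topology is configured by an arrow string such
as ``"l→l→r→l→r→l"``: each token names an atom set (``l`` ligand, ``r``
receptor, ``lr`` both) and each arrow a message-passing layer from the set on
its left (sources) to the set on its right (targets).  By construction the
sources of layer ``ℓ`` are the targets of layer ``ℓ−1``.  Within a layer,
every ordered source→target atom pair closer than the layer's radial cutoff
receives a directed edge; covalent structure plays no role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_model import ComplexExample, assemble_atoms

TOKENS = ("l", "r", "lr")

#: Default radial cutoffs (Å): contact-shell radii for same-entity layers and
#: a wider shell whenever ligand-receptor pairs can form edges.
DEFAULT_INTRA_CUTOFF = 4.0
DEFAULT_CROSS_CUTOFF = 5.0


class LayerSpecError(ValueError):
    """The layer-routing string could not be parsed."""


@dataclass(frozen=True)
class LayerConfig:
    """Parsed routing plan: initial source set plus (source, target, cutoff) layers."""

    initial_source: str
    layers: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        if self.initial_source not in TOKENS:
            raise LayerSpecError(f"unknown token {self.initial_source!r}")
        prev = self.initial_source
        for src, tgt, cutoff in self.layers:
            if src not in TOKENS or tgt not in TOKENS:
                raise LayerSpecError(f"unknown token in layer ({src},{tgt})")
            if src != prev:
                raise LayerSpecError(
                    "source set of each layer must equal the previous target set")
            if cutoff <= 0:
                raise LayerSpecError("cutoffs must be positive")
            prev = tgt

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def spec_string(self) -> str:
        tokens = [self.initial_source] + [tgt for _, tgt, _ in self.layers]
        return "->".join(tokens)


def token_includes(token: str, entity: str) -> bool:
    """Whether an atom entity ('ligand'/'receptor') belongs to a set token."""
    return (entity == "ligand" and token in ("l", "lr")) or \
           (entity == "receptor" and token in ("r", "lr"))


def _is_cross(src: str, tgt: str) -> bool:
    return src != tgt or src == "lr"


def parse_layer_config(spec: str,
                       cutoffs: float | list[float] | None = None) -> LayerConfig:
    """Parse an arrow string into a :class:`LayerConfig`.

    ``spec`` uses tokens ``l``/``r``/``lr`` joined by ``→`` or ``->``.  A spec
    with k+1 tokens yields k layers.  ``cutoffs`` may be a single value used
    for every layer, a per-layer list, or ``None`` for the defaults (4 Å for
    same-entity layers, 5 Å when ligand-receptor edges are possible).
    """
    if not spec or not spec.strip():
        raise LayerSpecError("empty layer spec")
    tokens = [t.strip() for t in spec.replace("→", "->").split("->")]
    if any(t not in TOKENS for t in tokens):
        bad = [t for t in tokens if t not in TOKENS]
        raise LayerSpecError(f"unknown token(s) {bad} in {spec!r}")
    pairs = list(zip(tokens[:-1], tokens[1:]))
    if cutoffs is None:
        cut = [DEFAULT_CROSS_CUTOFF if _is_cross(s, t) else DEFAULT_INTRA_CUTOFF
               for s, t in pairs]
    elif np.isscalar(cutoffs):
        cut = [float(cutoffs)] * len(pairs)
    else:
        if len(cutoffs) != len(pairs):
            raise LayerSpecError(
                f"{len(cutoffs)} cutoffs for {len(pairs)} layers")
        cut = [float(c) for c in cutoffs]
    layers = tuple((s, t, c) for (s, t), c in zip(pairs, cut))
    return LayerConfig(initial_source=tokens[0], layers=layers)


@dataclass(frozen=True)
class DirectedNeighborhood:
    """Per-layer directed edge lists (source idx, target idx, distance)."""

    layers: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]

    def n_edges(self, layer: int) -> int:
        return len(self.layers[layer][0])


def _entity_mask(is_ligand: np.ndarray, token: str) -> np.ndarray:
    if token == "l":
        return is_ligand
    if token == "r":
        return ~is_ligand
    return np.ones_like(is_ligand)


def build_layer_edges(coords: np.ndarray, is_ligand: np.ndarray,
                      src_token: str, tgt_token: str, cutoff: float,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed edges j→i with d_ij < cutoff, j in source set, i in target set.

    Self-edges are excluded (identity information flows through the skip
    connection; d=0 would also degenerate the radial basis).  Edges are sorted
    by target then source index.  Uses a k-d tree internally; the contract is
    the brute-force all-pairs result.
    """
    src_idx = np.flatnonzero(_entity_mask(is_ligand, src_token))
    tgt_idx = np.flatnonzero(_entity_mask(is_ligand, tgt_token))
    empty = (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0),)
    if len(src_idx) == 0 or len(tgt_idx) == 0:
        return empty
    if len(src_idx) * len(tgt_idx) <= 200_000:
        # dense path: for pocket-sized complexes the full distance matrix is
        # cheaper than a tree; nonzero() yields target-major (sorted) pairs
        d = np.linalg.norm(coords[tgt_idx][:, None, :]
                           - coords[src_idx][None, :, :], axis=2)
        tt, ss = np.nonzero(d < cutoff)
        src, tgt = src_idx[ss], tgt_idx[tt]
        keep = src != tgt
        return src[keep], tgt[keep], d[tt[keep], ss[keep]]
    tree = cKDTree(coords[src_idx])
    neighbors = tree.query_ball_point(coords[tgt_idx], r=cutoff)
    srcs, tgts = [], []
    for t_pos, hits in enumerate(neighbors):
        i = tgt_idx[t_pos]
        for s_pos in hits:
            j = src_idx[s_pos]
            if j != i:
                srcs.append(j)
                tgts.append(i)
    if not srcs:
        return empty
    src = np.array(srcs, dtype=np.int64)
    tgt = np.array(tgts, dtype=np.int64)
    dist = np.linalg.norm(coords[src] - coords[tgt], axis=1)
    # query_ball_point uses d <= r; the neighborhood definition is strict.
    keep = dist < cutoff
    src, tgt, dist = src[keep], tgt[keep], dist[keep]
    order = np.lexsort((src, tgt))
    return src[order], tgt[order], dist[order]


def build_neighborhoods(example: ComplexExample, config: LayerConfig,
                        pocket_margin: float | None = None,
                        ) -> DirectedNeighborhood:
    """Per-layer directed edge sets for one complex under a routing plan."""
    coords, is_ligand, _ = assemble_atoms(example, pocket_margin=pocket_margin)
    layers = tuple(
        build_layer_edges(coords, is_ligand, src, tgt, cutoff)
        for src, tgt, cutoff in config.layers)
    return DirectedNeighborhood(layers=layers)
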