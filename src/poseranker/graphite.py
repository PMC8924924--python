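"""GRAPHite: a directional message-passing network for pose ranking.

Atoms are nodes carrying one-hot SYBYL-type features; no covalent structure
enters the graph.  Each interaction block is a continuous-filter convolution
whose radial kernel is a learnable linear combination of zeroth-order
spherical Bessel functions

    b_n(d) = sqrt(2/R_c) * j0(z_0n * d / R_c),     j0(x) = sin(x)/x,

where ``z_0n = n*pi`` is the n-th zero of ``j0``, so every kernel vanishes
exactly at the layer cutoff ``R_c``.  Source features entering a layer are a
bottleneck projection of the concatenation of all previously computed feature
layers of the matching source atoms; a second bottleneck of the target atom's
history forms a skip connection added before a Linear-LeakyReLU-Linear-
LayerNorm block.  Ligand and receptor features are pooled independently at
every layer, concatenated (``z_read = z_L ⊕ z_R``) and passed through a final
Linear-LeakyReLU-Linear head to produce the ranking logit: higher means a
better pose.

The whole network — forward pass, gradients, and the Adam update used by
``traineval`` — is implemented directly on numpy arrays.  Everything is
deterministic given the parameters and the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_model import ComplexExample, POCKET_MARGIN, assemble_arrays
from .posegraph import LayerConfig, build_layer_edges, parse_layer_config, token_includes
from .sybyl import SybylVocabulary

LEAKY_SLOPE = 0.01
LN_EPS = 1e-5
CHECKPOINT_VERSION = 1


class DomainError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Radial basis


@dataclass(frozen=True)
class BesselBasis:
    """Spherical-Bessel radial basis on [0, cutoff] that vanishes at the cutoff."""

    cutoff: float
    n_basis: int = 16

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.n_basis < 1:
            raise ValueError("cutoff must be positive and n_basis >= 1")

    @property
    def zeros(self) -> np.ndarray:
        """z_0n = n*pi, the zeros of j0."""
        return np.arange(1, self.n_basis + 1) * np.pi

    def values(self, d) -> np.ndarray:
        """Basis values b_n(d) for distances d (scalar or array), shape (..., N_b).

        d=0 is handled by the analytic limit j0(0)=1; d=cutoff is exactly 0.
        """
        d = np.asarray(d, dtype=float)
        if np.any(d < 0) or np.any(d > self.cutoff):
            raise DomainError("distance outside [0, cutoff]")
        scalar = d.ndim == 0
        d = np.atleast_1d(d)[:, None]
        x = self.zeros[None, :] * d / self.cutoff
        norm = np.sqrt(2.0 / self.cutoff)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = norm * np.sin(x) / x
        out[np.broadcast_to(d == 0.0, out.shape)] = norm  # j0(0) = 1
        out[np.broadcast_to(d == self.cutoff, out.shape)] = 0.0  # exact zero of j0
        return out[0] if scalar else out


def bessel_basis_values(d, basis: BesselBasis) -> np.ndarray:
    """Functional alias for :meth:`BesselBasis.values`."""
    return basis.values(d)


# ---------------------------------------------------------------------------
# Standalone block primitives (the same math the forward pass uses inline)


def continuous_filter_conv(h: np.ndarray, edges, basis: BesselBasis,
                           kernel: np.ndarray, n_targets: int) -> np.ndarray:
    """Sum over incoming edges of W(d_ij) ⊙ h_j, per target atom.

    ``edges`` is ``(src_pos, tgt_pos, dist)`` with positions indexing rows of
    ``h`` and of the output respectively.  Targets without edges get zeros.
    """
    src, tgt, dist = edges
    out = np.zeros((n_targets, kernel.shape[1]))
    if len(src):
        filt = basis.values(dist) @ kernel
        np.add.at(out, np.asarray(tgt), filt * h[np.asarray(src)])
    return out


def _leaky(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, LEAKY_SLOPE * x)


def _segment_sum(values: np.ndarray, index_sorted: np.ndarray,
                 n: int) -> np.ndarray:
    """Scatter-add rows of ``values`` into ``n`` bins given sorted indices."""
    out = np.zeros((n, values.shape[1]))
    if len(index_sorted):
        starts = np.concatenate(
            [[0], np.flatnonzero(np.diff(index_sorted)) + 1])
        out[index_sorted[starts]] = np.add.reduceat(values, starts, axis=0)
    return out


def _layernorm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray):
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (x - mu) * inv_std
    return gamma * xhat + beta, (xhat, inv_std)


def interaction_block(h_source: np.ndarray, skip_target: np.ndarray, edges,
                      basis: BesselBasis, params: dict) -> np.ndarray:
    """One interaction block on explicit inputs.

    ``f_i = LayerNorm(Linear(LeakyReLU(Linear(conv_i + skip_i))))`` where the
    convolution term is :func:`continuous_filter_conv`.  Atoms with no
    incoming edges receive only the skip path through the MLP.
    """
    n_tgt, c = skip_target.shape
    if params["W1"].shape[0] != c:
        raise ValueError("feature width does not match parameters")
    conv = continuous_filter_conv(h_source, edges, basis, params["kernel"], n_tgt)
    x = conv + skip_target
    a2 = _leaky(x @ params["W1"] + params["b1"]) @ params["W2"] + params["b2"]
    y, _ = _layernorm(a2, params["gamma"], params["beta"])
    return y


def readout(ligand_feats: list, receptor_feats: list, params: dict,
            pooling: str = "sum") -> float:
    """Pool per-layer ligand/receptor features, concatenate, and apply the head.

    Each element of the two lists is an (n_atoms, dim) array or ``None`` for a
    layer whose target set excludes that entity; such layers contribute
    nothing.  Raises :class:`ConfigurationError` if both sides are empty.
    """
    parts = []
    for feats in list(ligand_feats) + list(receptor_feats):
        if feats is None:
            continue
        pooled = feats.sum(axis=0)
        if pooling == "mean" and len(feats):
            pooled = pooled / len(feats)
        parts.append(pooled)
    if not parts:
        raise ConfigurationError("both ligand and receptor readouts are empty")
    z = np.concatenate(parts)
    q = _leaky(z @ params["W1"] + params["b1"])
    return float((q @ params["W2"] + params["b2"])[0])


# ---------------------------------------------------------------------------
# Parameter bookkeeping


def feature_slots(config: LayerConfig) -> list[str]:
    """Atom-set token of every feature layer: slot 0 is the embedding, slot
    ℓ+1 the output of interaction layer ℓ."""
    return [config.initial_source] + [tgt for _, tgt, _ in config.layers]


def _history_slots(config: LayerConfig, entity: str, layer: int) -> list[int]:
    """Feature slots (ids ≤ layer) available for an atom of ``entity`` before
    interaction layer ``layer`` runs.

    The one-hot embedding (slot 0) exists for every atom — any atom may act
    as a bottleneck source — while interaction outputs exist only for atoms
    of the layer's target set.  Readout inclusion is governed separately by
    the slot tokens (the embedding is read out only for the initial source
    set)."""
    tokens = feature_slots(config)
    return [0] + [s for s in range(1, layer + 1)
                  if token_includes(tokens[s], entity)]


def _entities(token: str) -> list[str]:
    out = []
    if token_includes(token, "ligand"):
        out.append("ligand")
    if token_includes(token, "receptor"):
        out.append("receptor")
    return out


@dataclass
class GraphiteParams:
    """All learnable arrays of a GRAPHite network, keyed by layer and role."""

    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def __setitem__(self, key: str, value: np.ndarray) -> None:
        self.arrays[key] = value

    def __contains__(self, key: str) -> bool:
        return key in self.arrays

    def keys(self):
        return self.arrays.keys()

    def check_finite(self) -> None:
        for k, v in self.arrays.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite parameter {k}")

    def zeros_like(self) -> "GraphiteParams":
        return GraphiteParams({k: np.zeros_like(v) for k, v in self.arrays.items()})


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[0]
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


@dataclass(frozen=True)
class ScoredPose:
    """A pose with its ranking logit and rank within one docking attempt."""

    example: ComplexExample
    logit: float
    rank: int
    docking_rank: int


class GraphiteNet:
    """The full network: embedding, interaction stack, dual readout, logit head.

    Parameters
    ----------
    config : LayerConfig or arrow string such as ``"l→l→r→l→r→l"``.
    vocab : SYBYL one-hot vocabulary (disjoint ligand/receptor blocks).
    channels : feature width of every interaction layer (also bottleneck width).
    hidden : hidden width of the final MLP head.
    n_basis : number of spherical-Bessel basis functions per layer.
    pooling : "sum" (default; preserves pooling linearity) or "mean".
    pocket_margin : receptor truncation margin in Å around the ligand pose
        bounding box; ``None`` keeps the whole receptor.
    seed : initialization seed (recorded; forward is bit-reproducible).
    """

    def __init__(self, config: LayerConfig | str,
                 vocab: SybylVocabulary | None = None,
                 channels: int = 64, hidden: int = 128, n_basis: int = 16,
                 pooling: str = "sum",
                 pocket_margin: float | None = POCKET_MARGIN,
                 seed: int = 0,
                 cutoffs=None):
        if isinstance(config, str):
            config = parse_layer_config(config, cutoffs)
        self.config = config
        self.vocab = vocab if vocab is not None else SybylVocabulary()
        self.channels = channels
        self.hidden = hidden
        self.n_basis = n_basis
        if pooling not in ("sum", "mean"):
            raise ConfigurationError(f"unknown pooling {pooling!r}")
        self.pooling = pooling
        self.pocket_margin = pocket_margin
        self.seed = seed
        self.bases = [BesselBasis(cutoff, n_basis) for _, _, cutoff in config.layers]
        self._slot_tokens = feature_slots(config)
        self._slot_dims = [self.vocab.size] + [channels] * config.n_layers
        self._readout_plan = self._build_readout_plan()
        self.params = self._init_params()

    # -- construction ------------------------------------------------------

    def _build_readout_plan(self) -> list[tuple[int, str]]:
        """(slot, entity) pairs contributing to z_read, ligand parts first."""
        plan = [(s, "ligand") for s, tok in enumerate(self._slot_tokens)
                if token_includes(tok, "ligand")]
        plan += [(s, "receptor") for s, tok in enumerate(self._slot_tokens)
                 if token_includes(tok, "receptor")]
        if not plan:
            raise ConfigurationError("readout would be empty for this config")
        return plan

    @property
    def readout_dim(self) -> int:
        return sum(self._slot_dims[s] for s, _ in self._readout_plan)

    def _init_params(self) -> GraphiteParams:
        rng = np.random.default_rng(self.seed)
        c = self.channels
        p = GraphiteParams()
        for ell, (src_tok, tgt_tok, _) in enumerate(self.config.layers):
            p[f"L{ell}.kernel"] = _kaiming(rng, (self.n_basis, c))
            for e in _entities(src_tok):
                dim = sum(self._slot_dims[s] for s in _history_slots(self.config, e, ell))
                p[f"L{ell}.src.{e}"] = _kaiming(rng, (dim, c))
            for e in _entities(tgt_tok):
                dim = sum(self._slot_dims[s] for s in _history_slots(self.config, e, ell))
                if dim:
                    p[f"L{ell}.tgt.{e}"] = _kaiming(rng, (dim, c))
            p[f"L{ell}.W1"] = _kaiming(rng, (c, c))
            p[f"L{ell}.b1"] = np.zeros(c)
            p[f"L{ell}.W2"] = _kaiming(rng, (c, c))
            p[f"L{ell}.b2"] = np.zeros(c)
            p[f"L{ell}.gamma"] = np.ones(c)
            p[f"L{ell}.beta"] = np.zeros(c)
        p["out.W1"] = _kaiming(rng, (self.readout_dim, self.hidden))
        p["out.b1"] = np.zeros(self.hidden)
        p["out.W2"] = _kaiming(rng, (self.hidden, 1))
        p["out.b2"] = np.zeros(1)
        return p

    # -- input preparation -------------------------------------------------

    def prepare(self, example: ComplexExample) -> dict:
        """Precompute the static, parameter-independent parts of the forward
        pass: one-hot embeddings, entity rows, and per-layer edge lists.

        The returned dict is a single-example "merged" structure; several can
        be concatenated into one disjoint batch graph with
        :func:`merge_prepared`."""
        coords, is_ligand, types, entities = assemble_arrays(
            example, self.pocket_margin)
        n = len(types)
        x0 = np.zeros((n, self.vocab.size))
        for k, (t, e) in enumerate(zip(types, entities)):
            x0[k, self.vocab.index(t, e)] = 1.0
        rows = {"ligand": np.flatnonzero(is_ligand),
                "receptor": np.flatnonzero(~is_ligand)}
        edges = []
        for src_tok, tgt_tok, cutoff in self.config.layers:
            src, tgt, dist = build_layer_edges(coords, is_ligand,
                                               src_tok, tgt_tok, cutoff)
            src = src.astype(np.int64)
            edges.append((src, tgt.astype(np.int64),
                          dist.astype(np.float64),
                          np.argsort(src, kind="stable")))
        tok_rows = {}
        for tok in set(t for layer in self.config.layers for t in layer[:2]):
            tok_rows[tok] = np.concatenate([rows[e] for e in _entities(tok)])
        ex_id = {e: np.zeros(len(rows[e]), dtype=np.int64) for e in rows}
        counts = {e: np.array([len(rows[e])]) for e in rows}
        return {"n": n, "x0": x0, "rows": rows, "tok_rows": tok_rows,
                "edges": edges, "ex_id": ex_id, "counts": counts,
                "n_examples": 1, "example": example}

    def merge_prepared(self, prepared_list: list[dict]) -> dict:
        """Concatenate prepared examples into one disjoint batch graph."""
        if len(prepared_list) == 1:
            return prepared_list[0]
        offsets = np.cumsum([0] + [p["n"] for p in prepared_list])
        n = int(offsets[-1])
        x0 = np.vstack([p["x0"] for p in prepared_list])
        rows, ex_id, counts = {}, {}, {}
        for e in ("ligand", "receptor"):
            rows[e] = np.concatenate(
                [p["rows"][e] + off for p, off in zip(prepared_list, offsets)])
            ex_id[e] = np.concatenate(
                [np.full(len(p["rows"][e]), b, dtype=np.int64)
                 for b, p in enumerate(prepared_list)])
            counts[e] = np.array([len(p["rows"][e]) for p in prepared_list])
        tok_rows = {}
        for tok in prepared_list[0]["tok_rows"]:
            tok_rows[tok] = np.concatenate(
                [p["tok_rows"][tok] + off
                 for p, off in zip(prepared_list, offsets)])
        edges = []
        for ell in range(self.config.n_layers):
            e_off = np.cumsum([0] + [len(p["edges"][ell][0])
                                     for p in prepared_list])
            src = np.concatenate([p["edges"][ell][0] + off
                                  for p, off in zip(prepared_list, offsets)])
            tgt = np.concatenate([p["edges"][ell][1] + off
                                  for p, off in zip(prepared_list, offsets)])
            dist = np.concatenate([p["edges"][ell][2] for p in prepared_list])
            order = np.concatenate([p["edges"][ell][3] + off
                                    for p, off in zip(prepared_list, e_off)])
            edges.append((src, tgt, dist, order))
        return {"n": n, "x0": x0, "rows": rows, "tok_rows": tok_rows,
                "edges": edges, "ex_id": ex_id, "counts": counts,
                "n_examples": len(prepared_list),
                "example": [p["example"] for p in prepared_list]}

    # -- forward / backward ------------------------------------------------

    def forward_batch(self, merged: dict,
                      params: GraphiteParams | None = None,
                      with_cache: bool = False):
        """Logits for a (possibly batched) prepared graph, shape (B,)."""
        p = params if params is not None else self.params
        n, c = merged["n"], self.channels
        n_ex = merged["n_examples"]
        rows = merged["rows"]
        feats: list[np.ndarray] = [merged["x0"]]
        caches = []
        for ell, (src_tok, tgt_tok, _) in enumerate(self.config.layers):
            src, tgt, dist, _order = merged["edges"][ell]
            basis_vals = self.bases[ell].values(dist) if len(dist) else \
                np.zeros((0, self.n_basis))
            kernel = p[f"L{ell}.kernel"]
            filt = basis_vals @ kernel
            h_full = np.zeros((n, c))
            hcats = {}
            for e in _entities(src_tok):
                re_ = rows[e]
                hist = _history_slots(self.config, e, ell)
                hcat = np.concatenate([feats[s][re_] for s in hist], axis=1)
                hcats[e] = hcat
                h_full[re_] = hcat @ p[f"L{ell}.src.{e}"]
            # edges are sorted by target, so a reduceat segment sum applies
            msg = _segment_sum(filt * h_full[src], tgt, n) if len(src) \
                else np.zeros((n, c))
            t_full = np.zeros((n, c))
            tcats = {}
            for e in _entities(tgt_tok):
                key = f"L{ell}.tgt.{e}"
                if key in p:
                    re_ = rows[e]
                    hist = _history_slots(self.config, e, ell)
                    tcat = np.concatenate([feats[s][re_] for s in hist], axis=1)
                    tcats[e] = tcat
                    t_full[re_] = tcat @ p[key]
            tgt_rows = merged["tok_rows"][tgt_tok]
            x = msg[tgt_rows] + t_full[tgt_rows]
            a1 = x @ p[f"L{ell}.W1"] + p[f"L{ell}.b1"]
            r1 = _leaky(a1)
            a2 = r1 @ p[f"L{ell}.W2"] + p[f"L{ell}.b2"]
            y, (xhat, inv_std) = _layernorm(a2, p[f"L{ell}.gamma"], p[f"L{ell}.beta"])
            f_new = np.zeros((n, c))
            f_new[tgt_rows] = y
            feats.append(f_new)
            if with_cache:
                caches.append({"basis_vals": basis_vals, "filt": filt,
                               "h_full": h_full, "hcats": hcats, "tcats": tcats,
                               "x": x, "a1": a1, "r1": r1, "xhat": xhat,
                               "inv_std": inv_std, "tgt_rows": tgt_rows})
        # readout: pool each slot per example and entity
        inv_counts = {e: np.where(merged["counts"][e] > 0,
                                  1.0 / np.maximum(merged["counts"][e], 1), 0.0)
                      for e in rows}
        parts = []
        for slot, e in self._readout_plan:
            re_ = rows[e]
            pooled = _segment_sum(feats[slot][re_], merged["ex_id"][e], n_ex) \
                if len(re_) else np.zeros((n_ex, feats[slot].shape[1]))
            if self.pooling == "mean":
                pooled = pooled * inv_counts[e][:, None]
            parts.append(pooled)
        z = np.concatenate(parts, axis=1)
        q1 = z @ p["out.W1"] + p["out.b1"]
        r_out = _leaky(q1)
        logits = r_out @ p["out.W2"][:, 0] + p["out.b2"][0]
        if not with_cache:
            return logits
        cache = {"merged": merged, "feats": feats, "layers": caches,
                 "z": z, "q1": q1, "r_out": r_out, "params": p,
                 "inv_counts": inv_counts}
        return logits, cache

    def forward(self, prepared: dict, params: GraphiteParams | None = None,
                with_cache: bool = False):
        """Scalar logit for a single prepared example."""
        out = self.forward_batch(prepared, params=params, with_cache=with_cache)
        if with_cache:
            logits, cache = out
            return float(logits[0]), cache
        return float(out[0])

    def backward_batch(self, cache: dict, dlogits: np.ndarray,
                       out: GraphiteParams | None = None) -> GraphiteParams:
        """Gradients of ``sum(dlogits * logits)`` w.r.t. every parameter.

        Accumulates into ``out`` when given (avoids reallocating per batch).
        """
        p = cache["params"]
        merged = cache["merged"]
        n, c = merged["n"], self.channels
        rows = merged["rows"]
        feats = cache["feats"]
        dlogits = np.asarray(dlogits, dtype=float)
        grads = out if out is not None else p.zeros_like()

        # head
        grads["out.W2"] += cache["r_out"].T @ dlogits[:, None]
        grads["out.b2"] += np.array([dlogits.sum()])
        dr = dlogits[:, None] * p["out.W2"][:, 0][None, :]
        dq1 = dr * np.where(cache["q1"] > 0, 1.0, LEAKY_SLOPE)
        grads["out.W1"] += cache["z"].T @ dq1
        grads["out.b1"] += dq1.sum(axis=0)
        dz = dq1 @ p["out.W1"].T

        dfeats = [np.zeros_like(f) for f in feats]
        offset = 0
        for slot, e in self._readout_plan:
            dim = self._slot_dims[slot]
            dpart = dz[:, offset:offset + dim]
            if self.pooling == "mean":
                dpart = dpart * cache["inv_counts"][e][:, None]
            re_ = rows[e]
            if len(re_):
                dfeats[slot][re_] += dpart[merged["ex_id"][e]]
            offset += dim

        for ell in reversed(range(self.config.n_layers)):
            lc = cache["layers"][ell]
            src, tgt, _d, src_order = merged["edges"][ell]
            tgt_rows = lc["tgt_rows"]
            dy = dfeats[ell + 1][tgt_rows]
            # LayerNorm backward
            xhat, inv_std = lc["xhat"], lc["inv_std"]
            grads[f"L{ell}.gamma"] += (dy * xhat).sum(axis=0)
            grads[f"L{ell}.beta"] += dy.sum(axis=0)
            dxhat = dy * p[f"L{ell}.gamma"]
            da2 = inv_std * (dxhat - dxhat.mean(axis=1, keepdims=True)
                             - xhat * (dxhat * xhat).mean(axis=1, keepdims=True))
            grads[f"L{ell}.W2"] += lc["r1"].T @ da2
            grads[f"L{ell}.b2"] += da2.sum(axis=0)
            dr1 = da2 @ p[f"L{ell}.W2"].T
            da1 = dr1 * np.where(lc["a1"] > 0, 1.0, LEAKY_SLOPE)
            grads[f"L{ell}.W1"] += lc["x"].T @ da1
            grads[f"L{ell}.b1"] += da1.sum(axis=0)
            dx = da1 @ p[f"L{ell}.W1"].T
            dU = np.zeros((n, c))
            dU[tgt_rows] = dx
            # skip path
            for e, tcat in lc["tcats"].items():
                key = f"L{ell}.tgt.{e}"
                re_ = rows[e]
                dx_e = dU[re_]
                grads[key] += tcat.T @ dx_e
                dtcat = dx_e @ p[key].T
                off = 0
                for s in _history_slots(self.config, e, ell):
                    dim = self._slot_dims[s]
                    dfeats[s][re_] += dtcat[:, off:off + dim]
                    off += dim
            # convolution path
            if len(src):
                dedge = dU[tgt]  # (E, C)
                h_src = lc["h_full"][src]
                dfilt = dedge * h_src
                grads[f"L{ell}.kernel"] += lc["basis_vals"].T @ dfilt
                dh_edges = dedge * lc["filt"]
                dh_full = _segment_sum(dh_edges[src_order], src[src_order], n)
            else:
                dh_full = np.zeros((n, c))
            for e, hcat in lc["hcats"].items():
                key = f"L{ell}.src.{e}"
                re_ = rows[e]
                dh_e = dh_full[re_]
                grads[key] += hcat.T @ dh_e
                dhcat = dh_e @ p[key].T
                off = 0
                for s in _history_slots(self.config, e, ell):
                    dim = self._slot_dims[s]
                    dfeats[s][re_] += dhcat[:, off:off + dim]
                    off += dim
        return grads

    def backward(self, cache: dict, dlogit: float,
                 out: GraphiteParams | None = None) -> GraphiteParams:
        """Single-example convenience wrapper over :meth:`backward_batch`."""
        n_ex = cache["merged"]["n_examples"]
        if n_ex != 1:
            raise ValueError("use backward_batch for batched caches")
        return self.backward_batch(cache, np.array([dlogit]), out=out)

    # -- user-facing scoring ----------------------------------------------

    def score(self, example: ComplexExample) -> float:
        """Ranking logit for one complex (higher = better pose)."""
        return self.forward(self.prepare(example))

    def rescore_attempt(self, examples: list[ComplexExample]) -> list[ScoredPose]:
        """Rank the poses of one docking attempt by descending logit.

        Ties are broken by the original docking rank (stable reranking).
        """
        if not examples:
            raise ValueError("empty docking attempt")
        merged = self.merge_prepared([self.prepare(ex) for ex in examples])
        logits = np.atleast_1d(self.forward_batch(merged))
        scored = [(float(l), ex) for l, ex in zip(logits, examples)]
        order = sorted(range(len(scored)),
                       key=lambda k: (-scored[k][0], scored[k][1].pose.rank))
        return [ScoredPose(example=scored[k][1], logit=scored[k][0],
                           rank=pos + 1, docking_rank=scored[k][1].pose.rank)
                for pos, k in enumerate(order)]

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        """Serialize config, vocabulary, and parameters to one ``.npz`` map."""
        meta = {"layer_spec": self.config.spec_string(),
                "cutoffs": [c for _, _, c in self.config.layers],
                "ligand_types": list(self.vocab.ligand_types),
                "receptor_types": list(self.vocab.receptor_types),
                "allow_other": self.vocab.allow_other,
                "channels": self.channels, "hidden": self.hidden,
                "n_basis": self.n_basis, "pooling": self.pooling,
                "pocket_margin": self.pocket_margin, "seed": self.seed,
                "version": CHECKPOINT_VERSION}
        arrays = {f"param:{k}": v for k, v in self.params.arrays.items()}
        np.savez(path, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "GraphiteNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            vocab = SybylVocabulary(
                ligand_types=tuple(meta["ligand_types"]),
                receptor_types=tuple(meta["receptor_types"]),
                allow_other=meta["allow_other"])
            net = cls(config=parse_layer_config(meta["layer_spec"], meta["cutoffs"]),
                      vocab=vocab, channels=meta["channels"], hidden=meta["hidden"],
                      n_basis=meta["n_basis"], pooling=meta["pooling"],
                      pocket_margin=meta["pocket_margin"], seed=meta["seed"])
            for key in data.files:
                if key.startswith("param:"):
                    net.params[key[len("param:"):]] = data[key].copy()
        net.params.check_finite()
        return net


def forward(example: ComplexExample, config: LayerConfig,
            params_net: GraphiteNet) -> ScoredPose:
    """Score one complex with an existing network (thin functional wrapper)."""
    logit = params_net.score(example)
    return ScoredPose(example=example, logit=logit, rank=1,
                      docking_rank=example.pose.rank)
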