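"""Time-conditioned E(3)-equivariant vector field u_θ(x, t | CGR).

The network maps the current flow state x_t (one 3-vector per atom), the flow
time t, and the invariant CGR features to one velocity 3-vector per atom. It
is an equivariant attention network over scalar node/edge features and
steerable per-node features up to degree L_max (degree-1 vectors, and
degree-2 traceless symmetric tensors stored in a 5-component basis). Edge
geometry enters exclusively through distances (radial basis) and real
spherical harmonics of the unit relative positions; no Clebsch–Gordan tensor
products are used. Because only relative positions are consumed, translation
invariance holds by construction; rotation/reflection equivariance follows
from the velocity being assembled purely from degree-1 features.

Under a reflection the degree-1 basis Y¹(r̂) flips sign while degree-2
components are even; degree-2 information reaches the output only through
invariant channel norms, so the predicted velocity transforms as a proper
vector under all of O(3) — mirroring the input mirrors the prediction, which
is exactly the chirality failure mode a distance-based metric cannot see.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import nn
from .cgr import (
    CGRGraph,
    DEFAULT_ELEMENTS,
    atom_feature_dim,
    build_edge_set,
    pair_feature_dim,
    pair_feature_matrix,
    sinusoidal_time_embedding,
)
from .errors import InputError
from .nn import (MLP, LayerNorm, Linear, Module, Tensor, cols, concat,
                 gather_rows, repeat_cols, segment_softmax, segment_sum)

__all__ = ["FieldConfig", "FieldNet", "save_checkpoint", "load_checkpoint"]


@dataclass
class FieldConfig:
    width: int = 256          # atom-basis dimension (invariant scalar channels)
    n_layers: int = 4
    n_heads: int = 8
    vec_channels: int = 0     # steerable channels; 0 -> width // 4
    l_max: int = 2            # 1 = vectors only, 2 = vectors + rank-2 tensors
    n_rbf: int = 20
    cutoff: float = 10.0      # Å, radius-graph cutoff on the current geometry
    max_hops: int = 3         # hop-distance bound in the CGR union graph
    recompute_edges: bool = True
    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    seed: int = 0

    def __post_init__(self):
        if self.vec_channels == 0:
            self.vec_channels = max(self.n_heads, self.width // 4)
        if self.width % self.n_heads or self.vec_channels % self.n_heads:
            raise InputError("width and vec_channels must be divisible by n_heads")
        if self.l_max not in (1, 2):
            raise InputError("l_max must be 1 or 2")
        self.elements = tuple(self.elements)

    def schema(self) -> dict:
        return {"node_dim": atom_feature_dim(self.elements), "edge_dim": pair_feature_dim()}


def _sph_l2(rhat: np.ndarray) -> np.ndarray:
    """Real second-degree spherical-harmonic basis (5 components, unnormalized)."""
    x, y, z = rhat[:, 0], rhat[:, 1], rhat[:, 2]
    return np.stack([
        np.sqrt(3.0) * x * y,
        np.sqrt(3.0) * y * z,
        0.5 * (3.0 * z ** 2 - 1.0),
        np.sqrt(3.0) * x * z,
        np.sqrt(3.0) * 0.5 * (x ** 2 - y ** 2),
    ], axis=1)


def _channel_norm(v: Tensor, axis: int = 1) -> Tensor:
    return ((v * v).sum(axis=axis) + 1e-12) ** 0.5


class _Interaction(Module):
    """One equivariant attention layer: scalar, vector, and tensor updates."""

    def __init__(self, cfg: FieldConfig, rng: np.random.Generator, last: bool = False):
        w, c, heads = cfg.width, cfg.vec_channels, cfg.n_heads
        self.cfg = cfg
        n_gates = 2 if cfg.l_max == 1 else 4
        self.ln_h = LayerNorm(w)
        self.ln_e = LayerNorm(w)
        self.phi = MLP([3 * w + cfg.n_rbf, w, w + n_gates * c + heads], rng)
        self.node_mlp = MLP([2 * w + cfg.l_max * c, w, w], rng)
        self.edge_mlp = None if last else MLP([w + c, w], rng)
        self.vmix = nn.parameter(rng.standard_normal((c, c)) / np.sqrt(c))
        if cfg.l_max >= 2:
            self.tmix = nn.parameter(rng.standard_normal((c, c)) / np.sqrt(c))

    def __call__(self, h, e, v, t2, geo, update_edges: bool = True):
        cfg = self.cfg
        w, c = cfg.width, cfg.vec_channels
        src, dst, rbf, rhat, y2, n_nodes = geo

        h_in = self.ln_h(h)
        e_in = self.ln_e(e)
        inv = concat([gather_rows(h_in, dst), gather_rows(h_in, src), e_in, Tensor(rbf)])
        phi = self.phi(inv)
        logits = cols(phi, phi.shape[1] - cfg.n_heads, phi.shape[1])
        alpha = segment_softmax(logits, dst, n_nodes)   # (E, heads)
        a_w = repeat_cols(alpha, w // cfg.n_heads)      # per-scalar-channel weight
        a_c = repeat_cols(alpha, c // cfg.n_heads)      # per-steerable-channel weight

        h_agg = segment_sum(a_w * cols(phi, 0, w), dst, n_nodes)

        g1 = cols(phi, w, w + c).expand_dims(1)
        g2 = cols(phi, w + c, w + 2 * c).expand_dims(1)
        a3 = a_c.expand_dims(1)
        v_msg = a3 * (g1 * Tensor(rhat[:, :, None]) + g2 * gather_rows(v, src))
        v = v + segment_sum(v_msg, dst, n_nodes) @ self.vmix

        if cfg.l_max >= 2:
            g3 = cols(phi, w + 2 * c, w + 3 * c).expand_dims(1)
            g4 = cols(phi, w + 3 * c, w + 4 * c).expand_dims(1)
            t_msg = a3 * (g3 * Tensor(y2[:, :, None]) + g4 * gather_rows(t2, src))
            t2 = t2 + segment_sum(t_msg, dst, n_nodes) @ self.tmix
            inv_node = concat([h_in, h_agg, _channel_norm(v), _channel_norm(t2)])
        else:
            inv_node = concat([h_in, h_agg, _channel_norm(v)])
        h = h + self.node_mlp(inv_node)

        # geometry-aware edge refinement: invariant projection of vector
        # features onto the edge direction (skipped after the last layer,
        # where no consumer remains)
        if update_edges and self.edge_mlp is not None:
            proj = (gather_rows(v, dst) * Tensor(rhat[:, :, None])).sum(axis=1)
            e = e + self.edge_mlp(concat([e_in, proj]))
        return h, e, v, t2


class FieldNet(Module):
    """E(3)-equivariant velocity-field network (see module docstring)."""

    def __init__(self, config: FieldConfig | None = None):
        cfg = config or FieldConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.width
        self.node_proj = Linear(atom_feature_dim(cfg.elements), w, rng)
        self.edge_proj = Linear(pair_feature_dim(), w, rng)
        self.layers = [_Interaction(cfg, rng, last=(i == cfg.n_layers - 1))
                       for i in range(cfg.n_layers)]
        self.ln_out = LayerNorm(w)
        self.head_gate = Linear(w, cfg.vec_channels, rng)
        self.head_out = nn.parameter(
            rng.standard_normal((cfg.vec_channels, 1)) / np.sqrt(cfg.vec_channels))

    # ------------------------------------------------------------------
    def forward(self, coords: np.ndarray, t: float, cgr: CGRGraph,
                edge_index: np.ndarray | None = None) -> np.ndarray:
        """Velocity (N×3 NumPy array) for a single molecule at flow time t."""
        out, _ = self.forward_batch([np.asarray(coords)], [float(t)], [cgr],
                                    None if edge_index is None else [edge_index])
        return out.data

    def forward_batch(self, coords_list: list[np.ndarray], t_list: list[float],
                      cgrs: list[CGRGraph],
                      edge_sets: list[np.ndarray] | None = None,
                      ) -> tuple[Tensor, np.ndarray]:
        """Batched forward over a disjoint union of molecular graphs.

        Returns the velocity Tensor (N_total × 3, differentiable w.r.t.
        parameters) and the per-atom graph-id array.
        """
        cfg = self.config
        w = cfg.width
        node_feats, pair_feats, coords_all = [], [], []
        srcs, dsts, t_nodes, t_edges, graph_ids = [], [], [], [], []
        offset = 0
        for k, (coords, t, cgr) in enumerate(zip(coords_list, t_list, cgrs)):
            coords = np.asarray(coords, dtype=np.float64)
            if not np.all(np.isfinite(coords)):
                raise InputError("non-finite coordinates passed to the field network")
            if coords.shape != (cgr.n_atoms, 3):
                raise InputError(
                    f"coords shape {coords.shape} does not match graph with "
                    f"{cgr.n_atoms} atoms")
            ei = (edge_sets[k] if edge_sets is not None
                  else build_edge_set(cgr, coords, cfg.cutoff, cfg.max_hops))
            node_feats.append(cgr.node_features)
            pair_feats.append(pair_feature_matrix(cgr, ei))
            coords_all.append(coords)
            srcs.append(ei[0] + offset)
            dsts.append(ei[1] + offset)
            t_nodes.append(np.full(cgr.n_atoms, t))
            t_edges.append(np.full(ei.shape[1], t))
            graph_ids.append(np.full(cgr.n_atoms, k, dtype=np.intp))
            offset += cgr.n_atoms

        x = np.concatenate(coords_all)
        src = np.concatenate(srcs)
        dst = np.concatenate(dsts)
        n_nodes = offset

        rel = x[dst] - x[src]
        dist = np.linalg.norm(rel, axis=1)
        rhat = rel / np.maximum(dist, 1e-10)[:, None]
        centers = np.linspace(0.0, cfg.cutoff, cfg.n_rbf)
        delta = cfg.cutoff / cfg.n_rbf
        rbf = np.exp(-((dist[:, None] - centers[None, :]) / delta) ** 2)
        y2 = _sph_l2(rhat)

        tau_n = sinusoidal_time_embedding(np.concatenate(t_nodes), w)
        tau_e = sinusoidal_time_embedding(np.concatenate(t_edges), w)
        h = self.node_proj(Tensor(np.concatenate(node_feats))) + Tensor(tau_n)
        e = self.edge_proj(Tensor(np.concatenate(pair_feats))) + Tensor(tau_e)
        v = Tensor(np.zeros((n_nodes, 3, cfg.vec_channels)))
        t2 = Tensor(np.zeros((n_nodes, 5, cfg.vec_channels)))

        geo = (src, dst, rbf, rhat, y2, n_nodes)
        for li, layer in enumerate(self.layers):
            h, e, v, t2 = layer(h, e, v, t2, geo, update_edges=li < len(self.layers) - 1)

        gate = self.head_gate(self.ln_out(h)).silu().expand_dims(1)  # (N, 1, c)
        vel = ((v * gate) @ self.head_out).reshape(n_nodes, 3)
        return vel, np.concatenate(graph_ids)

    def count_parameters(self) -> int:
        return self.n_parameters()


# ---- checkpointing ------------------------------------------------------


def save_checkpoint(net: FieldNet, path: str | Path) -> None:
    """Flat parameter archive (.npz) with a JSON config header."""
    cfg = asdict(net.config)
    cfg["elements"] = list(cfg["elements"])
    header = json.dumps({"config": cfg, "schema": net.config.schema()})
    arrays = {f"p{i}": a for i, a in enumerate(net.state_arrays())}
    np.savez(path, header=np.array(header), **arrays)


def load_checkpoint(path: str | Path) -> FieldNet:
    with np.load(path, allow_pickle=False) as blob:
        header = json.loads(str(blob["header"]))
        cfg_d = header["config"]
        cfg_d["elements"] = tuple(cfg_d["elements"])
        cfg = FieldConfig(**cfg_d)
        if header["schema"] != cfg.schema():
            raise InputError("checkpoint feature schema does not match this build")
        net = FieldNet(cfg)
        n = len(net.parameters())
        net.load_state_arrays([blob[f"p{i}"] for i in range(n)])
    return net
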