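"""Symmetry-adapted molecular channels.

Turns a :class:`~react3d.mol_graph.MolGraph` into a per-atom local
representation ``X`` (N_at x D).  Each convolutional layer forms messages as
the tensor product of neighbor features with the edge's spherical-harmonic
filter, contracted through real Clebsch-Gordan intertwiners into the output
degrees, with per-path channel-mixing weights produced by a two-layer
perceptron on the embedded edge features.  Messages are mean-aggregated and
combined with a learned self-interaction; vector (l = 1) channels pass
through a sigmoid gate driven by the scalar channels.

The invariant variant restricts the filters to l = 0, reducing the
architecture to a continuous-filter distance-based network; the equivariant
variant carries n_v additional l = 1 channels coupled through filters up to
l = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from react3d import so3
from react3d.autodiff import (Parameter, Tensor, einsum, concat, gather,
                              glorot, segment_mean, segment_sum, slice_cols)

__all__ = ["ChannelConfig", "Linear", "MLP", "ConvLayer",
           "MolecularEncoder", "allowed_paths"]


@dataclass
class ChannelConfig:
    """Hyperparameters of the convolution stack.

    n_s : scalar (l = 0) channel count / embedding size ({16, 32, 48, 64}).
    n_v : vector (l = 1) channel count, equivariant variant only.
    n_conv : number of convolutional layers ({2, 3}).
    dropout : dropout probability on scalar channels ({0.0, 0.05, 0.1}).
    sum_mode : "node" (X from node scalars) or "both" (node scalars
        concatenated with mean-pooled incident edge embeddings).
    """

    variant: str = "invariant"           # "invariant" | "equivariant"
    n_s: int = 16
    n_v: int = 16
    n_conv: int = 2
    dropout: float = 0.0
    sum_mode: str = "node"               # "node" | "both"

    def __post_init__(self):
        if self.variant not in ("invariant", "equivariant"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.sum_mode not in ("node", "both"):
            raise ValueError(f"unknown sum_mode {self.sum_mode!r}")
        if self.n_conv < 1:
            raise ValueError("n_conv must be >= 1")

    @property
    def l_max(self) -> int:
        return 0 if self.variant == "invariant" else 2

    @property
    def rep_dim(self) -> int:
        """D, the width of the local representation X."""
        return self.n_s if self.sum_mode == "node" else 2 * self.n_s


def allowed_paths(cfg: ChannelConfig) -> list[tuple[int, int, int]]:
    """(l_in, l_filter, l_out) triples used by the tensor product."""
    if cfg.variant == "invariant":
        return [(0, 0, 0)]
    paths = []
    for l_in in (0, 1):
        for l_f in (0, 1, 2):
            for l_out in (0, 1):
                if abs(l_in - l_f) <= l_out <= l_in + l_f:
                    paths.append((l_in, l_f, l_out))
    return paths


class Linear:
    """Affine map on the last-but-one (channel) axis of (N, C, d) tensors,
    or on the last axis of 2-D tensors."""

    def __init__(self, rng, n_in, n_out, bias=True):
        self.W = Parameter(glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim == 3:
            out = einsum("ncd,co->nod", x, self.W)
            if self.b is not None:
                out = out + self.b.reshape(1, -1, 1)
            return out
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Perceptron with SiLU between layers (fixed project-wide)."""

    def __init__(self, rng, sizes, bias=True, final_bias=None):
        if final_bias is None:
            final_bias = bias
        self.layers = []
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = i == len(sizes) - 2
            self.layers.append(Linear(rng, a, b,
                                      bias=final_bias if last else bias))

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.silu()
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


def _dropout(x: Tensor, p: float, train: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def _channels(cfg: ChannelConfig, l: int) -> int:
    return cfg.n_s if l == 0 else cfg.n_v


class ConvLayer:
    """One fully connected weighted tensor-product convolution."""

    #: messages are summed over incoming edges and scaled by this constant
    #: (a typical inverse square-root coordination number); a plain mean
    #: would erase neighbor-count information from the representation.
    AGG_SCALE = 1.0 / np.sqrt(10.0)

    def __init__(self, cfg: ChannelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.paths = allowed_paths(cfg)
        # per-path channel-mixing weights: a learned base matrix modulated
        # additively by a two-layer perceptron on the embedded edge features
        # (base-centered so messages have healthy scale at initialization)
        self._offsets = []
        self.base = []
        total = 0
        for (l_in, _l_f, l_out) in self.paths:
            n_in, n_out = _channels(cfg, l_in), _channels(cfg, l_out)
            self._offsets.append((total, n_in, n_out))
            self.base.append(Parameter(glorot(rng, n_in, n_out,
                                              shape=(n_out, n_in))))
            total += n_in * n_out
        self.weight_mlp = MLP(rng, [cfg.n_s, cfg.n_s, total])
        self.self0 = Linear(rng, cfg.n_s, cfg.n_s)
        if cfg.variant == "equivariant":
            self.self1 = Linear(rng, cfg.n_v, cfg.n_v, bias=False)
            self.gate = Linear(rng, cfg.n_s, cfg.n_v)

    def parameters(self):
        ps = list(self.base) + self.weight_mlp.parameters() \
            + self.self0.parameters()
        if self.cfg.variant == "equivariant":
            ps += self.self1.parameters() + self.gate.parameters()
        return ps

    def __call__(self, feats, edge_index, sph, edge_emb,
                 train=False, rng=None):
        """feats: dict {l: Tensor (N, C_l, 2l+1)} -> same structure."""
        cfg = self.cfg
        n_nodes = feats[0].shape[0]
        agg = {l: None for l in feats}
        if edge_index.shape[1] > 0:
            src, dst = edge_index
            w_all = self.weight_mlp(edge_emb)       # (E, total)
            for k, (path, (off, n_in, n_out)) in enumerate(
                    zip(self.paths, self._offsets)):
                l_in, l_f, l_out = path
                if l_f > cfg.l_max:
                    raise ValueError("filter degree exceeds configured l_max")
                C = Tensor(so3.w3j(l_in, l_f, l_out))   # (d_out, d_in, d_f)
                x_src = gather(feats[l_in], src)        # (E, n_in, d_in)
                Y = Tensor(sph[l_f])                    # (E, d_f)
                tp = einsum("kij,eci,ej->eck", C, x_src, Y)
                w_slice = (w_all if len(self.paths) == 1 else
                           slice_cols(w_all, off, off + n_in * n_out))
                W = (self.base[k].reshape(1, n_out, n_in)
                     + w_slice.reshape(-1, n_out, n_in))
                msg = einsum("eoc,eck->eok", W, tp)     # (E, n_out, d_out)
                pooled = segment_sum(msg, dst, n_nodes) * self.AGG_SCALE
                agg[l_out] = pooled if agg[l_out] is None \
                    else agg[l_out] + pooled
        # self-interaction + aggregation + nonlinearity
        pre0 = self.self0(feats[0])
        if agg[0] is not None:
            pre0 = pre0 + agg[0]
        x0 = _dropout(pre0.silu(), cfg.dropout, train, rng)
        out = {0: x0}
        if cfg.variant == "equivariant":
            pre1 = self.self1(feats[1])
            if agg.get(1) is not None:
                pre1 = pre1 + agg[1]
            gates = self.gate(x0.reshape(-1, cfg.n_s)).sigmoid()
            out[1] = pre1 * gates.reshape(-1, cfg.n_v, 1)
        return out


class MolecularEncoder:
    """Embeddings + n_conv tensor-product convolutions + readout to X.

    One encoder instance is shared by every molecule on both sides of a
    reaction (weight sharing across reactant and product channels).
    """

    def __init__(self, cfg: ChannelConfig, n_node_feats: int, n_g: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.embed_node = MLP(rng, [n_node_feats, cfg.n_s, cfg.n_s])
        self.embed_edge = MLP(rng, [n_g, cfg.n_s, cfg.n_s])
        self.convs = [ConvLayer(cfg, rng) for _ in range(cfg.n_conv)]

    def parameters(self):
        ps = self.embed_node.parameters() + self.embed_edge.parameters()
        for c in self.convs:
            ps += c.parameters()
        return ps

    def embed(self, node_feats0: np.ndarray, edge_feats0: np.ndarray
              ) -> tuple[Tensor, Tensor]:
        """Initial embeddings x^(1) (N, n_s) and e (E, n_s)."""
        x = self.embed_node(Tensor(node_feats0))
        e = self.embed_edge(Tensor(edge_feats0))
        return x, e

    def __call__(self, node_feats0, edge_index, edge_feats0, sph,
                 train=False, rng=None) -> Tensor:
        """Local representation X (N, D) for a (possibly batched) graph."""
        cfg = self.cfg
        n = node_feats0.shape[0]
        x0_flat, e = self.embed(node_feats0, edge_feats0)
        feats = {0: x0_flat.reshape(n, cfg.n_s, 1)}
        if cfg.variant == "equivariant":
            feats[1] = Tensor(np.zeros((n, cfg.n_v, 3)))
        for conv in self.convs:
            feats = conv(feats, edge_index, sph, e, train=train, rng=rng)
        return self.local_representation(feats, e, edge_index, n)

    def local_representation(self, feats, edge_emb, edge_index,
                             n_nodes) -> Tensor:
        """X from final node scalars, optionally with pooled edge features."""
        x = feats[0].reshape(n_nodes, self.cfg.n_s)
        if self.cfg.sum_mode == "node":
            return x
        if edge_index.shape[1] > 0:
            pooled = segment_mean(edge_emb, edge_index[1], n_nodes)
        else:
            pooled = Tensor(np.zeros((n_nodes, self.cfg.n_s)))
        return concat([x, pooled], axis=1)
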