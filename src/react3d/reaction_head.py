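"""Combining reactant and product representations into predictions.

Three mapping variants link the two sides of a reaction:

* ``M`` — atom-mapped: product atom rows are reordered so that row i
  corresponds to the same atom as reactant row i (requires a mapping);
* ``X`` — cross-attention: a learned soft alignment from reactant queries
  over product atoms stands in for the mapping;
* ``S`` — mapping-free: each side is pooled globally before combination.

Two readout modes produce the scalar: ``vector`` builds a global reaction
vector and regresses the target with a perceptron; ``energy`` learns
per-atom scalar contributions ("quasi-molecular energies") that are summed.
Energy-mode perceptrons are entirely bias-free and use the odd tanh
nonlinearity, so an identity reaction under ``diff`` combination predicts
exactly zero and swapping the sides negates the prediction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from react3d.autodiff import Parameter, Tensor, concat, gather, segment_sum
from react3d.mol_graph import GraphConfig, MolGraph, N_NODE_FEATURES
from react3d.reaction_io import ReactionRecord
from react3d.sym_channels import ChannelConfig, Linear, MolecularEncoder

__all__ = [
    "HeadConfig",
    "ReactionModel",
    "PreparedReaction",
    "reorder_by_mapping",
    "CrossAttention",
    "combine_local",
]


@dataclass
class HeadConfig:
    """How the two sides are linked, combined, and read out."""

    mapping_variant: str = "S"           # "M" | "X" | "S"
    combine_mode: str = "diff"           # "diff" | "sum" | "mean" | "mlp"
    graph_mode: str = "energy"           # "vector" | "energy"

    def __post_init__(self):
        if self.mapping_variant not in ("M", "X", "S"):
            raise ValueError(f"unknown mapping variant {self.mapping_variant!r}")
        if self.combine_mode not in ("diff", "sum", "mean", "mlp"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")
        if self.graph_mode not in ("vector", "energy"):
            raise ValueError(f"unknown graph_mode {self.graph_mode!r}")


# ---------------------------------------------------------------------------
# alignment and combination primitives
# ---------------------------------------------------------------------------

def reorder_by_mapping(X_product, atom_map) -> Tensor:
    """Reorder product rows so row i matches reactant atom i.

    ``atom_map[j] = i`` assigns product atom j to reactant atom i; it must
    be a full permutation of the modeled atoms (unbalanced reactions are
    rejected).
    """
    atom_map = np.asarray(atom_map, dtype=np.intp)
    X_product = Tensor._lift(X_product)
    n = X_product.shape[0]
    if len(atom_map) != n or sorted(atom_map.tolist()) != list(range(n)):
        raise ValueError("unbalanced reaction: atom map is not a bijection "
                         "over the modeled atoms")
    inv = np.empty(n, dtype=np.intp)
    inv[atom_map] = np.arange(n)
    return gather(X_product, inv)


class CrossAttention:
    """Single-head scaled dot-product attention, reactant queries over
    product atoms."""

    def __init__(self, rng, dim):
        self.dim = dim
        self.Wq = Linear(rng, dim, dim, bias=False)
        self.Wk = Linear(rng, dim, dim, bias=False)
        self.Wv = Linear(rng, dim, dim, bias=False)

    def parameters(self):
        return (self.Wq.parameters() + self.Wk.parameters()
                + self.Wv.parameters())

    def __call__(self, X_reactant: Tensor, X_product: Tensor) -> Tensor:
        if X_product.shape[0] == 0:
            raise ValueError("empty product side")
        q = self.Wq(X_reactant)
        k = self.Wk(X_product)
        v = self.Wv(X_product)
        att = (q @ _transpose(k)) * (1.0 / np.sqrt(self.dim))
        att = att.softmax(axis=-1)          # rows sum to 1
        return att @ v


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, (t,))
    out._backward = lambda g: t.requires_grad and t._accum(g.T)
    return out


def combine_local(X_reactant: Tensor, X_product: Tensor, mode: str,
                  mlp=None) -> Tensor:
    """Rowwise combination of aligned representations."""
    if X_reactant.shape != X_product.shape:
        raise ValueError("shape mismatch between reactant and product "
                         "representations")
    if mode == "diff":
        return X_product - X_reactant
    if mode == "sum":
        return X_product + X_reactant
    if mode == "mean":
        return (X_product + X_reactant) * 0.5
    if mode == "mlp":
        return mlp(concat([X_reactant, X_product], axis=1))
    raise ValueError(f"unknown combine_mode {mode!r}")


class _TanhMLP:
    """Bias-free tanh perceptron (odd function; exactly zero at zero)."""

    def __init__(self, rng, sizes):
        self.layers = [Linear(rng, a, b, bias=False)
                       for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.tanh()
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class _BiasedMLP:
    """tanh perceptron with biases (vector-mode readouts)."""

    def __init__(self, rng, sizes):
        self.layers = [Linear(rng, a, b, bias=True)
                       for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.tanh()
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


# ---------------------------------------------------------------------------
# prepared reactions and batching
# ---------------------------------------------------------------------------

@dataclass
class PreparedReaction:
    """A reaction converted to model-ready graphs (H exclusion applied)."""

    id: str
    target: float
    r_graphs: list[MolGraph]
    p_graphs: list[MolGraph]
    align: np.ndarray | None    # variant M: product-local row for reactant i

    @property
    def n_r(self):
        return sum(g.n_atoms for g in self.r_graphs)

    @property
    def n_p(self):
        return sum(g.n_atoms for g in self.p_graphs)


def _heavy_alignment(record: ReactionRecord, exclude_h: bool) -> np.ndarray:
    """Side-local permutation: align[i_react_model] = product model row.

    Model atoms are the heavy atoms when ``exclude_h`` (hydrogens drop out
    of the mapping requirement), otherwise all atoms.
    """
    if record.atom_map is None:
        raise ValueError(f"reaction {record.id}: mapping variant M requires "
                         "an atom map")

    def model_positions(mols):
        pos, off = [], 0
        for m in mols:
            for i, el in enumerate(m.elements):
                if not (exclude_h and el == "H"):
                    pos.append(off + i)
            off += m.n_atoms
        return {g: k for k, g in enumerate(pos)}, pos

    r_index, _ = model_positions(record.reactants)
    p_index, p_pos = model_positions(record.products)
    if len(r_index) != len(p_index):
        raise ValueError(f"reaction {record.id}: unbalanced reaction")
    align = np.full(len(r_index), -1, dtype=np.intp)
    for j_global in p_pos:
        i_global = record.atom_map[j_global]
        if i_global < 0:
            raise ValueError(f"reaction {record.id}: unmapped modeled atom")
        if i_global not in r_index:
            raise ValueError(f"reaction {record.id}: atom map crosses the "
                             "hydrogen-exclusion boundary")
        align[r_index[i_global]] = p_index[j_global]
    if np.any(align < 0):
        raise ValueError(f"reaction {record.id}: incomplete atom map")
    return align


def _batch_graphs(graphs: list[MolGraph], l_max: int):
    """Disjoint union of graphs: stacked features + offset edge index."""
    node_feats = np.vstack([g.node_feats0 for g in graphs])
    offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
    edges = []
    for g, off in zip(graphs, offsets[:-1]):
        if g.n_edges:
            edges.append(g.edge_index + off)
    edge_index = (np.concatenate(edges, axis=1) if edges
                  else np.zeros((2, 0), dtype=np.intp))
    edge_feats = np.vstack([g.edge_feats0 for g in graphs])
    sph = {l: np.vstack([g.sph[l] for g in graphs])
           for l in range(l_max + 1)}
    return node_feats, edge_index, edge_feats, sph, offsets


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class ReactionModel:
    """End-to-end model: shared molecular encoder + reaction head."""

    def __init__(self,
                 graph_cfg: GraphConfig | None = None,
                 channel_cfg: ChannelConfig | None = None,
                 head_cfg: HeadConfig | None = None,
                 seed: int = 0):
        self.graph_cfg = graph_cfg or GraphConfig()
        self.channel_cfg = channel_cfg or ChannelConfig()
        self.head_cfg = head_cfg or HeadConfig()
        # filter degrees follow the variant
        self.graph_cfg.l_max = self.channel_cfg.l_max
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = MolecularEncoder(self.channel_cfg, N_NODE_FEATURES,
                                        self.graph_cfg.n_g, rng)
        D = self.channel_cfg.rep_dim
        h = self.head_cfg
        self.attention = (CrossAttention(rng, D)
                          if h.mapping_variant == "X" else None)
        self.combine_mlp = (_BiasedMLP(rng, [2 * D, D, D, D])
                            if h.combine_mode == "mlp" else None)
        if h.graph_mode == "energy":
            self.energy_mlp = _TanhMLP(rng, [D, D, D, 1])
            self.out_mlp = (_BiasedMLP(rng, [2, 4, 4, 1])
                            if (h.mapping_variant == "S"
                                and h.combine_mode == "mlp") else None)
        else:
            self.atom_mlp = _BiasedMLP(rng, [D, D, D, D])
            self.out_mlp = _BiasedMLP(rng, [D, D, D, 1])
        # target standardization constants (set during training)
        self.target_mean = 0.0
        self.target_std = 1.0

    # -- parameters --------------------------------------------------------

    def parameters(self) -> list[Parameter]:
        ps = self.encoder.parameters()
        if self.attention is not None:
            ps += self.attention.parameters()
        if self.combine_mlp is not None:
            ps += self.combine_mlp.parameters()
        if self.head_cfg.graph_mode == "energy":
            ps += self.energy_mlp.parameters()
        else:
            ps += self.atom_mlp.parameters()
        if getattr(self, "out_mlp", None) is not None:
            ps += self.out_mlp.parameters()
        return ps

    # -- data preparation --------------------------------------------------

    def prepare(self, records: list[ReactionRecord]) -> list[PreparedReaction]:
        out = []
        need_align = self.head_cfg.mapping_variant == "M"
        for rec in records:
            align = (_heavy_alignment(rec, self.graph_cfg.exclude_h)
                     if need_align else None)
            out.append(PreparedReaction(
                id=rec.id, target=rec.target,
                r_graphs=[MolGraph.build(m, self.graph_cfg)
                          for m in rec.reactants],
                p_graphs=[MolGraph.build(m, self.graph_cfg)
                          for m in rec.products],
                align=align))
        return out

    # -- forward -----------------------------------------------------------

    def forward(self, prepared: list[PreparedReaction],
                train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Standardized-scale predictions, shape (B,)."""
        all_graphs = []
        r_spans, p_spans = [], []
        cursor = 0
        for pr in prepared:
            all_graphs.extend(pr.r_graphs)
            r_spans.append((cursor, cursor + pr.n_r))
            cursor += pr.n_r
            all_graphs.extend(pr.p_graphs)
            p_spans.append((cursor, cursor + pr.n_p))
            cursor += pr.n_p
        node_feats, edge_index, edge_feats, sph, _ = _batch_graphs(
            all_graphs, self.channel_cfg.l_max)
        X = self.encoder(node_feats, edge_index, edge_feats, sph,
                         train=train, rng=rng)

        h = self.head_cfg
        B = len(prepared)
        if h.mapping_variant == "S":
            return self._head_unmapped(X, prepared, r_spans, p_spans)

        # aligned local reaction representation (variants M and X)
        if h.mapping_variant == "M":
            r_idx, p_idx, rxn_ids = [], [], []
            for b, pr in enumerate(prepared):
                if pr.align is None:
                    raise ValueError("variant M requires prepared alignments")
                r0, r1 = r_spans[b]
                p0, _ = p_spans[b]
                r_idx.append(np.arange(r0, r1))
                p_idx.append(p0 + pr.align)
                rxn_ids.append(np.full(r1 - r0, b))
            Xr = gather(X, np.concatenate(r_idx))
            Xp = gather(X, np.concatenate(p_idx))
            rxn_ids = np.concatenate(rxn_ids)
        else:  # variant X
            xr_list, xp_list, rxn_ids = [], [], []
            for b, pr in enumerate(prepared):
                r0, r1 = r_spans[b]
                p0, p1 = p_spans[b]
                xr = X[r0:r1]
                xp_aligned = self.attention(xr, X[p0:p1])
                xr_list.append(xr)
                xp_list.append(xp_aligned)
                rxn_ids.append(np.full(r1 - r0, b))
            Xr = concat(xr_list, axis=0)
            Xp = concat(xp_list, axis=0)
            rxn_ids = np.concatenate(rxn_ids)

        X_rxn = combine_local(Xr, Xp, h.combine_mode, self.combine_mlp)
        if h.graph_mode == "energy":
            contrib = self.energy_mlp(X_rxn)                # (ΣN, 1)
            pred = segment_sum(contrib, rxn_ids, B)
        else:
            phi = self.atom_mlp(X_rxn)
            Xbar = segment_sum(phi, rxn_ids, B)             # (B, D)
            pred = self.out_mlp(Xbar)
        return pred.reshape(B)

    def _head_unmapped(self, X, prepared, r_spans, p_spans) -> Tensor:
        """Variant S: per-side pooling before combination."""
        h = self.head_cfg
        B = len(prepared)
        side_ids = np.empty(X.shape[0], dtype=np.intp)
        for b in range(B):
            r0, r1 = r_spans[b]
            p0, p1 = p_spans[b]
            side_ids[r0:r1] = 2 * b
            side_ids[p0:p1] = 2 * b + 1
        if h.graph_mode == "energy":
            contrib = self.energy_mlp(X)                    # (ΣN, 1)
            E = segment_sum(contrib, side_ids, 2 * B)       # (2B, 1)
            E_r, E_p = E[0::2], E[1::2]
            if h.combine_mode == "diff":
                pred = E_p - E_r
            elif h.combine_mode == "sum":
                pred = E_p + E_r
            elif h.combine_mode == "mean":
                pred = (E_p + E_r) * 0.5
            else:
                pred = self.out_mlp(concat([E_r, E_p], axis=1))
            return pred.reshape(B)
        phi = self.atom_mlp(X)
        Xbar = segment_sum(phi, side_ids, 2 * B)            # (2B, D)
        Xbar_r, Xbar_p = Xbar[0::2], Xbar[1::2]
        combined = combine_local(Xbar_r, Xbar_p, h.combine_mode,
                                 self.combine_mlp)
        return self.out_mlp(combined).reshape(B)

    # -- inference ---------------------------------------------------------

    def predict(self, records_or_prepared) -> np.ndarray:
        """Predictions in original target units (kcal/mol)."""
        items = list(records_or_prepared)
        if items and isinstance(items[0], ReactionRecord):
            items = self.prepare(items)
        preds = []
        for start in range(0, len(items), 64):
            chunk = items[start:start + 64]
            preds.append(self.forward(chunk).data)
        out = np.concatenate(preds) if preds else np.zeros(0)
        return out * self.target_std + self.target_mean

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str) -> None:
        meta = {
            "version": 1,
            "graph_cfg": asdict(self.graph_cfg),
            "channel_cfg": asdict(self.channel_cfg),
            "head_cfg": asdict(self.head_cfg),
            "seed": self.seed,
            "target_mean": self.target_mean,
            "target_std": self.target_std,
        }
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "ReactionModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            model = cls(GraphConfig(**meta["graph_cfg"]),
                        ChannelConfig(**meta["channel_cfg"]),
                        HeadConfig(**meta["head_cfg"]),
                        seed=meta["seed"])
            model.target_mean = meta["target_mean"]
            model.target_std = meta["target_std"]
            for i, p in enumerate(model.parameters()):
                p.data[...] = data[f"p{i}"]
        return model

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data[...] = s
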