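"""Convolution stack: oracle equivalence, equivariance, probe behavior."""

import numpy as np
import pytest

from react3d import so3
from react3d.autodiff import Tensor
from react3d.mol_graph import (GraphConfig, MolGraph, N_NODE_FEATURES,
                               sph_filters)
from react3d.reaction_io import Molecule3D
from react3d.sym_channels import (ChannelConfig, ConvLayer, MolecularEncoder,
                                  allowed_paths)
from react3d.synthetic_fixtures import make_angle_probe_pair


def _np_silu(x):
    return x / (1.0 + np.exp(-x))


def _np_mlp(mlp, x):
    """Evaluate an MLP's forward pass with plain NumPy."""
    for i, layer in enumerate(mlp.layers):
        x = x @ layer.W.data
        if layer.b is not None:
            x = x + layer.b.data
        if i < len(mlp.layers) - 1:
            x = _np_silu(x)
    return x


def brute_force_conv(layer, feats, edge_index, sph, edge_emb):
    """Reference implementation: explicit loops over edges, tensor-product
    paths, and Clebsch-Gordan component indices."""
    cfg = layer.cfg
    n = feats[0].shape[0]
    E = edge_index.shape[1]
    w_all = _np_mlp(layer.weight_mlp, edge_emb)
    agg = {l: np.zeros_like(feats[l]) for l in feats}
    for e in range(E):
        a, b = int(edge_index[0, e]), int(edge_index[1, e])
        for path, (off, n_in, n_out), base in zip(
                layer.paths, layer._offsets, layer.base):
            l_in, l_f, l_out = path
            C = so3.w3j(l_in, l_f, l_out)
            W = base.data + w_all[e, off:off + n_in * n_out].reshape(
                n_out, n_in)
            for o in range(n_out):
                for c in range(n_in):
                    for k in range(2 * l_out + 1):
                        s = 0.0
                        for i in range(2 * l_in + 1):
                            for j in range(2 * l_f + 1):
                                s += C[k, i, j] * feats[l_in][a, c, i] \
                                    * sph[l_f][e, j]
                        agg[l_out][b, o, k] += W[o, c] * s
    for l in agg:
        agg[l] *= layer.AGG_SCALE
    pre0 = np.einsum("ncd,co->nod", feats[0], layer.self0.W.data) \
        + layer.self0.b.data.reshape(1, -1, 1) + agg[0]
    out = {0: _np_silu(pre0)}
    if cfg.variant == "equivariant":
        pre1 = np.einsum("ncd,co->nod", feats[1], layer.self1.W.data) \
            + agg[1]
        gates = 1.0 / (1.0 + np.exp(-(out[0][:, :, 0] @ layer.gate.W.data
                                      + layer.gate.b.data)))
        out[1] = pre1 * gates[:, :, None]
    return out


@pytest.mark.parametrize("variant", ["invariant", "equivariant"])
def test_conv_layer_matches_brute_force_path_sum(variant):
    """Criterion: vectorized tensor-product convolution equals an explicit
    Clebsch-Gordan path-sum loop on a 3-atom graph (n_s = n_v = 2)."""
    rng = np.random.default_rng(0)
    cfg = ChannelConfig(variant=variant, n_s=2, n_v=2)
    layer = ConvLayer(cfg, rng)
    coords = np.array([[0.0, 0, 0], [1.3, 0.2, 0], [0.4, 1.1, 0.7]])
    edge_index = np.array([[0, 0, 1, 1, 2, 2], [1, 2, 0, 2, 0, 1]])
    rel = coords[edge_index[1]] - coords[edge_index[0]]
    sph = sph_filters(rel, l_max=cfg.l_max)
    feats_np = {0: rng.normal(size=(3, 2, 1))}
    if variant == "equivariant":
        feats_np[1] = rng.normal(size=(3, 2, 3))
    edge_emb = rng.normal(size=(6, cfg.n_s))
    out = layer({l: Tensor(v) for l, v in feats_np.items()},
                edge_index, sph, Tensor(edge_emb))
    ref = brute_force_conv(layer, feats_np, edge_index, sph, edge_emb)
    for l in ref:
        np.testing.assert_allclose(out[l].data, ref[l], atol=1e-6)


def _run_encoder(encoder, mol, gcfg):
    g = MolGraph.build(mol, gcfg)
    return encoder(g.node_feats0, g.edge_index, g.edge_feats0, g.sph).data


def _random_cloud(rng, n=7):
    return Molecule3D(["C"] * n, rng.uniform(0, 3.2, size=(n, 3)))


def test_invariant_output_unchanged_by_rotation():
    rng = np.random.default_rng(1)
    mol = _random_cloud(rng)
    gcfg = GraphConfig(r_max=4.0, l_max=0, exclude_h=False)
    enc = MolecularEncoder(ChannelConfig("invariant", n_s=8), N_NODE_FEATURES,
                           gcfg.n_g, np.random.default_rng(2))
    X1 = _run_encoder(enc, mol, gcfg)
    R = so3.random_rotation(rng)
    X2 = _run_encoder(
        enc, Molecule3D(list(mol.elements), mol.coords @ R.T + 1.5), gcfg)
    np.testing.assert_allclose(X1, X2, atol=1e-6)


def test_equivariant_l1_features_rotate_with_input():
    """Internal l=1 features of a rotated input equal the rotation applied
    to the original l=1 features."""
    rng = np.random.default_rng(4)
    mol = _random_cloud(rng)
    gcfg = GraphConfig(r_max=4.0, l_max=2, exclude_h=False)
    ccfg = ChannelConfig("equivariant", n_s=8, n_v=8)
    enc = MolecularEncoder(ccfg, N_NODE_FEATURES, gcfg.n_g,
                           np.random.default_rng(5))
    R = so3.random_rotation(rng)

    def features_l1(m):
        g = MolGraph.build(m, gcfg)
        x0, e = enc.embed(g.node_feats0, g.edge_feats0)
        feats = {0: x0.reshape(m.n_atoms, ccfg.n_s, 1),
                 1: Tensor(np.zeros((m.n_atoms, ccfg.n_v, 3)))}
        for conv in enc.convs:
            feats = conv(feats, g.edge_index, g.sph, e)
        return feats[1].data

    f1 = features_l1(mol)
    f2 = features_l1(Molecule3D(list(mol.elements), mol.coords @ R.T))
    np.testing.assert_allclose(f2, f1 @ R.T, atol=1e-5)


def test_isolated_node_output_is_pure_self_interaction():
    rng = np.random.default_rng(6)
    # two far-apart atoms plus one bonded pair: the far atom has no edges
    coords = np.array([[0.0, 0, 0], [1.4, 0, 0], [30.0, 0, 0]])
    mol = Molecule3D(["C", "C", "C"], coords)
    gcfg = GraphConfig(r_max=4.0, l_max=0, exclude_h=False)
    enc = MolecularEncoder(ChannelConfig("invariant", n_s=8),
                           N_NODE_FEATURES, gcfg.n_g,
                           np.random.default_rng(7))
    X = _run_encoder(enc, mol, gcfg)
    lone = _run_encoder(enc, Molecule3D(["C"], coords[2:3]), gcfg)
    np.testing.assert_allclose(X[2], lone[0], atol=1e-12)


def test_permutation_equivariance_of_rows():
    rng = np.random.default_rng(8)
    mol = _random_cloud(rng, n=6)
    gcfg = GraphConfig(r_max=4.0, l_max=0, exclude_h=False)
    enc = MolecularEncoder(ChannelConfig("invariant", n_s=8),
                           N_NODE_FEATURES, gcfg.n_g,
                           np.random.default_rng(9))
    X = _run_encoder(enc, mol, gcfg)
    perm = rng.permutation(6)
    mol_p = Molecule3D([mol.elements[i] for i in perm], mol.coords[perm])
    Xp = _run_encoder(enc, mol_p, gcfg)
    np.testing.assert_allclose(Xp, X[perm], atol=1e-10)


def test_embedding_of_identical_descriptors_is_identical():
    enc = MolecularEncoder(ChannelConfig("invariant", n_s=8),
                           N_NODE_FEATURES, 32, np.random.default_rng(0))
    feats = np.tile(np.arange(16.0), (3, 1))
    x, _ = enc.embed(feats, np.zeros((0, 32)))
    assert x.shape == (3, 8)
    np.testing.assert_allclose(x.data[0], x.data[1], atol=1e-15)
    np.testing.assert_allclose(x.data[0], x.data[2], atol=1e-15)


def test_sum_mode_both_concatenates_pooled_edges():
    rng = np.random.default_rng(10)
    mol = _random_cloud(rng, n=5)
    gcfg = GraphConfig(r_max=4.0, l_max=0, exclude_h=False)
    enc = MolecularEncoder(ChannelConfig("invariant", n_s=8,
                                         sum_mode="both"),
                           N_NODE_FEATURES, gcfg.n_g,
                           np.random.default_rng(11))
    X = _run_encoder(enc, mol, gcfg)
    assert X.shape == (5, 16)
    # edgeless graph: pooled edge block is zero
    lone = _run_encoder(enc, Molecule3D(["C"], np.zeros((1, 3))), gcfg)
    np.testing.assert_array_equal(lone[0, 8:], np.zeros(8))


@pytest.mark.parametrize("n_conv", [2, 3])
def test_angle_probe_invariant_blind_equivariant_sensitive(n_conv):
    """Below-cutoff neighbor geometry: identical radial environments make
    the invariant channels blind to the planar/pyramidal difference, while
    equivariant channels separate the two structures."""
    planar, pyram = make_angle_probe_pair(r=1.5, cutoff=1.9)
    inv_cfg = GraphConfig(r_max=1.9, n_neigh=10, l_max=0, exclude_h=False)
    eq_cfg = GraphConfig(r_max=1.9, n_neigh=10, l_max=2, exclude_h=False)
    # invariant: identical representations for every seed
    for seed in range(3):
        enc = MolecularEncoder(ChannelConfig("invariant", n_conv=n_conv),
                               N_NODE_FEATURES, inv_cfg.n_g,
                               np.random.default_rng(seed))
        X1 = _run_encoder(enc, planar, inv_cfg)
        X2 = _run_encoder(enc, pyram, inv_cfg)
        assert np.abs(X1 - X2).max() <= 1e-6
    # equivariant: separation in most initializations
    hits = 0
    for seed in range(5):
        enc = MolecularEncoder(
            ChannelConfig("equivariant", n_conv=n_conv, n_v=16),
            N_NODE_FEATURES, eq_cfg.n_g, np.random.default_rng(seed))
        X1 = _run_encoder(enc, planar, eq_cfg)
        X2 = _run_encoder(enc, pyram, eq_cfg)
        rel = np.linalg.norm(X1 - X2) / np.linalg.norm(X1)
        hits += rel > 1e-3
    assert hits >= 4
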