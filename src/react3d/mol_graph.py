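"""Distance-based molecular graphs and their initial features.

A molecule enters the network as a radius graph: directed edges to all
atoms within the cutoff ``r_max``, truncated to the ``n_neigh`` nearest and
symmetrized.  Nodes carry 16 cheminformatics descriptors, edges carry a
smooth radial basis expansion of the interatomic distance, and each edge
additionally carries the real spherical harmonics of its direction up to
``l_max`` (``l_max = 0`` for the invariant model, 2 for the equivariant
one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from react3d import so3
from react3d.reaction_io import Molecule3D

__all__ = [
    "GraphConfig",
    "MolGraph",
    "build_radius_graph",
    "radial_edge_features",
    "sph_filters",
    "initial_node_features",
    "rdkit_atom_descriptors",
    "fallback_descriptors",
    "N_NODE_FEATURES",
]

N_NODE_FEATURES = 16


@dataclass
class GraphConfig:
    """Graph construction hyperparameters.

    r_max : radial cutoff in Å (search space {2.5, 5.0, 10.0}).
    n_neigh : cap on neighbors per atom (search space {10, 25, 50}).
    n_g : number of radial edge features (search space {16, 32, 48, 64}).
    l_max : highest spherical-harmonic degree of the edge filters
        (0 = invariant model, 2 = equivariant model).
    exclude_h : drop hydrogen atoms as nodes; hydrogen counts survive in
        the attached-H node descriptor of the heavy atoms.
    """

    r_max: float = 5.0
    n_neigh: int = 25
    n_g: int = 32
    l_max: int = 0
    exclude_h: bool = True

    def __post_init__(self):
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.n_neigh < 1:
            raise ValueError("n_neigh must be >= 1")
        if self.n_g < 2:
            raise ValueError("n_g must be >= 2")
        if self.l_max not in (0, 1, 2):
            raise ValueError("l_max must be 0, 1 or 2")


def build_radius_graph(coords: np.ndarray, r_max: float,
                       n_neigh: int) -> np.ndarray:
    """Directed edge index (2, E) of the truncated radius graph.

    Each atom points to its neighbors within ``r_max``, keeping the
    ``n_neigh`` smallest distances (ties broken by atom index); the edge
    set is then symmetrized by union with its reversal, so (a, b) is
    present iff (b, a) is.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n == 0:
        raise ValueError("empty molecule")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    pairs: set[tuple[int, int]] = set()
    for i in range(n):
        cand = [(d[i, j], j) for j in range(n) if j != i and d[i, j] <= r_max]
        cand.sort()
        for _, j in cand[:n_neigh]:
            pairs.add((i, j))
    pairs |= {(b, a) for a, b in pairs}
    if not pairs:
        return np.zeros((2, 0), dtype=np.intp)
    edges = np.array(sorted(pairs), dtype=np.intp).T
    return edges


def radial_edge_features(d: np.ndarray, cfg: GraphConfig) -> np.ndarray:
    """Smooth radial basis expansion of distances, shape (E, n_g).

    Gaussians with ``n_g`` centers uniformly spaced on [0, r_max], width
    equal to the spacing, enveloped by a cosine cutoff vanishing at
    ``r_max``.  Symmetric in the edge direction by construction.
    """
    d = np.atleast_1d(np.asarray(d, dtype=np.float64))
    if np.any(d <= 0):
        raise ValueError("coincident atoms: zero interatomic distance")
    if np.any(d > cfg.r_max + 1e-12):
        raise ValueError("edge beyond the radial cutoff")
    centers = np.linspace(0.0, cfg.r_max, cfg.n_g)
    width = centers[1] - centers[0]
    basis = np.exp(-((d[:, None] - centers[None, :]) ** 2) / (2.0 * width**2))
    envelope = 0.5 * (np.cos(np.pi * d / cfg.r_max) + 1.0)
    return basis * envelope[:, None]


def sph_filters(rel_vecs: np.ndarray, l_max: int) -> dict[int, np.ndarray]:
    """Real spherical harmonics of edge directions for l = 0..l_max."""
    return {l: so3.sph_harm(rel_vecs, l) for l in range(l_max + 1)}


# ---------------------------------------------------------------------------
# node descriptors
# ---------------------------------------------------------------------------

_HYBRIDIZATION = {
    "UNSPECIFIED": 0, "S": 1, "SP": 2, "SP2": 3, "SP3": 4,
    "SP2D": 5, "SP3D": 5, "SP3D2": 6, "OTHER": 7,
}


def _chirality_class(atom) -> int:
    tag = str(atom.GetChiralTag())
    if tag == "CHI_UNSPECIFIED":
        return 0
    if tag in ("CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW",
               "CHI_TETRAHEDRAL"):
        return 1
    return 2


def rdkit_atom_descriptors(mol, n_total: int | None = None) -> np.ndarray:
    """The 16 cheminformatics node descriptors for a heavy-atom RDKit mol.

    Fixed slot order: atomic number; chirality class; number of directly
    bonded (heavy) neighbors; number of rings containing the atom; implicit
    valence; formal charge; attached-hydrogen count; unpaired-electron
    count; hybridization class; aromaticity flag; membership flags for
    rings of size 3-7; generic in-ring flag.

    When ``n_total`` exceeds the heavy-atom count, the remaining rows are
    filled with the hydrogen fallback descriptor (explicit-H graphs).
    """
    mol.UpdatePropertyCache(strict=False)
    ri = mol.GetRingInfo()
    rows = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        rows.append([
            atom.GetAtomicNum(),
            _chirality_class(atom),
            atom.GetDegree(),
            ri.NumAtomRings(i),
            atom.GetImplicitValence(),
            atom.GetFormalCharge(),
            atom.GetTotalNumHs(includeNeighbors=True),
            atom.GetNumRadicalElectrons(),
            _HYBRIDIZATION.get(str(atom.GetHybridization()), 7),
            int(atom.GetIsAromatic()),
            int(ri.IsAtomInRingOfSize(i, 3)),
            int(ri.IsAtomInRingOfSize(i, 4)),
            int(ri.IsAtomInRingOfSize(i, 5)),
            int(ri.IsAtomInRingOfSize(i, 6)),
            int(ri.IsAtomInRingOfSize(i, 7)),
            int(atom.IsInRing()),
        ])
    feats = np.array(rows, dtype=np.float64).reshape(-1, N_NODE_FEATURES)
    if n_total is not None and n_total > feats.shape[0]:
        h_rows = np.tile(_h_fallback_row(), (n_total - feats.shape[0], 1))
        feats = np.vstack([feats, h_rows])
    return feats


def _h_fallback_row() -> np.ndarray:
    row = np.zeros(N_NODE_FEATURES)
    row[0] = 1.0  # atomic number
    row[2] = 1.0  # bonded to one heavy atom
    return row


def fallback_descriptors(elements: list[str]) -> np.ndarray:
    """Element-only descriptors for molecules without a SMILES annotation.

    Only the atomic-number slot is populated; geometric context is left to
    the convolution stack.
    """
    from rdkit import Chem
    pt = Chem.GetPeriodicTable()
    feats = np.zeros((len(elements), N_NODE_FEATURES))
    for i, el in enumerate(elements):
        feats[i, 0] = pt.GetAtomicNumber(el)
    return feats


def initial_node_features(mol: Molecule3D, exclude_h: bool = True
                          ) -> np.ndarray:
    """Per-atom descriptor matrix in xyz order (H rows dropped on request)."""
    feats = mol.features if mol.features is not None \
        else fallback_descriptors(mol.elements)
    if exclude_h:
        keep = [i for i, el in enumerate(mol.elements) if el != "H"]
        feats = feats[keep]
    return feats


# ---------------------------------------------------------------------------
# assembled graph
# ---------------------------------------------------------------------------

@dataclass
class MolGraph:
    """A molecule ready for the convolution stack."""

    coords: np.ndarray                    # (N, 3) Å, after H exclusion
    elements: list[str]
    node_feats0: np.ndarray               # (N, 16)
    edge_index: np.ndarray                # (2, E) directed, symmetric set
    edge_feats0: np.ndarray               # (E, n_g)
    sph: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    @classmethod
    def build(cls, mol: Molecule3D, cfg: GraphConfig) -> "MolGraph":
        feats = initial_node_features(mol, exclude_h=cfg.exclude_h)
        if cfg.exclude_h:
            keep = [i for i, el in enumerate(mol.elements) if el != "H"]
            coords = mol.coords[keep]
            elements = [mol.elements[i] for i in keep]
        else:
            coords = mol.coords
            elements = list(mol.elements)
        if coords.shape[0] == 0:
            raise ValueError("molecule has no atoms after hydrogen exclusion")
        edge_index = build_radius_graph(coords, cfg.r_max, cfg.n_neigh)
        if edge_index.shape[1]:
            rel = coords[edge_index[1]] - coords[edge_index[0]]
            dist = np.linalg.norm(rel, axis=1)
            edge_feats = radial_edge_features(dist, cfg)
            sph = sph_filters(rel, cfg.l_max)
        else:
            edge_feats = np.zeros((0, cfg.n_g))
            sph = {l: np.zeros((0, so3.dim(l))) for l in range(cfg.l_max + 1)}
        return cls(coords=coords, elements=elements, node_feats0=feats,
                   edge_index=edge_index, edge_feats0=edge_feats, sph=sph)
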