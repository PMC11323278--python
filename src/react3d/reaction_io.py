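"""Reaction dataset I/O and curation.

Parses xyz geometries and (optionally atom-mapped) reaction SMILES, matches
the SMILES graph of each molecule onto its xyz geometry by labeled-graph
isomorphism on covalent-radius connectivity, derives reaction-type
signatures from the bond changes between mapped atoms, and assembles curated
:class:`ReactionRecord` lists from a manifest table.

Reactions whose SMILES and xyz disagree (no graph isomorphism) are excluded
with a per-record reason, mirroring the curation that real barrier datasets
require.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "Molecule3D",
    "LabeledGraph",
    "ReactionRecord",
    "ReactionTypeSignature",
    "MatchError",
    "COVALENT_RADII",
    "parse_xyz",
    "write_xyz",
    "parse_mapped_reaction_smiles",
    "graph_from_xyz",
    "match_smiles_to_xyz",
    "reaction_type_signature",
    "curate_dataset",
]

# Cordero et al. covalent radii (Å); single-bond, low-spin where applicable.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
}

DEFAULT_BOND_TOLERANCE = 0.4  # Å added on top of the covalent-radius sum


class MatchError(ValueError):
    """Raised when a SMILES graph cannot be matched onto an xyz geometry."""


@dataclass
class Molecule3D:
    """One molecule: element symbols plus Cartesian coordinates in Å.

    ``map_numbers`` holds per-atom SMILES atom-map numbers (0 = unmapped);
    ``features`` caches the 16 cheminformatics node descriptors once a
    SMILES annotation has been matched to the geometry; ``source_smiles``
    is the canonical (map-free) SMILES used e.g. for scaffold splitting.
    """

    elements: list[str]
    coords: np.ndarray
    map_numbers: np.ndarray | None = None
    source_smiles: str | None = None
    features: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("element count does not match coordinate rows")
        if self.map_numbers is not None:
            self.map_numbers = np.asarray(self.map_numbers, dtype=np.intp)
            nonzero = self.map_numbers[self.map_numbers > 0]
            if len(set(nonzero.tolist())) != len(nonzero):
                raise ValueError("duplicate atom-map numbers within molecule")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class LabeledGraph:
    """Element-labeled undirected connectivity graph (no bond orders).

    Nodes are integers ``0..n-1`` with attributes ``element`` and, where
    known, ``map_number`` (0 = unmapped).
    """

    graph: nx.Graph

    def __post_init__(self):
        if any(a == b for a, b in self.graph.edges):
            raise ValueError("self-loop in molecular graph")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def elements(self) -> list[str]:
        return [self.graph.nodes[i]["element"] for i in range(self.n_nodes)]

    @property
    def map_numbers(self) -> np.ndarray:
        return np.array(
            [self.graph.nodes[i].get("map_number", 0)
             for i in range(self.n_nodes)], dtype=np.intp)

    def adjacency_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}


@dataclass
class ReactionRecord:
    """A balanced reaction: reactant/product molecules, mapping, target.

    ``atom_map[j]`` gives, for product atom ``j`` (global index over the
    concatenated product molecules), the corresponding reactant global
    index, or -1 where no correspondence is known (e.g. unmapped
    hydrogens).  ``target`` is the scalar regression target in kcal/mol.
    """

    id: str
    reactants: list[Molecule3D]
    products: list[Molecule3D]
    regime: str = "None"                    # "True" | "RXNMapper" | "None"
    atom_map: np.ndarray | None = None
    target: float = 0.0
    signature: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.target):
            raise ValueError("target is not finite")
        if self.atom_map is not None:
            self.atom_map = np.asarray(self.atom_map, dtype=np.intp)
            if len(self.atom_map) != self.n_product_atoms:
                raise ValueError("atom_map length != product atom count")
            mapped = self.atom_map[self.atom_map >= 0]
            if len(set(mapped.tolist())) != len(mapped):
                raise ValueError("atom_map is not injective")

    @property
    def n_reactant_atoms(self) -> int:
        return sum(m.n_atoms for m in self.reactants)

    @property
    def n_product_atoms(self) -> int:
        return sum(m.n_atoms for m in self.products)


@dataclass(frozen=True)
class ReactionTypeSignature:
    """Multisets of formed (+) and broken (-) bonds, canonically ordered."""

    formed: tuple[str, ...]   # e.g. ("+C-H",)
    broken: tuple[str, ...]   # e.g. ("-C-C", "-C-H")

    @property
    def canonical(self) -> str:
        return ",".join(self.formed + self.broken)

    @property
    def display(self) -> str:
        """Typographic form with en-dashes, as printed in the literature."""
        return self.canonical.replace("-", "–")

    def __str__(self) -> str:
        return self.canonical


# ---------------------------------------------------------------------------
# xyz parsing
# ---------------------------------------------------------------------------

_PT = Chem.GetPeriodicTable()


def _check_element(symbol: str) -> str:
    try:
        if _PT.GetAtomicNumber(symbol) <= 0:
            raise ValueError
    except Exception:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None
    return symbol


def parse_xyz(text: str) -> Molecule3D:
    """Parse standard xyz text (count line, comment line, atom lines)."""
    lines = text.splitlines()
    if not lines:
        raise ValueError("empty xyz file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"bad atom count line: {lines[0]!r}") from None
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) != n:
        raise ValueError(
            f"xyz header declares {n} atoms but {len(atom_lines)} found")
    elements, coords = [], []
    for ln in atom_lines:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"unparsable xyz line: {ln!r}")
        elements.append(_check_element(parts[0]))
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise ValueError(f"unparsable coordinate in line: {ln!r}") from None
    return Molecule3D(elements=elements, coords=np.array(coords))


def write_xyz(mol: Molecule3D, comment: str = "") -> str:
    lines = [str(mol.n_atoms), comment.replace("\n", " ")]
    for el, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reaction SMILES
# ---------------------------------------------------------------------------

def _strip_maps(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        atom.SetAtomMapNum(0)
    return out


def _side_to_fragments(side_smiles: str):
    """Per-molecule (LabeledGraph with explicit H, heavy-atom Mol) pairs.

    Within each fragment, heavy atoms come first (in SMILES order), then
    its hydrogens, so heavy-atom indices agree between the two forms.
    """
    mol = Chem.MolFromSmiles(side_smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {side_smiles!r}")
    molH = Chem.AddHs(mol)
    frags_heavy = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    frags_H = Chem.GetMolFrags(molH, asMols=True, sanitizeFrags=False)
    out = []
    for fragH, frag in zip(frags_H, frags_heavy):
        g = nx.Graph()
        for atom in fragH.GetAtoms():
            g.add_node(atom.GetIdx(), element=atom.GetSymbol(),
                       map_number=atom.GetAtomMapNum())
        for bond in fragH.GetBonds():
            g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        out.append((LabeledGraph(g), frag))
    return out


def parse_mapped_reaction_smiles(
    rxn: str,
) -> tuple[list[LabeledGraph], list[LabeledGraph]]:
    """Parse ``R1.R2>>P1.P2`` into per-molecule labeled graphs.

    Hydrogens are made explicit; atom-map numbers (``:n``), where present,
    are attached as node attributes.  Molecule order within each side is
    preserved.  Duplicate map numbers within one side raise ``ValueError``.
    """
    parts = rxn.split(">")
    if len(parts) != 3:
        raise ValueError(f"not a reaction SMILES: {rxn!r}")
    lhs, _agents, rhs = parts
    sides = []
    for side in (lhs, rhs):
        graphs = [g for g, _ in _side_to_fragments(side)]
        seen: set[int] = set()
        for g in graphs:
            for m in g.map_numbers:
                if m > 0:
                    if m in seen:
                        raise ValueError(
                            f"duplicate atom-map number {m} within one side")
                    seen.add(int(m))
        sides.append(graphs)
    return sides[0], sides[1]


# ---------------------------------------------------------------------------
# xyz connectivity and graph matching
# ---------------------------------------------------------------------------

def graph_from_xyz(
    mol: Molecule3D,
    radii: dict[str, float] | None = None,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> LabeledGraph:
    """Covalent-radius connectivity: bond iff d(a,b) <= r_a + r_b + tol."""
    radii = COVALENT_RADII if radii is None else radii
    for el in set(mol.elements):
        if el not in radii:
            raise KeyError(f"no covalent radius for element {el!r}")
    g = nx.Graph()
    for i, el in enumerate(mol.elements):
        g.add_node(i, element=el,
                   map_number=0 if mol.map_numbers is None
                   else int(mol.map_numbers[i]))
    d = np.linalg.norm(mol.coords[:, None] - mol.coords[None, :], axis=-1)
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= (radii[mol.elements[i]] + radii[mol.elements[j]]
                           + tolerance):
                g.add_edge(i, j)
    return LabeledGraph(g)


def _ordered_copy(lg: LabeledGraph) -> nx.Graph:
    """Copy with nodes inserted by (element, degree, index) for determinism."""
    g = lg.graph
    order = sorted(g.nodes,
                   key=lambda i: (g.nodes[i]["element"], g.degree[i], i))
    h = nx.Graph()
    for i in order:
        h.add_node(i, **g.nodes[i])
    h.add_edges_from(g.edges)
    return h


def match_smiles_to_xyz(g_xyz: LabeledGraph,
                        g_smiles: LabeledGraph) -> np.ndarray:
    """Element-labeled graph isomorphism from xyz atoms to SMILES atoms.

    Returns ``perm`` with ``perm[i_xyz] = i_smiles``.  Any one valid
    bijection is returned (the procedure is blind to stereochemistry); the
    search order is deterministic, so repeated runs agree.
    """
    if g_xyz.n_nodes != g_smiles.n_nodes:
        raise MatchError("SMILES/xyz mismatch: different atom counts")
    if sorted(g_xyz.elements) != sorted(g_smiles.elements):
        raise MatchError("SMILES/xyz mismatch: different element multisets")
    gm = nx.algorithms.isomorphism.GraphMatcher(
        _ordered_copy(g_xyz), _ordered_copy(g_smiles),
        node_match=lambda a, b: a["element"] == b["element"])
    for mapping in gm.isomorphisms_iter():
        perm = np.empty(g_xyz.n_nodes, dtype=np.intp)
        for i_xyz, i_smi in mapping.items():
            perm[i_xyz] = i_smi
        return perm
    raise MatchError("SMILES/xyz mismatch: no graph isomorphism")


# ---------------------------------------------------------------------------
# reaction-type signatures
# ---------------------------------------------------------------------------

def _mapped_bonds(graphs: list[LabeledGraph]) -> tuple[dict[int, str], set]:
    elem: dict[int, str] = {}
    bonds: set[frozenset] = set()
    for lg in graphs:
        g = lg.graph
        for i in g.nodes:
            m = g.nodes[i].get("map_number", 0)
            if m > 0:
                elem[m] = g.nodes[i]["element"]
        for a, b in g.edges:
            ma = g.nodes[a].get("map_number", 0)
            mb = g.nodes[b].get("map_number", 0)
            if ma > 0 and mb > 0:
                bonds.add(frozenset((ma, mb)))
    return elem, bonds


def reaction_type_signature(
    reactant_graphs: list[LabeledGraph],
    product_graphs: list[LabeledGraph],
) -> ReactionTypeSignature:
    """Bond changes between mapped atoms, ignoring bond orders.

    A bond present only in the products contributes ``+X-Y``; only in the
    reactants, ``-X-Y`` (element pair alphabetical).  The canonical string
    lists formed bonds before broken ones, each group sorted.
    """
    r_elem, r_bonds = _mapped_bonds(reactant_graphs)
    p_elem, p_bonds = _mapped_bonds(product_graphs)
    if set(r_elem) != set(p_elem):
        raise ValueError(
            "unmapped atom encountered among compared atoms: map-number sets "
            "differ between reactants and products")
    for m, el in r_elem.items():
        if p_elem[m] != el:
            raise ValueError(f"map number {m} labels different elements")

    def labels(bonds, elem, sign):
        out = []
        for pair in bonds:
            a, b = sorted(elem[m] for m in pair)
            out.append(f"{sign}{a}-{b}")
        return tuple(sorted(out))

    return ReactionTypeSignature(
        formed=labels(p_bonds - r_bonds, p_elem, "+"),
        broken=labels(r_bonds - p_bonds, r_elem, "-"),
    )


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def _pair_hydrogens(atom_map: np.ndarray,
                    r_graphs: list[LabeledGraph],
                    p_graphs: list[LabeledGraph],
                    r_offsets, p_offsets) -> np.ndarray:
    """Pair unmapped hydrogens attached to mapped heavy atoms, by count.

    Hydrogens are usually implicit in SMILES and hence unmapped; they are
    matched per mapped heavy atom, in index order, whenever the attached-H
    counts agree between the two sides.
    """
    def h_neighbors(graphs, offsets):
        out: dict[int, list[int]] = {}
        for lg, off in zip(graphs, offsets):
            g = lg.graph
            for i in g.nodes:
                m = g.nodes[i].get("map_number", 0)
                if m > 0:
                    out[m] = sorted(
                        off + j for j in g.neighbors(i)
                        if g.nodes[j]["element"] == "H"
                        and g.nodes[j].get("map_number", 0) == 0)
        return out

    r_h = h_neighbors(r_graphs, r_offsets)
    p_h = h_neighbors(p_graphs, p_offsets)
    taken = set(atom_map[atom_map >= 0].tolist())
    for m, p_list in p_h.items():
        r_list = r_h.get(m, [])
        if len(p_list) == len(r_list):
            for pj, ri in zip(p_list, r_list):
                if atom_map[pj] < 0 and ri not in taken:
                    atom_map[pj] = ri
                    taken.add(ri)
    return atom_map


def _process_side(mols: list[Molecule3D], side_smiles: str,
                  radii, tolerance) -> list[LabeledGraph]:
    """Match SMILES onto xyz per molecule; annotate maps + descriptors.

    Returns the covalent-radius xyz graphs with map numbers attached (used
    for signatures and hydrogen pairing).
    """
    from react3d.mol_graph import rdkit_atom_descriptors  # avoid cycle

    frags = _side_to_fragments(side_smiles)
    if len(frags) != len(mols):
        raise MatchError("SMILES/xyz mismatch: molecule counts differ")
    xyz_graphs = []
    for mol, (g_smi, frag_heavy) in zip(mols, frags):
        g_xyz = graph_from_xyz(mol, radii=radii, tolerance=tolerance)
        perm = match_smiles_to_xyz(g_xyz, g_smi)
        mol.map_numbers = g_smi.map_numbers[perm]
        mol.source_smiles = Chem.MolToSmiles(_strip_maps(frag_heavy))
        mol.features = rdkit_atom_descriptors(frag_heavy,
                                              n_total=g_smi.n_nodes)[perm]
        for i in g_xyz.graph.nodes:
            g_xyz.graph.nodes[i]["map_number"] = int(mol.map_numbers[i])
        xyz_graphs.append(g_xyz)
    return xyz_graphs


def _curate_one(row, base_dir, radii, tolerance, regime) -> ReactionRecord:
    def load_side(paths_field):
        mols = []
        for path in str(paths_field).split(";"):
            path = path.strip()
            full = path if os.path.isabs(path) else os.path.join(base_dir, path)
            with open(full) as fh:
                mols.append(parse_xyz(fh.read()))
        return mols

    r_mols = load_side(row["reactant_xyz"])
    p_mols = load_side(row["product_xyz"])
    target = float(row["target"])
    rxn_smiles = row.get("rxn_smiles", "")
    if rxn_smiles is None or (isinstance(rxn_smiles, float)
                              and np.isnan(rxn_smiles)):
        rxn_smiles = ""
    rxn_smiles = str(rxn_smiles).strip()

    if not rxn_smiles:
        # geometry-only record: no SMILES annotations, no atom map
        return ReactionRecord(id=str(row["id"]), reactants=r_mols,
                              products=p_mols, regime="None", target=target)

    parts = rxn_smiles.split(">")
    if len(parts) != 3:
        raise ValueError(f"not a reaction SMILES: {rxn_smiles!r}")
    r_graphs = _process_side(r_mols, parts[0], radii, tolerance)
    p_graphs = _process_side(p_mols, parts[2], radii, tolerance)

    mapped_r = sum(int((m.map_numbers > 0).sum()) for m in r_mols)
    mapped_p = sum(int((m.map_numbers > 0).sum()) for m in p_mols)
    if mapped_r != mapped_p:
        raise MatchError("unbalanced reaction: mapped atom counts differ")

    atom_map = None
    signature = None
    if mapped_p > 0:
        signature = reaction_type_signature(r_graphs, p_graphs).canonical
        r_offsets = np.cumsum([0] + [m.n_atoms for m in r_mols])[:-1]
        p_offsets = np.cumsum([0] + [m.n_atoms for m in p_mols])[:-1]
        r_map_to_global: dict[int, int] = {}
        for mol, off in zip(r_mols, r_offsets):
            for i, m in enumerate(mol.map_numbers):
                if m > 0:
                    r_map_to_global[int(m)] = int(off + i)
        atom_map = np.full(sum(m.n_atoms for m in p_mols), -1, dtype=np.intp)
        for mol, off in zip(p_mols, p_offsets):
            for i, m in enumerate(mol.map_numbers):
                if m > 0:
                    if int(m) not in r_map_to_global:
                        raise MatchError(
                            f"product map number {m} absent in reactants")
                    atom_map[off + i] = r_map_to_global[int(m)]
        atom_map = _pair_hydrogens(atom_map, r_graphs, p_graphs,
                                   r_offsets, p_offsets)

    return ReactionRecord(id=str(row["id"]), reactants=r_mols,
                          products=p_mols, regime=regime,
                          atom_map=atom_map, target=target,
                          signature=signature)


def curate_dataset(
    manifest: pd.DataFrame,
    base_dir: str = ".",
    radii: dict[str, float] | None = None,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
    regime: str = "True",
) -> tuple[list[ReactionRecord], pd.DataFrame]:
    """Assemble reaction records from a manifest, excluding mismatches.

    The manifest needs columns ``id``, ``reactant_xyz`` (";"-joined paths),
    ``product_xyz``, ``rxn_smiles`` (may be empty for geometry-only data)
    and ``target``.  Failures never abort the batch; each failed record is
    listed in the exclusion report with its reason.
    """
    records: list[ReactionRecord] = []
    excluded: list[dict] = []
    for _, row in manifest.iterrows():
        try:
            records.append(_curate_one(row, base_dir, radii, tolerance,
                                       regime))
        except (ValueError, KeyError, OSError) as exc:
            excluded.append({"id": str(row.get("id", "?")),
                             "reason": str(exc)})
    report = pd.DataFrame(excluded, columns=["id", "reason"])
    return records, report
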