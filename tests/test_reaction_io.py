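"""Parsing, graph matching, signatures, and dataset curation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from react3d.reaction_io import (LabeledGraph, MatchError,
                                 Molecule3D, ReactionRecord, curate_dataset,
                                 graph_from_xyz, match_smiles_to_xyz,
                                 parse_mapped_reaction_smiles, parse_xyz,
                                 reaction_type_signature, write_xyz)


# -- xyz -------------------------------------------------------------------

def test_parse_minimal_xyz():
    mol = parse_xyz("1\n\nHe 0 0 0")
    assert mol.elements == ["He"]
    np.testing.assert_allclose(mol.coords, [[0, 0, 0]])


def test_xyz_roundtrip(water):
    back = parse_xyz(write_xyz(water, comment="water"))
    assert back.elements == water.elements
    np.testing.assert_allclose(back.coords, water.coords, atol=1e-7)


@pytest.mark.parametrize("text", [
    "3\n\nH 0 0 0\nH 0 0 0.7",        # count mismatch
    "2\n\nH 0 0 0\nH 0 zz 0.7",       # unparsable coordinate
    "1\n\nQq 0 0 0",                  # unknown element
    "abc\n\nH 0 0 0",                 # bad header
])
def test_malformed_xyz_rejected(text):
    with pytest.raises(ValueError):
        parse_xyz(text)


# -- reaction SMILES -------------------------------------------------------

def test_identity_mapped_methane():
    r, p = parse_mapped_reaction_smiles("[CH4:1]>>[CH4:1]")
    assert len(r) == len(p) == 1
    assert r[0].n_nodes == 5  # explicit hydrogens
    assert list(r[0].map_numbers).count(1) == 1
    assert p[0].map_numbers.max() == 1


def test_unmapped_reaction_has_no_map_numbers():
    r, p = parse_mapped_reaction_smiles("CC>>CC")
    assert all((g.map_numbers == 0).all() for g in r + p)


def test_multimolecule_sides_preserve_order_and_maps():
    r, p = parse_mapped_reaction_smiles("[C:1][C:2].[O:3]>>[C:1][C:2][O:3]")
    assert len(r) == 2 and len(p) == 1
    # first reactant molecule is the two-carbon fragment
    assert sorted(r[0].elements).count("C") == 2
    assert sorted(r[1].elements).count("O") == 1
    mapped = sorted(m for g in r for m in g.map_numbers if m > 0)
    assert mapped == [1, 2, 3]
    assert sorted(m for m in p[0].map_numbers if m > 0) == [1, 2, 3]


def test_duplicate_map_number_rejected():
    with pytest.raises(ValueError):
        parse_mapped_reaction_smiles("[CH3:1][CH3:1]>>[CH3:1][CH3:1]")


def test_invalid_smiles_rejected():
    with pytest.raises(ValueError):
        parse_mapped_reaction_smiles("C(>>C")


# -- covalent-radius graphs ------------------------------------------------

def test_h2_bond_within_radii_plus_tolerance():
    mol = Molecule3D(["H", "H"], np.array([[0, 0, 0], [0.74, 0, 0]]))
    g = graph_from_xyz(mol, tolerance=0.4)
    # 0.74 <= 0.31 + 0.31 + 0.4
    assert g.adjacency_set() == {frozenset((0, 1))}


def test_distant_he_atoms_unbonded():
    mol = Molecule3D(["He", "He"], np.array([[0, 0, 0], [3.0, 0, 0]]))
    assert graph_from_xyz(mol).adjacency_set() == set()


def test_water_graph_has_exactly_two_oh_bonds(water):
    g = graph_from_xyz(water)
    assert g.adjacency_set() == {frozenset((0, 1)), frozenset((0, 2))}


def test_missing_radius_errors():
    mol = Molecule3D(["U"], np.zeros((1, 3)))
    with pytest.raises(KeyError):
        graph_from_xyz(mol)


# -- graph matching --------------------------------------------------------

def _graph(elements, edges):
    g = nx.Graph()
    for i, el in enumerate(elements):
        g.add_node(i, element=el)
    g.add_edges_from(edges)
    return LabeledGraph(g)


def _is_valid_matching(g_xyz, g_smi, perm):
    """Check perm maps g_xyz exactly onto g_smi (labels + adjacency)."""
    for i, el in enumerate(g_xyz.elements):
        if g_smi.elements[perm[i]] != el:
            return False
    mapped = {frozenset((perm[a], perm[b])) for a, b in
              (tuple(e) for e in g_xyz.adjacency_set())}
    return mapped == g_smi.adjacency_set()


def test_identity_ordering_matches():
    g = _graph(["O", "H", "H"], [(0, 1), (0, 2)])
    perm = match_smiles_to_xyz(g, g)
    assert _is_valid_matching(g, g, perm)


def test_reversed_water_matches_and_agrees_with_brute_force():
    g_xyz = _graph(["H", "H", "O"], [(2, 0), (2, 1)])
    g_smi = _graph(["O", "H", "H"], [(0, 1), (0, 2)])
    perm = match_smiles_to_xyz(g_xyz, g_smi)
    assert _is_valid_matching(g_xyz, g_smi, perm)
    assert perm[2] == 0  # O must map to O
    # brute force: returned permutation is among all valid ones
    valid = [p for p in itertools.permutations(range(3))
             if _is_valid_matching(g_xyz, g_smi, np.array(p))]
    assert tuple(perm) in valid


def test_atom_count_mismatch_raises():
    methane = _graph(["C", "H", "H", "H", "H"],
                     [(0, i) for i in (1, 2, 3, 4)])
    ethane = _graph(["C", "C"], [(0, 1)])
    with pytest.raises(MatchError):
        match_smiles_to_xyz(methane, ethane)


def test_no_isomorphism_raises():
    path = _graph(["C", "C", "C"], [(0, 1), (1, 2)])
    triangle = _graph(["C", "C", "C"], [(0, 1), (1, 2), (0, 2)])
    with pytest.raises(MatchError):
        match_smiles_to_xyz(path, triangle)


# -- reaction-type signatures ---------------------------------------------

def _mapped_graph(elements, maps, edges):
    g = nx.Graph()
    for i, (el, m) in enumerate(zip(elements, maps)):
        g.add_node(i, element=el, map_number=m)
    g.add_edges_from(edges)
    return LabeledGraph(g)


def test_identity_reaction_has_empty_signature():
    g = _mapped_graph(["C", "H"], [1, 2], [(0, 1)])
    sig = reaction_type_signature([g], [g])
    assert sig.canonical == ""


def test_hydrogen_transfer_signature():
    # C-H + O  ->  C + O-H on a 4-atom mapped system
    r = _mapped_graph(["C", "H", "O", "C"], [1, 2, 3, 4],
                      [(0, 1), (0, 3)])
    p = _mapped_graph(["C", "H", "O", "C"], [1, 2, 3, 4],
                      [(1, 2), (0, 3)])
    sig = reaction_type_signature([r], [p])
    assert sig.canonical == "+H-O,-C-H"
    assert sig.display == "+H–O,–C–H"


def test_signature_matches_printed_convention():
    # break C-C and C-H, form C-H: "+C-H,-C-C,-C-H"
    r = _mapped_graph(["C", "C", "H", "C"], [1, 2, 3, 4],
                      [(0, 1), (1, 2), (1, 3)])
    p = _mapped_graph(["C", "C", "H", "C"], [1, 2, 3, 4],
                      [(0, 2), (1, 3)])
    sig = reaction_type_signature([r], [p])
    assert sig.canonical == "+C-H,-C-C,-C-H"
    assert sig.display == "+C–H,–C–C,–C–H"


def test_signature_invariant_to_molecule_order_and_relabeling():
    r1 = _mapped_graph(["C", "H"], [1, 2], [(0, 1)])
    r2 = _mapped_graph(["O"], [3], [])
    p = _mapped_graph(["C", "H", "O"], [1, 2, 3], [(1, 2)])
    sig_a = reaction_type_signature([r1, r2], [p])
    sig_b = reaction_type_signature([r2, r1], [p])
    assert sig_a == sig_b
    # relabel map numbers consistently (1,2,3) -> (7,5,9)
    relab = {1: 7, 2: 5, 3: 9}
    r1b = _mapped_graph(["C", "H"], [relab[1], relab[2]], [(0, 1)])
    r2b = _mapped_graph(["O"], [relab[3]], [])
    pb = _mapped_graph(["C", "H", "O"],
                       [relab[1], relab[2], relab[3]], [(1, 2)])
    assert reaction_type_signature([r1b, r2b], [pb]) == sig_a


def test_signature_unbalanced_maps_rejected():
    r = _mapped_graph(["C", "H"], [1, 2], [(0, 1)])
    p = _mapped_graph(["C", "H"], [1, 3], [(0, 1)])
    with pytest.raises(ValueError):
        reaction_type_signature([r], [p])


# -- curation --------------------------------------------------------------

def _write_xyz_file(tmp_path, name, mol):
    path = tmp_path / name
    path.write_text(write_xyz(mol))
    return name


@pytest.fixture
def toy_manifest(tmp_path):
    """Three consistent single-molecule reactions (mapped methane and water
    relabelings)."""
    methane = Molecule3D(
        ["C", "H", "H", "H", "H"],
        np.array([[0, 0, 0], [1.09, 0, 0], [-0.36, 1.03, 0],
                  [-0.36, -0.51, 0.89], [-0.36, -0.51, -0.89]]))
    water = Molecule3D(
        ["O", "H", "H"],
        np.array([[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]]))
    rows = []
    for i, (mol, smi) in enumerate([
            (methane, "[CH4:1]>>[CH4:1]"),
            (water, "[OH2:1]>>[OH2:1]"),
            (methane, "[CH4:1]>>[CH4:1]")]):
        name = _write_xyz_file(tmp_path, f"m{i}.xyz", mol)
        rows.append({"id": f"r{i}", "reactant_xyz": name,
                     "product_xyz": name, "rxn_smiles": smi,
                     "target": 1.0 + i})
    return tmp_path, pd.DataFrame(rows)


def test_consistent_manifest_is_fully_kept(toy_manifest):
    base, frame = toy_manifest
    records, report = curate_dataset(frame, base_dir=str(base))
    assert len(records) == 3 and len(report) == 0
    for rec in records:
        assert np.isfinite(rec.target)
        if rec.atom_map is not None:
            mapped = rec.atom_map[rec.atom_map >= 0]
            assert len(set(mapped.tolist())) == len(mapped)


def test_planted_mismatch_is_excluded_with_reason(toy_manifest, tmp_path):
    base, frame = toy_manifest
    ethane = Molecule3D(
        ["C", "C", "H", "H", "H", "H", "H", "H"],
        np.array([[0, 0, 0], [1.54, 0, 0],
                  [-0.4, 1.0, 0], [-0.4, -0.5, 0.87], [-0.4, -0.5, -0.87],
                  [1.94, 1.0, 0], [1.94, -0.5, 0.87], [1.94, -0.5, -0.87]]))
    name = _write_xyz_file(tmp_path, "ethane.xyz", ethane)
    bad = pd.DataFrame([{
        "id": "bad", "reactant_xyz": name, "product_xyz": name,
        "rxn_smiles": "CO>>CO", "target": 0.0}])
    records, report = curate_dataset(pd.concat([frame, bad]),
                                     base_dir=str(base))
    assert len(records) == 3
    assert list(report["id"]) == ["bad"]
    assert "mismatch" in report["reason"].iloc[0]


def test_curation_attaches_descriptors_and_hydrogen_maps(toy_manifest):
    base, frame = toy_manifest
    records, _ = curate_dataset(frame, base_dir=str(base))
    rec = records[0]  # methane identity
    mol = rec.reactants[0]
    assert mol.features.shape == (5, 16)
    c_row = mol.features[mol.elements.index("C")]
    assert c_row[0] == 6           # atomic number
    assert c_row[6] == 4           # attached hydrogens
    # identity reaction: carbon maps to carbon; hydrogens paired by count
    assert (rec.atom_map >= 0).all()


def test_missing_file_reported_not_raised(tmp_path):
    frame = pd.DataFrame([{"id": "x", "reactant_xyz": "nope.xyz",
                           "product_xyz": "nope.xyz",
                           "rxn_smiles": "C>>C", "target": 0.0}])
    records, report = curate_dataset(frame, base_dir=str(tmp_path))
    assert len(records) == 0 and len(report) == 1
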