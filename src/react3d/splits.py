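"""Data splits: random interpolation plus three extrapolation regimes.

All splits are 80/10/10 (train/validation/test) by default, disjoint,
exhaustive, and reproducible from an integer seed.  Scaffold splits keep
every Bemis-Murcko ring-system group entirely within one partition; size
splits train on the smallest molecules and test on the largest; property
splits train on high-barrier reactions and test on low-barrier ones (both
orders available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from react3d.reaction_io import ReactionRecord

__all__ = [
    "SplitSpec",
    "random_split",
    "scaffold_split",
    "size_split",
    "property_split",
    "make_split",
    "split_to_frame",
]


@dataclass
class SplitSpec:
    type: str = "random"                  # random | scaffold | size | property
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    scaffold_side: str = "reactant"       # "reactant" | "product"
    reverse: bool = False                 # reversed order for size/property

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.scaffold_side not in ("reactant", "product"):
            raise ValueError("scaffold_side must be 'reactant' or 'product'")


def _sizes(n: int, fractions) -> tuple[int, int, int]:
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    return n_train, n_val, n - n_train - n_val


def _partition_sorted(order: np.ndarray, spec: SplitSpec) -> dict:
    n_train, n_val, _ = _sizes(len(order), spec.fractions)
    return {
        "train": np.sort(order[:n_train]),
        "val": np.sort(order[n_train:n_train + n_val]),
        "test": np.sort(order[n_train + n_val:]),
    }


def random_split(n: int, spec: SplitSpec) -> dict[str, np.ndarray]:
    """Seeded random 80/10/10 index partition."""
    if n < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(spec.seed)
    return _partition_sorted(rng.permutation(n), spec)


def _record_scaffold_key(rec: ReactionRecord, side: str) -> str:
    """Canonical ring-system backbone of the designated side's molecules.

    Element-retaining Murcko framework per molecule, joined sorted; acyclic
    molecules contribute an empty scaffold, so fully acyclic records group
    together under the empty key.
    """
    mols = rec.reactants if side == "reactant" else rec.products
    parts = []
    for m in mols:
        if m.source_smiles:
            rd = Chem.MolFromSmiles(m.source_smiles)
            if rd is not None:
                parts.append(MurckoScaffold.MurckoScaffoldSmiles(mol=rd))
                continue
        parts.append("")
    return ".".join(sorted(p for p in parts if p))


def scaffold_split(records: list[ReactionRecord],
                   spec: SplitSpec) -> dict[str, np.ndarray]:
    """Whole scaffold groups are assigned to one partition each.

    Groups are taken largest-first (ties in seed-shuffled order) and placed
    into the first of train/val/test whose current occupancy is below its
    target size, so the fraction targets are met as closely as the grouping
    allows while guaranteeing zero scaffold overlap.
    """
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    keys = [_record_scaffold_key(r, spec.scaffold_side) for r in records]
    groups: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    n_train, n_val, n_test = _sizes(n, spec.fractions)
    if max(len(g) for g in groups.values()) > n_train:
        biggest = max(groups, key=lambda k: len(groups[k]))
        raise ValueError(
            f"scaffold group {biggest!r} holds {len(groups[biggest])} of "
            f"{n} records, exceeding the training-set capacity {n_train}")
    rng = np.random.default_rng(spec.seed)
    names = list(groups)
    rng.shuffle(names)
    names.sort(key=lambda k: -len(groups[k]))  # stable: keeps shuffled ties
    caps = {"train": n_train, "val": n_val, "test": n_test}
    filled = {"train": [], "val": [], "test": []}
    for name in names:
        g = groups[name]
        for part in ("train", "val", "test"):
            if len(filled[part]) < caps[part]:
                filled[part].extend(g)
                break
        else:
            filled["test"].extend(g)
    return {k: np.sort(np.array(v, dtype=np.intp)) for k, v in filled.items()}


def _heavy_atom_count(rec: ReactionRecord, side: str) -> int:
    mols = rec.reactants if side == "reactant" else rec.products
    return sum(1 for m in mols for el in m.elements if el != "H")


def size_split(records: list[ReactionRecord], spec: SplitSpec,
               side: str = "reactant") -> dict[str, np.ndarray]:
    """Smallest molecules in train, largest in validation and test.

    Size is the total heavy-atom count of the chosen side.  A seeded
    shuffle before the stable sort breaks ties, so equal-size records are
    distributed randomly.
    """
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(spec.seed)
    shuffled = rng.permutation(n)
    sizes = np.array([_heavy_atom_count(records[i], side) for i in shuffled])
    order = shuffled[np.argsort(-sizes if spec.reverse else sizes,
                                kind="stable")]
    return _partition_sorted(order, spec)


def property_split(records: list[ReactionRecord],
                   spec: SplitSpec) -> dict[str, np.ndarray]:
    """Train on high-barrier reactions, test on low-barrier ones."""
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(spec.seed)
    shuffled = rng.permutation(n)
    targets = np.array([records[i].target for i in shuffled])
    key = targets if spec.reverse else -targets   # default: descending
    order = shuffled[np.argsort(key, kind="stable")]
    return _partition_sorted(order, spec)


def make_split(records: list[ReactionRecord],
               spec: SplitSpec) -> dict[str, np.ndarray]:
    if spec.type == "random":
        return random_split(len(records), spec)
    if spec.type == "scaffold":
        return scaffold_split(records, spec)
    if spec.type == "size":
        return size_split(records, spec)
    if spec.type == "property":
        return property_split(records, spec)
    raise ValueError(f"unknown split type {spec.type!r}")


def split_to_frame(records: list[ReactionRecord],
                   split: dict[str, np.ndarray],
                   fold: int = 0) -> pd.DataFrame:
    """Tabular (id, fold, partition) form for split files."""
    rows = []
    for part, idx in split.items():
        for i in idx:
            rows.append({"id": records[i].id, "fold": fold,
                         "partition": part})
    return pd.DataFrame(rows, columns=["id", "fold", "partition"])
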