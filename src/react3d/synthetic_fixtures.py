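"""Synthetic inputs that exercise the full pipeline without downloads.

Three generators:

* a homometric He4 pair — two collinear arrangements sharing the same
  multiset of pairwise distances without being congruent, the classic
  counterexample for models that see only the global distance spectrum;
* an angle-probe pair — a central atom with three neighbors at a common
  radius, trigonal-planar in one structure and pyramidal in the other,
  with all neighbor-neighbor distances beyond the radial cutoff, so the
  within-cutoff *distance* environment of the central atom is identical
  while the *angular* environment differs (invariant channels cannot
  separate the two, equivariant ones can);
* random reaction datasets with an additive atomic-energy ground truth:
  the target is the sum over atoms of a seeded lookup ``f(element,
  coordination number within 2.5 Å)`` over products minus reactants, plus
  Gaussian noise, which a mapping-free energy-mode model should recover.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from react3d.reaction_io import Molecule3D, ReactionRecord, write_xyz

__all__ = [
    "SyntheticSpec",
    "make_homometric_pair",
    "make_angle_probe_pair",
    "make_synthetic_reactions",
    "additive_target",
    "coordination_numbers",
    "distance_multiset",
    "write_fixture_dataset",
]


# ---------------------------------------------------------------------------
# geometric probes
# ---------------------------------------------------------------------------

def make_homometric_pair() -> tuple[Molecule3D, Molecule3D]:
    """Two He4 structures with equal distance multisets, not congruent.

    Planar placements at {(0,0), (0,1), (0,2), (1,3)} and
    {(0,0), (0,1), (1,1), (1,3)} Å: both give the squared-distance
    multiset {1, 1, 2, 4, 5, 10} Å², yet no rigid motion or reflection
    maps one onto the other (collinear candidates fail this second
    requirement — a 1-D reversal is always a proper 3-D rotation).
    """
    def planar(xy):
        coords = np.zeros((len(xy), 3))
        coords[:, :2] = xy
        return Molecule3D(elements=["He"] * len(xy), coords=coords)

    return (planar([(0.0, 0.0), (0.0, 1.0), (0.0, 2.0), (1.0, 3.0)]),
            planar([(0.0, 0.0), (0.0, 1.0), (1.0, 1.0), (1.0, 3.0)]))


def make_angle_probe_pair(r: float = 1.5, cutoff: float = 1.9,
                          pyramid_polar_deg: float = 75.0
                          ) -> tuple[Molecule3D, Molecule3D]:
    """Planar vs pyramidal He probes with identical radial environments.

    The central atom (index 0) has three neighbors at distance ``r``; in
    both structures every neighbor-neighbor distance exceeds ``cutoff``,
    so with ``r_max = cutoff`` each central atom sees three neighbors at
    the same distance and the structures differ only in angles.
    """
    azim = np.deg2rad([0.0, 120.0, 240.0])

    def probe(polar_deg):
        th = np.deg2rad(polar_deg)
        dirs = np.stack([np.sin(th) * np.cos(azim),
                         np.sin(th) * np.sin(azim),
                         np.full(3, np.cos(th))], axis=1)
        coords = np.vstack([np.zeros(3), r * dirs])
        return Molecule3D(elements=["He"] * 4, coords=coords)

    planar, pyramidal = probe(90.0), probe(pyramid_polar_deg)
    for mol in (planar, pyramidal):
        d = np.linalg.norm(mol.coords[1:] - mol.coords[0], axis=1)
        if not np.allclose(d, r, atol=1e-9):
            raise ValueError("central-neighbor distances violated")
        nn = [np.linalg.norm(mol.coords[i] - mol.coords[j])
              for i in (1, 2, 3) for j in (1, 2, 3) if i < j]
        if min(nn) <= cutoff:
            raise ValueError(
                f"neighbor-neighbor distance {min(nn):.3f} Å does not "
                f"exceed the cutoff {cutoff} Å; geometry infeasible for "
                f"(r={r}, cutoff={cutoff})")
    return planar, pyramidal


def distance_multiset(mol: Molecule3D) -> np.ndarray:
    """Sorted multiset of pairwise interatomic distances."""
    d = np.linalg.norm(mol.coords[:, None] - mol.coords[None, :], axis=-1)
    iu = np.triu_indices(mol.n_atoms, k=1)
    return np.sort(d[iu])


# ---------------------------------------------------------------------------
# additive-energy reaction datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic reaction generator.

    Molecules are jittered cubic-lattice point clouds (spacing 1.6 Å,
    coordinate jitter 0.05 Å), small enough that a few hundred reactions
    train in minutes yet large enough that coordination numbers vary; the
    product perturbs the reactant by relocating one atom, so a handful of
    atoms change their environment per reaction.
    """

    n_reactions: int = 500
    atoms_range: tuple[int, int] = (4, 7)      # inclusive bounds
    elements: tuple[str, ...] = ("C", "O")
    sigma: float = 0.1                         # target noise, kcal/mol
    seed: int = 0
    lattice_a: float = 1.6                     # Å
    jitter: float = 0.05                       # Å, per coordinate
    coord_cutoff: float = 2.5                  # Å, coordination sphere
    p_two_molecules: float = 0.25              # fraction with 2-mol sides

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        lo, hi = self.atoms_range
        if not 1 <= lo <= hi:
            raise ValueError("empty atoms-per-molecule range")
        if hi > 27:
            raise ValueError("atoms per molecule exceeds the 3x3x3 lattice; "
                             "minimum-distance constraint infeasible")


def coordination_numbers(mol: Molecule3D, cutoff: float = 2.5) -> np.ndarray:
    """Number of other atoms within ``cutoff`` Å of each atom."""
    d = np.linalg.norm(mol.coords[:, None] - mol.coords[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return (d <= cutoff).sum(axis=1)


def additive_target(reactants: list[Molecule3D], products: list[Molecule3D],
                    ftable: dict[tuple[str, int], float],
                    cutoff: float = 2.5) -> float:
    """Sum of per-atom energies over products minus reactants."""
    def side(mols):
        total = 0.0
        for m in mols:
            for el, c in zip(m.elements, coordination_numbers(m, cutoff)):
                total += ftable[(el, int(c))]
        return total

    return side(products) - side(reactants)


_LATTICE = np.array([(i, j, k) for i in range(3)
                     for j in range(3) for k in range(3)], dtype=float)


def _random_molecule(rng, spec: SyntheticSpec) -> tuple[Molecule3D, np.ndarray]:
    n = int(rng.integers(spec.atoms_range[0], spec.atoms_range[1] + 1))
    site_idx = rng.choice(len(_LATTICE), size=n, replace=False)
    coords = (_LATTICE[site_idx] * spec.lattice_a
              + rng.normal(0.0, spec.jitter, size=(n, 3)))
    elements = [spec.elements[i]
                for i in rng.integers(len(spec.elements), size=n)]
    return Molecule3D(elements=elements, coords=coords), site_idx


def _perturb(mol: Molecule3D, site_idx: np.ndarray, rng,
             spec: SyntheticSpec) -> Molecule3D:
    """Relocate one atom to a free lattice site (re-jittered)."""
    free = np.setdiff1d(np.arange(len(_LATTICE)), site_idx)
    atom = int(rng.integers(mol.n_atoms))
    new_site = int(free[rng.integers(len(free))])
    coords = mol.coords.copy()
    coords[atom] = (_LATTICE[new_site] * spec.lattice_a
                    + rng.normal(0.0, spec.jitter, size=3))
    return Molecule3D(elements=list(mol.elements), coords=coords)


def make_synthetic_reactions(
    spec: SyntheticSpec,
) -> tuple[list[ReactionRecord], pd.DataFrame, pd.DataFrame]:
    """Generate reactions with additive ground truth.

    Returns (records, per-reaction truth table, f-table).  Records carry
    the identity atom map (product atoms keep their reactant indices), so
    all three mapping variants can consume them.
    """
    rng = np.random.default_rng(spec.seed)
    # the atomic-energy lookup: one value per (element, coordination)
    ftable = {(el, c): float(rng.normal(0.0, 1.0))
              for el in spec.elements for c in range(27)}
    records, truth_rows = [], []
    for k in range(spec.n_reactions):
        n_mols = 2 if rng.random() < spec.p_two_molecules else 1
        r_mols, r_sites = [], []
        for _ in range(n_mols):
            mol, sites = _random_molecule(rng, spec)
            r_mols.append(mol)
            r_sites.append(sites)
        # perturb one molecule on the product side
        which = int(rng.integers(n_mols))
        p_mols = list(r_mols)
        p_mols[which] = _perturb(r_mols[which], r_sites[which], rng, spec)
        clean = additive_target(r_mols, p_mols, ftable, spec.coord_cutoff)
        noise = float(rng.normal(0.0, spec.sigma)) if spec.sigma > 0 else 0.0
        n_p = sum(m.n_atoms for m in p_mols)
        records.append(ReactionRecord(
            id=f"synth-{k:05d}",
            reactants=[Molecule3D(list(m.elements), m.coords.copy())
                       for m in r_mols],
            products=[Molecule3D(list(m.elements), m.coords.copy())
                      for m in p_mols],
            regime="True",
            atom_map=np.arange(n_p),
            target=clean + noise))
        truth_rows.append({"id": records[-1].id, "target_clean": clean,
                           "noise": noise, "target": clean + noise})
    truth = pd.DataFrame(truth_rows)
    frows = [{"element": el, "coordination": c, "value": v}
             for (el, c), v in sorted(ftable.items())]
    return records, truth, pd.DataFrame(frows)


def write_fixture_dataset(records: list[ReactionRecord],
                          truth: pd.DataFrame, out_dir: str) -> str:
    """Write xyz files + manifest + ground truth so the CLI pipeline can
    run end-to-end on fixtures.  Returns the manifest path."""
    xyz_dir = os.path.join(out_dir, "xyz")
    os.makedirs(xyz_dir, exist_ok=True)
    rows = []
    for rec in records:
        r_paths, p_paths = [], []
        for side, mols, paths in (("r", rec.reactants, r_paths),
                                  ("p", rec.products, p_paths)):
            for i, m in enumerate(mols):
                name = f"{rec.id}_{side}{i}.xyz"
                with open(os.path.join(xyz_dir, name), "w") as fh:
                    fh.write(write_xyz(m, comment=rec.id))
                paths.append(os.path.join("xyz", name))
        rows.append({"id": rec.id, "reactant_xyz": ";".join(r_paths),
                     "product_xyz": ";".join(p_paths),
                     "rxn_smiles": "", "target": rec.target})
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    truth.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
    return manifest
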