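"""Synthetic toy reactions with known "ground-truth" TS geometries.

The generator emulates the *shape* of a small-molecule gas-phase reaction
dataset (H/C/N/O, up to seven heavy atoms, fully atom-mapped single-step
reactions, one TS geometry per reaction, a scalar barrier height) so that
training, sampling, metrics, and splitting are testable end-to-end without
any download. The geometries are NOT physical saddle points: a reactant
conformer is embedded with RDKit's distance-geometry method, then relaxed by
least squares onto target distances where breaking/forming bonds are
stretched to 1.3× their equilibrium length. They are distribution targets
for exercising the generative machinery, nothing more.

Reactions are drawn from a parametric template library (homolytic bond
breaking, bond-order demotion, 1,2-hydrogen shifts across a double bond, each
instantiated over element pairs). Every template yields a structurally
identical reaction core, so template identity and extracted core key
coincide by construction; template cluster sizes follow a power law (a few
large clusters, many singleton cores). A minimum interatomic distance of
0.8 Å — above the 0.7 Å steric-clash cutoff — is enforced on every generated
TS, making clash-free ground truth a sharp regression target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .errors import FixtureError
from .reaction_io import Geometry, Reaction, parse_reaction

__all__ = ["FixtureSpec", "TEMPLATE_LIBRARY", "make_fixture_dataset",
           "make_chiral_pair", "make_overfit_fixture"]

_VALENCE = {"H": 1, "C": 4, "N": 3, "O": 2}

_LENGTH = {
    ("H", "H", 1): 0.74, ("C", "H", 1): 1.09, ("H", "N", 1): 1.01,
    ("H", "O", 1): 0.96, ("C", "C", 1): 1.54, ("C", "C", 2): 1.34,
    ("C", "C", 3): 1.20, ("C", "N", 1): 1.47, ("C", "N", 2): 1.28,
    ("C", "O", 1): 1.43, ("C", "O", 2): 1.22, ("N", "N", 1): 1.45,
    ("N", "N", 2): 1.25, ("N", "O", 1): 1.40, ("N", "O", 2): 1.21,
    ("O", "O", 1): 1.48,
}

#: (kind, (element a, element b)); "break" removes an a–b bond, "demote"
#: turns a double bond single, "hshift" moves an H from a to b across an
#: a=b double bond (which becomes single). Each entry defines one distinct
#: reaction core.
TEMPLATE_LIBRARY: list[tuple[str, tuple[str, str]]] = [
    ("break", ("C", "H")), ("break", ("C", "C")), ("break", ("C", "O")),
    ("break", ("O", "H")), ("break", ("C", "N")), ("break", ("N", "H")),
    ("demote", ("C", "C")), ("hshift", ("C", "C")), ("hshift", ("C", "O")),
    ("demote", ("C", "O")), ("hshift", ("C", "N")), ("demote", ("C", "N")),
    ("break", ("N", "N")), ("break", ("N", "O")), ("break", ("O", "O")),
    ("demote", ("N", "N")), ("hshift", ("N", "C")), ("hshift", ("N", "N")),
]

_MIN_TS_DISTANCE = 0.8  # Å; keeps every fixture TS strictly clash-free


@dataclass
class FixtureSpec:
    n_reactions: int = 200
    n_heavy_range: tuple[int, int] = (3, 7)
    elements: tuple[str, ...] = ("H", "C", "N", "O")
    seed: int = 0
    noise: float = 0.02        # Å, isotropic jitter added to each TS
    n_cores: int = 12          # number of distinct templates to use
    cluster_exponent: float = 2.5  # power-law exponent for cluster sizes


def _bond_length(a: str, b: str, order: int) -> float:
    key = (*sorted((a, b)), order)
    if key not in _LENGTH:
        raise FixtureError(f"no reference length for bond {key}")
    return _LENGTH[key]


class _MolGraph:
    """Mutable molecular graph used only inside the generator."""

    def __init__(self):
        self.elements: list[str] = []
        self.bonds: dict[tuple[int, int], int] = {}

    def add_atom(self, el: str) -> int:
        self.elements.append(el)
        return len(self.elements) - 1

    def add_bond(self, i: int, j: int, order: int = 1) -> None:
        self.bonds[(min(i, j), max(i, j))] = order

    def free_valence(self, i: int, reserved: dict[int, int]) -> int:
        used = sum(o for (a, b), o in self.bonds.items() if i in (a, b))
        return _VALENCE[self.elements[i]] - used - reserved.get(i, 0)

    def n_heavy(self) -> int:
        return sum(1 for el in self.elements if el != "H")


_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
               3: Chem.BondType.TRIPLE}


def _to_smiles(elements: list[str], bonds: dict[tuple[int, int], int]) -> str:
    em = Chem.RWMol()
    for i, el in enumerate(elements):
        atom = Chem.Atom(el)
        atom.SetAtomMapNum(i + 1)
        atom.SetNoImplicit(True)
        em.AddAtom(atom)
    for (i, j), order in sorted(bonds.items()):
        em.AddBond(i, j, _BOND_TYPES[order])
    mol = em.GetMol()
    mol.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(mol)


def _grow_molecule(rng: np.random.Generator, template: tuple[str, tuple[str, str]],
                   n_heavy_target: int, palette: tuple[str, ...]) -> tuple[_MolGraph, dict]:
    """Seed the template motif, grow a random tree, then fill hydrogens."""
    kind, (a, b) = template
    g = _MolGraph()
    reserved: dict[int, int] = {}
    info: dict = {"kind": kind}
    i0 = g.add_atom(a)
    if kind == "break" and b == "H":
        reserved[i0] = 1
        info["mode"] = "break_h"
    elif kind == "break":
        i1 = g.add_atom(b)
        g.add_bond(i0, i1, 1)
        info["mode"] = "break_heavy"
    elif kind == "demote":
        i1 = g.add_atom(b)
        g.add_bond(i0, i1, 2)
        info["mode"] = "demote"
    elif kind == "hshift":
        i1 = g.add_atom(b)
        g.add_bond(i0, i1, 2)
        reserved[i0] = 1
        info["mode"] = "hshift"
    else:  # pragma: no cover
        raise FixtureError(f"unknown template kind {kind!r}")

    heavy_palette = tuple(el for el in palette if el != "H")
    if not heavy_palette or "H" not in palette:
        raise FixtureError("element palette must contain H and at least one heavy element")
    for el in {a, b} - {"H"}:
        if el not in palette:
            raise FixtureError(f"template needs element {el!r} outside palette {palette}")

    while g.n_heavy() < n_heavy_target:
        sites = [i for i, el in enumerate(g.elements)
                 if el != "H" and g.free_valence(i, reserved) > 0]
        if not sites:
            break
        site = int(rng.choice(sites))
        new = g.add_atom(str(rng.choice(heavy_palette)))
        g.add_bond(site, new, 1)

    # hydrogen fill; reserved slots become tracked hydrogens
    h_special = None
    for i in list(range(len(g.elements))):
        if g.elements[i] == "H":
            continue
        for _ in range(max(0, g.free_valence(i, reserved))):
            h = g.add_atom("H")
            g.add_bond(i, h, 1)
        for _ in range(reserved.get(i, 0)):
            h = g.add_atom("H")
            g.add_bond(i, h, 1)
            if i == 0:
                h_special = h
    info["h_special"] = h_special
    return g, info


def _product_bonds(g: _MolGraph, info: dict) -> dict[tuple[int, int], int]:
    bonds = dict(g.bonds)
    mode = info["mode"]
    if mode == "break_h":
        del bonds[(0, info["h_special"])]
    elif mode == "break_heavy":
        del bonds[(0, 1)]
    elif mode == "demote":
        bonds[(0, 1)] = 1
    elif mode == "hshift":
        bonds[(0, 1)] = 1
        h = info["h_special"]
        del bonds[(min(0, h), max(0, h))]
        bonds[(1, h)] = 1
    return bonds


def _embed_reactant(elements: list[str], bonds: dict[tuple[int, int], int],
                    seed: int) -> np.ndarray:
    em = Chem.RWMol()
    for el in elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        em.AddAtom(atom)
    for (i, j), order in sorted(bonds.items()):
        em.AddBond(i, j, _BOND_TYPES[order])
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise FixtureError("distance-geometry embedding failed")
    conf = mol.GetConformer()
    return np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                      conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])


def _ts_coordinates(elements: list[str], r_bonds: dict, p_bonds: dict,
                    x_init: np.ndarray) -> np.ndarray:
    """Relax the reactant conformer onto TS-like target distances."""
    n = len(elements)
    union = sorted(set(r_bonds) | set(p_bonds))
    targets = []
    for (i, j) in union:
        ro, po = r_bonds.get((i, j), 0), p_bonds.get((i, j), 0)
        if ro and po:
            tgt = (_bond_length(elements[i], elements[j], ro)
                   + _bond_length(elements[i], elements[j], po)) / 2.0
        else:
            order = ro or po
            tgt = 1.3 * _bond_length(elements[i], elements[j], order)
        targets.append(((i, j), tgt))
    bonded = set(union)
    nonbonded = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if (i, j) not in bonded]

    def residuals(flat: np.ndarray) -> np.ndarray:
        x = flat.reshape(n, 3)
        res = [np.linalg.norm(x[i] - x[j]) - tgt for (i, j), tgt in targets]
        for i, j in nonbonded:
            d = np.linalg.norm(x[i] - x[j])
            res.append(2.0 * max(0.0, 1.1 - d))
        res.extend(0.05 * (flat - x_init.ravel()))
        return np.asarray(res)

    sol = least_squares(residuals, x_init.ravel(), max_nfev=300)
    return sol.x.reshape(n, 3)


def _cluster_sizes(n_reactions: int, n_cores: int, exponent: float) -> np.ndarray:
    if n_cores > n_reactions:
        raise FixtureError("more cores requested than reactions")
    w = 1.0 / np.arange(1, n_cores + 1, dtype=np.float64) ** exponent
    w /= w.sum()
    sizes = np.maximum(1, np.floor(w * n_reactions).astype(np.intp))
    while sizes.sum() > n_reactions:
        sizes[int(np.argmax(sizes))] -= 1
    sizes[0] += n_reactions - sizes.sum()
    return sizes


def _make_reaction(rxn_id: str, template, n_heavy: int, spec: FixtureSpec,
                   rng: np.random.Generator) -> Reaction:
    for _ in range(10):
        g, info = _grow_molecule(rng, template, n_heavy, spec.elements)
        p_bonds = _product_bonds(g, info)
        try:
            x_react = _embed_reactant(g.elements, g.bonds, int(rng.integers(1, 2 ** 31 - 1)))
        except FixtureError:
            continue
        x_ts = _ts_coordinates(g.elements, g.bonds, p_bonds, x_react)
        x_ts = x_ts + rng.normal(0.0, spec.noise, x_ts.shape)
        if pdist(x_ts).min() < _MIN_TS_DISTANCE:
            continue
        rxn = parse_reaction(
            f"{_to_smiles(g.elements, g.bonds)}>>{_to_smiles(g.elements, p_bonds)}",
            rxn_id=rxn_id)
        rxn.ts_geometry = Geometry(list(g.elements), x_ts - x_ts.mean(axis=0), rxn_id)
        rxn.reactant_geometry = Geometry(list(g.elements),
                                         x_react - x_react.mean(axis=0), rxn_id)
        rxn.barrier_height = float(rng.lognormal(np.log(25.0), 0.6))
        return rxn
    raise FixtureError(f"could not realize template {template} within retry budget")


def make_fixture_dataset(spec: FixtureSpec | None = None) -> list[Reaction]:
    """Deterministic toy dataset with TS + reactant geometries and barriers."""
    spec = spec or FixtureSpec()
    if spec.n_cores > len(TEMPLATE_LIBRARY):
        raise FixtureError(
            f"n_cores <= {len(TEMPLATE_LIBRARY)} supported, got {spec.n_cores}")
    rng = np.random.default_rng(spec.seed)
    sizes = _cluster_sizes(spec.n_reactions, spec.n_cores, spec.cluster_exponent)
    lo, hi = spec.n_heavy_range
    reactions = []
    k = 0
    for template, size in zip(TEMPLATE_LIBRARY[:spec.n_cores], sizes):
        for _ in range(int(size)):
            n_heavy = int(rng.integers(lo, hi + 1))
            reactions.append(_make_reaction(f"rxn{k:04d}", template, n_heavy, spec, rng))
            k += 1
    return reactions


def make_overfit_fixture(seed: int = 0) -> Reaction:
    """A single reaction designed for memorization sanity checks.

    Formic-acid O–H homolysis: HC(=O)OH -> HC(=O)O· + H·. Every atom has a
    distinct graph environment (no non-trivial automorphism), so the
    conditional OT target given (x_t, t) is single-valued. Molecules with
    interchangeable hydrogens (CH2, CH3, NH2) make the target multimodal —
    symmetric atoms occupy distinct target positions — which is a property of
    the learning problem, not of the machinery a memorization check is meant
    to exercise.
    """
    g = _MolGraph()
    c = g.add_atom("C")
    o_carbonyl = g.add_atom("O")
    o_hydroxyl = g.add_atom("O")
    h_c = g.add_atom("H")
    h_o = g.add_atom("H")
    g.add_bond(c, o_carbonyl, 2)
    g.add_bond(c, o_hydroxyl, 1)
    g.add_bond(c, h_c, 1)
    g.add_bond(o_hydroxyl, h_o, 1)
    p_bonds = dict(g.bonds)
    del p_bonds[(o_hydroxyl, h_o)]

    rng = np.random.default_rng(seed)
    x_react = _embed_reactant(g.elements, g.bonds, int(rng.integers(1, 2 ** 31 - 1)))
    x_ts = _ts_coordinates(g.elements, g.bonds, p_bonds, x_react)
    x_ts = x_ts - x_ts.mean(axis=0)
    rxn = parse_reaction(
        f"{_to_smiles(g.elements, g.bonds)}>>{_to_smiles(g.elements, p_bonds)}",
        rxn_id="overfit0")
    rxn.ts_geometry = Geometry(list(g.elements), x_ts, "overfit0")
    rxn.reactant_geometry = Geometry(list(g.elements),
                                     x_react - x_react.mean(axis=0), "overfit0")
    rxn.barrier_height = float(rng.lognormal(np.log(25.0), 0.6))
    return rxn


def make_chiral_pair(seed: int = 0) -> tuple[Reaction, Geometry]:
    """A reaction with a chiral TS plus the mirror image of that TS.

    The mirror preserves all interatomic distances (D-MAE = 0 against the
    original) but cannot be superimposed by any proper rotation, so RMSD and
    the align residual are strictly positive — the enantiomer failure mode.
    """
    g = _MolGraph()
    # chiral carbon with four distinct substituents: H, NH2, OH, CH3
    c0 = g.add_atom("C")
    h1 = g.add_atom("H")
    n2 = g.add_atom("N")
    o3 = g.add_atom("O")
    c4 = g.add_atom("C")
    for other in (h1, n2, o3, c4):
        g.add_bond(c0, other, 1)
    for _ in range(2):
        g.add_bond(n2, g.add_atom("H"), 1)
    g.add_bond(o3, g.add_atom("H"), 1)
    for _ in range(3):
        g.add_bond(c4, g.add_atom("H"), 1)

    p_bonds = dict(g.bonds)
    del p_bonds[(c0, h1)]  # homolytic C–H cleavage at the stereocenter
    rng = np.random.default_rng(seed)
    x_react = _embed_reactant(g.elements, g.bonds, int(rng.integers(1, 2 ** 31 - 1)))
    x_ts = _ts_coordinates(g.elements, g.bonds, p_bonds, x_react)
    x_ts = x_ts - x_ts.mean(axis=0)

    rxn = parse_reaction(
        f"{_to_smiles(g.elements, g.bonds)}>>{_to_smiles(g.elements, p_bonds)}",
        rxn_id="chiral0")
    rxn.ts_geometry = Geometry(list(g.elements), x_ts, "chiral0")
    rxn.reactant_geometry = Geometry(list(g.elements),
                                     x_react - x_react.mean(axis=0), "chiral0")
    mirrored = Geometry(list(g.elements), x_ts * np.array([-1.0, 1.0, 1.0]),
                        "chiral0-mirror")
    return rxn, mirrored
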