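"""Condensed graph of reaction (CGR) featurization and the model edge set.

The CGR superimposes the reactant and product graphs onto one graph over the
shared atom set; every atom and bond carries dual labels describing its state
before and after the reaction. Node features concatenate an element one-hot
with six chemistry descriptors (aromaticity, formal charge, hybridization,
number of bonds, degree, ring membership) computed on the reactant side and
again on the product side. Bond features are dual bond-order categories, where
"absent" is a first-class category so that forming and breaking bonds are
representable.

The network's edge set is geometry-dependent: the union of all atom pairs
within a radius cutoff (default 10 Å) of the current flow state and all pairs
within a hop-distance bound (default 3) in the CGR union graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

from .errors import FeatureError
from .nn import Tensor, ensure
from .reaction_io import Reaction, map_to_index

__all__ = [
    "DEFAULT_ELEMENTS",
    "BOND_CATEGORIES",
    "CGRGraph",
    "atom_features",
    "bond_features",
    "build_cgr",
    "build_edge_set",
    "pair_feature_matrix",
    "sinusoidal_time_embedding",
    "initial_embeddings",
]

DEFAULT_ELEMENTS: tuple[str, ...] = ("H", "C", "N", "O")

#: bond-order categories; index 0 ("absent") encodes a missing bond
BOND_CATEGORIES: tuple[str, ...] = ("absent", "single", "double", "triple", "aromatic")

_BOND_TYPE_TO_CAT = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}

_HYB_SLOTS = {
    Chem.HybridizationType.S: 0,
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
}

#: hop-distance categories for model edges: 1, 2, 3, and "far" (>3 or disconnected)
N_HOP_CATEGORIES = 4

ATOM_SIDE_DIM = 1 + 1 + 5 + 1 + 1 + 1  # aromatic, charge, hyb(5), n_bonds, degree, ring


def atom_feature_dim(elements: tuple[str, ...] = DEFAULT_ELEMENTS) -> int:
    return len(elements) + 2 * ATOM_SIDE_DIM


def pair_feature_dim() -> int:
    return 2 * len(BOND_CATEGORIES) + N_HOP_CATEGORIES


def _side_features(mol: Chem.Mol, idx: int) -> list[float]:
    atom = mol.GetAtomWithIdx(idx)
    hyb = [0.0] * 5
    hyb[_HYB_SLOTS.get(atom.GetHybridization(), 4)] = 1.0
    n_bonds = sum(b.GetBondTypeAsDouble() for b in atom.GetBonds())
    return [
        float(atom.GetIsAromatic()),
        float(atom.GetFormalCharge()),
        *hyb,
        float(n_bonds),
        float(atom.GetDegree()),
        float(atom.IsInRing()),
    ]


def atom_features(reaction: Reaction, atom_map_no: int,
                  elements: tuple[str, ...] = DEFAULT_ELEMENTS) -> np.ndarray:
    """Dual-labelled feature vector for one atom, identified by map number."""
    symbol = reaction.elements[atom_map_no - 1]
    if symbol not in elements:
        raise FeatureError(f"element {symbol!r} outside supported set {elements}")
    one_hot = [1.0 if symbol == el else 0.0 for el in elements]
    r_idx = map_to_index(reaction.reactant_mol)[atom_map_no]
    p_idx = map_to_index(reaction.product_mol)[atom_map_no]
    return np.array(one_hot
                    + _side_features(reaction.reactant_mol, r_idx)
                    + _side_features(reaction.product_mol, p_idx))


def bond_category_matrices(reaction: Reaction) -> tuple[np.ndarray, np.ndarray]:
    """(reactant, product) N×N integer bond-category matrices in map order."""
    n = reaction.n_atoms
    mats = []
    for mol in (reaction.reactant_mol, reaction.product_mol):
        idx_to_map = {a.GetIdx(): a.GetAtomMapNum() for a in mol.GetAtoms()}
        mat = np.zeros((n, n), dtype=np.intp)
        for bond in mol.GetBonds():
            i = idx_to_map[bond.GetBeginAtomIdx()] - 1
            j = idx_to_map[bond.GetEndAtomIdx()] - 1
            cat = _BOND_TYPE_TO_CAT.get(bond.GetBondType(), 1)
            mat[i, j] = mat[j, i] = cat
        mats.append(mat)
    return mats[0], mats[1]


def bond_features(reaction: Reaction, i: int, j: int) -> np.ndarray:
    """Dual bond-order one-hot for the pair of map numbers (i, j).

    Raises FeatureError when the pair is bonded on neither side.
    """
    r_cat, p_cat = bond_category_matrices(reaction)
    rc, pc = r_cat[i - 1, j - 1], p_cat[i - 1, j - 1]
    if rc == 0 and pc == 0:
        raise FeatureError(f"atoms {i} and {j} are bonded in neither reactant nor product")
    vec = np.zeros(2 * len(BOND_CATEGORIES))
    vec[rc] = 1.0
    vec[len(BOND_CATEGORIES) + pc] = 1.0
    return vec


@dataclass
class CGRGraph:
    """Featurized condensed graph of reaction."""

    n_atoms: int
    elements: list[str]
    node_features: np.ndarray          # (N, Dn)
    edge_index: np.ndarray             # (2, E) directed union-bond edges
    edge_features: np.ndarray          # (E, 10) dual bond one-hots
    hop_distance: np.ndarray           # (E,) graph distance of each edge (all 1)
    r_cat: np.ndarray = field(repr=False)  # (N, N) reactant bond categories
    p_cat: np.ndarray = field(repr=False)  # (N, N) product bond categories
    hop_matrix: np.ndarray = field(repr=False)  # (N, N) union-graph distances

    @property
    def union_adjacency(self) -> np.ndarray:
        return ((self.r_cat > 0) | (self.p_cat > 0)).astype(np.intp)


def build_cgr(reaction: Reaction,
              elements: tuple[str, ...] = DEFAULT_ELEMENTS) -> CGRGraph:
    n = reaction.n_atoms
    node_feat = np.stack([atom_features(reaction, m, elements) for m in range(1, n + 1)])
    r_cat, p_cat = bond_category_matrices(reaction)
    union = (r_cat > 0) | (p_cat > 0)
    hop = shortest_path(union.astype(float), method="D", unweighted=True)

    src, dst = np.nonzero(union)  # both directions present by symmetry
    edge_index = np.stack([src, dst])
    nc = len(BOND_CATEGORIES)
    edge_feat = np.zeros((src.size, 2 * nc))
    edge_feat[np.arange(src.size), r_cat[src, dst]] = 1.0
    edge_feat[np.arange(src.size), nc + p_cat[src, dst]] = 1.0
    return CGRGraph(
        n_atoms=n,
        elements=list(reaction.elements),
        node_features=node_feat,
        edge_index=edge_index,
        edge_features=edge_feat,
        hop_distance=hop[src, dst],
        r_cat=r_cat,
        p_cat=p_cat,
        hop_matrix=hop,
    )


def build_edge_set(cgr: CGRGraph, coords: np.ndarray, cutoff: float = 10.0,
                   max_hops: int = 3) -> np.ndarray:
    """Directed model edges: pairs within `cutoff` Å ∪ pairs within `max_hops`.

    Symmetric by construction, no self-edges. `coords` is the current flow
    state, so radius edges follow the geometry at every network call.
    """
    n = cgr.n_atoms
    coords = np.asarray(coords, dtype=np.float64)
    within_radius = squareform(pdist(coords)) <= cutoff if n > 1 else np.zeros((n, n), bool)
    within_hops = cgr.hop_matrix <= max_hops
    keep = within_radius | within_hops
    np.fill_diagonal(keep, False)
    src, dst = np.nonzero(keep)
    return np.stack([src, dst])


def pair_feature_matrix(cgr: CGRGraph, edge_index: np.ndarray) -> np.ndarray:
    """Invariant 2D features for arbitrary atom pairs (model edges).

    Dual bond-order one-hot (absent/absent for nonbonded pairs) plus a
    hop-distance category one-hot (1, 2, 3, far).
    """
    src, dst = edge_index
    nc = len(BOND_CATEGORIES)
    feat = np.zeros((src.size, pair_feature_dim()))
    rows = np.arange(src.size)
    feat[rows, cgr.r_cat[src, dst]] = 1.0
    feat[rows, nc + cgr.p_cat[src, dst]] = 1.0
    hop = cgr.hop_matrix[src, dst]
    hop_cat = np.where(np.isfinite(hop) & (hop <= 3), np.maximum(hop, 1) - 1, 3).astype(np.intp)
    feat[rows, 2 * nc + hop_cat] = 1.0
    return feat


def sinusoidal_time_embedding(t: np.ndarray | float, dim: int) -> np.ndarray:
    """Transformer-style interleaved sin/cos embedding of flow time t ∈ [0, 1].

    Even slots are sines, odd slots cosines, over a geometric frequency ladder;
    at t = 0 the embedding is (0, 1, 0, 1, ...).
    """
    if dim % 2 != 0:
        raise ValueError("time-embedding dimension must be even")
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / half)
    args = t_arr[:, None] * freqs[None, :]
    emb = np.empty((t_arr.size, dim))
    emb[:, 0::2] = np.sin(args)
    emb[:, 1::2] = np.cos(args)
    return emb[0] if np.isscalar(t) or np.ndim(t) == 0 else emb


def initial_embeddings(cgr: CGRGraph, t: float, node_proj, edge_proj,
                       edge_index: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
    """Initial node and edge states: learned affine maps plus time embedding.

    `node_proj`/`edge_proj` are Linear modules owned by the field network; the
    sinusoidal embedding of t is added to both projected states.
    """
    if edge_index is None:
        edge_index = cgr.edge_index
        edge_raw = pair_feature_matrix(cgr, edge_index)
    else:
        edge_raw = pair_feature_matrix(cgr, edge_index)
    width = node_proj.bias.data.shape[0]
    tau = sinusoidal_time_embedding(float(t), width)
    h0 = node_proj(ensure(cgr.node_features)) + Tensor(tau)
    e0 = edge_proj(ensure(edge_raw)) + Tensor(tau)
    return h0, e0
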