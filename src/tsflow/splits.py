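"""Dataset splitting: random, reaction-core, and barrier-height strategies.

The reaction core (template) of a reaction is the set of atoms incident to
any bond whose (reactant-order, product-order) pair differs — including
formed and broken bonds and aromaticity changes. Core-disjoint splitting
groups reactions by a canonical key of the dual-labelled subgraph induced on
the core atoms, so no reaction type leaks between sets. The barrier-height
split reserves the upper and lower deciles of barrier heights for validation
and test, leaving the contiguous inner 80% for training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .cgr import bond_category_matrices
from .errors import EmptyCoreError, SplitError, SplitWarning
from .reaction_io import Reaction

__all__ = ["ReactionCore", "SplitAssignment", "extract_core", "split_random",
           "split_by_core", "split_by_barrier", "write_split"]

DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)


@dataclass
class ReactionCore:
    core_atoms: set[int]   # atom-map numbers
    core_key: str          # canonical (isomorphism-invariant) serialization


@dataclass
class SplitAssignment:
    train: set[str]
    val: set[str]
    test: set[str]
    strategy: str
    seed: int
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS

    def as_dict(self) -> dict:
        return {"strategy": self.strategy, "seed": self.seed,
                "fractions": list(self.fractions),
                "train": sorted(self.train), "val": sorted(self.val),
                "test": sorted(self.test)}


def extract_core(reaction: Reaction, include_h: bool = True) -> ReactionCore:
    """Changed-bond subgraph with dual labels, canonically keyed.

    Two reactions that are atom-map renumberings (or any graph isomorphism)
    of the same transformation receive identical core keys. With
    `include_h=False`, explicit hydrogens are dropped from the core (relevant
    for H-transfer chemistry).
    """
    r_cat, p_cat = bond_category_matrices(reaction)
    changed = np.triu(r_cat != p_cat, k=1)
    ii, jj = np.nonzero(changed)
    core_atoms = set((ii + 1).tolist()) | set((jj + 1).tolist())
    if not include_h:
        core_atoms = {m for m in core_atoms if reaction.elements[m - 1] != "H"}
    if not core_atoms:
        raise EmptyCoreError(f"{reaction.rxn_id}: no changed bond, core is empty")

    g = nx.Graph()
    for m in sorted(core_atoms):
        g.add_node(m, label=reaction.elements[m - 1])
    for m in sorted(core_atoms):
        for m2 in sorted(core_atoms):
            if m2 <= m:
                continue
            rc, pc = int(r_cat[m - 1, m2 - 1]), int(p_cat[m - 1, m2 - 1])
            if rc or pc:
                g.add_edge(m, m2, label=f"{rc}>{pc}")
    key = nx.weisfeiler_lehman_graph_hash(g, node_attr="label", edge_attr="label",
                                          iterations=4)
    return ReactionCore(core_atoms=core_atoms, core_key=key)


def _check_fractions(fractions) -> tuple[float, float, float]:
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise SplitError(f"fractions must be three non-negatives summing to 1, "
                         f"got {fractions}")
    return fractions


def split_random(ids: list[str], fractions=DEFAULT_FRACTIONS,
                 seed: int = 0) -> SplitAssignment:
    """Seeded shuffle then partition; floor sizes for val/test, remainder to train."""
    fractions = _check_fractions(fractions)
    ids = [str(i) for i in ids]
    if len(ids) < 3:
        raise SplitError("need at least 3 reactions to split")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    n_val, n_test = int(fractions[1] * n), int(fractions[2] * n)
    test = set(order[:n_test])
    val = set(order[n_test:n_test + n_val])
    train = set(order[n_test + n_val:])
    return SplitAssignment(train, val, test, "random", seed, fractions)


def split_by_core(reactions: list[Reaction], fractions=DEFAULT_FRACTIONS,
                  seed: int = 0, include_h: bool = True) -> SplitAssignment:
    """Assign whole cores greedily to test, then val; no core spans two sets."""
    fractions = _check_fractions(fractions)
    by_core: dict[str, list[str]] = {}
    for rxn in reactions:
        key = extract_core(rxn, include_h=include_h).core_key
        by_core.setdefault(key, []).append(rxn.rxn_id)
    rng = np.random.default_rng(seed)
    keys = sorted(by_core)
    keys = [keys[i] for i in rng.permutation(len(keys))]

    n = sum(len(v) for v in by_core.values())
    want_test, want_val = fractions[2] * n, fractions[1] * n
    test, val, train = set(), set(), set()
    for key in keys:
        members = by_core[key]
        if len(test) < want_test:
            test.update(members)
        elif len(val) < want_val:
            val.update(members)
        else:
            train.update(members)
    if not train:
        warnings.warn("core clusters too coarse for the requested fractions; "
                      "training set is empty", SplitWarning)
    largest = max(len(v) for v in by_core.values())
    if largest > (1.0 - fractions[1] - fractions[2]) * n:
        warnings.warn(
            f"one core covers {largest}/{n} reactions; requested fractions "
            "are unattainable, proceeding best-effort", SplitWarning)
    return SplitAssignment(train, val, test, "core", seed, fractions)


def split_by_barrier(reactions: list[Reaction], decile: float = 0.10,
                     seed: int = 0) -> SplitAssignment:
    """Upper + lower `decile` of barrier heights go to val/test; middle to train.

    The two tails are pooled and randomly halved between val and test (seeded).
    Ties at a decile boundary are broken by rxn_id order.
    """
    missing = [r.rxn_id for r in reactions if r.barrier_height is None]
    if missing:
        raise SplitError(f"reactions without barrier_height: {sorted(missing)}")
    if not 0 < decile < 0.5:
        raise SplitError("decile must lie in (0, 0.5)")
    ranked = sorted(reactions, key=lambda r: (r.barrier_height, r.rxn_id))
    n = len(ranked)
    k = int(decile * n)
    tails = [r.rxn_id for r in ranked[:k]] + [r.rxn_id for r in ranked[n - k:]]
    train = {r.rxn_id for r in ranked[k:n - k]}
    rng = np.random.default_rng(seed)
    tails = [tails[i] for i in rng.permutation(len(tails))]
    val = set(tails[:len(tails) // 2])
    test = set(tails[len(tails) // 2:])
    return SplitAssignment(train, val, test, "barrier", seed,
                           (1.0 - 2 * decile, decile, decile))


def write_split(assignment: SplitAssignment, out_dir: str | Path,
                core_sizes: dict[str, int] | None = None) -> None:
    """Three plain-text id lists plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("train", "val", "test"):
        ids = sorted(getattr(assignment, name))
        (out_dir / f"{name}.txt").write_text("\n".join(ids) + ("\n" if ids else ""))
    manifest = assignment.as_dict()
    manifest["sizes"] = {k: len(getattr(assignment, k)) for k in ("train", "val", "test")}
    if core_sizes is not None:
        manifest["core_cluster_sizes"] = sorted(core_sizes.values(), reverse=True)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
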