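"""Geometry evaluation metrics: D-MAE, RMSD, angle error, steric clash.

All metrics compare coordinate arrays in atom-map row order.

* D-MAE — mean absolute error over all interatomic distances; invariant to
  any rigid motion *or reflection* of either argument, so it is blind to
  enantiomer mistakes.
* RMSD — root mean square deviation after optimal superposition over proper
  rotations only (Kabsch, det = +1); a mirror-image prediction scores high.
* Angle error — mean absolute difference (degrees) of bond angles over all
  bonded triplets of the CGR union graph; undefined (NaN) for molecules
  without such a triplet, and NaN entries are excluded from aggregates.
* Steric clash — repulsion-only Lennard-Jones score 4ε(σ/r)¹² summed over
  atom pairs with r ≤ 0.7 Å (ε = 0.25 kcal/mol, σ = 0.7 Å); the dispersion
  term is omitted and larger distances contribute zero, so only contacts at
  or below the shortest realistic bond length (H₂) register.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .cgr import CGRGraph
from .errors import InputError
from .geom import superimpose_rmsd

__all__ = ["ClashParams", "MetricsReport", "d_mae", "rmsd", "angle_error",
           "steric_clash", "evaluate"]


@dataclass
class ClashParams:
    epsilon: float = 0.25  # kcal/mol
    sigma: float = 0.7     # Å
    cutoff: float = 0.7    # Å; pairs farther than this contribute zero

    def __post_init__(self):
        if min(self.epsilon, self.sigma, self.cutoff) <= 0:
            raise InputError("clash parameters must be positive")


def _coords(geom) -> np.ndarray:
    arr = np.asarray(getattr(geom, "coords", geom), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InputError(f"expected N×3 coordinates, got shape {arr.shape}")
    return arr


def d_mae(pred, truth) -> float:
    """Mean absolute interatomic-distance error in Å (alignment-free)."""
    p, q = _coords(pred), _coords(truth)
    if p.shape != q.shape:
        raise InputError(f"shape mismatch: {p.shape} vs {q.shape}")
    if p.shape[0] < 2:
        raise InputError("D-MAE needs at least two atoms")
    return float(np.mean(np.abs(pdist(p) - pdist(q))))


def rmsd(pred, truth) -> float:
    """Minimum RMSD (Å) over proper rigid motions; reflections are not allowed."""
    return superimpose_rmsd(_coords(pred), _coords(truth))


def _angles(coords: np.ndarray, triplets: np.ndarray) -> np.ndarray:
    a = coords[triplets[:, 0]] - coords[triplets[:, 1]]
    b = coords[triplets[:, 2]] - coords[triplets[:, 1]]
    cosang = np.sum(a * b, axis=1) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def bonded_triplets(cgr: CGRGraph) -> np.ndarray:
    """(i, j, k) with j–i and j–k bonds in the union graph, i < k. Shape (T, 3)."""
    adj = cgr.union_adjacency
    trips = []
    for j in range(cgr.n_atoms):
        nbrs = np.nonzero(adj[j])[0]
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                trips.append((nbrs[a], j, nbrs[b]))
    return np.asarray(trips, dtype=np.intp).reshape(-1, 3)


def angle_error(pred, truth, cgr: CGRGraph) -> float:
    """Mean absolute bond-angle deviation in degrees; NaN if no bonded triplet."""
    trips = bonded_triplets(cgr)
    if trips.shape[0] == 0:
        return float("nan")
    return float(np.mean(np.abs(_angles(_coords(pred), trips)
                                - _angles(_coords(truth), trips))))


def steric_clash(pred, params: ClashParams | None = None) -> float:
    """Repulsive-LJ clash score in kcal/mol; +inf for coincident atoms."""
    params = params or ClashParams()
    p = _coords(pred)
    if p.shape[0] < 2:
        raise InputError("steric clash needs at least two atoms")
    r = pdist(p)
    close = r <= params.cutoff
    if not np.any(close):
        return 0.0
    r_close = r[close]
    if np.any(r_close == 0.0):
        return float("inf")
    return float(np.sum(4.0 * params.epsilon * (params.sigma / r_close) ** 12))


@dataclass
class MetricsReport:
    per_reaction: pd.DataFrame            # one row per reaction
    aggregates: dict                      # {metric: {mean, median, q25, q75, q95}}
    histogram: dict = field(default_factory=dict)  # D-MAE histogram (edges, counts)

    def to_json(self, path: str | Path) -> None:
        import json
        payload = {
            "aggregates": self.aggregates,
            "per_reaction": self.per_reaction.replace([np.inf], "inf")
                                             .to_dict(orient="records"),
            "histogram": self.histogram,
        }
        Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True))

    def to_csv(self, path: str | Path) -> None:
        self.per_reaction.to_csv(path, index=False)


def evaluate(predictions: dict[str, np.ndarray], truths: dict[str, np.ndarray],
             cgrs: dict[str, CGRGraph], clash_params: ClashParams | None = None,
             n_bins: int = 40) -> MetricsReport:
    """Per-reaction metrics plus dataset aggregates (means over the test set).

    The three dicts must share an identical key set of reaction ids.
    """
    if set(predictions) != set(truths) or set(predictions) != set(cgrs):
        missing = set(truths).symmetric_difference(predictions) | \
            set(cgrs).symmetric_difference(predictions)
        raise InputError(f"id sets differ between inputs: {sorted(missing)}")
    rows = []
    for rid in sorted(predictions):
        rows.append({
            "rxn_id": rid,
            "d_mae": d_mae(predictions[rid], truths[rid]),
            "rmsd": rmsd(predictions[rid], truths[rid]),
            "angle_error": angle_error(predictions[rid], truths[rid], cgrs[rid]),
            "steric_clash": steric_clash(predictions[rid], clash_params),
        })
    table = pd.DataFrame(rows)
    aggregates = {}
    for col in ("d_mae", "rmsd", "angle_error", "steric_clash"):
        vals = table[col].to_numpy(dtype=np.float64)
        vals = vals[np.isfinite(vals)] if col == "angle_error" else vals
        aggregates[col] = {
            "mean": float(np.mean(vals)) if vals.size else float("nan"),
            "median": float(np.median(vals)) if vals.size else float("nan"),
            "q25": float(np.quantile(vals, 0.25)) if vals.size else float("nan"),
            "q75": float(np.quantile(vals, 0.75)) if vals.size else float("nan"),
            "q95": float(np.quantile(vals, 0.95)) if vals.size else float("nan"),
        }
    dmae_vals = table["d_mae"].to_numpy(dtype=np.float64)
    counts, edges = np.histogram(dmae_vals, bins=n_bins,
                                 range=(0.0, max(float(dmae_vals.max()), 1e-6)))
    return MetricsReport(per_reaction=table, aggregates=aggregates,
                         histogram={"bin_edges": edges.tolist(),
                                    "counts": counts.tolist()})
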