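"""Reactions, geometries, and dataset I/O.

A reaction is a pair of atom-mapped molecular graphs (reactant, product) over
the same atom set: every atom, including hydrogens, carries an atom-map number,
and the map numbers 1..N are a permutation on both sides. All coordinate arrays
in the package are ordered by ascending atom-map number — row i holds the atom
with map number i+1. This is the single row-order convention everywhere
(features, flow states, metrics).

Sanitization is deliberately lenient: transition-state-adjacent species
(radicals from homolysis, carbenes, zwitterions) are valid inputs, so molecules
are parsed without valence enforcement and only ring/aromaticity/hybridization
perception is run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import DatasetError, FormatError, InputError, MappingError, ParseError

__all__ = [
    "Geometry",
    "Reaction",
    "parse_reaction",
    "serialize_reaction",
    "deserialize_reaction",
    "read_xyz",
    "write_xyz",
    "load_dataset",
    "write_dataset",
]

_PARTIAL_SANITIZE = (
    Chem.SanitizeFlags.SANITIZE_SYMMRINGS
    | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
    | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION
    | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION
)


@dataclass
class Geometry:
    """Atom-ordered Cartesian coordinates in Å.

    Row i corresponds to atom-map number i+1.
    """

    elements: list[str]
    coords: np.ndarray
    comment: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError(f"coords must be N×3, got {self.coords.shape}")
        if len(self.elements) != self.coords.shape[0]:
            raise InputError("elements/coords length mismatch")
        if self.coords.shape[0] < 2:
            raise InputError("a Geometry needs at least 2 atoms")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coords contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def centered(self) -> "Geometry":
        return Geometry(list(self.elements), self.coords - self.centroid(), self.comment)

    @property
    def is_centered(self) -> bool:
        return bool(np.linalg.norm(self.centroid()) < 1e-6)

    def to_dict(self) -> dict:
        return {"elements": list(self.elements), "coords": self.coords.tolist(),
                "comment": self.comment}

    @staticmethod
    def from_dict(d: dict) -> "Geometry":
        return Geometry(list(d["elements"]), np.asarray(d["coords"]), d.get("comment", ""))


@dataclass
class Reaction:
    """Atom-mapped single-step reaction, optionally with geometries and barrier."""

    rxn_id: str
    reactant_smiles: str
    product_smiles: str
    reactant_mol: Chem.Mol = field(repr=False, compare=False)
    product_mol: Chem.Mol = field(repr=False, compare=False)
    elements: list[str] = field(default_factory=list)  # by ascending map number
    ts_geometry: Geometry | None = None
    reactant_geometry: Geometry | None = None
    barrier_height: float | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def smiles(self) -> str:
        return f"{self.reactant_smiles}>>{self.product_smiles}"


def _parse_side(smi: str, side: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smi, sanitize=False)
    if mol is None:
        raise ParseError(f"unparsable {side} SMILES: {smi!r}")
    try:
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(mol, _PARTIAL_SANITIZE, catchErrors=True)
    except Exception as exc:  # pragma: no cover - rdkit raises rarely here
        raise ParseError(f"failed to perceive {side} molecule {smi!r}: {exc}") from exc
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum() <= 0:
            raise MappingError(
                f"unmapped atom {atom.GetSymbol()} (index {atom.GetIdx()}) in {side}: {smi!r}")
        if atom.GetTotalNumHs() > 0:
            raise MappingError(
                f"atom map {atom.GetAtomMapNum()} in {side} carries implicit hydrogens; "
                "all hydrogens must be explicit mapped atoms")
    return mol


def map_to_index(mol: Chem.Mol) -> dict[int, int]:
    """Atom-map number -> RDKit atom index."""
    return {atom.GetAtomMapNum(): atom.GetIdx() for atom in mol.GetAtoms()}


def parse_reaction(smiles_pair: str, rxn_id: str = "") -> Reaction:
    """Parse an atom-mapped "reactant>>product" SMILES into a validated Reaction."""
    parts = smiles_pair.split(">>")
    if len(parts) != 2:
        raise ParseError(f"expected exactly one '>>' in {smiles_pair!r}")
    r_mol = _parse_side(parts[0], "reactant")
    p_mol = _parse_side(parts[1], "product")

    r_maps = {a.GetAtomMapNum(): a.GetSymbol() for a in r_mol.GetAtoms()}
    p_maps = {a.GetAtomMapNum(): a.GetSymbol() for a in p_mol.GetAtoms()}
    n = r_mol.GetNumAtoms()
    if len(r_maps) != n or len(p_maps) != p_mol.GetNumAtoms():
        raise MappingError("duplicate atom-map numbers within one side")
    expected = set(range(1, n + 1))
    if set(r_maps) != expected:
        raise MappingError(f"reactant maps are not a permutation of 1..{n}")
    if set(p_maps) != expected:
        raise MappingError("product atom maps do not match the reactant atom set")
    for m in expected:
        if r_maps[m] != p_maps[m]:
            raise MappingError(
                f"element changes under map number {m}: {r_maps[m]} -> {p_maps[m]}")

    elements = [r_maps[m] for m in range(1, n + 1)]
    return Reaction(
        rxn_id=rxn_id,
        reactant_smiles=Chem.MolToSmiles(r_mol, canonical=True),
        product_smiles=Chem.MolToSmiles(p_mol, canonical=True),
        reactant_mol=r_mol,
        product_mol=p_mol,
        elements=elements,
    )


def serialize_reaction(reaction: Reaction) -> dict:
    d: dict = {"rxn_id": reaction.rxn_id, "rxn_smiles": reaction.smiles}
    if reaction.barrier_height is not None:
        d["barrier_height"] = reaction.barrier_height
    if reaction.ts_geometry is not None:
        d["ts_geometry"] = reaction.ts_geometry.to_dict()
    if reaction.reactant_geometry is not None:
        d["reactant_geometry"] = reaction.reactant_geometry.to_dict()
    return d


def deserialize_reaction(d: dict) -> Reaction:
    rxn = parse_reaction(d["rxn_smiles"], rxn_id=d.get("rxn_id", ""))
    rxn.barrier_height = d.get("barrier_height")
    if "ts_geometry" in d:
        rxn.ts_geometry = Geometry.from_dict(d["ts_geometry"])
    if "reactant_geometry" in d:
        rxn.reactant_geometry = Geometry.from_dict(d["reactant_geometry"])
    _check_geometries(rxn)
    return rxn


def write_xyz(geom: Geometry, path: str | Path) -> None:
    lines = [str(geom.n_atoms), geom.comment]
    for el, (x, y, z) in zip(geom.elements, geom.coords):
        lines.append(f"{el:<2s} {x: .8f} {y: .8f} {z: .8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> Geometry:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise FormatError(f"{path}: first line is not an atom count") from exc
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != n:
        raise FormatError(f"{path}: header claims {n} atoms but {len(body)} listed")
    elements, coords = [], []
    for ln in body:
        fields = ln.split()
        if len(fields) < 4:
            raise FormatError(f"{path}: malformed atom line {ln!r}")
        elements.append(fields[0])
        try:
            coords.append([float(v) for v in fields[1:4]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric coordinate in {ln!r}") from exc
    return Geometry(elements, np.asarray(coords), comment)


def _check_geometries(rxn: Reaction) -> None:
    for name, geom in (("ts", rxn.ts_geometry), ("reactant", rxn.reactant_geometry)):
        if geom is None:
            continue
        if geom.n_atoms != rxn.n_atoms:
            raise DatasetError(
                f"{rxn.rxn_id}: {name} geometry has {geom.n_atoms} atoms, "
                f"reaction has {rxn.n_atoms}")
        if list(geom.elements) != list(rxn.elements):
            raise DatasetError(
                f"{rxn.rxn_id}: {name} geometry element order disagrees with "
                "atom-map order of the reaction")


def load_dataset(csv_path: str | Path, xyz_dir: str | Path | None = None, *,
                 require_ts: bool = True, require_reactant: bool = False,
                 strict: bool = True) -> list[Reaction]:
    """Load a reaction table (rxn_id, rxn_smiles[, barrier_height]) plus XYZ files.

    Per reaction, ``<xyz_dir>/<rxn_id>.ts.xyz`` holds the transition-state
    geometry and ``<rxn_id>.rxt.xyz`` (optional) the reactant geometry. Returns
    reactions sorted by rxn_id.
    """
    csv_path = Path(csv_path)
    try:
        table = pd.read_csv(csv_path, dtype={"rxn_id": str})
    except pd.errors.EmptyDataError:
        return []
    if table.empty:
        return []
    for col in ("rxn_id", "rxn_smiles"):
        if col not in table.columns:
            raise DatasetError(f"{csv_path}: missing required column {col!r}")

    reactions: list[Reaction] = []
    for row in table.itertuples(index=False):
        rxn = parse_reaction(row.rxn_smiles, rxn_id=str(row.rxn_id))
        if "barrier_height" in table.columns:
            b = float(getattr(row, "barrier_height"))
            rxn.barrier_height = None if math.isnan(b) else b
        if xyz_dir is not None:
            ts_path = Path(xyz_dir) / f"{rxn.rxn_id}.ts.xyz"
            rxt_path = Path(xyz_dir) / f"{rxn.rxn_id}.rxt.xyz"
            if ts_path.exists():
                rxn.ts_geometry = read_xyz(ts_path)
            elif require_ts and strict:
                raise DatasetError(f"missing TS geometry for {rxn.rxn_id}: {ts_path}")
            elif require_ts:
                continue
            if rxt_path.exists():
                rxn.reactant_geometry = read_xyz(rxt_path)
            elif require_reactant:
                if strict:
                    raise DatasetError(f"missing reactant geometry for {rxn.rxn_id}")
                continue
        elif require_ts and strict:
            raise DatasetError("require_ts=True but no xyz_dir given")
        _check_geometries(rxn)
        reactions.append(rxn)
    reactions.sort(key=lambda r: r.rxn_id)
    return reactions


def write_dataset(reactions: list[Reaction], csv_path: str | Path,
                  xyz_dir: str | Path) -> None:
    """Inverse of load_dataset: emit the CSV table and per-reaction XYZ files."""
    xyz_dir = Path(xyz_dir)
    xyz_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rxn in sorted(reactions, key=lambda r: r.rxn_id):
        rows.append({"rxn_id": rxn.rxn_id, "rxn_smiles": rxn.smiles,
                     "barrier_height": rxn.barrier_height})
        if rxn.ts_geometry is not None:
            geom = Geometry(rxn.ts_geometry.elements, rxn.ts_geometry.coords, rxn.rxn_id)
            write_xyz(geom, xyz_dir / f"{rxn.rxn_id}.ts.xyz")
        if rxn.reactant_geometry is not None:
            geom = Geometry(rxn.reactant_geometry.elements, rxn.reactant_geometry.coords,
                            rxn.rxn_id)
            write_xyz(geom, xyz_dir / f"{rxn.rxn_id}.rxt.xyz")
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def reactions_to_json(reactions: list[Reaction], path: str | Path) -> None:
    Path(path).write_text(json.dumps([serialize_reaction(r) for r in reactions], indent=1))


def reactions_from_json(path: str | Path) -> list[Reaction]:
    return [deserialize_reaction(d) for d in json.loads(Path(path).read_text())]
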