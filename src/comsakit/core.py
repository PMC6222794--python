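"""Shared data model and file I/O.

Molecules are ordered lists of point charges (element, Cartesian Å
coordinates, partial charge in e) with an optional activity (IC50 on a
consistent, unitless scale). Labelled matrices — descriptor blocks, field
blocks, receptor-array responses — are pandas DataFrames with unique string
row/column labels; NaN marks a missing cell and is never silently coerced
to zero.

Two on-disk formats are supported: a plain "atom-csv" table
(mol_id, element, x, y, z, charge[, activity]) that is always available,
and read-only V2000 SDF through RDKit when it is installed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import VDW_RADII, vdw_radius

log = logging.getLogger("comsakit")

# Exact-round-trip float formatting used by every writer in the package.
FLOAT_FMT = "%.17g"


@dataclasses.dataclass(frozen=True)
class Atom:
    """A point charge on a van der Waals sphere.

    Coordinates are Å, ``charge`` is in elementary-charge units, and
    ``vdw_radius`` (Å) defaults to the bundled Bondi value for ``element``.
    """

    element: str
    x: float
    y: float
    z: float
    charge: float
    vdw_radius: float = 0.0

    def __post_init__(self):
        if self.vdw_radius == 0.0:
            object.__setattr__(self, "vdw_radius", vdw_radius(self.element))
        if not (self.vdw_radius > 0):
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")
        for v in (self.x, self.y, self.z, self.charge):
            if not math.isfinite(v):
                raise ValueError(f"non-finite atom field in {self!r}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclasses.dataclass
class MoleculeRecord:
    """One molecule: unique id, ordered atoms, optional activity (IC50)."""

    id: str
    atoms: list[Atom]
    activity: float | None = None

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ValueError(f"molecule {self.id!r} has no atoms")

    @property
    def coords(self) -> np.ndarray:
        """n_atoms × 3 coordinate array (Å)."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


ATOM_CSV_COLUMNS = ("mol_id", "element", "x", "y", "z", "charge")


def read_molecules(path, format: str = "atom-csv",
                   radius_overrides: dict[str, float] | None = None
                   ) -> list[MoleculeRecord]:
    """Read molecules from ``path``.

    ``format`` is ``"atom-csv"`` (always available) or ``"sdf"`` (V2000,
    requires RDKit; charges from atom property ``_TriposPartialCharge`` or
    formal charges). Records keep file order; charges are preserved exactly
    as read. Duplicate mol_id with conflicting activity is an error.
    """
    if format == "atom-csv":
        return _read_atom_csv(path, radius_overrides)
    if format == "sdf":
        return _read_sdf(path, radius_overrides)
    raise ValueError(f"unknown molecule format {format!r}")


def _read_atom_csv(path, radius_overrides) -> list[MoleculeRecord]:
    df = pd.read_csv(path, dtype={"mol_id": str, "element": str},
                     float_precision="round_trip")
    for col in ATOM_CSV_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"atom-csv {path} is missing required column {col!r}")
    if df["charge"].isna().any():
        bad = df.index[df["charge"].isna()][0]
        raise ValueError(f"atom-csv {path}: missing charge value at row {bad}")
    has_activity = "activity" in df.columns
    records: dict[str, MoleculeRecord] = {}
    for i, row in df.iterrows():
        el = row["element"]
        if el not in VDW_RADII and not (radius_overrides and el in radius_overrides):
            raise ValueError(f"atom-csv {path}: unknown element {el!r} at row {i}")
        atom = Atom(el, float(row["x"]), float(row["y"]), float(row["z"]),
                    float(row["charge"]),
                    vdw_radius(el, radius_overrides))
        mid = row["mol_id"]
        act = None
        if has_activity and not pd.isna(row["activity"]):
            act = float(row["activity"])
        if mid in records:
            rec = records[mid]
            if act is not None:
                if rec.activity is not None and rec.activity != act:
                    raise ValueError(
                        f"molecule {mid!r} has conflicting activity values "
                        f"({rec.activity} vs {act})")
                rec.activity = act
            rec.atoms.append(atom)
        else:
            records[mid] = MoleculeRecord(mid, [atom], act)
    return list(records.values())


def _read_sdf(path, radius_overrides) -> list[MoleculeRecord]:
    try:
        from rdkit import Chem
    except ImportError as e:  # pragma: no cover - depends on optional extra
        raise ImportError("SDF reading requires the optional rdkit dependency") from e
    records = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"SDF {path}: unparseable record #{i}")
        conf = mol.GetConformer()
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        atoms = []
        for a in mol.GetAtoms():
            p = conf.GetAtomPosition(a.GetIdx())
            if a.HasProp("_TriposPartialCharge"):
                q = float(a.GetProp("_TriposPartialCharge"))
            else:
                q = float(a.GetFormalCharge())
            el = a.GetSymbol()
            atoms.append(Atom(el, p.x, p.y, p.z, q, vdw_radius(el, radius_overrides)))
        records.append(MoleculeRecord(name or f"mol{i}", atoms))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"SDF {path}: duplicate molecule ids")
    return records


def write_molecules(molecules: list[MoleculeRecord], path) -> None:
    """Write molecules as atom-csv (with activity column when present)."""
    rows = []
    any_activity = any(m.activity is not None for m in molecules)
    for m in molecules:
        for a in m.atoms:
            row = {"mol_id": m.id, "element": a.element, "x": a.x, "y": a.y,
                   "z": a.z, "charge": a.charge}
            if any_activity:
                row["activity"] = m.activity if m.activity is not None else np.nan
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_activities(path) -> pd.Series:
    """Read an activity table (CSV: id in first column, activity in second)."""
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"activity table {path} needs id + value columns")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"activity table {path}: duplicate compound ids")
    return pd.Series(df.iloc[:, 1].to_numpy(float), index=ids.to_numpy(),
                     name=df.columns[1])


def write_activities(activities: pd.Series, path) -> None:
    activities.rename_axis("id").to_frame().to_csv(path, float_format=FLOAT_FMT)


def read_matrix(path) -> pd.DataFrame:
    """Read a labelled numeric matrix (header = column ids, first column =
    row ids). Empty cells become NaN (missing), never zero. Duplicate labels
    on either axis are an error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise ValueError(f"matrix {path}: duplicate column label {dup!r}")
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"matrix {path}: duplicate row label {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"matrix {path}: duplicate column label {dup!r}")
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, float_format=FLOAT_FMT)


def validate_matrix(matrix: pd.DataFrame, allow_missing: bool = True) -> pd.DataFrame:
    """Check LabeledMatrix invariants; return the matrix unchanged."""
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValueError("matrix labels must be unique per axis")
    if not allow_missing and matrix.isna().any().any():
        raise ValueError("matrix contains missing cells")
    return matrix


def ensure_outdir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
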