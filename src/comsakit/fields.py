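"""CoMFA-style interaction field lattices.

A rectangular lattice with 2.0 Å spacing is laid out around the aligned
molecule set, extending at least 4.0 Å beyond every van der Waals envelope,
with bounds rounded outward to spacing multiples (so the lattice does not
depend on molecule order). At every node two probe interaction energies
are evaluated for each molecule:

* electrostatic — Coulomb energy of the probe charge with a
  distance-dependent dielectric ε(r) = r:  E = k·q_p·Σ qᵢ/rᵢ²;
* steric — Lennard-Jones 6-12 energy with Lorentz–Berthelot combination:
  S = Σᵢ εᵢₚ[(rminᵢₚ/rᵢ)¹² − 2(rminᵢₚ/rᵢ)⁶].

Energies beyond ±30 kcal/mol are truncated to the cutoff (sign preserved);
a node inside an atom is set to +cutoff. The steric block and the
electrostatic block are concatenated column-wise per molecule, CoMFA
convention. Columns with energy standard deviation below the sigma
threshold (2.0 kcal/mol) are discarded before modelling.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import MoleculeRecord
from .elements import COULOMB_K, SP3_CARBON_PROBE, lj_params

log = logging.getLogger("comsakit")

DEFAULT_SPACING = 2.0   # Å
DEFAULT_MARGIN = 4.0    # Å beyond the vdW envelopes
DEFAULT_CUTOFF = 30.0   # kcal/mol truncation


@dataclasses.dataclass(frozen=True)
class ProbeSpec:
    """Probe atom: charge (e) and Lennard-Jones well (kcal/mol, Å)."""

    charge: float = SP3_CARBON_PROBE["charge"]
    lj_epsilon: float = SP3_CARBON_PROBE["lj_epsilon"]
    lj_rmin: float = SP3_CARBON_PROBE["lj_rmin"]

    def __post_init__(self):
        if self.lj_epsilon < 0 or not self.lj_rmin > 0:
            raise ValueError("invalid probe LJ parameters")


@dataclasses.dataclass(frozen=True)
class LatticeSpec:
    """Regular lattice: origin (Å), spacing (Å), node counts per axis."""

    origin: tuple[float, float, float]
    spacing: float
    n_nodes: tuple[int, int, int]

    def __post_init__(self):
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if any(n < 1 for n in self.n_nodes):
            raise ValueError("need at least one node per axis")

    @property
    def total_nodes(self) -> int:
        nx, ny, nz = self.n_nodes
        return nx * ny * nz

    def nodes(self) -> np.ndarray:
        """All node coordinates, z varying fastest (row-major over x,y,z)."""
        ax = [np.asarray(self.origin)[i] + self.spacing * np.arange(self.n_nodes[i])
              for i in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([a.ravel() for a in g])

    def node_ids(self, prefix: str) -> list[str]:
        nx, ny, nz = self.n_nodes
        return [f"{prefix}_{i}_{j}_{k}"
                for i in range(nx) for j in range(ny) for k in range(nz)]


def build_lattice(molecules: list[MoleculeRecord],
                  spacing: float = DEFAULT_SPACING,
                  margin: float = DEFAULT_MARGIN,
                  radius_scale: float = 1.0) -> LatticeSpec:
    """Lattice covering all molecules' scaled vdW envelopes plus ``margin``,
    bounds rounded outward to multiples of ``spacing``."""
    if not molecules:
        raise ValueError("build_lattice needs at least one molecule")
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for m in molecules:
        c = m.coords
        r = (m.radii * radius_scale)[:, None]
        lo = np.minimum(lo, (c - r).min(axis=0))
        hi = np.maximum(hi, (c + r).max(axis=0))
    lo -= margin
    hi += margin
    lo = np.floor(lo / spacing) * spacing
    hi = np.ceil(hi / spacing) * spacing
    n = np.maximum(np.round((hi - lo) / spacing).astype(int) + 1, 1)
    spec = LatticeSpec(tuple(float(v) for v in lo), spacing,
                       tuple(int(v) for v in n))
    log.info("lattice: %s nodes (%d total), origin %s, spacing %.2f",
             spec.n_nodes, spec.total_nodes, spec.origin, spacing)
    return spec


def _node_distances(molecule: MoleculeRecord, lattice: LatticeSpec) -> np.ndarray:
    nodes = lattice.nodes()
    diff = nodes[:, None, :] - molecule.coords[None, :, :]
    return np.linalg.norm(diff, axis=2)  # n_nodes × n_atoms


def electrostatic_field(molecule: MoleculeRecord, lattice: LatticeSpec,
                        probe: ProbeSpec = ProbeSpec(),
                        cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Coulomb probe energy per node (kcal/mol), ε(r)=r, clamped to
    ±cutoff. A node coinciding with an atom is set to +cutoff and logged."""
    r = _node_distances(molecule, lattice)
    coincident = (r < 1e-9).any(axis=1)
    r_safe = np.where(r < 1e-9, 1.0, r)
    E = COULOMB_K * probe.charge * (molecule.charges[None, :] / r_safe ** 2).sum(axis=1)
    if coincident.any():
        log.warning("%d lattice nodes coincide with atoms of %s; set to +cutoff",
                    int(coincident.sum()), molecule.id)
        E[coincident] = cutoff
    return np.clip(E, -cutoff, cutoff)


def steric_field(molecule: MoleculeRecord, lattice: LatticeSpec,
                 probe: ProbeSpec = ProbeSpec(),
                 cutoff: float = DEFAULT_CUTOFF,
                 lj_overrides: dict[str, tuple[float, float]] | None = None
                 ) -> np.ndarray:
    """Lennard-Jones probe energy per node (kcal/mol), clamped to ±cutoff.

    Lorentz–Berthelot combination: rminᵢₚ = (rminᵢ + rmin_probe)/2,
    εᵢₚ = sqrt(εᵢ·ε_probe). Values below −cutoff are clamped too (logged);
    a node inside an atom saturates at +cutoff.
    """
    eps = np.empty(len(molecule.atoms))
    rmin = np.empty(len(molecule.atoms))
    for i, el in enumerate(molecule.elements):
        e_i, r_i = lj_params(el, lj_overrides)
        eps[i] = np.sqrt(e_i * probe.lj_epsilon)
        rmin[i] = 0.5 * (r_i + probe.lj_rmin)
    r = _node_distances(molecule, lattice)
    r_safe = np.maximum(r, 1e-9)
    ratio6 = (rmin[None, :] / r_safe) ** 6
    S = (eps[None, :] * (ratio6 ** 2 - 2.0 * ratio6)).sum(axis=1)
    n_low = int((S < -cutoff).sum())
    if n_low:
        log.warning("%d steric values below -cutoff clamped for %s",
                    n_low, molecule.id)
    return np.clip(S, -cutoff, cutoff)


def variance_filter(matrix: pd.DataFrame, sigma: float = 2.0,
                    sigma_is_variance: bool = False) -> pd.DataFrame:
    """Drop columns with energy standard deviation (n−1 denominator) below
    ``sigma`` kcal/mol; with ``sigma_is_variance`` the threshold applies to
    the variance instead. Survivors keep their column ids."""
    if matrix.isna().any().any():
        raise ValueError("variance filter requires a complete matrix")
    stat = matrix.var(ddof=1) if sigma_is_variance else matrix.std(ddof=1)
    keep = stat >= sigma
    if not keep.any():
        raise ValueError(
            f"all columns fall below sigma={sigma}; lower the threshold")
    return matrix.loc[:, keep]


class FieldGridVectorizer(BaseEstimator, TransformerMixin):
    """CoMFA-style field transformer.

    ``fit(molecules)`` builds the shared lattice from the batch's vdW
    envelopes; ``transform(molecules)`` returns a DataFrame with one row
    per molecule — steric block columns (``s_i_j_k``) followed by
    electrostatic block columns (``e_i_j_k``).
    """

    def __init__(self, spacing: float = DEFAULT_SPACING,
                 margin: float = DEFAULT_MARGIN,
                 cutoff: float = DEFAULT_CUTOFF,
                 probe: ProbeSpec = ProbeSpec()):
        self.spacing = spacing
        self.margin = margin
        self.cutoff = cutoff
        self.probe = probe

    def fit(self, molecules: list[MoleculeRecord], y=None):
        self.lattice_ = build_lattice(molecules, self.spacing, self.margin)
        return self

    def transform(self, molecules: list[MoleculeRecord]) -> pd.DataFrame:
        if not hasattr(self, "lattice_"):
            raise ValueError("FieldGridVectorizer is not fitted")
        rows = {}
        for m in molecules:
            s = steric_field(m, self.lattice_, self.probe, self.cutoff)
            e = electrostatic_field(m, self.lattice_, self.probe, self.cutoff)
            rows[m.id] = np.concatenate([s, e])
        cols = self.lattice_.node_ids("s") + self.lattice_.node_ids("e")
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def comfa_matrix(molecules: list[MoleculeRecord],
                 spacing: float = DEFAULT_SPACING,
                 margin: float = DEFAULT_MARGIN,
                 cutoff: float = DEFAULT_CUTOFF,
                 probe: ProbeSpec = ProbeSpec()
                 ) -> tuple[pd.DataFrame, LatticeSpec]:
    """Functional wrapper: build the lattice and compute both field blocks."""
    vec = FieldGridVectorizer(spacing, margin, cutoff, probe).fit(molecules)
    return vec.transform(molecules), vec.lattice_
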