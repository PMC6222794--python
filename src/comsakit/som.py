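"""Molecular-surface self-organizing maps (CoMSA descriptors).

The descriptor pipeline: sample points on the scaled van der Waals surface
of a molecule, evaluate the molecular electrostatic potential at those
points, train a rectangular Kohonen map on the *template* molecule's
surface coordinates, then project every molecule's surface points through
the trained map. Each map cell collects the mean potential of the points
it wins; unfolding the rows×cols map row-major gives a fixed-length
descriptor vector (400 for a 20×20 map, 2500 for 50×50) suitable for PLS.

The winning neuron of a point x is the one minimizing the squared
Euclidean distance to its 3-element weight vector; ties break to the lower
row-major index. Training uses a winner-takes-most rule with a Gaussian
grid neighbourhood and linearly decaying learning rate and width. The
``winning_distance`` acts at projection time as a discard radius: points
farther than it from their winning neuron's weight vector are dropped,
so a counter-template molecule only marks the cells whose template-surface
neighbourhood it actually reaches.

The electrostatic potential is a Coulomb sum over atomic point charges
with a distance-dependent dielectric ε(r) = r:

    V(p) = k · Σᵢ qᵢ / rᵢ² ,   k = 332.0636 kcal·Å/(mol·e²),

so values are kcal/mol per unit probe charge.

Molecules are assumed pre-aligned on a common scaffold; alignment is an
input contract, not performed here.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import MoleculeRecord
from .elements import COULOMB_K

log = logging.getLogger("comsakit")


@dataclasses.dataclass
class SurfacePoints:
    """Points on a molecule's scaled vdW surface with optional potential
    values (kcal/mol·e)."""

    coords: np.ndarray                # n × 3, Å
    molecule_id: str
    values: np.ndarray | None = None  # n, electrostatic potential
    atom_index: np.ndarray | None = None  # owning atom per point

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 1:
            raise ValueError("surface points must be a non-empty n×3 array")


@dataclasses.dataclass
class SOMGrid:
    """A trained rows×cols Kohonen map with 3-element weight vectors (Å)."""

    rows: int
    cols: int
    weights: np.ndarray   # (rows*cols) × 3
    winning_distance: float
    epochs: int
    seed: int
    template_id: str = ""

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols


@dataclasses.dataclass
class FeatureMap:
    """rows×cols grid of mean projected values; NaN marks an empty cell."""

    values: np.ndarray     # rows × cols, NaN where empty
    occupancy: np.ndarray  # rows × cols, int counts
    n_presented: int
    n_discarded: int

    def __post_init__(self):
        empty = self.occupancy == 0
        assert np.all(np.isnan(self.values) == empty), \
            "empty cells must be exactly the zero-occupancy cells"


# ---------------------------------------------------------------------------
# Surface sampling and potential


def sample_surface(molecule: MoleculeRecord, points_per_atom: int,
                   radius_scale: float = 1.0, seed: int | None = None
                   ) -> SurfacePoints:
    """Sample points uniformly on each atom's scaled vdW sphere, discarding
    points buried inside any *other* atom's scaled sphere.

    A molecule whose every candidate point is buried is an error.
    """
    if seed is None:
        raise ValueError("sample_surface requires an explicit integer seed")
    if points_per_atom < 1:
        raise ValueError("points_per_atom must be >= 1")
    if not radius_scale > 0:
        raise ValueError("radius_scale must be positive")
    rng = np.random.default_rng(seed)
    centers = molecule.coords
    radii = molecule.radii * radius_scale
    n_atoms = len(centers)
    kept_pts = []
    kept_atom = []
    for i in range(n_atoms):
        # uniform directions on the sphere
        d = rng.standard_normal((points_per_atom, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pts = centers[i] + radii[i] * d
        buried = np.zeros(points_per_atom, dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            rj = np.linalg.norm(pts - centers[j], axis=1)
            buried |= rj < radii[j] - 1e-9
        if buried.all():
            continue
        kept_pts.append(pts[~buried])
        kept_atom.append(np.full((~buried).sum(), i))
    if not kept_pts:
        raise ValueError(
            f"molecule {molecule.id!r}: every surface point is buried")
    return SurfacePoints(np.vstack(kept_pts), molecule.id,
                         atom_index=np.concatenate(kept_atom))


def electrostatic_potential(molecule: MoleculeRecord, coords: np.ndarray
                            ) -> np.ndarray:
    """Coulomb potential with distance-dependent dielectric ε(r)=r at each
    coordinate: V = k Σ qᵢ/rᵢ² (kcal/mol per unit probe charge)."""
    coords = np.asarray(coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    diff = coords[:, None, :] - molecule.coords[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    if np.any(r < 1e-9):
        p, a = np.argwhere(r < 1e-9)[0]
        raise ValueError(
            f"point {p} coincides with atom {a} of molecule {molecule.id!r}")
    return COULOMB_K * (molecule.charges[None, :] / r ** 2).sum(axis=1)


# ---------------------------------------------------------------------------
# Kohonen map


def find_winner(som: SOMGrid, x: np.ndarray) -> int:
    """Index (row-major) of the neuron nearest to x; ties → lowest index."""
    d2 = ((som.weights - np.asarray(x, dtype=float)) ** 2).sum(axis=1)
    return int(np.argmin(d2))  # argmin returns the first minimum


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def train_som(points: SurfacePoints, rows: int, cols: int,
              winning_distance: float, epochs: int, seed: int | None = None,
              alpha: tuple[float, float] = (0.5, 0.01),
              sigma: tuple[float, float] | None = None) -> SOMGrid:
    """Train a rows×cols map on surface coordinates.

    Winner-takes-most updates: for each presented point x,
    Δw_j = α(t)·exp(−d_grid(j, winner)²/(2σ(t)²))·(x − w_j),
    with the learning rate α decaying linearly over the epochs between the
    values in ``alpha`` (default 0.5 → 0.01) and the neighbourhood width σ
    between those in ``sigma`` (default max(rows, cols)/2 → 0.5).
    Presentation order is reshuffled each epoch; weights start uniform in
    the training data's bounding box. Deterministic per seed.
    """
    if seed is None:
        raise ValueError("train_som requires an explicit integer seed")
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X = points.coords
    if len(X) == 0:
        raise ValueError("empty point set")
    rng = np.random.default_rng(seed)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    weights = rng.uniform(lo, hi, size=(rows * cols, 3))
    grid = _grid_coords(rows, cols)

    alpha0, alpha1 = alpha
    sigma0, sigma1 = sigma if sigma is not None else (max(rows, cols) / 2.0, 0.5)
    denom = max(epochs - 1, 1)
    for epoch in range(epochs):
        frac = epoch / denom if epochs > 1 else 0.0
        alpha = alpha0 + (alpha1 - alpha0) * frac
        sigma = sigma0 + (sigma1 - sigma0) * frac
        order = rng.permutation(len(X))
        g2 = 2.0 * sigma * sigma
        for idx in order:
            x = X[idx]
            w = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
            gd2 = ((grid - grid[w]) ** 2).sum(axis=1)
            h = np.exp(-gd2 / g2)
            weights += (alpha * h)[:, None] * (x - weights)
    log.info("SOM trained: %dx%d grid, %d points, %d epochs",
             rows, cols, len(X), epochs)
    return SOMGrid(rows, cols, weights, winning_distance, epochs, seed,
                   points.molecule_id)


def project(som: SOMGrid, points: SurfacePoints,
            winning_distance: float | None = None) -> FeatureMap:
    """Project valued surface points through a trained map.

    Each point goes to its winning neuron unless its Euclidean distance to
    that neuron's weight vector exceeds the winning distance (then it is
    discarded). Cell value = arithmetic mean of assigned point values;
    zero-occupancy cells are empty (NaN).
    """
    if points.values is None:
        raise ValueError("projection needs surface points with values")
    wd = som.winning_distance if winning_distance is None else winning_distance
    X = points.coords
    d2 = ((X[:, None, :] - som.weights[None, :, :]) ** 2).sum(axis=2)
    winners = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(X)), winners])
    keep = dist <= wd
    n_disc = int((~keep).sum())
    sums = np.zeros(som.n_neurons)
    counts = np.zeros(som.n_neurons, dtype=int)
    np.add.at(sums, winners[keep], points.values[keep])
    np.add.at(counts, winners[keep], 1)
    values = np.full(som.n_neurons, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    if n_disc == len(X):
        warnings.warn(
            f"all {len(X)} points of {points.molecule_id!r} discarded at "
            f"winning_distance={wd}", RuntimeWarning, stacklevel=2)
    return FeatureMap(values.reshape(som.rows, som.cols),
                      counts.reshape(som.rows, som.cols),
                      n_presented=len(X), n_discarded=n_disc)


def unfold(feature_map: FeatureMap, empty_value: float = 0.0) -> np.ndarray:
    """Row-major flattening of a feature map; empty cells → empty_value."""
    v = feature_map.values.ravel().copy()
    v[np.isnan(v)] = empty_value
    return v


# ---------------------------------------------------------------------------
# Full descriptor matrix


class CoMSAVectorizer(BaseEstimator, TransformerMixin):
    """Template-SOM surface descriptor transformer.

    ``fit(molecules)`` samples the template molecule's surface and trains
    the map on it; ``transform(molecules)`` samples each molecule's
    surface, evaluates the electrostatic potential, projects through the
    template map, and unfolds into a rows·cols descriptor row. Surface
    sampling seeds are derived deterministically from ``seed`` and each
    molecule's id, so a molecule's descriptor row does not depend on the
    composition or order of the batch.

    Parameters
    ----------
    template : str
        id of the template molecule (must be present in the fit batch).
    rows, cols : int
        Map dimensions (20×20 → 400-element rows, 50×50 → 2500).
    winning_distance : float
        Projection discard radius in Å.
    points_per_atom : int
        Surface sampling density.
    radius_scale : float
        vdW radius scaling of the sampled surface.
    epochs : int
        SOM training epochs.
    seed : int
        Master seed; required.
    """

    def __init__(self, template: str = "", rows: int = 20, cols: int = 20,
                 winning_distance: float = 2.0, points_per_atom: int = 20,
                 radius_scale: float = 1.0, epochs: int = 10,
                 seed: int | None = None, empty_value: float = 0.0):
        self.template = template
        self.rows = rows
        self.cols = cols
        self.winning_distance = winning_distance
        self.points_per_atom = points_per_atom
        self.radius_scale = radius_scale
        self.epochs = epochs
        self.seed = seed
        self.empty_value = empty_value

    def _mol_seed(self, mol_id: str) -> int:
        ss = np.random.SeedSequence([int(self.seed), _stable_id_hash(mol_id)])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    def _surface(self, mol: MoleculeRecord) -> SurfacePoints:
        pts = sample_surface(mol, self.points_per_atom, self.radius_scale,
                             seed=self._mol_seed(mol.id))
        pts.values = electrostatic_potential(mol, pts.coords)
        return pts

    def fit(self, molecules: list[MoleculeRecord], y=None):
        if self.seed is None:
            raise ValueError("CoMSAVectorizer requires an explicit integer seed")
        by_id = {m.id: m for m in molecules}
        if self.template not in by_id:
            raise ValueError(f"template {self.template!r} not among molecules")
        tpl_points = self._surface(by_id[self.template])
        self.som_ = train_som(tpl_points, self.rows, self.cols,
                              self.winning_distance, self.epochs,
                              seed=int(self.seed))
        self.template_points_ = tpl_points
        return self

    def transform(self, molecules: list[MoleculeRecord]) -> pd.DataFrame:
        if not hasattr(self, "som_"):
            raise ValueError("CoMSAVectorizer is not fitted")
        rows = {}
        occupancy = {}
        for mol in molecules:
            pts = self._surface(mol)
            fmap = project(self.som_, pts)
            rows[mol.id] = unfold(fmap, self.empty_value)
            occupancy[mol.id] = (fmap.n_presented - fmap.n_discarded,
                                 fmap.n_discarded)
        self.occupancy_report_ = pd.DataFrame(
            occupancy, index=["assigned", "discarded"]).T
        cols = [f"som_{r}_{c}" for r in range(self.rows) for c in range(self.cols)]
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _stable_id_hash(s: str) -> int:
    # FNV-1a; process-stable unlike hash()
    h = 2166136261
    for b in s.encode():
        h = ((h ^ b) * 16777619) & 0xFFFFFFFF
    return h


def comsa_matrix(template: MoleculeRecord, molecules: list[MoleculeRecord],
                 rows: int = 20, cols: int = 20, winning_distance: float = 2.0,
                 points_per_atom: int = 20, radius_scale: float = 1.0,
                 epochs: int = 10, seed: int | None = None) -> pd.DataFrame:
    """Train a template SOM and return the n_molecules × (rows·cols)
    descriptor matrix (functional wrapper over CoMSAVectorizer)."""
    pool = list(molecules)
    if all(m.id != template.id for m in pool):
        pool = [template] + pool
    vec = CoMSAVectorizer(template=template.id, rows=rows, cols=cols,
                          winning_distance=winning_distance,
                          points_per_atom=points_per_atom,
                          radius_scale=radius_scale, epochs=epochs, seed=seed)
    vec.fit(pool)
    return vec.transform(molecules)
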