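"""Synthetic datasets with planted, recoverable structure.

Three generators emulate the shapes of data this toolkit analyses:

* ``make_molecule_set`` — a congeneric series of point-charge molecules:
  every record shares a literally identical scaffold (same coordinates and
  charges, standing in for a common aligned core) plus per-molecule
  substituent atoms. Activity is a linear function of the total substituent
  charge plus Gaussian noise, so the surface electrostatics carry the
  activity signal by construction and a noise-free run is exactly
  recoverable by least squares.

* ``make_response_dataset`` — a nonnegative compounds×receptors response
  matrix over the full 120-receptor dipeptide library, clipped to the
  working range [0.001, 73.9]. Uninformative receptors respond with
  moderately right-skewed (lognormal) intensities; the small planted set of
  *informative* receptors instead discriminates the compounds across the
  whole response range (uniform over [1, 70]) — the realistic signature of
  a receptor that carries activity signal — and drives the activity
  linearly. Decanoic-gated columns receive an additive mean shift emulating
  the stronger guest-host interaction of the longer lipid chain.

* ``make_descriptor_table`` — a descriptor block with labelled pathological
  columns (constant, near-constant sd < 1e-4, missing cells) for
  exercising the pre-filter; ground truth lives in ``DataFrame.attrs``.

All generators are deterministic per seed (a seed is mandatory).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .adr import ReceptorID, enumerate_receptors
from .core import Atom, MoleculeRecord

_SCAFFOLD_ELEMENTS = ("C", "N", "C", "O", "C")  # cycled; organic mix
_SUBST_ELEMENTS = ("C", "O", "N", "H", "Cl", "S")


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the congeneric molecule generator.

    The defaults mirror the modelling scenario this package targets: 20
    analogues sharing a 15-atom aligned core, a handful of substituent
    atoms carrying the activity-determining charge, and mild activity
    noise.
    """

    n_molecules: int = 20
    n_scaffold_atoms: int = 15
    n_substituent_atoms: int = 5
    charge_scale: float = 0.2      # e; sd of generated partial charges
    noise_sd: float = 0.05         # activity noise
    activity_intercept: float = 50.0
    activity_slope: float = -30.0  # per unit total substituent charge
    seed: int = 0

    def __post_init__(self):
        if min(self.n_molecules, self.n_scaffold_atoms,
               self.n_substituent_atoms) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_molecule_set(spec: SyntheticSpec) -> list[MoleculeRecord]:
    """Generate the congeneric series described by ``spec``.

    All molecules share the first ``n_scaffold_atoms`` atoms verbatim;
    activity = intercept + slope·(total substituent charge) + N(0, noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    # scaffold: a kinked chain with ~1.5 Å steps, fixed for the whole set
    steps = rng.normal(0.0, 1.0, size=(spec.n_scaffold_atoms, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    steps *= 1.5
    scaffold_xyz = np.cumsum(steps, axis=0)
    scaffold_q = rng.normal(0.0, spec.charge_scale, size=spec.n_scaffold_atoms)
    scaffold = [
        Atom(_SCAFFOLD_ELEMENTS[i % len(_SCAFFOLD_ELEMENTS)],
             *scaffold_xyz[i], round(float(scaffold_q[i]), 6))
        for i in range(spec.n_scaffold_atoms)
    ]
    anchor = scaffold_xyz[-1]
    records = []
    for m in range(spec.n_molecules):
        subst = []
        total_q = 0.0
        for k in range(spec.n_substituent_atoms):
            direction = rng.normal(0.0, 1.0, size=3)
            direction /= np.linalg.norm(direction)
            dist = 1.2 + 2.0 * rng.random()
            pos = anchor + direction * dist * (1 + 0.3 * k)
            q = round(float(rng.normal(0.0, spec.charge_scale)), 6)
            el = _SUBST_ELEMENTS[int(rng.integers(len(_SUBST_ELEMENTS)))]
            subst.append(Atom(el, *pos, q))
            total_q += q
        activity = (spec.activity_intercept
                    + spec.activity_slope * total_q
                    + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0))
        records.append(MoleculeRecord(f"mol{m + 1:02d}", scaffold + subst,
                                      float(activity)))
    return records


@dataclasses.dataclass
class ResponseTruth:
    """Planted ground truth of the receptor-response generator.

    ``coefficients`` maps informative receptor ids (string form, e.g.
    "D-EP") to signed activity effects per response unit. The defaults
    plant three Pro-linker receptors with equal-magnitude effects well
    clear of the activity noise and keep the generated activities strictly
    positive (|Σ negative effects|·informative_high < intercept), so
    IC50-style log transforms are always defined and the activities span
    all four potency classes.
    """

    coefficients: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"D-EP": -0.5, "D-QP": 0.5, "H-CP": -0.5})
    noise_sd: float = 0.1
    clip_range: tuple[float, float] = (0.001, 73.9)
    decanoic_shift: float = 4.0   # additive mean shift of D-gated columns
    activity_intercept: float = 75.0
    base_log_mean: float = 2.2    # lognormal parameters of uninformative
    base_log_sigma: float = 0.9   # responses
    informative_range: tuple[float, float] = (1.0, 70.0)

    @property
    def informative_receptors(self) -> set[str]:
        return set(self.coefficients)

    def __post_init__(self):
        lo, hi = self.clip_range
        if not lo < hi:
            raise ValueError("clip_range low must be below high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for rid in self.coefficients:
            ReceptorID.parse(rid)  # validates codes


def make_response_dataset(n_compounds: int, truth: ResponseTruth,
                          seed: int | None = None
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Generate (response matrix, activities).

    Uninformative responses are lognormal per cell with decanoic columns
    shifted up by ``truth.decanoic_shift``; informative columns are
    uniform over ``truth.informative_range`` (a strongly discriminating
    receptor). Everything is clipped to ``truth.clip_range`` (clipping,
    not rejection). Activity is a linear combination of the *clipped*
    informative columns plus N(0, noise_sd), so the planted model is
    exactly recoverable at noise_sd = 0.
    """
    if seed is None:
        raise ValueError("make_response_dataset requires an explicit integer seed")
    receptors = enumerate_receptors()
    ids = [str(r) for r in receptors]
    missing = truth.informative_receptors.difference(ids)
    if missing:
        raise ValueError(f"informative receptors not in the library: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    lo, hi = truth.clip_range
    R = rng.lognormal(mean=truth.base_log_mean, sigma=truth.base_log_sigma,
                      size=(n_compounds, len(ids)))
    d_cols = np.array([r.gating_acid == "D" for r in receptors])
    R[:, d_cols] += truth.decanoic_shift
    for rid in sorted(truth.coefficients):
        R[:, ids.index(rid)] = rng.uniform(*truth.informative_range,
                                           size=n_compounds)
    R = np.clip(R, lo, hi)
    matrix = pd.DataFrame(R, index=[f"cmp{i + 1:02d}" for i in range(n_compounds)],
                          columns=ids)
    activity = np.full(n_compounds, truth.activity_intercept)
    for rid, coef in truth.coefficients.items():
        activity = activity + coef * matrix[rid].to_numpy()
    if truth.noise_sd > 0:
        activity = activity + rng.normal(0.0, truth.noise_sd, size=n_compounds)
    return matrix, pd.Series(activity, index=matrix.index, name="activity")


def make_descriptor_table(n_rows: int, n_informative: int, n_noise: int,
                          n_constant: int, n_near_constant: int,
                          n_missing: int, seed: int | None = None
                          ) -> pd.DataFrame:
    """Descriptor table with exactly the requested pathological columns.

    Informative columns correlate with a latent response stored in
    ``attrs["latent_y"]``; ``attrs["truth"]`` maps each column kind to its
    column ids. Near-constant columns have sample sd < 1e-4; missing
    columns contain 1–3 NaN cells (and are otherwise well-varying).
    """
    if seed is None:
        raise ValueError("make_descriptor_table requires an explicit integer seed")
    if min(n_rows, 1) < 1 or min(n_informative, n_noise, n_constant,
                                 n_near_constant, n_missing) < 0:
        raise ValueError("counts must be >= 0 (n_rows >= 1)")
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, 1.0, size=n_rows)
    cols: dict[str, np.ndarray] = {}
    truth: dict[str, list[str]] = {"informative": [], "noise": [],
                                   "constant": [], "near_constant": [],
                                   "missing": []}
    for j in range(n_informative):
        name = f"inf_{j}"
        cols[name] = y * rng.uniform(0.5, 2.0) + rng.normal(0, 0.1, n_rows)
        truth["informative"].append(name)
    for j in range(n_noise):
        name = f"noise_{j}"
        cols[name] = rng.normal(0.0, 1.0, n_rows)
        truth["noise"].append(name)
    for j in range(n_constant):
        name = f"const_{j}"
        # dyadic value so the column mean is exact and the sd exactly zero
        cols[name] = np.full(n_rows, float(rng.integers(-40, 40)) / 8.0)
        truth["constant"].append(name)
    for j in range(n_near_constant):
        name = f"nearconst_{j}"
        cols[name] = rng.uniform(-5, 5) + rng.normal(0.0, 2e-5, n_rows)
        truth["near_constant"].append(name)
    for j in range(n_missing):
        name = f"miss_{j}"
        v = rng.normal(0.0, 1.0, n_rows)
        k = int(rng.integers(1, min(3, n_rows) + 1))
        v[rng.choice(n_rows, size=k, replace=False)] = np.nan
        cols[name] = v
        truth["missing"].append(name)
    df = pd.DataFrame(cols, index=[f"obj{i + 1:02d}" for i in range(n_rows)])
    df.attrs["truth"] = truth
    df.attrs["latent_y"] = y
    return df
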