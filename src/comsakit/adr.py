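"""Artificial dipeptide receptor (ADR) library analysis.

The library is the full 2×20×3 combinatorial design: a gating fatty acid
(H = heptanoic or D = decanoic), one of the 20 proteinogenic residues
attached to the gating acid (X), and one of {Ala, Phe, Pro} bonded to the
linker scaffold (Y) — 120 receptors, written "<acid>-<X><Y>" (e.g. D-EP).

Analyses over a compounds×receptors response matrix: the indicator
displacement intensity I_D = I_Drd − I_Da; IC50 activity-class labels
(hA < 25 ≤ A < 50 ≤ IN < 100 ≤ hIN, half-open intervals); the fraction of
responses above a threshold per gating-acid group; Pearson correlation of
transformed activity against each receptor column and against per-group
mean responses; and building-block selection profiles (with enrichment
against the uniform library background) for receptor sets picked by
IVE-PLS.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

AA_CODES = tuple("ACDEFGHIKLMNPQRSTVWY")   # alphabetical one-letter codes
GATING_ACIDS = ("H", "D")                   # heptanoic, decanoic
LINKER_RESIDUES = ("A", "F", "P")

ACTIVITY_CLASSES = ("hA", "A", "IN", "hIN")
_CLASS_EDGES = (25.0, 50.0, 100.0)


@dataclasses.dataclass(frozen=True, order=True)
class ReceptorID:
    """One receptor: gating acid, residue on the acid, residue on the linker."""

    gating_acid: str
    aa_acid: str
    aa_linker: str

    def __post_init__(self):
        if self.gating_acid not in GATING_ACIDS:
            raise ValueError(f"gating acid must be H or D, got {self.gating_acid!r}")
        if self.aa_acid not in AA_CODES:
            raise ValueError(f"unknown residue code {self.aa_acid!r}")
        if self.aa_linker not in LINKER_RESIDUES:
            raise ValueError(
                f"linker residue must be one of {LINKER_RESIDUES}, got "
                f"{self.aa_linker!r}")

    def __str__(self) -> str:
        return f"{self.gating_acid}-{self.aa_acid}{self.aa_linker}"

    @classmethod
    def parse(cls, s: str) -> "ReceptorID":
        try:
            acid, rest = s.split("-")
            aa_acid, aa_linker = rest[0], rest[1]
            if len(rest) != 2:
                raise ValueError
        except (ValueError, IndexError):
            raise ValueError(f"unparseable receptor id {s!r}; expected "
                             "'<H|D>-<XY>'") from None
        return cls(acid, aa_acid, aa_linker)


def enumerate_receptors(acids=GATING_ACIDS, linker_set=LINKER_RESIDUES
                        ) -> list[ReceptorID]:
    """Cartesian product of the design, ordered by (acid as given,
    acid-residue alphabetical, linker residue alphabetical)."""
    if not acids or not linker_set:
        raise ValueError("acid and linker sets must be non-empty")
    return [ReceptorID(acid, aa, y)
            for acid in acids
            for aa in sorted(AA_CODES)
            for y in sorted(linker_set)]


def displacement_intensity(i_drd, i_da):
    """Indicator displacement intensity I_D = I_Drd − I_Da on the 256-level
    gray scale. Returns (I_D, negative_flag); negatives are kept, flagged."""
    i_drd = np.asarray(i_drd, dtype=float)
    i_da = np.asarray(i_da, dtype=float)
    diff = i_drd - i_da
    flag = diff < 0
    if diff.ndim == 0:
        return float(diff), bool(flag)
    return diff, flag


def classify_activity(ic50: float) -> str:
    """Activity class by half-open IC50 intervals: [0,25) hA, [25,50) A,
    [50,100) IN, [100,∞) hIN."""
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    for label, edge in zip(ACTIVITY_CLASSES, _CLASS_EDGES):
        if ic50 < edge:
            return label
    return "hIN"


def _gating_groups(columns) -> pd.Series:
    return pd.Series({c: ReceptorID.parse(str(c)).gating_acid for c in columns})


def response_fraction_above(matrix: pd.DataFrame, threshold: float = 50.0
                            ) -> pd.Series:
    """Per-gating-acid fraction of response cells strictly above
    ``threshold``. Column ids must parse as receptor ids."""
    groups = _gating_groups(matrix.columns)
    out = {}
    for acid in GATING_ACIDS:
        cols = groups.index[groups == acid]
        if len(cols) == 0:
            continue
        block = matrix[cols].to_numpy(float)
        out[acid] = float((block > threshold).mean())
    return pd.Series(out, name=f"fraction_above_{threshold:g}")


def transform_activity(ic50, transform: str = "pic50") -> np.ndarray:
    """Activity transform: ``pic50`` = −log10(IC50) (the field's standard),
    or ``literal`` = log10(IC50) (reading "−log(1/activity)" exactly as an
    algebraic expression; it is the negation of pIC50)."""
    a = np.asarray(ic50, dtype=float)
    if np.any(a <= 0):
        raise ValueError("activities must be positive for the log transform")
    if transform == "pic50":
        return -np.log10(a)
    if transform == "literal":
        return np.log10(a)
    raise ValueError(f"unknown transform {transform!r}")


def receptor_activity_correlation(matrix: pd.DataFrame, activities: pd.Series,
                                  subset: str = "active_only",
                                  transform: str = "pic50"
                                  ) -> tuple[pd.Series, pd.Series]:
    """Pearson r of transformed activity vs each receptor column and vs the
    per-gating-acid mean response.

    ``subset``: ``"active_only"`` restricts to compounds in classes hA/A
    (IC50 < 50); ``"all"`` uses every compound. Requires ≥3 compounds in
    the subset. Returns (per-receptor r, per-gating-acid mean-response r).
    """
    activities = activities.loc[matrix.index]
    if subset == "active_only":
        mask = np.array([classify_activity(v) in ("hA", "A") for v in activities])
    elif subset == "all":
        mask = np.ones(len(activities), dtype=bool)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if mask.sum() < 3:
        raise ValueError(
            f"correlation subset has {int(mask.sum())} compounds; need >= 3")
    sub = matrix.loc[mask]
    y = transform_activity(activities[mask].to_numpy(), transform)
    per_receptor = {}
    for col in sub.columns:
        x = sub[col].to_numpy(float)
        if np.std(x) < 1e-12 or np.std(y) < 1e-12:
            per_receptor[col] = np.nan
        else:
            per_receptor[col] = float(stats.pearsonr(x, y).statistic)
    groups = _gating_groups(matrix.columns)
    per_group = {}
    for acid in GATING_ACIDS:
        cols = groups.index[groups == acid]
        if len(cols) == 0:
            continue
        mean_resp = sub[cols].mean(axis=1).to_numpy()
        if np.std(mean_resp) < 1e-12:
            per_group[acid] = np.nan
        else:
            per_group[acid] = float(stats.pearsonr(mean_resp, y).statistic)
    return (pd.Series(per_receptor, name="r"),
            pd.Series(per_group, name="mean_response_r"))


def residue_selection_profile(selected: list[ReceptorID | str],
                              library: list[ReceptorID] | None = None
                              ) -> dict[str, pd.DataFrame]:
    """Building-block composition of a selected receptor set.

    For each of the three design positions (gating acid, acid residue,
    linker residue) returns counts, fractions among the selection, and
    enrichment = selected fraction / library-background fraction.
    """
    if not selected:
        raise ValueError("selection is empty")
    sel = [r if isinstance(r, ReceptorID) else ReceptorID.parse(r)
           for r in selected]
    lib = library if library is not None else enumerate_receptors()
    out = {}
    for name, attr in (("gating_acid", "gating_acid"),
                       ("aa_acid", "aa_acid"),
                       ("aa_linker", "aa_linker")):
        sel_counts = pd.Series([getattr(r, attr) for r in sel]).value_counts()
        lib_counts = pd.Series([getattr(r, attr) for r in lib]).value_counts()
        idx = lib_counts.index
        counts = sel_counts.reindex(idx, fill_value=0)
        frac = counts / len(sel)
        background = lib_counts / len(lib)
        out[name] = pd.DataFrame({
            "count": counts.astype(int),
            "fraction": frac,
            "enrichment": frac / background,
        }).sort_values(["count", "fraction"], ascending=False)
    return out


def binds_all_filter(matrix: pd.DataFrame) -> list[str]:
    """Receptor columns whose displacement response is positive for every
    compound ("binds all compounds" filter)."""
    keep = (matrix > 0).all(axis=0)
    cols = list(matrix.columns[keep])
    if not cols:
        warnings.warn("no receptor binds every compound", RuntimeWarning,
                      stacklevel=2)
    return cols
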