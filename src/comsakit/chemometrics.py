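"""PLS regression, cross-validation statistics, iterative variable
elimination (IVE-PLS), PCA, and descriptor pre-filtering.

The regression model is ordinary univariate-response PLS,

    y = X b + e,

fit by NIPALS on column-centred X and centred y. Model complexity is chosen
by leave-one-out cross-validation: for a candidate number of latent
components *a*,

    q²(a) = 1 − Σᵢ (obsᵢ − predᵢ)² / Σᵢ (obsᵢ − mean(obs))²,

where predᵢ comes from the model fit without object *i* and the mean is
taken over the full observed vector. External predictions are scored by

    SDEP = sqrt( Σ (pred − obs)² / n )      and
    q²test = 1 − SS_res / SS_tot,   SS_tot about the test-set mean.

IVE-PLS removes, one at a time, the column whose regression coefficient is
least stable across the LOO submodels — lowest |mean(b_j)| / std(b_j) — and
keeps the column set at which the cross-validated q² peaks. The component
count is re-estimated after every elimination and is capped at 7, the usual
small-n QSAR limit.

The NIPALS core here is deliberately lightweight: model validation over all
C(20,6) = 38,760 train/test partitions performs hundreds of thousands of
tiny PLS fits, so the inner loop is a few dense numpy products with a
*nested* coefficient sequence (one fit yields b for every truncation
a = 1..A). Equivalence with scikit-learn's PLSRegression and with the OLS
closed form at full rank is enforced by the test suite.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

log = logging.getLogger("comsakit")

MAX_COMPONENTS = 7  # hard cap on PLS latent components for small-n QSAR

_EPS = 1e-12


# ---------------------------------------------------------------------------
# NIPALS core


def _nipals_coefs(Xc: np.ndarray, yc: np.ndarray, a_max: int) -> np.ndarray:
    """Nested PLS coefficient matrix for centred data.

    Returns ``B`` of shape (p, A) where column a-1 is the coefficient
    vector of the a-component model; A ≤ a_max (smaller when X runs out of
    rank, in which case trailing columns repeat the last achievable model).
    """
    n, p = Xc.shape
    a_max = max(1, min(a_max, n - 1, p))
    W = np.empty((p, a_max))
    P = np.empty((p, a_max))
    q = np.empty(a_max)
    Xk = Xc.copy()
    yk = yc.copy()
    a_done = 0
    for a in range(a_max):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = Xk @ w
        tt = t @ t
        if tt < _EPS:
            break
        p_load = (Xk.T @ t) / tt
        q_a = (yk @ t) / tt
        Xk -= np.outer(t, p_load)
        yk = yk - q_a * t
        W[:, a] = w
        P[:, a] = p_load
        q[a] = q_a
        a_done += 1
    B = np.zeros((p, a_max))
    if a_done == 0:
        return B  # y orthogonal to X: all-zero coefficients
    for a in range(1, a_done + 1):
        # b_a = W_a (P_aᵀ W_a)⁻¹ q_a ; P_aᵀW_a is upper triangular
        M = P[:, :a].T @ W[:, :a]
        B[:, a - 1] = W[:, :a] @ np.linalg.solve(M, q[:a])
    for a in range(a_done, a_max):
        B[:, a] = B[:, a_done - 1]
    return B


@dataclasses.dataclass
class PLSModel:
    """Fitted PLS regression: ``predict(X) = (X - x_mean) @ b + y_mean``."""

    b: np.ndarray
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    column_ids: list[str] | None = None

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.b)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.b + self.y_mean


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        cols = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        cols = None
    yv = np.asarray(y, dtype=float).ravel()
    if Xv.ndim != 2 or Xv.shape[0] != yv.shape[0]:
        raise ValueError(f"incompatible shapes X {Xv.shape}, y {yv.shape}")
    if np.isnan(Xv).any():
        raise ValueError("X contains missing values; prefilter first")
    return Xv, yv, cols


def fit_pls(X, y, n_components: int) -> PLSModel:
    """Fit a PLS model with ``n_components`` latent components.

    If X runs out of rank before the requested number of components, the
    achievable model is returned with a warning.
    """
    Xv, yv, cols = _as_xy(X, y)
    n, p = Xv.shape
    if not (1 <= n_components <= min(n - 1, p, MAX_COMPONENTS)):
        raise ValueError(
            f"n_components={n_components} outside 1..min(n-1={n-1}, p={p}, "
            f"{MAX_COMPONENTS})")
    x_mean = Xv.mean(axis=0)
    y_mean = float(yv.mean())
    B = _nipals_coefs(Xv - x_mean, yv - y_mean, n_components)
    achieved = _achieved_components(B, n_components)
    if achieved < n_components:
        warnings.warn(
            f"rank-deficient X: fit with {achieved} components instead of "
            f"{n_components}", RuntimeWarning, stacklevel=2)
    return PLSModel(B[:, n_components - 1], achieved, x_mean, y_mean, cols)


def _achieved_components(B: np.ndarray, requested: int) -> int:
    a = requested
    while a > 1 and np.array_equal(B[:, a - 1], B[:, a - 2]):
        a -= 1
    return a


# ---------------------------------------------------------------------------
# Cross-validation statistics


@dataclasses.dataclass
class CVResult:
    """Leave-one-out cross-validation summary."""

    q2: float
    optimal_components: int
    predictions: np.ndarray          # LOO predictions at optimal_components
    q2_per_components: np.ndarray    # q² for a = 1..A


def _loo_fold_coefs(Xv: np.ndarray, yv: np.ndarray, a_max: int):
    """Per-fold nested coefficients and fold means for LOO.

    Yields (i, B, x_mean, y_mean) for each left-out row i.
    """
    n = Xv.shape[0]
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt = Xv[mask]
        yt = yv[mask]
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        B = _nipals_coefs(Xt - x_mean, yt - y_mean, a_max)
        yield i, B, x_mean, y_mean


def loo_q2(X, y, max_components: int = MAX_COMPONENTS) -> CVResult:
    """Leave-one-out q² over component counts 1..max_components.

    The optimal component count is the smallest one attaining the maximum
    q². Requires n ≥ 3 and non-constant y.
    """
    Xv, yv, _ = _as_xy(X, y)
    n, p = Xv.shape
    if n < 3:
        raise ValueError(f"LOO cross-validation needs n >= 3, got {n}")
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    if ss_tot < _EPS:
        raise ValueError("y has zero variance; q2 undefined")
    a_max = max(1, min(max_components, n - 2, p, MAX_COMPONENTS))
    preds = np.empty((n, a_max))
    for i, B, x_mean, y_mean in _loo_fold_coefs(Xv, yv, a_max):
        preds[i] = (Xv[i] - x_mean) @ B + y_mean
    ss_res = ((yv[:, None] - preds) ** 2).sum(axis=0)
    q2s = 1.0 - ss_res / ss_tot
    a_opt = int(np.argmax(q2s)) + 1  # argmax returns first (smallest) max
    return CVResult(float(q2s[a_opt - 1]), a_opt, preds[:, a_opt - 1], q2s)


def sdep(obs, pred) -> float:
    """Standard deviation of the error of prediction: sqrt(Σ(pred−obs)²/n)."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: obs {obs.shape} vs pred {pred.shape}")
    if obs.size < 1:
        raise ValueError("sdep needs at least one observation")
    return float(np.sqrt(((pred - obs) ** 2).mean()))


def q2_external(obs_test, pred_test) -> float:
    """External q²: 1 − SS_res/SS_tot with SS_tot about the test-set mean."""
    obs = np.asarray(obs_test, dtype=float).ravel()
    pred = np.asarray(pred_test, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("length mismatch between obs and pred")
    if obs.size < 2:
        raise ValueError("external q2 needs at least 2 test objects")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot < _EPS:
        raise ValueError("test observations have zero variance; q2test undefined")
    return float(1.0 - ((obs - pred) ** 2).sum() / ss_tot)


# ---------------------------------------------------------------------------
# Coefficient stability and IVE-PLS


def column_stability(X, y, n_components: int) -> np.ndarray:
    """Per-column coefficient stability |mean(b_j)| / std(b_j) over LOO folds.

    std uses the n−1 denominator. A column whose coefficient is numerically
    constant across folds (std < 1e-12) is perfectly stable (+inf) unless
    its mean is also ~0, in which case the stability is 0 (an all-zero
    coefficient carries no information).
    """
    Xv, yv, _ = _as_xy(X, y)
    n, p = Xv.shape
    if n < 3:
        raise ValueError("column stability needs n >= 3")
    bs = np.empty((n, p))
    for i, B, _, _ in _loo_fold_coefs(Xv, yv, n_components):
        bs[i] = B[:, min(n_components, B.shape[1]) - 1]
    return _stability_from_coefs(bs)


def _stability_from_coefs(bs: np.ndarray) -> np.ndarray:
    mean = bs.mean(axis=0)
    std = bs.std(axis=0, ddof=1)
    stab = np.empty(bs.shape[1])
    degenerate = std < _EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        stab = np.abs(mean) / std
    stab[degenerate & (np.abs(mean) >= _EPS)] = np.inf
    stab[degenerate & (np.abs(mean) < _EPS)] = 0.0
    return stab


@dataclasses.dataclass
class IVERecord:
    iteration: int
    dropped: str | None
    stability: float | None
    q2: float
    n_components: int


@dataclasses.dataclass
class IVETrace:
    """Full elimination trace.

    ``records[0]`` is the no-elimination baseline; each later record drops
    exactly one column. ``best_iteration`` indexes the record with maximal
    q² (earliest on ties); ``selected_columns`` is the surviving column set
    there.
    """

    records: list[IVERecord]
    best_iteration: int
    selected_columns: list[str]

    @property
    def best_q2(self) -> float:
        return self.records[self.best_iteration].q2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records]
                            ).set_index("iteration")


def _loo_eval(Xv, yv, max_components):
    """One pass of LOO fits: (q2 at optimum, a_opt, per-fold nested
    coefficient cube n × p × a_max).

    Shares the fold fits between the q² estimate and the stability score so
    each IVE iteration costs a single LOO sweep.
    """
    n, p = Xv.shape
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    if ss_tot < _EPS:
        raise ValueError("y has zero variance")
    a_max = max(1, min(max_components, n - 2, p, MAX_COMPONENTS))
    preds = np.empty((n, a_max))
    folds = np.empty((n, p, a_max))
    for i, B, x_mean, y_mean in _loo_fold_coefs(Xv, yv, a_max):
        preds[i] = (Xv[i] - x_mean) @ B + y_mean
        folds[i] = B
    q2s = 1.0 - ((yv[:, None] - preds) ** 2).sum(axis=0) / ss_tot
    a_opt = int(np.argmax(q2s)) + 1
    return float(q2s[a_opt - 1]), a_opt, folds


def ive_pls(X, y, max_components: int = MAX_COMPONENTS,
            min_columns: int = 2, stability_components: str = "max",
            ensemble: str = "loo", seed: int | None = None) -> IVETrace:
    """Iterative variable elimination by coefficient stability.

    Repeats: LOO-cross-validate the current matrix, drop the single column
    with the lowest stability |mean(b_j)/std(b_j)| (ties → lower column
    index), until ``min_columns`` remain. The q² component count is
    re-estimated at every iteration; the stability score is computed from
    the submodel coefficients at the *capped* component count
    (``stability_components="max"``, the UVE convention — early in the
    elimination the cross-validated optimum is an unreliable basis) or at
    the per-iteration optimum (``"optimal"``). ``ensemble`` selects the
    submodel ensemble: ``"loo"`` (deterministic, default) or
    ``"bootstrap:k"`` (k resampled models, requires ``seed``). Returns the
    full trace; the selected column set is the one at the global q²
    maximum (earliest iteration on ties).
    """
    Xv, yv, cols = _as_xy(X, y)
    n, p = Xv.shape
    if cols is None:
        cols = [str(j) for j in range(p)]
    if p <= min_columns:
        raise ValueError(f"need more than min_columns={min_columns} columns, got {p}")
    if stability_components not in ("max", "optimal"):
        raise ValueError("stability_components must be 'max' or 'optimal'")
    k_boot = 0
    if ensemble != "loo":
        kind, _, k = ensemble.partition(":")
        if kind != "bootstrap" or not k.isdigit():
            raise ValueError(f"ensemble must be 'loo' or 'bootstrap:k', got {ensemble!r}")
        k_boot = int(k)
        if seed is None:
            raise ValueError("bootstrap ensemble requires an explicit integer seed")
    rng = np.random.default_rng(seed) if k_boot else None

    def _stability(Xc, folds, a_opt):
        a_sel = folds.shape[2] if stability_components == "max" else a_opt
        if k_boot:
            bs = np.empty((k_boot, Xc.shape[1]))
            a_max = folds.shape[2]
            for b_i in range(k_boot):
                idx = rng.integers(0, n, n)
                Xb, yb = Xc[idx], yv[idx]
                B = _nipals_coefs(Xb - Xb.mean(axis=0), yb - yb.mean(), a_max)
                bs[b_i] = B[:, min(a_sel, B.shape[1]) - 1]
            return _stability_from_coefs(bs)
        return _stability_from_coefs(folds[:, :, a_sel - 1])

    active = list(range(p))
    q2, a_opt, folds = _loo_eval(Xv, yv, max_components)
    records = [IVERecord(0, None, None, q2, a_opt)]
    while len(active) > min_columns:
        Xcur = Xv[:, active]
        stab = _stability(Xcur, folds, a_opt)
        j_local = int(np.argmin(stab))  # argmin takes the first (lowest index)
        dropped = cols[active[j_local]]
        stab_dropped = float(stab[j_local])
        del active[j_local]
        Xcur = Xv[:, active]
        q2, a_opt, folds = _loo_eval(Xcur, yv, max_components)
        records.append(IVERecord(len(records), dropped, stab_dropped, q2, a_opt))
    q2_seq = np.array([r.q2 for r in records])
    best = int(np.argmax(q2_seq))
    dropped_upto = {r.dropped for r in records[1:best + 1]}
    selected = [c for c in cols if c not in dropped_upto]
    log.info("IVE-PLS: %d -> %d columns, best q2=%.4f at iteration %d",
             p, len(selected), q2_seq[best], best)
    return IVETrace(records, best, selected)


# ---------------------------------------------------------------------------
# Descriptor pre-filter


def prefilter_columns(matrix: pd.DataFrame, sd_tol: float = 1e-4
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove constant/near-constant (sd < sd_tol, n−1 denominator) columns
    and columns with any missing value.

    Returns (filtered matrix, removal report) where the report lists each
    removed column id with its reason.
    """
    removed = []
    keep = []
    for col in matrix.columns:
        v = matrix[col]
        if v.isna().any():
            removed.append({"column": col, "reason": "missing"})
        elif float(v.std(ddof=1)) < sd_tol or len(v) == 1:
            removed.append({"column": col, "reason": "constant/near-constant"})
        else:
            keep.append(col)
    if not keep:
        raise ValueError("prefilter removed every column; nothing to model")
    report = pd.DataFrame(removed, columns=["column", "reason"])
    return matrix[keep], report


# ---------------------------------------------------------------------------
# PCA


@dataclasses.dataclass
class PCAResult:
    """Scores T, loadings P (columns = components), explained variance
    fractions, and the preprocessing mode, for X ≈ T Pᵀ + mean."""

    scores: np.ndarray
    loadings: np.ndarray
    explained: np.ndarray
    mode: str
    mean: np.ndarray
    scale: np.ndarray | None
    row_ids: list[str] | None = None
    col_ids: list[str] | None = None


def pca_decompose(matrix, mode: str = "center",
                  n_components: int | None = None) -> PCAResult:
    """SVD-based principal component analysis.

    ``mode`` is ``"center"`` (column-centred) or ``"autoscale"`` (centred
    and divided by column sd; zero-variance columns are an error — run
    ``prefilter_columns`` first). Sign convention: in each loading vector
    the entry of largest magnitude is positive.
    """
    if isinstance(matrix, pd.DataFrame):
        row_ids = [str(i) for i in matrix.index]
        col_ids = [str(c) for c in matrix.columns]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        row_ids = col_ids = None
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values; prefilter first")
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    scale = None
    if mode == "autoscale":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd < _EPS):
            raise ValueError(
                "zero-variance column under autoscale; apply prefilter_columns")
        scale = sd
        Xc = Xc / sd
    elif mode != "center":
        raise ValueError(f"unknown PCA mode {mode!r}")
    k_full = min(n, p)
    k = k_full if n_components is None else min(n_components, k_full)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s ** 2).sum())
    explained = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    T = U[:, :k] * s[:k]
    P = Vt[:k].T
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(P[:, j])))
        if P[i_max, j] < 0:
            P[:, j] = -P[:, j]
            T[:, j] = -T[:, j]
    return PCAResult(T, P, explained, mode, mean, scale, row_ids, col_ids)


# ---------------------------------------------------------------------------
# Estimator classes


class PLSQSAR(BaseEstimator, RegressorMixin):
    """scikit-learn style wrapper around the package PLS core.

    Parameters
    ----------
    n_components : int, default 2
        Latent components (capped at 7).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        model = fit_pls(X, y, self.n_components)
        self.model_ = model
        self.coef_ = model.b
        self.intercept_ = model.intercept
        self.n_components_ = model.n_components
        self.n_features_in_ = model.b.shape[0]
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise ValueError("PLSQSAR is not fitted")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return self.model_.predict(X)


class IVEPLS(BaseEstimator, RegressorMixin):
    """Iterative variable elimination PLS as an estimator.

    After ``fit``, ``selected_columns_`` holds the surviving column ids,
    ``trace_`` the full elimination trace, and ``model_`` a PLS model refit
    on the selected columns at the cross-validated optimal component count.
    """

    def __init__(self, max_components: int = MAX_COMPONENTS, min_columns: int = 2):
        self.max_components = max_components
        self.min_columns = min_columns

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
        self.trace_ = ive_pls(X, y, self.max_components, self.min_columns)
        self.selected_columns_ = list(self.trace_.selected_columns)
        self.best_q2_ = self.trace_.best_q2
        Xsel = X[self.selected_columns_]
        a = self.trace_.records[self.trace_.best_iteration].n_components
        self.model_ = fit_pls(Xsel, y, a)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise ValueError("IVEPLS is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
        return self.model_.predict(X[self.selected_columns_].to_numpy(float))


class ColumnPrefilter(BaseEstimator):
    """Transformer applying the sd < 1e-4 / missing-value column filter."""

    def __init__(self, sd_tol: float = 1e-4):
        self.sd_tol = sd_tol

    def fit(self, X, y=None):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        filtered, report = prefilter_columns(X, self.sd_tol)
        self.columns_ = list(filtered.columns)
        self.report_ = report
        return self

    def transform(self, X):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        return X[self.columns_]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
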