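"""Stochastic model validation: statistics over train/test partitions.

For a small congeneric series the train/test division is itself a modelling
decision. This module enumerates (or samples) k-test-compound partitions of
the dataset, fits a PLS model on each training block with LOO-chosen
complexity, scores the held-out block (external q², SDEP), and summarizes
how often each compound lands in the test set of the *good* models
(cross-validated q² above a threshold, 0.75 by default) — compounds
over-represented there are the ones whose exclusion from training makes
models look good, i.e. the ones that disrupt modelling.

Deterministic splitters are also provided: Kennard–Stone maximin selection
on the dependent variable, and a ranked cyclic split (sort by activity,
assign 2 to train / 1 to test along the ranking).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd

from .chemometrics import MAX_COMPONENTS, fit_pls, loo_q2, q2_external, sdep

log = logging.getLogger("comsakit")

DEFAULT_K_TEST = 6          # 14/6 split of a 20-compound series (2:1)
DEFAULT_Q2_THRESHOLD = 0.75
EXHAUSTIVE_CEILING = 100_000


@dataclasses.dataclass(frozen=True)
class Partition:
    train: tuple[str, ...]
    test: tuple[str, ...]

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise ValueError("train and test sets overlap")


@dataclasses.dataclass
class SMVResult:
    """Per-partition records plus run settings.

    ``records`` columns: train_ids, test_ids (';'-joined), q2cv,
    n_components, q2test (NaN when the test block has no activity
    variance), sdep.
    """

    records: pd.DataFrame
    mode: str
    seed: int | None
    k_test: int


def enumerate_partitions(ids: list[str], k_test: int):
    """All C(n, k_test) partitions, test subsets in lexicographic order of
    sorted id indices. Yields ``Partition`` objects lazily."""
    n = len(ids)
    if not 0 < k_test < n:
        raise ValueError(f"k_test must be in 1..{n - 1}, got {k_test}")
    idx = range(n)
    for test_idx in itertools.combinations(idx, k_test):
        test = set(test_idx)
        yield Partition(tuple(ids[i] for i in idx if i not in test),
                        tuple(ids[i] for i in test_idx))


def n_partitions(n: int, k_test: int) -> int:
    return math.comb(n, k_test)


def _sampled_partitions(ids: list[str], k_test: int, n_samples: int, seed: int):
    n = len(ids)
    total = math.comb(n, k_test)
    if n_samples > total:
        raise ValueError(f"cannot draw {n_samples} distinct partitions from {total}")
    rng = np.random.default_rng(seed)
    seen = set()
    out = []
    while len(out) < n_samples:
        pick = tuple(sorted(rng.choice(n, size=k_test, replace=False).tolist()))
        if pick in seen:
            continue
        seen.add(pick)
        test = set(pick)
        out.append(Partition(tuple(ids[i] for i in range(n) if i not in test),
                             tuple(ids[i] for i in pick)))
    return out


def run_smv(X: pd.DataFrame, y: pd.Series, k_test: int = DEFAULT_K_TEST,
            max_components: int = MAX_COMPONENTS, mode: str = "exhaustive",
            n_samples: int | None = None, seed: int | None = None) -> SMVResult:
    """Fit and score a PLS model on every (or a sampled set of) train/test
    partitions.

    Per partition: LOO q² on the training block selects the component
    count; the refit model predicts the held-out block, scored by external
    q² and SDEP. A test block with zero activity variance is recorded with
    q2test = NaN (not dropped). Exhaustive mode refuses to run above
    ``EXHAUSTIVE_CEILING`` partitions.
    """
    ids = [str(i) for i in X.index]
    y = y.loc[X.index]
    n = len(ids)
    if n < k_test + 3:
        raise ValueError(f"need n >= k_test + 3 (= {k_test + 3}), got {n}")
    if mode == "exhaustive":
        total = math.comb(n, k_test)
        if total > EXHAUSTIVE_CEILING:
            raise ValueError(
                f"{total} partitions exceed the exhaustive ceiling "
                f"({EXHAUSTIVE_CEILING}); use mode='sampled'")
        partitions = enumerate_partitions(ids, k_test)
    elif mode == "sampled":
        if n_samples is None:
            raise ValueError("sampled mode requires n_samples")
        if seed is None:
            raise ValueError("sampled mode requires an explicit integer seed")
        partitions = _sampled_partitions(ids, k_test, n_samples, seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    pos = {i: k for k, i in enumerate(ids)}
    rows = []
    n_undefined = 0
    for part in partitions:
        tr = np.fromiter((pos[i] for i in part.train), dtype=int)
        te = np.fromiter((pos[i] for i in part.test), dtype=int)
        cv = loo_q2(Xv[tr], yv[tr], max_components)
        model = fit_pls(Xv[tr], yv[tr], cv.optimal_components)
        pred = model.predict(Xv[te])
        obs = yv[te]
        sd = sdep(obs, pred)
        if float(((obs - obs.mean()) ** 2).sum()) < 1e-12:
            q2t = np.nan
            n_undefined += 1
        else:
            q2t = q2_external(obs, pred)
        rows.append((";".join(part.train), ";".join(part.test), cv.q2,
                     cv.optimal_components, q2t, sd))
    records = pd.DataFrame(rows, columns=["train_ids", "test_ids", "q2cv",
                                          "n_components", "q2test", "sdep"])
    if n_undefined:
        log.info("SMV: %d partitions had zero test variance (q2test undefined)",
                 n_undefined)
    log.info("SMV: %d partitions evaluated (mode=%s, k_test=%d)",
             len(records), mode, k_test)
    return SMVResult(records, mode, seed, k_test)


def test_membership_frequency(result: SMVResult,
                              q2_threshold: float = DEFAULT_Q2_THRESHOLD
                              ) -> pd.DataFrame:
    """Per-compound test-set membership among the good models.

    For partitions with q2cv ≥ threshold: the fraction of them in which
    each compound sits in the test block, alongside the unconditional
    fraction over all partitions; ranked descending by the conditional
    fraction. An empty selection returns an empty table with a warning.
    """
    rec = result.records
    if rec.empty:
        raise ValueError("SMV result is empty")
    all_ids = sorted(set(itertools.chain.from_iterable(
        r.split(";") for r in rec["train_ids"])) |
        set(itertools.chain.from_iterable(r.split(";") for r in rec["test_ids"])))
    test_sets = [set(r.split(";")) for r in rec["test_ids"]]
    uncond = pd.Series(
        {i: sum(i in t for t in test_sets) / len(test_sets) for i in all_ids})
    good = rec["q2cv"] >= q2_threshold
    if not good.any():
        warnings.warn(f"no partition reaches q2cv >= {q2_threshold}",
                      RuntimeWarning, stacklevel=2)
        return pd.DataFrame(columns=["test_frequency", "unconditional"])
    good_sets = [t for t, g in zip(test_sets, good) if g]
    cond = pd.Series(
        {i: sum(i in t for t in good_sets) / len(good_sets) for i in all_ids})
    out = pd.DataFrame({"test_frequency": cond, "unconditional": uncond})
    return out.sort_values("test_frequency", ascending=False)


def kennard_stone_split(values: pd.Series, k_train: int) -> Partition:
    """Kennard–Stone maximin selection on a 1-D variable.

    Seeds with the pair at maximum absolute difference, then repeatedly
    adds the candidate maximizing its minimum distance to the selected set;
    ties break to the lower index. Selected compounds form the training
    set.
    """
    ids = [str(i) for i in values.index]
    v = values.to_numpy(dtype=float)
    n = len(v)
    if k_train < 2:
        raise ValueError("k_train must be >= 2")
    if k_train > n:
        raise ValueError(f"k_train={k_train} exceeds n={n}")
    d = np.abs(v[:, None] - v[None, :])
    # seeding pair: maximum distance, lowest (i, j) on ties
    best = (-1.0, (0, 1))
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best[0]:
                best = (d[i, j], (i, j))
    selected = list(best[1])
    while len(selected) < k_train:
        remaining = [i for i in range(n) if i not in selected]
        min_d = [d[i, selected].min() for i in remaining]
        selected.append(remaining[int(np.argmax(min_d))])  # first max → lower idx
    if k_train == n:
        warnings.warn("k_train = n leaves an empty test set", RuntimeWarning,
                      stacklevel=2)
    sel = set(selected)
    return Partition(tuple(ids[i] for i in sorted(sel)),
                     tuple(ids[i] for i in range(n) if i not in sel))


def ranked_split(values: pd.Series, ratio: tuple[int, int] = (2, 1)) -> Partition:
    """Activity-ranked cyclic split: sort by value (stable), then assign
    ``ratio[0]`` consecutive compounds to train and ``ratio[1]`` to test,
    cycling; an incomplete final cycle goes to train first."""
    a, b = ratio
    if a < 1 or b < 1:
        raise ValueError("ratio entries must be positive integers")
    order = values.sort_values(kind="stable").index
    train, test = [], []
    for k, i in enumerate(order):
        (train if k % (a + b) < a else test).append(str(i))
    return Partition(tuple(train), tuple(test))
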