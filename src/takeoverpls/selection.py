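"""Leave-one-out evaluation, Minimax selection, and exhaustive subset search.

A candidate model (predictor subset, number of components H) is scored by
leave-one-out cross-validation: for each participant the PLS-GLR model is
refit on the remaining n-1 rows (with fold-local standardization), the
held-out row is classified at probability threshold 0.5, and false positives
(predicted success, actual fail) and false negatives (predicted fail, actual
success) are tallied.  The Minimax criterion selects the candidate
minimizing max(FP, FN); ties are broken by total errors, then by fewer
predictors, smaller H, and lowest subset bitmask, making the selection a
total order.

The exhaustive search enumerates all 2^p - 1 non-empty predictor subsets.
One-component evaluations run through a fold-vectorized solver that shares
fold standardizations across subsets; its results are identical to the naive
per-fold loop (which it falls back to whenever the vectorized iteration does
not cleanly converge).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .ability_data import AbilitiesMatrix, SuccessVector
from .errors import EvaluationError, FitError, ValidationError
from .plsglm import (
    ETA_CLIP,
    IRLS_MAX_ITER,
    IRLS_TOL,
    classify,
    fit_pls_glr,
    predict_proba,
)

__all__ = [
    "LOOEvaluation", "SubsetSearchResult", "ComponentSearchResult",
    "loo_evaluate", "minimax_select", "select_n_components",
    "exhaustive_subset_search", "search_table",
]

#: Largest p for which exhaustive enumeration is allowed without an override.
DEFAULT_ENUMERATION_CAP = 20


@dataclass(frozen=True)
class LOOEvaluation:
    """Leave-one-out error profile of one (subset, H) candidate."""

    subset: tuple[int, ...]    # sorted column indices into the catalogue
    n_components: int
    fp: int                    # predicted success, actual fail
    fn: int                    # predicted fail, actual success
    n: int

    @property
    def max_errors(self) -> int:
        return max(self.fp, self.fn)

    @property
    def total_errors(self) -> int:
        return self.fp + self.fn

    @property
    def bitmask(self) -> int:
        return sum(1 << i for i in self.subset)


@dataclass(frozen=True)
class ComponentSearchResult:
    """Component-count selection: one full-predictor-set evaluation per H."""

    evaluations: tuple[LOOEvaluation, ...]
    selected: LOOEvaluation

    @property
    def selected_n_components(self) -> int:
        return self.selected.n_components


@dataclass(frozen=True)
class SubsetSearchResult:
    """All enumerated subset evaluations plus the Minimax winner."""

    evaluations: tuple[LOOEvaluation, ...]
    selected: LOOEvaluation
    tie_break_trail: tuple[str, ...]
    n_failed: int = 0           # subsets whose evaluation aborted (ineligible)


# ---------------------------------------------------------------------------
# Minimax selection
# ---------------------------------------------------------------------------

def _selection_stages():
    return (
        ("max_errors", lambda e: e.max_errors),
        ("total_errors", lambda e: e.total_errors),
        ("n_predictors", lambda e: len(e.subset)),
        ("n_components", lambda e: e.n_components),
        ("bitmask", lambda e: e.bitmask),
    )


def minimax_select(
    candidates: Sequence[LOOEvaluation],
    trail: list[str] | None = None,
) -> LOOEvaluation:
    """Candidate minimizing max(FP, FN); ties broken by total errors, then
    fewer predictors, smaller H, lowest subset bitmask (deterministic)."""
    pool = list(candidates)
    if not pool:
        raise ValidationError("minimax_select needs at least one candidate")
    for label, key in _selection_stages():
        best = min(key(e) for e in pool)
        pool = [e for e in pool if key(e) == best]
        if trail is not None:
            trail.append(f"{label} = {best}: {len(pool)} candidate(s) remain")
        if len(pool) == 1:
            break
    return pool[0]


# ---------------------------------------------------------------------------
# Fold cache and vectorized one-component LOO
# ---------------------------------------------------------------------------

class _FoldCache:
    """Per-fold standardized training blocks, shared across subsets.

    For fold i, ``Ztr[i]`` is the training matrix (row i removed) with every
    column standardized by the training rows' mean and sample SD, ``z0[i]``
    the held-out row on that fold's standardized scale, and ``Ytr[i]`` the
    training outcomes.  Matches the naive delete-standardize-fit loop
    exactly, column by column.
    """

    def __init__(self, values: np.ndarray, y: np.ndarray):
        n, p = values.shape
        if n < 4:
            raise ValidationError("leave-one-out needs at least 4 participants")
        idx = np.arange(n)
        tr_idx = np.stack([np.delete(idx, i) for i in range(n)])   # (n, n-1)
        Xtr = values[tr_idx]                                       # (n, n-1, p)
        self.Ytr = y[tr_idx]
        for i in range(n):
            s = self.Ytr[i].sum()
            if s == 0 or s == n - 1:
                raise EvaluationError(
                    f"training fold {i} contains a single outcome class", fold=i
                )
        mean = Xtr.mean(axis=1)                                    # (n, p)
        sd = Xtr.std(axis=1, ddof=1)
        if np.any(sd <= 0):
            i, j = map(int, np.argwhere(sd <= 0)[0])
            raise EvaluationError(
                f"training fold {i}: column {j} has zero variance", fold=i
            )
        self.Ztr = (Xtr - mean[:, None, :]) / sd[:, None, :]
        self.z0 = (values - mean) / sd
        self.y = y
        self.n = n


def _batched_newton(design_terms, Ytr):
    """Shared Newton loop for per-fold 2-parameter logistic fits.

    ``design_terms`` has shape (F, m) (the single non-intercept regressor per
    fold) or (F, m, k) for k independent per-fold single-regressor problems.
    Returns (a, b) or None if the iteration fails to converge cleanly.
    """
    X = design_terms
    per_column = X.ndim == 3
    Y = Ytr[:, :, None] if per_column else Ytr
    shape = (X.shape[0], X.shape[2]) if per_column else (X.shape[0],)
    a = np.zeros(shape)
    b = np.zeros(shape)
    expand = (lambda v: v[:, None, :]) if per_column else (lambda v: v[:, None])
    for _ in range(IRLS_MAX_ITER):
        eta = np.clip(expand(a) + X * expand(b), -ETA_CLIP, ETA_CLIP)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        r = Y - mu
        g0 = r.sum(axis=1)
        g1 = (X * r).sum(axis=1)
        s00 = w.sum(axis=1)
        s01 = (w * X).sum(axis=1)
        s11 = (w * X * X).sum(axis=1)
        det = s00 * s11 - s01 * s01
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (s11 * g0 - s01 * g1) / det
            db = (s00 * g1 - s01 * g0) / det
        a = a + da
        b = b + db
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            return None
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < IRLS_TOL:
            return a, b
    return None


def _loo_h1_vectorized(cache: _FoldCache, cols: Sequence[int]):
    """All n one-component fold fits at once; None if any fold needs the
    stabilized (ridge) solver, in which case the caller falls back to the
    naive loop so results stay identical to it."""
    cols = list(cols)
    Z = cache.Ztr[:, :, cols]            # (n, m, k)
    z0 = cache.z0[:, cols]               # (n, k)
    uni = _batched_newton(Z, cache.Ytr)
    if uni is None:
        return None
    _a, slopes = uni                     # (n, k)
    norms = np.linalg.norm(slopes, axis=1)
    if np.any(norms < 1e-12):
        return None
    w1 = slopes / norms[:, None]
    t = np.einsum("fmk,fk->fm", Z, w1)   # (n, m)
    comp = _batched_newton(t, cache.Ytr)
    if comp is None:
        return None
    g0, g1 = comp                        # (n,), (n,)
    t0 = (z0 * w1).sum(axis=1)
    p0 = expit(g0 + g1 * t0)
    return (p0 >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Leave-one-out evaluation
# ---------------------------------------------------------------------------

def _normalize_inputs(X, y, subset):
    if isinstance(X, AbilitiesMatrix):
        values = X.values
        name_to_idx = {n: i for i, n in enumerate(X.names)}
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ValidationError("predictor matrix must be 2-D")
        name_to_idx = None
    if subset is None:
        cols = tuple(range(values.shape[1]))
    else:
        cols = []
        for s in subset:
            if isinstance(s, str):
                if name_to_idx is None or s not in name_to_idx:
                    raise ValidationError(f"unknown predictor name {s!r}")
                cols.append(name_to_idx[s])
            else:
                cols.append(int(s))
        cols = tuple(sorted(set(cols)))
        if not cols:
            raise ValidationError("subset must be non-empty")
        if cols[0] < 0 or cols[-1] >= values.shape[1]:
            raise ValidationError(f"subset indices out of range: {cols}")
    yv = y.values if isinstance(y, SuccessVector) else np.asarray(y)
    yv = np.asarray(yv, dtype=float)
    if yv.shape != (values.shape[0],):
        raise ValidationError("outcome length does not match the matrix rows")
    if not np.all(np.isin(yv, (0.0, 1.0))):
        raise ValidationError("outcome values must be 0 or 1")
    n_pos = int(yv.sum())
    if n_pos == 0 or n_pos == len(yv):
        raise ValidationError("both outcome classes must be present")
    return values, yv.astype(np.int64), cols


def _loo_generic(values, y, cols, H):
    """The naive leave-one-out loop: per fold, delete-refit-predict."""
    n = values.shape[0]
    sub = values[:, list(cols)]
    preds = np.empty(n, dtype=int)
    for i in range(n):
        tr = np.delete(sub, i, axis=0)
        ytr = np.delete(y, i)
        if ytr.sum() in (0, len(ytr)):
            raise EvaluationError(
                f"training fold {i} contains a single outcome class", fold=i
            )
        model = fit_pls_glr(tr, ytr, H)
        preds[i] = classify(float(predict_proba(model, sub[i])[0]))
    return preds


def _tally(preds, y, cols, H) -> LOOEvaluation:
    fp = int(np.sum((preds == 1) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    return LOOEvaluation(subset=tuple(cols), n_components=H, fp=fp, fn=fn,
                         n=len(y))


def _evaluate(values, y, cols, H, cache: _FoldCache | None):
    H_eff = min(H, len(cols))
    if H_eff == 1 and cache is not None:
        preds = _loo_h1_vectorized(cache, cols)
        if preds is not None:
            return _tally(preds, y, cols, H_eff)
    return _tally(_loo_generic(values, y, cols, H_eff), y, cols, H_eff)


def loo_evaluate(X, y, subset=None, n_components: int = 1) -> LOOEvaluation:
    """Leave-one-out FP/FN tally for one (subset, H) candidate.

    ``X`` is an :class:`AbilitiesMatrix` in oriented raw units (or 2-D
    array); each fold standardizes on its own n-1 training rows.  Rows are
    classified at threshold 0.5.
    """
    values, yv, cols = _normalize_inputs(X, y, subset)
    H = int(n_components)
    if not 1 <= H <= len(cols):
        raise ValidationError(f"n_components must be in [1, {len(cols)}], got {H}")
    cache = _FoldCache(values, yv) if H == 1 else None
    return _evaluate(values, yv, cols, H, cache)


def select_n_components(X, y, h_max: int) -> ComponentSearchResult:
    """Choose the number of components on the full predictor set.

    Runs :func:`loo_evaluate` for H = 1..h_max and applies the Minimax
    criterion; with equal error profiles the smaller H wins.
    """
    values, yv, cols = _normalize_inputs(X, y, None)
    if not 1 <= h_max <= len(cols):
        raise ValidationError(f"h_max must be in [1, {len(cols)}], got {h_max}")
    cache = _FoldCache(values, yv)
    evaluations = tuple(
        _evaluate(values, yv, cols, H, cache) for H in range(1, h_max + 1)
    )
    return ComponentSearchResult(evaluations, minimax_select(evaluations))


def exhaustive_subset_search(
    X, y, n_components: int = 1,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
    n_jobs: int = 1,
) -> SubsetSearchResult:
    """Evaluate every non-empty predictor subset and select by Minimax.

    All 2^p - 1 subsets are enumerated (refused above ``enumeration_cap``
    predictors; raise the cap explicitly for larger searches).  H is applied
    as ``min(n_components, |subset|)`` per subset.  Subsets whose evaluation
    aborts (degenerate fold) are recorded as ineligible rather than imputed.
    Results are independent of execution order, so ``n_jobs`` only changes
    wall time, never the outcome.
    """
    values, yv, cols = _normalize_inputs(X, y, None)
    p = len(cols)
    if p > enumeration_cap:
        raise ValidationError(
            f"{p} predictors exceed the enumeration cap of {enumeration_cap} "
            f"(2^{p}-1 subsets); pass enumeration_cap={p} to run anyway"
        )
    H = int(n_components)
    if H < 1:
        raise ValidationError("n_components must be >= 1")
    cache = _FoldCache(values, yv)
    subsets = [
        combo
        for size in range(1, p + 1)
        for combo in combinations(range(p), size)
    ]

    def run(combo):
        try:
            return _evaluate(values, yv, combo, H, cache)
        except (EvaluationError, FitError):
            return None

    if n_jobs not in (None, 1):
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(run)(c) for c in subsets
        )
    else:
        results = [run(c) for c in subsets]

    evaluations = tuple(e for e in results if e is not None)
    n_failed = len(results) - len(evaluations)
    if not evaluations:
        raise EvaluationError("every candidate subset failed to evaluate")
    trail: list[str] = []
    selected = minimax_select(evaluations, trail)
    # post-hoc audit of the selection invariant
    assert selected.max_errors == min(e.max_errors for e in evaluations)
    return SubsetSearchResult(evaluations, selected, tuple(trail), n_failed)


def search_table(
    result: SubsetSearchResult | ComponentSearchResult,
    names: Sequence[str] | None = None,
    top: int | None = None,
) -> pd.DataFrame:
    """Ranked table of evaluations (bitmask, members, H, FP, FN, max, total)."""
    evals = sorted(
        result.evaluations,
        key=lambda e: (e.max_errors, e.total_errors, len(e.subset),
                       e.n_components, e.bitmask),
    )
    if top is not None:
        evals = evals[:top]
    rows = []
    for e in evals:
        members = (
            ",".join(names[i] for i in e.subset) if names is not None
            else ",".join(str(i) for i in e.subset)
        )
        rows.append({
            "bitmask": e.bitmask,
            "members": members,
            "n_components": e.n_components,
            "fp": e.fp,
            "fn": e.fn,
            "max_errors": e.max_errors,
            "total_errors": e.total_errors,
        })
    return pd.DataFrame(rows)


def write_search_table(result, names, path: str | Path, top: int | None = None) -> None:
    search_table(result, names, top).to_csv(path, sep="\t", index=False)
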