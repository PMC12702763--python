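"""PLS logistic regression (PLS-GLR, binomial link) for a binary outcome.

The model builds ``H`` orthogonal components from standardized predictors:

* component 1 weights are proportional to the slopes of univariate logistic
  regressions of the outcome on each predictor, normalized to unit norm;
  ``t_1 = X w_1``;
* for ``h >= 2`` each predictor column is deflated by OLS regression on the
  components built so far, and the weight of predictor ``j`` is the
  coefficient of its deflated column in a logistic regression of the outcome
  on ``(t_1, ..., t_{h-1}, deflated x_j)``, again normalized;
* finally the outcome is logistically regressed on ``t_1..t_H`` giving
  component coefficients ``gamma``, which are back-transformed to
  per-predictor coefficients ``beta`` on the standardized ("per 1 SD") scale
  through the adjusted weights ``W* = W (P'W)^{-1}``.

With ``H`` equal to the number of predictors (full rank, well conditioned)
the components span the predictor space and the fit reproduces the ordinary
maximum-likelihood multiple logistic regression.

The inner solver is iteratively reweighted least squares (Newton) with a
small ridge (1e-6 on the normal equations) applied, and the fit flagged,
when the unpenalized iteration fails to stabilize (quasi-separation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .ability_data import (
    AbilitiesMatrix,
    StandardizationParams,
    SuccessVector,
)
from .errors import FitError, ValidationError

__all__ = [
    "LogisticFit", "PLSGLRModel", "fit_pls_glr", "predict_proba",
    "classify", "interpret_coefficient",
]

#: Convergence tolerance of the inner solver (max absolute coefficient change).
IRLS_TOL = 1e-8
#: Iteration cap of the inner solver.
IRLS_MAX_ITER = 100
#: Ridge added to the normal equations when stabilization is needed.
IRLS_RIDGE = 1e-6
#: Linear predictors are clipped at +/- this value inside the solver.
ETA_CLIP = 30.0


@dataclass(frozen=True)
class LogisticFit:
    """Result of a maximum-likelihood (or ridge-stabilized) logistic fit."""

    coef: np.ndarray          # intercept first
    converged: bool
    n_iter: int
    stabilized: bool          # True if the ridge fallback was used


class _IRLSDiverged(Exception):
    pass


def _irls(design: np.ndarray, y: np.ndarray, ridge: float) -> tuple[np.ndarray, bool, int]:
    """One IRLS run; raises _IRLSDiverged on numerical breakdown."""
    n, k = design.shape
    beta = np.zeros(k)
    for it in range(1, IRLS_MAX_ITER + 1):
        eta = np.clip(design @ beta, -ETA_CLIP, ETA_CLIP)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        a = (design * w[:, None]).T @ design
        if ridge:
            a[np.diag_indices_from(a)] += ridge
        g = design.T @ (y - mu)
        try:
            step = np.linalg.solve(a, g)
        except np.linalg.LinAlgError as exc:
            raise _IRLSDiverged(str(exc)) from exc
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            raise _IRLSDiverged("non-finite coefficients")
        if np.max(np.abs(step)) < IRLS_TOL:
            return beta, True, it
    return beta, False, IRLS_MAX_ITER


def logistic_fit(design: np.ndarray, y: np.ndarray) -> LogisticFit:
    """Logistic regression of ``y`` on ``design`` (intercept column included
    by the caller), with ridge stabilization on (quasi-)separation."""
    try:
        beta, converged, n_iter = _irls(design, y, ridge=0.0)
        if converged:
            return LogisticFit(beta, True, n_iter, stabilized=False)
    except _IRLSDiverged:
        pass
    try:
        beta, converged, n_iter = _irls(design, y, ridge=IRLS_RIDGE)
    except _IRLSDiverged as exc:
        raise FitError(f"inner logistic solver diverged after stabilization: {exc}")
    return LogisticFit(beta, converged, n_iter, stabilized=True)


def _univariate_slopes(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Slopes of per-column logistic regressions ``y ~ 1 + x_j``, computed for
    all columns at once (vectorized Newton, shared iteration loop)."""

    def run(ridge: float) -> tuple[np.ndarray, np.ndarray, bool]:
        n, k = X.shape
        a = np.zeros(k)
        b = np.zeros(k)
        converged = False
        for _ in range(IRLS_MAX_ITER):
            eta = np.clip(a + X * b, -ETA_CLIP, ETA_CLIP)
            mu = expit(eta)
            w = np.maximum(mu * (1.0 - mu), 1e-12)
            r = y[:, None] - mu
            g0 = r.sum(axis=0)
            g1 = (X * r).sum(axis=0)
            s00 = w.sum(axis=0) + ridge
            s01 = (w * X).sum(axis=0)
            s11 = (w * X * X).sum(axis=0) + ridge
            det = s00 * s11 - s01 * s01
            with np.errstate(divide="ignore", invalid="ignore"):
                da = (s11 * g0 - s01 * g1) / det
                db = (s00 * g1 - s01 * g0) / det
            a = a + da
            b = b + db
            if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
                return a, b, False
            if max(np.max(np.abs(da)), np.max(np.abs(db))) < IRLS_TOL:
                converged = True
                break
        return a, b, converged

    a, b, converged = run(0.0)
    if converged:
        return b, False
    a, b, converged = run(IRLS_RIDGE)
    if not np.all(np.isfinite(b)):
        raise FitError("univariate logistic slopes diverged after stabilization")
    return b, True


@dataclass(frozen=True)
class PLSGLRModel:
    """A fitted PLS logistic regression.

    ``weights`` (p x H) holds the unit-norm component weights on deflated
    predictors; ``weights_star`` re-expresses components on the original
    standardized predictors, so ``t(x) = x_std @ weights_star``.  ``gamma``
    holds the component-space logistic coefficients (intercept first) and
    ``beta = weights_star @ gamma[1:]`` the per-predictor coefficients on the
    standardized scale.  ``standardization`` carries the training means/SDs
    used by :func:`predict_proba` on raw oriented rows.
    """

    variable_names: tuple[str, ...]
    subset: tuple[int, ...]
    n_components: int
    weights: np.ndarray
    weights_star: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    standardization: StandardizationParams
    stabilized: bool

    # -- prediction --------------------------------------------------------
    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        """gamma_0 + sum_h gamma_h t_h(x) for rows in raw oriented units."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.variable_names):
            raise ValidationError(
                f"expected {len(self.variable_names)} predictors, got {x.shape[1]}"
            )
        z = self.standardization.apply(x)
        t = z @ self.weights_star
        return self.gamma[0] + t @ self.gamma[1:]

    def predict_proba(self, x) -> np.ndarray:
        return predict_proba(self, x)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variable_names": list(self.variable_names),
            "subset": list(self.subset),
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "weights_star": self.weights_star.tolist(),
            "gamma": self.gamma.tolist(),
            "beta": self.beta.tolist(),
            "mean": self.standardization.mean.tolist(),
            "sd": self.standardization.sd.tolist(),
            "stabilized": self.stabilized,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def from_dict(cls, data: dict) -> "PLSGLRModel":
        names = tuple(data["variable_names"])
        return cls(
            variable_names=names,
            subset=tuple(int(i) for i in data["subset"]),
            n_components=int(data["n_components"]),
            weights=np.asarray(data["weights"], dtype=float),
            weights_star=np.asarray(data["weights_star"], dtype=float),
            gamma=np.asarray(data["gamma"], dtype=float),
            beta=np.asarray(data["beta"], dtype=float),
            standardization=StandardizationParams(
                names=names,
                mean=np.asarray(data["mean"], dtype=float),
                sd=np.asarray(data["sd"], dtype=float),
            ),
            stabilized=bool(data["stabilized"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSGLRModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _fit_components(Z: np.ndarray, y: np.ndarray, n_components: int):
    """Core PLS-GLR iteration on an already standardized matrix ``Z``."""
    n, p = Z.shape
    H = n_components
    W = np.zeros((p, H))
    T = np.zeros((n, H))
    P = np.zeros((p, H))
    Xc = Z.copy()
    stabilized = False
    for h in range(H):
        if h == 0:
            w, stab = _univariate_slopes(Xc, y)
            stabilized = stabilized or stab
        else:
            w = np.zeros(p)
            for j in range(p):
                col = Xc[:, j]
                if np.sqrt(np.mean(col * col)) < 1e-10:
                    continue  # predictor fully explained by earlier components
                design = np.column_stack([np.ones(n), T[:, :h], col])
                fit = logistic_fit(design, y)
                stabilized = stabilized or fit.stabilized
                w[j] = fit.coef[-1]
        norm = float(np.linalg.norm(w))
        if norm < 1e-12:
            raise FitError(
                f"component {h + 1}: no remaining predictive information "
                "(all candidate weights are zero)"
            )
        w = w / norm
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-12:
            raise FitError(f"component {h + 1} has (near-)zero variance")
        p_h = Xc.T @ t / tt
        W[:, h], T[:, h], P[:, h] = w, t, p_h
        Xc = Xc - np.outer(t, p_h)
    final = logistic_fit(np.column_stack([np.ones(n), T]), y)
    stabilized = stabilized or final.stabilized
    gamma = final.coef
    try:
        weights_star = W @ np.linalg.inv(P.T @ W)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular loading-weight system: {exc}") from exc
    beta = weights_star @ gamma[1:]
    return W, weights_star, T, gamma, beta, stabilized


def _as_xy(X, y, subset):
    """Normalize (AbilitiesMatrix | array, SuccessVector | array, subset)."""
    if isinstance(X, AbilitiesMatrix):
        matrix = X.restrict(subset) if subset is not None else X
        names = matrix.names
        values = matrix.values
        idx = (
            tuple(X.column_index(s) if isinstance(s, str) else int(s) for s in subset)
            if subset is not None else tuple(range(X.n_variables))
        )
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ValidationError("predictor matrix must be 2-D")
        if subset is not None:
            idx = tuple(int(s) for s in subset)
            values = values[:, list(idx)]
        else:
            idx = tuple(range(values.shape[1]))
        names = tuple(f"x{j + 1:02d}" for j in idx)
    yv = y.values if isinstance(y, SuccessVector) else np.asarray(y)
    yv = np.asarray(yv, dtype=float)
    if yv.ndim != 1 or yv.shape[0] != values.shape[0]:
        raise ValidationError("outcome length does not match the matrix rows")
    if not np.all(np.isin(yv, (0.0, 1.0))):
        raise ValidationError("outcome values must be 0 or 1")
    return values, yv, names, idx


def fit_pls_glr(X, y, n_components: int, subset: Sequence[int | str] | None = None
                ) -> PLSGLRModel:
    """Fit a PLS logistic regression with ``n_components`` components.

    Parameters
    ----------
    X:
        :class:`AbilitiesMatrix` in oriented raw units, or a plain 2-D array.
        Columns are standardized internally (sample SD, divisor n-1) and the
        parameters stored on the model, so prediction accepts raw rows.
    y:
        :class:`SuccessVector` or binary array aligned with ``X`` rows.
    n_components:
        Number of PLS components ``H`` with ``1 <= H <= p``.
    subset:
        Optional predictor subset (indices into, or names of, ``X`` columns);
        the model records the chosen identity.
    """
    values, yv, names, idx = _as_xy(X, y, subset)
    n, p = values.shape
    H = int(n_components)
    if not 1 <= H <= p:
        raise ValidationError(f"n_components must be in [1, {p}], got {H}")
    n_pos = int(yv.sum())
    if n_pos == 0 or n_pos == n:
        raise ValidationError("both outcome classes must be present to fit")
    if n <= H + 1:
        raise ValidationError(f"need more than H + 1 = {H + 1} rows, got {n}")

    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        j = int(np.argmax(sd <= 0))
        raise ValidationError(f"predictor {names[j]!r} has zero variance")
    Z = (values - mean) / sd

    W, weights_star, _T, gamma, beta, stabilized = _fit_components(Z, yv, H)
    return PLSGLRModel(
        variable_names=tuple(names),
        subset=idx,
        n_components=H,
        weights=W,
        weights_star=weights_star,
        gamma=gamma,
        beta=beta,
        standardization=StandardizationParams(tuple(names), mean, sd),
        stabilized=stabilized,
    )


def predict_proba(model: PLSGLRModel, x) -> np.ndarray:
    """Probability of take-over success for rows in raw oriented units.

    ``x`` may be an :class:`AbilitiesMatrix` (restricted to the model's
    predictors by name; missing predictors raise), a single row, or a 2-D
    array already in the model's column order.  Returns probabilities in
    (0, 1), one per row (scalar-shaped input gives a length-1 array).
    """
    if isinstance(x, AbilitiesMatrix):
        missing = [n for n in model.variable_names if n not in x.names]
        if missing:
            raise ValidationError(f"input lacks model predictor(s): {missing}")
        x = x.restrict(list(model.variable_names)).values
    return expit(model.linear_predictor(x))


def classify(p, threshold: float = 0.5):
    """Hard 0/1 classification; the boundary ``p == threshold`` maps to 1."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    out = (arr >= threshold).astype(int)
    return int(out) if np.isscalar(p) or arr.ndim == 0 else out


def interpret_coefficient(beta: float) -> tuple[float, int]:
    """Odds multiplier and rounded percent change per 1-SD increase.

    Returns ``(exp(beta), round(100 * (exp(beta) - 1)))``; the percent change
    is rounded to the nearest integer for reporting.
    """
    if not math.isfinite(beta):
        raise ValidationError("coefficient must be finite")
    multiplier = math.exp(beta)
    percent = int(math.floor(100.0 * (multiplier - 1.0) + 0.5))
    return multiplier, percent
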