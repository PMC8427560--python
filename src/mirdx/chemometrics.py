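"""PLSR calibration core: NIPALS partial-least-squares regression (PLS2),
dataset splitting, k-fold RMSECV and marginal-decrement component selection.

The model regresses a multi-analyte concentration matrix Y (mM) on
preprocessed, first-differenced spectra X.  Both blocks are column
mean-centered (no autoscaling: differenced absorbances share a common
scale); components are extracted one at a time by the NIPALS iteration with
X- and Y-deflation by the X-scores.  Fits are deterministic: deflation order
is fixed and each weight vector is sign-normalized so that its
largest-magnitude element is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

DEFAULT_N_FOLDS = 5
DEFAULT_K_MAX = 10
DEFAULT_SELECTION_THRESHOLD = 0.02

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 5000


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint training / validation / test row indices covering a dataset."""

    training: np.ndarray
    validation: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        for name in ("training", "validation", "test"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), int))
        combined = np.concatenate([self.training, self.validation, self.test])
        if len(np.unique(combined)) != combined.size:
            raise ValueError("index sets must be disjoint")


def split_dataset(
    n_rows: int, sizes: tuple[int, int, int], seed: int
) -> SplitIndices:
    """Uniformly random disjoint partition into (train, validation, test).

    Default protocol sizes for a 46-spectrum calibration set are 19/13/14.
    """
    if sum(sizes) != n_rows:
        raise ValueError(f"sizes {sizes} do not sum to n_rows={n_rows}")
    if any(s < 0 for s in sizes):
        raise ValueError("sizes must be non-negative")
    order = np.random.default_rng(seed).permutation(n_rows)
    n_train, n_val, _ = sizes
    return SplitIndices(
        training=np.sort(order[:n_train]),
        validation=np.sort(order[n_train : n_train + n_val]),
        test=np.sort(order[n_train + n_val :]),
    )


@dataclass(frozen=True)
class PLSRModel:
    """Fitted PLS2 model: centers, weights/loadings and regression coefficients.

    Prediction is the affine map ``Y_hat = (X - x_mean) B + y_mean`` with
    ``B = W (P' W)^-1 Q'``.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray       # (p, k)
    x_loadings: np.ndarray    # (p, k)
    y_loadings: np.ndarray    # (m, k)
    coefficients: np.ndarray  # (p, m)
    preprocessing: dict[str, Any] = field(default_factory=dict)
    analytes: tuple[str, ...] = ()

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        return predict(self, x_new)

    def to_dict(self) -> dict[str, Any]:
        return {
            "format": "mirdx-plsr",
            "version": 1,
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "preprocessing": self.preprocessing,
            "analytes": list(self.analytes),
        }

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PLSRModel":
        if payload.get("format") != "mirdx-plsr":
            raise ValueError("not a mirdx PLSR model document")
        if payload.get("version") != 1:
            raise ValueError(f"unsupported model version {payload.get('version')!r}")
        return cls(
            n_components=int(payload["n_components"]),
            x_mean=np.asarray(payload["x_mean"], float),
            y_mean=np.asarray(payload["y_mean"], float),
            weights=np.asarray(payload["weights"], float),
            x_loadings=np.asarray(payload["x_loadings"], float),
            y_loadings=np.asarray(payload["y_loadings"], float),
            coefficients=np.asarray(payload["coefficients"], float),
            preprocessing=dict(payload.get("preprocessing", {})),
            analytes=tuple(payload.get("analytes", ())),
        )


def _as_2d(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return y[:, None] if y.ndim == 1 else y


def fit_plsr(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    preprocessing: dict[str, Any] | None = None,
    analytes: tuple[str, ...] = (),
) -> PLSRModel:
    """Fit a mean-centered NIPALS PLS2 model with ``n_components`` latent variables.

    Raises ``ValueError`` for an invalid component count or an X block with
    no variance.  An inner iteration that exceeds its cap (a near-degenerate
    singular pair) is resolved exactly via the SVD of the cross-covariance.
    """
    x = np.asarray(x, dtype=float)
    y = _as_2d(y)
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    max_components = min(n - 1, p)
    if not 1 <= n_components <= max_components:
        raise ValueError(
            f"n_components must be in [1, {max_components}] for X of shape {x.shape}"
        )
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xc = x - x_mean
    yc = y - y_mean
    if not np.any(np.abs(xc) > 0):
        raise ValueError("X has zero variance; nothing to model")

    p_dim, m_dim = p, y.shape[1]
    weights = np.zeros((p_dim, n_components))
    x_loadings = np.zeros((p_dim, n_components))
    y_loadings = np.zeros((m_dim, n_components))

    for component in range(n_components):
        y_norms = np.linalg.norm(yc, axis=0)
        if np.max(y_norms) == 0.0:
            # Y residual exhausted: remaining components model X only.
            u = xc[:, int(np.argmax(np.linalg.norm(xc, axis=0)))].copy()
        else:
            u = yc[:, int(np.argmax(y_norms))].copy()
        w = np.zeros(p_dim)
        for iteration in range(_NIPALS_MAX_ITER):
            w_new = xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0.0:
                raise ValueError("X residual has zero variance during deflation")
            w_new /= norm
            t = xc @ w_new
            tt = t @ t
            q = yc.T @ t / tt
            qq = q @ q
            u_new = yc @ q / qq if qq > 0 else t
            converged = np.linalg.norm(w_new - w) < _NIPALS_TOL
            w = w_new
            u = u_new
            if converged or m_dim == 1:
                break
        else:
            # Near-degenerate singular pair: the power iteration rotates in
            # the tied subspace without settling.  Resolve it exactly with
            # the dominant singular vector of the cross-covariance, which is
            # the fixed point the iteration approximates.
            w = np.linalg.svd(xc.T @ yc, full_matrices=False)[0][:, 0]
        # Deterministic sign: largest-magnitude weight element positive.
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
        t = xc @ w
        tt = t @ t
        p_vec = xc.T @ t / tt
        q_vec = yc.T @ t / tt
        xc = xc - np.outer(t, p_vec)
        yc = yc - np.outer(t, q_vec)
        weights[:, component] = w
        x_loadings[:, component] = p_vec
        y_loadings[:, component] = q_vec

    rotation = weights @ np.linalg.solve(x_loadings.T @ weights, np.eye(n_components))
    coefficients = rotation @ y_loadings.T
    return PLSRModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=weights,
        x_loadings=x_loadings,
        y_loadings=y_loadings,
        coefficients=coefficients,
        preprocessing=dict(preprocessing or {}),
        analytes=analytes,
    )


def predict(model: PLSRModel, x_new: np.ndarray) -> np.ndarray:
    """Predicted concentrations (mM) for new preprocessed spectra."""
    x_new = np.asarray(x_new, dtype=float)
    single = x_new.ndim == 1
    if single:
        x_new = x_new[None, :]
    if x_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {x_new.shape[1]} columns, model expects {model.x_mean.size}"
        )
    out = (x_new - model.x_mean) @ model.coefficients + model.y_mean
    return out[0] if single else out


@dataclass(frozen=True)
class CVResult:
    """RMSECV (mM) per component count, per analyte and aggregated."""

    components: np.ndarray      # 1..k_max
    per_analyte: np.ndarray     # (k_max, m)
    aggregate: np.ndarray       # (k_max,)
    n_folds: int
    seed: int
    analytes: tuple[str, ...] = ()


def kfold_rmsecv(
    x: np.ndarray,
    y: np.ndarray,
    k_max: int,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    *,
    analytes: tuple[str, ...] = (),
) -> CVResult:
    """k-fold cross-validated RMSE for 1..k_max latent components.

    Held-out squared errors are pooled over folds; the aggregate curve is
    the root of the mean MSECV across analytes (all in mM, unweighted).
    """
    x = np.asarray(x, dtype=float)
    y = _as_2d(y)
    n = x.shape[0]
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if n_folds > n:
        raise ValueError("more folds than samples")
    folds = np.array_split(np.random.default_rng(seed).permutation(n), n_folds)
    smallest_train = n - max(len(f) for f in folds)
    max_k = min(smallest_train - 1, x.shape[1])
    if not 1 <= k_max <= max_k:
        raise ValueError(f"k_max must be in [1, {max_k}] for these folds")
    sse = np.zeros((k_max, y.shape[1]))
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        for k in range(1, k_max + 1):
            model = fit_plsr(x[train], y[train], k)
            residual = predict(model, x[fold]) - y[fold]
            sse[k - 1] += (residual**2).sum(axis=0)
    mse = sse / n
    return CVResult(
        components=np.arange(1, k_max + 1),
        per_analyte=np.sqrt(mse),
        aggregate=np.sqrt(mse.mean(axis=1)),
        n_folds=n_folds,
        seed=seed,
        analytes=analytes,
    )


def select_n_components(
    cv: CVResult,
    rel_improvement_threshold: float = DEFAULT_SELECTION_THRESHOLD,
) -> int:
    """Marginal-decrement rule on the aggregate RMSECV curve.

    Returns the smallest k whose relative improvement to k+1 falls below the
    threshold — the point where the curve starts to flatten — or k_max if
    every step still improves materially.
    """
    curve = np.asarray(cv.aggregate, dtype=float)
    if curve.size == 0:
        raise ValueError("empty cross-validation result")
    for k in range(curve.size - 1):
        if curve[k] <= 0.0:
            return k + 1
        if (curve[k] - curve[k + 1]) / curve[k] < rel_improvement_threshold:
            return k + 1
    return int(curve.size)


def rmse(predicted: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Root-mean-square error per analyte (mM)."""
    predicted = _as_2d(predicted)
    reference = _as_2d(reference)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference shapes differ")
    if predicted.shape[0] == 0:
        raise ValueError("need at least one pair")
    return np.sqrt(((predicted - reference) ** 2).mean(axis=0))
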