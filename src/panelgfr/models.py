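"""Development-model bank and robust GFR estimation.

Fitting happens once, in the development population: eight single-marker
OLS regressions of log mGFR on each log marker, the full eight-marker OLS
model, lazily cached subset models (all 28 six-marker models can be
pre-fitted), correlation weights, and the stored development rows used by
K-nearest-neighbor marginalized estimation.

Prediction in application data combines an outlier-detection strategy
(univariate / multivariate / consistency, see :mod:`panelgfr.outliers`)
with one of three robust estimators:

* **trimmed**  — weighted mean of the single-marker estimates from the
  non-outlying markers, weighting each marker by the absolute value of its
  development correlation with log mGFR;
* **knn**      — average of the full-model predictions over the k
  development rows nearest to the application row in the standardized
  metric restricted to the trustworthy markers;
* **screened** — prediction from the OLS model refit on development data
  using exactly the trustworthy markers.

A ``naive`` estimator (full OLS on the raw application row, no outlier
handling) serves as the reference.  :class:`PanelGFREstimator` packages
the whole pipeline as a scikit-learn regressor.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .core_data import MARKERS, CohortData
from .outliers import (
    ReferenceSummary,
    detect_univariate,
    fit_reference,
    select_consistent_matrix,
    winsorize_multivariate,
)

DETECTION_METHODS = ("univariate", "multivariate", "consistency")
ESTIMATORS = ("trimmed", "knn", "screened")
DEFAULT_K_GRID: tuple[int, ...] = (1, 3, 5, 10, 15, 20, 30, 50)

_P = len(MARKERS)


def _xy(data: CohortData | tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, CohortData):
        return data.X(), data.y()
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients [intercept, slopes...] via least squares."""
    A = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef


@dataclasses.dataclass
class ModelBank:
    """Everything fitted on the development data.

    Attributes
    ----------
    univariate : ndarray (8, 2)
        Per marker, [intercept, slope] of log mGFR on that log marker.
    full : ndarray (9,)
        [intercept, 8 slopes] of the all-marker OLS model.
    weights : ndarray (8,)
        |corr(log marker, log mGFR)| in the development data.
    dev_X, dev_y : ndarray
        Stored development design (log scale), used by KNN estimation.
    dev_sd : ndarray (8,)
        Per-marker development SDs (KNN distance standardization).
    k : int or None
        Neighbor count; chosen by :func:`choose_k` or set explicitly.
    subsets : dict
        Cached OLS coefficients keyed by sorted marker-index tuples.
    """

    univariate: np.ndarray
    full: np.ndarray
    weights: np.ndarray
    dev_X: np.ndarray
    dev_y: np.ndarray
    dev_sd: np.ndarray
    k: int | None = None
    subsets: dict = dataclasses.field(default_factory=dict)
    _dev_pred: np.ndarray | None = dataclasses.field(default=None, repr=False)

    # -- model access --------------------------------------------------------
    def univariate_estimates(self, X: np.ndarray) -> np.ndarray:
        """(n, 8) matrix of single-marker log-GFR estimates."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.univariate[:, 0] + self.univariate[:, 1] * X

    def predict_full(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.full[0] + X @ self.full[1:]

    def subset_model(self, subset: Sequence[int]) -> np.ndarray:
        """OLS coefficients for a marker subset, fitted lazily and cached."""
        key = tuple(sorted(int(j) for j in subset))
        if key not in self.subsets:
            self.subsets[key] = _ols(self.dev_X[:, key], self.dev_y)
        return self.subsets[key]

    def prefit_six_marker_models(self) -> int:
        """Eagerly fit all C(8, 6) = 28 six-marker models; returns the count."""
        keys = list(itertools.combinations(range(_P), 6))
        for key in keys:
            self.subset_model(key)
        return len(keys)

    @property
    def dev_pred(self) -> np.ndarray:
        """Full-model predictions at the development rows (cached)."""
        if self._dev_pred is None:
            self._dev_pred = self.predict_full(self.dev_X)
        return self._dev_pred

    # -- serialization -------------------------------------------------------
    def to_json(self, path, include_dev_rows: bool = True) -> None:
        doc = {
            "marker_names": list(MARKERS),
            "univariate": self.univariate.tolist(),
            "full": self.full.tolist(),
            "weights": self.weights.tolist(),
            "dev_sd": self.dev_sd.tolist(),
            "k": self.k,
            "subsets": {",".join(map(str, k)): v.tolist() for k, v in self.subsets.items()},
        }
        if include_dev_rows:
            doc["dev_X"] = self.dev_X.tolist()
            doc["dev_y"] = self.dev_y.tolist()
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "ModelBank":
        with open(path) as fh:
            doc = json.load(fh)
        dev_X = np.asarray(doc.get("dev_X", []), dtype=float).reshape(-1, _P)
        dev_y = np.asarray(doc.get("dev_y", []), dtype=float)
        bank = cls(
            univariate=np.asarray(doc["univariate"], dtype=float),
            full=np.asarray(doc["full"], dtype=float),
            weights=np.asarray(doc["weights"], dtype=float),
            dev_X=dev_X,
            dev_y=dev_y,
            dev_sd=np.asarray(doc["dev_sd"], dtype=float),
            k=doc.get("k"),
        )
        bank.subsets = {
            tuple(int(i) for i in k.split(",")): np.asarray(v, dtype=float)
            for k, v in doc.get("subsets", {}).items()
        }
        return bank


def fit_model_bank(
    dev: CohortData | tuple[np.ndarray, np.ndarray],
    k_grid: Sequence[int] | None = None,
    seed: int = 0,
    k: int | None = None,
    prefit_subsets: bool = False,
) -> ModelBank:
    """Fit the full development-model bank.

    Parameters
    ----------
    dev : CohortData or (X, y) log-scale arrays
        Complete-case, log-transformed development data.
    k_grid : sequence of int, optional
        Candidate neighbor counts; when given (and ``k`` is not), the
        neighbor count is chosen by :func:`choose_k`.
    k : int, optional
        Fix the neighbor count directly, skipping the cross-validated
        choice.
    prefit_subsets : bool
        Eagerly fit the 28 six-marker models.
    """
    X, y = _xy(dev)
    if X.shape[1] != _P:
        raise ValueError(f"expected {_P} marker columns, got {X.shape[1]}")

    univariate = np.empty((_P, 2))
    for m in range(_P):
        univariate[m] = _ols(X[:, [m]], y)
    full = _ols(X, y)
    if not np.all(np.isfinite(full)):
        raise ValueError("full design is collinear; cannot fit the 8-marker model")
    with np.errstate(invalid="ignore"):
        weights = np.abs(np.array([np.corrcoef(X[:, m], y)[0, 1] for m in range(_P)]))
    weights = np.nan_to_num(weights)  # constant marker -> weight 0
    dev_sd = X.std(axis=0, ddof=1)

    bank = ModelBank(
        univariate=univariate, full=full, weights=weights,
        dev_X=X.copy(), dev_y=y.copy(), dev_sd=dev_sd, k=k,
    )
    if prefit_subsets:
        bank.prefit_six_marker_models()
    if bank.k is None and k_grid is not None:
        bank.k = choose_k((X, y), k_grid=k_grid, seed=seed)
    return bank


def choose_k(
    dev: CohortData | tuple[np.ndarray, np.ndarray],
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    n_iterations: int = 10,
    seed: int = 0,
    val_fraction: float = 0.2,
) -> int:
    """Choose the KNN neighbor count by cross-validation within development data.

    KNN marginalized estimation is only invoked when some predictors are
    untrustworthy, so the tuning condition emulates that: in each of
    ``n_iterations`` random train/validation splits, every validation row
    has a random pair of markers masked, KNN predictions are formed from
    the remaining six, and k is chosen to minimize the mean validation
    RMSE on the log scale.  Deterministic for a fixed seed; ties go to the
    smallest k.
    """
    X, y = _xy(dev)
    k_grid = sorted(int(k) for k in k_grid)
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    n = len(X)
    if max(k_grid) >= n:
        raise ValueError("max(k_grid) must be below the number of development rows")
    if len(k_grid) == 1:
        return k_grid[0]

    rng = np.random.default_rng(seed)
    losses = np.zeros((n_iterations, len(k_grid)))
    for it in range(n_iterations):
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        val, tr = perm[:n_val], perm[n_val:]
        sub = fit_model_bank((X[tr], y[tr]))
        dev_pred = sub.dev_pred
        sd = np.where(sub.dev_sd > 0, sub.dev_sd, 1.0)
        Z_tr = X[tr] / sd
        Z_val = X[val] / sd
        # per-marker squared-distance components, shape (n_val, n_tr)
        comp = (Z_val[:, None, :] - Z_tr[None, :, :]) ** 2
        masked = np.array([rng.choice(_P, size=2, replace=False) for _ in range(n_val)])
        err2 = {k: [] for k in k_grid}
        d2 = comp.sum(axis=2)
        d2 -= np.take_along_axis(comp, masked[:, None, :], axis=2).sum(axis=2)
        order = np.argsort(d2, axis=1, kind="stable")
        sorted_pred = dev_pred[order]
        cmeans = np.cumsum(sorted_pred, axis=1) / np.arange(1, len(tr) + 1)
        for j, k in enumerate(k_grid):
            losses[it, j] = np.mean((cmeans[:, k - 1] - y[val]) ** 2)
    mean_loss = losses.mean(axis=0)
    return k_grid[int(np.argmin(mean_loss))]


# ---------------------------------------------------------------------------
# robust predictors
# ---------------------------------------------------------------------------

def predict_weighted_trimmed(
    bank: ModelBank, ghat: Sequence[float], clean_set: Sequence[int]
) -> float:
    """Correlation-weighted mean of the clean-set single-marker estimates."""
    clean = list(clean_set)
    if not clean:
        raise ValueError("clean_set must be nonempty")
    g = np.asarray(ghat, dtype=float)[clean]
    w = bank.weights[clean]
    if w.sum() == 0:
        warnings.warn("all correlation weights are zero in the clean set; "
                      "falling back to the unweighted mean")
        return float(g.mean())
    return float(np.sum(w * g) / np.sum(w))


def predict_knn_marginalized(
    bank: ModelBank, x_row: Sequence[float], clean_set: Sequence[int]
) -> float:
    """Average full-model prediction over development neighbors.

    Neighbors are the ``bank.k`` development rows closest to the
    application row in standardized Euclidean distance computed over the
    clean markers only; each neighbor is scored with the full eight-marker
    model at its own (complete) marker values.  With all eight markers
    clean this reduces to the full-model prediction at the row itself.
    """
    clean = sorted(set(int(j) for j in clean_set))
    if not clean:
        raise ValueError("clean_set must be nonempty")
    x = np.asarray(x_row, dtype=float)
    if len(clean) == _P:
        return float(bank.predict_full(x)[0])
    if bank.k is None:
        raise ValueError("bank.k is unset; fit with a k_grid or set k explicitly")
    sd = np.where(bank.dev_sd > 0, bank.dev_sd, 1.0)
    d2 = (((bank.dev_X[:, clean] - x[clean]) / sd[clean]) ** 2).sum(axis=1)
    nearest = np.argpartition(d2, bank.k - 1)[: bank.k]
    return float(bank.dev_pred[nearest].mean())


def predict_screened(
    bank: ModelBank, x_row: Sequence[float], clean_set: Sequence[int]
) -> float:
    """Prediction from the development OLS refit on the clean markers only."""
    clean = sorted(set(int(j) for j in clean_set))
    if not clean:
        raise ValueError("clean_set must be nonempty")
    coef = bank.subset_model(clean)
    x = np.asarray(x_row, dtype=float)
    return float(coef[0] + x[clean] @ coef[1:])


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _clean_sets_univariate(flags: np.ndarray) -> list[tuple[int, ...]]:
    return [tuple(np.flatnonzero(~row)) for row in flags]


def estimate(
    bank: ModelBank,
    ref: ReferenceSummary,
    X_app: np.ndarray,
    detection: str = "consistency",
    estimator: str = "screened",
    n_keep: int = 6,
) -> np.ndarray:
    """Log-eGFR for every application row, per detection/estimator pair.

    ``estimator='naive'`` ignores detection entirely and applies the full
    eight-marker model to the raw rows.  Under multivariate detection the
    rows are Winsorized first and the estimator then uses all eight cleaned
    predictors (per-marker trimming does not apply); ``knn`` and
    ``screened`` therefore coincide with the full model on the cleaned
    rows.  If univariate detection flags all eight markers of a row, the
    row falls back to the full-model prediction at its Winsorized values
    (with a warning) rather than refusing to predict.
    """
    X = np.atleast_2d(np.asarray(X_app, dtype=float))

    if estimator == "naive" or detection in (None, "none"):
        return bank.predict_full(X)
    if detection not in DETECTION_METHODS or estimator not in ESTIMATORS:
        raise ValueError(
            f"unknown method pair ({detection!r}, {estimator!r}); "
            f"detection in {DETECTION_METHODS}, estimator in {ESTIMATORS} or 'naive'"
        )
    if ref is None and detection in ("univariate", "multivariate"):
        raise ValueError(f"{detection} detection requires a ReferenceSummary")

    if detection == "multivariate":
        cleaned = winsorize_multivariate(ref, X).cleaned
        if estimator == "trimmed":
            ghat = bank.univariate_estimates(cleaned)
            return np.array([
                predict_weighted_trimmed(bank, g, range(_P)) for g in ghat
            ])
        # knn and screened both use the full model on all 8 cleaned markers
        return bank.predict_full(cleaned)

    ghat_all = bank.univariate_estimates(X)
    if detection == "univariate":
        flags = detect_univariate(ref, X).flags
        clean_sets = _clean_sets_univariate(flags)
    else:  # consistency
        clean_sets = select_consistent_matrix(ghat_all, n_keep=n_keep)

    out = np.empty(len(X))
    all_markers = tuple(range(_P))
    fallback_rows = [i for i, s in enumerate(clean_sets) if len(s) == 0]
    if fallback_rows:
        warnings.warn(
            f"{len(fallback_rows)} row(s) had all markers flagged; "
            "falling back to the full model on Winsorized values"
        )
        wins = winsorize_multivariate(ref, X[fallback_rows]).cleaned
        out[fallback_rows] = bank.predict_full(wins)

    for i, clean in enumerate(clean_sets):
        if len(clean) == 0:
            continue
        if estimator == "trimmed":
            out[i] = predict_weighted_trimmed(bank, ghat_all[i], clean)
        elif estimator == "knn":
            if clean == all_markers:
                out[i] = bank.predict_full(X[i])[0]
            else:
                out[i] = predict_knn_marginalized(bank, X[i], clean)
        else:  # screened
            out[i] = predict_screened(bank, X[i], clean)
    return out


def method_grid(include_naive: bool = False) -> list[tuple[str, str]]:
    """The 3 x 3 grid of (detection, estimator) pairs, optionally + naive."""
    grid = [(d, e) for d in DETECTION_METHODS for e in ESTIMATORS]
    if include_naive:
        grid.append(("none", "naive"))
    return grid


# ---------------------------------------------------------------------------
# scikit-learn front end
# ---------------------------------------------------------------------------

class PanelGFREstimator(BaseEstimator, RegressorMixin):
    """Panel GFR regressor robust to outlying predictors at prediction time.

    Fit on development data (X = log-scale marker matrix with the 8 panel
    columns in canonical order, y = log mGFR); predictions on application
    data first detect outlying markers per row and then estimate log GFR
    from the trustworthy ones.

    Parameters
    ----------
    detection : {'univariate', 'multivariate', 'consistency', 'none'}
        Outlier-detection strategy applied to application rows.
    estimator : {'trimmed', 'knn', 'screened', 'naive'}
        Robust estimation approach ('naive' = plain full-model OLS).
    n_keep : int
        Markers retained by consistency screening (6 = drop the two most
        inconsistent).
    k : int, optional
        KNN neighbor count; if None and ``estimator='knn'``, chosen by
        internal cross-validation over ``k_grid``.
    k_grid : sequence of int
        Candidate neighbor counts for the internal choice.
    ridge : float
        Diagonal inflation for a singular development covariance.
    random_state : int
        Seed for the internal k-choice cross-validation.

    Attributes
    ----------
    bank_ : ModelBank
        All fitted development models.
    reference_ : ReferenceSummary
        Development summaries used for detection.
    n_features_in_ : int
    """

    def __init__(
        self,
        detection: str = "consistency",
        estimator: str = "screened",
        n_keep: int = 6,
        k: int | None = None,
        k_grid: Sequence[int] = DEFAULT_K_GRID,
        ridge: float = 0.0,
        random_state: int = 0,
    ):
        self.detection = detection
        self.estimator = estimator
        self.n_keep = n_keep
        self.k = k
        self.k_grid = k_grid
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[1] != _P:
            raise ValueError(f"expected {_P} marker columns, got {X.shape[1]}")
        self.n_features_in_ = X.shape[1]
        need_k = self.estimator == "knn" and self.k is None
        self.bank_ = fit_model_bank(
            (X, y),
            k_grid=self.k_grid if need_k else None,
            seed=self.random_state,
            k=self.k,
        )
        self.reference_ = fit_reference(X, ridge=self.ridge)
        return self

    def predict(self, X):
        check_is_fitted(self, "bank_")
        X = check_array(X)
        return estimate(
            self.bank_, self.reference_, X,
            detection=self.detection, estimator=self.estimator,
            n_keep=self.n_keep,
        )

    def predict_gfr(self, X):
        """Predictions on the natural mGFR scale (mL/min/1.73 m²)."""
        return np.exp(self.predict(X))
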