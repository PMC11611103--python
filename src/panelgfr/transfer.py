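"""Two-step transfer learning for population-specific GFR equations.

When an estimating equation must be tailored to a small target population
(tens of measured-GFR participants) and larger related source studies
exist, a two-step transfer estimator can outperform both the external
(pooled-source) model and a model fit on the target alone:

1. **pooled step** — an L1-penalized least-squares fit of log mGFR on the
   eight log markers over the transferable sources plus the target
   training rows yields rough coefficients ``w``;
2. **bias-correction step** — an L1-penalized fit of the target training
   residuals (log mGFR − X w) on the same design yields a sparse
   correction ``delta``; the final coefficients are ``beta = w + delta``.

Which sources are transferable is decided by an internal three-fold
cross-validation on the target training data: a source is kept when
transferring from it alone does not do worse than the target-only fit
(within a small margin of the fold-loss spread).  This guards against
negative transfer from sources whose marker–GFR relationship differs
systematically.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .core_data import MARKERS, CohortData
from .models import ModelBank, _ols, _xy
from .outliers import select_consistent_matrix

_P = len(MARKERS)

XY = tuple[np.ndarray, np.ndarray]


@dataclasses.dataclass
class TransferConfig:
    """Knobs of the transfer algorithm.

    ``epsilon0`` is the transferability margin: source s is kept when its
    3-fold CV loss on the target training data is at most the target-only
    loss plus ``epsilon0`` times the SD of the target-only fold losses.
    The default margin of one fold-loss SD keeps sources whose pooled fit
    performs indistinguishably from the target-only fit (the loss
    difference for a genuinely transferable source sits well inside the
    fold noise) while still rejecting systematically shifted sources,
    whose loss excess is many SDs.
    ``penalty='l1'`` uses cross-validated Lasso in both steps (the default;
    it stabilizes n=25 fits); ``'none'`` uses plain least squares, in which
    case the bias-correction step absorbs the pooled fit entirely and
    transfer reduces to the target-only model.
    """

    penalty: str = "l1"
    epsilon0: float = 1.0
    n_folds: int = 3
    n_alphas: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penalty not in ("l1", "none"):
            raise ValueError("penalty must be 'l1' or 'none'")


@dataclasses.dataclass
class TransferModel:
    """Fitted two-step transfer model: beta = w + delta, exactly."""

    w: np.ndarray                 # pooled-stage [intercept, 8 slopes]
    delta: np.ndarray             # bias-correction stage, same layout
    sources_used: tuple[str, ...]
    config: TransferConfig

    @property
    def beta(self) -> np.ndarray:
        return self.w + self.delta

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        b = self.beta
        return b[0] + X @ b[1:]

    def to_json(self, path) -> None:
        doc = {
            "w": self.w.tolist(),
            "delta": self.delta.tolist(),
            "sources_used": list(self.sources_used),
            "config": dataclasses.asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _as_xy(data) -> XY:
    if isinstance(data, CohortData):
        return data.X(), data.y()
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def _penalized_fit(X: np.ndarray, y: np.ndarray, config: TransferConfig,
                   seed: int) -> np.ndarray:
    """[intercept, slopes] from an L1 (or plain OLS) fit on standardized X."""
    if config.penalty == "none":
        return _ols(X, y)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - X.mean(axis=0)) / sd
    n_folds = min(config.n_folds, len(X))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = LassoCV(
            alphas=config.n_alphas, cv=n_folds, random_state=seed,
            max_iter=5000,
        ).fit(Z, y)
    slopes = model.coef_ / sd
    intercept = model.intercept_ - (X.mean(axis=0) * slopes).sum()
    return np.concatenate([[intercept], slopes])


def _two_step(sources_xy: Sequence[XY], target_xy: XY,
              config: TransferConfig, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Pooled fit then target bias correction; returns (w, delta)."""
    Xt, yt = target_xy
    if sources_xy:
        Xp = np.vstack([Xt] + [X for X, _ in sources_xy])
        yp = np.concatenate([yt] + [y for _, y in sources_xy])
    else:
        Xp, yp = Xt, yt
    w = _penalized_fit(Xp, yp, config, seed)
    resid = yt - (w[0] + Xt @ w[1:])
    delta = _penalized_fit(Xt, resid, config, seed + 1)
    return w, delta


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % n_folds
    return folds


def detect_transferable(
    sources: Mapping[str, CohortData | XY],
    target_train: CohortData | XY,
    seed: int = 0,
    config: TransferConfig | None = None,
) -> list[str]:
    """Decide which source studies are transferable to the target.

    For each source, three-fold CV on the target training rows compares
    (a) a target-only fit against (b) the pooled-stage fit on that source
    plus the target training folds (no bias correction — the correction
    stage could mask an arbitrarily shifted source); the source is kept
    when mean loss (b) <= mean loss (a) + epsilon0 * SD of (a)'s fold
    losses.  Squared error on the log scale throughout.  Deterministic for
    a fixed seed.
    """
    config = config or TransferConfig()
    Xt, yt = _as_xy(target_train)
    n = len(Xt)
    if n < 3 * config.n_folds:
        raise ValueError(
            f"target training set too small ({n} rows; need >= {3 * config.n_folds})"
        )
    if not sources:
        return []

    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, config.n_folds, rng)

    loss_a = np.empty(config.n_folds)
    fitted_a = []
    for f in range(config.n_folds):
        tr, va = folds != f, folds == f
        coef = _penalized_fit(Xt[tr], yt[tr], config, seed + 100 + f)
        fitted_a.append((tr, va, coef))
        loss_a[f] = np.mean((yt[va] - coef[0] - Xt[va] @ coef[1:]) ** 2)
    threshold = loss_a.mean() + config.epsilon0 * loss_a.std(ddof=0)

    kept = []
    for name, src in sources.items():
        sxy = _as_xy(src)
        loss_b = np.empty(config.n_folds)
        for f, (tr, va, _) in enumerate(fitted_a):
            Xp = np.vstack([Xt[tr], sxy[0]])
            yp = np.concatenate([yt[tr], sxy[1]])
            w = _penalized_fit(Xp, yp, config, seed + 200 + f)
            loss_b[f] = np.mean((yt[va] - w[0] - Xt[va] @ w[1:]) ** 2)
        if loss_b.mean() <= threshold:
            kept.append(name)
    return kept


def fit_transfer(
    sources: Mapping[str, CohortData | XY],
    target_train: CohortData | XY,
    config: TransferConfig | None = None,
    seed: int = 0,
) -> TransferModel:
    """Fit the two-step transfer model.

    Transferable sources are selected by :func:`detect_transferable`, then
    pooled with the target training rows for the rough fit; the
    bias-correction stage uses the target rows only.  With no transferable
    sources the pooled stage degenerates to the target-only fit.
    """
    config = config or TransferConfig()
    kept = (detect_transferable(sources, target_train, seed=seed, config=config)
            if sources else [])
    sources_xy = [_as_xy(sources[name]) for name in kept]
    w, delta = _two_step(sources_xy, _as_xy(target_train), config, seed)
    return TransferModel(w=w, delta=delta, sources_used=tuple(kept), config=config)


def predict_transfer(model: TransferModel, X_app: np.ndarray) -> np.ndarray:
    """Log eGFR = X beta (with intercept)."""
    return model.predict(X_app)


class RobustTransferPredictor:
    """Transfer learning composed with consistency screening.

    Application rows are first screened for their six most consistent
    markers (using the target model bank's univariate models); each row is
    then scored by a transfer model refit on that six-marker design
    (pooled step + bias correction restricted to the subset's columns),
    fitted lazily and cached per subset.
    """

    def __init__(
        self,
        sources: Mapping[str, CohortData | XY],
        target_train: CohortData | XY,
        bank_target: ModelBank,
        config: TransferConfig | None = None,
        seed: int = 0,
        n_keep: int = 6,
    ):
        self.config = config or TransferConfig()
        self.seed = seed
        self.n_keep = n_keep
        self.bank_target = bank_target
        self._target_xy = _as_xy(target_train)
        self._sources_xy = {name: _as_xy(src) for name, src in sources.items()}
        self.sources_used = tuple(
            detect_transferable(self._sources_xy, self._target_xy,
                                seed=seed, config=self.config)
            if self._sources_xy else ()
        )
        self._subset_models: dict[tuple[int, ...], np.ndarray] = {}

    def _subset_beta(self, subset: tuple[int, ...]) -> np.ndarray:
        if subset not in self._subset_models:
            cols = list(subset)
            Xt, yt = self._target_xy
            srcs = [(X[:, cols], y) for name, (X, y) in self._sources_xy.items()
                    if name in self.sources_used]
            w, delta = _two_step(srcs, (Xt[:, cols], yt), self.config, self.seed)
            self._subset_models[subset] = w + delta
        return self._subset_models[subset]

    def predict(self, X_app: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X_app, dtype=float))
        ghat = self.bank_target.univariate_estimates(X)
        subsets = select_consistent_matrix(ghat, n_keep=self.n_keep)
        out = np.empty(len(X))
        for i, s in enumerate(subsets):
            b = self._subset_beta(s)
            out[i] = b[0] + X[i, list(s)] @ b[1:]
        return out


def fit_transfer_robust(
    sources: Mapping[str, CohortData | XY],
    target_train: CohortData | XY,
    bank_target: ModelBank,
    config: TransferConfig | None = None,
    seed: int = 0,
) -> RobustTransferPredictor:
    """Transfer + consistency screening + screened (subset) estimation."""
    return RobustTransferPredictor(sources, target_train, bank_target,
                                   config=config, seed=seed)


class TransferGFREstimator(BaseEstimator, RegressorMixin):
    """scikit-learn front end for the two-step transfer model.

    Parameters
    ----------
    sources : mapping of study label -> (X, y) or CohortData
        Candidate source populations.
    penalty : {'l1', 'none'}
    epsilon0 : float
        Transferability margin (see :class:`TransferConfig`).
    random_state : int

    Attributes
    ----------
    coef_, intercept_ : final coefficients beta = w + delta.
    w_, delta_ : the two stages.
    sources_used_ : tuple of transferable source labels.
    """

    def __init__(self, sources=None, penalty: str = "l1",
                 epsilon0: float = 1.0, random_state: int = 0):
        self.sources = sources
        self.penalty = penalty
        self.epsilon0 = epsilon0
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.n_features_in_ = X.shape[1]
        config = TransferConfig(penalty=self.penalty, epsilon0=self.epsilon0,
                                seed=self.random_state)
        model = fit_transfer(self.sources or {}, (X, y), config=config,
                             seed=self.random_state)
        self.model_ = model
        self.w_ = model.w
        self.delta_ = model.delta
        self.coef_ = model.beta[1:]
        self.intercept_ = model.beta[0]
        self.sources_used_ = model.sources_used
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return self.model_.predict(X)
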