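"""Outlier detection for application-population predictors.

Three strategies for spotting problematic filtration-marker values in new
(application) data, all referenced to the development population:

* **univariate** — flag any marker value falling strictly outside the 1st
  or 99th percentile of that marker's development distribution;
* **multivariate** — compute each row's squared Mahalanobis distance from
  the development mean and Winsorize (shrink) distant rows onto the
  boundary of the chi-squared tolerance ellipse;
* **consistency** — among the eight single-marker GFR estimates for a row,
  keep the six that agree best (smallest sum of absolute pairwise
  differences), treating the two most discordant markers as outlying.

The first two need only development summary statistics, collected in
:class:`ReferenceSummary`; consistency screening needs the fitted
univariate model bank (see :mod:`panelgfr.models`).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from scipy import stats

from .core_data import MARKERS, CohortData

#: degrees of freedom of the tolerance ellipse = panel size
_P = len(MARKERS)


@dataclasses.dataclass
class ReferenceSummary:
    """Development-population summaries used for outlier detection.

    Attributes
    ----------
    q01, q99 : ndarray, shape (8,)
        Per-marker 1st / 99th percentiles of the development log markers.
    mu : ndarray, shape (8,)
        Development mean of the log markers.
    sigma : ndarray, shape (8, 8)
        Development covariance of the log markers (sample covariance).
    c : float
        Tolerance threshold: 99th percentile of chi-squared with 8 df.
    """

    q01: np.ndarray
    q99: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    c: float
    sigma_inv: np.ndarray = dataclasses.field(repr=False, default=None)

    def __post_init__(self) -> None:
        if np.any(self.q01 > self.q99):
            raise ValueError("q01 must not exceed q99 for any marker")
        if self.c <= 0:
            raise ValueError("tolerance threshold must be positive")
        if self.sigma_inv is None:
            self.sigma_inv = np.linalg.inv(self.sigma)


@dataclasses.dataclass
class OutlierReport:
    """Result of one detection pass over an application matrix.

    Which fields are populated depends on ``method``: per-row/per-marker
    ``flags`` (univariate), squared distances ``D2`` plus the Winsorized
    matrix ``cleaned`` (multivariate), or the per-row retained
    ``consistent_set`` and univariate estimates ``ghat`` (consistency).
    """

    method: str
    flags: np.ndarray | None = None
    D2: np.ndarray | None = None
    cleaned: np.ndarray | None = None
    consistent_set: list[tuple[int, ...]] | None = None
    ghat: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        if self.method == "univariate":
            return pd.DataFrame(self.flags, columns=list(MARKERS))
        if self.method == "multivariate":
            df = pd.DataFrame(self.cleaned, columns=[f"clean_{m}" for m in MARKERS])
            df.insert(0, "D2", self.D2)
            return df
        df = pd.DataFrame(self.ghat, columns=[f"ghat_{m}" for m in MARKERS])
        df["consistent_set"] = [
            "|".join(MARKERS[i] for i in s) for s in self.consistent_set
        ]
        return df


def fit_reference(
    dev: CohortData | np.ndarray,
    ridge: float = 0.0,
) -> ReferenceSummary:
    """Summarize the development log-marker distribution.

    Percentiles use the linear-interpolation convention; the mean and
    covariance are the classical (non-robust) estimates, as the detection
    rules are defined relative to the bulk of the development data.

    Parameters
    ----------
    dev : CohortData or (n, 8) array of log markers.
    ridge : float
        Added to the covariance diagonal when it is singular (e.g. a
        constant marker column); zero by default, in which case singular
        covariance raises.
    """
    X = dev.X() if isinstance(dev, CohortData) else np.asarray(dev, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 development rows")
    sigma = np.cov(X, rowvar=False)
    if ridge:
        sigma = sigma + ridge * np.eye(X.shape[1])
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0 or not np.isfinite(logdet) or np.linalg.cond(sigma) > 1e12:
        raise ValueError(
            "development covariance is singular; pass ridge > 0 to inflate the diagonal"
        )
    q01 = np.percentile(X, 1, axis=0)
    q99 = np.percentile(X, 99, axis=0)
    mu = X.mean(axis=0)
    c = float(stats.chi2.ppf(0.99, df=X.shape[1]))
    return ReferenceSummary(q01=q01, q99=q99, mu=mu, sigma=sigma, c=c)


def detect_univariate(ref: ReferenceSummary, X_app: np.ndarray) -> OutlierReport:
    """Flag values strictly outside the development 1st/99th percentiles.

    Boundary values (exactly at a percentile) are not flagged: only values
    *more extreme than* the percentile count as outliers.
    """
    X = np.asarray(X_app, dtype=float)
    flags = (X < ref.q01) | (X > ref.q99)
    return OutlierReport(method="univariate", flags=flags)


def mahalanobis_d2(ref: ReferenceSummary, X_app: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each row from the development mean."""
    diff = np.asarray(X_app, dtype=float) - ref.mu
    return np.einsum("ij,jk,ik->i", diff, ref.sigma_inv, diff)


def winsorize_multivariate(ref: ReferenceSummary, X_app: np.ndarray) -> OutlierReport:
    """Shrink distant rows onto the development tolerance ellipse.

    A row with squared Mahalanobis distance D² within the chi-squared
    threshold ``c`` is returned unchanged; otherwise its deviation from the
    development mean is scaled by ``sqrt(c / D²)`` so that the cleaned row
    lies exactly on the ellipse D² = c.  All eight cleaned predictors are
    then usable downstream — no per-marker trimming is implied.
    """
    X = np.asarray(X_app, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("application matrix contains non-finite values")
    D2 = mahalanobis_d2(ref, X)
    cleaned = X.copy()
    outside = D2 > ref.c  # rows inside the ellipse stay bitwise unchanged
    if outside.any():
        factor = np.sqrt(ref.c / D2[outside])
        cleaned[outside] = ref.mu + factor[:, None] * (X[outside] - ref.mu)
    return OutlierReport(method="multivariate", D2=D2, cleaned=cleaned)


def pairwise_disagreement(ghat: Sequence[float], subset: Sequence[int]) -> float:
    """Sum of absolute pairwise differences of the estimates in ``subset``."""
    g = np.asarray(ghat, dtype=float)
    return float(sum(abs(g[j] - g[k]) for j, k in itertools.combinations(subset, 2)))


def select_consistent(
    ghat: Sequence[float], n_keep: int = 6
) -> tuple[tuple[int, ...], float]:
    """Pick the most mutually consistent subset of single-marker estimates.

    Enumerates all C(8, n_keep) subsets and returns the one minimizing the
    sum of absolute pairwise differences of its univariate GFR estimates;
    ties go to the lexicographically smallest marker-index set (the
    enumeration order of :func:`itertools.combinations`).

    Returns
    -------
    (subset, score) : the retained marker indices and its disagreement sum.
    """
    g = np.asarray(ghat, dtype=float)
    if g.ndim != 1:
        raise ValueError("ghat must be a flat vector of univariate estimates")
    best_subset, best_score = None, np.inf
    for subset in itertools.combinations(range(len(g)), n_keep):
        score = pairwise_disagreement(g, subset)
        if score < best_score:
            best_subset, best_score = subset, score
    return best_subset, best_score


def select_consistent_matrix(
    ghat_matrix: np.ndarray, n_keep: int = 6
) -> list[tuple[int, ...]]:
    """Vectorized :func:`select_consistent` over rows of an (n, 8) matrix."""
    G = np.asarray(ghat_matrix, dtype=float)
    subsets = list(itertools.combinations(range(G.shape[1]), n_keep))
    pairs_per_subset = [list(itertools.combinations(s, 2)) for s in subsets]
    # |g_j - g_k| for all 28 pairs, then sum the relevant pairs per subset
    all_pairs = list(itertools.combinations(range(G.shape[1]), 2))
    pair_index = {p: i for i, p in enumerate(all_pairs)}
    absdiff = np.abs(G[:, [p[0] for p in all_pairs]] - G[:, [p[1] for p in all_pairs]])
    scores = np.stack(
        [absdiff[:, [pair_index[p] for p in pairs]].sum(axis=1)
         for pairs in pairs_per_subset],
        axis=1,
    )
    winners = np.argmin(scores, axis=1)  # argmin takes the first (lexicographic) tie
    return [subsets[w] for w in winners]
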