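"""Simulated contamination of application-population predictors.

Application populations (e.g. patients with acute or chronic illness) can
show far more outlying filtration-marker values than development cohorts,
driven by non-GFR determinants.  This module emulates that: a random
fraction of application rows (default 10%) has selected markers replaced
with outliers, on the log scale, under one of three models:

* ``mean``          — shift the value by ``shift`` development SDs;
* ``variance``      — inflate the deviation from the development mean by
  ``sqrt(inflate)``;
* ``mean_variance`` — both.

Default magnitudes (3 development SDs, variance multiplier 9) make
contaminated values conspicuous jointly yet often *not* beyond the
univariate 1st/99th percentile bounds — the regime in which univariate
detection underperforms and multivariate / consistency methods matter.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .core_data import MARKERS

_DIRECTIONS = ("up", "down", "random-sign")
_MODELS = ("mean", "variance", "mean_variance")


@dataclasses.dataclass
class ContaminationSpec:
    """What to contaminate and how.

    ``shift`` is in units of the development log-scale SD of each marker;
    ``inflate`` multiplies the variance of the deviation from the
    development mean.  ``direction`` applies to the mean shift: 'up',
    'down', or an independent random sign per (row, marker).
    """

    markers: tuple[str, ...]
    model: str = "mean_variance"
    fraction: float = 0.10
    shift: float = 3.0
    inflate: float = 9.0
    direction: str = "random-sign"
    seed: int = 0

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        if not self.markers:
            raise ValueError("markers must be nonempty")
        unknown = [m for m in self.markers if m not in MARKERS]
        if unknown:
            raise ValueError(f"unknown marker(s) {unknown}; panel is {list(MARKERS)}")
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        if self.shift < 0:
            raise ValueError("shift must be non-negative")
        if self.inflate < 1:
            raise ValueError("inflate must be >= 1")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")

    @property
    def marker_indices(self) -> list[int]:
        return [MARKERS.index(m) for m in self.markers]


@dataclasses.dataclass
class ContaminationMask:
    """Which rows/markers were altered, plus the spec that did it."""

    rows: np.ndarray          # (n,) bool, row was selected
    cells: np.ndarray         # (n, 8) bool, marker altered in that row
    spec: ContaminationSpec

    @property
    def n_altered(self) -> int:
        return int(self.rows.sum())

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.cells, columns=[f"altered_{m}" for m in MARKERS])
        df.insert(0, "altered_row", self.rows)
        return df


def contaminate(
    X_test: np.ndarray,
    dev_mean: Sequence[float],
    dev_sd: Sequence[float],
    spec: ContaminationSpec,
) -> tuple[np.ndarray, ContaminationMask]:
    """Contaminate selected markers in a random subset of test rows.

    Exactly ``round(fraction * n)`` rows are drawn without replacement
    (round-half-even, so masks are reproducible); within each selected row
    every marker in ``spec.markers`` is altered on the log scale.  All
    other entries are returned bitwise unchanged.

    Parameters
    ----------
    X_test : (n, 8) log-scale application marker matrix.
    dev_mean, dev_sd : per-marker development log-scale mean and SD.
    """
    X = np.asarray(X_test, dtype=float).copy()
    mu = np.asarray(dev_mean, dtype=float)
    sd = np.asarray(dev_sd, dtype=float)
    n = len(X)
    rng = np.random.default_rng(spec.seed)

    n_altered = int(round(spec.fraction * n))
    selected = rng.choice(n, size=n_altered, replace=False)
    rows = np.zeros(n, dtype=bool)
    rows[selected] = True
    cells = np.zeros_like(X, dtype=bool)

    idx = spec.marker_indices
    for j in idx:
        cells[selected, j] = True
        x = X[selected, j]
        if spec.model in ("variance", "mean_variance"):
            x = mu[j] + np.sqrt(spec.inflate) * (x - mu[j])
        if spec.model in ("mean", "mean_variance"):
            if spec.direction == "up":
                s = 1.0
            elif spec.direction == "down":
                s = -1.0
            else:
                s = rng.choice([-1.0, 1.0], size=n_altered)
            x = x + s * spec.shift * sd[j]
        X[selected, j] = x

    return X, ContaminationMask(rows=rows, cells=cells, spec=spec)
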