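"""Participant-level cohort container, tabular I/O, and preprocessing.

The package works throughout on a table with one row per participant:
a study label, measured GFR (mGFR, mL/min/1.73 m²) with the clearance
method used to measure it, and serum concentrations of the eight panel
filtration markers.  Preprocessing follows the standard pipeline for GFR
estimating equations: harmonize mGFR across clearance methods, drop
incomplete rows, and log-transform the response and every predictor.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Canonical panel ordering.  Five metabolites and three low-molecular-weight
#: proteins; subset indices used elsewhere (e.g. six-marker model keys) are
#: relative to this order, so it must never change.
MARKERS: tuple[str, ...] = (
    "creatinine",
    "cystatin_c",
    "b2m",
    "btp",
    "acetylthreonine",
    "phenylacetylglutamine",
    "pseudouridine",
    "tryptophan",
)

#: Clearance methods accepted in ``mgfr_method``.  Iothalamate is the
#: reference; iohexol and inulin clearances read ~5% low relative to it.
MGFR_METHODS: tuple[str, ...] = ("iothalamate", "iohexol", "inulin")

#: Multiplier applied to iohexol / inulin mGFR to align with iothalamate.
HARMONIZATION_FACTOR: float = 1.05


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


@dataclasses.dataclass
class CohortData:
    """Participant-level cohort table.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``id``, ``study``, ``mgfr``, ``mgfr_method`` and one column
        per marker in :data:`MARKERS`, all on the natural scale.  After
        :func:`log_transform`, ``log_mgfr`` and ``log_<marker>`` columns are
        present as well.
    harmonized : bool
        Whether iohexol/inulin mGFR values have already been rescaled.
    logged : bool
        Whether log columns have been populated.
    """

    frame: pd.DataFrame
    harmonized: bool = False
    logged: bool = False

    marker_names: tuple[str, ...] = MARKERS

    def __post_init__(self) -> None:
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names must be unique")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def studies(self) -> list[str]:
        return list(pd.unique(self.frame["study"]))

    # -- matrix accessors ---------------------------------------------------
    def X(self) -> np.ndarray:
        """Log-scale marker matrix, shape (n, 8), canonical column order."""
        self._require_logged()
        cols = [f"log_{m}" for m in self.marker_names]
        return self.frame[cols].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        """Log-scale mGFR vector."""
        self._require_logged()
        return self.frame["log_mgfr"].to_numpy(dtype=float)

    def _require_logged(self) -> None:
        if not self.logged:
            raise ValueError("cohort has not been log-transformed yet")

    def subset(self, mask: np.ndarray) -> "CohortData":
        """Row-subset, preserving flags."""
        return CohortData(
            self.frame.loc[np.asarray(mask)].reset_index(drop=True),
            harmonized=self.harmonized,
            logged=self.logged,
            marker_names=self.marker_names,
        )

    def split_by_study(self) -> dict[str, "CohortData"]:
        return {
            s: self.subset((self.frame["study"] == s).to_numpy())
            for s in self.studies
        }

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def load_cohort(
    source: str | Path | pd.DataFrame,
    schema: Mapping[str, str] | None = None,
) -> CohortData:
    """Read a delimited-text cohort table.

    Parameters
    ----------
    source : path or DataFrame
        CSV or TSV file (delimiter chosen by extension) or an in-memory
        frame.  A header row is required.
    schema : mapping, optional
        Maps canonical column names (``id``, ``study``, ``mgfr``,
        ``mgfr_method``, marker names) to the names used in the file.

    Returns
    -------
    CohortData
        Natural-scale values; no transforms applied.  Rows with non-positive
        mGFR or marker values are flagged in a boolean ``valid`` column
        rather than silently dropped.
    """
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        path = Path(source)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        frame = pd.read_csv(path, sep=sep)

    if schema:
        rename = {v: k for k, v in schema.items()}
        frame = frame.rename(columns=rename)

    required = ["id", "study", "mgfr", "mgfr_method", *MARKERS]
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"required column missing: {col!r}")

    numeric = ["mgfr", *MARKERS]
    for col in numeric:
        frame[col] = pd.to_numeric(frame[col], errors="raise")

    values = frame[numeric].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        nonpositive = values <= 0
    frame["valid"] = ~np.any(nonpositive & np.isfinite(values), axis=1)
    return CohortData(frame.reset_index(drop=True))


def harmonize_mgfr(cohort: CohortData) -> CohortData:
    """Align iohexol and inulin mGFR with iothalamate clearance.

    Values measured by iohexol or inulin clearance are multiplied by
    :data:`HARMONIZATION_FACTOR` (1.05); iothalamate rows are unchanged.
    Refuses a second application.
    """
    if cohort.harmonized:
        raise ValueError("cohort is already harmonized; refusing to rescale twice")
    frame = cohort.frame.copy()
    methods = frame["mgfr_method"].astype(str)
    unknown = sorted(set(methods) - set(MGFR_METHODS))
    if unknown:
        raise ValueError(
            f"unknown mGFR method(s) {unknown}; accepted values: {list(MGFR_METHODS)}"
        )
    scale = np.where(methods.isin(["iohexol", "inulin"]), HARMONIZATION_FACTOR, 1.0)
    frame["mgfr"] = frame["mgfr"].to_numpy(dtype=float) * scale
    return CohortData(frame, harmonized=True, logged=cohort.logged,
                      marker_names=cohort.marker_names)


def exclude_incomplete(cohort: CohortData) -> tuple[CohortData, int]:
    """Complete-case filter: drop rows missing mGFR or any marker.

    Returns the filtered cohort and the number of rows removed.  Raises if
    nothing survives, since downstream fitting needs data.
    """
    cols = ["mgfr", *cohort.marker_names]
    frame = cohort.frame
    keep = frame[cols].notna().all(axis=1)
    if "valid" in frame.columns:
        keep &= frame["valid"].astype(bool)
    n_excluded = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all rows excluded: no complete cases remain")
    out = CohortData(frame.loc[keep].reset_index(drop=True),
                     harmonized=cohort.harmonized, logged=cohort.logged,
                     marker_names=cohort.marker_names)
    return out, n_excluded


def log_transform(cohort: CohortData) -> CohortData:
    """Populate natural-log columns for mGFR and every marker."""
    frame = cohort.frame.copy()
    for col in ["mgfr", *cohort.marker_names]:
        vals = frame[col].to_numpy(dtype=float)
        bad = ~(vals > 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-positive value in column {col!r} at row {i}: {vals[i]}"
            )
        frame[f"log_{col}"] = np.log(vals)
    return CohortData(frame, harmonized=cohort.harmonized, logged=True,
                      marker_names=cohort.marker_names)


def preprocess(cohort: CohortData) -> tuple[CohortData, int]:
    """Harmonize, complete-case filter, and log-transform in one step."""
    cohort = harmonize_mgfr(cohort)
    cohort, n_excluded = exclude_incomplete(cohort)
    return log_transform(cohort), n_excluded


@dataclasses.dataclass
class FoldPlan:
    """Cross-validation plan: per-iteration fold index for every row.

    ``assignments`` has shape (n_iterations, n_rows); entry (i, r) is the
    fold (0..n_folds-1) in which row r is a *test* row during iteration i.
    Within every iteration the folds partition the rows into near-equal
    groups (sizes differ by at most 1).
    """

    n_iterations: int
    n_folds: int
    assignments: np.ndarray
    seed: int

    def test_mask(self, iteration: int, fold: int) -> np.ndarray:
        return self.assignments[iteration] == fold


def plan_folds(
    n_rows_or_cohort: int | CohortData,
    n_iterations: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    stratify_by_study: bool = False,
) -> FoldPlan:
    """Plan repeated K-fold cross-validation assignments.

    Rows are shuffled with a seeded generator and dealt into folds
    round-robin, so fold sizes differ by at most one.  With
    ``stratify_by_study`` the deal happens within each study label.
    """
    if isinstance(n_rows_or_cohort, CohortData):
        cohort = n_rows_or_cohort
        n_rows = len(cohort)
    else:
        cohort = None
        n_rows = int(n_rows_or_cohort)
    if n_folds > n_rows:
        raise ValueError(f"n_folds={n_folds} exceeds number of rows ({n_rows})")
    if stratify_by_study and cohort is None:
        raise ValueError("stratified folds require a CohortData input")

    rng = np.random.default_rng(seed)
    assignments = np.empty((n_iterations, n_rows), dtype=np.int64)
    for i in range(n_iterations):
        if stratify_by_study:
            for s in cohort.studies:
                idx = np.flatnonzero((cohort.frame["study"] == s).to_numpy())
                perm = rng.permutation(idx)
                assignments[i, perm] = np.arange(len(perm)) % n_folds
        else:
            perm = rng.permutation(n_rows)
            assignments[i, perm] = np.arange(n_rows) % n_folds
    return FoldPlan(n_iterations=n_iterations, n_folds=n_folds,
                    assignments=assignments, seed=seed)
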