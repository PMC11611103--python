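"""Accuracy metrics, cross-validation harness, and experiment templates.

Everything is evaluated on the log scale (where the models are linear and
residual variance is stable): RMSE of log errors, mean log bias (positive
= mGFR underestimated; its exponential is the mGFR/eGFR ratio), and the
clinical P30 (share of estimates within 30% of measured GFR, boundary
inclusive).

The harness runs repeated K-fold cross-validation with strict train/test
separation: all development summaries and models are fit on training
folds only, and simulated contamination — when requested — touches test
rows only.  Three experiment templates mirror the questions a robust
panel-eGFR method must answer: how much does contaminating each marker
(or pair) hurt each detection/estimation combination; how do external,
study-specific, and transfer models compare as target data grows; and
what does combining consistency screening with transfer buy at small
target sizes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .contamination import ContaminationSpec, contaminate
from .core_data import MARKERS, CohortData, FoldPlan, plan_folds
from .models import (
    choose_k,
    estimate,
    fit_model_bank,
    method_grid,
    _ols,
)
from .outliers import fit_reference
from .synthetic import PanelDesign, generate_multistudy
from .transfer import TransferConfig, fit_transfer, fit_transfer_robust

_P = len(MARKERS)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_positive(*vectors) -> list[np.ndarray]:
    out = []
    for v in vectors:
        a = np.asarray(v, dtype=float)
        if np.any(a <= 0):
            raise ValueError("metric inputs must be strictly positive (natural scale)")
        out.append(a)
    lengths = {len(a) for a in out}
    if len(lengths) != 1:
        raise ValueError("mgfr and egfr must have equal length")
    return out


def rmse_log(mgfr, egfr) -> float:
    """Root mean squared error of log mGFR - log eGFR."""
    m, e = _check_positive(mgfr, egfr)
    return float(np.sqrt(np.mean((np.log(m) - np.log(e)) ** 2)))


def bias_log(mgfr, egfr) -> float:
    """Mean of log mGFR - log eGFR; positive values are underestimates."""
    m, e = _check_positive(mgfr, egfr)
    return float(np.mean(np.log(m) - np.log(e)))


def p30(mgfr, egfr) -> float:
    """Proportion of estimates within 30% of measured GFR (inclusive)."""
    m, e = _check_positive(mgfr, egfr)
    return float(np.mean(np.abs(e - m) / m <= 0.30))


def _metrics_from_logs(y_log: np.ndarray, pred_log: np.ndarray) -> dict:
    err = y_log - pred_log
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "bias": float(np.mean(err)),
        "p30": float(np.mean(np.abs(np.exp(pred_log - y_log) - 1.0) <= 0.30)),
    }


@dataclasses.dataclass
class EvalResult:
    """Cross-validated accuracy for one method pair.

    Grand metrics are means of the per-iteration metrics (each iteration
    predicts every row exactly once).
    """

    detection: str
    estimator: str
    rmse: float
    bias: float
    p30: float
    per_iteration: pd.DataFrame
    spec: ContaminationSpec | None = None


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

def _derive_spec_seed(spec: ContaminationSpec, base_seed: int,
                      iteration: int, fold: int) -> ContaminationSpec:
    derived = (np.random.SeedSequence([base_seed, spec.seed, iteration, fold])
               .generate_state(1)[0] % (2**31))
    return dataclasses.replace(spec, seed=int(derived))


def cross_validate_methods(
    cohort: CohortData,
    methods: Sequence[tuple[str, str]],
    spec: ContaminationSpec | None = None,
    plan: FoldPlan | None = None,
    n_iterations: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    k: int | None = None,
    n_keep: int = 6,
) -> list[EvalResult]:
    """Repeated K-fold CV of several (detection, estimator) pairs at once.

    The model bank and reference summaries are fitted per fold on training
    rows only and shared across method pairs; test rows are optionally
    contaminated (with a seed derived per iteration and fold, so runs are
    reproducible and a fraction-0 spec is a bitwise no-op).

    ``k`` fixes the KNN neighbor count; if any method needs KNN and ``k``
    is None, it is chosen once by cross-validation within the first
    training fold and reused.
    """
    X, y = cohort.X(), cohort.y()
    if plan is None:
        plan = plan_folds(len(cohort), n_iterations=n_iterations,
                          n_folds=n_folds, seed=seed)
    needs_k = any(e == "knn" for _, e in methods)

    rows = []
    for it in range(plan.n_iterations):
        preds = {me: np.empty(len(X)) for me in methods}
        for f in range(plan.n_folds):
            test = plan.test_mask(it, f)
            train = ~test
            if needs_k and k is None:
                k = choose_k((X[train], y[train]), n_iterations=5, seed=seed)
            bank = fit_model_bank((X[train], y[train]), k=k)
            # the reference summary is only defined for a non-degenerate
            # development covariance; naive/consistency paths never need it
            needs_ref = any(d in ("univariate", "multivariate") for d, _ in methods)
            ref = fit_reference(X[train]) if needs_ref else None
            X_test = X[test]
            if spec is not None:
                fold_spec = _derive_spec_seed(spec, seed, it, f)
                X_test, _ = contaminate(X_test, X[train].mean(axis=0),
                                        bank.dev_sd, fold_spec)
            for det, est in methods:
                preds[(det, est)][test] = estimate(
                    bank, ref, X_test, detection=det, estimator=est,
                    n_keep=n_keep,
                )
        for me in methods:
            rows.append({"iteration": it, "detection": me[0], "estimator": me[1],
                         **_metrics_from_logs(y, preds[me])})

    per_iter = pd.DataFrame(rows)
    results = []
    for det, est in methods:
        sub = per_iter[(per_iter.detection == det) & (per_iter.estimator == est)]
        results.append(EvalResult(
            detection=det, estimator=est,
            rmse=float(sub.rmse.mean()), bias=float(sub.bias.mean()),
            p30=float(sub.p30.mean()), per_iteration=sub.reset_index(drop=True),
            spec=spec,
        ))
    return results


def cross_validate(
    cohort: CohortData,
    detection: str = "none",
    estimator: str = "naive",
    spec: ContaminationSpec | None = None,
    plan: FoldPlan | None = None,
    **kwargs,
) -> EvalResult:
    """Repeated K-fold CV for a single method pair."""
    return cross_validate_methods(cohort, [(detection, estimator)], spec=spec,
                                  plan=plan, **kwargs)[0]


# ---------------------------------------------------------------------------
# experiment templates
# ---------------------------------------------------------------------------

def run_contamination_grid(
    cohort: CohortData,
    targets: Sequence[Sequence[str]] | None = None,
    models: Sequence[str] = ("mean", "variance", "mean_variance"),
    methods: Sequence[tuple[str, str]] | None = None,
    n_iterations: int = 3,
    n_folds: int = 10,
    seed: int = 0,
    k: int | None = 20,
    fraction: float = 0.10,
    shift: float = 3.0,
    inflate: float = 9.0,
) -> pd.DataFrame:
    """Sweep contamination targets x models x method pairs.

    ``targets`` is a list of marker groups to contaminate together (single
    markers and/or pairs); the default sweeps each of the eight markers
    singly plus the canonical pairs mixing strong and weak predictors.
    Returns a tidy long-format table with one row per cell and method.
    """
    if targets is None:
        targets = [[m] for m in MARKERS] + [
            ["pseudouridine", "cystatin_c"],
            ["cystatin_c", "creatinine"],
            ["cystatin_c", "tryptophan"],
            ["tryptophan", "phenylacetylglutamine"],
        ]
    if methods is None:
        methods = method_grid(include_naive=True)

    out = []
    for group in targets:
        for model in models:
            spec = ContaminationSpec(markers=tuple(group), model=model,
                                     fraction=fraction, shift=shift,
                                     inflate=inflate, seed=seed)
            results = cross_validate_methods(
                cohort, methods, spec=spec, n_iterations=n_iterations,
                n_folds=n_folds, seed=seed, k=k,
            )
            for r in results:
                out.append({
                    "contaminated": "+".join(group), "model": model,
                    "detection": r.detection, "estimator": r.estimator,
                    "rmse": r.rmse, "bias": r.bias, "p30": r.p30,
                })
    return pd.DataFrame(out)


def run_learning_curve(
    design: PanelDesign,
    target_study: str,
    sizes: Sequence[int] = (25, 50, 100, 200),
    n_iterations: int = 10,
    seed: int = 0,
    transfer_config: TransferConfig | None = None,
) -> pd.DataFrame:
    """External vs study-specific vs transfer models across training sizes.

    For each size and iteration, a random sample of the target study is
    the training set and the remaining target rows are the test set.  The
    external model (all other studies pooled, no target data) is constant
    across sizes by construction.
    """
    if target_study not in design.names:
        raise ValueError(f"{target_study!r} not in design studies {design.names}")
    cohort = generate_multistudy(design)
    by_study = cohort.split_by_study()
    target = by_study[target_study]
    Xt_all, yt_all = target.X(), target.y()
    n_target = len(Xt_all)
    if max(sizes) >= n_target:
        raise ValueError(f"max size {max(sizes)} must be below the target "
                         f"study size ({n_target})")
    sources = {s: (c.X(), c.y()) for s, c in by_study.items() if s != target_study}

    X_src = np.vstack([xy[0] for xy in sources.values()])
    y_src = np.concatenate([xy[1] for xy in sources.values()])
    ext_coef = _ols(X_src, y_src)

    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for it in range(n_iterations):
            idx = rng.permutation(n_target)
            tr, te = idx[:size], idx[size:]
            Xtr, ytr, Xte, yte = Xt_all[tr], yt_all[tr], Xt_all[te], yt_all[te]

            ext_pred = ext_coef[0] + Xte @ ext_coef[1:]
            own_coef = _ols(Xtr, ytr)
            own_pred = own_coef[0] + Xte @ own_coef[1:]
            tm = fit_transfer(sources, (Xtr, ytr), config=transfer_config,
                              seed=int(rng.integers(2**31)))
            tr_pred = tm.predict(Xte)

            for label, pred in (("external", ext_pred),
                                ("target_only", own_pred),
                                ("transfer", tr_pred)):
                rows.append({"size": size, "iteration": it, "model": label,
                             **_metrics_from_logs(yte, pred)})
    return pd.DataFrame(rows)


def run_combined_experiment(
    design: PanelDesign,
    n_target: int = 25,
    n_iterations: int = 10,
    seed: int = 0,
    studies: Sequence[str] | None = None,
    transfer_config: TransferConfig | None = None,
    fraction: float = 0.10,
    shift: float = 3.0,
    inflate: float = 9.0,
) -> pd.DataFrame:
    """Small-target experiment combining contamination, screening, transfer.

    Per study and iteration: a random sample of ``n_target`` rows trains,
    the rest test.  Conditions: (a) plain linear model, no contamination;
    (b) plain linear model with one (pseudouridine) or two (pseudouridine
    + cystatin-C) strongly predictive markers contaminated in 10% of test
    rows; (c) same contamination handled by consistency screening with
    screened (six-marker) estimation; (d) transfer learning from the other
    studies combined with the same screening.  Tidy long-format output.
    """
    cohort = generate_multistudy(design)
    by_study = cohort.split_by_study()
    names = list(studies) if studies is not None else design.names
    contam_sets = {"single": ("pseudouridine",),
                   "double": ("pseudouridine", "cystatin_c")}

    rng = np.random.default_rng(seed)
    rows = []
    for study in names:
        target = by_study[study]
        Xs, ys = target.X(), target.y()
        if n_target >= len(Xs):
            raise ValueError(f"n_target={n_target} >= study size {len(Xs)}")
        sources = {s: (c.X(), c.y()) for s, c in by_study.items() if s != study}
        for it in range(n_iterations):
            idx = rng.permutation(len(Xs))
            tr, te = idx[:n_target], idx[n_target:]
            Xtr, ytr, Xte, yte = Xs[tr], ys[tr], Xs[te], ys[te]
            bank = fit_model_bank((Xtr, ytr))
            ref = fit_reference(Xtr)
            it_seed = int(rng.integers(2**31))

            naive_clean = bank.predict_full(Xte)
            rows.append({"study": study, "iteration": it, "condition": "none",
                         "method": "naive", **_metrics_from_logs(yte, naive_clean)})

            robust = fit_transfer_robust(sources, (Xtr, ytr), bank,
                                         config=transfer_config, seed=it_seed)
            for label, markers in contam_sets.items():
                if fraction == 0:
                    Xc = Xte
                else:
                    spec = ContaminationSpec(markers=markers, fraction=fraction,
                                             shift=shift, inflate=inflate,
                                             model="mean_variance", seed=it_seed)
                    Xc, _ = contaminate(Xte, ref.mu, bank.dev_sd, spec)
                preds = {
                    "naive": bank.predict_full(Xc),
                    "consistency_screened": estimate(bank, ref, Xc,
                                                     detection="consistency",
                                                     estimator="screened"),
                    "transfer_screened": robust.predict(Xc),
                }
                for method, pred in preds.items():
                    rows.append({"study": study, "iteration": it,
                                 "condition": label, "method": method,
                                 **_metrics_from_logs(yte, pred)})
    return pd.DataFrame(rows)
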