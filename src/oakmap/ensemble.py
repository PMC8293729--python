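"""Four-algorithm SDM ensemble with TSS-weighted averaging.

Each region is fitted independently. For every one of the 15 pseudo-absence
replicates, a stratified 50/50 train/test split is drawn 30 times; each of
the four learner families — a logistic GLM, gradient-boosted trees, a
random forest and a small neural network — is fitted on the training half
and scored on the held-out half with the true skill statistic (TSS =
sensitivity + specificity - 1) at the TSS-maximizing threshold. The
per-region probability raster is the weighted mean of every converged run's
probability surface, weighted by max(TSS, 0), so better runs contribute
more and skill-free runs contribute nothing.

Hyperparameters are fixed, documented defaults (no search): 100 trees for
the forest and the boosted machine, one hidden layer of 8 units for the
network. A run counts as failed (``converged=False``) if fitting raises or
produces non-finite predictions; failed runs stay in the evaluation ledger
but are excluded from averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .grids import GridSpec
from .prep import PresenceAbsenceSet
from .synthetic import BiophysicalStack

__all__ = [
    "ConfusionCounts",
    "RunEvaluation",
    "FittedRun",
    "ProbabilityRaster",
    "ALGORITHMS",
    "make_algorithm",
    "tss",
    "best_threshold_tss",
    "cross_validate_region",
    "ensemble_predict",
    "exclude_unstable_algorithms",
    "evaluations_to_frame",
]

ALGORITHMS = ("glm", "gbm", "rf", "ann")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class RunEvaluation:
    region_id: int
    algorithm: str
    replicate_index: int  # 1..15
    repeat_index: int  # 1..30
    tss: float
    threshold: float
    converged: bool


@dataclass
class FittedRun:
    evaluation: RunEvaluation
    model: object
    variable_names: list[str]


@dataclass
class ProbabilityRaster:
    """TSS-weighted ensemble oak probability, NaN outside the region."""

    region_id: int
    values: np.ndarray
    grid: GridSpec
    provenance: dict[str, int]  # algorithm -> contributing run count


def make_algorithm(name: str, random_state: int):
    """Instantiate one learner family with its fixed default configuration."""
    if name == "glm":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=random_state)
        )
    if name == "gbm":
        return GradientBoostingClassifier(
            n_estimators=100, learning_rate=0.1, max_depth=3, random_state=random_state
        )
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=random_state)
    if name == "ann":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(8,), max_iter=300, random_state=random_state),
        )
    raise ValueError(f"unknown algorithm {name!r}")


def tss(c: ConfusionCounts) -> float:
    """True skill statistic: sensitivity + specificity - 1, in [-1, 1]."""
    if c.tp + c.fn == 0:
        raise ValueError("TSS undefined: no positive observations (tp + fn = 0)")
    if c.tn + c.fp == 0:
        raise ValueError("TSS undefined: no negative observations (tn + fp = 0)")
    sensitivity = c.tp / (c.tp + c.fn)
    specificity = c.tn / (c.tn + c.fp)
    return sensitivity + specificity - 1.0


def best_threshold_tss(
    scores: np.ndarray, labels: np.ndarray, grid_step: float = 0.01
) -> tuple[float, float]:
    """Threshold in {0, grid_step, ..., 1} maximizing TSS on (scores, labels).

    A pixel scores positive when ``score >= threshold``. Ties are broken
    toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to evaluate TSS")
    thresholds = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    pred = scores[:, None] >= thresholds[None, :]
    pos = labels[:, None].astype(bool)
    tp = (pred & pos).sum(axis=0)
    fp = (pred & ~pos).sum(axis=0)
    tss_vec = tp / n_pos + (n_neg - fp) / n_neg - 1.0
    best = int(np.argmax(tss_vec))  # first max -> smallest threshold
    return float(thresholds[best]), float(tss_vec[best])


def cross_validate_region(
    data: PresenceAbsenceSet,
    algorithms: tuple[str, ...] = ALGORITHMS,
    n_repeats: int = 30,
    split: float = 0.5,
    seed: int = 0,
) -> tuple[list[RunEvaluation], list[FittedRun]]:
    """Repeated stratified cross-validation over all pseudo-absence replicates.

    Returns the complete evaluation ledger — ``len(algorithms) x
    k_replicates x n_repeats`` rows, failures included with
    ``converged=False`` — together with the converged fitted runs needed for
    prediction. Fully deterministic for a fixed seed.
    """
    if not algorithms:
        raise ValueError("need at least one algorithm")
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    root = np.random.default_rng(seed)
    evaluations: list[RunEvaluation] = []
    fitted: list[FittedRun] = []
    for rep in range(data.k_replicates):
        X, y = data.design(rep)
        if min(int(y.sum()), int(len(y) - y.sum())) < 2:
            raise ValueError("need at least 2 records per class")
        for repeat in range(n_repeats):
            split_seed = int(root.integers(2**31))
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, train_size=split, stratify=y, random_state=split_seed
            )
            for name in algorithms:
                model_seed = int(root.integers(2**31))
                model = make_algorithm(name, model_seed)
                converged = True
                tss_val = np.nan
                thr = np.nan
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        model.fit(X_tr, y_tr)
                        scores = model.predict_proba(X_te)[:, 1]
                    if not np.all(np.isfinite(scores)):
                        raise FloatingPointError("non-finite predictions")
                    thr, tss_val = best_threshold_tss(scores, y_te)
                except Exception:
                    converged = False
                ev = RunEvaluation(
                    region_id=data.region_id,
                    algorithm=name,
                    replicate_index=rep + 1,
                    repeat_index=repeat + 1,
                    tss=float(tss_val),
                    threshold=float(thr),
                    converged=converged,
                )
                evaluations.append(ev)
                if converged:
                    fitted.append(
                        FittedRun(evaluation=ev, model=model, variable_names=data.variable_names)
                    )
    return evaluations, fitted


def evaluations_to_frame(evaluations: list[RunEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": e.region_id,
                "algorithm": e.algorithm,
                "replicate": e.replicate_index,
                "repeat": e.repeat_index,
                "tss": e.tss,
                "threshold": e.threshold,
                "converged": e.converged,
            }
            for e in evaluations
        ]
    )


def ensemble_predict(
    stack: BiophysicalStack,
    fitted_runs: list[FittedRun],
    region_id: int | None = None,
    algorithms: tuple[str, ...] | None = None,
    per_algorithm: bool = False,
) -> ProbabilityRaster:
    """TSS-weighted mean probability surface over converged runs.

    Per pixel: ``sum_i w_i p_i / sum_i w_i`` with ``w_i = max(TSS_i, 0)``;
    negative-skill runs get zero weight so the result stays a convex
    combination. ``per_algorithm=True`` first averages runs within each
    algorithm, then weights algorithms by their mean TSS (a two-stage
    variant; the default single-stage weighting is equivalent in
    expectation). Pixels outside the region or with NoData covariates are
    NaN.
    """
    runs = [
        r
        for r in fitted_runs
        if r.evaluation.converged
        and (region_id is None or r.evaluation.region_id == region_id)
        and (algorithms is None or r.evaluation.algorithm in algorithms)
    ]
    if not runs:
        raise ValueError("no converged runs to ensemble")
    weights = np.array([max(r.evaluation.tss, 0.0) for r in runs])
    if weights.sum() == 0:
        raise ValueError("all ensemble weights are zero (no run with TSS > 0)")

    grid = stack.grid
    mask = np.ones(grid.shape, dtype=bool)
    if region_id is not None:
        mask &= stack.region_id == region_id
    var_names = runs[0].variable_names
    finite = np.ones(grid.shape, dtype=bool)
    for name in var_names:
        finite &= np.isfinite(stack.layers[name])
    mask &= finite

    rows, cols = np.nonzero(mask)
    X = stack.covariates_at(rows, cols)[var_names].to_numpy(dtype=float)

    acc = np.zeros(len(rows))
    provenance: dict[str, int] = {}
    if per_algorithm:
        alg_names = sorted({r.evaluation.algorithm for r in runs})
        alg_acc = np.zeros(len(rows))
        alg_w = 0.0
        for alg in alg_names:
            sub = [r for r in runs if r.evaluation.algorithm == alg]
            mean_tss = float(np.mean([r.evaluation.tss for r in sub]))
            w = max(mean_tss, 0.0)
            if w == 0:
                provenance[alg] = len(sub)
                continue
            p = np.zeros(len(rows))
            for r in sub:
                p += r.model.predict_proba(X)[:, 1]
            alg_acc += w * p / len(sub)
            alg_w += w
            provenance[alg] = len(sub)
        if alg_w == 0:
            raise ValueError("all ensemble weights are zero (no run with TSS > 0)")
        acc = alg_acc / alg_w
    else:
        wsum = 0.0
        for r, w in zip(runs, weights):
            provenance[r.evaluation.algorithm] = provenance.get(r.evaluation.algorithm, 0) + 1
            if w == 0:
                continue
            acc += w * r.model.predict_proba(X)[:, 1]
            wsum += w
        acc /= wsum

    values = np.full(grid.shape, np.nan)
    values[rows, cols] = np.clip(acc, 0.0, 1.0)
    rid = region_id if region_id is not None else -1
    return ProbabilityRaster(region_id=rid, values=values, grid=grid, provenance=provenance)


def exclude_unstable_algorithms(
    evaluations: list[RunEvaluation] | pd.DataFrame,
    min_converged_fraction: float = 0.5,
) -> tuple[dict[int, list[str]], pd.DataFrame]:
    """Drop, per region, algorithms whose converged-run fraction is too low.

    Returns the retained algorithm list per region and a report frame with
    each (region, algorithm) convergence fraction and its verdict. A region
    in which no algorithm survives raises.
    """
    frame = (
        evaluations
        if isinstance(evaluations, pd.DataFrame)
        else evaluations_to_frame(evaluations)
    )
    if frame.empty:
        raise ValueError("empty evaluation ledger")
    report = (
        frame.groupby(["region", "algorithm"])["converged"]
        .mean()
        .rename("converged_fraction")
        .reset_index()
    )
    report["retained"] = report["converged_fraction"] >= min_converged_fraction
    retained: dict[int, list[str]] = {}
    for region, grp in report.groupby("region"):
        kept = sorted(grp.loc[grp["retained"], "algorithm"])
        if not kept:
            raise ValueError(f"no algorithm survives in region {region}")
        retained[int(region)] = kept
    return retained, report
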