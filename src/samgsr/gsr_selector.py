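"""Gene-set reduction, union-of-cores feature selection, and grid-search tuning.

The reduction step turns a significant gene set into a concise "core": order
the members by decreasing ``|d|``, and for k = 1, 2, ... test the complement
(everything below the top k) with the set-level permutation test. The core is
the shortest prefix whose complement is no longer significant at threshold
``c``; by convention the empty complement has p-value 1, so the full set is
the worst case and termination is guaranteed.

Two knobs jointly control sparsity of the final model: ``alpha``, the
set-level significance cut deciding which sets are reduced at all, and ``c``,
the complement-significance threshold deciding how deep each reduction goes.
Both are tuned by a grid search under stratified k-fold cross-validation,
optimizing mean misclassification error with ties broken toward sparser
models (then smaller alpha, then smaller c).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core_data import ExpressionStudy, GeneSetCollection, DISEASED
from .classifier_metrics import FittedClassifier, fit_classifier, evaluate
from .errors import ClassSizeError, EmptySelectionError
from .sam_engine import (
    PermutationEngine,
    PermutationScheme,
    build_permutation_scheme,
)

logger = logging.getLogger("samgsr")

DEFAULT_C_GRID = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
DEFAULT_ALPHA_GRID = (0.01, 0.05, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class ReductionResult:
    """One set's reduction trace and selected core."""

    set_name: str
    ordered_genes: tuple[str, ...]
    c_trace: tuple[float, ...]
    core_size: int
    c_threshold: float

    def __post_init__(self):
        m = len(self.ordered_genes)
        if len(self.c_trace) != m:
            raise ValueError("c_trace must have one entry per member")
        if not 1 <= self.core_size <= m:
            raise ValueError("core_size out of range")

    @property
    def core_genes(self) -> tuple[str, ...]:
        return self.ordered_genes[: self.core_size]


@dataclass(frozen=True)
class SelectionModel:
    """Significant sets, their reductions, and the union of core genes."""

    alpha: float
    c_threshold: float
    significant_sets: tuple[str, ...]
    set_pvalues: dict[str, float]
    reductions: dict[str, ReductionResult]
    selected_genes: tuple[str, ...]
    s0: float

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "c_threshold": self.c_threshold,
            "s0": self.s0,
            "set_pvalues": self.set_pvalues,
            "significant_sets": list(self.significant_sets),
            "selected_genes": list(self.selected_genes),
            "reductions": {
                name: {
                    "ordered_genes": list(r.ordered_genes),
                    "c_trace": list(r.c_trace),
                    "core_size": r.core_size,
                }
                for name, r in self.reductions.items()
            },
        }


@dataclass(frozen=True)
class TuningResult:
    """Full cross-validation grid plus the winning (c, alpha) pair."""

    grid: tuple[dict, ...]
    best_c: float
    best_alpha: float
    cv_folds: int
    seed: int
    criterion: str = "error"

    def to_dict(self) -> dict:
        return {
            "best_c": self.best_c,
            "best_alpha": self.best_alpha,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "criterion": self.criterion,
            "grid": list(self.grid),
        }


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

def _order_by_abs_d(engine: PermutationEngine, member_idx: np.ndarray) -> np.ndarray:
    # stable sort: |d| ties resolve by input order
    abs_d = np.abs(engine.profile.d[member_idx])
    order = np.argsort(-abs_d, kind="stable")
    return member_idx[order]


def _reduce_indices(
    engine: PermutationEngine, ordered_idx: np.ndarray, c_threshold: float
) -> tuple[np.ndarray, int]:
    """Full c_k trace (k = 1..m, with c_m = 1) and the selected core size."""
    m = ordered_idx.size
    trace = np.ones(m)
    if m > 1:
        trace[:-1] = engine.suffix_pvalues(ordered_idx)
    above = np.flatnonzero(trace > c_threshold)
    core_size = int(above[0]) + 1  # guaranteed nonempty: trace[-1] == 1
    return trace, core_size


def reduce_set(
    study: ExpressionStudy,
    set_members: Sequence[str],
    scheme: PermutationScheme,
    c_threshold: float,
    s0: float | None = None,
    set_name: str = "",
    engine: PermutationEngine | None = None,
) -> ReductionResult:
    """Reduce one gene set to its core subset.

    ``engine`` may be supplied to reuse a precomputed permutation profile;
    otherwise one is built for this call.
    """
    if not 0.0 < c_threshold < 1.0:
        raise ValueError("c_threshold must lie in (0, 1)")
    if engine is None:
        engine = PermutationEngine(study, scheme, s0=s0)
    member_idx = study.gene_index(set_members)
    ordered_idx = _order_by_abs_d(engine, member_idx)
    trace, core_size = _reduce_indices(engine, ordered_idx, c_threshold)
    return ReductionResult(
        set_name=set_name,
        ordered_genes=tuple(study.gene_ids[i] for i in ordered_idx),
        c_trace=tuple(float(c) for c in trace),
        core_size=core_size,
        c_threshold=c_threshold,
    )


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def fit_selection(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    alpha: float,
    c_threshold: float,
    scheme: PermutationScheme,
    s0: float | None = None,
    engine: PermutationEngine | None = None,
) -> SelectionModel:
    """Run the set-level test on every mapped set, reduce the significant
    ones, and pool the cores.

    Selected genes are the deduplicated union of core genes over all sets
    with permutation p <= alpha, ordered by decreasing ``|d|`` (ties by gene
    ID) so the output is deterministic. No significant set yields an empty
    model with a warning, not an error.
    """
    if engine is None:
        engine = PermutationEngine(study, scheme, s0=s0)
    pvalues: dict[str, float] = {}
    significant: list[str] = []
    reductions: dict[str, ReductionResult] = {}
    for name, members in sets:
        idx = study.gene_index(members)
        _, p = engine.set_pvalue(idx)
        pvalues[name] = p
        if p <= alpha:
            significant.append(name)
            ordered_idx = _order_by_abs_d(engine, idx)
            trace, core_size = _reduce_indices(engine, ordered_idx, c_threshold)
            reductions[name] = ReductionResult(
                set_name=name,
                ordered_genes=tuple(study.gene_ids[i] for i in ordered_idx),
                c_trace=tuple(float(c) for c in trace),
                core_size=core_size,
                c_threshold=c_threshold,
            )
    union: set[str] = set()
    for r in reductions.values():
        union.update(r.core_genes)
    if union:
        pool = sorted(union)
        idx = study.gene_index(pool)
        abs_d = np.abs(engine.profile.d[idx])
        order = np.lexsort((np.array(pool), -abs_d))
        selected = tuple(pool[i] for i in order)
    else:
        selected = ()
        logger.warning(
            "no gene set significant at alpha=%.3g; selection is empty", alpha
        )
    return SelectionModel(
        alpha=alpha,
        c_threshold=c_threshold,
        significant_sets=tuple(significant),
        set_pvalues=pvalues,
        reductions=reductions,
        selected_genes=selected,
        s0=engine.profile.s0,
    )


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def _majority_error(train_labels: Sequence[str], test_labels: Sequence[str]) -> float:
    """Error of always predicting the training majority class."""
    n_dis = sum(c == DISEASED for c in train_labels)
    majority = DISEASED if n_dis * 2 >= len(train_labels) else "control"
    wrong = sum(c != majority for c in test_labels)
    return wrong / len(test_labels)


def tune(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    k_folds: int = 5,
    seed: int = 0,
    n_perm_cv: int = 500,
    s0: float | None = None,
) -> TuningResult:
    """Joint grid search over (c, alpha) under stratified k-fold CV.

    Folds are shared across all grid cells so cells are compared on
    identical splits, and the permutation profile is computed once per fold
    (every cell reuses it — the reduction trace depends on neither c nor
    alpha). A cell whose selection is empty on a fold scores that fold at
    the majority-class error and is flagged.
    """
    labels = np.asarray(study.labels)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    cells = [(c, a) for c in c_grid for a in alpha_grid]
    fold_errors = {cell: [] for cell in cells}
    fold_sizes = {cell: [] for cell in cells}
    fold_empty = {cell: 0 for cell in cells}

    for fold, (train_ix, test_ix) in enumerate(
        skf.split(np.zeros(study.n_samples), labels)
    ):
        train = study.subset_samples(train_ix)
        test = study.subset_samples(test_ix)
        for part, name in ((train, "training"), (test, "held-out")):
            if part.labels is None or len(set(part.labels)) < 2:
                raise ClassSizeError(
                    f"fold {fold}: {name} part has a single class; "
                    "change the seed or fold count"
                )
        scheme = build_permutation_scheme(
            train.labels, n_perm=n_perm_cv, seed=seed * 100_003 + fold
        )
        engine = PermutationEngine(train, scheme, s0=s0)
        # per-set p-values and reduction traces, shared by all grid cells
        set_info = []
        for name, members in sets:
            idx = train.gene_index(members)
            _, p = engine.set_pvalue(idx)
            ordered_idx = _order_by_abs_d(engine, idx)
            trace, _ = _reduce_indices(engine, ordered_idx, 0.5)
            set_info.append((name, p, ordered_idx, trace))
        base_error = _majority_error(train.labels, test.labels)
        for c, a in cells:
            union: set[int] = set()
            for name, p, ordered_idx, trace in set_info:
                if p <= a:
                    core = int(np.flatnonzero(trace > c)[0]) + 1
                    union.update(ordered_idx[:core].tolist())
            if not union:
                fold_errors[(c, a)].append(base_error)
                fold_sizes[(c, a)].append(0)
                fold_empty[(c, a)] += 1
                continue
            genes = [train.gene_ids[i] for i in sorted(union)]
            clf = fit_classifier(train, genes, seed=seed)
            report = evaluate(clf.predict(test), test.labels)
            fold_errors[(c, a)].append(report.error_rate)
            fold_sizes[(c, a)].append(len(genes))

    grid = []
    for c, a in cells:
        grid.append(
            {
                "c": c,
                "alpha": a,
                "mean_cv_error": float(np.mean(fold_errors[(c, a)])),
                "mean_n_genes": float(np.mean(fold_sizes[(c, a)])),
                "fold_errors": [float(e) for e in fold_errors[(c, a)]],
                "fold_n_genes": fold_sizes[(c, a)],
                "empty_folds": fold_empty[(c, a)],
            }
        )
    best = select_best_cell(grid)
    return TuningResult(
        grid=tuple(grid),
        best_c=float(best["c"]),
        best_alpha=float(best["alpha"]),
        cv_folds=k_folds,
        seed=seed,
    )


def select_best_cell(grid: Sequence[dict]) -> dict:
    """Winning grid cell: minimal mean CV error, ties broken by smaller mean
    selected-gene count, then smaller alpha, then smaller c."""
    return min(
        grid,
        key=lambda g: (g["mean_cv_error"], g["mean_n_genes"], g["alpha"], g["c"]),
    )


def refit_final(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    tuning: TuningResult,
    n_perm: int = 1000,
    s0: float | None = None,
) -> tuple[SelectionModel, FittedClassifier]:
    """Re-fit the selection on the full training study at the tuned (c, alpha)
    and train the final classifier on the selected genes."""
    scheme = build_permutation_scheme(
        study.labels, n_perm=n_perm, seed=tuning.seed * 100_003 + 999_983
    )
    selection = fit_selection(
        study, sets, alpha=tuning.best_alpha, c_threshold=tuning.best_c,
        scheme=scheme, s0=s0,
    )
    if not selection.selected_genes:
        raise EmptySelectionError(
            "final selection is empty at the tuned parameters",
            grid=tuning.to_dict()["grid"],
        )
    clf = fit_classifier(study, list(selection.selected_genes), seed=tuning.seed)
    return selection, clf


def serialize_model(
    selection: SelectionModel,
    clf: FittedClassifier,
    tuning: TuningResult | None,
    path,
) -> None:
    """JSON dump of the fitted model: genes, coefficients, tuning provenance."""
    payload = {
        "selection": selection.to_dict(),
        "classifier": clf.to_dict(),
        "tuning": tuning.to_dict() if tuning is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
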