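"""SVM classification on selected genes and probabilistic evaluation metrics.

The classifier is a linear support-vector machine (cost C = 1) with
Platt-type sigmoid calibration of decision values, so its output is a belief
(probability) vector over (control, diseased) per sample. Linear at p >> n
keeps the per-gene weights interpretable; kernel and cost are overridable.

Four metrics summarize a set of beliefs against true labels, all on [0, 1]:

* **error rate** — fraction misclassified under the argmax-belief rule
  (belief ties at 0.5 predict diseased); lower is better.
* **GBS** (generalized Brier score) — mean squared distance between the
  belief vector and the true-class indicator vector, divided by 2 so a
  confidently wrong binary prediction scores exactly 1; lower is better.
* **BCM** (belief confusion metric) — mean belief assigned to the true
  class, the IMPROVER diagnostic-signature-challenge definition; higher is
  better.
* **AUPR** — area under the precision-recall curve for the diseased class,
  by step-wise interpolation (summing precision x recall-increment over
  descending score thresholds; no trapezoids, avoiding optimistic bias);
  higher is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .core_data import ExpressionStudy, CONTROL, DISEASED
from .errors import ClassSizeError

CLASS_ORDER = (CONTROL, DISEASED)


@dataclass(frozen=True)
class ProbPrediction:
    """Per-sample belief vectors over (control, diseased)."""

    sample_ids: tuple[str, ...]
    beliefs: np.ndarray  # (n, 2), columns in CLASS_ORDER
    class_order: tuple[str, str] = CLASS_ORDER

    def __post_init__(self):
        b = np.asarray(self.beliefs, dtype=float)
        object.__setattr__(self, "beliefs", b)
        if b.shape != (len(self.sample_ids), 2):
            raise ValueError("beliefs must be (n_samples, 2)")
        if np.any(b < 0) or np.any(np.abs(b.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each belief vector must be nonnegative and sum to 1")
        if tuple(self.class_order) != CLASS_ORDER:
            raise ValueError(f"class_order must be {CLASS_ORDER}")

    @property
    def belief_diseased(self) -> np.ndarray:
        return self.beliefs[:, 1]


@dataclass(frozen=True)
class MetricsReport:
    """The four evaluation metrics for one prediction set.

    Orientation: ``bcm`` and ``aupr`` are better near 1; ``error_rate`` and
    ``gbs`` are better near 0.
    """

    error_rate: float
    gbs: float
    bcm: float
    aupr: float
    n_samples: int
    positive_class: str = DISEASED

    #: metric name -> True if larger values are better
    HIGHER_IS_BETTER = {"error_rate": False, "gbs": False, "bcm": True, "aupr": True}

    def __post_init__(self):
        for name in ("error_rate", "gbs", "bcm", "aupr"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "error_rate": self.error_rate,
            "gbs": self.gbs,
            "bcm": self.bcm,
            "aupr": self.aupr,
            "n_samples": self.n_samples,
            "positive_class": self.positive_class,
        }


class FittedClassifier:
    """A trained probabilistic classifier restricted to a gene panel."""

    def __init__(self, model: CalibratedClassifierCV, genes: tuple[str, ...], seed: int):
        self._model = model
        self.genes = genes
        self.seed = seed

    def predict(self, study: ExpressionStudy) -> ProbPrediction:
        """Beliefs for every sample of ``study`` (genes matched by ID).

        Raises ``KeyError`` if a panel gene is absent from the study — no
        silent zero-imputation.
        """
        idx = study.gene_index(self.genes)
        X = study.values[idx].T
        proba = self._model.predict_proba(X)
        # sklearn orders classes lexicographically: control < diseased
        cols = [list(self._model.classes_).index(c) for c in CLASS_ORDER]
        return ProbPrediction(
            sample_ids=study.sample_ids, beliefs=proba[:, cols]
        )

    @property
    def _svc(self) -> SVC:
        return self._model.calibrated_classifiers_[0].estimator

    @property
    def coefficients(self) -> np.ndarray | None:
        try:
            return self._svc.coef_.ravel()
        except AttributeError:  # non-linear kernel
            return None

    def to_dict(self) -> dict:
        coef = self.coefficients
        return {
            "genes": list(self.genes),
            "seed": self.seed,
            "kernel": self._svc.kernel,
            "C": self._svc.C,
            "coefficients": None if coef is None else [float(w) for w in coef],
            "intercept": [float(b) for b in np.ravel(self._svc.intercept_)],
        }


def fit_classifier(
    study: ExpressionStudy,
    genes: Sequence[str],
    seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
) -> FittedClassifier:
    """Train the calibrated SVM on the study restricted to ``genes``.

    Platt calibration is fitted by internal cross-validation on decision
    values (scikit-learn's ``probability=True``); ``seed`` fixes its folds so
    refits are deterministic.
    """
    if not genes:
        raise ValueError("gene panel must be nonempty")
    if study.labels is None or len(set(study.labels)) < 2:
        raise ClassSizeError("training data must contain both classes")
    idx = study.gene_index(genes)
    X = study.values[idx].T
    y = np.asarray(study.labels)
    min_class = min(np.count_nonzero(y == c) for c in set(study.labels))
    cv = max(2, min(5, min_class))
    model = CalibratedClassifierCV(
        SVC(kernel=kernel, C=C, random_state=seed),
        method="sigmoid",
        cv=cv,
        ensemble=False,
    )
    model.fit(X, y)
    return FittedClassifier(model, tuple(genes), seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_truth(pred: ProbPrediction, truth: Sequence[str]) -> np.ndarray:
    truth = list(truth)
    if len(truth) != len(pred.sample_ids):
        raise ValueError("truth length must match prediction")
    bad = sorted(set(truth) - set(CLASS_ORDER))
    if bad:
        raise ValueError(f"unknown class label(s): {bad}")
    return np.array([c == DISEASED for c in truth], dtype=bool)


def aupr_step(scores: np.ndarray, positive: np.ndarray) -> float:
    """Area under the precision-recall curve by step interpolation.

    Thresholds sweep the distinct scores in descending order; tied scores
    enter together. The area is sum over threshold steps of
    precision * (recall increment).
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValueError("no positive sample; AUPR undefined")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = positive[order]
    tp = np.cumsum(p)
    pred_pos = np.arange(1, s.size + 1)
    # keep only the last index of each tied-score block
    block_end = np.r_[s[1:] != s[:-1], True]
    tp_b = tp[block_end]
    pp_b = pred_pos[block_end]
    precision = tp_b / pp_b
    recall = tp_b / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * d_recall))


def evaluate(pred: ProbPrediction, truth: Sequence[str]) -> MetricsReport:
    """Score beliefs against true classes with the four metrics."""
    y = _check_truth(pred, truth)
    b = pred.beliefs
    bd = pred.belief_diseased
    # argmax rule; belief ties at 0.5 predict the diseased class
    predicted_diseased = bd >= 0.5
    error = float(np.mean(predicted_diseased != y))
    indicator = np.column_stack([~y, y]).astype(float)
    gbs = float(np.mean(np.sum((b - indicator) ** 2, axis=1) / 2.0))
    bcm = float(np.mean(np.where(y, b[:, 1], b[:, 0])))
    aupr = aupr_step(bd, y)
    return MetricsReport(
        error_rate=error, gbs=gbs, bcm=bcm, aupr=aupr, n_samples=y.size
    )
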