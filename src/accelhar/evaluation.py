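"""Classification performance metrics.

Everything reported downstream comes from here: the 3x3 confusion matrix
(rows = predicted, columns = observed, fixed class order walking, running,
jumping, with a per-column percentage view), overall percent agreement and
Cohen's Kappa, one-vs-all ROC-AUC per class with an unweighted macro
average, per-activity one-vs-all agreement/Kappa on collapsed 2x2 tables,
and permutation feature importance of a fitted model on held-out rows.

Kappa is the chance-corrected agreement (p_o - p_e) / (1 - p_e) with the
expected agreement p_e computed from the matrix marginals; it is reported
unweighted since the activity classes are nominal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import ACTIVITIES

CLASS_ORDER: tuple[str, ...] = ACTIVITIES


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of predicted (rows) against observed (columns) classes."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_labels(
        cls,
        observed: Sequence[str],
        predicted: Sequence[str],
        classes: Sequence[str] = CLASS_ORDER,
    ) -> "ConfusionMatrix":
        observed = np.asarray(observed)
        predicted = np.asarray(predicted)
        if observed.shape != predicted.shape:
            raise ValueError("observed and predicted must have the same length")
        index = {label: i for i, label in enumerate(classes)}
        unknown = (set(observed) | set(predicted)) - set(classes)
        if unknown:
            raise ValueError(f"labels outside the class set {tuple(classes)}: {sorted(unknown)}")
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for obs, pred in zip(observed, predicted):
            counts[index[pred], index[obs]] += 1
        return cls(counts=counts, classes=tuple(classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def observed_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def predicted_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_percentages(self) -> np.ndarray:
        """Counts as percentages of each observed class's total (per column)."""
        totals = self.observed_totals.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * self.counts / totals[np.newaxis, :]
        return np.where(totals[np.newaxis, :] > 0, pct, 0.0)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "counts": self.counts.tolist(),
            "column_percentages": np.round(self.column_percentages(), 3).tolist(),
            "total": self.total,
        }


def percent_agreement(cm: ConfusionMatrix) -> float:
    """Overall accuracy as a percentage: 100 * trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_observed = float(np.trace(cm.counts)) / n
    p_expected = float(np.sum(cm.predicted_totals * cm.observed_totals)) / n**2
    if p_expected == 1.0:
        warnings.warn("kappa undefined (expected agreement is 1); returning 0", stacklevel=2)
        return 0.0
    return (p_observed - p_expected) / (1.0 - p_expected)


def roc_auc_ova(
    observed: Sequence[str],
    probabilities: pd.DataFrame | np.ndarray,
    classes: Sequence[str] = CLASS_ORDER,
) -> tuple[dict[str, float], float]:
    """One-vs-all ROC-AUC per class and their unweighted macro average.

    Per class, the binary AUC of that class's score against the membership
    indicator, computed with the rank (Mann-Whitney) formulation in which
    ties receive midranks. A class absent from ``observed`` has no defined
    AUC; it is excluded from the macro mean with a warning.
    """
    observed = np.asarray(observed)
    if isinstance(probabilities, pd.DataFrame):
        scores = probabilities.loc[:, list(classes)].to_numpy(dtype=float)
    else:
        scores = np.asarray(probabilities, dtype=float)
    if scores.shape != (observed.size, len(classes)):
        raise ValueError(
            f"probabilities must have shape ({observed.size}, {len(classes)}), got {scores.shape}"
        )
    per_class: dict[str, float] = {}
    for j, label in enumerate(classes):
        indicator = (observed == label).astype(int)
        if indicator.min() == indicator.max():
            warnings.warn(
                f"class {label!r} absent from observed labels (or covers all of them); "
                "its one-vs-all AUC is undefined and excluded from the macro average",
                stacklevel=2,
            )
            continue
        per_class[label] = float(roc_auc_score(indicator, scores[:, j]))
    if not per_class:
        raise ValueError("no class has a defined one-vs-all AUC")
    macro = float(np.mean(list(per_class.values())))
    return per_class, macro


def collapse_binary(cm: ConfusionMatrix, label: str) -> ConfusionMatrix:
    """Collapse a KxK matrix to the 2x2 one-vs-all table for ``label``.

    Rows/columns are (label, rest); entry [0, 0] is the true positives.
    """
    if label not in cm.classes:
        raise ValueError(f"unknown class {label!r}")
    i = cm.classes.index(label)
    tp = cm.counts[i, i]
    fp = cm.counts[i, :].sum() - tp
    fn = cm.counts[:, i].sum() - tp
    tn = cm.total - tp - fp - fn
    return ConfusionMatrix(
        counts=np.array([[tp, fp], [fn, tn]]), classes=(label, "rest")
    )


def per_class_metrics(
    cm: ConfusionMatrix,
    observed: Sequence[str] | None = None,
    probabilities: pd.DataFrame | np.ndarray | None = None,
) -> dict[str, dict[str, float]]:
    """One-vs-all agreement, kappa (and AUC when scores are given) per class."""
    aucs: dict[str, float] = {}
    if observed is not None and probabilities is not None:
        aucs, _ = roc_auc_ova(observed, probabilities, cm.classes)
    out: dict[str, dict[str, float]] = {}
    for label in cm.classes:
        binary = collapse_binary(cm, label)
        metrics = {
            "percent_agreement": percent_agreement(binary),
            "kappa": cohens_kappa(binary),
        }
        if label in aucs:
            metrics["roc_auc"] = aucs[label]
        out[label] = metrics
    return out


@dataclass(frozen=True)
class EvaluationReport:
    """All reported performance quantities for one fitted model."""

    percent_agreement: float
    roc_auc: float
    kappa: float
    per_class: Mapping[str, Mapping[str, float]]
    confusion: ConfusionMatrix
    importance: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.percent_agreement <= 100:
            raise ValueError("percent_agreement must lie in [0, 100]")
        if not 0 <= self.roc_auc <= 1:
            raise ValueError("roc_auc must lie in [0, 1]")
        if not -1 <= self.kappa <= 1:
            raise ValueError("kappa must lie in [-1, 1]")

    def to_dict(self) -> dict:
        payload = {
            "overall": {
                "percent_agreement": self.percent_agreement,
                "roc_auc": self.roc_auc,
                "kappa": self.kappa,
            },
            "per_class": {k: dict(v) for k, v in self.per_class.items()},
            "confusion": self.confusion.to_dict(),
        }
        if self.importance is not None:
            payload["importance"] = dict(self.importance)
        return payload


def evaluate_predictions(
    observed: Sequence[str],
    predicted: Sequence[str],
    probabilities: pd.DataFrame | np.ndarray,
    classes: Sequence[str] = CLASS_ORDER,
) -> EvaluationReport:
    """Full report (overall + per-class metrics + confusion) from predictions."""
    cm = ConfusionMatrix.from_labels(observed, predicted, classes)
    _, macro_auc = roc_auc_ova(observed, probabilities, classes)
    return EvaluationReport(
        percent_agreement=percent_agreement(cm),
        roc_auc=macro_auc,
        kappa=cohens_kappa(cm),
        per_class=per_class_metrics(cm, observed, probabilities),
        confusion=cm,
    )


def permutation_importance(
    predict: Callable[[pd.DataFrame], np.ndarray],
    matrix: pd.DataFrame,
    observed: Sequence[str],
    feature_columns: Sequence[str],
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance on held-out rows.

    For each feature, importance is the drop in percent agreement when
    that column is independently shuffled, averaged over ``n_repeats``
    seeded shuffles: ``baseline - mean(permuted)``. Returned sorted by
    descending importance with the per-feature permutation SD.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    observed = np.asarray(observed)
    baseline_cm = ConfusionMatrix.from_labels(observed, predict(matrix))
    baseline = percent_agreement(baseline_cm)
    rng = np.random.default_rng(seed)
    rows = []
    for name in feature_columns:
        drops = np.empty(n_repeats)
        for repeat in range(n_repeats):
            shuffled = matrix.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            permuted_cm = ConfusionMatrix.from_labels(observed, predict(shuffled))
            drops[repeat] = baseline - percent_agreement(permuted_cm)
        rows.append(
            {
                "feature": name,
                "importance": float(np.mean(drops)),
                "sd": float(np.std(drops, ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    frame = pd.DataFrame(rows).sort_values("importance", ascending=False, kind="stable")
    return frame.reset_index(drop=True)


def plot_importance(importance: pd.DataFrame, top: int = 15, ax=None):
    """Horizontal-bar chart of the top permutation-importance scores."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * top + 1))
    head = importance.head(top).iloc[::-1]
    ax.barh(head["feature"], head["importance"], xerr=head.get("sd"), color="#4878a8")
    ax.set_xlabel("Decrease in percent agreement when permuted")
    ax.set_title("Permutation feature importance")
    ax.figure.tight_layout()
    return ax
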