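"""Activity classification models: grid-searched RF, SVM-RBF and KNN.

The public surface follows the model/results idiom: an
:class:`ActivityClassifier` is constructed from a training feature matrix
(typically via :meth:`ActivityClassifier.from_dataframe`), and
:meth:`~ActivityClassifier.fit` runs the whole training procedure —
hyperparameter grid construction, participant-grouped 5-fold
cross-validated grid search with preprocessing re-fitted inside every
fold, and a final refit on all training rows — returning an
:class:`ActivityClassifierResults` that carries the chosen
hyperparameters, the per-setting cross-validation table (mean +/- SE of
percent agreement, one-vs-all macro ROC-AUC and Kappa), the frozen
preprocessing state and the fitted estimator, with ``predict``,
``predict_proba``, ``evaluate``, ``permutation_importance``, ``summary``
and ``save``/``load`` hanging off it.

Algorithms and tuned hyperparameters:

* ``rf`` — random forest, 500 trees fixed; tuned: ``mtry`` (predictors
  sampled per split) and ``min_n`` (minimum points to split a node);
* ``svm_rbf`` — support-vector machine with RBF kernel; tuned: ``cost``
  and ``rbf_sigma`` (the kernel coefficient). Class scores are converted
  to probabilities by a softmax over the one-vs-rest decision values — a
  documented approximation chosen over Platt scaling, which would need an
  internal refit per model;
* ``knn`` — k-nearest neighbours; tuned: ``n_neighbors``.

Ten candidate settings are drawn by a seeded Latin-hypercube over
documented ranges; the winner maximises mean CV ROC-AUC (ties: higher
agreement, then the simpler model).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .evaluation import (
    CLASS_ORDER,
    ConfusionMatrix,
    EvaluationReport,
    cohens_kappa,
    evaluate_predictions,
    percent_agreement,
    permutation_importance,
    roc_auc_ova,
)
from .features import FEATURE_NAMES
from .io import METADATA_COLUMNS
from .prep import PreprocessState, apply_preprocess, fit_preprocess

ALGORITHMS: tuple[str, ...] = ("rf", "svm_rbf", "knn")

#: Fixed forest size; only mtry and min_n are tuned.
RF_N_TREES: int = 500

#: Hyperparameter search ranges (log2 for cost, log10 for rbf_sigma).
GRID_RANGES = {
    "rf": {"mtry": (1, None), "min_n": (2, 40)},  # mtry upper bound = feature count
    "svm_rbf": {"log2_cost": (-5.0, 10.0), "log10_rbf_sigma": (-4.0, 0.0)},
    "knn": {"n_neighbors": (1, None)},  # upper bound = 2 * round(sqrt(train size))
}


@dataclass(frozen=True)
class ClassifierSpec:
    """What to train and how to tune it."""

    algorithm: str
    n_grid_points: int = 10
    cv_folds: int = 5
    seed: int = 0
    grid: tuple[Mapping[str, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.n_grid_points < 1:
            raise ValueError("n_grid_points must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


def _unique_ints(values: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Nudge duplicate integers apart (within [lo, hi]) so the grid keeps
    exactly n distinct settings where the range allows it."""
    values = values.copy()
    if hi - lo + 1 < values.size:
        return values  # range too small for distinct values; duplicates allowed
    seen = set()
    for i, v in enumerate(values):
        step = 0
        candidate = int(v)
        while candidate in seen:
            step += 1
            up, down = int(v) + step, int(v) - step
            if up <= hi and up not in seen:
                candidate = up
            elif down >= lo and down not in seen:
                candidate = down
        seen.add(candidate)
        values[i] = candidate
    return values


def make_grid(
    algorithm: str,
    feature_count: int,
    train_size: int,
    n_grid_points: int = 10,
    seed: int = 0,
) -> tuple[dict[str, float], ...]:
    """Space-filling (Latin-hypercube) hyperparameter grid, seeded.

    Ranges: rf mtry in [1, feature_count], min_n in [2, 40]; svm cost in
    2^[-5, 10], rbf_sigma in 10^[-4, 0]; knn n_neighbors in
    [1, 2 * round(sqrt(train_size))].
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if feature_count < 1:
        raise ValueError("feature_count must be at least 1")
    if train_size < 1:
        raise ValueError("train_size must be at least 1")
    if algorithm == "rf":
        sampler = qmc.LatinHypercube(d=2, seed=seed)
        u = sampler.random(n_grid_points)
        mtry = np.clip(1 + np.floor(u[:, 0] * feature_count), 1, feature_count).astype(int)
        min_n = np.clip(2 + np.round(u[:, 1] * 38), 2, 40).astype(int)
        return tuple(
            {"mtry": int(m), "min_n": int(n)} for m, n in zip(mtry, min_n)
        )
    if algorithm == "svm_rbf":
        sampler = qmc.LatinHypercube(d=2, seed=seed)
        u = sampler.random(n_grid_points)
        lo_c, hi_c = GRID_RANGES["svm_rbf"]["log2_cost"]
        lo_s, hi_s = GRID_RANGES["svm_rbf"]["log10_rbf_sigma"]
        cost = 2.0 ** (lo_c + u[:, 0] * (hi_c - lo_c))
        sigma = 10.0 ** (lo_s + u[:, 1] * (hi_s - lo_s))
        return tuple({"cost": float(c), "rbf_sigma": float(s)} for c, s in zip(cost, sigma))
    hi_k = max(1, 2 * round(math.sqrt(train_size)))
    sampler = qmc.LatinHypercube(d=1, seed=seed)
    u = sampler.random(n_grid_points)[:, 0]
    k = np.clip(1 + np.floor(u * hi_k), 1, hi_k).astype(int)
    k = _unique_ints(k, 1, hi_k)
    return tuple({"n_neighbors": int(v)} for v in k)


def build_estimator(algorithm: str, params: Mapping[str, float], seed: int = 0):
    """Instantiate the scikit-learn estimator for one hyperparameter setting."""
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=RF_N_TREES,
            max_features=int(params["mtry"]),
            min_samples_split=int(params["min_n"]),
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "svm_rbf":
        return SVC(
            kernel="rbf",
            C=float(params["cost"]),
            gamma=float(params["rbf_sigma"]),
            decision_function_shape="ovr",
            random_state=seed,
        )
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=int(params["n_neighbors"]))
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _predict_proba(estimator, X: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    """Class probabilities in CLASS_ORDER, summing to 1 per row.

    SVC exposes no native probabilities without an internal refit, so its
    one-vs-rest decision values go through a softmax (monotone in each
    class's own score, so the argmax matches the decision rule).
    """
    if hasattr(estimator, "predict_proba"):
        raw = estimator.predict_proba(X)
    else:
        decision = estimator.decision_function(X)
        if decision.ndim == 1:
            decision = np.column_stack([-decision, decision])
        shifted = decision - decision.max(axis=1, keepdims=True)
        raw = np.exp(shifted)
        raw /= raw.sum(axis=1, keepdims=True)
    order = [list(estimator.classes_).index(label) for label in classes]
    proba = raw[:, order]
    # Guard against classes unseen in a fold: renormalize.
    return proba / proba.sum(axis=1, keepdims=True)


def _labels_from_proba(proba: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    """Hard labels = argmax probability; ties go to the earliest class."""
    return np.asarray(classes, dtype=object)[np.argmax(proba, axis=1)]


def _shuffled_group_folds(
    groups: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition rows into folds by participant, shuffled then dealt round-robin.

    Every participant lands in exactly one held-out fold, so no individual
    appears on both sides of any fold.
    """
    unique = pd.unique(groups)
    if len(unique) < n_folds:
        raise ValueError(
            f"need at least {n_folds} training participants for {n_folds}-fold grouped CV, "
            f"got {len(unique)}"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unique)
    assignment = {participant: i % n_folds for i, participant in enumerate(shuffled)}
    fold_of_row = np.array([assignment[g] for g in groups])
    folds = []
    for fold in range(n_folds):
        held_out = fold_of_row == fold
        folds.append((np.flatnonzero(~held_out), np.flatnonzero(held_out)))
    return folds


def cross_validate(
    matrix: pd.DataFrame,
    spec: ClassifierSpec,
    grid: Sequence[Mapping[str, float]],
    feature_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Participant-grouped k-fold grid search.

    Preprocessing (near-zero-variance filter + standardization) is
    re-fitted inside each fold on the analysis portion only. Returns one
    row per grid setting with mean and standard error (over folds) of
    percent agreement, macro one-vs-all ROC-AUC and Kappa.
    """
    if feature_columns is None:
        feature_columns = [c for c in FEATURE_NAMES if c in matrix.columns]
    groups = matrix["participant_id"].to_numpy()
    y = matrix["label"].to_numpy()
    folds = _shuffled_group_folds(groups, spec.cv_folds, spec.seed)
    metrics = np.empty((len(grid), len(folds), 3))
    for fold_index, (analysis_rows, assessment_rows) in enumerate(folds):
        analysis = matrix.iloc[analysis_rows]
        assessment = matrix.iloc[assessment_rows]
        state = fit_preprocess(analysis, feature_columns=feature_columns)
        X_train = apply_preprocess(state, analysis)[list(state.kept_features)].to_numpy()
        X_test = apply_preprocess(state, assessment)[list(state.kept_features)].to_numpy()
        y_train, y_test = y[analysis_rows], y[assessment_rows]
        for setting_index, params in enumerate(grid):
            estimator = build_estimator(spec.algorithm, _clip_params(params, X_train), spec.seed)
            estimator.fit(X_train, y_train)
            proba = _predict_proba(estimator, X_test, CLASS_ORDER)
            predicted = _labels_from_proba(proba, CLASS_ORDER)
            cm = ConfusionMatrix.from_labels(y_test, predicted)
            _, macro_auc = roc_auc_ova(y_test, proba)
            metrics[setting_index, fold_index] = (
                percent_agreement(cm),
                macro_auc,
                cohens_kappa(cm),
            )
    n_folds = len(folds)
    rows = []
    for setting_index, params in enumerate(grid):
        block = metrics[setting_index]
        row: dict[str, object] = {"setting": setting_index, **params}
        for j, name in enumerate(("percent_agreement", "roc_auc", "kappa")):
            row[f"{name}_mean"] = float(block[:, j].mean())
            row[f"{name}_se"] = float(block[:, j].std(ddof=1) / math.sqrt(n_folds))
        rows.append(row)
    return pd.DataFrame(rows)


def _clip_params(params: Mapping[str, float], X: np.ndarray) -> dict[str, float]:
    """Keep hyperparameters feasible for the actual design matrix."""
    out = dict(params)
    if "mtry" in out:
        out["mtry"] = int(min(out["mtry"], X.shape[1]))
    if "n_neighbors" in out:
        out["n_neighbors"] = int(min(out["n_neighbors"], X.shape[0]))
    return out


def _model_complexity(algorithm: str, params: Mapping[str, float]) -> float:
    """Tie-break key: prefer the simpler model (lower value wins)."""
    if algorithm == "rf":
        return params["mtry"] + params["min_n"] * -0.01  # fewer predictors per split
    if algorithm == "svm_rbf":
        return math.log2(params["cost"])  # softer margin = simpler boundary
    return -params["n_neighbors"]  # more neighbours = smoother rule


def select_best(
    cv_results: pd.DataFrame, algorithm: str, grid: Sequence[Mapping[str, float]]
) -> int:
    """Winning setting index: max mean CV ROC-AUC, tie -> higher agreement,
    then the simpler model.

    AUC is compared at 3 decimals — the precision at which the metric is
    meaningful over 5 folds — so near-ceiling settings whose AUCs differ
    only in the 4th decimal are ranked by their agreement instead of by
    ranking noise.
    """
    keys = [
        (
            -round(cv_results.loc[i, "roc_auc_mean"], 3),
            -cv_results.loc[i, "percent_agreement_mean"],
            _model_complexity(algorithm, grid[i]),
            i,
        )
        for i in range(len(grid))
    ]
    return min(keys)[-1]


class ActivityClassifier:
    """Activity-classification model built from a training feature matrix.

    Parameters
    ----------
    X : DataFrame
        Training feature columns (a subset of the 54 canonical names).
    y : sequence of str
        Window labels (walking / running / jumping).
    groups : sequence of str
        Participant id per window, used for grouped cross-validation.
    algorithm : {"rf", "svm_rbf", "knn"}
    n_grid_points, cv_folds, seed
        Tuning-budget and reproducibility knobs; see :class:`ClassifierSpec`.

    Examples
    --------
    >>> model = ActivityClassifier.from_dataframe(train_df, algorithm="rf", seed=7)
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[str],
        groups: Sequence[str],
        algorithm: str = "rf",
        n_grid_points: int = 10,
        cv_folds: int = 5,
        seed: int = 0,
    ) -> None:
        self.feature_columns = [c for c in FEATURE_NAMES if c in X.columns]
        if not self.feature_columns:
            raise ValueError("X contains none of the canonical feature columns")
        self.spec = ClassifierSpec(
            algorithm=algorithm, n_grid_points=n_grid_points, cv_folds=cv_folds, seed=seed
        )
        self._matrix = X.loc[:, self.feature_columns].copy()
        self._matrix["label"] = np.asarray(y)
        self._matrix["participant_id"] = np.asarray(groups)
        if len(self._matrix) == 0:
            raise ValueError("training matrix is empty")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, algorithm: str = "rf", **kwargs):
        """Build from a feature matrix carrying label and participant_id columns."""
        for required in ("label", "participant_id"):
            if required not in frame.columns:
                raise ValueError(f"frame must carry a {required!r} column")
        feature_cols = [c for c in FEATURE_NAMES if c in frame.columns]
        return cls(
            X=frame.loc[:, feature_cols],
            y=frame["label"].to_numpy(),
            groups=frame["participant_id"].to_numpy(),
            algorithm=algorithm,
            **kwargs,
        )

    def fit(self) -> "ActivityClassifierResults":
        """Grid search with grouped CV, then a final refit on all rows."""
        grid = make_grid(
            self.spec.algorithm,
            feature_count=len(self.feature_columns),
            train_size=len(self._matrix),
            n_grid_points=self.spec.n_grid_points,
            seed=self.spec.seed,
        )
        cv_results = cross_validate(self._matrix, self.spec, grid, self.feature_columns)
        best = select_best(cv_results, self.spec.algorithm, grid)
        chosen = dict(grid[best])
        state = fit_preprocess(self._matrix, feature_columns=self.feature_columns)
        X = apply_preprocess(state, self._matrix)[list(state.kept_features)].to_numpy()
        y = self._matrix["label"].to_numpy()
        estimator = build_estimator(self.spec.algorithm, _clip_params(chosen, X), self.spec.seed)
        estimator.fit(X, y)
        return ActivityClassifierResults(
            spec=self.spec,
            params=chosen,
            cv_results=cv_results,
            preprocess=state,
            estimator=estimator,
            n_train_rows=len(self._matrix),
            n_train_participants=int(self._matrix["participant_id"].nunique()),
        )


class ActivityClassifierResults:
    """Fitted activity classifier: estimates, diagnostics and predictions.

    Attributes
    ----------
    params : dict
        The winning hyperparameter setting.
    cv_results : DataFrame
        Per-setting cross-validation table (mean and SE per metric).
    preprocess : PreprocessState
        Frozen near-zero-variance drops and center/scale, estimated on the
        training rows.
    estimator
        The underlying fitted scikit-learn model.
    """

    def __init__(
        self,
        spec: ClassifierSpec,
        params: Mapping[str, float],
        cv_results: pd.DataFrame,
        preprocess: PreprocessState,
        estimator,
        n_train_rows: int,
        n_train_participants: int,
    ) -> None:
        self.spec = spec
        self.params = dict(params)
        self.cv_results = cv_results
        self.preprocess = preprocess
        self.estimator = estimator
        self.n_train_rows = n_train_rows
        self.n_train_participants = n_train_participants
        self.classes = CLASS_ORDER

    # -- prediction ---------------------------------------------------------

    def _design(self, matrix: pd.DataFrame) -> np.ndarray:
        return apply_preprocess(self.preprocess, matrix)[
            list(self.preprocess.kept_features)
        ].to_numpy()

    def predict_proba(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Per-class probabilities (columns walking, running, jumping)."""
        proba = _predict_proba(self.estimator, self._design(matrix), self.classes)
        return pd.DataFrame(proba, columns=list(self.classes), index=matrix.index)

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        """Hard labels: argmax probability, ties to the earliest class."""
        return _labels_from_proba(self.predict_proba(matrix).to_numpy(), self.classes)

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, matrix: pd.DataFrame) -> EvaluationReport:
        """Full held-out evaluation of a labeled feature matrix."""
        if "label" not in matrix.columns:
            raise ValueError("matrix must carry a 'label' column to evaluate against")
        proba = self.predict_proba(matrix)
        predicted = _labels_from_proba(proba.to_numpy(), self.classes)
        return evaluate_predictions(matrix["label"].to_numpy(), predicted, proba)

    def permutation_importance(
        self, matrix: pd.DataFrame, n_repeats: int = 10, seed: int = 0
    ) -> pd.DataFrame:
        """Permutation importance of each kept feature on held-out rows."""
        if "label" not in matrix.columns:
            raise ValueError("matrix must carry a 'label' column")
        return permutation_importance(
            predict=self.predict,
            matrix=matrix,
            observed=matrix["label"].to_numpy(),
            feature_columns=list(self.preprocess.kept_features),
            n_repeats=n_repeats,
            seed=seed,
        )

    def summary(self) -> str:
        """Human-readable fit summary (chosen setting + CV table)."""
        lines = [
            "Activity classifier results",
            "=" * 60,
            f"algorithm:            {self.spec.algorithm}",
            f"training windows:     {self.n_train_rows}"
            f"  (participants: {self.n_train_participants})",
            f"features kept:        {len(self.preprocess.kept_features)}"
            f"  (dropped: {len(self.preprocess.dropped_features)})",
            f"grid size:            {self.spec.n_grid_points}"
            f"  ({self.spec.cv_folds}-fold grouped CV, seed {self.spec.seed})",
            f"chosen setting:       {self.params}",
            "",
            "Cross-validation (mean ± SE over folds):",
        ]
        best = self.cv_results.sort_values("roc_auc_mean", ascending=False)
        for _, row in best.iterrows():
            setting = {
                k: int(row[k]) if float(row[k]).is_integer() else round(float(row[k]), 4)
                for k in self.params
                if k in row.index
            }
            lines.append(
                f"  {setting}: agreement {row['percent_agreement_mean']:.1f} "
                f"± {row['percent_agreement_se']:.1f} %, "
                f"ROC-AUC {row['roc_auc_mean']:.3f} ± {row['roc_auc_se']:.3f}, "
                f"κ {row['kappa_mean']:.3f} ± {row['kappa_se']:.3f}"
            )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist the artifact: JSON metadata + preprocess + estimator."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        metadata = {
            "algorithm": self.spec.algorithm,
            "n_grid_points": self.spec.n_grid_points,
            "cv_folds": self.spec.cv_folds,
            "seed": self.spec.seed,
            "params": self.params,
            "n_train_rows": self.n_train_rows,
            "n_train_participants": self.n_train_participants,
            "classes": list(self.classes),
        }
        (directory / "metadata.json").write_text(json.dumps(metadata, indent=2) + "\n")
        self.preprocess.to_json(directory / "preprocess.json")
        self.cv_results.to_csv(directory / "cv_results.csv", index=False)
        joblib.dump(self.estimator, directory / "estimator.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ActivityClassifierResults":
        directory = Path(directory)
        metadata = json.loads((directory / "metadata.json").read_text())
        spec = ClassifierSpec(
            algorithm=metadata["algorithm"],
            n_grid_points=metadata["n_grid_points"],
            cv_folds=metadata["cv_folds"],
            seed=metadata["seed"],
        )
        return cls(
            spec=spec,
            params=metadata["params"],
            cv_results=pd.read_csv(directory / "cv_results.csv"),
            preprocess=PreprocessState.from_json(directory / "preprocess.json"),
            estimator=joblib.load(directory / "estimator.joblib"),
            n_train_rows=metadata["n_train_rows"],
            n_train_participants=metadata["n_train_participants"],
        )
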