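"""Participant-level train/test splitting and feature preprocessing.

Splitting is grouped by participant: no individual contributes windows to
both sides, which would otherwise leak identity-specific signal into the
test set. Stratification uses each participant's activity-window
composition (quartiles of the jumping fraction) so train and test class
proportions stay close; when every participant performs the same fixed
protocol the strata are near-identical and the split degenerates
gracefully to a simple random participant split.

Preprocessing follows the usual tabular-ML recipe: drop near-zero-variance
features, then center and scale the rest. All statistics are estimated on
training rows only and applied unchanged to any other matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES


@dataclass(frozen=True)
class SplitSpec:
    """A participant-level partition into training and testing sets."""

    train_participants: tuple[str, ...]
    test_participants: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        train, test = set(self.train_participants), set(self.test_participants)
        if train & test:
            raise ValueError(f"participants on both sides of the split: {sorted(train & test)}")
        if not train or not test:
            raise ValueError("both split sides must be non-empty")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_participants": sorted(self.train_participants),
                    "test_participants": sorted(self.test_participants),
                    "seed": self.seed,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitSpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            train_participants=tuple(payload["train_participants"]),
            test_participants=tuple(payload["test_participants"]),
            seed=int(payload["seed"]),
        )


def split_participants(
    window_participants: Sequence[str],
    window_labels: Sequence[str],
    test_fraction: float = 0.2,
    seed: int = 0,
    n_strata: int = 4,
) -> SplitSpec:
    """Stratified participant-level split.

    Participants are ranked by the fraction of their windows labeled
    jumping, cut into ``n_strata`` rank strata, and the test set is drawn
    within strata (largest-remainder apportionment) so class proportions
    are maintained. ``round(test_fraction * n_participants)`` participants
    (at least 1) go to the test side. Deterministic given the seed.
    """
    if len(window_participants) != len(window_labels):
        raise ValueError("window_participants and window_labels must align")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    frame = pd.DataFrame({"participant": window_participants, "label": window_labels})
    participants = frame["participant"].unique()
    n = len(participants)
    if n < 5:
        raise ValueError(f"need at least 5 participants to stratify a split, got {n}")

    jumping_fraction = (
        frame.assign(is_jumping=frame["label"].eq("jumping"))
        .groupby("participant")["is_jumping"]
        .mean()
    )
    order = jumping_fraction.loc[participants].rank(method="first").to_numpy()
    n_strata = min(n_strata, n)
    strata = np.minimum((order - 1) * n_strata // n, n_strata - 1).astype(int)

    n_test = max(1, round(test_fraction * n))
    rng = np.random.default_rng(seed)
    # Largest-remainder apportionment of the test quota across strata.
    sizes = np.bincount(strata, minlength=n_strata)
    quotas = n_test * sizes / n
    take = np.floor(quotas).astype(int)
    remainder_order = np.argsort(-(quotas - take))
    for idx in remainder_order:
        if take.sum() >= n_test:
            break
        if take[idx] < sizes[idx]:
            take[idx] += 1
    test: list[str] = []
    for stratum in range(n_strata):
        members = participants[strata == stratum]
        if take[stratum] > 0 and len(members) > 0:
            chosen = rng.choice(members, size=min(take[stratum], len(members)), replace=False)
            test.extend(chosen.tolist())
    test_set = set(test)
    train = tuple(p for p in participants if p not in test_set)
    return SplitSpec(train_participants=train, test_participants=tuple(test), seed=seed)


@dataclass(frozen=True)
class PreprocessState:
    """Frozen preprocessing: near-zero-variance drops plus center/scale.

    Estimated once on training rows; application never re-estimates.
    """

    kept_features: tuple[str, ...]
    dropped_features: Mapping[str, str]
    center: Mapping[str, float]
    scale: Mapping[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kept_features": list(self.kept_features),
                    "dropped_features": dict(self.dropped_features),
                    "center": dict(self.center),
                    "scale": dict(self.scale),
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessState":
        payload = json.loads(Path(path).read_text())
        return cls(
            kept_features=tuple(payload["kept_features"]),
            dropped_features=payload["dropped_features"],
            center=payload["center"],
            scale=payload["scale"],
        )


def _near_zero_variance(
    column: np.ndarray, freq_ratio: float, unique_pct: float
) -> str | None:
    """Reason a column should be dropped, or None to keep it.

    The frequency-ratio rule: ratio of the most common value's count to the
    second most common's exceeds ``freq_ratio`` AND the percentage of
    distinct values is below ``unique_pct``.
    """
    if np.var(column) == 0.0:
        return "zero variance"
    values, counts = np.unique(column, return_counts=True)
    percent_unique = 100.0 * values.size / column.size
    counts_sorted = np.sort(counts)[::-1]
    ratio = counts_sorted[0] / counts_sorted[1] if counts_sorted.size > 1 else np.inf
    if ratio > freq_ratio and percent_unique < unique_pct:
        return "near-zero variance"
    return None


def fit_preprocess(
    train_matrix: pd.DataFrame,
    feature_columns: Sequence[str] | None = None,
    nzv_freq_ratio: float = 19.0,
    nzv_unique_pct: float = 10.0,
) -> PreprocessState:
    """Estimate the preprocessing state on training rows.

    Near-zero-variance features are dropped (zero variance, or frequency
    ratio > ``nzv_freq_ratio`` with percent-unique < ``nzv_unique_pct`` —
    the common 95/5 convention); the rest are centered on the training
    mean and scaled by the training (n-1) standard deviation.
    """
    if feature_columns is None:
        feature_columns = [c for c in FEATURE_NAMES if c in train_matrix.columns]
    if len(train_matrix) == 0:
        raise ValueError("cannot fit preprocessing on an empty training matrix")
    if len(train_matrix) < 2:
        raise ValueError("need at least 2 training rows to estimate scales")
    kept: list[str] = []
    dropped: dict[str, str] = {}
    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    for name in feature_columns:
        column = train_matrix[name].to_numpy(dtype=float)
        reason = _near_zero_variance(column, nzv_freq_ratio, nzv_unique_pct)
        if reason is not None:
            dropped[name] = reason
            continue
        kept.append(name)
        center[name] = float(np.mean(column))
        scale[name] = float(np.std(column, ddof=1))
    if not kept:
        raise ValueError("every feature was dropped as near-zero variance")
    return PreprocessState(
        kept_features=tuple(kept), dropped_features=dropped, center=center, scale=scale
    )


def apply_preprocess(state: PreprocessState, matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize a matrix with a fitted state (no re-estimation).

    Dropped feature columns are removed; kept ones are transformed to
    ``(x - center) / scale``. Non-feature (metadata) columns pass through
    unchanged.
    """
    missing = [c for c in state.kept_features if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix missing preprocessed feature column(s): {missing}")
    out = matrix.drop(columns=[c for c in state.dropped_features if c in matrix.columns]).copy()
    for name in state.kept_features:
        out[name] = (out[name].to_numpy(dtype=float) - state.center[name]) / state.scale[name]
    return out
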