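"""Per-side-effect and aggregate evaluation of triplet scores.

Scores are distances: lower means a more plausible interaction, so ranking
metrics are computed on negated scores.  AUC/AUPR are computed within each
side effect and macro-averaged (unweighted) over side effects.  Threshold
selection maximizes Youden's J over midpoints of the sorted unique scores.
The module also carries the external-validation machinery: per-pair
side-effect counting against a cutoff and a sampling-without-replacement
permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .triplets import TripletDataset

__all__ = [
    "PerSideEffectMetrics",
    "PairLabeling",
    "auc",
    "aupr",
    "optimal_threshold",
    "per_side_effect_report",
    "label_pairs_by_count",
    "mean_side_effects_per_pair",
    "permutation_test",
]


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC of distance scores (lower = positive); ties get half credit."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, -scores))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under precision-recall via step-wise integration (average precision)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(average_precision_score(labels, -scores))


def optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Pick the distance threshold maximizing Youden's J = sens + spec - 1.

    Candidates are midpoints of sorted unique scores; a triplet is predicted
    positive when its score is <= the threshold.  Ties in J go to the lower
    threshold.  Returns (threshold, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    if uniq.size == 1:
        # degenerate: everything predicted positive at the single value
        return float(uniq[0]), 1.0, 0.0
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    best = (-np.inf, np.inf, 0.0, 0.0)
    for thr in candidates:
        pred = scores <= thr
        sens = float(np.sum(pred & (labels == 1))) / n_pos
        spec = float(np.sum(~pred & (labels == 0))) / n_neg
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    return best[1], best[2], best[3]


@dataclass
class PerSideEffectMetrics:
    side_effect: str
    auc: float
    aupr: float
    sensitivity: float
    specificity: float
    precision: float
    threshold: float


def per_side_effect_report(
    scores: np.ndarray,
    dataset: TripletDataset,
    threshold_scores: np.ndarray | None = None,
    threshold_dataset: TripletDataset | None = None,
) -> tuple[list[PerSideEffectMetrics], dict]:
    """Metrics within each side effect plus unweighted macro averages.

    ``scores`` align row-wise with ``dataset.frame``.  If validation scores
    are supplied (``threshold_scores``/``threshold_dataset``), thresholds are
    selected there and applied to the test scores; otherwise they are chosen
    on the test scores themselves.  Side effects with a single class in the
    test set are excluded with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    frame = dataset.frame
    if len(scores) != len(frame):
        raise ValueError("scores must align with the dataset rows")
    thr_frame = threshold_dataset.frame if threshold_dataset is not None else None
    rows: list[PerSideEffectMetrics] = []
    for eff in dataset.side_effects:
        mask = (frame["side_effect"] == eff).to_numpy()
        s = scores[mask]
        y = frame.loc[mask, "label"].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            warnings.warn(f"side effect {eff!r} has a single class in test; excluded")
            continue
        if thr_frame is not None and threshold_scores is not None:
            vmask = (thr_frame["side_effect"] == eff).to_numpy()
            vy = thr_frame.loc[vmask, "label"].to_numpy(dtype=int)
            if vmask.any() and len(np.unique(vy)) == 2:
                thr, _, _ = optimal_threshold(
                    np.asarray(threshold_scores)[vmask], vy
                )
            else:
                thr, _, _ = optimal_threshold(s, y)
        else:
            thr, _, _ = optimal_threshold(s, y)
        pred = s <= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        rows.append(
            PerSideEffectMetrics(
                side_effect=eff,
                auc=auc(s, y),
                aupr=aupr(s, y),
                sensitivity=tp / (tp + fn) if tp + fn else 0.0,
                specificity=tn / (tn + fp) if tn + fp else 0.0,
                precision=tp / (tp + fp) if tp + fp else 0.0,
                threshold=float(thr),
            )
        )
    if not rows:
        raise ValueError("no evaluable side effects (need both classes in test)")
    macro = {
        "auc": float(np.mean([r.auc for r in rows])),
        "aupr": float(np.mean([r.aupr for r in rows])),
        "sensitivity": float(np.mean([r.sensitivity for r in rows])),
        "specificity": float(np.mean([r.specificity for r in rows])),
        "precision": float(np.mean([r.precision for r in rows])),
        "n_side_effects": len(rows),
    }
    return rows, macro


@dataclass
class PairLabeling:
    """Per-pair positive side-effect counts with a binary cutoff label."""

    counts: pd.Series  # index: (drug_a, drug_b) canonical order
    cutoff: int

    @property
    def labels(self) -> pd.Series:
        return (self.counts > self.cutoff).astype(int)


def label_pairs_by_count(
    predicted_positive_triplets: pd.DataFrame, cutoff: int = 65
) -> PairLabeling:
    """Label a drug pair positive when it exceeds ``cutoff`` predicted side effects.

    The inequality is strict: a pair with exactly ``cutoff`` predicted side
    effects is negative.  Input rows are (drug_i, drug_j, side_effect)
    predictions; pair order is ignored.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    df = predicted_positive_triplets.copy()
    a = np.minimum(df["drug_i"].astype(str), df["drug_j"].astype(str))
    b = np.maximum(df["drug_i"].astype(str), df["drug_j"].astype(str))
    key = pd.MultiIndex.from_arrays([a, b], names=["drug_a", "drug_b"])
    counts = (
        pd.DataFrame({"side_effect": df["side_effect"].values}, index=key)
        .groupby(level=[0, 1])["side_effect"]
        .nunique()
    )
    return PairLabeling(counts=counts, cutoff=cutoff)


def mean_side_effects_per_pair(ds: TripletDataset) -> float:
    """Positive triplets per distinct unordered drug pair."""
    pos = ds.frame[ds.frame["label"] == 1]
    if pos.empty:
        raise ValueError("no positive triplets")
    n_pairs = len(pos[["drug_i", "drug_j"]].drop_duplicates())
    return len(pos) / n_pairs


def permutation_test(
    observed_hits: int,
    candidate_pool: Sequence,
    hit_predicate: Callable[[object], bool],
    sample_size: int,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Permutation test of an observed hit count against random draws.

    Each of ``n_perm`` iterations draws ``sample_size`` items from the pool
    without replacement and counts hits.  The p-value is
    (1 + #{null >= observed}) / n_perm, clipped to 1, so a result exceeding
    every null draw reports the floor 1/n_perm.
    """
    pool = list(candidate_pool)
    if sample_size > len(pool):
        raise ValueError("sample_size exceeds the candidate pool")
    hits = np.array([bool(hit_predicate(x)) for x in pool])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    n = len(pool)
    for it in range(n_perm):
        idx = rng.choice(n, size=sample_size, replace=False)
        null[it] = int(hits[idx].sum())
    p = (1 + int(np.sum(null >= observed_hits))) / n_perm
    return min(1.0, p), null
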