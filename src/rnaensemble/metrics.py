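"""Evaluation metrics, prediction concordance and ensemble-combination search.

Base-pair prediction is scored as binary classification over the unordered
position pairs i < j of a sequence (the n(n-1)/2 upper-triangle universe;
this choice halves TN counts relative to scoring the full matrix and is
stated here because it changes INF magnitudes).  Scores: precision, recall,
F1, and the interaction network fidelity INF, which coincides numerically
with the Matthews correlation coefficient.  Concordance between two
predictions of the same sequence is the Jaccard distance between their
base-pair sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .structure_io import ContactMap


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and derived scores for one prediction."""

    TP: int
    FP: int
    TN: int
    FN: int
    precision: float
    recall: float
    f1: float
    inf: float

    @classmethod
    def from_counts(cls, TP: int, FP: int, TN: int, FN: int) -> "EvalResult":
        precision, recall, f1 = precision_recall_f1((TP, FP, TN, FN))
        return cls(TP, FP, TN, FN, precision, recall, f1, inf_score((TP, FP, TN, FN)))


def confusion(pred: ContactMap, truth: ContactMap) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) over unordered pairs i < j."""
    if pred.n != truth.n:
        raise ValueError(f"length mismatch: pred n={pred.n}, truth n={truth.n}")
    tp = len(pred.pairs & truth.pairs)
    fp = len(pred.pairs - truth.pairs)
    fn = len(truth.pairs - pred.pairs)
    tn = pred.n * (pred.n - 1) // 2 - tp - fp - fn
    return tp, fp, tn, fn


def precision_recall_f1(counts: Sequence[int]) -> tuple[float, float, float]:
    """Standard precision/recall/F1 with the 0/0 -> 0 convention."""
    TP, FP, TN, FN = counts
    precision = TP / (TP + FP) if TP + FP else 0.0
    recall = TP / (TP + FN) if TP + FN else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def inf_score(counts: Sequence[int]) -> float:
    """Interaction network fidelity (numerically the MCC); 0 on zero factors."""
    TP, FP, TN, FN = (float(c) for c in counts)
    denom2 = (TP + FP) * (TN + FP) * (TP + FN) * (TN + FN)
    if denom2 == 0:
        return 0.0
    return (TP * TN - FP * FN) / float(np.sqrt(denom2))


def evaluate(pred: ContactMap, truth: ContactMap) -> EvalResult:
    return EvalResult.from_counts(*_reorder(confusion(pred, truth)))


def _reorder(c: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    tp, fp, tn, fn = c
    return tp, fp, tn, fn


def jaccard_distance(A: ContactMap, B: ContactMap) -> float:
    """J(A, B) = (|A u B| - |A n B|) / |A u B| over pair sets; 0 if both empty."""
    union = A.pairs | B.pairs
    if not union:
        return 0.0
    return (len(union) - len(A.pairs & B.pairs)) / len(union)


def pairwise_concordance(
    predictions: Mapping[str, Sequence[ContactMap]]
) -> pd.DataFrame:
    """Mean Jaccard distance between every two algorithms over shared samples."""
    names = list(predictions)
    lengths = {len(v) for v in predictions.values()}
    if len(lengths) != 1:
        raise ValueError("all algorithms must predict the same sample list")
    D = np.zeros((len(names), len(names)))
    for a, b in combinations(range(len(names)), 2):
        dists = [
            jaccard_distance(x, y)
            for x, y in zip(predictions[names[a]], predictions[names[b]])
        ]
        D[a, b] = D[b, a] = float(np.mean(dists))
    return pd.DataFrame(D, index=names, columns=names)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_points(
    Y_list: Sequence[np.ndarray],
    truth_list: Sequence[ContactMap],
    masks: Sequence[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled ROC over upper-triangle cells; returns (fpr, tpr, auc).

    Scores from all sequences are pooled; ``masks`` optionally restricts to
    allowed cells (e.g. the constraint mask).  The area is trapezoidal.
    """
    scores, labels = [], []
    for k, (Y, truth) in enumerate(zip(Y_list, truth_list)):
        n = truth.n
        iu = np.triu_indices(n, k=1)
        s = 0.5 * (Y + Y.T)[iu]
        z = truth.matrix()[iu]
        if masks is not None:
            keep = np.asarray(masks[k])[iu] > 0
            s, z = s[keep], z[keep]
        scores.append(s)
        labels.append(z)
    s = np.concatenate(scores)
    z = np.concatenate(labels)
    order = np.argsort(-s, kind="stable")
    z = z[order]
    tps = np.cumsum(z)
    fps = np.cumsum(1 - z)
    P, N = tps[-1], fps[-1]
    # collapse threshold ties: keep the last point of each distinct score
    distinct = np.r_[np.nonzero(np.diff(s[order]))[0], len(z) - 1]
    tpr = np.r_[0.0, tps[distinct] / max(P, 1)]
    fpr = np.r_[0.0, fps[distinct] / max(N, 1)]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# Combination search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationReport:
    """F1 of every nonempty learner subset plus a best-by-size summary."""

    per_subset: pd.DataFrame  # columns: subset, size, mean_f1, median_f1
    per_size: pd.DataFrame  # columns: size, best_median_f1, best_subset


def combination_search(
    records,
    stacks,
    cfg=None,
    train_fraction: float = 0.8,
    force: bool = False,
    epochs: int = 8,
) -> CombinationReport:
    """Train a lite ensemble on every nonempty learner subset and score it.

    The sample list is split (in order) into training and evaluation parts;
    for each of the 2^l - 1 subsets a lite ensemble is trained on the
    training part and its median/mean F1 on the evaluation part recorded.
    Refuses l > 10 without ``force`` (exponential blow-up).
    """
    from .trainer import TrainConfig, dataset_views, train
    from .decoder import decode

    l = stacks[0].l
    if l > 10 and not force:
        raise ValueError(f"{l} learners means {2**l - 1} subsets; pass force=True")
    if cfg is None:
        cfg = TrainConfig(epochs=epochs)
    names = stacks[0].learner_names
    n_train = int(round(train_fraction * len(records)))
    rows = []
    for size in range(1, l + 1):
        for subset in combinations(range(l), size):
            sub_stacks = [s.subset(subset) for s in stacks]
            train_view, val_view = dataset_views(records, sub_stacks)
            params, _ = train(
                train_view[:n_train], val_view[n_train:], cfg, model="lite"
            )
            f1s = []
            for rec, stack in zip(records[n_train:], sub_stacks[n_train:]):
                from .ensemble_net import lite_forward

                pred = decode(lite_forward(stack, params), rec.sequence, cfg.decoder)
                f1s.append(precision_recall_f1(confusion(pred, rec.structure))[2])
            rows.append(
                {
                    "subset": "+".join(names[i] for i in subset),
                    "size": size,
                    "mean_f1": float(np.mean(f1s)),
                    "median_f1": float(np.median(f1s)),
                }
            )
    per_subset = pd.DataFrame(rows)
    best_rows = []
    for size in range(1, l + 1):
        upto = per_subset[per_subset["size"] <= size]
        best = upto.loc[upto["median_f1"].idxmax()]
        best_rows.append(
            {
                "size": size,
                "best_median_f1": float(best["median_f1"]),
                "best_subset": best["subset"],
            }
        )
    return CombinationReport(per_subset=per_subset, per_size=pd.DataFrame(best_rows))


# ---------------------------------------------------------------------------
# PCA of per-structure error maps
# ---------------------------------------------------------------------------

def pca_error_embedding(
    predictions: Mapping[str, Sequence[ContactMap]],
    truths: Sequence[ContactMap],
) -> pd.DataFrame:
    """Embed algorithms in 2-D by PCA of concatenated squared-error maps.

    Each algorithm's feature vector concatenates, over all sequences, the
    flattened squared error of its contact map against the ground truth;
    PCA across algorithms yields the first two component scores.
    """
    names = list(predictions)
    feats = []
    for name in names:
        parts = [
            ((p.matrix() - t.matrix()) ** 2).ravel()
            for p, t in zip(predictions[name], truths)
        ]
        feats.append(np.concatenate(parts))
    X = np.stack(feats)
    k = min(2, len(names), X.shape[1])
    pca = PCA(n_components=k, random_state=0)
    coords = pca.fit_transform(X)
    if k < 2:  # degenerate: fewer than two algorithms/features
        coords = np.pad(coords, ((0, 0), (0, 2 - k)))
    return pd.DataFrame(coords, index=names, columns=["PC1", "PC2"])
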