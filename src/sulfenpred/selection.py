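"""Feature ranking and subset selection.

The pipeline mirrors classic filter-plus-wrapper selection for
high-dimensional motif encodings:

1. every continuous feature is discretized by supervised entropy-based
   binning with the Fayyad-Irani minimum-description-length (MDL)
   stopping rule;
2. features are ranked by greedy mRMR with the MID (mutual-information
   difference) criterion on the discretized copies;
3. a forward incremental pass walks the ranking and keeps a feature only
   when it does not hurt either of two cross-validated wrapper models
   (a random forest and an SVM), stopping once the AUC curve has passed
   its peak;
4. random-forest permutation importance is computed on out-of-bag
   samples (per-tree correct-classification difference).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils import check_random_state

from .evaluation import CVSpec, cross_validate, roc_auc

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MDL (Fayyad-Irani) supervised discretization


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy in bits from non-negative class counts."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mdl_split(sorted_values, prefix, lo, hi, cuts):
    """Recursively split [lo, hi) of the sorted feature; append cut values."""
    total = prefix[hi] - prefix[lo]
    n = total.sum()
    if n < 2:
        return
    ent_s = _entropy_from_counts(total)
    # Candidate boundaries: value changes between adjacent sorted samples.
    idx = np.arange(lo + 1, hi)
    idx = idx[sorted_values[idx] != sorted_values[idx - 1]]
    if idx.size == 0:
        return
    left = prefix[idx] - prefix[lo]          # (m, k) class counts left of cut
    right = total - left
    nl = left.sum(axis=1)
    nr = right.sum(axis=1)

    def ent_rows(c):
        s = c.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(s > 0, c / np.maximum(s, 1), 0.0)
            term = np.where(p > 0, p * np.log2(p), 0.0)
        return -term.sum(axis=1)

    weighted = (nl * ent_rows(left) + nr * ent_rows(right)) / n
    gains = ent_s - weighted
    best = int(np.argmax(gains))
    gain = gains[best]

    k = int((total > 0).sum())
    k1 = int((left[best] > 0).sum())
    k2 = int((right[best] > 0).sum())
    ent1 = _entropy_from_counts(left[best])
    ent2 = _entropy_from_counts(right[best])
    delta = math.log2(3**k - 2) - (k * ent_s - k1 * ent1 - k2 * ent2)
    threshold = (math.log2(n - 1) + delta) / n
    if gain <= threshold:
        return
    cut_at = int(idx[best])
    cuts.append((sorted_values[cut_at - 1] + sorted_values[cut_at]) / 2.0)
    _mdl_split(sorted_values, prefix, lo, cut_at, cuts)
    _mdl_split(sorted_values, prefix, cut_at, hi, cuts)


def mdl_discretize(values, labels) -> tuple[np.ndarray, list[float]]:
    """Supervised entropy binning with the MDL stopping criterion.

    Returns the discretized copy (integer bin codes) and the sorted list
    of accepted cut points. A feature for which no cut passes the MDL
    test — constant features included — collapses to a single bin.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.ndim != 1 or v.shape != y.shape:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    classes, y_codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("mdl_discretize requires at least 2 classes")
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    onehot = np.zeros((v.size, classes.size))
    onehot[np.arange(v.size), y_codes[order]] = 1.0
    prefix = np.vstack([np.zeros(classes.size), np.cumsum(onehot, axis=0)])
    cuts: list[float] = []
    _mdl_split(sv, prefix, 0, v.size, cuts)
    cuts.sort()
    codes = np.searchsorted(np.asarray(cuts), v, side="right")
    return codes.astype(np.int64), cuts


# ---------------------------------------------------------------------------
# mutual information and mRMR


def mutual_information(a, b) -> float:
    """Plug-in mutual information (natural log) between discrete vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=na * nb).astype(float)
    joint /= joint.sum()
    pa = joint.reshape(na, nb).sum(axis=1)
    pb = joint.reshape(na, nb).sum(axis=0)

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    return max(0.0, h(pa) + h(pb) - h(joint))


@dataclass
class SelectionResult:
    """mRMR ranking plus the forward-selection trajectory and subset."""

    ranking: list[tuple[str, float]]
    trajectory: list[tuple[int, float, float]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    peak_index: int = -1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "ranking": self.ranking,
                    "trajectory": self.trajectory,
                    "selected": self.selected,
                    "peak_index": self.peak_index,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            ranking=[tuple(r) for r in d["ranking"]],
            trajectory=[tuple(t) for t in d["trajectory"]],
            selected=list(d["selected"]),
            peak_index=int(d["peak_index"]),
        )


def discretize_matrix(X, labels) -> np.ndarray:
    """MDL-discretize every column of X; returns integer codes."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        out[:, j], _ = mdl_discretize(X[:, j], labels)
    return out


def mrmr_rank(
    X,
    labels,
    n: int,
    feature_names: Sequence[str] | None = None,
    discretized: np.ndarray | None = None,
) -> list[tuple[str, float]]:
    """Greedy mRMR ranking with the MID criterion.

    At each step the remaining feature maximizing
    ``I(f; y) - mean_{s in selected} I(f; s)`` is appended; mutual
    information is computed on MDL-discretized copies. Ties break by
    column order. Raises on an all-constant matrix (no feature carries
    any discretizable signal).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    n_feat = X.shape[1]
    if n > n_feat:
        raise ValueError(f"n={n} exceeds {n_feat} features")
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(n_feat)
    ]
    if np.all(X.max(axis=0) == X.min(axis=0)):
        raise ValueError("all features are constant")
    D = discretized if discretized is not None else discretize_matrix(X, y)
    # Bin codes are already dense 0..n_bins-1; cache widths and entropies.
    # Features whose discretization collapses to one bin carry no
    # discretizable signal; they keep zero relevance and rank last in
    # column order (a null dataset still yields a valid ranking).
    n_bins = D.max(axis=0).astype(np.int64) + 1
    n_samp = D.shape[0]
    _, y_codes = np.unique(y, return_inverse=True)
    ny = int(y_codes.max()) + 1

    def _h(counts: np.ndarray) -> float:
        p = counts[counts > 0] / n_samp
        return float(-(p * np.log(p)).sum())

    col_entropy = np.array(
        [_h(np.bincount(D[:, j], minlength=n_bins[j]).astype(float))
         for j in range(n_feat)]
    )
    h_y = _h(np.bincount(y_codes).astype(float))

    def _mi(j: int, other: np.ndarray, n_other: int, h_other: float) -> float:
        joint = np.bincount(
            D[:, j] * n_other + other, minlength=n_bins[j] * n_other
        ).astype(float)
        return max(0.0, col_entropy[j] + h_other - _h(joint))

    relevance = np.array(
        [_mi(j, y_codes, ny, h_y) if n_bins[j] > 1 else 0.0
         for j in range(n_feat)]
    )

    selected: list[int] = []
    red_sum = np.zeros(n_feat)
    remaining = np.ones(n_feat, dtype=bool)
    ranking: list[tuple[str, float]] = []
    for _ in range(n):
        k = len(selected)
        scores = relevance - (red_sum / k if k else 0.0)
        scores = np.where(remaining, scores, -np.inf)
        j = int(np.argmax(scores))  # first max = column-order tie-break
        ranking.append((names[j], float(scores[j])))
        selected.append(j)
        remaining[j] = False
        if len(selected) < n and n_bins[j] > 1:
            dj = D[:, j]
            hj = col_entropy[j]
            nj = int(n_bins[j])
            for m in np.nonzero(remaining)[0]:
                # single-bin features have zero MI with anything
                if n_bins[m] > 1:
                    red_sum[m] += _mi(m, dj, nj, hj)
    return ranking


# ---------------------------------------------------------------------------
# forward incremental selection


def _default_wrappers(seed: int, rf_trees: int = 100):
    rf = RandomForestClassifier(
        n_estimators=rf_trees, class_weight="balanced", random_state=seed,
        n_jobs=1,
    )
    # Standardized inputs keep the SMO solver's iteration count bounded
    # on raw feature columns of wildly different scales.
    svm = make_pipeline(
        StandardScaler(),
        SVC(kernel="rbf", gamma="scale", max_iter=200_000, random_state=seed),
    )
    return rf, svm


def _cv_auc(model, X, y, cv: CVSpec, use_decision: bool) -> float:
    def fit_score(Xtr, ytr, Xte):
        model.fit(Xtr, ytr)
        if use_decision:
            return model.decision_function(Xte)
        return model.predict_proba(Xte)[:, 1]

    return cross_validate(fit_score, X, y, cv)["pooled"].auc


def forward_incremental_select(
    ranking: list[tuple[str, float]],
    X,
    labels,
    feature_names: Sequence[str],
    cv: CVSpec | None = None,
    patience: int = 20,
    rf_trees: int = 100,
) -> SelectionResult:
    """Walk the mRMR ranking, growing the subset under a dual-model rule.

    A candidate is kept iff adding it does not decrease either the RF or
    the SVM cross-validated AUC and strictly increases at least one.
    The walk stops after ``patience`` consecutive rejections beyond the
    running AUC peak, or at the end of the ranking.
    """
    if not ranking:
        raise ValueError("empty ranking")
    cv = cv or CVSpec(n_folds=5, seed=0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(int)
    cv.check(y)
    col = {name: j for j, name in enumerate(feature_names)}
    rf, svm = _default_wrappers(cv.seed, rf_trees)

    selected: list[str] = []
    trajectory: list[tuple[int, float, float]] = []
    best_rf = best_svm = 0.0
    peak_index = -1
    rejections = 0
    for name, _score in ranking:
        trial = selected + [name]
        Xt = X[:, [col[f] for f in trial]]
        auc_rf = _cv_auc(rf, Xt, y, cv, use_decision=False)
        auc_svm = _cv_auc(svm, Xt, y, cv, use_decision=True)
        trajectory.append((len(trial), auc_rf, auc_svm))
        improves = auc_rf > best_rf or auc_svm > best_svm
        degrades = auc_rf < best_rf or auc_svm < best_svm
        if improves and not degrades:
            selected.append(name)
            best_rf, best_svm = auc_rf, auc_svm
            peak_index = len(trajectory) - 1
            rejections = 0
        else:
            rejections += 1
            if rejections >= patience:
                break
    return SelectionResult(
        ranking=list(ranking),
        trajectory=trajectory,
        selected=selected,
        peak_index=peak_index,
    )


# ---------------------------------------------------------------------------
# random-forest permutation importance on out-of-bag samples


def _oob_indices(tree, n_samples: int) -> np.ndarray:
    """Out-of-bag sample indices of one tree, reconstructed from its seed.

    Replicates the forest's bootstrap draw: ``n_samples`` indices with
    replacement from ``RandomState(tree.random_state)``.
    """
    rng = check_random_state(tree.random_state)
    sampled = rng.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.nonzero(mask)[0]


def rf_permutation_importance(
    model: RandomForestClassifier, X, labels, seed: int = 0
) -> np.ndarray:
    """Per-feature OOB permutation importance.

    For each tree, the importance contribution of feature j is the drop
    in the count of correctly classified out-of-bag samples after
    permuting column j, divided by the OOB size; the reported importance
    is the mean over trees. Permuting a feature the forest never splits
    on yields exactly 0.
    """
    if not getattr(model, "bootstrap", False):
        raise ValueError("permutation importance needs a bootstrap forest "
                         "(no out-of-bag samples otherwise)")
    if not hasattr(model, "estimators_"):
        raise ValueError("model is not fitted")
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    n, p = X.shape
    rng = np.random.RandomState(seed)
    imp = np.zeros(p)
    for tree in model.estimators_:
        oob = _oob_indices(tree, n)
        if oob.size == 0:
            continue
        Xo = X[oob]
        yo = y[oob]
        correct = float(np.sum(tree.predict(Xo) == yo))
        used = set(tree.tree_.feature[tree.tree_.feature >= 0].tolist())
        for j in range(p):
            if j not in used:
                continue  # identical predictions; difference identically 0
            Xp = Xo.copy()
            Xp[:, j] = Xo[rng.permutation(oob.size), j]
            correct_perm = float(np.sum(tree.predict(Xp) == yo))
            imp[j] += (correct - correct_perm) / oob.size
    return imp / len(model.estimators_)
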