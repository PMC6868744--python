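"""Two-stage stacked ensemble for sulphenylation-site prediction.

Stage 1 trains one random forest and one SVM per feature set (the nine
encoder clusters plus the selected-feature subset, ten sets in total).
Their out-of-fold positive-class probabilities — never in-sample scores,
which would leak the training labels into the meta level — form a
20-column matrix. Stage 2 fits a small feed-forward neural network
(logistic activations, one hidden unit and L2 weight decay 0.1 by
default) on that matrix to produce the final probability.

The RF tree count follows the square-root-of-predictors rule, floored
at a configurable minimum (a literal sqrt(20) forest for the AAC block
would be statistically meaningless). The SVM kernel (linear, polynomial
or RBF) is chosen per feature set by cross-validated AUC; the winning
kernel is refit with Platt-calibrated probability outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .encoders import EncoderConfig, FeatureMatrix, MinMaxParams, assemble_feature_matrix
from .evaluation import CVSpec, roc_auc
from .motif_io import MotifDataset

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "sulfenpred-model-1"

SVM_KERNELS = ("linear", "poly", "rbf")

#: Name of the selected-feature set alongside the nine encoder clusters.
SELECTED_SET = "SELECTED"


@dataclass(frozen=True)
class BaseModelSpec:
    """Record of one trained stage-1 learner."""

    set_name: str
    algorithm: str  # "RF" | "SVM"
    kernel: str | None
    n_features: int
    cv_auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cv_auc <= 1.0:
            raise ValueError(f"cv_auc {self.cv_auc} outside [0,1]")


def labels_to_binary(dataset: MotifDataset) -> np.ndarray:
    y = np.array([1 if lab == "positive" else 0 for lab in dataset.labels])
    return y


def feature_sets_from_matrix(
    fm: FeatureMatrix, selected_features: Sequence[str] | None
) -> dict[str, np.ndarray]:
    """Split a feature matrix into per-cluster sets plus the selected set."""
    sets = {b.cluster_name: b.values for b in fm.blocks}
    if selected_features:
        names = fm.feature_names
        col = {n: j for j, n in enumerate(names)}
        missing = [f for f in selected_features if f not in col]
        if missing:
            raise ValueError(f"selected feature(s) absent from matrix: {missing[:5]}")
        sets[SELECTED_SET] = fm.values[:, [col[f] for f in selected_features]]
    return sets


def rf_tree_count(n_features: int, min_trees: int = 100) -> int:
    """Square root of the predictor count, floored at ``min_trees``."""
    return max(min_trees, int(round(np.sqrt(n_features))))


def _make_rf(n_features: int, seed: int, min_trees: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=rf_tree_count(n_features, min_trees),
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )


def _make_svm(kernel: str, seed: int, probability: bool):
    # Features are standardized inside the estimator: the SMO solver's
    # iteration count explodes on raw columns whose scales differ by
    # orders of magnitude, and the kernel-SVM implementations this design
    # follows scale by default. max_iter bounds the worst case.
    svc = make_pipeline(
        StandardScaler(),
        SVC(kernel=kernel, gamma="scale", max_iter=200_000, random_state=seed),
    )
    if not probability:
        return svc
    # Platt-calibrated probabilities (sigmoid on decision values).
    return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)


def train_base_models(
    feature_sets: dict[str, np.ndarray],
    labels,
    cv: CVSpec,
    min_trees: int = 100,
    svm_kernels: Sequence[str] = SVM_KERNELS,
) -> tuple[dict[str, dict], np.ndarray, list[BaseModelSpec]]:
    """Train the per-set RF and SVM learners and collect stacking inputs.

    Returns ``(models, oof, specs)`` where ``oof`` is the
    (n_samples, 2 * n_sets) matrix of out-of-fold positive-class
    probabilities, column order ``[rf_set1, svm_set1, rf_set2, ...]``.
    The returned models are refit on the full training data for
    prediction time.
    """
    y = np.asarray(labels).astype(int)
    cv.check(y)
    for name, X in feature_sets.items():
        if X.shape[1] == 0:
            raise ValueError(f"feature set {name!r} has zero columns")
        if X.shape[0] != y.size:
            raise ValueError(f"feature set {name!r} row count mismatch")
    folds = list(cv.splitter().split(next(iter(feature_sets.values())), y))

    models: dict[str, dict] = {}
    specs: list[BaseModelSpec] = []
    oof_cols: list[np.ndarray] = []
    for name, X in feature_sets.items():
        X = np.asarray(X, dtype=float)
        p = X.shape[1]

        # --- random forest ---
        oof_rf = np.full(y.shape, np.nan)
        for tr, te in folds:
            rf = _make_rf(p, cv.seed, min_trees)
            rf.fit(X[tr], y[tr])
            oof_rf[te] = rf.predict_proba(X[te])[:, 1]
        rf_auc = roc_auc(y, oof_rf)
        rf_full = _make_rf(p, cv.seed, min_trees).fit(X, y)

        # --- SVM: pick the kernel by CV AUC on decision values, then
        # produce calibrated out-of-fold probabilities with the winner ---
        kernel_aucs: dict[str, float] = {}
        for kernel in svm_kernels:
            dec = np.full(y.shape, np.nan)
            for tr, te in folds:
                svm = _make_svm(kernel, cv.seed, probability=False)
                svm.fit(X[tr], y[tr])
                dec[te] = svm.decision_function(X[te])
            kernel_aucs[kernel] = roc_auc(y, dec)
        best_kernel = max(kernel_aucs, key=lambda k: (kernel_aucs[k], -list(
            svm_kernels).index(k)))
        oof_svm = np.full(y.shape, np.nan)
        for tr, te in folds:
            svm = _make_svm(best_kernel, cv.seed, probability=True)
            svm.fit(X[tr], y[tr])
            oof_svm[te] = svm.predict_proba(X[te])[:, 1]
        svm_auc = roc_auc(y, oof_svm)
        svm_full = _make_svm(best_kernel, cv.seed, probability=True).fit(X, y)

        models[name] = {"rf": rf_full, "svm": svm_full, "svm_kernel": best_kernel}
        specs.append(BaseModelSpec(name, "RF", None, p, rf_auc))
        specs.append(BaseModelSpec(name, "SVM", best_kernel, p, svm_auc))
        oof_cols.extend([oof_rf, oof_svm])
        logger.info("base models for %s: RF AUC %.3f, SVM(%s) AUC %.3f",
                    name, rf_auc, best_kernel, svm_auc)
    oof = np.column_stack(oof_cols)
    return models, oof, specs


def _make_meta(units: int, decay: float, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(units,),
        activation="logistic",
        solver="lbfgs",
        alpha=decay,
        max_iter=5000,
        random_state=seed,
    )


def train_meta_network(
    oof_scores,
    labels,
    units: int = 1,
    decay: float = 0.1,
    seed: int = 0,
) -> MLPClassifier:
    """Fit the stage-2 feed-forward network on stacking inputs.

    A single hidden layer with logistic activations and L2 weight decay,
    trained to convergence by L-BFGS from a seeded initialization. The
    bias terms of the hidden and output layers play the role of the
    balancing nodes of the classic three-layer formulation.
    """
    X = np.asarray(oof_scores, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("meta-network inputs must be finite")
    y = np.asarray(labels).astype(int)
    net = _make_meta(units, decay, seed)
    net.fit(X, y)
    return net


def meta_grid_search(
    oof_scores,
    labels,
    cv: CVSpec,
    units_grid: Sequence[int] = (1, 3, 5),
    decay_grid: Sequence[float] = (0.0, 4e-4, 0.1),
) -> dict[tuple[int, float], float]:
    """Cross-validated AUC for each (hidden units, weight decay) cell."""
    X = np.asarray(oof_scores, dtype=float)
    y = np.asarray(labels).astype(int)
    cv.check(y)
    folds = list(cv.splitter().split(X, y))
    out: dict[tuple[int, float], float] = {}
    for units in units_grid:
        for decay in decay_grid:
            scores = np.full(y.shape, np.nan)
            for tr, te in folds:
                net = _make_meta(units, decay, cv.seed)
                net.fit(X[tr], y[tr])
                scores[te] = net.predict_proba(X[te])[:, 1]
            out[(units, float(decay))] = roc_auc(y, scores)
    return out


@dataclass
class StackedModel:
    """The full two-stage model plus everything needed to re-encode."""

    config: EncoderConfig
    clusters: list[str]
    selected_features: list[str]
    set_names: list[str]
    base_models: dict[str, dict]
    specs: list[BaseModelSpec]
    meta: MLPClassifier
    acc_norm: MinMaxParams | None
    threshold: float = 0.5
    seed: int = 0
    version: str = MODEL_FORMAT_VERSION

    def base_probabilities(self, feature_sets: dict[str, np.ndarray]) -> np.ndarray:
        cols = []
        for name in self.set_names:
            if name not in feature_sets:
                raise ValueError(f"feature set {name!r} missing at prediction time")
            X = np.asarray(feature_sets[name], dtype=float)
            pair = self.base_models[name]
            cols.append(pair["rf"].predict_proba(X)[:, 1])
            cols.append(pair["svm"].predict_proba(X)[:, 1])
        return np.column_stack(cols)


def train_stacked(
    fm: FeatureMatrix,
    labels,
    selected_features: Sequence[str] | None,
    cv: CVSpec | None = None,
    units: int = 1,
    decay: float = 0.1,
    min_trees: int = 100,
    threshold: float = 0.5,
    config: EncoderConfig | None = None,
) -> tuple[StackedModel, np.ndarray]:
    """Train stage 1 and stage 2; returns the model and the OOF matrix."""
    cv = cv or CVSpec()
    y = np.asarray(labels).astype(int)
    sets = feature_sets_from_matrix(fm, selected_features)
    models, oof, specs = train_base_models(sets, y, cv, min_trees=min_trees)
    meta = train_meta_network(oof, y, units=units, decay=decay, seed=cv.seed)
    stacked = StackedModel(
        config=config or EncoderConfig(),
        clusters=fm.cluster_names(),
        selected_features=list(selected_features or []),
        set_names=list(sets.keys()),
        base_models=models,
        specs=specs,
        meta=meta,
        acc_norm=fm.acc_norm,
        threshold=threshold,
        seed=cv.seed,
    )
    return stacked, oof


def predict_stacked(
    model: StackedModel, dataset: MotifDataset, providers=None
) -> dict[str, np.ndarray]:
    """Score motifs through the full two-stage model.

    Motifs are encoded with the training-time configuration and
    normalization constants; deterministic given (model, inputs).
    """
    fm = assemble_feature_matrix(
        dataset,
        blocks=model.clusters,
        providers=providers,
        config=model.config,
        acc_norm=model.acc_norm,
    )
    sets = feature_sets_from_matrix(fm, model.selected_features or None)
    base = model.base_probabilities(sets)
    prob = model.meta.predict_proba(base)[:, 1]
    return {
        "probability": prob,
        "label": (prob >= model.threshold).astype(int),
        "base_probabilities": base,
    }


def save_model(model: StackedModel, path: str | Path) -> None:
    joblib.dump({"version": model.version, "model": model}, path)


def load_model(path: str | Path) -> StackedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted archive
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "version" not in payload:
        raise ValueError(f"{path} is not a sulfenpred model archive")
    if payload["version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format {payload['version']!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION!r})"
        )
    return payload["model"]
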