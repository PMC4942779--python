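"""Two-class LDA with LD-value thresholding, leave-one-out cross-validation
and greedy forward feature selection — one model per histological index.

The discriminant is Fisher's: pooled within-class covariance S_w
(denominator n-2), ridge-regularised as S_w + lambda*(tr(S_w)/d)*I, weights
w = S_w^-1 (mu_alt - mu_0) and an equal-prior midpoint threshold
t = w.(mu_0 + mu_alt)/2, with the sign convention LD(mu_alt) > t. Features
are z-scored on the training data (re-derived inside every LOO fold, so no
information leaks from the held-out sample). Feature selection is a greedy
forward search maximising LOO accuracy, as transparent stand-in for the
"best LOO accuracy over feature groups" procedure; subset-size caps default
to 10 features for architecture and 20 for chronicity/activity.

`TwoClassLDA` and `GreedyLDASelector` are scikit-learn style estimators;
`fit_lda`, `loo_cv`, `select_features` and `predict_indices` are thin
functional wrappers.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import DegenerateClassesError, FeatureMismatchError
from .ranking import rank_features
from .types import FeatureTable, IndexLabels, labels_to_frame

DEFAULT_MAX_FEATURES = {"architecture": 10, "chronicity": 20, "activity": 20}


def _lda_solve(X: np.ndarray, y01: np.ndarray, lam: float
               ) -> Tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Weights and midpoint threshold on (already standardised) data."""
    X0, X1 = X[y01 == 0], X[y01 == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    d = X.shape[1]
    A0, A1 = X0 - mu0, X1 - mu1
    sw = (A0.T @ A0 + A1.T @ A1) / (len(X) - 2)
    scale = np.trace(sw) / d
    if scale <= 0:
        scale = 1.0
    reg = sw + lam * scale * np.eye(d)
    try:
        w = np.linalg.solve(reg, mu1 - mu0)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(reg, mu1 - mu0, rcond=None)[0]
    t = float(w @ (mu0 + mu1) / 2.0)
    return w, t, mu0, mu1


class TwoClassLDA(BaseEstimator, ClassifierMixin):
    """Fisher LDA for two classes with a midpoint LD threshold.

    Parameters
    ----------
    reg_lambda : float, default 1e-3
        Relative ridge on the pooled covariance,
        S_w + reg_lambda * (tr(S_w)/d) * I.
    standardize : bool, default True
        z-score features on the training data before fitting.

    Attributes (after fit)
    ----------------------
    classes_ : sorted class codes (level_0, level_alt)
    weights_ : discriminant weights in standardised space
    threshold_ : midpoint threshold t; predict returns level_alt iff LD > t
        (ties go to level_0)
    degenerate_ : True when the class means coincide (w ~ 0); prediction
        falls back to the majority training class.
    """

    def __init__(self, reg_lambda: float = 1e-3, standardize: bool = True):
        self.reg_lambda = reg_lambda
        self.standardize = standardize

    # -- helpers ---------------------------------------------------------
    def _coerce(self, X, fit: bool):
        if isinstance(X, pd.DataFrame):
            if fit:
                self.feature_names_in_ = list(X.columns)
            else:
                names = getattr(self, "feature_names_in_", None)
                if names is not None:
                    missing = [n for n in names if n not in X.columns]
                    if missing:
                        raise FeatureMismatchError(f"missing feature(s): {missing}")
                    X = X[names]
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not fit and hasattr(self, "n_features_in_") and X.shape[1] != self.n_features_in_:
            raise FeatureMismatchError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def fit(self, X, y):
        X = self._coerce(X, fit=True)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise DegenerateClassesError(
                f"need exactly two classes, got {classes.tolist()}"
            )
        if counts.min() < 2:
            raise DegenerateClassesError("each class needs >= 2 samples")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_
        y01 = (y == classes[1]).astype(int)
        w, t, mu0, mu1 = _lda_solve(Xs, y01, self.reg_lambda)
        self.weights_ = w
        self.threshold_ = t
        self.degenerate_ = bool(np.allclose(mu0, mu1))
        if self.degenerate_:
            warnings.warn("identical class means: falling back to majority class",
                          stacklevel=2)
        # tie toward level_0 when counts are equal
        self.majority_class_ = classes[int(counts[1] > counts[0])]
        return self

    def project(self, X) -> np.ndarray:
        """Raw LD values w.x (standardised space)."""
        X = self._coerce(X, fit=False)
        Xs = (X - self.mean_) / self.scale_
        return Xs @ self.weights_

    def decision_function(self, X) -> np.ndarray:
        return self.project(X) - self.threshold_

    def predict(self, X) -> np.ndarray:
        ld = self.project(X)
        if self.degenerate_:
            return np.full(len(ld), self.majority_class_)
        return np.where(ld > self.threshold_, self.classes_[1], self.classes_[0])

    @property
    def effective_weights_(self) -> np.ndarray:
        """Weights expressed against raw (unstandardised) features."""
        return self.weights_ / self.scale_

    # -- persistence -----------------------------------------------------
    def to_dict(self, feature_names: Sequence[str] | None = None) -> dict:
        return {
            "feature_names": list(feature_names
                                  if feature_names is not None
                                  else getattr(self, "feature_names_in_", [])),
            "weights": self.weights_.tolist(),
            "threshold": self.threshold_,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "classes": [int(c) for c in self.classes_],
            "reg_lambda": self.reg_lambda,
            "standardize": self.standardize,
            "degenerate": self.degenerate_,
            "majority_class": int(self.majority_class_),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "TwoClassLDA":
        model = cls(reg_lambda=payload["reg_lambda"],
                    standardize=payload["standardize"])
        model.feature_names_in_ = list(payload["feature_names"]) or None
        if model.feature_names_in_ is None:
            del model.feature_names_in_
        model.weights_ = np.asarray(payload["weights"], dtype=float)
        model.threshold_ = float(payload["threshold"])
        model.mean_ = np.asarray(payload["mean"], dtype=float)
        model.scale_ = np.asarray(payload["scale"], dtype=float)
        model.classes_ = np.asarray(payload["classes"])
        model.degenerate_ = bool(payload["degenerate"])
        model.majority_class_ = payload["majority_class"]
        model.n_features_in_ = len(model.weights_)
        return model


def fit_lda(X, y, reg_lambda: float = 1e-3, standardize: bool = True) -> TwoClassLDA:
    return TwoClassLDA(reg_lambda=reg_lambda, standardize=standardize).fit(X, y)


def loo_cv(X, y, reg_lambda: float = 1e-3, standardize: bool = True
           ) -> Tuple[float, np.ndarray]:
    """Leave-one-out accuracy plus held-out threshold-centred LD values.

    Each sample is scored by a model fit on the remaining n-1; returned LD
    values are LD_i - t_i (the per-fold threshold varies, so values are
    centred to be comparable; positive means 'predicted level_alt').
    Folds whose training part would leave a singleton class are skipped
    with a warning and counted as errors (LD recorded as NaN).
    """
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2 or n < 4:
        raise DegenerateClassesError(
            "leave-one-out needs n >= 4 with >= 2 samples per class"
        )
    ld = np.full(n, np.nan)
    correct = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        ytr = y[mask]
        tr_counts = np.array([(ytr == c).sum() for c in classes])
        if tr_counts.min() < 2:
            warnings.warn(f"fold {i}: singleton training class, counted as error",
                          stacklevel=2)
            continue
        Xtr = X[mask]
        if standardize:
            mean = Xtr.mean(axis=0)
            scale = Xtr.std(axis=0)
            scale[scale == 0] = 1.0
        else:
            mean = np.zeros(X.shape[1])
            scale = np.ones(X.shape[1])
        Xs = (Xtr - mean) / scale
        y01 = (ytr == classes[1]).astype(int)
        w, t, mu0, mu1 = _lda_solve(Xs, y01, reg_lambda)
        xi = (X[i] - mean) / scale
        ld_i = float(xi @ w)
        ld[i] = ld_i - t
        if np.allclose(mu0, mu1):
            pred = classes[int(tr_counts[1] > tr_counts[0])]
        else:
            pred = classes[1] if ld_i > t else classes[0]
        correct += int(pred == y[i])
    return correct / n, ld


@dataclass
class SelectionResult:
    """Outcome of greedy forward feature selection for one index."""

    index_name: str
    families: str
    selected_features: List[str]
    loo_accuracy: float
    ld_values: np.ndarray
    trace: List[Tuple[str, float]]
    model: TwoClassLDA | None

    def to_dict(self) -> dict:
        return {
            "index_name": self.index_name,
            "families": self.families,
            "selected_features": list(self.selected_features),
            "loo_accuracy": self.loo_accuracy,
            "ld_values": [None if np.isnan(v) else float(v) for v in self.ld_values],
            "trace": [[f, float(a)] for f, a in self.trace],
            "model": self.model.to_dict(self.selected_features) if self.model else None,
        }


class GreedyLDASelector(BaseEstimator):
    """Greedy forward feature selection maximising LOO accuracy of a
    TwoClassLDA, with deterministic tie-breaking.

    At each step the feature giving the highest LOO accuracy is added;
    ties break by higher mean held-out |LD - t| margin, then better FDR
    rank, then name. The search stops when no candidate strictly improves
    accuracy or ``max_features`` is reached. ``families`` restricts the
    candidate pool ('geometry_only' or 'geometry_plus_irp').
    """

    def __init__(self, max_features: int = 20,
                 families: str = "geometry_plus_irp",
                 reg_lambda: float = 1e-3,
                 feature_meta: Mapping[str, Mapping[str, str]] | None = None,
                 fdr_rank: Mapping[str, int] | None = None):
        self.max_features = max_features
        self.families = families
        self.reg_lambda = reg_lambda
        self.feature_meta = feature_meta
        self.fdr_rank = fdr_rank

    def _candidates(self, columns) -> List[str]:
        meta = self.feature_meta or {}
        if self.families == "geometry_only":
            return [c for c in columns
                    if meta.get(c, {}).get("family") == "geometry"]
        if self.families == "geometry_plus_irp":
            return list(columns)
        raise ValueError(f"unknown family restriction {self.families!r}")

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise DegenerateClassesError("selection needs exactly two classes")
        candidates = self._candidates(X.columns)
        fdr_rank = dict(self.fdr_rank) if self.fdr_rank else {}
        baseline = counts.max() / counts.sum()
        selected: List[str] = []
        trace: List[Tuple[str, float]] = []
        best_acc = baseline
        best_ld = np.zeros(len(y))
        while len(selected) < self.max_features:
            step: List[Tuple[float, float, int, str, np.ndarray]] = []
            for name in candidates:
                if name in selected:
                    continue
                acc, ld = loo_cv(X[selected + [name]], y,
                                 reg_lambda=self.reg_lambda)
                margin = float(np.nanmean(np.abs(ld))) if np.any(~np.isnan(ld)) else 0.0
                step.append((acc, margin, fdr_rank.get(name, len(candidates)),
                             name, ld))
            if not step:
                break
            step.sort(key=lambda s: (-s[0], -s[1], s[2], s[3]))
            acc, _, _, name, ld = step[0]
            if acc <= best_acc:
                break
            selected.append(name)
            trace.append((name, acc))
            best_acc, best_ld = acc, ld
        self.selected_features_ = selected
        self.loo_accuracy_ = float(best_acc)
        self.ld_values_ = best_ld
        self.trace_ = trace
        self.model_ = (fit_lda(X[selected], y, reg_lambda=self.reg_lambda)
                       if selected else None)
        return self

    def predict(self, X: pd.DataFrame):
        if self.model_ is None:
            raise DegenerateClassesError("no features were selected")
        return self.model_.predict(X)


def _labels_series(labels, index_name: str, sample_ids) -> np.ndarray:
    frame = labels_to_frame(labels) if isinstance(labels, Mapping) else labels
    missing = [s for s in sample_ids if s not in frame.index]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    return frame.loc[list(sample_ids), index_name].to_numpy()


def select_features(table: FeatureTable, labels, index_name: str,
                    max_features: int | None = None,
                    families: str = "geometry_plus_irp",
                    reg_lambda: float = 1e-3) -> SelectionResult:
    """Greedy LOO-driven feature selection for one histological index.

    ``max_features`` defaults to 10 for architecture and 20 for chronicity
    and activity.
    """
    if max_features is None:
        max_features = DEFAULT_MAX_FEATURES.get(index_name, 20)
    y = _labels_series(labels, index_name, table.sample_ids)
    ranking = rank_features(table, labels, index_name)
    fdr_rank = {name: i for i, (name, _) in enumerate(ranking.entries)}
    selector = GreedyLDASelector(max_features=max_features, families=families,
                                 reg_lambda=reg_lambda,
                                 feature_meta=table.meta, fdr_rank=fdr_rank)
    selector.fit(table.data, y)
    return SelectionResult(
        index_name=index_name, families=families,
        selected_features=selector.selected_features_,
        loo_accuracy=selector.loo_accuracy_,
        ld_values=selector.ld_values_,
        trace=selector.trace_,
        model=selector.model_,
    )


def predict_indices(feature_row, models: Mapping[str, TwoClassLDA]) -> IndexLabels:
    """Assemble the three independent per-index predictions for one sample.

    ``feature_row`` is a name -> value mapping/Series for the full
    catalogue; each model pulls its own features by name, so column order
    is irrelevant.
    """
    if isinstance(feature_row, pd.Series):
        frame = feature_row.to_frame().T
    else:
        frame = pd.DataFrame([dict(feature_row)])
    levels = {}
    for index_name in ("architecture", "chronicity", "activity"):
        model = models[index_name]
        levels[index_name] = int(model.predict(frame)[0])
    return IndexLabels(**levels)


def save_model(model: TwoClassLDA, path, feature_names=None) -> None:
    Path(path).write_text(json.dumps(model.to_dict(feature_names), indent=2))


def load_model(path) -> TwoClassLDA:
    return TwoClassLDA.from_dict(json.loads(Path(path).read_text()))
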