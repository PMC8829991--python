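"""The routed three-layer classifier bank and its repeated evaluation.

The screening model mirrors how much data a subject actually has:

* **layer 1** — demographic characteristics only,
* **layer 2** — demographics + routine laboratory values ("clinical data"),
* **layer 3** — clinical data + CT texture features.

The layers are nested and exactly one layer serves a given subject — the
highest one whose feature set is fully available (:func:`route_subject`).

Each layer can be driven by any of six classifiers: logistic regression
(LR, min–max scaled inputs), an RBF-kernel SVM, a single-hidden-layer neural
network (ANN), random forests (RF), gradient-boosted trees (XGB), and a
Stacking ensemble whose five base learners are the others and whose
meta-learner is an LR trained on their out-of-fold predictions only.
Hyperparameters come from a grid search with stratified tenfold
cross-validation on the training set, selecting by mean ROC AUC (ties go to
the least complex candidate, which is listed first in each grid).

Evaluation repeats a stratified 80/20 train/test split (default five times,
per-repeat seed = ``seed + repeat``), reports train and test ROC AUC per
(layer, classifier, repeat), and extracts feature importance for the three
classifiers that expose one (LR coefficients, RF Gini importance, XGB mean
split gain).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .feature_table import FeatureMatrix, SubjectRecord, one_hot_encode
from .selection import FeatureSelector, SelectionConfig

__all__ = [
    "CLASSIFIER_NAMES",
    "BASE_CLASSIFIER_NAMES",
    "LAYERS",
    "ScreeningClassifier",
    "EvaluationResult",
    "route_subject",
    "fit_classifier",
    "fit_stacking",
    "evaluate",
    "feature_importance",
    "stratified_splits",
]

BASE_CLASSIFIER_NAMES = ("LR", "SVM", "ANN", "RF", "XGB")
CLASSIFIER_NAMES = BASE_CLASSIFIER_NAMES + ("Stacking",)
LAYERS = (1, 2, 3)

# Grids are listed least-complex-first so grid-search ties resolve to the
# simplest candidate.  The "compact" preset trades grid resolution for
# runtime in large repeated simulations.
GRID_PRESETS: dict[str, dict[str, dict]] = {
    "default": {
        "LR": {"clf__C": [0.01, 0.1, 1.0, 10.0, 100.0]},
        "SVM": {"C": [0.1, 1.0, 10.0, 100.0],
                "gamma": ["scale", 1e-3, 1e-2, 1e-1]},
        "ANN": {"hidden_layer_sizes": [(16,), (32,), (64,)]},
        "RF": {"n_estimators": [100, 300], "max_depth": [None, 5, 10]},
        "XGB": {"n_estimators": [100, 300], "max_depth": [2, 4, 6],
                "learning_rate": [0.05, 0.1]},
    },
    "compact": {
        "LR": {"clf__C": [0.1, 1.0, 10.0]},
        "SVM": {"C": [1.0, 10.0], "gamma": ["scale", 1e-2]},
        "ANN": {"hidden_layer_sizes": [(32,)]},
        "RF": {"n_estimators": [100], "max_depth": [None, 5]},
        "XGB": {"n_estimators": [100], "max_depth": [2, 4], "learning_rate": [0.1]},
    },
}


def _base_estimator(name: str, random_state: int, scaled: Sequence[str]):
    scale = name in scaled
    if name == "LR":
        est = LogisticRegression(max_iter=5000, random_state=random_state)
        return Pipeline([("scale", MinMaxScaler()), ("clf", est)])
    if name == "SVM":
        est = SVC(kernel="rbf", random_state=random_state)
    elif name == "ANN":
        # lbfgs: deterministic and reliable on cohort-sized tabular data,
        # where adam's early-stopping validation split is too small to guide
        # training; L2 (alpha) provides the regularisation instead.
        est = MLPClassifier(solver="lbfgs", max_iter=600,
                            random_state=random_state)
    elif name == "RF":
        est = RandomForestClassifier(random_state=random_state, n_jobs=1)
    elif name == "XGB":
        est = XGBClassifier(tree_method="hist", n_jobs=1, verbosity=0,
                            eval_metric="logloss", random_state=random_state)
    else:
        raise ValueError(f"unknown classifier {name!r}")
    if scale:
        return Pipeline([("scale", MinMaxScaler()), ("clf", est)])
    return est


def _grid_for(name: str, grids: Mapping[str, dict], wrapped: bool) -> dict:
    grid = dict(grids[name])
    if name == "LR":
        return grid  # already addressed through the pipeline
    if wrapped:
        return {f"clf__{k}": v for k, v in grid.items()}
    return grid


class ScreeningClassifier(BaseEstimator, ClassifierMixin):
    """One grid-search-tuned member of the classifier bank.

    Parameters
    ----------
    name:
        "LR", "SVM", "ANN", "RF", "XGB" or "Stacking".
    grids:
        Grid preset name ("default"/"compact") or an explicit mapping
        classifier-name → parameter grid.
    cv:
        Folds of the stratified cross-validation used by the grid search
        (tenfold unless configured).
    scaled:
        Classifier names that receive min–max scaled inputs.  Logistic
        regression is scale-sensitive and always listed; extending this to
        ("LR", "SVM", "ANN") is recommended for real cohorts.

    Fitted attributes: ``estimator_``, ``best_params_``, ``cv_auc_``,
    ``classes_``, ``feature_names_``.
    """

    def __init__(self, name: str = "LR", grids: str | Mapping[str, dict] = "default",
                 cv: int = 10, scaled: tuple[str, ...] = ("LR",),
                 stacking_cv: int = 5, random_state: int = 0):
        self.name = name
        self.grids = grids
        self.cv = cv
        self.scaled = scaled
        self.stacking_cv = stacking_cv
        self.random_state = random_state

    def _resolve_grids(self) -> Mapping[str, dict]:
        if isinstance(self.grids, str):
            return GRID_PRESETS[self.grids]
        return self.grids

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("ScreeningClassifier is a binary classifier")
        if counts.min() < self.cv:
            raise ValueError(
                f"minority class has {counts.min()} members, fewer than the "
                f"{self.cv} CV folds; use fewer folds"
            )
        self.classes_ = classes
        self.feature_names_ = (list(feature_names) if feature_names is not None
                               else [f"x{i}" for i in range(X.shape[1])])
        grids = self._resolve_grids()
        if self.name == "Stacking":
            self._fit_stacking(X, y, grids)
            return self
        est = _base_estimator(self.name, self.random_state, self.scaled)
        wrapped = isinstance(est, Pipeline) and self.name != "LR"
        grid = _grid_for(self.name, grids, wrapped)
        search = GridSearchCV(
            est, grid, scoring="roc_auc", refit=True,
            cv=StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state),
            n_jobs=1,
        )
        search.fit(X, y)
        self.estimator_ = search.best_estimator_
        self.best_params_ = dict(search.best_params_)
        self.cv_auc_ = float(search.best_score_)
        return self

    def _fit_stacking(self, X, y, grids) -> None:
        bases = []
        params: dict[str, dict] = {}
        cv_scores: list[float] = []
        for base_name in BASE_CLASSIFIER_NAMES:
            member = ScreeningClassifier(
                name=base_name, grids=grids, cv=self.cv, scaled=self.scaled,
                random_state=self.random_state,
            ).fit(X, y)
            bases.append((base_name, clone(member.estimator_)))
            params[base_name] = member.best_params_
            cv_scores.append(member.cv_auc_)
        meta = LogisticRegression(max_iter=5000, random_state=self.random_state)
        stack = StackingClassifier(
            estimators=bases, final_estimator=meta,
            cv=StratifiedKFold(self.stacking_cv, shuffle=True,
                               random_state=self.random_state),
            stack_method="auto", passthrough=False, n_jobs=1,
        )
        stack.fit(X, y)
        self.estimator_ = stack
        self.best_params_ = params
        self.cv_auc_ = float(np.mean(cv_scores))

    def decision_scores(self, X) -> np.ndarray:
        """Continuous scores for ROC analysis (probability of class 1 when
        available, otherwise the decision function)."""
        if not hasattr(self, "estimator_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if hasattr(self.estimator_, "predict_proba"):
            return self.estimator_.predict_proba(X)[:, 1]
        return self.estimator_.decision_function(X)

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return self.estimator_.predict(np.asarray(X, dtype=float))

    def score(self, X, y) -> float:
        """ROC AUC of the decision scores."""
        return float(roc_auc_score(np.asarray(y), self.decision_scores(X)))


def fit_classifier(X, y, name: str, seed: int = 0,
                   grids: str | Mapping[str, dict] = "default",
                   cv: int = 10) -> ScreeningClassifier:
    """Tune and fit one classifier (thin functional wrapper)."""
    return ScreeningClassifier(name=name, grids=grids, cv=cv, random_state=seed).fit(X, y)


def fit_stacking(X, y, seed: int = 0,
                 grids: str | Mapping[str, dict] = "default",
                 cv: int = 10) -> ScreeningClassifier:
    """Tune the five base learners and fit the stacked ensemble."""
    return ScreeningClassifier(name="Stacking", grids=grids, cv=cv,
                               random_state=seed).fit(X, y)


def route_subject(record: SubjectRecord,
                  lab_columns: Iterable[str] | None = None) -> int:
    """Route a subject to the highest layer whose inputs are complete."""
    from .feature_table import _DEMOGRAPHICS, _LAB_PANEL  # default schema

    demo = [c for c in _DEMOGRAPHICS]
    labs = list(lab_columns) if lab_columns is not None else list(_LAB_PANEL)

    def _ok(col: str) -> bool:
        v = record.clinical.get(col)
        if col == "pulse_pressure" and v is None:
            return _ok("systolic_bp") and _ok("diastolic_bp")
        return v is not None and not (isinstance(v, float) and np.isnan(v))

    if not all(_ok(c) for c in demo):
        missing = [c for c in demo if not _ok(c)]
        raise ValueError(f"subject {record.subject_id}: missing demographics {missing}")
    layer = 1
    if all(_ok(c) for c in labs):
        layer = 2
        if record.vertebrae:
            layer = 3
    return layer


def stratified_splits(y: pd.Series, n_repeats: int, test_fraction: float,
                      seed: int) -> list[tuple[pd.Index, pd.Index]]:
    """The repeated stratified train/test splits used by :func:`evaluate`."""
    splits = []
    for rep in range(n_repeats):
        tr, te = train_test_split(
            y.index, test_size=test_fraction, stratify=y.values,
            random_state=seed + rep,
        )
        splits.append((pd.Index(tr), pd.Index(te)))
    return splits


@dataclasses.dataclass
class EvaluationResult:
    """Per-(layer, classifier, repeat) AUC table plus importance rankings."""

    results: pd.DataFrame
    importances: pd.DataFrame
    selection_kept: dict
    seed: int

    def summary(self) -> pd.DataFrame:
        """Mean train/test AUC per (layer, classifier) over repeats."""
        return (self.results
                .groupby(["layer", "classifier"], sort=True)[["train_auc", "test_auc"]]
                .mean())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "results": [
                {k: (v if not isinstance(v, (np.floating, np.integer)) else v.item())
                 for k, v in row.items()}
                for row in self.results.to_dict(orient="records")
            ],
            "summary": {
                f"layer{layer}/{clf}": {"train_auc": row["train_auc"],
                                        "test_auc": row["test_auc"]}
                for (layer, clf), row in self.summary().iterrows()
            },
            "selection_kept": self.selection_kept,
        }
        text = json.dumps(payload, indent=1, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def _layer_matrix(matrix: FeatureMatrix, layer: int) -> FeatureMatrix:
    cols = matrix.columns_of(layer=layer)
    rows = matrix.X[cols].notna().all(axis=1)
    return matrix.subset(cols, rows=matrix.X.index[rows])


def evaluate(
    matrix: FeatureMatrix,
    layers: Sequence[int] = LAYERS,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    n_repeats: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
    grids: str | Mapping[str, dict] = "default",
    cv: int = 10,
    scaled: tuple[str, ...] = ("LR",),
    selection: SelectionConfig | None = None,
    compute_importance: bool = True,
    splits: Sequence[tuple[pd.Index, pd.Index]] | None = None,
) -> EvaluationResult:
    """Repeated stratified evaluation of the layered classifier bank.

    Per repeat: one stratified 80/20 split (per-repeat seed ``seed + r``);
    per layer: restrict to the layer's columns and the rows complete for
    them, optionally run the selection ledger on the *training* rows only,
    one-hot encode, then tune/fit/score every classifier.  Feature
    importance is taken from the last repeat's LR/RF/XGB fits.
    """
    if matrix.y.nunique() < 2:
        raise ValueError("both classes must be present")
    rows = []
    importance_rows = []
    selection_kept: dict[str, list[str]] = {}
    for layer in layers:
        layer_m = _layer_matrix(matrix, layer)
        if splits is None:
            layer_splits = stratified_splits(layer_m.y, n_repeats, test_fraction, seed)
        else:  # caller-fixed splits, restricted to the layer's complete rows
            layer_splits = [(tr.intersection(layer_m.X.index),
                             te.intersection(layer_m.X.index)) for tr, te in splits]
        for rep, (tr_idx, te_idx) in enumerate(layer_splits):
            rep_seed = seed + rep
            work = layer_m
            if selection is not None:
                sel = FeatureSelector(config=selection)
                sel.fit(work.subset(work.feature_names, rows=tr_idx))
                work = sel.transform(work)
                selection_kept[f"layer{layer}/repeat{rep}"] = sel.support_
            if not work.feature_names:
                raise ValueError(f"layer {layer}: selection left no feature")
            enc = one_hot_encode(work)
            Xtr = enc.X.loc[tr_idx].to_numpy(dtype=float)
            Xte = enc.X.loc[te_idx].to_numpy(dtype=float)
            ytr = enc.y.loc[tr_idx].to_numpy()
            yte = enc.y.loc[te_idx].to_numpy()
            for clf_name in classifiers:
                sc = ScreeningClassifier(name=clf_name, grids=grids, cv=cv,
                                         scaled=scaled, random_state=rep_seed)
                sc.fit(Xtr, ytr, feature_names=enc.feature_names)
                rows.append({
                    "layer": layer, "classifier": clf_name, "repeat": rep,
                    "train_auc": sc.score(Xtr, ytr), "test_auc": sc.score(Xte, yte),
                    "n_train": len(ytr), "n_test": len(yte),
                    "best_params": json.dumps(sc.best_params_, sort_keys=True, default=str),
                    "seed": rep_seed,
                })
                if (compute_importance and rep == n_repeats - 1
                        and clf_name in ("LR", "RF", "XGB")):
                    imp = feature_importance(sc)
                    imp.insert(0, "layer", layer)
                    imp.insert(1, "classifier", clf_name)
                    importance_rows.append(imp)
    results = pd.DataFrame(rows)
    importances = (pd.concat(importance_rows, ignore_index=True)
                   if importance_rows else pd.DataFrame())
    return EvaluationResult(results=results, importances=importances,
                            selection_kept=selection_kept, seed=seed)


def feature_importance(model: ScreeningClassifier) -> pd.DataFrame:
    """Ranked feature importance for LR, RF or XGB.

    LR: absolute coefficients on the (min–max scaled) inputs; RF: Gini
    importance; XGB: mean gain over splits (features never split score 0).
    SVM, ANN and Stacking expose no comparable measure and raise.
    """
    if model.name not in ("LR", "RF", "XGB"):
        raise ValueError(
            f"feature importance is not defined for {model.name}; "
            "only LR, RF and XGB expose one"
        )
    names = model.feature_names_
    est = model.estimator_
    if model.name == "LR":
        coefs = est.named_steps["clf"].coef_.ravel()
        scores = np.abs(coefs)
    elif model.name == "RF":
        scores = est.feature_importances_
    else:  # XGB
        booster = est.get_booster()
        gain = booster.get_score(importance_type="gain")
        scores = np.array([gain.get(f"f{i}", 0.0) for i in range(len(names))])
    df = pd.DataFrame({"feature": names, "score": scores.astype(float)})
    df = df.sort_values(["score", "feature"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
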