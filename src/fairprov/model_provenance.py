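"""Audited model families with mechanism-level provenance.

Two model families are audited: an L2-penalized logistic regression and a
random forest. Fitting is delegated to scikit-learn; everything the audit
relies on — per-feature logit contributions, per-tree decision paths and
votes, impurity importances, content-hash model versions — is extracted into
plain-Python structures so that every prediction can be replayed and verified
without the fitting backend.

Sign conventions and invariants the rest of the toolkit depends on:

* logistic: ``logit = w0 + sum_j w_j * x_j`` and the logged contributions
  ``c_j = w_j * x_j`` reconstruct the logit exactly (it is *computed* as that
  sum, so the identity is algebraic, not approximate);
* forest: the ensemble probability is the mean of per-tree positive-class
  leaf proportions, and replaying a logged path against the stored tree
  reproduces that tree's vote;
* classification threshold 0.5, ties going to the positive class.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort_sim import Cohort
from .seeding import substream_seed

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FEATURES",
    "LogisticAuditModel",
    "ForestAuditModel",
    "PredictionProvenance",
    "GridSearchResult",
    "PAPER_GRID",
    "fit_logistic",
    "fit_forest",
    "tune_forest",
    "predict_with_provenance",
    "refit_without_feature",
    "default_clock",
]

#: Model input columns: standardized continuous features plus raw binaries.
DEFAULT_FEATURES = ("age_std", "bmi_std", "comorbidity", "gender")

#: The tuning grid of the main experiment (row-major candidate order).
PAPER_GRID: dict[str, tuple] = {
    "n_estimators": (50, 100, 200),
    "max_depth": (None, 10, 20),
    "min_samples_split": (2, 5),
}


def default_clock() -> datetime:
    return datetime.now(timezone.utc)


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def _data_fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(y, dtype=np.int64).tobytes())
    return h.hexdigest()


def _model_version(kind: str, config: Mapping, fingerprint: str) -> str:
    payload = _canonical_json({"kind": kind, "config": dict(config), "data": fingerprint})
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def _extract_xy(train, features: Sequence[str], outcome: str = "outcome"):
    table = train.table if isinstance(train, Cohort) else train
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features not present in training data: {missing}")
    X = table[list(features)].to_numpy(dtype=np.float64)
    y = table[outcome].to_numpy(dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single outcome class")
    return X, y


# ---------------------------------------------------------------------------
# Logistic family
# ---------------------------------------------------------------------------


@dataclass
class LogisticAuditModel:
    """A fitted L2-logistic model exposed as explicit weights.

    ``predict_proba`` evaluates ``sigmoid(w0 + sum w_j x_j)`` from the stored
    weights, so archived models replay without scikit-learn.
    """

    feature_names: tuple[str, ...]
    weights: dict[str, float]
    intercept: float
    config: dict
    model_version: str
    converged: bool = True
    fit_warnings: tuple[str, ...] = ()

    kind = "logistic"

    def logit(self, row: Mapping[str, float]) -> float:
        return self.intercept + sum(
            self.weights[f] * float(row[f]) for f in self.feature_names
        )

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Positive-class probability for each row."""
        X = table[list(self.feature_names)].to_numpy(dtype=np.float64)
        w = np.array([self.weights[f] for f in self.feature_names])
        return expit(self.intercept + X @ w)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(table) >= 0.5).astype(np.int64)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "weights": self.weights,
            "intercept": self.intercept,
            "config": self.config,
            "model_version": self.model_version,
            "converged": self.converged,
            "fit_warnings": list(self.fit_warnings),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LogisticAuditModel":
        return cls(
            feature_names=tuple(d["feature_names"]),
            weights=dict(d["weights"]),
            intercept=float(d["intercept"]),
            config=dict(d["config"]),
            model_version=d["model_version"],
            converged=bool(d.get("converged", True)),
            fit_warnings=tuple(d.get("fit_warnings", ())),
        )


def fit_logistic(
    train,
    features: Sequence[str] = DEFAULT_FEATURES,
    outcome: str = "outcome",
    C: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> LogisticAuditModel:
    """L2-penalized maximum-likelihood logistic fit.

    Penalty convention: ridge strength ``1/(2C)`` against the *summed*
    negative log-likelihood, intercept unpenalized (the lbfgs objective).
    Non-convergence is recorded as a provenance warning, not an error.
    """
    X, y = _extract_xy(train, features, outcome)
    config = {
        "penalty": "l2",
        "C": C,
        "solver": "lbfgs",
        "max_iter": max_iter,
        "tol": tol,
        "features": list(features),
    }
    est = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=tol)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(X, y)
        caught = [str(w.message) for w in rec if issubclass(w.category, ConvergenceWarning)]
    if caught:
        logger.warning("logistic fit did not converge within %d iterations", max_iter)
    return LogisticAuditModel(
        feature_names=tuple(features),
        weights={f: float(w) for f, w in zip(features, est.coef_[0])},
        intercept=float(est.intercept_[0]),
        config=config,
        model_version=_model_version("logistic", config, _data_fingerprint(X, y)),
        converged=not caught,
        fit_warnings=tuple(caught),
    )


# ---------------------------------------------------------------------------
# Forest family
# ---------------------------------------------------------------------------


@dataclass
class _TreeArrays:
    """Flat arrays of one decision tree (scikit-learn node layout)."""

    feature: np.ndarray        # split feature index, -2 at leaves
    threshold: np.ndarray      # split threshold, x <= t goes left
    children_left: np.ndarray  # -1 at leaves
    children_right: np.ndarray
    leaf_pos_fraction: np.ndarray  # positive-class proportion at each node

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "leaf_pos_fraction": self.leaf_pos_fraction.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "_TreeArrays":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=np.float64),
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            leaf_pos_fraction=np.asarray(d["leaf_pos_fraction"], dtype=np.float64),
        )


@dataclass
class ForestAuditModel:
    """A fitted random forest stored as explicit tree structures."""

    feature_names: tuple[str, ...]
    trees: list[_TreeArrays]
    hyperparams: dict
    importances: dict[str, float]
    model_version: str
    seed: int = 0

    kind = "forest"

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def _tree_pos_fractions(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_trees) positive-class leaf proportions via replay."""
        n = X.shape[0]
        out = np.empty((n, self.n_trees))
        for t, tree in enumerate(self.trees):
            node = np.zeros(n, dtype=np.int64)
            active = tree.children_left[node] != -1
            while active.any():
                idx = np.where(active)[0]
                nd = node[idx]
                go_left = X[idx, tree.feature[nd]] <= tree.threshold[nd]
                node[idx] = np.where(
                    go_left, tree.children_left[nd], tree.children_right[nd]
                )
                active = tree.children_left[node] != -1
            out[:, t] = tree.leaf_pos_fraction[node]
        return out

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Mean of per-tree positive-class leaf proportions."""
        X = table[list(self.feature_names)].to_numpy(dtype=np.float64)
        return self._tree_pos_fractions(X).mean(axis=1)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(table) >= 0.5).astype(np.int64)

    def tree_path(self, tree_index: int, row: Mapping[str, float]) -> list[dict]:
        """The decision path of one tree for one patient."""
        tree = self.trees[tree_index]
        x = np.array([float(row[f]) for f in self.feature_names])
        path = []
        node = 0
        while tree.children_left[node] != -1:
            f = int(tree.feature[node])
            thr = float(tree.threshold[node])
            left = bool(x[f] <= thr)
            path.append(
                {
                    "node": int(node),
                    "feature": self.feature_names[f],
                    "threshold": thr,
                    "branch": "left" if left else "right",
                }
            )
            node = int(tree.children_left[node] if left else tree.children_right[node])
        path.append(
            {"node": int(node), "leaf_pos_fraction": float(tree.leaf_pos_fraction[node])}
        )
        return path

    def replay_path(self, tree_index: int, path: list[dict]) -> float:
        """Walk a logged path against the stored tree; return the leaf fraction.

        Raises ``ValueError`` if the logged path disagrees with the tree
        structure at any node.
        """
        tree = self.trees[tree_index]
        node = 0
        for step in path[:-1]:
            if step["node"] != node or tree.children_left[node] == -1:
                raise ValueError(f"path diverges from tree {tree_index} at node {node}")
            f = int(tree.feature[node])
            if self.feature_names[f] != step["feature"]:
                raise ValueError(f"feature mismatch at node {node}")
            node = int(
                tree.children_left[node]
                if step["branch"] == "left"
                else tree.children_right[node]
            )
        leaf = path[-1]
        if leaf["node"] != node or tree.children_left[node] != -1:
            raise ValueError("logged leaf does not match tree structure")
        return float(tree.leaf_pos_fraction[node])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "trees": [t.to_dict() for t in self.trees],
            "hyperparams": self.hyperparams,
            "importances": self.importances,
            "model_version": self.model_version,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ForestAuditModel":
        return cls(
            feature_names=tuple(d["feature_names"]),
            trees=[_TreeArrays.from_dict(t) for t in d["trees"]],
            hyperparams=dict(d["hyperparams"]),
            importances=dict(d["importances"]),
            model_version=d["model_version"],
            seed=int(d.get("seed", 0)),
        )


def _forest_defaults() -> dict:
    return {
        "n_estimators": 100,
        "max_depth": None,
        "min_samples_split": 2,
        "criterion": "gini",
        "bootstrap": True,
        "max_features": "sqrt",
    }


def fit_forest(
    train,
    features: Sequence[str] = DEFAULT_FEATURES,
    hyperparams: Mapping | None = None,
    seed: int = 0,
    outcome: str = "outcome",
) -> ForestAuditModel:
    """Bootstrap random forest with Gini splits and sqrt(p) features per split.

    The fitted trees are flattened into plain arrays; the ensemble probability
    (mean of leaf positive-class proportions) matches the backend exactly.
    """
    X, y = _extract_xy(train, features, outcome)
    params = _forest_defaults()
    if hyperparams:
        params.update(hyperparams)
    config = dict(params)
    config["features"] = list(features)
    est = RandomForestClassifier(
        n_estimators=params["n_estimators"],
        max_depth=params["max_depth"],
        min_samples_split=params["min_samples_split"],
        criterion=params["criterion"],
        bootstrap=params["bootstrap"],
        max_features=params["max_features"],
        random_state=seed,
        n_jobs=1,
    )
    est.fit(X, y)
    pos_col = int(np.where(est.classes_ == 1)[0][0])
    trees = []
    for t in est.estimators_:
        tr = t.tree_
        value = tr.value[:, 0, :]
        totals = value.sum(axis=1)
        frac = np.where(totals > 0, value[:, pos_col] / np.where(totals > 0, totals, 1), 0.0)
        trees.append(
            _TreeArrays(
                feature=tr.feature.copy(),
                threshold=tr.threshold.copy(),
                children_left=tr.children_left.copy(),
                children_right=tr.children_right.copy(),
                leaf_pos_fraction=frac,
            )
        )
    serializable = {k: (v if v is not None else "unlimited") for k, v in params.items()}
    return ForestAuditModel(
        feature_names=tuple(features),
        trees=trees,
        hyperparams=dict(params),
        importances={f: float(v) for f, v in zip(features, est.feature_importances_)},
        model_version=_model_version(
            "forest", {**serializable, "features": list(features), "seed": seed},
            _data_fingerprint(X, y),
        ),
        seed=seed,
    )


@dataclass
class GridSearchResult:
    """All candidate scores of a grid search plus the selected candidate."""

    grid: dict
    candidates: list[dict]          # hyperparameter dict per candidate, row-major
    mean_scores: list[float]        # mean CV ROC-AUC per candidate
    fold_scores: list[list[float]]  # per-candidate per-fold AUCs (NaN = skipped)
    selected: dict
    selected_score: float
    cv_folds: int
    seed: int
    warnings: list[str] = field(default_factory=list)


def tune_forest(
    train,
    grid: Mapping[str, Sequence] = PAPER_GRID,
    cv_folds: int = 3,
    seed: int = 0,
    features: Sequence[str] = DEFAULT_FEATURES,
    outcome: str = "outcome",
) -> GridSearchResult:
    """Exhaustive grid search over forest hyperparameters, scored by CV ROC-AUC.

    Every candidate is evaluated on the same outcome-stratified folds. A fold
    whose held-out part has one outcome class is skipped with a warning and
    the candidate scored on the remaining folds. Ties break to the first
    candidate in row-major grid order.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    X, y = _extract_xy(train, features, outcome)
    keys = list(grid.keys())
    candidates = [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                          random_state=substream_seed(seed, "tune-cv"))
    folds = list(skf.split(X, y))
    warns: list[str] = []
    mean_scores: list[float] = []
    fold_scores: list[list[float]] = []
    for ci, cand in enumerate(candidates):
        scores: list[float] = []
        for fi, (tr, te) in enumerate(folds):
            if len(np.unique(y[te])) < 2:
                warns.append(f"candidate {ci}: fold {fi} has one class, skipped")
                scores.append(float("nan"))
                continue
            est = RandomForestClassifier(
                **{**_forest_defaults(), **cand},
                random_state=substream_seed(seed, f"tune-fit-{ci}-{fi}"),
                n_jobs=1,
            )
            est.fit(X[tr], y[tr])
            pos = int(np.where(est.classes_ == 1)[0][0])
            scores.append(float(roc_auc_score(y[te], est.predict_proba(X[te])[:, pos])))
        valid = [s for s in scores if not np.isnan(s)]
        if not valid:
            raise ValueError("no fold produced a defined score")
        mean_scores.append(float(np.mean(valid)))
        fold_scores.append(scores)
    best = int(np.argmax(mean_scores))  # argmax takes the first maximum
    for w in warns:
        logger.warning("tune_forest: %s", w)
    return GridSearchResult(
        grid={k: list(v) for k, v in grid.items()},
        candidates=candidates,
        mean_scores=mean_scores,
        fold_scores=fold_scores,
        selected=candidates[best],
        selected_score=mean_scores[best],
        cv_folds=cv_folds,
        seed=seed,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# Prediction provenance
# ---------------------------------------------------------------------------


@dataclass
class PredictionProvenance:
    """The mechanism record of one prediction.

    For a logistic model, ``mechanism`` holds the intercept, per-feature
    contributions ``c_j = w_j x_j`` and the logit (their exact sum). For a
    forest it holds per-tree paths, per-tree votes, the positive-vote
    fraction and a snapshot of the global importances.
    """

    patient_id: str
    model_version: str
    timestamp: str
    inputs: dict[str, float]
    mechanism: dict
    probability: float
    predicted_class: int

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "model_version": self.model_version,
            "timestamp": self.timestamp,
            "inputs": self.inputs,
            "mechanism": self.mechanism,
            "probability": self.probability,
            "predicted_class": self.predicted_class,
        }


def predict_with_provenance(
    model: LogisticAuditModel | ForestAuditModel,
    patient: Mapping[str, float] | pd.Series,
    clock: Callable[[], datetime] = default_clock,
) -> tuple[float, int, PredictionProvenance]:
    """Score one patient and log the full decision mechanism.

    Class is 1 iff probability >= 0.5.
    """
    if isinstance(patient, pd.Series):
        patient = patient.to_dict()
    missing = [f for f in model.feature_names if f not in patient]
    if missing:
        raise ValueError(f"patient record missing model feature(s): {missing}")
    inputs = {f: float(patient[f]) for f in model.feature_names}
    pid = str(patient.get("patient_id", ""))
    ts = clock().isoformat()

    if isinstance(model, LogisticAuditModel):
        contributions = {f: model.weights[f] * inputs[f] for f in model.feature_names}
        logit = model.intercept + sum(contributions[f] for f in model.feature_names)
        prob = float(expit(logit))
        mechanism = {
            "type": "logistic",
            "intercept": model.intercept,
            "contributions": contributions,
            "logit": logit,
        }
    elif isinstance(model, ForestAuditModel):
        paths = [model.tree_path(t, inputs) for t in range(model.n_trees)]
        fractions = [p[-1]["leaf_pos_fraction"] for p in paths]
        votes = [1 if f >= 0.5 else 0 for f in fractions]
        prob = float(np.mean(fractions))
        mechanism = {
            "type": "forest",
            "paths": paths,
            "tree_votes": votes,
            "positive_vote_fraction": float(np.mean(votes)),
            "importances": dict(model.importances),
        }
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    cls = 1 if prob >= 0.5 else 0
    return prob, cls, PredictionProvenance(
        patient_id=pid,
        model_version=model.model_version,
        timestamp=ts,
        inputs=inputs,
        mechanism=mechanism,
        probability=prob,
        predicted_class=cls,
    )


def refit_without_feature(
    model: LogisticAuditModel | ForestAuditModel,
    train,
    excluded: str,
    outcome: str = "outcome",
):
    """Refit the same model family with one feature excluded (bias ablation)."""
    if excluded not in model.feature_names:
        raise ValueError(f"feature {excluded!r} not in the model's feature set")
    remaining = tuple(f for f in model.feature_names if f != excluded)
    if not remaining:
        raise ValueError("cannot exclude every feature")
    if isinstance(model, LogisticAuditModel):
        cfg = model.config
        return fit_logistic(
            train, remaining, outcome=outcome,
            C=cfg.get("C", 1.0), max_iter=cfg.get("max_iter", 1000),
            tol=cfg.get("tol", 1e-4),
        )
    if isinstance(model, ForestAuditModel):
        return fit_forest(
            train, remaining, hyperparams=model.hyperparams, seed=model.seed,
            outcome=outcome,
        )
    raise TypeError(f"unsupported model type {type(model).__name__}")


def load_model(d: Mapping):
    """Rehydrate an archived model from its JSON dictionary."""
    kind = d.get("kind")
    if kind == "logistic":
        return LogisticAuditModel.from_dict(d)
    if kind == "forest":
        return ForestAuditModel.from_dict(d)
    raise ValueError(f"unknown model kind {kind!r}")
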