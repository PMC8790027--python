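"""Predictive carry-forward-effect analysis.

Response correctness is predicted from per-phase feature vectors with a
weighted ensemble of seven members: max-margin classifiers with linear,
radial and polynomial kernels, Gaussian-process classifiers with the
same three kernels, and a model tree (a shallow regression tree with
ridge models in its leaves).  Member weights are proportional to their
accuracy on the validation participant of each leave-one-participant-out
fold.  The class imbalance (about five right answers per wrong one) is
corrected on training folds only, with a nearest-neighbour minority
oversampler that places synthetic points at jittered neighbour means.

Feature importance is permutation importance on each fold's validation
set, combined across members by the ensemble weights and averaged
across folds; the carry-forward classification then reads the dense
ranks per phase: a feature carries forward perfectly when it sits in
the top fraction of every phase and its rank decays monotonically from
see-solve through move to respond.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF, DotProduct, Exponentiation
from sklearn.linear_model import Ridge
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "EvaluationResult", "EnsembleModel", "smote_balance", "lopo_folds",
    "fit_ensemble", "predict_and_evaluate", "rank_feature_importance",
    "classify_cfe_predictive", "majority_baseline", "random_baseline",
    "evaluate_metrics",
]

POSITIVE = "right"


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else float("nan")


def evaluate_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationResult:
    """Confusion counts and metrics with "right" as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == POSITIVE
    pos_p = y_pred == POSITIVE
    return EvaluationResult(
        tp=int(np.sum(pos_t & pos_p)), fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)), fn=int(np.sum(pos_t & ~pos_p)))


def majority_baseline(y: np.ndarray) -> EvaluationResult:
    """Metrics of the classifier that always predicts the majority class."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    maj = classes[np.argmax(counts)]
    return evaluate_metrics(y, np.full(y.shape, maj))


def random_baseline(y: np.ndarray, rng: np.random.Generator) -> EvaluationResult:
    """Metrics of a uniform random classifier on the given labels."""
    y = np.asarray(y)
    classes = np.unique(y)
    return evaluate_metrics(y, rng.choice(classes, size=y.size))


# --------------------------------------------------------------------------
# minority oversampling

def smote_balance(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                  n_neighbors: int = 5, per_point: int = 4
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class toward a 50:50 balance.

    For each minority point the ``n_neighbors`` nearest minority
    neighbours are found (Euclidean); each synthetic point is the mean
    of the point's four closest neighbours jittered by +25, -25, +50 and
    -50 % of those neighbours' per-feature SD.  Only the minority class
    is augmented and at most ``per_point`` synthetics per original point
    are produced; already-balanced input is returned unchanged.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    Xm = X[y == minority]
    if n_min < 5:
        raise ValueError("minority class has fewer than 5 points; pool more data")

    d2 = np.sum((Xm[:, None, :] - Xm[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    k = min(n_neighbors, n_min - 1)
    candidates: list[np.ndarray] = []
    offsets = (0.25, -0.25, 0.5, -0.5)
    for i in range(n_min):
        nn = np.argsort(d2[i])[:k]
        four = nn[:4]
        mu = Xm[four].mean(axis=0)
        sd = Xm[four].std(axis=0)
        for c in offsets[:per_point]:
            candidates.append(mu + c * sd)
    need = n_maj - n_min
    order = rng.permutation(len(candidates))[:need]
    synth = np.asarray([candidates[i] for i in order])
    if synth.size == 0:
        return X, y
    return (np.vstack([X, synth]),
            np.concatenate([y, np.full(len(synth), minority)]))


def lopo_folds(participant_ids: np.ndarray, rng: np.random.Generator,
               holdout_fraction: float = 0.10
               ) -> tuple[list, list[tuple[list, list]]]:
    """Outer holdout plus leave-one-participant-out folds.

    ``holdout_fraction`` of the participants (rounded up) is set aside
    for final testing; each remaining participant once serves as the
    validation side of a fold.  No participant ever appears on both
    sides of a split.
    """
    ids = sorted(set(map(str, participant_ids)))
    if len(ids) < 3:
        raise ValueError("need at least 3 participants")
    n_hold = math.ceil(holdout_fraction * len(ids))
    holdout = sorted(rng.choice(ids, size=n_hold, replace=False).tolist())
    rest = [p for p in ids if p not in holdout]
    folds = [([q for q in rest if q != p], [p]) for p in rest]
    return holdout, folds


# --------------------------------------------------------------------------
# ensemble members

class _ModelTree:
    """Shallow regression tree with a ridge model in every leaf (M5 style)."""

    def __init__(self, max_depth: int = 3, min_leaf: int = 10):
        self.max_depth = max_depth
        self.min_leaf = min_leaf

    def fit(self, X: np.ndarray, y01: np.ndarray) -> "_ModelTree":
        self.tree_ = DecisionTreeRegressor(
            max_depth=self.max_depth, min_samples_leaf=self.min_leaf,
            random_state=0)
        self.tree_.fit(X, y01)
        leaves = self.tree_.apply(X)
        self.models_ = {}
        for leaf in np.unique(leaves):
            m = leaves == leaf
            r = Ridge(alpha=1.0)
            r.fit(X[m], y01[m])
            self.models_[int(leaf)] = r
        return self

    def score01(self, X: np.ndarray) -> np.ndarray:
        leaves = self.tree_.apply(X)
        out = np.empty(len(X))
        for leaf in np.unique(leaves):
            m = leaves == leaf
            model = self.models_.get(int(leaf))
            out[m] = model.predict(X[m]) if model is not None else self.tree_.predict(X[m])[0]
        return np.clip(out, 0.0, 1.0)


class _Member:
    """One ensemble member emitting scores in [0, 1] (P of "right")."""

    def __init__(self, name: str, maker):
        self.name = name
        self._maker = maker

    def fit(self, X: np.ndarray, y01: np.ndarray) -> "_Member":
        self.mu_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        Z = (X - self.mu_) / self.sd_
        self.est_ = self._maker()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if isinstance(self.est_, _ModelTree):
                self.est_.fit(Z, y01.astype(float))
            else:
                if np.unique(y01).size < 2:
                    raise ValueError("single-class training set")
                self.est_.fit(Z, y01)
        return self

    def score01(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mu_) / self.sd_
        est = self.est_
        if isinstance(est, _ModelTree):
            return est.score01(Z)
        if isinstance(est, GaussianProcessClassifier):
            proba = est.predict_proba(Z)
            return proba[:, list(est.classes_).index(1)]
        return expit(est.decision_function(Z))


def _members(n_features: int) -> list[_Member]:
    # Gaussian-process kernels are scaled by the feature dimension so the
    # Gram matrices stay O(1) on standardized inputs; hyperparameters are
    # held fixed (single Laplace fit) for determinism and conditioning.
    d = max(n_features, 1)
    from sklearn.gaussian_process.kernels import ConstantKernel
    return [
        _Member("svm_linear", lambda: SVC(kernel="linear", random_state=0)),
        _Member("svm_radial", lambda: SVC(kernel="rbf", random_state=0)),
        _Member("svm_poly", lambda: SVC(kernel="poly", degree=3, random_state=0)),
        _Member("gp_linear", lambda: GaussianProcessClassifier(
            kernel=ConstantKernel(1.0 / d, "fixed")
            * DotProduct(sigma_0=1.0, sigma_0_bounds="fixed"),
            optimizer=None, random_state=0)),
        _Member("gp_radial", lambda: GaussianProcessClassifier(
            kernel=RBF(length_scale=math.sqrt(2 * d),
                       length_scale_bounds="fixed"),
            optimizer=None, random_state=0)),
        _Member("gp_poly", lambda: GaussianProcessClassifier(
            kernel=ConstantKernel(1.0 / d**2, "fixed")
            * Exponentiation(DotProduct(sigma_0=1.0, sigma_0_bounds="fixed"), 2),
            optimizer=None, random_state=0)),
        _Member("model_tree", lambda: _ModelTree()),
    ]


@dataclass
class EnsembleModel:
    members: list = field(default_factory=list)
    weights: np.ndarray = field(default_factory=lambda: np.array([]))
    medians: np.ndarray = field(default_factory=lambda: np.array([]))
    threshold: float = 0.5

    def impute(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float).copy()
        bad = ~np.isfinite(X)
        if bad.any():
            X[bad] = np.take(self.medians, np.nonzero(bad)[1])
        return X

    def score(self, X: np.ndarray) -> np.ndarray:
        X = self.impute(X)
        s = np.zeros(len(X))
        for w, m in zip(self.weights, self.members):
            s += w * m.score01(X)
        return s

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.score(X) >= self.threshold, "right", "wrong")


def _to01(y: np.ndarray) -> np.ndarray:
    return (np.asarray(y) == POSITIVE).astype(int)


def fit_ensemble(X_train: np.ndarray, y_train: np.ndarray,
                 X_val: np.ndarray, y_val: np.ndarray,
                 rng: np.random.Generator,
                 smote: bool = True, per_point: int = 4) -> EnsembleModel:
    """Fit the seven members and weight them by validation accuracy.

    Missing features are imputed with training-fold medians; the
    training fold (never validation or test) is rebalanced by
    :func:`smote_balance`.  Degenerate all-zero validation accuracies
    fall back to uniform weights.
    """
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("single-class training set")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(X_train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    model = EnsembleModel(medians=med)
    Xt = model.impute(X_train)
    if smote:
        counts = np.unique(y_train, return_counts=True)[1]
        if counts.min() >= 5:
            Xt, y_train = smote_balance(Xt, y_train, rng, per_point=per_point)
        else:
            warnings.warn("minority class under 5 points in this training "
                          "fold; fitting without oversampling", RuntimeWarning)
    y01 = _to01(y_train)

    Xv = model.impute(np.asarray(X_val, float))
    yv01 = _to01(y_val)
    members, accs = [], []
    for mem in _members(Xt.shape[1]):
        mem.fit(Xt, y01)
        acc = float(np.mean((mem.score01(Xv) >= 0.5).astype(int) == yv01))
        members.append(mem)
        accs.append(acc)
    accs = np.asarray(accs)
    if accs.sum() == 0:
        w = np.full(len(members), 1.0 / len(members))
    else:
        w = accs / accs.sum()
    model.members = members
    model.weights = w
    return model


def predict_and_evaluate(model: EnsembleModel, X_test: np.ndarray,
                         y_test: np.ndarray) -> EvaluationResult:
    if len(np.asarray(X_test)) == 0:
        raise ValueError("empty test set")
    return evaluate_metrics(y_test, model.predict(X_test))


# --------------------------------------------------------------------------
# importance and rank-based carry-forward classification

def rank_feature_importance(fitted_folds: list[tuple[EnsembleModel, np.ndarray, np.ndarray]],
                            feature_names: list[str],
                            rng: np.random.Generator,
                            top_fraction: float = 0.10,
                            n_repeats: int = 2) -> pd.DataFrame:
    """Permutation importance averaged over folds, with dense ranks.

    Each fold contributes the weight-combined accuracy drop of its
    members when one feature column of the validation set is permuted.
    Scores are scaled to [0, 100]; rank 1 is most important (ties share
    a dense rank); the top set holds features ranked within
    ``ceil(top_fraction * n_features)``.
    """
    if not fitted_folds:
        raise ValueError("need at least one fitted fold")
    k = len(feature_names)
    agg = np.zeros(k)
    for model, Xv, yv in fitted_folds:
        Xv = model.impute(np.asarray(Xv, float))
        yv01 = _to01(yv)
        drops = np.zeros(k)
        for w, mem in zip(model.weights, model.members):
            base = float(np.mean((mem.score01(Xv) >= 0.5).astype(int) == yv01))
            for j in range(k):
                drop = 0.0
                for _ in range(n_repeats):
                    Xp = Xv.copy()
                    Xp[:, j] = rng.permutation(Xp[:, j])
                    acc = float(np.mean((mem.score01(Xp) >= 0.5).astype(int) == yv01))
                    drop += base - acc
                drops[j] += w * drop / n_repeats
        agg += drops
    agg = np.maximum(agg / len(fitted_folds), 0.0)
    scaled = 100.0 * agg / agg.max() if agg.max() > 0 else agg

    # dense ranks, 1 = most important
    order = np.argsort(-scaled, kind="stable")
    ranks = np.empty(k, dtype=int)
    rank, prev = 0, None
    for idx in order:
        if prev is None or scaled[idx] < prev:
            rank += 1
            prev = scaled[idx]
        ranks[idx] = rank
    cutoff = math.ceil(top_fraction * k)
    return pd.DataFrame({
        "feature": feature_names,
        "importance": scaled,
        "rank": ranks,
        # zero-importance features never count as "most important",
        # however their shared dense rank falls
        "top": (ranks <= cutoff) & (scaled > 0),
    })


def classify_cfe_predictive(ranks: dict[str, float | None],
                            top: dict[str, bool]) -> str:
    """Carry-forward class from per-phase importance ranks.

    "Highest rank" means numerically smallest.  Perfect: in the top set
    in all three phases and rank(see_solve) < rank(move) <
    rank(respond).  Pseudo: top set everywhere, see-solve rank strictly
    smallest, but move does not outrank respond.  Ties fail the strict
    comparisons; anything else is none.
    """
    phases = ("see_solve", "move", "respond")
    if not all(top.get(ph, False) for ph in phases):
        return "none"
    r = [ranks[ph] for ph in phases]
    if any(v is None or not np.isfinite(v) for v in r):
        return "none"
    if r[0] < r[1] and r[1] < r[2]:
        return "perfect"
    if r[0] < r[1] and r[0] < r[2] and not (r[1] < r[2]):
        return "pseudo"
    return "none"
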