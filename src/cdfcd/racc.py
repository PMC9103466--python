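"""Random-subspace ensemble classification (RACC) and baseline classifiers.

Each of ``B1`` weak learners draws ``B2`` candidate feature subspaces from a
hierarchical-uniform distribution (subspace size uniform on {1..D_max}, then
features uniform without replacement), keeps the candidate with the lowest
out-of-bag misclassification of the base learner, and trains the base
learner on a bootstrap portion (63.2% unique-resampling) restricted to that
subspace.  The ensemble votes; a threshold ``alpha`` converts the binary
vote fraction into a label, and multiclass problems are handled one-vs-rest
by the argmax of per-class vote fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

_BASE_LEARNERS = {
    "svm": lambda seed: SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
    "lda": lambda seed: LinearDiscriminantAnalysis(),
    "knn": lambda seed: KNeighborsClassifier(n_neighbors=5),
    "dt": lambda seed: DecisionTreeClassifier(random_state=seed),
    "nbc": lambda seed: GaussianNB(),
}

BASELINES = {
    "LDA": lambda seed: LinearDiscriminantAnalysis(),
    "KNN": lambda seed: KNeighborsClassifier(n_neighbors=5),
    "NBC": lambda seed: GaussianNB(),
    "DT": lambda seed: DecisionTreeClassifier(random_state=seed),
    "RF": lambda seed: RandomForestClassifier(n_estimators=100, random_state=seed),
    "Adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
    "SVM": lambda seed: SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
}


@dataclass
class RACCModel:
    B1: int
    B2: int
    subspaces: list[np.ndarray]
    base_learners: list
    alpha: float
    feature_usage: np.ndarray  # per-feature chosen proportion eta
    classes_: np.ndarray | None = None  # None for native binary fit
    sub_models: list | None = None  # one-vs-rest children


def _fit_binary(
    X: np.ndarray,
    y01: np.ndarray,
    base: str,
    d_max: int,
    B1: int,
    B2: int,
    seed: int,
    resample_frac: float = 0.632,
) -> RACCModel:
    n, q = X.shape
    rng = np.random.default_rng(seed)
    maker = _BASE_LEARNERS[base]
    subspaces, learners = [], []
    usage = np.zeros(q)
    for j in range(B1):
        candidates = []
        for _ in range(B2):
            d = int(rng.integers(1, d_max + 1))
            candidates.append(np.sort(rng.choice(q, size=d, replace=False)))
        # out-of-bag selection: bootstrap indices, score on the left-out points
        if resample_frac >= 1.0:
            boot = np.arange(n)
            oob = np.array([], dtype=int)
        else:
            boot = rng.choice(n, size=int(round(resample_frac * n)), replace=False)
            oob = np.setdiff1d(np.arange(n), boot)
            if len(oob) == 0 or len(np.unique(y01[boot])) < 2:
                boot = rng.permutation(n)[: max(2, n // 2)]
                oob = np.setdiff1d(np.arange(n), boot)
        best_err, best_S, best_clf = None, None, None
        for S in candidates:
            clf = maker(seed + j)
            try:
                clf.fit(X[np.ix_(boot, S)], y01[boot])
                score_on = oob if len(oob) else boot
                err = np.mean(clf.predict(X[np.ix_(score_on, S)]) != y01[score_on])
            except ValueError:
                continue
            if best_err is None or err < best_err:
                best_err, best_S, best_clf = err, S, clf
        if best_clf is None:
            raise RuntimeError("no trainable candidate subspace (degenerate bootstrap)")
        subspaces.append(best_S)
        learners.append(best_clf)
        usage[best_S] += 1.0
    return RACCModel(B1, B2, subspaces, learners, 0.5, usage / B1)


def _binary_votes(model: RACCModel, X_star: np.ndarray) -> np.ndarray:
    votes = np.zeros(X_star.shape[0])
    for clf, S in zip(model.base_learners, model.subspaces):
        votes += clf.predict(X_star[:, S])
    return votes / model.B1


def racc_fit(
    X: np.ndarray,
    y: np.ndarray,
    base: str = "svm",
    D: int | None = None,
    B1: int = 50,
    B2: int = 10,
    criterion: str = "oob",
    seed: int = 0,
    alpha: float | str = 0.5,
    resample_frac: float = 0.632,
) -> RACCModel:
    """Train a RACC ensemble.

    Binary labels {0,1} use the native vote-threshold rule; more classes are
    handled one-vs-rest.  ``alpha='auto'`` picks the threshold on a grid
    {0.3..0.7 step 0.05} minimizing training error (binary only).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if base not in _BASE_LEARNERS:
        raise ValueError(f"unsupported base learner {base!r}; supported: {sorted(_BASE_LEARNERS)}")
    if B1 < 1 or B2 < 1:
        raise ValueError("B1 and B2 must be positive")
    if criterion != "oob":
        raise ValueError("only the out-of-bag criterion is supported")
    d_max = X.shape[1] if D is None else int(D)
    classes = np.unique(y)
    if len(classes) == 2 and set(classes) == {0, 1}:
        model = _fit_binary(X, y, base, d_max, B1, B2, seed, resample_frac)
        if alpha == "auto":
            votes = _binary_votes(model, X)
            grid = np.arange(0.30, 0.701, 0.05)
            errs = [np.mean((votes > a).astype(int) != y) for a in grid]
            model.alpha = float(grid[int(np.argmin(errs))])
        else:
            model.alpha = float(alpha)
        return model
    # one-vs-rest
    subs = []
    usage = np.zeros(X.shape[1])
    for ci, c in enumerate(classes):
        m = _fit_binary(X, (y == c).astype(int), base, d_max, B1, B2, seed + 1000 * ci, resample_frac)
        subs.append(m)
        usage += m.feature_usage
    parent = RACCModel(
        B1,
        B2,
        [s for m in subs for s in m.subspaces],
        [l for m in subs for l in m.base_learners],
        0.5 if alpha == "auto" else float(alpha),
        usage / len(classes),
        classes_=classes,
        sub_models=subs,
    )
    return parent


def racc_predict(model: RACCModel, X_star: np.ndarray, alpha: float | None = None) -> np.ndarray:
    """Ensemble prediction: binary thresholds the vote fraction at ``alpha``;
    one-vs-rest takes the argmax of per-class vote fractions."""
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    if model.sub_models is None:
        a = model.alpha if alpha is None else float(alpha)
        if not (0 < a < 1):
            raise ValueError("alpha must lie in (0, 1)")
        return (_binary_votes(model, X_star) > a).astype(int)
    votes = np.stack([_binary_votes(m, X_star) for m in model.sub_models])
    return model.classes_[np.argmax(votes, axis=0)]


def baselines_fit_predict(
    X: np.ndarray,
    y: np.ndarray,
    name: str,
    folds: int = 10,
    seed: int = 0,
):
    """Standard classifiers under the shared stratified CV harness."""
    from .pipeline import cross_validate

    if name not in BASELINES:
        raise ValueError(f"unknown baseline {name!r}; supported: {sorted(BASELINES)}")

    def spec(seed_):
        clf = BASELINES[name](seed_)

        def fit_predict(Xtr, ytr, Xte):
            c = clone(clf)
            c.fit(Xtr, ytr)
            return c.predict(Xte)

        return fit_predict

    return cross_validate(spec(seed), X, y, folds=folds, seed=seed)
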