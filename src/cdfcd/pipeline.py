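"""End-to-end staging pipeline: cluster -> reduce -> select -> classify.

The full chain mirrors the staged design: representative-subset selection
after clustering shrinks the epoch count (default to 90000/127658 of the
input, the proportional analogue of the reference protocol), SVD
rank-and-synchronize reduction keeps the top third of epochs by recovered
score, sparse selection trims the feature set to a budget, and the final
classifier is evaluated under stratified 10-fold cross-validation with
accuracy, Cohen's kappa and rank-based significance tests.  When the deep
(LSTM) classifier is chosen, the reduction and selection stages are
bypassed and the clustered epochs are fed to it directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .clustering import (
    ClusterAssignment,
    hierarchical_cluster,
    pca_subspace_cluster,
    select_representatives,
    spectral_cluster,
)
from .datamodel import EpochMatrix, LabelVector
from .gpc import mgc_fit, mgc_predict
from .lstm import TrainConfig, epochs_to_sequences, predict_lstm, train_lstm
from .preprocess import band_power_features
from .racc import BASELINES, racc_fit, racc_predict
from .ranking import epoch_measurement_graph, build_measurement_matrix, reduce_by_ranking, svd_rank_sync
from .ridge import rank_features_by_coeff, rr_lws_fit
from .sgl import GroupedDesign, sgl_dli_select
from .vbmf import vbmf

DEFAULT_CLUSTER_KEEP = 90000 / 127658
DEFAULT_RANK_FACTOR = 3.0


@dataclass
class PipelineConfig:
    clustering: str = "spectral"  # hier | spectral | subspace
    reduction: str = "svd-rank"  # svd-rank | vbmf
    selection: str = "sgl-dli"  # sgl-dli | rr-lws
    classifier: str = "racc"  # mgc | racc | lstm | baseline:<NAME>
    cluster_k: int | str = "auto"
    cluster_keep: float = DEFAULT_CLUSTER_KEEP
    rank_factor: float = DEFAULT_RANK_FACTOR
    vbmf_rank: int = 10
    feature_budget: int | None = None
    sgl_alpha: float = 0.5
    n_sites: int = 4
    featurize: bool = True
    fs: float = 100.0
    n_channels: int = 2
    folds: int = 10
    seed: int = 0
    racc_b1: int = 20
    racc_b2: int = 5
    lstm: TrainConfig | None = None

    def __post_init__(self) -> None:
        if self.clustering not in ("hier", "spectral", "subspace"):
            raise ValueError(f"unknown clustering method {self.clustering!r}")
        if self.reduction not in ("svd-rank", "vbmf"):
            raise ValueError(f"unknown reduction method {self.reduction!r}")
        if self.selection not in ("sgl-dli", "rr-lws"):
            raise ValueError(f"unknown selection method {self.selection!r}")
        if not (0 < self.cluster_keep <= 1):
            raise ValueError("cluster_keep must lie in (0, 1]")


@dataclass
class FitReport:
    accuracy: float
    kappa: float
    confusion: np.ndarray
    fold_accuracy: list[float]
    fold_predictions: list[np.ndarray]
    fold_indices: list[np.ndarray]
    stage_log: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "fold_accuracy": self.fold_accuracy,
            "confusion": self.confusion.tolist(),
            "stages": self.stage_log,
        }


def cohen_kappa(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)`` with
    marginal-product chance agreement; degenerate single-class input is 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    cats = np.unique(np.concatenate([y_true, y_pred]))
    if len(cats) < 2:
        warnings.warn("single-category input; kappa defined as 0")
        return 0.0
    n = len(y_true)
    p_o = np.mean(y_true == y_pred)
    p_e = sum(
        (np.mean(y_true == c)) * (np.mean(y_pred == c)) for c in cats
    )
    if p_e >= 1.0:
        warnings.warn("degenerate marginals; kappa defined as 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def cross_validate(fit_predict, X: np.ndarray, y: np.ndarray, folds: int = 10, seed: int = 0) -> FitReport:
    """Stratified K-fold evaluation of a ``fit_predict(Xtr, ytr, Xte)`` callable."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y)
    smallest = counts[counts > 0].min()
    if smallest < folds:
        raise ValueError(
            f"smallest class has {smallest} samples < {folds} folds; use folds <= {smallest}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n_classes = int(y.max()) + 1
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    fold_acc, fold_pred, fold_idx = [], [], []
    pooled_pred = np.empty_like(y)
    for tr, te in skf.split(X, y):
        pred = np.asarray(fit_predict(X[tr], y[tr], X[te]), dtype=int)
        pooled_pred[te] = pred
        fold_pred.append(pred)
        fold_idx.append(te)
        fold_acc.append(float(np.mean(pred == y[te])))
        for t, p in zip(y[te], pred):
            confusion[t, p] += 1
    acc = float(np.mean(pooled_pred == y))
    kap = cohen_kappa(y, pooled_pred)
    return FitReport(acc, kap, confusion, fold_acc, fold_pred, fold_idx)


def significance_tests(metric_table: np.ndarray) -> dict:
    """Friedman test across classifiers (rows) over folds (columns) plus
    paired two-sided Wilcoxon p-values for every classifier pair."""
    M = np.asarray(metric_table, dtype=float)
    if M.shape[0] < 3:
        raise ValueError("Friedman test needs at least 3 classifiers")
    if np.allclose(M, M[0]):
        warnings.warn("identical classifier rows; tests are degenerate")
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*[M[i] for i in range(M.shape[0])])
    wilcoxon = {}
    for i in range(M.shape[0]):
        for j in range(i + 1, M.shape[0]):
            d = M[i] - M[j]
            if np.all(d == 0):
                wilcoxon[(i, j)] = 1.0
            else:
                wilcoxon[(i, j)] = float(
                    stats.wilcoxon(M[i], M[j], alternative="two-sided", zero_method="wilcox").pvalue
                )
    return {"friedman_stat": float(stat), "friedman_p": float(p), "wilcoxon": wilcoxon}


def _cluster(cfg: PipelineConfig, A: np.ndarray, n_classes: int) -> ClusterAssignment:
    k = cfg.cluster_k
    if cfg.clustering == "hier":
        kk = n_classes if k == "auto" else int(k)
        return hierarchical_cluster(A, kk, mode="complete")
    if cfg.clustering == "spectral":
        return spectral_cluster(A, sigma="auto", K=k, seed=cfg.seed)
    kk = n_classes if k == "auto" else int(k)
    n_sample = min(len(A), max(10 * kk, len(A) // 3))
    labels = pca_subspace_cluster(A, k=kk, n_sample=n_sample, dmax=5, seed=cfg.seed)
    return ClusterAssignment.from_labels(labels, A)


def _select_features(cfg: PipelineConfig, X: np.ndarray, y: np.ndarray, budget: int, log: list) -> np.ndarray:
    classes = np.unique(y)
    scores = np.zeros(X.shape[1])
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    Xs = Xc / np.where(sd > 0, sd, 1.0)
    if cfg.selection == "sgl-dli":
        g_size = max(1, X.shape[1] // max(cfg.n_channels, 1))
        groups = [np.arange(s, min(s + g_size, X.shape[1])) for s in range(0, X.shape[1], g_size)]
        for c in classes:
            yc = (y == c).astype(float)
            d = GroupedDesign(Xs, yc - yc.mean(), groups)
            res = sgl_dli_select(d, alpha=cfg.sgl_alpha, budget=budget, tol=1e-6)
            scores += np.abs(res.beta)
        log.append(f"sgl-dli: aggregated |beta| over {len(classes)} one-vs-rest responses")
    else:
        rng = np.random.default_rng(cfg.seed)
        for c in classes:
            yc = (y == c).astype(float)
            yc = yc - yc.mean()
            perm = rng.permutation(len(y))
            parts = np.array_split(perm, cfg.n_sites)
            partitions = [(Xs[p], yc[p]) for p in parts if len(p) > 1]
            fit = rr_lws_fit(partitions, weight_mode="limiting", seed=cfg.seed)
            scores += np.abs(fit.beta_dist)
        log.append(f"rr-lws: aggregated |beta_dist| over {len(classes)} responses, {cfg.n_sites} sites")
    return rank_features_by_coeff(scores, budget)


def run_pipeline(
    config: PipelineConfig,
    epochs: EpochMatrix,
    labels: LabelVector,
) -> FitReport:
    """Execute the configured chain on paired epochs and labels."""
    cfg = config
    log: list[str] = [f"input: {epochs.n_epochs} epochs x {epochs.n_features} features"]
    if epochs.n_epochs != len(labels):
        raise ValueError("epoch count and label count differ")
    X = epochs
    if cfg.featurize:
        X = band_power_features(X, fs=cfg.fs, n_channels=cfg.n_channels)
        log.append(f"featurize: welch band powers -> {X.n_features} features")
    y = labels.y.copy()
    n_classes = labels.scheme.n_classes

    assignment = _cluster(cfg, X.X, n_classes)
    log.append(
        f"cluster[{cfg.clustering}]: K={assignment.K}, sizes={np.bincount(assignment.labels).tolist()}"
    )
    target_n = int(np.ceil(cfg.cluster_keep * X.n_epochs))
    X_sel, idx = select_representatives(X, assignment, target_n, seed=cfg.seed)
    y = y[idx]
    log.append(f"representatives: kept {X_sel.n_epochs} epochs (ratio {cfg.cluster_keep:.3f})")

    deep = cfg.classifier == "lstm"
    if deep:
        log.append("deep classifier: reduction and selection stages skipped")
        Xf, yf = X_sel.X, y
    else:
        if cfg.reduction == "svd-rank":
            # rank-and-reduce within each cluster so the reduction cannot
            # annihilate whole clusters (the recovered score tracks the
            # dominant spectral axis, which separates clusters)
            cluster_labels = assignment.labels[idx]
            kept: list[np.ndarray] = []
            total_upsets = 0
            for kcl in range(assignment.K):
                members = np.flatnonzero(cluster_labels == kcl)
                if len(members) < 5:
                    kept.append(members)
                    continue
                sub = X_sel.take(members)
                g, _ = epoch_measurement_graph(sub, seed=cfg.seed)
                H = build_measurement_matrix(g)
                sync = svd_rank_sync(H, g)
                total_upsets += sync.upsets
                _, ridx = reduce_by_ranking(sub, sync.r_hat, cfg.rank_factor)
                kept.append(members[ridx])
            ridx = np.sort(np.concatenate(kept))
            X_red = X_sel.take(ridx)
            y = y[ridx]
            log.append(
                f"svd-rank: kept {X_red.n_epochs} epochs (factor {cfg.rank_factor}, "
                f"per-cluster), upsets={total_upsets}"
            )
        else:
            K = min(cfg.vbmf_rank, X_sel.n_features, X_sel.n_epochs)
            C = X_sel.X - X_sel.X.mean(axis=0)
            res = vbmf(C, K=K, seed=cfg.seed)
            X_red = EpochMatrix(res.U.T, X_sel.epoch_len_s, list(X_sel.source_ids))
            log.append(f"vbmf: rank-{K} row embedding, noise_var={res.noise_var:.3g}")
        budget = cfg.feature_budget or min(X_red.n_features, 2000)
        budget = min(budget, X_red.n_features)
        keep = _select_features(cfg, X_red.X, y, budget, log)
        Xf, yf = X_red.X[:, keep], y
        log.append(f"selection[{cfg.selection}]: kept {len(keep)} features")

    seed = cfg.seed
    if cfg.classifier == "racc":
        def fit_predict(Xtr, ytr, Xte):
            m = racc_fit(Xtr, ytr, base="svm", B1=cfg.racc_b1, B2=cfg.racc_b2, seed=seed)
            return racc_predict(m, Xte)
    elif cfg.classifier == "mgc":
        def fit_predict(Xtr, ytr, Xte):
            m = mgc_fit(Xtr, ytr + 1, eps=0.05, seed=seed, max_iter=200)
            lab, _ = mgc_predict(m, Xte)
            return lab - 1
    elif cfg.classifier == "lstm":
        tc = cfg.lstm or TrainConfig(seed=seed)
        n_steps = 60 if Xf.shape[1] % 60 == 0 else _best_steps(Xf.shape[1])

        def fit_predict(Xtr, ytr, Xte):
            seq_tr = epochs_to_sequences(Xtr, n_steps)
            model = train_lstm(seq_tr, ytr, tc)
            lab, _ = predict_lstm(model, epochs_to_sequences(Xte, n_steps))
            return lab
    elif cfg.classifier.startswith("baseline:"):
        name = cfg.classifier.split(":", 1)[1]
        if name not in BASELINES:
            raise ValueError(f"unknown baseline {name!r}")
        from sklearn.base import clone

        proto = BASELINES[name](seed)

        def fit_predict(Xtr, ytr, Xte):
            c = clone(proto)
            c.fit(Xtr, ytr)
            return c.predict(Xte)
    else:
        raise ValueError(f"unknown classifier {cfg.classifier!r}")

    folds = cfg.folds
    smallest = np.bincount(yf)[np.bincount(yf) > 0].min()
    if smallest < folds:
        raise ValueError(
            f"class with {smallest} epochs cannot support {folds}-fold CV; reduce folds"
        )
    report = cross_validate(fit_predict, Xf, yf, folds=folds, seed=seed)
    report.stage_log = log + [f"cv: {folds}-fold stratified, classifier={cfg.classifier}"]
    cfg_dict = asdict(cfg)
    cfg_dict["lstm"] = asdict(cfg.lstm) if cfg.lstm else None
    report.config = cfg_dict
    return report


def _best_steps(q: int) -> int:
    for cand in (60, 50, 40, 30, 25, 20, 15, 10, 6, 5, 4, 3, 2):
        if q % cand == 0:
            return cand
    return 1
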