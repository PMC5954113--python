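"""Linear-SVM classification with repeated stratified 10-fold CV.

Evaluates the full pipeline — mine frequent subnetworks, select the
discriminative ones, rebuild networks, WL-kernel them, extract kernel-PCA
features, classify — under two leakage regimes:

fold_internal (default)
    Every data-dependent stage (mining, selection, the WL compression
    table, the KPCA eigenbasis, feature standardization) is fitted on the
    training folds only; test subjects are projected through the fitted
    objects.  Methodologically sound generalization estimate.
global_fit
    Mining, selection, kernel and KPCA run once on all subjects before the
    folds are drawn, and cross-validation covers only the SVM.  This
    mirrors pipelines that select features globally; its estimates are
    optimistic and the report records which regime produced them.

Metrics are ACC/SEN/SPE from the confusion table and AUC as the rank
probability that a positive's score exceeds a negative's (ties half).
The final figures are arithmetic means over repetitions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .graph_core import GraphDataset
from .gspan import MinerConfig, SubgraphPattern, mine_frequent_subgraphs
from .kernel_pca import kpca_fit, kpca_transform
from .selection import SelectionConfig, rebuild_network, select_discriminative
from .wl_kernel import WLConfig, cross_kernel, wl_feature_maps

__all__ = [
    "CVConfig",
    "EvalReport",
    "compute_metrics",
    "train_svm",
    "run_pipeline_cv",
    "mine_union_patterns",
]


@dataclass
class CVConfig:
    n_folds: int = 10
    n_repetitions: int = 100
    seed: int = 0
    leakage_mode: str = "fold_internal"

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.leakage_mode not in ("fold_internal", "global_fit"):
            raise ValueError(f"unknown leakage_mode {self.leakage_mode!r}")


@dataclass
class EvalReport:
    task: tuple[str, str]            # (positive class, negative class)
    per_repetition: list[dict]       # ACC/SEN/SPE/AUC per repetition
    mean_metrics: dict
    roc_points: list[tuple[float, float]]
    confusion: dict                  # pooled TP/FP/TN/FN over repetitions
    config: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "task": {"positive": self.task[0], "negative": self.task[1]},
            "mean_metrics": self.mean_metrics,
            "per_repetition": self.per_repetition,
            "confusion": self.confusion,
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
            "config": self.config,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def compute_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], scores: Sequence[float]
) -> dict:
    """Confusion-table metrics plus rank-based AUC and ROC sweep points."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    sc = np.asarray(scores, dtype=float)
    if not (len(yt) == len(yp) == len(sc)):
        raise ValueError("y_true, y_pred and scores must have equal length")
    if len(set(yt.tolist())) < 2:
        raise ValueError("AUC undefined: only one class present in y_true")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    fpr, tpr, _ = roc_curve(yt, sc)
    return {
        "ACC": (tp + tn) / len(yt),
        "SEN": tp / (tp + fn),
        "SPE": tn / (tn + fp),
        "AUC": float(roc_auc_score(yt, sc)),
        "TP": tp,
        "TN": tn,
        "FP": fp,
        "FN": fn,
        "roc": list(zip(fpr.tolist(), tpr.tolist())),
    }


def train_svm(features: np.ndarray, labels: Sequence[int], C: float = 1.0) -> SVC:
    """Linear-kernel SVM exposing continuous decision scores for ROC."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[0] != len(labels):
        raise ValueError("features and labels misaligned")
    if len(set(labels)) < 2:
        raise ValueError("training set contains a single class")
    clf = SVC(kernel="linear", C=C)
    clf.fit(x, np.asarray(labels, dtype=int))
    return clf


def mine_union_patterns(
    dataset: GraphDataset,
    config: MinerConfig,
    pooled: bool = False,
) -> list[SubgraphPattern]:
    """Candidate pattern pool: per-class mining united across classes.

    Patterns frequent in either group are candidates, since discriminative
    subnetworks are exactly those over-represented in one group.  With
    ``pooled`` the whole set is mined once instead.
    """
    if pooled:
        return mine_frequent_subgraphs(dataset, config)
    seen: dict[tuple, SubgraphPattern] = {}
    for cls in dataset.classes:
        for p in mine_frequent_subgraphs(dataset, config, class_filter=cls):
            seen.setdefault(p.code, p)
    out = list(seen.values())
    out.sort(key=lambda p: (p.n_edges, _code_sort_key(p)))
    return out


def _code_sort_key(p: SubgraphPattern):
    from .gspan import CODE_KEY

    return CODE_KEY(p.code)


def _extract_features(train_graphs, test_graphs, wl_cfg: WLConfig,
                      center: bool, m: Optional[int], mass: float):
    """WL kernel + KPCA fitted on train graphs; test graphs projected."""
    train_maps, table = wl_feature_maps(train_graphs, wl_cfg.h)
    n = len(train_maps)
    k_train = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            k_train[i, j] = k_train[j, i] = train_maps[i].dot(train_maps[j])
    model = kpca_fit(k_train, center=center, m=m, mass=mass)
    x_train = kpca_transform(model, k_train)
    test_maps, _ = wl_feature_maps(test_graphs, wl_cfg.h, table)
    x_test = kpca_transform(model, cross_kernel(test_maps, train_maps)) \
        if test_graphs else np.zeros((0, model.m))
    return np.atleast_2d(x_train), np.atleast_2d(x_test), model


def _fit_stage_on(
    train_ds: GraphDataset,
    task: tuple[str, str],
    miner_cfg: MinerConfig,
    sel_cfg: SelectionConfig,
    pooled_mining: bool,
):
    """Mining + selection on a graph set; empty pool degrades gracefully."""
    patterns = mine_union_patterns(train_ds, miner_cfg, pooled=pooled_mining)
    if not patterns:
        warnings.warn(
            "no frequent patterns at this support; rebuilt networks are "
            "edgeless and classification falls back to chance",
            stacklevel=2,
        )
        return []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k > available is fine inside CV
        return select_discriminative(patterns, sel_cfg, task[0], task[1])


def run_pipeline_cv(
    dataset: GraphDataset,
    task: tuple[str, str],
    miner_config: MinerConfig | None = None,
    selection_config: SelectionConfig | None = None,
    wl_config: WLConfig | None = None,
    cv: CVConfig | None = None,
    rebuild_rule: str = "embedded",
    kpca_center: bool = False,
    kpca_m: Optional[int] = None,
    kpca_mass: float = 0.9,
    svm_C: float = 1.0,
    pooled_mining: bool = False,
) -> EvalReport:
    """Repeated stratified k-fold evaluation of the whole pipeline.

    ``task`` is (positive class, negative class); by convention the
    positive class is the more impaired group.  Same config and seed give
    a byte-identical report.
    """
    miner_config = miner_config or MinerConfig()
    selection_config = selection_config or SelectionConfig()
    wl_config = wl_config or WLConfig()
    cv = cv or CVConfig()

    pos, neg = task
    idx = [i for i, c in enumerate(dataset.class_labels) if c in (pos, neg)]
    ds = dataset.subset(idx)
    for cls in (pos, neg):
        n_cls = sum(1 for c in ds.class_labels if c == cls)
        if n_cls == 0:
            raise ValueError(f"task class {cls!r} absent from dataset")
        if n_cls < cv.n_folds:
            raise ValueError(
                f"class {cls!r} has {n_cls} subjects, fewer than "
                f"{cv.n_folds} folds: stratification impossible"
            )
    y = np.array([1 if c == pos else 0 for c in ds.class_labels])

    global_features = None
    if cv.leakage_mode == "global_fit":
        selected = _fit_stage_on(ds, task, miner_config, selection_config,
                                 pooled_mining)
        rebuilt = [rebuild_network(g, selected, rebuild_rule) if selected
                   else _edgeless(g) for g in ds.graphs]
        x_all, _, _ = _extract_features(rebuilt, [], wl_config,
                                        kpca_center, kpca_m, kpca_mass)
        global_features = x_all

    per_rep: list[dict] = []
    pooled_scores: list[float] = []
    pooled_truth: list[int] = []
    pooled_conf = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}

    for rep in range(cv.n_repetitions):
        skf = StratifiedKFold(
            n_splits=cv.n_folds, shuffle=True, random_state=cv.seed + rep
        )
        y_pred = np.zeros(len(ds), dtype=int)
        scores = np.zeros(len(ds), dtype=float)
        for train_idx, test_idx in skf.split(np.zeros(len(ds)), y):
            if global_features is not None:
                x_train = global_features[train_idx]
                x_test = global_features[test_idx]
            else:
                train_ds = ds.subset(train_idx)
                selected = _fit_stage_on(
                    train_ds, task, miner_config, selection_config,
                    pooled_mining,
                )
                if selected:
                    reb_train = [rebuild_network(g, selected, rebuild_rule)
                                 for g in train_ds.graphs]
                    reb_test = [rebuild_network(ds.graphs[i], selected,
                                                rebuild_rule)
                                for i in test_idx]
                else:
                    reb_train = [_edgeless(g) for g in train_ds.graphs]
                    reb_test = [_edgeless(ds.graphs[i]) for i in test_idx]
                x_train, x_test, _ = _extract_features(
                    reb_train, reb_test, wl_config,
                    kpca_center, kpca_m, kpca_mass,
                )
            scaler = StandardScaler().fit(x_train)
            clf = train_svm(scaler.transform(x_train), y[train_idx], C=svm_C)
            xt = scaler.transform(x_test)
            y_pred[test_idx] = clf.predict(xt)
            scores[test_idx] = clf.decision_function(xt)
        rep_metrics = compute_metrics(y, y_pred, scores)
        rep_metrics.pop("roc")
        for key in ("TP", "TN", "FP", "FN"):
            pooled_conf[key] += rep_metrics[key]
        per_rep.append(
            {k: rep_metrics[k] for k in ("ACC", "SEN", "SPE", "AUC")}
        )
        pooled_scores.extend(scores.tolist())
        pooled_truth.extend(y.tolist())

    mean_metrics = {
        k: float(np.mean([r[k] for r in per_rep]))
        for k in ("ACC", "SEN", "SPE", "AUC")
    }
    fpr, tpr, _ = roc_curve(pooled_truth, pooled_scores)
    return EvalReport(
        task=task,
        per_repetition=per_rep,
        mean_metrics=mean_metrics,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        confusion=pooled_conf,
        config={
            "n_folds": cv.n_folds,
            "n_repetitions": cv.n_repetitions,
            "seed": cv.seed,
            "leakage_mode": cv.leakage_mode,
            "min_support": miner_config.min_support,
            "selection_mode": selection_config.mode,
            "selection_k": selection_config.k,
            "wl_h": wl_config.h,
            "kpca_center": kpca_center,
            "kpca_m": kpca_m if kpca_m is not None else "auto",
            "kpca_mass": kpca_mass,
            "rebuild_rule": rebuild_rule,
            "svm_C": svm_C,
            "positive_class": pos,
        },
    )


def _edgeless(g):
    from .graph_core import LabeledGraph

    return LabeledGraph(g.node_labels)
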