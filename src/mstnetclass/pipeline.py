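"""One-shot pipeline: build -> mine -> select -> rebuild -> kernel -> KPCA -> SVM.

The default profile encodes the reference settings of the method: MST
network construction, support 0.7, WL depth h=5, kernel-PCA dimension by
the 0.9 absolute-eigenvalue-mass rule, linear SVM, stratified 10-fold
cross-validation repeated 100 times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from . import __version__
from .classify_eval import CVConfig, EvalReport, mine_union_patterns, run_pipeline_cv
from .graph_core import GraphDataset, read_graph, read_manifest, write_graph
from .gspan import MinerConfig, SubgraphPattern
from .selection import SelectionConfig, rebuild_network, select_discriminative

log = logging.getLogger("mstnetclass")

__all__ = ["PipelineConfig", "run_end_to_end", "load_graph_dataset",
           "patterns_to_json", "patterns_from_json"]


@dataclass
class PipelineConfig:
    graphs_dir: str
    manifest: str
    out_dir: str
    tasks: list[tuple[str, str]]
    seed: int = 42
    min_support: float = 0.7
    per_class_mining: bool = True
    selection_mode: str = "top_k"
    selection_k: int = 50
    selection_min_diff: float = 0.5
    rebuild_rule: str = "embedded"
    wl_h: int = 5
    kpca_m: Optional[int] = None   # None -> eigenvalue-mass rule
    kpca_mass: float = 0.9
    kpca_center: bool = False
    n_folds: int = 10
    n_repetitions: int = 100
    leakage_mode: str = "fold_internal"
    svm_C: float = 1.0
    graph_format: str = "edgelist"
    max_pattern_edges: Optional[int] = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["tasks"] = [tuple(t) for t in raw["tasks"]]
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path: str) -> None:
        payload = asdict(self)
        payload["tasks"] = [list(t) for t in self.tasks]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_graph_dataset(graphs_dir: str, manifest_path: str,
                       graph_format: str = "edgelist") -> GraphDataset:
    """Assemble a dataset from per-subject graph files and a manifest."""
    ext = "graphml" if graph_format == "graphml" else "edgelist"
    pairs = read_manifest(manifest_path)
    graphs, labels, ids = [], [], []
    for sid, cls in pairs:
        path = os.path.join(graphs_dir, f"{sid}.{ext}")
        if not os.path.exists(path):
            raise FileNotFoundError(f"graph file missing for subject {sid}: {path}")
        graphs.append(read_graph(path, graph_format))
        labels.append(cls)
        ids.append(sid)
    return GraphDataset(graphs, labels, ids)


def patterns_to_json(patterns: list[SubgraphPattern]) -> list[dict]:
    return [
        {
            "edges": [list(map(str, e)) for e in p.label_edges()],
            "code": [list(map(str, t)) for t in p.code],
            "n_edges": p.n_edges,
            "frequency": {c: f for c, f in sorted(p.frequency.items())},
        }
        for p in patterns
    ]


def patterns_from_json(payload: list[dict]) -> list[SubgraphPattern]:
    """Rebuild pattern objects from their serialized label-pair edge lists."""
    from .graph_core import LabeledGraph
    from .gspan import min_dfs_code

    def _coerce(tok: str):
        try:
            return int(tok)
        except ValueError:
            return tok

    out = []
    for item in payload:
        edges = [tuple(_coerce(t) for t in e) for e in item["edges"]]
        nodes = sorted({u for e in edges for u in e}, key=str)
        node_ids = {l: i for i, l in enumerate(nodes)}
        g = LabeledGraph({i: l for l, i in node_ids.items()})
        for la, lb in edges:
            g.add_edge(node_ids[la], node_ids[lb])
        out.append(
            SubgraphPattern(g, min_dfs_code(g),
                            {c: float(f) for c, f in item["frequency"].items()})
        )
    return out


def run_end_to_end(config: PipelineConfig) -> dict[str, EvalReport]:
    """Execute all stages for every task; write artifacts and provenance.

    Returns one report per task, keyed ``"POS_vs_NEG"``.  Alongside each
    cross-validated report, the mined pattern pool, the selected patterns
    and the rebuilt networks fitted once on the full task data are written
    for inspection (the CV itself refits inside folds when
    ``leakage_mode="fold_internal"``).
    """
    t0 = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    dataset = load_graph_dataset(config.graphs_dir, config.manifest,
                                 config.graph_format)
    log.info("loaded %d subjects, classes %s", len(dataset), dataset.classes)

    miner_cfg = MinerConfig(config.min_support, config.max_pattern_edges)
    sel_cfg = SelectionConfig(config.selection_mode, config.selection_k,
                              config.selection_min_diff)
    reports: dict[str, EvalReport] = {}
    for pos, neg in config.tasks:
        task_key = f"{pos}_vs_{neg}"
        task_dir = os.path.join(config.out_dir, task_key)
        os.makedirs(task_dir, exist_ok=True)
        sub = dataset.subset(
            [i for i, c in enumerate(dataset.class_labels) if c in (pos, neg)]
        )

        t = time.time()
        patterns = mine_union_patterns(sub, miner_cfg,
                                       pooled=not config.per_class_mining)
        log.info("[%s] mined %d frequent patterns (%.2fs)",
                 task_key, len(patterns), time.time() - t)
        with open(os.path.join(task_dir, "patterns.json"), "w") as fh:
            json.dump(patterns_to_json(patterns), fh, indent=2)

        selected = (
            select_discriminative(patterns, sel_cfg, pos, neg)
            if patterns else []
        )
        log.info("[%s] selected %d discriminative patterns",
                 task_key, len(selected))
        with open(os.path.join(task_dir, "selected.json"), "w") as fh:
            json.dump(patterns_to_json(selected), fh, indent=2)

        rebuilt_dir = os.path.join(task_dir, "rebuilt")
        os.makedirs(rebuilt_dir, exist_ok=True)
        kept = 0
        for sid, g in zip(sub.subject_ids, sub.graphs):
            rg = rebuild_network(g, selected, config.rebuild_rule) if selected \
                else _empty_copy(g)
            kept += rg.n_edges
            write_graph(rg, os.path.join(rebuilt_dir, f"{sid}.edgelist"))
        log.info("[%s] rebuilt networks retain %d edges total", task_key, kept)

        t = time.time()
        report = run_pipeline_cv(
            sub, (pos, neg),
            miner_config=miner_cfg,
            selection_config=sel_cfg,
            wl_config=_wl(config),
            cv=CVConfig(config.n_folds, config.n_repetitions, config.seed,
                        config.leakage_mode),
            rebuild_rule=config.rebuild_rule,
            kpca_center=config.kpca_center,
            kpca_m=config.kpca_m,
            kpca_mass=config.kpca_mass,
            svm_C=config.svm_C,
            pooled_mining=not config.per_class_mining,
        )
        log.info("[%s] CV done (%.2fs): ACC %.3f SEN %.3f SPE %.3f AUC %.3f",
                 task_key, time.time() - t, *[
                     report.mean_metrics[k] for k in ("ACC", "SEN", "SPE", "AUC")
                 ])
        with open(os.path.join(task_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
        reports[task_key] = report

    provenance = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "package_version": __version__,
        "n_subjects": len(dataset),
        "classes": dataset.classes,
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    with open(os.path.join(config.out_dir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    return reports


def _wl(config: PipelineConfig):
    from .wl_kernel import WLConfig

    return WLConfig(h=config.wl_h)


def _empty_copy(g):
    from .graph_core import LabeledGraph

    return LabeledGraph(g.node_labels)
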