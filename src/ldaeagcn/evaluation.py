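"""Evaluation harness: cross-validation, metrics, ablation and ranking.

The harness mirrors the experimental designs common for link-prediction
classifiers on curated association data: stratified k-fold cross-validation
with per-fold and mean metric rows, an independent train/test/validation
split, edge-category ablation (delete one relational network at a time and
retrain), a comparison of walk-based versus uniformly random negatives, and
per-disease candidate ranking for case-study style output.

Threshold metrics are computed at 0.5 by default (configurable).  ROC AUC is
the Mann–Whitney statistic (ties get half credit); PR AUC is a trapezoid over
recall with tied scores grouped into one threshold step.  Zero-denominator
conventions: SEN/SPEC/PREC fall back to 0 (flagged), MCC is 0 when any of
its four factors vanishes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .cnwgsn import EDGE_CATEGORIES, PairGraph, build_pair_graph
from .data_io import AssociationTable, DiseaseDAG, build_ldcm
from .model import ModelConfig, ModelParams, predict_scores, train_model
from .rwrh import sample_negatives, score_all_pairs
from .similarity import disease_similarity_matrix, lncrna_similarity_matrix

METRIC_FIELDS = ("acc", "sen", "spec", "prec", "mcc", "auc", "aupr")


@dataclass
class MetricsReport:
    acc: float
    sen: float
    spec: float
    prec: float
    mcc: float
    auc: float
    aupr: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_FIELDS}


@dataclass
class FoldPlan:
    k: int
    folds: list[tuple[list[int], list[int]]]  # (train indices, test indices)
    seed: int


def kfold_split(labels: np.ndarray, k: int, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan over sample indices.

    Each class is shuffled and dealt round-robin, so fold sizes differ by at
    most one and every fold contains both classes.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} samples, fewer than k={k}")
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % k
    folds = []
    for f in range(k):
        test = [int(i) for i in np.flatnonzero(assignment == f)]
        train = [int(i) for i in np.flatnonzero(assignment != f)]
        folds.append((train, test))
    return FoldPlan(k, folds, seed)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score+ > score−) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    npos = int((labels == 1).sum())
    nneg = int((labels == 0).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("ROC AUC needs both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - npos * (npos + 1) / 2.0
    return float(u / (npos * nneg))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under precision–recall: trapezoid over recall, ties grouped."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    npos = int((labels == 1).sum())
    if npos == 0:
        raise ValueError("PR AUC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # keep only the last point of each tied-score group
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    recall = tp / npos
    precision = tp / (tp + fp)
    r = np.r_[0.0, recall]
    p = np.r_[precision[0], precision]
    return float(np.sum((r[1:] - r[:-1]) * (p[1:] + p[:-1]) / 2.0))


def binary_metrics(scores: np.ndarray, labels: np.ndarray,
                   threshold: float = 0.5) -> MetricsReport:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = tp + fp + tn + fn
    flags: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{name} denominator zero")
            return 0.0
        return num / den

    acc = ratio(tp + tn, n, "acc")
    sen = ratio(tp, tp + fn, "sen")
    spec = ratio(tn, tn + fp, "spec")
    prec = ratio(tp, tp + fp, "prec")
    factors = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if factors == 0:
        flags.append("mcc factor zero")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(factors)
    auc = roc_auc(scores, labels) if 0 < labels.sum() < n else 0.0
    aupr = pr_auc(scores, labels) if labels.sum() > 0 else 0.0
    return MetricsReport(acc, sen, spec, prec, float(mcc), auc, aupr,
                         tp, fp, tn, fn, threshold, flags)


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class PairDataset:
    """Labeled candidate pairs plus the matrices and graphs behind them."""

    table: AssociationTable
    llcm: np.ndarray
    ddscm: np.ndarray
    ldcm: np.ndarray
    pairs: list[tuple[int, int]]
    labels: np.ndarray
    n_lnc_nodes: int = 10
    n_dis_nodes: int = 10
    _graphs: list[PairGraph] | None = field(default=None, repr=False)

    def graphs(self) -> list[PairGraph]:
        if self._graphs is None:
            self._graphs = [
                build_pair_graph(i, j, self.llcm, self.ddscm, self.ldcm,
                                 self.n_lnc_nodes, self.n_dis_nodes,
                                 label=int(lab))
                for (i, j), lab in zip(self.pairs, self.labels)
            ]
        return self._graphs


def assemble_dataset(
    table: AssociationTable,
    dag: DiseaseDAG,
    delta: float = 0.5,
    negative_mode: str = "rwrh",
    ratio: float = 1.0,
    pool_fraction: float = 0.5,
    lambda_jump: float = 0.5,
    restart_prob: float = 0.7,
    seed: int = 0,
    n_lnc_nodes: int = 10,
    n_dis_nodes: int = 10,
) -> PairDataset:
    """Similarities, walk-sampled negatives and labeled pairs in one bundle."""
    ddscm = disease_similarity_matrix(dag, table.disease_ids, delta)
    llcm = lncrna_similarity_matrix(table, ddscm)
    ldcm = build_ldcm(table).values
    positives = sorted(table.pairs)
    score_table = score_all_pairs(llcm.values, ddscm.values, ldcm,
                                  lambda_jump=lambda_jump, restart_prob=restart_prob)
    negatives = sample_negatives(score_table, set(positives), ratio=ratio,
                                 pool_fraction=pool_fraction, seed=seed,
                                 mode=negative_mode)
    pairs = positives + negatives
    labels = np.r_[np.ones(len(positives)), np.zeros(len(negatives))].astype(int)
    return PairDataset(table, llcm.values, ddscm.values, ldcm, pairs, labels,
                       n_lnc_nodes, n_dis_nodes)


def with_permuted_labels(dataset: PairDataset, seed: int) -> PairDataset:
    """Label-permuted control: same graphs, labels shuffled (signal destroyed)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset.labels))
    new_labels = dataset.labels[perm]
    graphs = [dataclasses.replace(g, label=int(lab))
              for g, lab in zip(dataset.graphs(), new_labels)]
    out = dataclasses.replace(dataset, labels=new_labels)
    out._graphs = graphs
    return out


# ---------------------------------------------------------------------------
# experiment protocols


def _fit_and_score(graphs: list[PairGraph], train_idx: list[int],
                   eval_idx: list[int], config: ModelConfig,
                   threshold: float) -> MetricsReport:
    train_graphs = [graphs[i] for i in train_idx]
    eval_graphs = [graphs[i] for i in eval_idx]
    params, _ = train_model(train_graphs, config)
    scores = np.array(predict_scores(params, eval_graphs, config))
    labels = np.array([g.label for g in eval_graphs])
    return binary_metrics(scores, labels, threshold)


def mean_report(reports: list[MetricsReport]) -> dict:
    return {k: float(np.mean([getattr(r, k) for r in reports])) for k in METRIC_FIELDS}


def cross_validate(dataset: PairDataset, model_config: ModelConfig,
                   k: int = 10, seed: int = 0,
                   threshold: float = 0.5) -> dict:
    """Stratified k-fold train/predict/metrics with a mean row (Table-style)."""
    graphs = dataset.graphs()
    plan = kfold_split(dataset.labels, k, seed)
    folds = []
    for f, (train_idx, test_idx) in enumerate(plan.folds):
        cfg = dataclasses.replace(model_config, seed=model_config.seed + f)
        try:
            folds.append(_fit_and_score(graphs, train_idx, test_idx, cfg, threshold))
        except Exception as exc:  # annotate with the failing fold
            raise RuntimeError(f"fold {f + 1}/{k} failed: {exc}") from exc
    return {"k": k, "folds": folds, "mean": mean_report(folds)}


def independent_split_evaluate(dataset: PairDataset, model_config: ModelConfig,
                               seed: int = 0, threshold: float = 0.5) -> dict:
    """Hold out one tenth as validation, one tenth as test; train on the rest.

    Returns Table-3-style rows for the train, test and validation splits.
    """
    plan = kfold_split(dataset.labels, 10, seed)
    _, validation = plan.folds[0]
    _, test = plan.folds[1]
    held = set(validation) | set(test)
    train = [i for i in range(len(dataset.labels)) if i not in held]
    graphs = dataset.graphs()
    params, _ = train_model([graphs[i] for i in train], model_config)
    rows = {}
    for name, idx in (("train", train), ("test", test), ("validation", validation)):
        scores = np.array(predict_scores(params, [graphs[i] for i in idx], model_config))
        labels = np.array([graphs[i].label for i in idx])
        rows[name] = binary_metrics(scores, labels, threshold)
    return rows


def _drop_categories(graphs: list[PairGraph], drop: set[str]) -> list[PairGraph]:
    if "core_att" in drop:
        raise ValueError("the query edge (core_att) cannot be ablated")
    unknown = drop - set(EDGE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown edge categories: {sorted(unknown)}")
    out = []
    for g in graphs:
        repl = {cat: np.zeros_like(g.edge_tensor(cat)) for cat in drop}
        out.append(dataclasses.replace(g, **repl))
    return out


def ablate_edges(dataset: PairDataset, settings: list[set[str]],
                 model_config: ModelConfig, k: int = 10, seed: int = 0,
                 threshold: float = 0.5) -> list[dict]:
    """Re-run cross-validation with the named edge tensors zeroed out.

    One report per requested setting; the empty set reproduces the full model.
    """
    reports = []
    base_graphs = dataset.graphs()
    for drop in settings:
        ablated = dataclasses.replace(dataset)
        ablated._graphs = _drop_categories(base_graphs, set(drop))
        rep = cross_validate(ablated, model_config, k=k, seed=seed, threshold=threshold)
        rep["dropped"] = sorted(drop)
        reports.append(rep)
    return reports


def rank_candidates(params: ModelParams, model_config: ModelConfig,
                    dataset: PairDataset, disease_id: str,
                    top_k: int = 10) -> list[tuple[str, float]]:
    """Score every lncRNA not yet associated with the disease; top-k descending.

    Ties break by lncRNA index, and known partners never appear in the output.
    """
    table = dataset.table
    if disease_id not in table.disease_ids:
        raise KeyError(f"unknown disease: {disease_id!r}")
    j = table.disease_ids.index(disease_id)
    candidates = [i for i in range(table.n_lncrnas) if dataset.ldcm[i, j] == 0]
    graphs = [build_pair_graph(i, j, dataset.llcm, dataset.ddscm, dataset.ldcm,
                               dataset.n_lnc_nodes, dataset.n_dis_nodes)
              for i in candidates]
    scores = predict_scores(params, graphs, model_config)
    order = sorted(range(len(candidates)), key=lambda t: (-scores[t], candidates[t]))
    return [(table.lncrna_ids[candidates[t]], float(scores[t])) for t in order[:top_k]]
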