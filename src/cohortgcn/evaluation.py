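"""Repeated stratified cross-validation, metrics, baselines, and comparisons.

The labeled subjects are partitioned into 5 near-equal portions per
repeat; one portion tests while the other four train.  Unlabeled subjects
never enter a test fold but (for the semi-supervised GCN) remain in the
cohort graph so their features aid training.  The whole procedure is
repeated (50 times in the published protocol) with re-randomized folds and
re-initialized weights, and five metrics are reported per repeat and fold:
accuracy, balanced accuracy, sensitivity, specificity, and AUC.

Folds are stratified by class by default — at a 1:2 class ratio with ~119
labeled subjects unstratified folds make fold-level sensitivity unstable —
with per-class remainders placed so the overall fold sizes are as equal as
possible (119 subjects -> {24, 24, 24, 24, 23}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .connectome import CohortManifest, Connectome, vectorize
from .gcn import GCNConfig, train, predict
from .graph import DEFAULT_SIGMA, PopulationGraph, kernel_matrix, propagation_operator

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "balanced_accuracy", "sensitivity", "specificity", "auc")
BASELINE_MODELS = ("logistic", "ridge", "svm_linear", "svm_rbf", "mlp")


class EvaluationError(ValueError):
    """Invalid evaluation input or incompatible reports."""


@dataclass
class CVScheme:
    """Cross-validation protocol: 5 folds x 50 repeats, stratified, by default."""

    n_folds: int = 5
    n_repeats: int = 50
    stratified: bool = True
    include_unlabeled: bool = True
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise EvaluationError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.n_repeats < 1:
            raise EvaluationError(f"n_repeats must be >= 1, got {self.n_repeats}")


def make_folds(manifest: CohortManifest, scheme: CVScheme) -> list[list[np.ndarray]]:
    """Per-repeat partitions of the labeled subjects into near-equal folds.

    Returns ``folds[repeat][fold]`` = array of manifest positions.  With
    stratification each class is spread as evenly as possible across folds
    and per-class remainders go to the folds with the smallest running
    totals, so overall fold sizes differ by at most one.  Deterministic
    from ``base_seed`` and the repeat index.
    """
    y = manifest.y
    labeled_idx = np.where(y >= 0)[0]
    if labeled_idx.size < scheme.n_folds:
        raise EvaluationError(
            f"{labeled_idx.size} labeled subjects cannot fill {scheme.n_folds} folds"
        )
    k = scheme.n_folds
    if scheme.stratified:
        for c in (0, 1):
            n_c = int((y[labeled_idx] == c).sum())
            if 0 < n_c < k:
                raise EvaluationError(
                    f"class {c} has only {n_c} labeled subjects; too few for {k} stratified folds"
                )
    repeats: list[list[np.ndarray]] = []
    for r in range(scheme.n_repeats):
        rng = np.random.default_rng([scheme.base_seed, r])
        folds: list[list[np.ndarray]] = [[] for _ in range(k)]
        if scheme.stratified:
            totals = np.zeros(k, dtype=int)
            classes = sorted(
                np.unique(y[labeled_idx]),
                key=lambda c: -int((y[labeled_idx] == c).sum()),
            )
            for c in classes:
                idx_c = labeled_idx[y[labeled_idx] == c]
                idx_c = rng.permutation(idx_c)
                counts = np.full(k, idx_c.size // k, dtype=int)
                extras = idx_c.size % k
                order = np.argsort(totals, kind="stable")
                counts[order[:extras]] += 1
                start = 0
                for f in range(k):
                    folds[f].append(idx_c[start : start + counts[f]])
                    start += counts[f]
                totals += counts
        else:
            perm = rng.permutation(labeled_idx)
            for f, chunk in enumerate(np.array_split(perm, k)):
                folds[f].append(chunk)
        repeats.append([np.sort(np.concatenate(parts)) for parts in folds])
    return repeats


def compute_metrics(
    truth: np.ndarray, predicted: np.ndarray, scores: np.ndarray | None = None
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, balanced accuracy, and AUC.

    Sensitivity is TP/(TP+FN) on the positive (high-risk) class; AUC uses
    the rank statistic with midranks for ties and is NaN when the truth
    contains a single class or scores are absent.
    """
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.size == 0:
        raise EvaluationError("empty truth vector")
    if truth.shape != predicted.shape:
        raise EvaluationError("truth and prediction lengths differ")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    acc = (tp + tn) / truth.size
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    ba = (sens + spec) / 2.0
    if scores is not None and len(np.unique(truth)) == 2:
        auc = float(roc_auc_score(truth, np.asarray(scores, dtype=float)))
    else:
        auc = np.nan
    return {
        "accuracy": float(acc),
        "balanced_accuracy": float(ba),
        "sensitivity": float(sens),
        "specificity": float(spec),
        "auc": auc,
    }


@dataclass
class EvaluationReport:
    """Tidy per-(repeat, fold, model) metric records with aggregation helpers."""

    records: pd.DataFrame

    COLUMNS = ["repeat", "fold", "model"] + list(METRICS)

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise EvaluationError(f"report missing columns: {missing}")
        self.records = self.records[self.COLUMNS].reset_index(drop=True)

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- SD per model over all (repeat, fold) records."""
        g = self.records.groupby("model")[list(METRICS)]
        agg = g.agg(["mean", "std"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        return agg.reset_index()

    def per_repeat(self, metric: str, model: str) -> pd.Series:
        """Repeat-level means of one metric for one model (indexed by repeat)."""
        sub = self.records[self.records["model"] == model]
        if sub.empty:
            raise EvaluationError(f"no records for model {model!r}")
        return sub.groupby("repeat")[metric].mean()

    @property
    def models(self) -> list[str]:
        return sorted(self.records["model"].unique())

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EvaluationReport":
        return cls(pd.read_csv(path))

    @classmethod
    def concat(cls, reports: Sequence["EvaluationReport"]) -> "EvaluationReport":
        return cls(pd.concat([r.records for r in reports], ignore_index=True))


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _cv_graphs(
    connectomes: Sequence[Connectome],
    manifest: CohortManifest,
    include_unlabeled: bool,
    sigma: float,
    kernel: str,
    standardize: bool,
) -> tuple[PopulationGraph, np.ndarray]:
    """Build the (fold-independent) cohort graph once; masks are set per fold.

    Returns the graph over the included node set and the manifest positions
    of its nodes.
    """
    features = [vectorize(c) for c in connectomes]
    by_id = {f.subject_id: f for f in features}
    if set(by_id) != set(manifest.subject_ids):
        raise EvaluationError("connectome subject ids do not match the manifest")
    X_all = np.vstack([by_id[sid].values for sid in manifest.subject_ids])
    if standardize:
        sd = X_all.std(axis=0)
        sd[sd == 0] = 1.0
        X_all = (X_all - X_all.mean(axis=0)) / sd
    y = manifest.y
    node_pos = np.arange(len(manifest)) if include_unlabeled else np.where(y >= 0)[0]
    X = X_all[node_pos]
    A = kernel_matrix(X, sigma, kernel)
    S = propagation_operator(A)
    masks = {
        "train_labeled": y[node_pos] >= 0,
        "test_labeled": np.zeros(node_pos.size, dtype=bool),
        "unlabeled": y[node_pos] < 0,
    }
    graph = PopulationGraph(
        X=X,
        A=A,
        S=S,
        sigma=float(sigma),
        node_ids=[manifest.subject_ids[i] for i in node_pos],
        y=y[node_pos],
        masks=masks,
    )
    return graph, node_pos


def run_cv(
    connectomes: Sequence[Connectome],
    manifest: CohortManifest,
    scheme: CVScheme,
    config: GCNConfig | None = None,
    sigma: float = DEFAULT_SIGMA,
    kernel: str = "gaussian",
    standardize: bool = False,
    model_name: str | None = None,
) -> EvaluationReport:
    """Repeated k-fold CV of the GCN on the cohort graph.

    Per (repeat, fold) the GCN trains on the other folds' labeled nodes —
    plus, when ``scheme.include_unlabeled``, all unlabeled nodes' features —
    and is scored on the held-out fold.  Weights are re-initialized per
    fold with a seed derived from (base_seed, repeat, fold, config.seed),
    so a fixed base seed reproduces the report exactly.
    """
    config = config or GCNConfig()
    name = model_name or ("gcn_semisup" if scheme.include_unlabeled else "gcn")
    graph0, node_pos = _cv_graphs(
        connectomes, manifest, scheme.include_unlabeled, sigma, kernel, standardize
    )
    pos_of = {int(p): i for i, p in enumerate(node_pos)}
    folds = make_folds(manifest, scheme)
    labeled_graph_idx = set(np.where(graph0.y >= 0)[0])
    rows = []
    for r, repeat_folds in enumerate(folds):
        for f, test_manifest_idx in enumerate(repeat_folds):
            test_idx = [pos_of[int(i)] for i in test_manifest_idx]
            train_idx = sorted(labeled_graph_idx - set(test_idx))
            g = graph0.with_masks(train_idx, test_idx)
            cfg = replace(config, seed=_derived_seed(scheme.base_seed, r, f, config.seed))
            result = train(g, cfg)
            pred, scores = predict(result, g.masks["test_labeled"])
            truth = g.y[g.masks["test_labeled"]]
            rows.append({"repeat": r, "fold": f, "model": name, **compute_metrics(truth, pred, scores)})
    return EvaluationReport(pd.DataFrame(rows))


def _make_baseline(name: str, seed: int):
    if name == "logistic":
        return LogisticRegression(class_weight="balanced", max_iter=5000)
    if name == "ridge":
        return RidgeClassifier(class_weight="balanced")
    if name == "svm_linear":
        return SVC(kernel="linear", class_weight="balanced")
    if name == "svm_rbf":
        return SVC(kernel="rbf", gamma="scale", class_weight="balanced")
    raise EvaluationError(f"unknown baseline {name!r}; expected one of {BASELINE_MODELS}")


def _mlp_fold(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: GCNConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Feed-forward baseline: the GCN engine with an identity propagation operator.

    With A = 0 the operator S is the identity, so each block reduces to a
    dense layer with batch norm, ReLU and dropout — a 2-hidden-layer
    perceptron (at the default 3 blocks of 128 units) trained with the same
    weighted cross-entropy as the GCN, on labeled subjects only.
    """
    idx = np.concatenate([train_idx, test_idx])
    n = idx.size
    masks = {
        "train_labeled": np.arange(n) < train_idx.size,
        "test_labeled": np.arange(n) >= train_idx.size,
        "unlabeled": np.zeros(n, dtype=bool),
    }
    graph = PopulationGraph(
        X=X[idx],
        A=np.zeros((n, n)),
        S=np.eye(n),
        sigma=1.0,
        node_ids=[str(i) for i in idx],
        y=y[idx],
        masks=masks,
    )
    result = train(graph, replace(config, seed=seed))
    return predict(result, graph.masks["test_labeled"])


def run_baselines(
    connectomes: Sequence[Connectome],
    manifest: CohortManifest,
    scheme: CVScheme,
    models: Sequence[str] = BASELINE_MODELS,
    mlp_config: GCNConfig | None = None,
    standardize: bool = False,
) -> EvaluationReport:
    """Supervised baselines on the vectorized connectomes of labeled subjects.

    Class-weighted logistic regression, ridge classifier, linear and RBF
    SVMs (scikit-learn, ``class_weight="balanced"``) and a feed-forward
    network with weighted cross-entropy, evaluated under the identical fold
    assignments as the GCN (same scheme, same base seed).
    """
    unknown = set(models) - set(BASELINE_MODELS)
    if unknown:
        raise EvaluationError(f"unknown baselines: {sorted(unknown)}")
    features = [vectorize(c) for c in connectomes]
    by_id = {f.subject_id: f for f in features}
    if set(by_id) != set(manifest.subject_ids):
        raise EvaluationError("connectome subject ids do not match the manifest")
    X = np.vstack([by_id[sid].values for sid in manifest.subject_ids])
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    y = manifest.y
    labeled = np.where(y >= 0)[0]
    folds = make_folds(manifest, scheme)
    mlp_config = mlp_config or GCNConfig()
    rows = []
    for r, repeat_folds in enumerate(folds):
        for f, test_idx in enumerate(repeat_folds):
            train_idx = np.setdiff1d(labeled, test_idx)
            truth = y[test_idx]
            for name in models:
                if name == "mlp":
                    pred, scores = _mlp_fold(
                        X, y, train_idx, test_idx, mlp_config,
                        seed=_derived_seed(scheme.base_seed, r, f, mlp_config.seed),
                    )
                else:
                    est = _make_baseline(name, seed=_derived_seed(scheme.base_seed, r, f))
                    est.fit(X[train_idx], y[train_idx])
                    pred = est.predict(X[test_idx])
                    if hasattr(est, "predict_proba"):
                        scores = est.predict_proba(X[test_idx])[:, 1]
                    else:
                        scores = est.decision_function(X[test_idx])
                rows.append(
                    {"repeat": r, "fold": f, "model": name, **compute_metrics(truth, pred, scores)}
                )
    return EvaluationReport(pd.DataFrame(rows))


def compare(
    report_a: EvaluationReport,
    report_b: EvaluationReport,
    metric: str,
    model_a: str | None = None,
    model_b: str | None = None,
    test: str = "ttest",
) -> dict:
    """Paired comparison of two models on repeat-level metric means.

    Collapses each report to one mean per repeat, pairs repeats, and runs a
    two-sided paired t-test (default) or Wilcoxon signed-rank test.
    Returns the mean difference (a - b), a 95% CI, and the p-value.
    """
    if metric not in METRICS:
        raise EvaluationError(f"unknown metric {metric!r}")
    model_a = model_a or _single_model(report_a)
    model_b = model_b or _single_model(report_b)
    a = report_a.per_repeat(metric, model_a)
    b = report_b.per_repeat(metric, model_b)
    if not a.index.equals(b.index):
        raise EvaluationError("reports do not share the same repeat structure")
    n_folds_a = report_a.records[report_a.records["model"] == model_a].groupby("repeat").size()
    n_folds_b = report_b.records[report_b.records["model"] == model_b].groupby("repeat").size()
    if not n_folds_a.equals(n_folds_b):
        raise EvaluationError("reports do not share the same fold structure")
    diff = (a - b).to_numpy(dtype=float)
    n = diff.size
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0 or n < 2:
        p = 1.0 if mean == 0.0 else 0.0
        ci = (mean, mean)
    else:
        if test == "ttest":
            p = float(stats.ttest_rel(a.to_numpy(), b.to_numpy()).pvalue)
        elif test == "wilcoxon":
            p = float(stats.wilcoxon(a.to_numpy(), b.to_numpy()).pvalue)
        else:
            raise EvaluationError(f"unknown test {test!r}; expected 'ttest' or 'wilcoxon'")
        half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
        ci = (mean - half, mean + half)
    return {
        "metric": metric,
        "model_a": model_a,
        "model_b": model_b,
        "mean_difference": mean,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p_value": p,
        "n_repeats": n,
        "test": test,
    }


def _single_model(report: EvaluationReport) -> str:
    models = report.models
    if len(models) != 1:
        raise EvaluationError(
            f"report contains {len(models)} models ({models}); specify which to compare"
        )
    return models[0]
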