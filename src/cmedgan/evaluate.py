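"""Performance measurement: AUCs, F1, calibration, bootstrap CIs, CV, ablation.

ROC-AUC is the Mann-Whitney probability that a random positive outscores a
random negative (ties at 1/2); PR-AUC is average precision with tied scores
grouped at one threshold.  Both delegate to scikit-learn, whose conventions
match those definitions exactly; the test suite cross-checks them against
brute-force pairwise / threshold-sweep oracles.

Confidence intervals are percentile bootstrap over test rows; calibration is
the Hosmer-Lemeshow-style binned reliability curve (10 equal-frequency bins by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .preprocess import FeatureTable, SplitSpec, subsample

__all__ = [
    "MetricReport",
    "CalibrationCurve",
    "roc_auc",
    "pr_auc",
    "f1_precision_recall",
    "calibration_curve",
    "bootstrap_ci",
    "metric_report",
    "grid_search_cv",
    "run_ablation",
    "AblationResult",
]


def _validate(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=int).reshape(-1)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must align")
    return scores, y


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    scores, y = _validate(scores, y)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC-AUC undefined for single-class labels")
    return float(roc_auc_score(y, scores))


def pr_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Average precision (area under the precision-recall curve)."""
    scores, y = _validate(scores, y)
    if y.sum() == 0:
        raise ValueError("PR-AUC undefined without positives")
    return float(average_precision_score(y, scores))


def f1_precision_recall(
    scores: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float]:
    """(F1, precision, recall) at a decision threshold; degenerate cases -> 0."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    scores, y = _validate(scores, y)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if tp else 0.0
    return f1, precision, recall


@dataclass
class CalibrationCurve:
    mean_predicted: np.ndarray
    observed_fraction: np.ndarray
    counts: np.ndarray
    n_bins: int


def calibration_curve(
    scores: np.ndarray, y: np.ndarray, n_bins: int = 10, *, strategy: str = "quantile"
) -> CalibrationCurve:
    """Binned reliability curve: mean predicted risk vs observed event rate.

    Equal-frequency (score-rank) bins by default, the Hosmer-Lemeshow
    convention; ``strategy="uniform"`` uses equal-width bins and drops empty
    ones with a warning.  Bin counts always sum to the number of rows.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scores, y = _validate(scores, y)
    if strategy == "quantile":
        edges = np.unique(np.quantile(scores, np.linspace(0, 1, n_bins + 1)))
    elif strategy == "uniform":
        edges = np.linspace(scores.min(), scores.max(), n_bins + 1)
    else:
        raise ValueError("strategy must be 'quantile' or 'uniform'")
    if len(edges) < 2:  # all scores identical
        return CalibrationCurve(
            np.array([scores.mean()]), np.array([y.mean()]),
            np.array([len(y)]), n_bins,
        )
    idx = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, len(edges) - 2)
    mp, of, ct = [], [], []
    for b in range(len(edges) - 1):
        m = idx == b
        if not m.any():
            warnings.warn(f"dropping empty calibration bin {b}")
            continue
        mp.append(scores[m].mean())
        of.append(y[m].mean())
        ct.append(int(m.sum()))
    return CalibrationCurve(np.array(mp), np.array(of), np.array(ct, dtype=int), n_bins)


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    *,
    max_redraws: int = 1000,
) -> tuple[float, float, float]:
    """Percentile 95% CI of a metric over row resamples with replacement.

    Resamples that leave the metric undefined (e.g. a single class for
    ROC-AUC) are redrawn, up to a bounded number of extra attempts.
    Returns (point estimate, lower, upper).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores, y = _validate(scores, y)
    point = metric(scores, y)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    redraws = 0
    n = len(y)
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, n)
        try:
            vals[i] = metric(scores[idx], y[idx])
        except ValueError:
            redraws += 1
            if redraws > max_redraws:
                raise ValueError("metric repeatedly undefined under resampling")
            continue
        i += 1
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(point), float(lo), float(hi)


@dataclass
class MetricReport:
    """Point estimates with percentile-bootstrap 95% CIs."""

    pr_auc: tuple[float, float, float]
    roc_auc: tuple[float, float, float]
    f1: tuple[float, float, float]
    precision: tuple[float, float, float]
    recall: tuple[float, float, float]
    n_bootstrap: int
    threshold: float
    seed: int
    calibration: CalibrationCurve | None = None

    def as_dict(self) -> dict:
        d = {}
        for name in ("pr_auc", "roc_auc", "f1", "precision", "recall"):
            point, lo, hi = getattr(self, name)
            d[name] = {"value": point, "ci95": [lo, hi]}
        d["n_bootstrap"] = self.n_bootstrap
        d["threshold"] = self.threshold
        return d


def metric_report(
    scores: np.ndarray,
    y: np.ndarray,
    *,
    threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
    with_calibration: bool = True,
    n_bins: int = 10,
) -> MetricReport:
    """The full Table-1-style row for one model's test scores."""
    mk = lambda f: bootstrap_ci(f, scores, y, n_boot, seed)  # noqa: E731
    rep = MetricReport(
        pr_auc=mk(pr_auc),
        roc_auc=mk(roc_auc),
        f1=mk(lambda s, t: f1_precision_recall(s, t, threshold)[0]),
        precision=mk(lambda s, t: f1_precision_recall(s, t, threshold)[1]),
        recall=mk(lambda s, t: f1_precision_recall(s, t, threshold)[2]),
        n_bootstrap=n_boot,
        threshold=threshold,
        seed=seed,
    )
    if with_calibration:
        rep.calibration = calibration_curve(scores, y, n_bins)
    return rep


def grid_search_cv(
    train_fn: Callable[[FeatureTable, np.ndarray, dict, int], object],
    predict_fn: Callable[[object, FeatureTable], np.ndarray],
    ft: FeatureTable,
    y: np.ndarray,
    grid: list[dict],
    k: int = 5,
    seed: int = 0,
    *,
    selection_metric: Callable[[np.ndarray, np.ndarray], float] = pr_auc,
) -> tuple[dict, object, list[dict]]:
    """Stratified k-fold grid search; selects by mean validation PR-AUC.

    PR-AUC is the selection metric because the outcome is heavily
    class-imbalanced (configurable via ``selection_metric``).  Returns
    (best config, model refit on all data, per-config fold records).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not grid:
        raise ValueError("empty grid")
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    records = []
    for config in grid:
        fold_vals = []
        for fold, (tr, va) in enumerate(skf.split(ft.X, y)):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                raise ValueError(f"fold {fold} has a single class; too few positives")
            params = train_fn(ft.take(tr), y[tr], config, seed + fold)
            fold_vals.append(selection_metric(predict_fn(params, ft.take(va)), y[va]))
        records.append({"config": config, "fold_scores": fold_vals,
                        "mean_score": float(np.mean(fold_vals))})
    best = max(records, key=lambda r: r["mean_score"])
    model = train_fn(ft, y, best["config"], seed)
    return best["config"], model, records


@dataclass
class AblationResult:
    """Mean metrics per (dataset fraction, model) plus percent change vs full."""

    fractions: list[float]
    models: list[str]
    metrics: dict = field(default_factory=dict)  # (fraction, model) -> {metric: mean}
    pct_change: dict = field(default_factory=dict)  # (fraction, model) -> {metric: %}

    def to_markdown(self) -> str:
        cols = ["pr_auc", "roc_auc", "f1"]
        lines = ["| model | fraction | " + " | ".join(cols) + " | pct change (pr_auc) |",
                 "|---|---|" + "---|" * (len(cols) + 1)]
        for m in self.models:
            for f in self.fractions:
                row = self.metrics[(f, m)]
                pc = self.pct_change[(f, m)]["pr_auc"]
                lines.append(
                    f"| {m} | {f:g} | "
                    + " | ".join(f"{row[c]:.3f}" for c in cols)
                    + f" | {pc:+.1f}% |"
                )
        return "\n".join(lines)


def run_ablation(
    train_ft: FeatureTable,
    train_y: np.ndarray,
    test_ft: FeatureTable,
    test_y: np.ndarray,
    models: dict[str, Callable[[FeatureTable, np.ndarray, int], np.ndarray]],
    fractions: list[float] = (1.0, 0.5, 0.1),
    n_repeats: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> AblationResult:
    """Dataset-size ablation: shrink the training set, keep the test set fixed.

    Each model entry maps (train features, train labels, seed) to test-set
    scores.  For every fraction, ``n_repeats`` stratified subsamples of the
    training data are drawn (the full fraction runs once per repeat seed as
    well, so seed variability is averaged identically), metrics are averaged,
    and percent change is reported against the full-data mean.
    """
    train_y = np.asarray(train_y, dtype=int)
    test_y = np.asarray(test_y, dtype=int)
    res = AblationResult(list(fractions), list(models))
    for frac in fractions:
        spec = SplitSpec(fraction=frac, n_repeats=n_repeats, seed=seed, stratified=True)
        subsets = subsample(train_ft, train_y, spec)
        for name, run in models.items():
            vals = {"pr_auc": [], "roc_auc": [], "f1": []}
            for r, (sft, sy) in enumerate(subsets):
                scores = run(sft, sy, seed + 1000 * r)
                vals["pr_auc"].append(pr_auc(scores, test_y))
                vals["roc_auc"].append(roc_auc(scores, test_y))
                vals["f1"].append(f1_precision_recall(scores, test_y, threshold)[0])
            res.metrics[(frac, name)] = {k: float(np.mean(v)) for k, v in vals.items()}
    full = fractions[0]
    if full != 1.0:
        raise ValueError("fractions must start with the full dataset (1.0)")
    for frac in fractions:
        for name in models:
            base = res.metrics[(full, name)]
            cur = res.metrics[(frac, name)]
            res.pct_change[(frac, name)] = {
                k: 100.0 * (cur[k] - base[k]) / base[k] if base[k] else 0.0 for k in cur
            }
    return res
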