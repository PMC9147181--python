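"""Metrics, the repeated 2:1:1 split protocol, ablation and importance analysis.

"Five-fold cross-validation" here means five independent random
train/validation/test partitions in a 2:1:1 ratio: the validation third
drives GA selection, the held-out test quarter is scored by the best
individual's ensemble retrained on the training half, and the five test
scores are averaged. Normalization is fit on each fold's training rows
only, so no statistic of validation or test rows ever reaches training.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .ensemble import RotationBoostClassifier
from .featurize import FusedFeatureMatrix, MinMaxNormalizer
from .ga import GAConfig, EvolutionResult, _stream, evolve

logger = logging.getLogger(__name__)

N_FOLDS = 5


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float  # NaN when labels are single-class or scores absent

    def as_dict(self) -> dict:
        return dict(tp=self.tp, fp=self.fp, fn=self.fn, tn=self.tn,
                    accuracy=self.accuracy, precision=self.precision,
                    recall=self.recall, f1=self.f1, auc=self.auc)


def compute_metrics(labels, predictions, scores=None) -> MetricsReport:
    """Confusion counts, accuracy, precision/recall/F1 (positive class) and AUC.

    Zero-division conventions: precision/recall/F1 are 0 when their
    denominator is 0. AUC is the Mann-Whitney rank statistic (ties get
    half credit) and is NaN when only one class is present or no scores
    are given.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))
    n = len(y)
    accuracy = (tp + tn) / n if n else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    if scores is None or len(np.unique(y)) < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    return MetricsReport(tp, fp, fn, tn, accuracy, precision, recall, f1, auc)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    fold: int
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def make_splits(n: int, seed: int) -> list[SplitSpec]:
    """Five independent random 2:1:1 partitions of ``range(n)``.

    Sizes are floor(n/2) / floor(n/4) / remainder; each partition is
    disjoint and exhaustive, with its own stream spawned from ``seed``.
    """
    if n < 8:
        raise ValueError("need at least 8 samples for a 2:1:1 split")
    n_train, n_val = n // 2, n // 4
    splits = []
    for fold in range(N_FOLDS):
        perm = _stream(seed, 10, fold).permutation(n)
        splits.append(SplitSpec(
            fold,
            np.sort(perm[:n_train]),
            np.sort(perm[n_train:n_train + n_val]),
            np.sort(perm[n_train + n_val:]),
        ))
    return splits


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    spec: SplitSpec
    metrics: MetricsReport
    evolution: EvolutionResult


@dataclass
class CVResult:
    folds: list[FoldResult]
    table: pd.DataFrame = field(init=False)
    mean: dict = field(init=False)

    def __post_init__(self) -> None:
        rows = [{"fold": f.spec.fold, **f.metrics.as_dict()} for f in self.folds]
        self.table = pd.DataFrame(rows)
        self.mean = {k: float(self.table[k].mean())
                     for k in ("accuracy", "f1", "auc")}


def run_cv(matrix: FusedFeatureMatrix, labels, config: GAConfig,
           track_test: bool = False) -> CVResult:
    """Evolve and score each of the five 2:1:1 folds; report per-fold and mean.

    Per fold: min-max normalization is fit on the training rows, the GA
    evolves on (train, validation), the final best individual's ensemble
    is retrained on the training rows and scored on the test rows.
    """
    y = np.asarray(labels).astype(int)
    if matrix.is_normalized:
        raise ValueError("pass a raw matrix; normalization is fit per fold")
    config.n_features = matrix.n_features
    config.column_kinds = list(matrix.column_kinds)
    folds = []
    for spec in make_splits(matrix.n_samples, config.seed):
        norm = MinMaxNormalizer().fit(matrix.values[spec.train])
        X = norm.transform(matrix.values)
        fold_cfg = GAConfig(**{k: getattr(config, k) for k in (
            "generations", "population_size", "mutation_prob", "n_subsets",
            "subset_size", "n_features", "base_estimator", "max_retries")},
            seed=int(_stream(config.seed, 11, spec.fold).integers(2**31)))
        fold_cfg.column_kinds = config.column_kinds
        result = evolve(
            fold_cfg, X[spec.train], y[spec.train], X[spec.validation],
            y[spec.validation],
            X_test=X[spec.test] if track_test else None,
            y_test=y[spec.test] if track_test else None)
        model = RotationBoostClassifier(
            subsets=result.best_individual, column_kinds=config.column_kinds,
            base_estimator=config.base_estimator, max_retries=config.max_retries,
            random_state=_stream(fold_cfg.seed, 4),
        ).fit(X[spec.train], y[spec.train])
        report = compute_metrics(y[spec.test], model.predict(X[spec.test]),
                                 model.decision_function(X[spec.test]))
        folds.append(FoldResult(spec, report, result))
        logger.info("fold %d: acc=%.3f f1=%.3f auc=%.3f", spec.fold,
                    report.accuracy, report.f1, report.auc)
    return CVResult(folds)


def ablation(matrix: FusedFeatureMatrix, labels, combinations, config: GAConfig,
             track_test: bool = False) -> pd.DataFrame:
    """Re-run the CV harness restricted to each requested block combination.

    ``combinations`` is a list whose entries are either the string "all"
    or a sequence of block names; unknown names raise ``KeyError``.
    """
    rows = []
    for combo in combinations:
        if isinstance(combo, str) and combo.lower() == "all":
            sub, name = matrix, "all"
        else:
            sub = matrix.select_blocks(list(combo))
            name = "+".join(combo)
        res = run_cv(sub, labels, config, track_test=track_test)
        rows.append({"blocks": name, "n_features": sub.n_features, **res.mean})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature importance from the final population
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    counts: np.ndarray            # per-feature-index occurrence count
    ranking: np.ndarray           # feature indices, descending count (ties: asc index)
    top_n: int
    per_block: pd.DataFrame | None  # block, count_in_top, width, ratio

    @property
    def top_features(self) -> np.ndarray:
        return self.ranking[:self.top_n]


def feature_importance(population: Sequence[np.ndarray], top_n: int,
                       blocks=None, n_features: int | None = None) -> ImportanceTable:
    """Count feature-index occurrences over all genes of the final population.

    Ranks features by descending count with ties broken by ascending
    index, and aggregates the top-``top_n`` set per block (count and
    count/width ratio) when block specs are given.
    """
    if not population:
        raise ValueError("population is empty")
    genes = np.concatenate([np.asarray(ind).ravel() for ind in population])
    if n_features is None:
        n_features = (sum(b.width for b in blocks) if blocks
                      else int(genes.max()) + 1)
    counts = np.bincount(genes, minlength=n_features)
    ranking = np.lexsort((np.arange(n_features), -counts))
    top = ranking[:top_n]
    per_block = None
    if blocks is not None:
        rows = []
        for b in blocks:
            in_top = int(np.sum((top >= b.offset) & (top < b.offset + b.width)))
            rows.append({"block": b.name, "count_in_top": in_top,
                         "width": b.width, "ratio": in_top / b.width})
        per_block = pd.DataFrame(rows)
    return ImportanceTable(counts, ranking, top_n, per_block)
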