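"""Evaluation protocol: confusion metrics, stratified cross-validation,
and the per-fold report.

Metrics are accuracy, sensitivity (recall on the interacting class),
precision, and the Matthews correlation coefficient:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    SN  = TP / (TP + FN)
    PE  = TP / (TP + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

A metric whose denominator vanishes is reported as undefined (None)
rather than silently coerced to 0.

``cross_validate`` runs the full protocol on encoded pairs: stratified
k-fold split, then per fold a [-1, 1] rescaling, a PCA projection and a
majority-vote ELM ensemble — each fitted on the training split only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .decomposition import PCAReducer
from .ensemble import DEFAULT_N_MEMBERS, EELMClassifier
from .features import EncoderConfig, encode_pairs
from .preprocessing import IntervalScaler

logger = logging.getLogger(__name__)

_FOLD_SEED_STRIDE = 1_000_003  # per-fold classifier seed counter


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts of a binary prediction."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """ACC/SN/PE/MCC; a field is None when its denominator vanished."""

    accuracy: float | None
    sensitivity: float | None
    precision: float | None
    mcc: float | None

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in ("accuracy", "sensitivity", "precision", "mcc")
            if getattr(self, name) is None
        )


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/FP/TN/FN, with label 1 the interacting (positive) class."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"shape mismatch: y_true {t.shape} vs y_pred {p.shape}")
    for name, arr in (("y_true", t), ("y_pred", p)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary values")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Evaluate ACC, SN, PE and MCC from confusion counts."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = (c.tp + c.tn) / c.total
    sn = c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    pe = c.tp / (c.tp + c.fp) if c.tp + c.fp else None
    denom = (c.tp + c.fn) * (c.tn + c.fp) * (c.tp + c.fp) * (c.tn + c.fn)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else None
    return MetricSet(accuracy=acc, sensitivity=sn, precision=pe, mcc=mcc)


def stratified_kfold(labels, k: int = 5, random_state: int | None = None) -> np.ndarray:
    """Assign each sample to one of k stratified folds.

    Folds have near-equal size and per-fold class proportions within
    one sample of the global proportions.  Each class needs >= k
    members.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, cannot stratify into {k} folds"
        )
    seed = None if random_state is None else int(random_state) % (2**31)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = f
    return assignment


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the scaler -> PCA -> ensemble pipeline."""

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    n_components: int | float = 0.95
    n_hidden: int = 200
    n_members: int = DEFAULT_N_MEMBERS
    folds: int = 5
    clip: bool = True


@dataclass(frozen=True)
class FoldResult:
    index: int
    n_test: int
    counts: ConfusionCounts
    metrics: MetricSet


_REPORT_COLUMNS = {
    "sensitivity": "Sens. (%)",
    "precision": "Prec. (%)",
    "accuracy": "Accu. (%)",
    "mcc": "MCC (%)",
}


@dataclass(frozen=True)
class CVReport:
    """Per-fold metrics plus mean +/- SD aggregation."""

    folds: tuple[FoldResult, ...]

    def _percent(self, metrics: MetricSet, name: str) -> float:
        v = getattr(metrics, name)
        return float("nan") if v is None else 100.0 * v

    def summary(self) -> pd.DataFrame:
        """Per-fold rows plus 'mean' and 'sd' rows, in percent."""
        rows = {
            str(f.index + 1): [self._percent(f.metrics, m) for m in _REPORT_COLUMNS]
            for f in self.folds
        }
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=list(_REPORT_COLUMNS.values())
        )
        df.loc["mean"] = df.mean(axis=0)
        df.loc["sd"] = df.iloc[:-1].std(axis=0, ddof=1)
        df.index.name = "fold"
        return df

    def mean(self, name: str) -> float:
        """Mean of a metric over folds, as a fraction (nan if undefined)."""
        vals = [getattr(f.metrics, name) for f in self.folds]
        if any(v is None for v in vals):
            return float("nan")
        return float(np.mean(vals))

    @property
    def mean_accuracy(self) -> float:
        return self.mean("accuracy")

    def format_table(self) -> str:
        return self.summary().round(2).to_string()

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", float_format="%.4f")


def cross_validate_features(
    X,
    y,
    config: PipelineConfig | None = None,
    random_state: int = 0,
    fold_hook: Callable[..., None] | None = None,
) -> CVReport:
    """Stratified k-fold CV of the scaler -> PCA -> EELM pipeline on an
    encoded feature matrix.

    Every pipeline stage is fitted on the training split only and
    applied to the held-out split.  ``fold_hook``, if given, is called
    per fold with the indices and fitted components (for leakage
    instrumentation in tests).
    """
    cfg = config or PipelineConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    assignment = stratified_kfold(y, k=cfg.folds, random_state=random_state)
    results = []
    for f in range(cfg.folds):
        test_mask = assignment == f
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)

        scaler = IntervalScaler(clip=cfg.clip).fit(X[train_idx])
        Xtr = scaler.transform(X[train_idx])
        Xte = scaler.transform(X[test_idx])

        pca = PCAReducer(n_components=cfg.n_components).fit(Xtr)
        Ztr = pca.transform(Xtr)
        Zte = pca.transform(Xte)
        logger.info(
            "fold %d: %d train / %d test, %d -> %d features after PCA",
            f + 1, len(train_idx), len(test_idx), X.shape[1], Ztr.shape[1],
        )

        fold_seed = (int(random_state) + (f + 1) * _FOLD_SEED_STRIDE) % (2**31)
        clf = EELMClassifier(
            n_hidden=cfg.n_hidden,
            n_members=cfg.n_members,
            random_state=fold_seed,
        ).fit(Ztr, y[train_idx])
        pred = clf.predict(Zte)

        counts = confusion_counts(y[test_idx], pred)
        results.append(
            FoldResult(
                index=f,
                n_test=len(test_idx),
                counts=counts,
                metrics=compute_metrics(counts),
            )
        )
        if fold_hook is not None:
            fold_hook(
                fold=f,
                train_idx=train_idx,
                test_idx=test_idx,
                scaler=scaler,
                pca=pca,
                classifier=clf,
            )
    return CVReport(folds=tuple(results))


def cross_validate(
    proteome: Mapping,
    pairs: pd.DataFrame,
    config: PipelineConfig | None = None,
    random_state: int = 0,
    fold_hook: Callable[..., None] | None = None,
) -> CVReport:
    """Encode a pair table and run the cross-validation protocol."""
    cfg = config or PipelineConfig()
    X, y = encode_pairs(proteome, pairs, cfg.encoder)
    return cross_validate_features(
        X, y, config=cfg, random_state=random_state, fold_hook=fold_hook
    )
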