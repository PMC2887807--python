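"""Confusion-matrix metrics, cross-validation, ROC points and Q3 scoring.

Metric definitions (all from the confusion counts TP, FP, TN, FN):

    Sn  = TP / (TP + FN)                      sensitivity, reported in %
    Sp  = TN / (TN + FP)                      specificity, reported in %
    Ac  = (TP + TN) / (TP + FP + TN + FN)     accuracy, reported in %
    FPR = FP / (FP + TN) = 1 - Sp             fraction in [0, 1]
    Mcc = (TP*TN - FP*FN) /
          sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))  in [-1, 1]; 0 when any
                                              denominator factor is 0

Q3 is benchmark sensitivity: the fraction of annotated positive sites
predicted +1, reported as a percentage to one decimal, round-half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from phosite.dataset import (
    RATIO_FACTORS,
    WINDOW_SIZES,
    BalancePlan,
    Instance,
    balance,
    split_folds,
)
from phosite.errors import ConfigError, DataError
from phosite.model import ModelConfig, train, predict


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.total == 0:
            raise DataError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricsReport:
    """Derived metrics for one evaluation cell.

    ``ac``, ``sn``, ``sp`` are percentages; ``fpr`` is a fraction in
    [0, 1]; ``mcc`` is dimensionless in [-1, 1].  A rate with a zero
    denominator is reported as 0.0 and flagged in ``undefined``.
    """

    ac: float
    sn: float
    sp: float
    mcc: float
    fpr: float
    counts: ConfusionCounts | None = None
    residue: str | None = None
    w: int | None = None
    ratio_factor: float | None = None
    q3_percent: float | None = None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        out = {
            "Ac": round(self.ac, 2),
            "Sn": round(self.sn, 2),
            "Sp": round(self.sp, 2),
            "Mcc": round(self.mcc, 4),
            "FPR": round(self.fpr, 4),
        }
        for name, value in (
            ("residue", self.residue),
            ("W", self.w),
            ("ratio", self.ratio_factor),
            ("Q3", self.q3_percent),
        ):
            if value is not None:
                out[name] = value
        return out


def score(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """Count TP/FP/TN/FN from two equal-length {+1, -1} label sequences."""
    if len(truth) != len(predicted):
        raise DataError(
            f"label sequences differ in length: {len(truth)} vs {len(predicted)}"
        )
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        if t not in (+1, -1) or p not in (+1, -1):
            raise DataError(f"labels must be +1 or -1, got ({t}, {p})")
        if t == +1:
            if p == +1:
                tp += 1
            else:
                fn += 1
        else:
            if p == +1:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def metrics(
    counts: ConfusionCounts,
    residue: str | None = None,
    w: int | None = None,
    ratio_factor: float | None = None,
) -> MetricsReport:
    """Derive Ac/Sn/Sp/Mcc/FPR from confusion counts."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    undefined: list[str] = []

    def rate(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sn = rate(tp, tp + fn, "Sn")
    sp = rate(tn, tn + fp, "Sp")
    fpr = rate(fp, fp + tn, "FPR")
    ac = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        ac=100.0 * ac,
        sn=100.0 * sn,
        sp=100.0 * sp,
        mcc=mcc,
        fpr=fpr,
        counts=counts,
        residue=residue,
        w=w,
        ratio_factor=ratio_factor,
        undefined=tuple(undefined),
    )


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 at one decimal rounds to 0.1)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def q3(
    positive_sites: Sequence[tuple[str, int]],
    predictions: Mapping[tuple[str, int], int],
) -> tuple[int, float]:
    """Correct-positive count and percentage over annotated benchmark sites.

    ``positive_sites`` are (protein_id, position) pairs of annotated
    positives; ``predictions`` maps each such site to its predicted label.
    Every annotated site must have a prediction.
    """
    if not positive_sites:
        raise DataError("Q3 requires at least one annotated positive site")
    missing = [site for site in positive_sites if site not in predictions]
    if missing:
        raise DataError(f"missing predictions for {len(missing)} annotated site(s): "
                        f"{missing[:5]}")
    correct = sum(1 for site in positive_sites if predictions[site] == +1)
    return correct, round_half_up(100.0 * correct / len(positive_sites), 1)


def _average_reports(reports: Sequence[MetricsReport], **cell) -> MetricsReport:
    return MetricsReport(
        ac=float(np.mean([r.ac for r in reports])),
        sn=float(np.mean([r.sn for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        fpr=float(np.mean([r.fpr for r in reports])),
        **cell,
    )


def cross_validate(
    instances: Sequence[Instance],
    config: ModelConfig,
    folds: int = 3,
    seed: int = 0,
    pooled: bool = False,
    ratio_factor: float | None = None,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Stratified k-fold cross-validation of one (residue, W) classifier.

    Returns the cross-fold summary and the per-fold reports.  By default
    the five metrics are averaged arithmetically across folds; with
    ``pooled=True`` the confusion counts are summed first instead.
    """
    fold_reports: list[MetricsReport] = []
    pooled_counts: ConfusionCounts | None = None
    for train_set, test_set in split_folds(instances, folds=folds, seed=seed):
        bundle = train(train_set, config, seed=seed)
        predicted = predict(bundle, test_set)
        counts = score([inst.target for inst in test_set], predicted.tolist())
        fold_reports.append(
            metrics(counts, residue=config.residue, w=config.w, ratio_factor=ratio_factor)
        )
        pooled_counts = counts if pooled_counts is None else pooled_counts + counts
    cell = dict(residue=config.residue, w=config.w, ratio_factor=ratio_factor)
    if pooled:
        summary = metrics(pooled_counts, **cell)
    else:
        summary = _average_reports(fold_reports, **cell)
    return summary, fold_reports


def experiment_grid(
    instance_sets: Mapping[str, tuple[Sequence[Instance], Sequence[Instance]]],
    build_for_window=None,
    ratios: Sequence[float] = RATIO_FACTORS,
    windows: Sequence[int] = WINDOW_SIZES,
    folds: int = 3,
    seed: int = 0,
    pooled: bool = False,
) -> list[MetricsReport]:
    """Run the full ratio x window x residue cross-validation grid.

    ``instance_sets`` maps residue -> (positives, negatives) at some
    window size; when ``build_for_window`` is given it is called as
    ``build_for_window(residue, w) -> (positives, negatives)`` so each
    window gets its own feature vectors.  Returns one summary report per
    grid cell, iterating ratios, then windows, then residues.
    """
    if not instance_sets:
        raise ConfigError("experiment grid needs at least one residue instance set")
    reports: list[MetricsReport] = []
    for ratio in ratios:
        for w in windows:
            for residue in sorted(instance_sets):
                if build_for_window is not None:
                    positives, negatives = build_for_window(residue, w)
                else:
                    positives, negatives = instance_sets[residue]
                plan = BalancePlan(p=len(positives), n=len(negatives), factor=ratio)
                kept = balance(list(negatives), plan)
                merged = list(positives) + kept
                config = ModelConfig(residue=residue, w=w)
                summary, _ = cross_validate(
                    merged, config, folds=folds, seed=seed, pooled=pooled,
                    ratio_factor=ratio,
                )
                reports.append(summary)
    return reports


def roc_points(reports: Sequence[MetricsReport]) -> list[dict]:
    """(FPR, TPR) pair per report — the ROC position of a hard classifier."""
    return [
        {
            "residue": r.residue,
            "W": r.w,
            "ratio": r.ratio_factor,
            "fpr": r.fpr,
            "tpr": r.sn / 100.0,
        }
        for r in reports
    ]


def write_reports_tsv(reports: Sequence[MetricsReport], path) -> None:
    """Render grid reports as a TSV table (percentages to 2 decimals)."""
    with open(path, "w") as handle:
        handle.write("residue\tW\tratio\tAc\tSn\tSp\tMcc\tFPR\n")
        for r in reports:
            handle.write(
                f"{r.residue}\t{r.w}\t{r.ratio_factor}\t"
                f"{round_half_up(r.ac, 2):.2f}\t{round_half_up(r.sn, 2):.2f}\t"
                f"{round_half_up(r.sp, 2):.2f}\t{round_half_up(r.mcc, 2):.2f}\t"
                f"{round_half_up(r.fpr, 2):.2f}\n"
            )
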