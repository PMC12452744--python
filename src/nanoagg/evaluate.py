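"""Threshold-based evaluation of aggregation scores against SEC labels.

The experimental label is the percentage of monomeric species in size
exclusion chromatography.  The positive class is the *non-aggregation-prone*
domain (monomer percentage at or above a cut of 90 or 95); a domain is
predicted positive when its aggregation score strictly exceeds a score
threshold.  On top of the confusion matrix the usual operating-point
metrics are derived (accuracy, balanced accuracy, sensitivity, specificity,
Youden J, Fβ), and a full threshold sweep yields ROC and precision-recall
curves together with the argmax thresholds for Youden J and each Fβ.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class LabeledScore:
    id: str
    aggregation_score: float
    monomer_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.monomer_pct <= 100.0:
            raise ValueError(f"{self.id}: monomer_pct {self.monomer_pct} outside [0, 100]")
        if self.aggregation_score < 0:
            raise ValueError(f"{self.id}: negative aggregation score")


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int
    positive_definition: float   # monomer-% cut defining the positive class
    threshold: float             # score cut

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclasses.dataclass(frozen=True)
class MetricSet:
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    youden_j: float
    f_beta: float
    beta: float


def confusion(
    data: Sequence[LabeledScore],
    score_threshold: float,
    monomer_cut: float,
) -> ConfusionMatrix:
    """Tally the confusion matrix at a score threshold and monomer cut.

    Positive = monomer_pct >= cut; predicted positive = score strictly above
    the threshold (a score exactly at the threshold is predicted negative).
    """
    if not data:
        raise ValueError("empty dataset")
    tp = fp = tn = fn = 0
    for rec in data:
        actual = rec.monomer_pct >= monomer_cut
        predicted = rec.aggregation_score > score_threshold
        if actual and predicted:
            tp += 1
        elif actual:
            fn += 1
        elif predicted:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(TP=tp, FP=fp, TN=tn, FN=fn,
                           positive_definition=monomer_cut, threshold=score_threshold)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(cm: ConfusionMatrix, beta: float = 1.0) -> MetricSet:
    """Operating-point metrics; degenerate denominators yield NaN, never 0."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.TP, cm.TP + cm.FN)
    spec = _ratio(cm.TN, cm.TN + cm.FP)
    b2 = beta * beta
    return MetricSet(
        accuracy=_ratio(cm.TP + cm.TN, cm.total),
        balanced_accuracy=(sens + spec) / 2.0,
        sensitivity=sens,
        specificity=spec,
        youden_j=sens + spec - 1.0,
        f_beta=_ratio((1 + b2) * cm.TP, (1 + b2) * cm.TP + cm.FP + b2 * cm.FN),
        beta=beta,
    )


@dataclasses.dataclass(frozen=True)
class SweepResult:
    table: pd.DataFrame                 # one row per candidate threshold
    best: dict[str, float]              # criterion name -> argmax threshold
    roc_auc: float                      # NaN when only one class is present
    roc: pd.DataFrame                   # fpr, tpr per threshold
    pr: pd.DataFrame                    # recall, precision per threshold


def threshold_sweep(
    data: Sequence[LabeledScore],
    monomer_cut: float,
    beta_values: Sequence[float] = (0.5, 1.0, 2.0),
) -> SweepResult:
    """Evaluate every achievable operating point of the score.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores plus -inf/+inf sentinels, so every distinct confusion
    matrix appears exactly once.  Argmax thresholds for Youden J and each
    Fβ break ties toward the lowest threshold.  With a single class in the
    data the ROC is undefined and ``roc_auc`` is NaN.
    """
    scores = sorted({rec.aggregation_score for rec in data})
    if len(scores) < 2:
        raise ValueError("need at least 2 distinct scores to sweep")
    thresholds = [-math.inf]
    thresholds += [(a + b) / 2.0 for a, b in zip(scores, scores[1:])]
    thresholds.append(math.inf)

    rows = []
    for thr in thresholds:
        cm = confusion(data, thr, monomer_cut)
        base = metrics(cm, beta=1.0)
        row = {
            "threshold": thr,
            "TP": cm.TP, "FP": cm.FP, "TN": cm.TN, "FN": cm.FN,
            "accuracy": base.accuracy,
            "balanced_accuracy": base.balanced_accuracy,
            "sensitivity": base.sensitivity,
            "specificity": base.specificity,
            "youden_j": base.youden_j,
            "precision": _ratio(cm.TP, cm.TP + cm.FP),
            "recall": base.sensitivity,
            "fpr": 1.0 - base.specificity if not math.isnan(base.specificity) else math.nan,
        }
        for beta in beta_values:
            row[f"f_{beta:g}"] = metrics(cm, beta=beta).f_beta
        rows.append(row)
    table = pd.DataFrame(rows)

    best: dict[str, float] = {}
    for criterion in ["youden_j"] + [f"f_{b:g}" for b in beta_values]:
        col = table[criterion]
        if col.isna().all():
            best[criterion] = math.nan
            continue
        best_value = col.max()
        best[criterion] = float(table.loc[col == best_value, "threshold"].min())

    roc = table[["threshold", "fpr", "sensitivity"]].rename(columns={"sensitivity": "tpr"})
    pr = table[["threshold", "recall", "precision"]]
    if roc[["fpr", "tpr"]].isna().any().any():
        auc = math.nan
    else:
        pts = roc.sort_values(["fpr", "tpr"])
        auc = float(np.trapezoid(pts["tpr"].to_numpy(), pts["fpr"].to_numpy()))
    return SweepResult(table=table, best=best, roc_auc=auc, roc=roc, pr=pr)


def stratified_summary(
    data: Sequence[LabeledScore],
    score_threshold: float = 1.0,
    bands: Sequence[float] = (90.0, 95.0),
) -> pd.DataFrame:
    """Per-monomer-band summary: counts, mean score, selected at threshold.

    Bands follow the SEC convention: below the first cut (aggregation-
    prone), between cuts, and at or above the last cut.
    """
    lo, hi = bands
    groups = {
        f"<{lo:g}%": [r for r in data if r.monomer_pct < lo],
        f"{lo:g}-{hi:g}%": [r for r in data if lo <= r.monomer_pct < hi],
        f">={hi:g}%": [r for r in data if r.monomer_pct >= hi],
    }
    rows = []
    for name, members in groups.items():
        selected = sum(1 for r in members if r.aggregation_score > score_threshold)
        rows.append({
            "band": name,
            "n": len(members),
            "mean_score": float(np.mean([r.aggregation_score for r in members]))
            if members else math.nan,
            "selected": selected,
        })
    return pd.DataFrame(rows)


def read_scores(path: str | Path) -> list[LabeledScore]:
    """Read a labeled score TSV with columns ``id``, ``AS``, ``monomer_pct``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    score_col = "AS" if "AS" in df.columns else "aggregation_score"
    missing = {"id", score_col, "monomer_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    return [
        LabeledScore(str(r["id"]), float(r[score_col]), float(r["monomer_pct"]))
        for _, r in df.iterrows()
    ]


def write_scores(data: Iterable[LabeledScore], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": r.id, "AS": r.aggregation_score, "monomer_pct": r.monomer_pct} for r in data]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
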