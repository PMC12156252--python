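"""Diagnostic performance metrics and reporting.

Standard binary-classification metrics at the patient level — accuracy,
precision, recall, F1 — plus the expert-agreement fraction (identical to
accuracy) and its 95% Wald confidence interval.  All quantities are
expressed in percent.

Edge conventions: precision is undefined (NaN) when no positive call was
made (TP + FP = 0); recall is undefined when there are no true positives
to find (TP + FN = 0); F1 is undefined whenever precision or recall is
undefined or zero (0/0 in the harmonic mean).  Undefined values are
rendered as "-" in reports.

The Wald interval is computed from the agreement proportion rounded to one
decimal percentage point, with z = 1.96, clipped to [0, 100] and rounded to
one decimal — the convention under which tabulated intervals in the
clinical literature on this method reproduce exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from popsono.modeling import FittedModel, predict_patients

Z_95 = 1.96


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    target: str
    agreement_k: int
    agreement_n: int
    agreement_pct: float
    ci_low: float
    ci_high: float
    precision_pct: float  # NaN when undefined
    accuracy_pct: float
    recall_pct: float  # NaN when undefined
    f1_pct: float  # NaN when undefined


def confusion(predictions, truths) -> ConfusionCounts:
    """Exact confusion counts from aligned binary vectors."""
    p = np.asarray(predictions).astype(int)
    t = np.asarray(truths).astype(int)
    if p.shape != t.shape:
        raise ValueError("predictions and truths must have equal length")
    if not (np.isin(p, (0, 1)).all() and np.isin(t, (0, 1)).all()):
        raise ValueError("predictions and truths must be binary")
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


def metrics(counts: ConfusionCounts, target: str = "") -> MetricReport:
    """Accuracy, precision, recall and F1 (percent) from confusion counts."""
    n = counts.n
    if n == 0:
        raise ValueError("cannot compute metrics on an empty cohort")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    accuracy = 100.0 * (tp + tn) / n
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if math.isnan(precision) or math.isnan(recall) or precision == 0 or recall == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 / (1.0 / precision + 1.0 / recall)
    k = tp + tn
    ci_low, ci_high = wald_ci(k, n)
    return MetricReport(
        target=target,
        agreement_k=k,
        agreement_n=n,
        agreement_pct=round(100.0 * k / n, 1),
        ci_low=ci_low,
        ci_high=ci_high,
        precision_pct=precision,
        accuracy_pct=accuracy,
        recall_pct=recall,
        f1_pct=f1,
    )


def wald_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """95% Wald interval for a binomial proportion, in percent.

    The point estimate is first rounded to one decimal percentage point
    (the precision at which agreement proportions are reported); the
    normal-approximation half-width is added on that scale, clipped to
    [0, 100] and rounded to one decimal.
    """
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("need 0 <= successes <= n with n > 0")
    if abs(level - 0.95) > 1e-12:
        raise ValueError("only the 95% level is supported (z = 1.96)")
    p_pct = round(100.0 * successes / n, 1)
    p = p_pct / 100.0
    half = Z_95 * math.sqrt(p * (1.0 - p) / n) * 100.0
    low = min(max(p_pct - half, 0.0), 100.0)
    high = min(max(p_pct + half, 0.0), 100.0)
    return round(low, 1), round(high, 1)


def format_value(x: float, decimals: int = 2) -> str:
    """Render a metric percentage, using '-' for undefined values."""
    return "-" if (isinstance(x, float) and math.isnan(x)) else f"{x:.{decimals}f}"


def report_frame(reports: list[MetricReport]) -> pd.DataFrame:
    rows = [
        {
            "target": r.target,
            "agreement_pct": r.agreement_pct,
            "agreement_k": r.agreement_k,
            "agreement_n": r.agreement_n,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "precision_pct": r.precision_pct,
            "accuracy_pct": r.accuracy_pct,
            "recall_pct": r.recall_pct,
            "f1_pct": r.f1_pct,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def evaluate_cohort(
    models: dict[str, FittedModel],
    test_table: pd.DataFrame,
    truth: pd.DataFrame,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Per-target patient-level evaluation of a fitted model set.

    ``truth`` must carry one row per patient with a ``patient_id`` column
    and one binary column per evaluated target.  Returns (and optionally
    writes) one report row per target.
    """
    truth = truth.set_index("patient_id") if "patient_id" in truth.columns else truth
    reports: list[MetricReport] = []
    for target, model in models.items():
        if target not in truth.columns:
            raise ValueError(f"truth table lacks labels for target {target!r}")
        preds = predict_patients(model, test_table)
        missing = set(preds["patient_id"]) - set(truth.index.astype(str))
        if missing:
            raise ValueError(f"truth table lacks patients: {sorted(missing)}")
        aligned = truth.loc[preds["patient_id"], target].to_numpy()
        counts = confusion(preds["prediction"].to_numpy(), aligned)
        reports.append(metrics(counts, target=target))
    frame = report_frame(reports)
    if out_csv is not None:
        frame.to_csv(out_csv, index=False)
    return frame
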