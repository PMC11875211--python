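"""Diagnostic-accuracy machinery: 2x2 tables, metrics, ROC/AUC, likelihood ratios.

Percents are reported rounded half-up to 2 decimals (matching how clinical
performance tables are printed); raw values are always retained.  AUC
significance uses the Hanley-McNeil standard error with a two-sided normal
test against the chance value 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .judgments import DecisionParams, classify

logger = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (1.005 -> 1.01), as printed tables use."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts for one judgment method over a cohort."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name}={v} is not a non-negative integer")
        if self.total < 1:
            raise ValueError("empty matrix: all four counts are zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


def confusion(calls, truths) -> ConfusionMatrix:
    """2x2 cross-classification of binary calls against truth labels."""
    calls = np.asarray(calls, dtype=bool)
    truths = np.asarray(truths, dtype=bool)
    if calls.shape != truths.shape:
        raise ValueError(f"length mismatch: {calls.shape} vs {truths.shape}")
    if calls.size < 1:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum(calls & truths)),
        fp=int(np.sum(calls & ~truths)),
        fn=int(np.sum(~calls & truths)),
        tn=int(np.sum(~calls & ~truths)),
    )


@dataclass
class MetricsReport:
    """The five standard percent metrics plus LR+, raw and rounded.

    A metric with a zero denominator is NaN and listed in ``undefined``.
    ``lr_plus`` is +inf when specificity is exactly 100%.
    """

    sensitivity: float
    specificity: float
    precision: float
    npv: float
    accuracy: float
    lr_plus: float
    undefined: list[str] = field(default_factory=list)

    _PERCENT_FIELDS = ("sensitivity", "specificity", "precision", "npv", "accuracy")

    def rounded(self) -> dict[str, float]:
        """Percent metrics rounded half-up to 2 decimals (NaN passed through)."""
        out = {}
        for name in self._PERCENT_FIELDS:
            v = getattr(self, name)
            out[name] = v if np.isnan(v) else round_half_up(v)
        return out

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self._PERCENT_FIELDS}
        d["lr_plus"] = self.lr_plus
        d["rounded"] = self.rounded()
        d["undefined"] = list(self.undefined)
        return d


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, specificity, precision, NPV, accuracy (percent) and LR+."""
    undefined: list[str] = []

    def pct(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return 100.0 * num / den

    sens = pct(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = pct(cm.tn, cm.tn + cm.fp, "specificity")
    prec = pct(cm.tp, cm.tp + cm.fp, "precision")
    npv = pct(cm.tn, cm.tn + cm.fn, "npv")
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    if np.isnan(sens) or np.isnan(spec):
        lr = float("nan")
    elif spec == 100.0:
        lr = float("inf") if sens > 0 else float("nan")
    else:
        lr = sens / (100.0 - spec)
    return MetricsReport(sens, spec, prec, npv, acc, lr, undefined)


@dataclass
class RocResult:
    """ROC operating points plus AUC and its significance test.

    Points are ordered from (0, 0) to (1, 1); ``thresholds`` holds the score
    cutoff producing each point (calls positive at score >= t), with +inf for
    the all-negative corner.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    se: float
    z: float
    p_two_sided: float
    lr_plus: np.ndarray | None = None
    max_lr_plus: float | None = None


def roc(scores, truths) -> RocResult:
    """ROC curve over every distinct score threshold, AUC by trapezoid.

    Tied scores collapse onto one operating point, so the trapezoidal area
    equals the midrank (concordance) form of the AUC.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    if scores.shape != truths.shape:
        raise ValueError("length mismatch between scores and truths")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(truths.sum())
    n_neg = int((~truths).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")

    order = np.argsort(-scores, kind="mergesort")
    s, t = scores[order], truths[order]
    # indices of the last element of each tied block
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(t)[distinct]
    fps = np.cumsum(~t)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    se, z, p = auc_test(auc, n_pos, n_neg)
    result = RocResult(fpr, tpr, thresholds, auc, n_pos, n_neg, se, z, p)
    likelihood_ratios(result)
    return result


def auc_test(auc: float, n_pos: int, n_neg: int) -> tuple[float, float, float]:
    """Hanley-McNeil SE of the AUC and a two-sided normal test against 0.5."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc={auc} outside [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        z = 0.0 if auc == 0.5 else float(np.sign(auc - 0.5) * np.inf)
    else:
        z = (auc - 0.5) / se
    p = float(2.0 * norm.sf(abs(z)))
    return se, z, float(min(p, 1.0))


def likelihood_ratios(roc_result: RocResult, include_infinite: bool = False) -> np.ndarray:
    """Per-operating-point LR+ = tpr/fpr; fpr = 0 points get +inf.

    ``max_lr_plus`` is taken over finite values by default; set
    ``include_infinite`` to let a zero-false-positive point dominate.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = roc_result.tpr / roc_result.fpr
    lr[(roc_result.fpr == 0) & (roc_result.tpr > 0)] = np.inf
    lr[(roc_result.fpr == 0) & (roc_result.tpr == 0)] = np.nan
    roc_result.lr_plus = lr
    candidates = lr[np.isfinite(lr)] if not include_infinite else lr[~np.isnan(lr)]
    roc_result.max_lr_plus = float(candidates.max()) if candidates.size else float("nan")
    return lr


#: channel name -> (column, graded?, cutoff attribute on DecisionParams)
METHOD_CHANNELS = {
    "human": ("human_ratio", True, "human_cutoff"),
    "ml": ("ml_call", False, None),
    "dl": ("dl_score", True, "dl_cutoff"),
    "fused_sum": ("fused_sum", True, "fused_sum_cutoff"),
    "fused_product": ("fused_product", True, "fused_product_cutoff"),
}


def evaluate_methods(
    prediction_table: pd.DataFrame, params: DecisionParams | None = None
) -> dict:
    """Confusion matrix, metrics, and (where graded) ROC for each method.

    ``prediction_table`` is the per-case table produced by
    :func:`ctgeval.judgments.build_prediction_table`; methods whose channel
    is entirely missing are skipped with a warning.
    """
    params = params or DecisionParams()
    truths_all = prediction_table["truth"].to_numpy(dtype=bool)
    report: dict = {"n_cases": int(len(prediction_table)), "methods": {}}
    for method, (column, graded, cutoff_attr) in METHOD_CHANNELS.items():
        if column not in prediction_table.columns:
            logger.warning("channel %s missing; skipping %s", column, method)
            continue
        values = prediction_table[column]
        present = values.notna().to_numpy()
        if not present.any():
            logger.warning("channel %s empty; skipping %s", column, method)
            continue
        truths = truths_all[present]
        vals = values.to_numpy(dtype=float)[present]
        entry: dict = {"n": int(present.sum())}
        if graded:
            cutoff = getattr(params, cutoff_attr)
            calls = classify(vals, cutoff)
            entry["cutoff"] = cutoff
            if truths.any() and not truths.all():
                r = roc(vals, truths)
                entry["roc"] = {
                    "auc": r.auc,
                    "se": r.se,
                    "z": r.z,
                    "p_two_sided": r.p_two_sided,
                    "max_lr_plus": r.max_lr_plus,
                    "fpr": r.fpr.tolist(),
                    "tpr": r.tpr.tolist(),
                    "thresholds": [float(t) for t in r.thresholds],
                }
        else:
            calls = vals >= 0.5  # binary channel stored as 0/1
        cm = confusion(calls, truths)
        entry["confusion"] = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
        entry["metrics"] = metrics(cm).to_dict()
        report["methods"][method] = entry
    return report


def render_report(report: dict) -> str:
    """Human-readable fixed-width table of the per-method percent metrics."""
    header = (
        f"{'method':<14}{'sens%':>8}{'spec%':>8}{'prec%':>8}{'npv%':>8}"
        f"{'acc%':>8}{'LR+':>8}{'AUC':>8}"
    )
    lines = [header, "-" * len(header)]
    for method, entry in report["methods"].items():
        m = entry["metrics"]["rounded"]
        lr = entry["metrics"]["lr_plus"]
        auc = entry.get("roc", {}).get("auc")
        lines.append(
            f"{method:<14}"
            + "".join(f"{m[k]:>8.2f}" for k in
                      ("sensitivity", "specificity", "precision", "npv", "accuracy"))
            + (f"{lr:>8.3f}" if np.isfinite(lr)
               else f"{'-':>8}" if np.isnan(lr) else f"{'inf':>8}")
            + (f"{auc:>8.4f}" if auc is not None else f"{'-':>8}")
        )
    return "\n".join(lines)
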