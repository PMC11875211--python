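"""Truth labeling, prediction ratios, thresholding and human/AI score fusion.

A case is labelled positive (asphyxia) when Apgar < 6 at 1 or 5 minutes or
umbilical-artery pH < 7.1 — strict inequalities on every branch.  Human
panels are summarized as the fraction of raters judging positive; model
scores are binarized at 0.50 by default; fusion combines the two graded
channels additively (range [0, 2]) or multiplicatively (range [0, 1]).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import CaseRecord, RaterResponseSet

logger = logging.getLogger(__name__)

APGAR_CUTOFF = 6
PH_CUTOFF = 7.1


class UnlabellableCaseError(ValueError):
    """A case whose outcome fields are missing or out of range."""


class EmptyResponseError(ValueError):
    """A prediction ratio was requested for a case with no rater responses."""


@dataclass
class DecisionParams:
    """Cutoffs used to binarize graded scores.

    The 0.50 cutoff on the deep-learning score is fixed by the study design;
    human-ratio and fused cutoffs are not published and are configurable.
    """

    dl_cutoff: float = 0.50
    human_cutoff: float = 0.50
    fused_sum_cutoff: float = 1.00
    fused_product_cutoff: float = 0.50

    def __post_init__(self) -> None:
        for name, hi in (("dl_cutoff", 1.0), ("human_cutoff", 1.0),
                         ("fused_sum_cutoff", 2.0), ("fused_product_cutoff", 1.0)):
            v = getattr(self, name)
            if not 0.0 <= v <= hi:
                raise ValueError(f"{name}={v} outside [0, {hi}]")


def label_outcome(apgar_1min, apgar_5min, ua_ph) -> bool:
    """True iff apgar_1min < 6 or apgar_5min < 6 or ua_ph < 7.1."""
    fields = {"apgar_1min": apgar_1min, "apgar_5min": apgar_5min, "ua_ph": ua_ph}
    for name, v in fields.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise UnlabellableCaseError(f"missing outcome field {name}")
    if not (0 <= apgar_1min <= 10 and 0 <= apgar_5min <= 10):
        raise UnlabellableCaseError("Apgar score outside [0, 10]")
    return apgar_1min < APGAR_CUTOFF or apgar_5min < APGAR_CUTOFF or ua_ph < PH_CUTOFF


def binarize_dl(score: float, params: DecisionParams | None = None) -> bool:
    """Positive iff score >= cutoff (0.50 by default; the cutoff is inclusive)."""
    params = params or DecisionParams()
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"dl score {score} outside [0, 1]")
    return score >= params.dl_cutoff


def human_ratio(responses, rater_class: str | None = None) -> float:
    """Fraction of rater responses judging positive.

    ``responses`` is a :class:`RaterResponseSet` or an iterable of booleans.
    ``rater_class`` restricts to one rater class ('obstetrician'/'midwife');
    the default pools both classes.
    """
    if isinstance(responses, RaterResponseSet):
        judgments = [
            r.judgment
            for r in responses.responses
            if rater_class is None or r.rater_class == rater_class
        ]
    else:
        if rater_class is not None:
            raise ValueError("rater_class requires a RaterResponseSet")
        judgments = [bool(j) for j in responses]
    if not judgments:
        raise EmptyResponseError("no rater responses to form a prediction ratio")
    return sum(judgments) / len(judgments)


def fuse_sum(human_ratio_value: float, dl_score: float) -> float:
    """Additive fusion of the two graded channels; range [0, 2]."""
    _check_unit("human_ratio", human_ratio_value)
    _check_unit("dl_score", dl_score)
    return human_ratio_value + dl_score


def fuse_product(human_ratio_value: float, dl_score: float) -> float:
    """Multiplicative fusion; range [0, 1].

    At any common cutoff t in (0, 1] a product-positive case is positive
    under both inputs individually, so product fusion can only tighten the
    positive set (specificity is non-decreasing).
    """
    _check_unit("human_ratio", human_ratio_value)
    _check_unit("dl_score", dl_score)
    return human_ratio_value * dl_score


def _check_unit(name: str, v: float) -> None:
    if v is None:
        raise ValueError(f"missing input {name}")
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name}={v} outside [0, 1]")


def classify(scores, cutoff: float) -> np.ndarray:
    """Threshold rule: score >= cutoff -> positive."""
    return np.asarray(scores, dtype=float) >= cutoff


def correct_response_ratio(responses, truth: bool) -> float:
    """Fraction of raters whose judgment matches the truth label.

    Literal 'percentage of correct responses' variant of the prediction
    ratio, kept behind this separate entry point for sensitivity analysis:
    it leaks the truth label into the fused score and is not the default.
    """
    if isinstance(responses, RaterResponseSet):
        judgments = [r.judgment for r in responses.responses]
    else:
        judgments = [bool(j) for j in responses]
    if not judgments:
        raise EmptyResponseError("no rater responses")
    return sum(j == truth for j in judgments) / len(judgments)


@dataclass
class PredictionTable:
    """Per-case prediction channels plus exclusion bookkeeping."""

    table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def build_prediction_table(
    cases: list[CaseRecord], params: DecisionParams | None = None
) -> PredictionTable:
    """Assemble the per-case table of truth, ratios, scores and fused scores.

    Cases lacking either the rater channel or the DL score have no fused
    scores; cases lacking all prediction channels are excluded and logged.
    """
    params = params or DecisionParams()
    rows, excluded = [], []
    for case in cases:
        hr = case.human_ratio
        if hr is None and case.responses is not None and len(case.responses) > 0:
            hr = human_ratio(case.responses)
        if hr is None and case.dl_score is None and case.ml_call is None:
            excluded.append(case.case_id)
            continue
        fused_s = fused_p = None
        if hr is not None and case.dl_score is not None:
            fused_s = fuse_sum(hr, case.dl_score)
            fused_p = fuse_product(hr, case.dl_score)
        rows.append(
            {
                "case_id": case.case_id,
                "truth": int(case.truth),
                "human_ratio": hr,
                "dl_score": case.dl_score,
                "ml_call": None if case.ml_call is None else int(case.ml_call),
                "fused_sum": fused_s,
                "fused_product": fused_p,
            }
        )
    if excluded:
        logger.info("excluded %d cases with no prediction channel", len(excluded))
    df = pd.DataFrame(
        rows,
        columns=[
            "case_id", "truth", "human_ratio", "dl_score",
            "ml_call", "fused_sum", "fused_product",
        ],
    )
    return PredictionTable(table=df, excluded=excluded)
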