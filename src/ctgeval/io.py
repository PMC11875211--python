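"""On-disk formats: trace CSVs, cohort tables, confusion fixtures, run config.

The trace dialect is a plain CSV (columns ``time_s, fhr_bpm, uc`` at strict
0.25 s steps) preceded by a ``# key: value`` header block carrying the case
metadata.  Missing FHR samples serialize as empty fields — never 0, which
is reserved for raw transducer dropout.
"""

from __future__ import annotations

import io as _stdio
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnostics import ConfusionMatrix
from .judgments import UnlabellableCaseError, label_outcome
from .records import (
    SAMPLE_RATE_HZ,
    CaseRecord,
    CtgTrace,
    OutcomeRecord,
    RaterResponse,
    RaterResponseSet,
)

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("time_s", "fhr_bpm", "uc")
TIME_STEP_S = 1.0 / SAMPLE_RATE_HZ


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


def read_trace_csv(path) -> CtgTrace:
    """Read one trace CSV; validates columns and the 0.25 s sampling grid."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line.lstrip("#").partition(":")
                if value:
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    df = pd.read_csv(_stdio.StringIO("".join(body_lines)))
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    time = df["time_s"].to_numpy(dtype=float)
    if len(time) > 1:
        steps = np.diff(time)
        bad = np.nonzero(np.abs(steps - TIME_STEP_S) > 1e-6)[0]
        if bad.size:
            raise FormatError(
                f"{path}: sampling interval {steps[bad[0]]:.4g} s at row "
                f"{bad[0] + 1} (expected {TIME_STEP_S} s)"
            )
    if "delivery_time_s" not in meta:
        raise FormatError(f"{path}: header lacks delivery_time_s")
    return CtgTrace(
        case_id=meta.get("case_id", path.stem),
        fhr=df["fhr_bpm"].to_numpy(dtype=float),
        uc=df["uc"].to_numpy(dtype=float),
        delivery_time_s=float(meta["delivery_time_s"]),
        uc_smoothed=meta.get("uc_smoothed", "false").lower() == "true",
    )


def write_trace_csv(trace: CtgTrace, path) -> None:
    """Write a trace re-readably; masked (NaN) FHR becomes an empty field."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "fhr_bpm": trace.fhr,
            "uc": trace.uc,
        }
    )
    with path.open("w") as fh:
        fh.write(f"# case_id: {trace.case_id}\n")
        fh.write(f"# sample_rate_hz: {trace.sample_rate}\n")
        fh.write(f"# delivery_time_s: {trace.delivery_time_s!r}\n")
        fh.write(f"# uc_smoothed: {str(trace.uc_smoothed).lower()}\n")
        df.to_csv(fh, index=False, na_rep="", float_format="%.6f")


JUDGMENT_STRINGS = {"positive": True, "negative": False}


def read_cohort_tables(outcomes_path, ratings_path=None, scores_path=None) -> list[CaseRecord]:
    """Join the outcome, rating and score tables into one record per case.

    One record per case in the outcomes table; cases missing ratings or
    scores keep those channels empty (and are logged).  Unlabellable cases
    (missing outcome fields) are dropped with a warning.
    """
    outcomes = pd.read_csv(outcomes_path)
    dup = outcomes["case_id"][outcomes["case_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicate case_id in outcomes: {dup.iloc[0]!r}")

    ratings_by_case: dict[str, list[RaterResponse]] = {}
    if ratings_path is not None:
        ratings = pd.read_csv(ratings_path)
        for row in ratings.itertuples(index=False):
            judgment = row.judgment
            if isinstance(judgment, str):
                judgment = JUDGMENT_STRINGS[judgment.strip().lower()]
            ratings_by_case.setdefault(str(row.case_id), []).append(
                RaterResponse(
                    rater_id=str(row.rater_id),
                    rater_class=str(row.rater_class),
                    judgment=bool(judgment),
                )
            )

    scores_by_case: dict[str, tuple] = {}
    if scores_path is not None:
        scores = pd.read_csv(scores_path)
        sdup = scores["case_id"][scores["case_id"].duplicated()]
        if not sdup.empty:
            raise FormatError(f"duplicate case_id in scores: {sdup.iloc[0]!r}")
        for row in scores.itertuples(index=False):
            dl = None if pd.isna(row.dl_score) else float(row.dl_score)
            ml = None if pd.isna(row.ml_call) else bool(int(row.ml_call))
            scores_by_case[str(row.case_id)] = (dl, ml)

    records: list[CaseRecord] = []
    n_unrated = n_unscored = 0
    for row in outcomes.itertuples(index=False):
        cid = str(row.case_id)
        try:
            outcome = OutcomeRecord(
                case_id=cid,
                apgar_1min=int(row.apgar_1min),
                apgar_5min=int(row.apgar_5min),
                ua_ph=float(row.ua_ph),
            )
            truth = label_outcome(outcome.apgar_1min, outcome.apgar_5min, outcome.ua_ph)
        except (UnlabellableCaseError, ValueError) as exc:
            logger.warning("case %s unlabellable, excluded: %s", cid, exc)
            continue
        resp_list = ratings_by_case.get(cid, [])
        if not resp_list:
            n_unrated += 1
        dl, ml = scores_by_case.get(cid, (None, None))
        if dl is None and ml is None:
            n_unscored += 1
        records.append(
            CaseRecord(
                case_id=cid,
                truth=truth,
                outcome=outcome,
                responses=RaterResponseSet(case_id=cid, responses=resp_list),
                dl_score=dl,
                ml_call=ml,
            )
        )
    logger.info(
        "joined %d cases (%d without ratings, %d without scores)",
        len(records), n_unrated, n_unscored,
    )
    return records


def write_cohort_tables(cohort, out_dir) -> dict[str, Path]:
    """Write outcomes/ratings/scores CSVs for a simulated cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    outcomes = pd.DataFrame(
        [
            {
                "case_id": o.case_id,
                "apgar_1min": o.apgar_1min,
                "apgar_5min": o.apgar_5min,
                "ua_ph": round(o.ua_ph, 3),
            }
            for o in cohort.outcomes
        ]
    )
    paths["outcomes"] = out_dir / "outcomes.csv"
    outcomes.to_csv(paths["outcomes"], index=False)

    rating_rows = []
    for cid, rset in cohort.responses.items():
        for r in rset.responses:
            rating_rows.append(
                {
                    "case_id": cid,
                    "rater_id": r.rater_id,
                    "rater_class": r.rater_class,
                    "judgment": "positive" if r.judgment else "negative",
                }
            )
    paths["ratings"] = out_dir / "ratings.csv"
    pd.DataFrame(
        rating_rows, columns=["case_id", "rater_id", "rater_class", "judgment"]
    ).to_csv(paths["ratings"], index=False)

    score_rows = [
        {
            "case_id": c.case_id,
            "dl_score": None if c.dl_score is None else round(c.dl_score, 6),
            "ml_call": None if c.ml_call is None else int(c.ml_call),
        }
        for c in cohort.cases
    ]
    paths["scores"] = out_dir / "scores.csv"
    pd.DataFrame(score_rows, columns=["case_id", "dl_score", "ml_call"]).to_csv(
        paths["scores"], index=False
    )
    return paths


def read_confusion_fixture(path) -> ConfusionMatrix:
    """Read a 2x2 fixture CSV with columns tp, fp, fn, tn (one data row)."""
    df = pd.read_csv(path)
    for col in ("tp", "fp", "fn", "tn"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) != 1:
        raise FormatError(f"{path}: expected exactly one data row, got {len(df)}")
    row = df.iloc[0]
    counts = {col: int(row[col]) for col in ("tp", "fp", "fn", "tn")}
    for col, v in counts.items():
        if v < 0:
            raise FormatError(f"{path}: negative count {col}={v}")
    if sum(counts.values()) == 0:
        raise FormatError(f"{path}: empty matrix")
    return ConfusionMatrix(**counts)


def write_confusion_fixture(cm: ConfusionMatrix, path) -> None:
    pd.DataFrame([{"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}]).to_csv(
        path, index=False
    )


#: bundled reference 2x2 fixtures for the four published judgment methods
BUNDLED_FIXTURES = {
    "human": "confusion_human.csv",
    "ml": "confusion_ml.csv",
    "dl": "confusion_dl.csv",
    "human_dl_product": "confusion_human_dl_product.csv",
}


def load_bundled_fixture(method: str) -> ConfusionMatrix:
    """Load one of the shipped reference confusion matrices by method name."""
    from importlib import resources

    if method not in BUNDLED_FIXTURES:
        raise KeyError(f"unknown fixture {method!r}; have {sorted(BUNDLED_FIXTURES)}")
    ref = resources.files("ctgeval").joinpath("data", BUNDLED_FIXTURES[method])
    with resources.as_file(ref) as p:
        return read_confusion_fixture(p)


def load_config(path) -> dict:
    """YAML run configuration -> plain dict ({} for an empty file)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
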