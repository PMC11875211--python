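"""Seeded synthetic CTG cohort generation.

Produces clean traces with a known event ledger, injects the artifact
classes the cleaner removes (dropout zeros, out-of-range spikes, jump
spikes), and emits outcome records, rater panels, and two model-score
channels with configurable operating points — everything needed to exercise
the downstream pipeline without clinical data.

Variability is modelled as band-limited Gaussian noise (smoothed white
noise), which gives the cleaner and feature extractor realistic band and
amplitude structure without a mechanistic cardiac model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .features import Event
from .records import (
    SAMPLE_RATE_HZ,
    CtgTrace,
    OutcomeRecord,
    RaterResponse,
    RaterResponseSet,
)

logger = logging.getLogger(__name__)

MIN_DURATION_S = 3000.0  # must cover the 50-min pre-delivery span


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class TraceGenParams:
    """Shape of a generated clean trace."""

    baseline_bpm: float = 140.0
    variability_amplitude_bpm: float = 10.0  # typical minute-range target
    accel_rate_per_h: float = 8.0
    decel_rate_per_h: float = 4.0
    decel_lag_s: float = 0.0  # nadir minus UC-peak lag; > 0 = late pattern
    contraction_period_s: float = 180.0
    duration_s: float = 3600.0
    accel_amplitude_bpm: tuple[float, float] = (18.0, 25.0)
    accel_sigma_s: float = 15.0
    decel_depth_bpm: tuple[float, float] = (20.0, 35.0)
    decel_sigma_s: float = 30.0
    uc_amplitude: float = 50.0
    uc_floor: float = 10.0

    def __post_init__(self) -> None:
        if not 50.0 < self.baseline_bpm < 200.0:
            raise ValueError("baseline_bpm must lie in (50, 200)")
        if self.accel_rate_per_h < 0 or self.decel_rate_per_h < 0:
            raise ValueError("event rates must be >= 0")
        if self.duration_s < MIN_DURATION_S:
            raise ValueError(
                f"duration_s must be >= {MIN_DURATION_S:.0f} s to cover the "
                "pre-delivery analysis span"
            )


@dataclass
class ArtifactParams:
    """Rates and magnitudes of the injected artifact classes."""

    dropout_rate_per_h: float = 6.0
    dropout_len_s: tuple[float, float] = (1.0, 8.0)
    spike_rate_per_h: float = 4.0          # out-of-range values (>=200 or <=50)
    spike_magnitude_bpm: tuple[float, float] = (200.0, 230.0)
    jump_rate_per_h: float = 4.0           # in-range steps deviating > 25 bpm
    jump_magnitude_bpm: tuple[float, float] = (35.0, 55.0)
    long_dropout_prob: float = 0.0         # chance of one >= 15 s zero run

    def __post_init__(self) -> None:
        for name in ("dropout_rate_per_h", "spike_rate_per_h", "jump_rate_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.long_dropout_prob <= 1.0:
            raise ValueError("long_dropout_prob must lie in [0, 1]")


@dataclass(frozen=True)
class Artifact:
    """One injected corruption: ``length`` consecutive samples from ``start``."""

    kind: str  # dropout | long_dropout | spike_range | spike_jump
    start: int
    length: int

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.length)


@dataclass
class OutcomeModelParams:
    """Logistic outcome model on ground-truth risk features."""

    intercept: float = -4.0
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "late_decel_count": 0.6,
            "variability_deficit": 0.35,
            "bradycardia_fraction": 3.0,
        }
    )
    target_prevalence: float = 31.0 / 489.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")


@dataclass
class RaterModelParams:
    """Panel design and per-rater error model.

    Each rater is assigned ``figures_per_rater`` cases sampled without
    replacement — ``positives_per_rater`` truth-positive and the rest
    truth-negative — and judges positives correctly with probability
    ``sensitivity``, negatives with probability ``specificity``.
    ``response_dropout`` optionally discards each judgment uniformly at
    random, emulating incomplete questionnaire returns.
    """

    sensitivity: float = 0.23
    specificity: float = 0.92
    n_raters: int = 56
    n_obstetricians: int = 34
    figures_per_rater: int = 50
    positives_per_rater: int = 10
    response_dropout: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "response_dropout"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.positives_per_rater > self.figures_per_rater:
            raise ValueError("positives_per_rater exceeds figures_per_rater")
        if not 0 <= self.n_obstetricians <= self.n_raters:
            raise ValueError("n_obstetricians must lie in [0, n_raters]")


@dataclass
class ScoreModelParams:
    """Label-conditional model-score channels.

    The graded score is Beta-distributed conditional on truth; the binary
    channel is a fixed sensitivity/specificity coin flip.
    """

    dl_pos_beta: tuple[float, float] = (2.0, 3.5)
    dl_neg_beta: tuple[float, float] = (1.0, 4.0)
    ml_sensitivity: float = 0.10
    ml_specificity: float = 0.94


def _contraction_peak_times(params: TraceGenParams) -> np.ndarray:
    period = params.contraction_period_s
    return np.arange(period / 2.0, params.duration_s, period)


def _place_centers(
    rng: np.random.Generator,
    n_events: int,
    duration_s: float,
    margin_s: float,
    min_sep_s: float,
    taken: list[float],
) -> list[float]:
    """Uniform event centers, rejection-sampled to stay min_sep apart."""
    centers: list[float] = []
    attempts = 0
    while len(centers) < n_events and attempts < 200 * max(n_events, 1):
        c = float(rng.uniform(margin_s, duration_s - margin_s))
        if all(abs(c - o) >= min_sep_s for o in centers + taken):
            centers.append(c)
        attempts += 1
    if len(centers) < n_events:
        raise ValueError("could not place events without overlap; lower the rates")
    return sorted(centers)


def generate_clean_trace(
    params: TraceGenParams, seed, case_id: str = "synthetic"
) -> tuple[CtgTrace, list[Event]]:
    """Clean FHR/UC trace plus the ground-truth ledger of injected events.

    FHR = baseline + band-limited noise + Gaussian acceleration bumps +
    Gaussian deceleration dips whose nadirs sit ``decel_lag_s`` after a
    contraction peak.  Event counts are rate * duration, rounded, so tests
    can predict the ledger length exactly.
    """
    rng = _rng(seed)
    n = int(round(params.duration_s * SAMPLE_RATE_HZ))
    t = np.arange(n) / SAMPLE_RATE_HZ

    if params.variability_amplitude_bpm > 0:
        noise = gaussian_filter1d(rng.standard_normal(n), sigma=SAMPLE_RATE_HZ)
        noise *= (params.variability_amplitude_bpm / 4.0) / noise.std()
    else:
        noise = np.zeros(n)
    fhr = params.baseline_bpm + noise

    peak_times = _contraction_peak_times(params)
    uc = np.full(n, params.uc_floor)
    sig_uc = params.contraction_period_s / 8.0
    for pt in peak_times:
        uc += params.uc_amplitude * np.exp(-0.5 * ((t - pt) / sig_uc) ** 2)

    hours = params.duration_s / 3600.0
    n_accel = int(round(params.accel_rate_per_h * hours))
    n_decel = int(round(params.decel_rate_per_h * hours))

    events: list[Event] = []
    taken: list[float] = []

    if n_decel > 0:
        interior = peak_times[
            (peak_times + params.decel_lag_s > 120)
            & (peak_times + params.decel_lag_s < params.duration_s - 120)
        ]
        if len(interior) < n_decel:
            raise ValueError("not enough contraction peaks to anchor decelerations")
        chosen = rng.choice(len(interior), size=n_decel, replace=False)
        for k in sorted(chosen.tolist()):
            center = interior[k] + params.decel_lag_s
            depth = float(rng.uniform(*params.decel_depth_bpm))
            sig = params.decel_sigma_s
            fhr -= depth * np.exp(-0.5 * ((t - center) / sig) ** 2)
            halfwidth = sig * np.sqrt(2.0 * np.log(depth / 15.0))
            events.append(
                Event(
                    kind="deceleration",
                    onset_s=center - halfwidth,
                    end_s=center + halfwidth,
                    extremum_bpm=params.baseline_bpm - depth,
                    lag_vs_uc_peak_s=params.decel_lag_s,
                )
            )
            taken.append(center)

    if n_accel > 0:
        margin = 4.0 * params.accel_sigma_s
        centers = _place_centers(
            rng, n_accel, params.duration_s, margin,
            min_sep_s=6.0 * params.accel_sigma_s + 2.0 * params.decel_sigma_s,
            taken=taken,
        )
        for center in centers:
            amp = float(rng.uniform(*params.accel_amplitude_bpm))
            sig = params.accel_sigma_s
            fhr += amp * np.exp(-0.5 * ((t - center) / sig) ** 2)
            halfwidth = sig * np.sqrt(2.0 * np.log(amp / 15.0))
            events.append(
                Event(
                    kind="acceleration",
                    onset_s=center - halfwidth,
                    end_s=center + halfwidth,
                    extremum_bpm=params.baseline_bpm + amp,
                )
            )

    events.sort(key=lambda e: e.onset_s)
    trace = CtgTrace(
        case_id=case_id, fhr=fhr, uc=uc, delivery_time_s=params.duration_s
    )
    return trace, events


def corrupt_trace(
    trace: CtgTrace, artifact_params: ArtifactParams, seed
) -> tuple[CtgTrace, list[Artifact]]:
    """Inject dropouts, out-of-range spikes and jump artifacts; ledger every index.

    Artifacts are kept >= 15 s apart (and away from the trace edges) so each
    cleaning rule sees its target in an otherwise clean neighbourhood; with
    all rates zero the trace passes through untouched.
    """
    rng = _rng(seed)
    ap = artifact_params
    fhr = trace.fhr.copy()
    n = len(fhr)
    hours = trace.duration_s / 3600.0
    sep = 16 * SAMPLE_RATE_HZ  # one spike window plus slack
    margin = 60 * SAMPLE_RATE_HZ
    occupied: list[tuple[int, int]] = []

    def free(start: int, length: int) -> bool:
        if start < margin or start + length > n - margin:
            return False
        return all(start + length + sep <= s or start >= s + l + sep
                   for s, l in occupied)

    def place(length: int) -> int | None:
        for _ in range(500):
            start = int(rng.integers(margin, n - margin - length))
            if free(start, length):
                occupied.append((start, length))
                return start
        return None

    ledger: list[Artifact] = []

    if ap.long_dropout_prob > 0 and rng.random() < ap.long_dropout_prob:
        length = int(round(float(rng.uniform(15.0, 30.0)) * SAMPLE_RATE_HZ))
        start = place(length)
        if start is not None:
            fhr[start : start + length] = 0.0
            ledger.append(Artifact("long_dropout", start, length))

    for _ in range(int(rng.poisson(ap.dropout_rate_per_h * hours))):
        len_s = float(rng.uniform(*ap.dropout_len_s))
        length = max(1, int(round(len_s * SAMPLE_RATE_HZ)))
        start = place(length)
        if start is not None:
            fhr[start : start + length] = 0.0
            ledger.append(Artifact("dropout", start, length))

    for _ in range(int(rng.poisson(ap.spike_rate_per_h * hours))):
        start = place(1)
        if start is not None:
            mag = float(rng.uniform(*ap.spike_magnitude_bpm))
            fhr[start] = mag if rng.random() < 0.5 else max(0.0, 250.0 - mag)
            ledger.append(Artifact("spike_range", start, 1))

    for _ in range(int(rng.poisson(ap.jump_rate_per_h * hours))):
        start = place(1)
        if start is not None:
            mag = float(rng.uniform(*ap.jump_magnitude_bpm))
            fhr[start] += mag if rng.random() < 0.5 else -mag
            ledger.append(Artifact("spike_jump", start, 1))

    ledger.sort(key=lambda a: a.start)
    out = CtgTrace(
        case_id=trace.case_id, fhr=fhr, uc=trace.uc.copy(),
        delivery_time_s=trace.delivery_time_s,
    )
    return out, ledger


def risk_features(events: list[Event], trace: CtgTrace) -> dict[str, float]:
    """Ground-truth risk summary used by the outcome model."""
    late = sum(
        1 for e in events
        if e.kind.startswith("decel") or e.kind == "deceleration"
        if (e.lag_vs_uc_peak_s or 0.0) > 15.0
    )
    fhr = trace.fhr
    return {
        "late_decel_count": float(late),
        "variability_deficit": float(max(0.0, 10.0 - np.std(fhr))),
        "bradycardia_fraction": float(np.mean(fhr < 110.0)),
    }


def outcome_probability(features: dict[str, float], params: OutcomeModelParams) -> float:
    eta = params.intercept + sum(
        beta * features.get(name, 0.0) for name, beta in params.coefficients.items()
    )
    return float(expit(eta))


def calibrate_intercept(
    feature_rows: list[dict[str, float]], params: OutcomeModelParams
) -> float:
    """Bisection on the intercept so the mean positive probability hits the
    target prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        trial = replace(params, intercept=mid)
        mean_p = float(
            np.mean([outcome_probability(f, trial) for f in feature_rows])
        )
        if mean_p < params.target_prevalence:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _draw_outcome_fields(positive: bool, rng: np.random.Generator) -> tuple[int, int, float]:
    """Apgar/pH draws consistent with the label by construction."""
    if positive:
        apgar1 = int(rng.integers(1, 6))  # < 6 guarantees a positive label
        apgar5 = int(min(10, apgar1 + rng.integers(0, 5)))
        ph = float(np.clip(rng.normal(7.03, 0.07), 6.7, 7.4))
    else:
        apgar1 = int(rng.integers(7, 11))
        apgar5 = int(rng.integers(8, 11))
        ph = float(np.clip(rng.normal(7.28, 0.06), 7.12, 7.6))
    return apgar1, apgar5, ph


def sample_outcome(
    case_id: str,
    features: dict[str, float],
    outcome_params: OutcomeModelParams,
    seed,
) -> OutcomeRecord:
    """Bernoulli label from the logistic model, then label-consistent fields."""
    rng = _rng(seed)
    p = outcome_probability(features, outcome_params)
    positive = bool(rng.random() < p)
    apgar1, apgar5, ph = _draw_outcome_fields(positive, rng)
    return OutcomeRecord(case_id=case_id, apgar_1min=apgar1, apgar_5min=apgar5, ua_ph=ph)


def simulate_raters(
    truth_labels: dict[str, bool], rater_params: RaterModelParams, seed
) -> dict[str, RaterResponseSet]:
    """Simulate the reader panel; returns a response set per case.

    Raters draw their positive and negative case quotas without replacement
    from the cohort, then judge each with the configured error model.
    """
    rng = _rng(seed)
    rp = rater_params
    pos_ids = [cid for cid, lab in truth_labels.items() if lab]
    neg_ids = [cid for cid, lab in truth_labels.items() if not lab]
    n_neg_quota = rp.figures_per_rater - rp.positives_per_rater
    if len(pos_ids) < rp.positives_per_rater:
        raise ValueError(
            f"only {len(pos_ids)} positive cases for a per-rater quota of "
            f"{rp.positives_per_rater}"
        )
    if len(neg_ids) < n_neg_quota:
        raise ValueError(
            f"only {len(neg_ids)} negative cases for a per-rater quota of {n_neg_quota}"
        )
    responses: dict[str, list[RaterResponse]] = {cid: [] for cid in truth_labels}
    for r in range(rp.n_raters):
        rater_class = "obstetrician" if r < rp.n_obstetricians else "midwife"
        rater_id = f"{'ob' if rater_class == 'obstetrician' else 'mw'}{r:03d}"
        shown = [
            pos_ids[i] for i in rng.choice(len(pos_ids), rp.positives_per_rater, replace=False)
        ] + [
            neg_ids[i] for i in rng.choice(len(neg_ids), n_neg_quota, replace=False)
        ]
        for cid in shown:
            if rp.response_dropout > 0 and rng.random() < rp.response_dropout:
                continue
            correct = rng.random() < (
                rp.sensitivity if truth_labels[cid] else rp.specificity
            )
            judged_positive = truth_labels[cid] if correct else not truth_labels[cid]
            responses[cid].append(
                RaterResponse(rater_id=rater_id, rater_class=rater_class,
                              judgment=judged_positive)
            )
    return {
        cid: RaterResponseSet(case_id=cid, responses=resp)
        for cid, resp in responses.items()
    }


@dataclass
class Cohort:
    """Everything one simulated study emits."""

    cases: list  # list[CaseRecord]; typed loosely to avoid an import cycle
    outcomes: list[OutcomeRecord]
    responses: dict[str, RaterResponseSet]
    traces: dict[str, CtgTrace] = field(default_factory=dict)
    clean_traces: dict[str, CtgTrace] = field(default_factory=dict)
    ledgers: dict[str, list[Artifact]] = field(default_factory=dict)
    event_lists: dict[str, list[Event]] = field(default_factory=dict)


def generate_study_cohort(
    n: int = 489,
    n_pos: int = 31,
    seed=0,
    trace_params_neg: TraceGenParams | None = None,
    trace_params_pos: TraceGenParams | None = None,
    artifact_params: ArtifactParams | None = None,
    rater_params: RaterModelParams | None = None,
    score_params: ScoreModelParams | None = None,
    include_traces: bool = False,
) -> Cohort:
    """Full simulated study with an exact positive count.

    Labels are assigned first (exactly ``n_pos`` positives, positions
    shuffled), then every per-case channel is drawn conditional on the
    label: outcome fields that the labeling rule reproduces, rater panels
    with the configured error model, and two model-score channels.  Traces
    (clean + corrupted, with ledgers) are generated only on request — the
    positive stratum uses a late-deceleration, low-variability profile.
    """
    from .judgments import label_outcome  # deferred: records-level cycle
    from .records import CaseRecord

    if not 0 <= n_pos <= n:
        raise ValueError("n_pos must lie in [0, n]")
    rng = _rng(seed)
    labels = np.zeros(n, dtype=bool)
    labels[:n_pos] = True
    rng.shuffle(labels)
    case_ids = [f"case{i:04d}" for i in range(n)]
    truth = dict(zip(case_ids, labels.tolist()))

    sp = score_params or ScoreModelParams()
    outcomes, cases = [], []
    cohort = Cohort(cases=cases, outcomes=outcomes, responses={})

    if include_traces:
        tp_neg = trace_params_neg or TraceGenParams()
        tp_pos = trace_params_pos or replace(
            TraceGenParams(),
            decel_rate_per_h=10.0,
            decel_lag_s=30.0,
            variability_amplitude_bpm=6.0,
            accel_rate_per_h=2.0,
        )
        ap = artifact_params or ArtifactParams()

    for cid in case_ids:
        positive = truth[cid]
        apgar1, apgar5, ph = _draw_outcome_fields(positive, rng)
        rec = OutcomeRecord(case_id=cid, apgar_1min=apgar1, apgar_5min=apgar5, ua_ph=ph)
        assert label_outcome(rec.apgar_1min, rec.apgar_5min, rec.ua_ph) == positive
        outcomes.append(rec)

        a, b = sp.dl_pos_beta if positive else sp.dl_neg_beta
        dl_score = float(rng.beta(a, b))
        ml_correct = rng.random() < (sp.ml_sensitivity if positive else sp.ml_specificity)
        ml_call = positive if ml_correct else not positive

        cases.append(
            CaseRecord(
                case_id=cid, truth=positive, outcome=rec,
                dl_score=dl_score, ml_call=ml_call,
            )
        )

        if include_traces:
            params = tp_pos if positive else tp_neg
            clean_tr, events = generate_clean_trace(params, rng, case_id=cid)
            corrupted, ledger = corrupt_trace(clean_tr, ap, rng)
            cohort.clean_traces[cid] = clean_tr
            cohort.traces[cid] = corrupted
            cohort.ledgers[cid] = ledger
            cohort.event_lists[cid] = events

    rp = rater_params or RaterModelParams()
    cohort.responses = simulate_raters(truth, rp, rng)
    for case in cases:
        case.responses = cohort.responses.get(case.case_id)
        if case.responses is not None and len(case.responses) > 0:
            case.human_ratio = sum(
                r.judgment for r in case.responses.responses
            ) / len(case.responses)

    n_responses = sum(len(r) for r in cohort.responses.values())
    logger.info(
        "simulated cohort: %d cases (%d positive), %d rater responses",
        n, int(labels.sum()), n_responses,
    )
    return cohort
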