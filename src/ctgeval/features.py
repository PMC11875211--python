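"""Guideline-style descriptors of a cleaned 30-minute FHR/UC segment.

Baseline is the modal FHR level (2.5 bpm binning, refined by the mean of
samples within +-10 bpm of the modal bin), which makes it insensitive to
transient accelerations/decelerations.  Events follow the usual 15 bpm /
15 s convention; decelerations are typed early/late/variable/prolonged by
nadir timing against the nearest contraction peak.  The full 44-descriptor
roster lives in ``feature_manifest.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.signal import find_peaks

from .preprocess import CleanTrace
from .records import SAMPLE_RATE_HZ, CtgTrace

EVENT_THRESHOLD_BPM = 15.0
EVENT_MIN_DURATION_S = 15.0
PROLONGED_MIN_DURATION_S = 120.0
EARLY_MAX_ABS_LAG_S = 15.0
LATE_MAX_LAG_S = 60.0
ABRUPT_ONSET_S = 30.0  # onset-to-nadir at or under this span = abrupt (variable)
BRADYCARDIA_BPM = 110.0
TACHYCARDIA_BPM = 160.0

DECEL_KINDS = ("early_decel", "late_decel", "variable_decel", "prolonged_decel")


def _load_manifest() -> list[dict]:
    text = resources.files("ctgeval").joinpath("feature_manifest.yaml").read_text()
    return yaml.safe_load(text)["features"]


_MANIFEST = _load_manifest()
FEATURE_NAMES: tuple[str, ...] = tuple(entry["name"] for entry in _MANIFEST)
FEATURE_GROUPS: dict[str, str] = {e["name"]: e["group"] for e in _MANIFEST}
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 44, f"manifest must list 44 features, found {N_FEATURES}"


@dataclass(frozen=True)
class Event:
    """One acceleration or deceleration episode."""

    kind: str  # 'acceleration' or one of DECEL_KINDS
    onset_s: float
    end_s: float
    extremum_bpm: float
    lag_vs_uc_peak_s: float | None = None  # decelerations only

    def __post_init__(self) -> None:
        if self.end_s <= self.onset_s:
            raise ValueError("event end must be after onset")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s


class FeatureVector:
    """Ordered mapping of the 44 named descriptors."""

    __slots__ = ("_values",)

    def __init__(self, values: dict[str, float]):
        missing = set(FEATURE_NAMES) - set(values)
        extra = set(values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"bad feature roster: missing={missing} extra={extra}")
        self._values = {name: float(values[name]) for name in FEATURE_NAMES}

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __len__(self) -> int:
        return len(self._values)

    def __iter__(self):
        return iter(FEATURE_NAMES)

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def to_array(self) -> np.ndarray:
        return np.array([self._values[n] for n in FEATURE_NAMES])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs; stop is exclusive."""
    padded = np.r_[False, mask, False]
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    stops = np.nonzero(~padded[1:] & padded[:-1])[0]
    return list(zip(starts.tolist(), stops.tolist()))


def estimate_baseline(segment: np.ndarray) -> float:
    """Modal FHR level: 2.5 bpm bin mode, refined by the +-10 bpm local mean."""
    x = np.asarray(segment, dtype=float)
    if len(x) == 0 or not np.all(np.isfinite(x)):
        raise ValueError("baseline needs a complete, non-empty segment")
    lo = np.floor(x.min() / 2.5) * 2.5
    hi = np.ceil(x.max() / 2.5) * 2.5
    edges = np.arange(lo, hi + 2.5, 2.5)
    if len(edges) < 2:
        return float(x.mean())
    counts, _ = np.histogram(x, bins=edges)
    mode_center = (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2
    near = np.abs(x - mode_center) <= 10.0
    return float(x[near].mean()) if near.any() else float(mode_center)


def detect_contractions(
    uc: np.ndarray, min_interval_s: float = 60.0
) -> np.ndarray:
    """Indices of contraction peaks in the (smoothed) UC channel."""
    x = np.asarray(uc, dtype=float)
    span = x.max() - x.min() if len(x) else 0.0
    if span <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        x,
        prominence=0.25 * span,
        distance=int(min_interval_s * SAMPLE_RATE_HZ),
    )
    return peaks


def detect_accelerations(segment: np.ndarray, baseline: float) -> list[Event]:
    """Maximal runs >= baseline + 15 bpm lasting >= 15 s."""
    x = np.asarray(segment, dtype=float)
    min_len = int(EVENT_MIN_DURATION_S * SAMPLE_RATE_HZ)
    events = []
    for start, stop in _runs(x >= baseline + EVENT_THRESHOLD_BPM):
        if stop - start < min_len:
            continue
        events.append(
            Event(
                kind="acceleration",
                onset_s=start / SAMPLE_RATE_HZ,
                end_s=stop / SAMPLE_RATE_HZ,
                extremum_bpm=float(x[start:stop].max()),
            )
        )
    return events


def detect_decelerations(
    segment: np.ndarray, baseline: float, smoothed_uc: np.ndarray
) -> list[Event]:
    """Maximal runs <= baseline - 15 bpm lasting >= 15 s, typed by UC timing.

    Typing precedence: duration >= 120 s -> prolonged; no contraction peak
    within 60 s of the nadir, or abrupt onset (onset-to-nadir <= 30 s) ->
    variable; |nadir - peak| <= 15 s -> early; nadir 15-60 s after the
    peak -> late; anything else -> variable.
    """
    x = np.asarray(segment, dtype=float)
    min_len = int(EVENT_MIN_DURATION_S * SAMPLE_RATE_HZ)
    peak_times = detect_contractions(smoothed_uc) / SAMPLE_RATE_HZ
    events = []
    for start, stop in _runs(x <= baseline - EVENT_THRESHOLD_BPM):
        if stop - start < min_len:
            continue
        # nadir time as the depth-weighted centroid of the excursion: the
        # raw argmin of a flat-bottomed dip jitters by seconds under
        # beat-to-beat noise, the centroid stays put
        depth_w = (baseline - EVENT_THRESHOLD_BPM) - x[start:stop]
        nadir_t = (
            start + float(np.sum(np.arange(stop - start) * depth_w) / depth_w.sum())
        ) / SAMPLE_RATE_HZ
        onset_t = start / SAMPLE_RATE_HZ
        end_t = stop / SAMPLE_RATE_HZ
        lag = None
        if peak_times.size:
            nearest = peak_times[np.argmin(np.abs(peak_times - nadir_t))]
            lag = nadir_t - nearest
        duration = end_t - onset_t
        onset_to_nadir = nadir_t - onset_t
        if duration >= PROLONGED_MIN_DURATION_S:
            kind = "prolonged_decel"
        elif lag is None or abs(lag) > LATE_MAX_LAG_S:
            kind = "variable_decel"
        elif onset_to_nadir <= ABRUPT_ONSET_S:
            kind = "variable_decel"
        elif abs(lag) <= EARLY_MAX_ABS_LAG_S:
            kind = "early_decel"
        elif EARLY_MAX_ABS_LAG_S < lag <= LATE_MAX_LAG_S:
            kind = "late_decel"
        else:
            kind = "variable_decel"
        events.append(
            Event(
                kind=kind,
                onset_s=onset_t,
                end_s=end_t,
                extremum_bpm=float(x[start:stop].min()),
                lag_vs_uc_peak_s=lag,
            )
        )
    return events


def compute_variability(
    segment: np.ndarray, baseline: float, events: list[Event] | None = None
) -> tuple[np.ndarray, float]:
    """Per-minute FHR range (max - min) excluding event samples, plus median.

    A minute entirely inside events yields NaN and is skipped in the
    aggregate (the median of the remaining minutes).
    """
    x = np.asarray(segment, dtype=float)
    exclude = np.zeros(len(x), dtype=bool)
    for ev in events or []:
        lo = int(ev.onset_s * SAMPLE_RATE_HZ)
        hi = int(ev.end_s * SAMPLE_RATE_HZ)
        exclude[lo:hi] = True
    win = 60 * SAMPLE_RATE_HZ
    amps = []
    for start in range(0, len(x) - win + 1, win):
        keep = ~exclude[start : start + win]
        if keep.any():
            vals = x[start : start + win][keep]
            amps.append(float(vals.max() - vals.min()))
        else:
            amps.append(float("nan"))
    amps = np.array(amps)
    valid = amps[np.isfinite(amps)]
    aggregate = float(np.median(valid)) if valid.size else float("nan")
    return amps, aggregate


def build_feature_vector(clean_trace: CleanTrace | CtgTrace) -> FeatureVector:
    """Deterministic 44-descriptor vector of a cleaned segment."""
    trace = clean_trace.trace if isinstance(clean_trace, CleanTrace) else clean_trace
    x = np.asarray(trace.fhr, dtype=float)
    uc = np.asarray(trace.uc, dtype=float)
    rate = trace.sample_rate

    baseline = estimate_baseline(x)
    accels = detect_accelerations(x, baseline)
    decels = detect_decelerations(x, baseline, uc)
    events = accels + decels
    minute_amps, _ = compute_variability(x, baseline, events)
    valid_amps = minute_amps[np.isfinite(minute_amps)]

    # per-minute medians -> least-squares drift in bpm per minute
    win = 60 * rate
    minute_medians = [
        float(np.median(x[s : s + win])) for s in range(0, len(x) - win + 1, win)
    ]
    if len(minute_medians) >= 2:
        drift = float(np.polyfit(np.arange(len(minute_medians)), minute_medians, 1)[0])
    else:
        drift = 0.0

    f: dict[str, float] = {}
    f["baseline_bpm"] = baseline
    f["baseline_drift_bpm_per_min"] = drift
    f["bradycardia_fraction"] = float(np.mean(x < BRADYCARDIA_BPM))
    f["tachycardia_fraction"] = float(np.mean(x > TACHYCARDIA_BPM))

    f["short_term_variability_bpm"] = (
        float(np.mean(np.abs(np.diff(x)))) if len(x) > 1 else 0.0
    )
    if valid_amps.size:
        f["minute_range_mean_bpm"] = float(valid_amps.mean())
        f["minute_range_median_bpm"] = float(np.median(valid_amps))
        f["minute_range_min_bpm"] = float(valid_amps.min())
        f["minute_range_max_bpm"] = float(valid_amps.max())
        f["low_variability_minutes_fraction"] = float(np.mean(valid_amps < 5.0))
        f["moderate_variability_minutes_fraction"] = float(
            np.mean((valid_amps >= 5.0) & (valid_amps <= 25.0))
        )
        f["marked_variability_minutes_fraction"] = float(np.mean(valid_amps > 25.0))
    else:
        for name in ("minute_range_mean_bpm", "minute_range_median_bpm",
                     "minute_range_min_bpm", "minute_range_max_bpm",
                     "low_variability_minutes_fraction",
                     "moderate_variability_minutes_fraction",
                     "marked_variability_minutes_fraction"):
            f[name] = 0.0

    f["accel_count"] = float(len(accels))
    durations = [e.duration_s for e in accels]
    amplitudes = [e.extremum_bpm - baseline for e in accels]
    f["accel_total_duration_s"] = float(sum(durations))
    f["accel_mean_duration_s"] = float(np.mean(durations)) if durations else 0.0
    f["accel_mean_amplitude_bpm"] = float(np.mean(amplitudes)) if amplitudes else 0.0
    f["accel_max_amplitude_bpm"] = float(max(amplitudes)) if amplitudes else 0.0

    for kind in DECEL_KINDS:
        of_kind = [e for e in decels if e.kind == kind]
        depths = [baseline - e.extremum_bpm for e in of_kind]
        lags = [e.lag_vs_uc_peak_s for e in of_kind if e.lag_vs_uc_peak_s is not None]
        f[f"{kind}_count"] = float(len(of_kind))
        f[f"{kind}_total_duration_s"] = float(sum(e.duration_s for e in of_kind))
        f[f"{kind}_mean_depth_bpm"] = float(np.mean(depths)) if depths else 0.0
        f[f"{kind}_mean_lag_s"] = float(np.mean(lags)) if lags else 0.0

    all_depths = [baseline - e.extremum_bpm for e in decels]
    f["decel_count"] = float(len(decels))
    f["decel_total_duration_s"] = float(sum(e.duration_s for e in decels))
    f["decel_max_depth_bpm"] = float(max(all_depths)) if all_depths else 0.0

    peaks = detect_contractions(uc)
    f["uc_contraction_count"] = float(len(peaks))
    f["uc_mean_interval_s"] = (
        float(np.mean(np.diff(peaks)) / rate) if len(peaks) >= 2 else 0.0
    )
    f["uc_mean_amplitude"] = float(uc[peaks].mean() - uc.min()) if len(peaks) else 0.0
    f["decels_per_contraction"] = (
        float(len(decels) / len(peaks)) if len(peaks) else 0.0
    )

    f["fhr_mean_bpm"] = float(x.mean())
    f["fhr_std_bpm"] = float(x.std())
    f["fhr_min_bpm"] = float(x.min())
    f["fhr_max_bpm"] = float(x.max())
    return FeatureVector(f)
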