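"""FHR/UC cleaning chain and pre-delivery segment extraction.

Pipeline order: truncate at the first >=15 s zero run, mask remaining zeros
and out-of-range values (>=200 or <=50 bpm), mask spikes deviating >25 bpm
from their 15 s window mean, linearly interpolate everything masked, smooth
UC with a centered 60 s moving average, then cut the 30-minute segment
ending 20 minutes before delivery.  All boundary semantics are strict as
stated: 200 and 50 are removed, a 25.0 bpm deviation is kept, a run of
exactly 15.0 s triggers truncation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .records import SAMPLE_RATE_HZ, CtgTrace

logger = logging.getLogger(__name__)


class UnusableTraceError(ValueError):
    """The trace cannot yield a usable cleaned segment."""


class InsufficientCoverageError(ValueError):
    """The trace does not span the required pre-delivery window."""


@dataclass
class CleaningParams:
    """Thresholds of the cleaning rules (seconds and bpm).

    ``truncate_on_long_zero_run`` keeps data before the first qualifying
    zero run and drops the rest; switching it off masks those zeros like
    any others instead.
    """

    zero_run_discontinue_s: float = 15.0
    fhr_max_bpm: float = 200.0   # inclusive removal: >= max removed
    fhr_min_bpm: float = 50.0    # inclusive removal: <= min removed
    spike_window_s: float = 15.0
    spike_max_dev_bpm: float = 25.0  # strict: dev > threshold removed
    uc_smooth_window_s: float = 60.0
    segment_len_s: float = 1800.0
    segment_end_offset_s: float = 1200.0
    truncate_on_long_zero_run: bool = True

    def __post_init__(self) -> None:
        for name in ("zero_run_discontinue_s", "fhr_max_bpm", "fhr_min_bpm",
                     "spike_window_s", "spike_max_dev_bpm", "uc_smooth_window_s",
                     "segment_len_s", "segment_end_offset_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CleanTrace:
    """A cleaned, fixed-length segment plus cleaning provenance.

    ``mask`` flags every segment sample: True = interpolated (was removed by
    some rule), False = observed.  ``truncation_point`` is the sample index
    (in the raw trace) where a qualifying zero run discontinued measurement,
    if any.  ``segment_start_index`` maps segment sample i back to raw
    sample ``segment_start_index + i`` of the (truncated) trace.
    """

    trace: CtgTrace
    mask: np.ndarray
    truncation_point: int | None
    removal_counts: dict[str, int] = field(default_factory=dict)
    segment_start_index: int = 0


def _zero_runs(fhr: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of exact zeros."""
    is_zero = np.r_[False, fhr == 0.0, False]
    starts = np.nonzero(is_zero[1:] & ~is_zero[:-1])[0]
    ends = np.nonzero(~is_zero[1:] & is_zero[:-1])[0]
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def truncate_at_zero_run(
    trace: CtgTrace, params: CleaningParams | None = None
) -> tuple[CtgTrace, int | None]:
    """Cut the trace at the first zero run lasting >= the discontinue span."""
    params = params or CleaningParams()
    if not params.truncate_on_long_zero_run:
        return trace, None
    min_len = int(round(params.zero_run_discontinue_s * trace.sample_rate))
    for start, length in _zero_runs(trace.fhr):
        if length >= min_len:
            if start < 1:
                raise UnusableTraceError(
                    "qualifying zero run at trace start leaves no data"
                )
            logger.info(
                "case %s: discontinued at sample %d (%.2f s zero run)",
                trace.case_id, start, length / trace.sample_rate,
            )
            return trace.slice(0, start), start
    return trace, None


def mask_invalid(
    fhr: np.ndarray, params: CleaningParams | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """NaN-out zeros and out-of-range values; count removals per rule."""
    params = params or CleaningParams()
    out = np.asarray(fhr, dtype=float).copy()
    finite = np.isfinite(out)
    zero = finite & (out == 0.0)
    high = finite & (out >= params.fhr_max_bpm)
    low = finite & (out <= params.fhr_min_bpm) & ~zero
    counts = {
        "zero": int(zero.sum()),
        "range_high": int(high.sum()),
        "range_low": int(low.sum()),
    }
    out[zero | high | low] = np.nan
    return out, counts


def mask_spikes(
    fhr: np.ndarray, params: CleaningParams | None = None
) -> tuple[np.ndarray, int]:
    """NaN-out samples deviating > 25 bpm from their 15 s window mean.

    Single pass: every decision uses the pre-pass values.  The window is
    centered on the sample (clipped at the edges); already-missing samples
    are excluded from the window mean.  A window holding only the sample
    itself has deviation 0 and is left untouched.
    """
    params = params or CleaningParams()
    x = np.asarray(fhr, dtype=float)
    n = len(x)
    if n == 0:
        return x.copy(), 0
    half = int(round(params.spike_window_s * SAMPLE_RATE_HZ / 2))
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    csum = np.r_[0.0, np.cumsum(vals)]
    ccnt = np.r_[0, np.cumsum(finite)]
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    wsum = csum[hi] - csum[lo]
    wcnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        wmean = wsum / wcnt
        dev = np.abs(x - wmean)
    spike = finite & (wcnt > 0) & (dev > params.spike_max_dev_bpm)
    out = x.copy()
    out[spike] = np.nan
    return out, int(spike.sum())


def interpolate_gaps(fhr: np.ndarray) -> np.ndarray:
    """Fill NaN gaps by linear interpolation; edges extend the nearest value."""
    x = np.asarray(fhr, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise UnusableTraceError("all samples missing; unusable trace")
    if finite.all():
        return x.copy()
    idx = np.arange(len(x))
    return np.interp(idx, idx[finite], x[finite])


def smooth_uc(uc: np.ndarray, params: CleaningParams | None = None) -> np.ndarray:
    """Centered 60 s moving average of the UC channel, length preserved.

    The kernel spans window+1 samples with half weights at both ends
    (normalizing to the stated window length), which keeps the average
    symmetric: constants and the interior of linear ramps pass unchanged.
    Near the edges the window shrinks symmetrically.
    """
    params = params or CleaningParams()
    x = np.asarray(uc, dtype=float)
    n = len(x)
    if n == 0:
        return x.copy()
    w = int(round(params.uc_smooth_window_s * SAMPLE_RATE_HZ))
    half = w // 2
    csum = np.r_[0.0, np.cumsum(x)]
    out = x.copy()
    if n > 2 * half:  # full-width interior, vectorized
        i = np.arange(half, n - half)
        inner = csum[i + half] - csum[i - half + 1]  # full-weight samples
        out[i] = (inner + 0.5 * (x[i - half] + x[i + half])) / (2 * half)
    for i in range(min(half, n)):  # shrunk edge windows
        for j in (i, n - 1 - i):
            h = min(j, n - 1 - j, half)
            if h > 0:
                inner = csum[j + h] - csum[j - h + 1]
                out[j] = (inner + 0.5 * (x[j - h] + x[j + h])) / (2 * h)
    return out


def extract_segment(
    trace: CtgTrace, params: CleaningParams | None = None
) -> tuple[CtgTrace, int]:
    """Cut the [delivery-50 min, delivery-20 min) window: exactly 7200 samples.

    Returns the segment trace and its start index in the input.  The output
    trace carries ``delivery_time_s = segment_len + offset`` so that
    re-extraction returns the segment itself.
    """
    params = params or CleaningParams()
    rate = trace.sample_rate
    span_s = params.segment_len_s + params.segment_end_offset_s
    start_t = trace.delivery_time_s - span_s
    n_seg = int(round(params.segment_len_s * rate))
    start = int(round(start_t * rate))
    if start < 0:
        raise InsufficientCoverageError(
            f"insufficient pre-delivery coverage: trace starts "
            f"{-start_t:.2f} s too late"
        )
    if start + n_seg > len(trace):
        missing = (start + n_seg - len(trace)) / rate
        raise InsufficientCoverageError(
            f"insufficient pre-delivery coverage: trace ends {missing:.2f} s "
            f"before the segment window closes"
        )
    return trace.slice(start, start + n_seg, delivery_time_s=span_s), start


def clean(trace: CtgTrace, params: CleaningParams | None = None) -> CleanTrace:
    """Run the full cleaning chain and return the fixed-length segment.

    Deterministic composition: truncate -> mask_invalid -> mask_spikes ->
    interpolate -> smooth_uc -> extract_segment.  Idempotent: the output
    trace re-enters the chain unchanged (UC smoothing is recorded on the
    trace and not applied twice).
    """
    params = params or CleaningParams()
    truncated, trunc_point = truncate_at_zero_run(trace, params)
    masked, counts = mask_invalid(truncated.fhr, params)
    masked, n_spikes = mask_spikes(masked, params)
    counts["spike"] = n_spikes
    removed = ~np.isfinite(masked)
    fhr = interpolate_gaps(masked)
    uc = truncated.uc if truncated.uc_smoothed else smooth_uc(truncated.uc, params)
    full = CtgTrace(
        case_id=truncated.case_id,
        fhr=fhr,
        uc=uc,
        delivery_time_s=truncated.delivery_time_s,
        uc_smoothed=True,
    )
    segment, start = extract_segment(full, params)
    mask = removed[start : start + len(segment)].copy()
    counts["interpolated_in_segment"] = int(mask.sum())
    logger.info(
        "case %s: removals %s; segment of %d samples", trace.case_id, counts,
        len(segment),
    )
    return CleanTrace(
        trace=segment,
        mask=mask,
        truncation_point=trunc_point,
        removal_counts=counts,
        segment_start_index=start,
    )
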