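"""Core domain records shared across the package.

Traces carry fetal heart rate (FHR, bpm) sampled at 4 Hz together with a
relative uterine-contraction (UC) strength channel.  Missing FHR samples are
represented as NaN; an exact 0 in a *raw* trace encodes transducer dropout
and is never used as a missing marker after cleaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SAMPLE_RATE_HZ = 4

PH_MIN, PH_MAX = 6.5, 7.8


class TraceError(ValueError):
    """Raised when a trace violates its structural invariants."""


@dataclass
class CtgTrace:
    """One CTG recording: FHR + UC at a fixed 4 Hz sample rate.

    Parameters
    ----------
    case_id : str
        Opaque case identifier.
    fhr : array-like of float
        Fetal heart rate in bpm.  NaN marks a masked (missing) sample.
    uc : array-like of float
        Relative uterine-contraction strength, same length as ``fhr``.
    delivery_time_s : float
        Delivery time in seconds from trace start.
    sample_rate : int
        Samples per second; fixed at 4.
    uc_smoothed : bool
        Set once the UC channel has been moving-average smoothed, so that
        re-cleaning does not smooth twice.
    """

    case_id: str
    fhr: np.ndarray
    uc: np.ndarray
    delivery_time_s: float
    sample_rate: int = SAMPLE_RATE_HZ
    uc_smoothed: bool = False

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.uc = np.asarray(self.uc, dtype=float)
        if self.fhr.ndim != 1 or self.uc.ndim != 1:
            raise TraceError("fhr and uc must be 1-D")
        if len(self.fhr) != len(self.uc):
            raise TraceError(
                f"fhr and uc length mismatch: {len(self.fhr)} != {len(self.uc)}"
            )
        if self.sample_rate != SAMPLE_RATE_HZ:
            raise TraceError(f"sample_rate must be {SAMPLE_RATE_HZ} Hz")
        if self.delivery_time_s < 0:
            raise TraceError("delivery_time_s must be >= 0")

    def __len__(self) -> int:
        return len(self.fhr)

    @property
    def duration_s(self) -> float:
        return len(self.fhr) / self.sample_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.fhr)) / self.sample_rate

    def slice(self, start: int, stop: int, delivery_time_s: float | None = None) -> "CtgTrace":
        return replace(
            self,
            fhr=self.fhr[start:stop].copy(),
            uc=self.uc[start:stop].copy(),
            delivery_time_s=self.delivery_time_s
            if delivery_time_s is None
            else delivery_time_s,
        )

    def equals(self, other: "CtgTrace") -> bool:
        return (
            self.case_id == other.case_id
            and self.sample_rate == other.sample_rate
            and self.uc_smoothed == other.uc_smoothed
            and np.isclose(self.delivery_time_s, other.delivery_time_s)
            and len(self) == len(other)
            and np.allclose(self.fhr, other.fhr, equal_nan=True)
            and np.allclose(self.uc, other.uc, equal_nan=True)
        )


@dataclass(frozen=True)
class OutcomeRecord:
    """Neonatal outcome fields for one delivery."""

    case_id: str
    apgar_1min: int
    apgar_5min: int
    ua_ph: float

    def __post_init__(self) -> None:
        for name in ("apgar_1min", "apgar_5min"):
            v = getattr(self, name)
            if not 0 <= v <= 10:
                raise ValueError(f"{name}={v} outside [0, 10]")
        if not PH_MIN <= self.ua_ph <= PH_MAX:
            raise ValueError(f"ua_ph={self.ua_ph} outside [{PH_MIN}, {PH_MAX}]")


RATER_CLASSES = ("obstetrician", "midwife")


@dataclass(frozen=True)
class RaterResponse:
    rater_id: str
    rater_class: str
    judgment: bool  # True = judged positive (asphyxia)

    def __post_init__(self) -> None:
        if self.rater_class not in RATER_CLASSES:
            raise ValueError(f"unknown rater_class {self.rater_class!r}")


@dataclass
class RaterResponseSet:
    """All rater judgments collected for one case."""

    case_id: str
    responses: list[RaterResponse] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.rater_id for r in self.responses]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate rater_id for case {self.case_id}")

    def __len__(self) -> int:
        return len(self.responses)


@dataclass
class CaseRecord:
    """One delivery joined across outcome, rater and model-score channels.

    ``human_ratio``, ``dl_score`` live in [0, 1]; ``fused_sum`` in [0, 2];
    ``fused_product`` in [0, 1].  Fused fields are present only when both
    inputs are.
    """

    case_id: str
    truth: bool
    outcome: OutcomeRecord | None = None
    responses: RaterResponseSet | None = None
    human_ratio: float | None = None
    dl_score: float | None = None
    ml_call: bool | None = None
    fused_sum: float | None = None
    fused_product: float | None = None

    def __post_init__(self) -> None:
        for name, hi in (("human_ratio", 1.0), ("dl_score", 1.0),
                         ("fused_sum", 2.0), ("fused_product", 1.0)):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= hi:
                raise ValueError(f"{name}={v} outside [0, {hi}]")


def as_bool_array(values: Sequence) -> np.ndarray:
    return np.asarray(values, dtype=bool)
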