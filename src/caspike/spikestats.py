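"""Per-cell spiking statistics and cohort aggregates.

Waiting times are measured maximum-to-maximum between consecutive
validated peaks.  The regularity of the spike train is summarized by the
lag-1 autocorrelation of the waiting-time sequence: negative values mean
short and long intervals alternate (anti-persistent spiking), positive
values mean long intervals tend to follow long ones (persistent spiking).
A cell is "actively responding" when it carries at least ``active_min``
validated peaks (default 3) in the recording window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .peaks import Peak

__all__ = [
    "SpikingProfile",
    "CohortSummary",
    "waiting_times",
    "lag1_autocorrelation",
    "classify_acf",
    "classify_active",
    "build_profile",
    "summarize_cohort",
    "ACF_CUTOFF",
    "ACTIVE_MIN",
]

#: default |r1| band outside which an autocorrelation is called a trend
ACF_CUTOFF = 0.2
#: default minimum validated peak count for an actively responding cell
ACTIVE_MIN = 3


@dataclass
class SpikingProfile:
    """Validated peaks and interval statistics for one cell."""

    sample_id: str
    peaks: list[Peak]
    waiting_times: list[float]
    mean_waiting_time: float | None
    acf1: float | None
    active: bool


@dataclass
class CohortSummary:
    """Aggregates over one cohort of profiles; means are over active cells."""

    n_samples: int
    n_active: int
    fraction_active: float
    mean_peaks_active: float | None
    mean_waiting_time: float | None
    acf_classes: tuple[int, int, int]  # (negative, neutral, positive)


def waiting_times(peaks: list[Peak], dt: float) -> list[float]:
    """Seconds between consecutive peak maxima (requires sorted peaks)."""
    idx = [p.i_max for p in peaks]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("peaks must be sorted by ascending i_max")
    return [(b - a) * dt for a, b in zip(idx, idx[1:])]


def lag1_autocorrelation(x) -> float | None:
    """Sample lag-1 autocorrelation, or None when undefined.

    r1 = sum_{j<m-1} (x_j - xbar)(x_{j+1} - xbar) / sum_j (x_j - xbar)^2
    with a single global mean and the full-sequence denominator.  Undefined
    (None) for fewer than 3 values or zero variance.
    """
    x = np.asarray(x, dtype=float)
    m = len(x)
    if m < 3:
        return None
    dev = x - x.mean()
    denom = float(np.sum(dev * dev))
    if denom == 0.0:
        return None
    return float(np.sum(dev[:-1] * dev[1:]) / denom)


def classify_acf(r: float | None, cutoff: float = ACF_CUTOFF) -> str:
    """'negative' if r < -cutoff, 'positive' if r > cutoff, else 'neutral';
    None propagates as 'undefined'."""
    if r is None:
        return "undefined"
    if r < -cutoff:
        return "negative"
    if r > cutoff:
        return "positive"
    return "neutral"


def classify_active(profile: SpikingProfile, active_min: int = ACTIVE_MIN) -> bool:
    """True iff the cell carries at least ``active_min`` validated peaks."""
    return len(profile.peaks) >= active_min


def build_profile(
    sample_id: str,
    peaks: list[Peak],
    dt: float,
    active_min: int = ACTIVE_MIN,
) -> SpikingProfile:
    """Assemble the per-cell profile from a validated peak list."""
    wt = waiting_times(peaks, dt)
    return SpikingProfile(
        sample_id=sample_id,
        peaks=peaks,
        waiting_times=wt,
        mean_waiting_time=float(np.mean(wt)) if wt else None,
        acf1=lag1_autocorrelation(wt),
        active=len(peaks) >= active_min,
    )


def summarize_cohort(
    profiles: list[SpikingProfile], cutoff: float = ACF_CUTOFF
) -> CohortSummary:
    """Cohort aggregates; peak-count and waiting-time means cover active
    cells only, and acf classes count only cells with a defined acf1."""
    if not profiles:
        raise ValueError("cannot summarize an empty cohort")
    active = [p for p in profiles if p.active]
    counts = {"negative": 0, "neutral": 0, "positive": 0}
    for p in profiles:
        cls = classify_acf(p.acf1, cutoff)
        if cls != "undefined":
            counts[cls] += 1
    wt_means = [p.mean_waiting_time for p in active if p.mean_waiting_time is not None]
    return CohortSummary(
        n_samples=len(profiles),
        n_active=len(active),
        fraction_active=len(active) / len(profiles),
        mean_peaks_active=float(np.mean([len(p.peaks) for p in active])) if active else None,
        mean_waiting_time=float(np.mean(wt_means)) if wt_means else None,
        acf_classes=(counts["negative"], counts["neutral"], counts["positive"]),
    )
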