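"""Shape-based peak detection with control-calibrated validation.

A candidate maximum is a point where the estimated first derivative
crosses from positive to non-positive and the second derivative is
negative — the discrete surrogate of f' = 0, f'' < 0.  Each candidate is
scored by a continuous merit function whose three factors encode the
logical conditions f > delta (value), -xi < f' < gamma (trend) and f'' < 0
(curvature/asymmetry); a candidate is a peak iff its merit exceeds the
threshold tau.  Peaks are delimited by the neighbouring troughs of the
derivative, integrated above the linear chord between their endpoints
(drift-invariant intensity), and finally validated against the q-quantile
of "false peak" intensities harvested from an untreated control set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .savgol import FilterParams, FilteredTrace, filter_trace

__all__ = [
    "DetectionParams",
    "Peak",
    "candidate_maxima",
    "peak_merit",
    "delimit_peak",
    "peak_intensity",
    "detect_peaks",
    "control_threshold",
    "validate_peaks",
    "estimate_detection_params",
]

logger = logging.getLogger("caspike")

#: slope-tolerance floor (signal units per second).  A peak apex that falls
#: between two samples leaves |f'| up to |f''|*dt/2 at the nearest sample,
#: far above the control-noise derivative scale, so a purely noise-derived
#: xi/gamma would clamp the trend factor to zero for every true peak.
SLOPE_TOLERANCE_FLOOR = 0.5

#: quantile of |f - rolling median| used for the data-driven height threshold
DELTA_RESIDUAL_QUANTILE = 0.9


@dataclass(frozen=True)
class DetectionParams:
    """Peak-detection thresholds.

    delta  height threshold in signal units (value condition f > delta)
    xi     tolerance for negative slope at the apex, signal units / s
    gamma  tolerance for positive slope at the apex, signal units / s
    tau    merit threshold; a candidate is a peak iff merit > tau
    q      validation quantile in [0, 1] applied to control false-peak
           intensities
    """

    delta: float
    xi: float = SLOPE_TOLERANCE_FLOOR
    gamma: float = SLOPE_TOLERANCE_FLOOR
    tau: float = 1.0
    q: float = 0.9

    def __post_init__(self) -> None:
        if self.xi <= 0 or self.gamma <= 0:
            raise ValueError("xi and gamma must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")


@dataclass(frozen=True)
class Peak:
    """One detected peak: apex index, start/end indices, amplitude above
    the start-end chord, chord-corrected area (signal * seconds) and the
    merit score that admitted it."""

    i_max: int
    t_s: int
    t_e: int
    amplitude: float
    intensity: float
    merit: float

    def __post_init__(self) -> None:
        if not self.t_s < self.i_max < self.t_e:
            raise ValueError(
                f"peak indices must satisfy t_s < i_max < t_e "
                f"(got {self.t_s}, {self.i_max}, {self.t_e})"
            )


def _interior(trace: FilteredTrace) -> tuple[int, int]:
    """First and last index eligible for peak calling (edges excluded)."""
    return trace.n, len(trace) - 1 - trace.n


def _slope_eps(trace: FilteredTrace) -> float:
    """Numerical zero for derivative sign decisions.

    An exactly flat stretch leaves O(1e-15) round-off in the derivative
    estimates; slopes that would take ~1e8 samples to traverse the signal
    range are treated as zero so such stretches produce no crossings.
    """
    scale = max(1.0, float(np.max(np.abs(trace.f))))
    return 1e-8 * scale / trace.dt


def candidate_maxima(trace: FilteredTrace) -> list[int]:
    """Indices where d1 crosses + -> <=0 and d2 < 0 (discrete maxima).

    The crossing between i and i+1 is assigned to whichever of the pair has
    the larger smoothed value (leftmost on a tie, so a flat plateau apex
    resolves to its left edge).  The first/last n edge points are excluded.
    """
    lo, hi = _interior(trace)
    d1, d2, f = trace.d1, trace.d2, trace.f
    eps = _slope_eps(trace)
    eps2 = eps / trace.dt
    out: list[int] = []
    for i in range(lo, hi):
        if d1[i] > eps >= d1[i + 1]:
            j = i if f[i] >= f[i + 1] else i + 1
            if lo < j < hi and d2[j] < -eps2 and (not out or out[-1] != j):
                out.append(j)
    return out


def peak_merit(trace: FilteredTrace, i: int, params: DetectionParams) -> float:
    """Continuous peak score peak_c(i) for a candidate index.

    peak_c(i) = max(f_i - delta, 0)
              * max(1 - |f'_i| * (1/xi + 1/gamma)/2, 0)
              * max(-f''_i * dt^2, 0)

    Each factor vanishes exactly where the corresponding logical condition
    (f_i > delta; -xi < f'_i < gamma; f''_i < 0) fails, and the score is 1
    at the reference point f_i = delta + 1, f'_i = 0, f''_i * dt^2 = -1.
    The curvature is expressed per sampling interval squared — the same
    convention in which the window width w is specified — so that merit is
    O(1) for peaks a few samples wide and the useful range of tau is ~1-2.
    """
    lo, hi = _interior(trace)
    if not lo <= i <= hi:
        raise ValueError(f"index {i} is not an interior candidate index")
    value = max(float(trace.f[i]) - params.delta, 0.0)
    trend = max(1.0 - abs(float(trace.d1[i])) * (1.0 / params.xi + 1.0 / params.gamma) / 2.0, 0.0)
    curvature = max(-float(trace.d2[i]) * trace.dt**2, 0.0)
    return value * trend * curvature


def _troughs(trace: FilteredTrace) -> list[int]:
    """Indices where d1 crosses from non-positive to non-negative.

    The crossing between i and i+1 is assigned to whichever of the pair has
    the smaller smoothed value (leftmost on a tie), so two adjacent peaks
    that share a trough delimit to the same index.  A descent that levels
    out into a flat stretch ends at the levelling point, and a flat stretch
    that starts rising troughs at the rise base.
    """
    d1, f = trace.d1, trace.f
    eps = _slope_eps(trace)
    out: list[int] = []
    for i in range(len(trace) - 1):
        if (d1[i] < -eps <= d1[i + 1]) or (d1[i] <= eps < d1[i + 1]):
            j = i if f[i] <= f[i + 1] else i + 1
            if not out or out[-1] != j:
                out.append(j)
    return out


def delimit_peak(trace: FilteredTrace, i_max: int) -> tuple[int, int]:
    """Start/end indices of the peak around ``i_max``.

    t_s is the nearest derivative trough left of the apex (the preceding
    minimum), t_e the nearest trough to its right; either falls back to the
    first/last non-edge index when the peak is truncated by the record
    boundary.  Guarantees t_s < i_max < t_e.
    """
    lo, hi = _interior(trace)
    troughs = _troughs(trace)
    t_s = max((j for j in troughs if j < i_max), default=lo)
    t_e = min((j for j in troughs if j > i_max), default=hi)
    t_s = max(min(t_s, i_max - 1), 0)
    t_e = min(max(t_e, i_max + 1), len(trace) - 1)
    return t_s, t_e


def peak_intensity(trace: FilteredTrace, t_s: int, t_e: int, dt: float | None = None) -> float:
    """Area of the smoothed trace above the chord joining (t_s, f) to
    (t_e, f), in signal * seconds, clamped at zero.

    Subtracting the linear chord makes the measure invariant to constant
    offsets and to linear baseline drift.
    """
    if t_s >= t_e:
        raise ValueError(f"t_s must precede t_e (got {t_s} >= {t_e})")
    dt = trace.dt if dt is None else dt
    seg = trace.f[t_s:t_e + 1]
    chord = np.linspace(seg[0], seg[-1], len(seg))
    return max(float(np.trapezoid(seg - chord, dx=dt)), 0.0)


def _chord_value(trace: FilteredTrace, t_s: int, t_e: int, i: int) -> float:
    frac = (i - t_s) / (t_e - t_s)
    return float(trace.f[t_s]) + frac * (float(trace.f[t_e]) - float(trace.f[t_s]))


def detect_peaks(trace: FilteredTrace, params: DetectionParams) -> list[Peak]:
    """Full per-trace detection: candidates, merit > tau, delimitation,
    amplitude and intensity.  Returns peaks sorted by apex index."""
    peaks: list[Peak] = []
    for i in candidate_maxima(trace):
        merit = peak_merit(trace, i, params)
        if merit <= params.tau:
            continue
        t_s, t_e = delimit_peak(trace, i)
        amplitude = float(trace.f[i]) - _chord_value(trace, t_s, t_e, i)
        intensity = peak_intensity(trace, t_s, t_e)
        peaks.append(Peak(i, t_s, t_e, amplitude, intensity, merit))
    return peaks


def control_threshold(
    control, fparams: FilterParams, dparams: DetectionParams
) -> float:
    """Intensity below which a treatment peak is not significant.

    Runs the detection pipeline with tau = 0 on every control trace to
    harvest false peaks, then returns the q-quantile (linear interpolation
    between order statistics) of their intensities; 0 when the control
    yields no false peaks at all.
    """
    if control.n_samples == 0:
        raise ValueError("control set is empty")
    harvest = replace(dparams, tau=0.0)
    intensities: list[float] = []
    for sid in control.sample_ids:
        trace = filter_trace(control.trace(sid), fparams, control.dt)
        intensities.extend(p.intensity for p in detect_peaks(trace, harvest))
    if not intensities:
        return 0.0
    return float(np.quantile(np.array(intensities), dparams.q, method="linear"))


def validate_peaks(peaks: list[Peak], threshold: float) -> list[Peak]:
    """Peaks whose intensity is strictly greater than the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return [p for p in peaks if p.intensity > threshold]


def estimate_detection_params(
    control,
    fparams: FilterParams,
    tau: float = 1.0,
    q: float = 0.9,
    slope_floor: float = SLOPE_TOLERANCE_FLOOR,
) -> DetectionParams:
    """Data-driven delta/xi/gamma from the control set.

    delta is the control median plus the 90th percentile of the absolute
    deviation of the smoothed control from its rolling median (a robust
    noise-band estimate); xi and gamma are three robust standard deviations
    (1.4826 * MAD) of the control's first-derivative estimate, floored at
    ``slope_floor`` to admit the slope offset of a discretely sampled apex.
    """
    from scipy.ndimage import median_filter

    if control.n_samples == 0:
        raise ValueError("control set is empty")
    f_all, d1_all = [], []
    for sid in control.sample_ids:
        trace = filter_trace(control.trace(sid), fparams, control.dt)
        f_all.append(trace.f)
        d1_all.append(trace.d1)
    f = np.concatenate(f_all)
    d1 = np.concatenate(d1_all)
    resid = [np.abs(t - median_filter(t, size=fparams.w, mode="nearest")) for t in f_all]
    delta = float(np.median(f)) + float(
        np.quantile(np.concatenate(resid), DELTA_RESIDUAL_QUANTILE)
    )
    robust_sd = 1.4826 * float(np.median(np.abs(d1 - np.median(d1))))
    slope = max(3.0 * robust_sd, slope_floor)
    logger.debug(
        "estimated detection params: delta=%.6g xi=gamma=%.6g", delta, slope
    )
    return DetectionParams(delta=delta, xi=slope, gamma=slope, tau=tau, q=q)
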