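"""Ground-truthed synthetic spiking cohorts.

Emulates 30-minute ratiometric recordings sampled every 5 s (360 points):
a baseline with optional linear drift, additive Gaussian noise, and
asymmetric spikes (fast rise, slow decay — a normalized double-exponential
kernel) planted at event times drawn from one of three waiting-time
regimes:

* ``Exponential`` — iid intervals (memoryless spiking),
* ``Alternating`` — strict short/long alternation (anti-persistent,
  negative interval autocorrelation),
* ``AR1`` — first-order autoregressive intervals with positive phi
  (persistent: long intervals follow long ones).

All intervals respect a refractory floor (default 45 s, about one visible
peak duration) so planted peaks never merge ambiguously.  A seed fully
determines the output.  The
matched control cohort shares baseline, drift and noise but carries no
events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log

import numpy as np
import pandas as pd

from .series_io import TimeSeriesSet, write_series_file

__all__ = [
    "Exponential",
    "Alternating",
    "AR1",
    "GenSpec",
    "kernel_apex_time",
    "peak_kernel_value",
    "gen_peak_kernel",
    "draw_intervals",
    "gen_trace",
    "gen_cohort",
    "write_cohort",
]

#: kernel samples below this fraction of the apex are truncated
KERNEL_TRUNCATION = 0.01


@dataclass(frozen=True)
class Exponential:
    """iid intervals: refractory floor + Exponential(mean - floor)."""

    mean: float = 150.0


@dataclass(frozen=True)
class Alternating:
    """Strict short/long alternation with Gaussian jitter (anti-persistent)."""

    short: float = 80.0
    long: float = 220.0
    jitter_sd: float = 8.0


@dataclass(frozen=True)
class AR1:
    """First-order autoregressive intervals (persistent for phi > 0)."""

    mean: float = 150.0
    phi: float = 0.8
    sd: float = 50.0


WaitingModel = Exponential | Alternating | AR1


@dataclass(frozen=True)
class GenSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate the acquisition regime of FRET-ratio spiking records:
    360 points at 5 s; ratio baseline 1.0 with a mild upward drift;
    spikes of apex amplitude 3.0 with 5 s rise and 20 s decay constants
    (≈45 s visible duration, matching the default filter window);
    waiting times exponential with mean 150 s.
    """

    n_cells: int = 5
    n_points: int = 360
    dt: float = 5.0
    rise: float = 5.0
    decay: float = 20.0
    amplitude: float = 3.0
    refractory_s: float = 45.0
    waiting: WaitingModel | None = field(default_factory=Exponential)
    baseline: float = 1.0
    drift: float = 5e-5  # signal units per second
    noise_sd: float = 0.02
    t_start: float = 50.0  # earliest event onset, seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.decay > self.rise > 0:
            raise ValueError("need decay > rise > 0 (fast rise, slow decay)")
        if self.n_points < 2 or self.dt <= 0:
            raise ValueError("need n_points >= 2 and dt > 0")
        if self.noise_sd < 0 or self.amplitude <= 0:
            raise ValueError("noise_sd must be >= 0 and amplitude > 0")
        if self.refractory_s < 3.0 * self.rise:
            raise ValueError("refractory_s must be at least 3x the rise constant")

    @property
    def refractory(self) -> float:
        """Minimum interval between events, seconds.

        Defaults to ~one visible peak duration (45 s) so that consecutive
        planted spikes remain visually distinct and never merge ambiguously;
        it can never drop below three rise times.
        """
        return self.refractory_s

    @property
    def duration(self) -> float:
        return self.n_points * self.dt


def kernel_apex_time(rise: float, decay: float) -> float:
    """Time of the double-exponential apex: t* = ln(decay/rise)/(1/rise - 1/decay)."""
    return log(decay / rise) / (1.0 / rise - 1.0 / decay)


def peak_kernel_value(t, rise: float, decay: float, amplitude: float):
    """Double-exponential spike shape, scaled to apex ``amplitude``; zero
    for t <= 0."""
    t = np.asarray(t, dtype=float)
    t_star = kernel_apex_time(rise, decay)
    norm = np.exp(-t_star / decay) - np.exp(-t_star / rise)
    with np.errstate(over="ignore"):
        raw = np.where(t > 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    return amplitude * raw / norm


def gen_peak_kernel(rise: float, decay: float, amplitude: float, dt: float) -> np.ndarray:
    """Kernel sampled on the dt grid from t = 0, truncated where the decay
    tail falls below 1% of the apex."""
    if not decay > rise > 0:
        raise ValueError("need decay > rise > 0")
    t_star = kernel_apex_time(rise, decay)
    # generous grid, then trim trailing samples below 1% of the apex
    norm = np.exp(-t_star / decay) - np.exp(-t_star / rise)
    t_end = -decay * log(KERNEL_TRUNCATION * norm)
    t = np.arange(0.0, t_end + dt, dt)
    kern = peak_kernel_value(t, rise, decay, amplitude)
    keep = np.nonzero(kern >= KERNEL_TRUNCATION * amplitude)[0]
    return kern[: keep[-1] + 1]


def draw_intervals(model: WaitingModel, rng: np.random.Generator, size: int,
                   floor: float = 0.0) -> np.ndarray:
    """Draw ``size`` waiting times (seconds) from one regime, respecting
    the refractory floor."""
    if isinstance(model, Exponential):
        if model.mean <= floor:
            raise ValueError("exponential mean must exceed the refractory floor")
        return floor + rng.exponential(model.mean - floor, size)
    if isinstance(model, Alternating):
        phase = int(rng.integers(2))
        base = np.where(np.arange(size) % 2 == phase, model.short, model.long)
        return np.maximum(base + rng.normal(0.0, model.jitter_sd, size), floor)
    if isinstance(model, AR1):
        sd0 = model.sd / np.sqrt(max(1.0 - model.phi**2, 1e-12))
        out = np.empty(size)
        x = model.mean + rng.normal(0.0, sd0)
        for i in range(size):
            out[i] = max(x, floor)
            x = model.mean + model.phi * (x - model.mean) + rng.normal(0.0, model.sd)
        return out
    raise TypeError(f"unknown waiting model {model!r}")


def _event_onsets(spec: GenSpec, rng: np.random.Generator) -> np.ndarray:
    t_star = kernel_apex_time(spec.rise, spec.decay)
    # keep every apex clear of the record tail so the planted truth is
    # recoverable (no boundary-truncated events)
    margin = 8 * spec.dt
    latest_apex = spec.duration - margin
    # draw the whole interval sequence in one call so that sequential
    # structure (alternation phase, AR(1) state) is preserved
    n_max = int(np.ceil(spec.duration / spec.refractory)) + 2
    intervals = draw_intervals(spec.waiting, rng, n_max, spec.refractory)
    t0 = spec.t_start + float(rng.uniform(0.0, spec.dt))
    times = t0 + np.concatenate([[0.0], np.cumsum(intervals)])
    return times[times + t_star <= latest_apex]


def gen_trace(spec: GenSpec, rng: np.random.Generator | None = None):
    """One synthetic trace.

    Returns ``(values, apex_times, intervals)`` where ``apex_times`` are the
    planted apex times in seconds and ``intervals`` their differences.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t_grid = np.arange(spec.n_points) * spec.dt
    values = spec.baseline + spec.drift * t_grid
    if spec.waiting is not None:
        onsets = _event_onsets(spec, rng)
    else:
        onsets = np.array([])
    for onset in onsets:
        values = values + peak_kernel_value(
            t_grid - onset, spec.rise, spec.decay, spec.amplitude
        )
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, spec.n_points)
    apex_times = onsets + kernel_apex_time(spec.rise, spec.decay)
    return values, apex_times, np.diff(apex_times)


def gen_cohort(spec: GenSpec, n_cells: int | None = None, seed: int | None = None):
    """Matched treatment/control cohorts plus the planted ground truth.

    Returns ``(treatment, control, truth)`` where the two TimeSeriesSets
    have one ``CELL_i`` column per cell and ``truth`` is a DataFrame with
    one row per planted event (cell_id, apex_time_s, apex_index,
    interval_prev_s).
    """
    n_cells = spec.n_cells if n_cells is None else n_cells
    if n_cells < 1:
        raise ValueError("need at least one cell")
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    children = root.spawn(2 * n_cells)
    ids = tuple(f"CELL_{i + 1}" for i in range(n_cells))
    control_spec = replace(spec, waiting=None)

    treat_cols, rows = [], []
    for i, sid in enumerate(ids):
        vals, apexes, _ = gen_trace(spec, np.random.default_rng(children[i]))
        treat_cols.append(vals)
        prev = np.concatenate([[np.nan], np.diff(apexes)])
        for apex, iv in zip(apexes, prev):
            rows.append({
                "cell_id": sid,
                "apex_time_s": apex,
                "apex_index": int(round(apex / spec.dt)),
                "interval_prev_s": iv,
            })
    ctrl_cols = [
        gen_trace(control_spec, np.random.default_rng(children[n_cells + i]))[0]
        for i in range(n_cells)
    ]
    treatment = TimeSeriesSet(ids, np.column_stack(treat_cols), spec.dt)
    control = TimeSeriesSet(ids, np.column_stack(ctrl_cols), spec.dt)
    truth = pd.DataFrame(
        rows, columns=["cell_id", "apex_time_s", "apex_index", "interval_prev_s"]
    )
    return treatment, control, truth


def write_cohort(treatment: TimeSeriesSet, control: TimeSeriesSet,
                 truth: pd.DataFrame, out_dir) -> None:
    """Emit treatment.txt / control.txt (input dialect) and truth.tsv."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_series_file(treatment, out / "treatment.txt")
    write_series_file(control, out / "control.txt")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
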