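"""I/O for ratiometric spiking time series and analysis reports.

The input dialect is a plain-text, tab-separated table: the first line
starts with ``#`` (a comment/header line), the second line holds the sample
ID codes (e.g. ``CELL_1``), and every following line holds one ratio value
per sample.  All columns must have the same length.  Numbers are written
with full double precision and a locale-independent ``.`` decimal
separator.  Blank trailing lines are ignored; any other deviation from the
dialect is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FormatError",
    "DataError",
    "TimeSeriesSet",
    "SampleResult",
    "RunReport",
    "read_series_file",
    "write_series_file",
    "ratio_from_fluorescence",
    "render_trace_plot",
    "build_trace_figure",
    "write_report",
    "read_report",
]


class FormatError(ValueError):
    """The file does not follow the tab-separated ``#``-headed dialect."""


class DataError(ValueError):
    """The file parses but carries invalid data (non-finite, bad ratio)."""


@dataclass(frozen=True)
class TimeSeriesSet:
    """Named, equal-length ratio traces with a common sampling interval.

    ``values`` has one column per sample (``n_points`` rows); ``dt`` is the
    sampling interval in seconds.
    """

    sample_ids: tuple[str, ...]
    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "sample_ids", ids)
        if not ids:
            raise ValueError("a TimeSeriesSet needs at least one sample")
        if any(not s for s in ids):
            raise ValueError("sample IDs must be non-empty")
        if len(set(ids)) != len(ids):
            raise ValueError("sample IDs must be unique")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != len(ids):
            raise ValueError(
                f"values must be a 2-D array with one column per sample "
                f"(got shape {vals.shape} for {len(ids)} samples)"
            )
        if not np.all(np.isfinite(vals)):
            raise DataError("time series contain non-finite values")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", vals)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    def trace(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


def read_series_file(path, dt: float = 5.0) -> TimeSeriesSet:
    """Read a spiking time-series file in the tab-separated text dialect."""
    with open(path, "r", encoding="utf-8") as fh:
        raw_lines = fh.read().split("\n")
    # blank trailing lines are tolerated; blank lines elsewhere are not
    while raw_lines and raw_lines[-1].strip() == "":
        raw_lines.pop()
    if not raw_lines or not raw_lines[0].lstrip()[:1] == "#":
        raise FormatError(
            "not a spiking time-series file: the first character must be '#' "
            "(comment/header line), followed by a tab-separated sample-ID row"
        )
    if len(raw_lines) < 2:
        raise FormatError("missing sample-ID row (line 2)")
    ids = raw_lines[1].rstrip("\r").split("\t")
    if any(not s.strip() for s in ids):
        raise FormatError("line 2: sample IDs must be non-empty")
    ids = [s.strip() for s in ids]

    rows: list[list[float]] = []
    for lineno, line in enumerate(raw_lines[2:], start=3):
        line = line.rstrip("\r")
        if line.strip() == "":
            raise FormatError(f"line {lineno}: blank line inside the data block")
        cells = line.split("\t")
        if len(cells) != len(ids):
            raise FormatError(
                f"line {lineno}: expected {len(ids)} tab-separated values, "
                f"got {len(cells)} (all columns must have the same length)"
            )
        row = []
        for col, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"line {lineno}, column {col}: non-numeric value {cell!r}"
                ) from None
        if not all(np.isfinite(row)):
            raise DataError(f"line {lineno}: non-finite value")
        rows.append(row)
    if not rows:
        raise FormatError("file contains no data rows")
    return TimeSeriesSet(tuple(ids), np.array(rows, dtype=float), dt)


def write_series_file(ts: TimeSeriesSet, path) -> None:
    """Write a TimeSeriesSet in the input dialect (round-trips exactly)."""
    lines = ["# ", "\t".join(ts.sample_ids)]
    for row in ts.values:
        lines.append("\t".join(repr(float(v)) for v in row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def ratio_from_fluorescence(numerator, denominator) -> np.ndarray:
    """Elementwise ratio of two fluorescence channels (e.g. YFP/CFP).

    The denominator must be strictly positive everywhere.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError(
            f"channel lengths differ: {num.shape} vs {den.shape}"
        )
    bad = np.nonzero(den <= 0)[0]
    if bad.size:
        raise DataError(
            f"denominator channel is not strictly positive at index {bad[0]} "
            f"(value {den[bad[0]]!r})"
        )
    return num / den


# ---------------------------------------------------------------------------
# plotting

def build_trace_figure(raw, filtered, peaks, sample_id: str | None = None):
    """Figure with the raw trace (red), filtered curve (blue) and, per peak,
    a green triangle at the maximum, a blue circle at the start and a green
    cross at the end."""
    import matplotlib.pyplot as plt

    raw = np.asarray(raw, dtype=float)
    if len(raw) != len(filtered.f):
        raise ValueError("raw and filtered traces differ in length")
    t = np.arange(len(raw)) * filtered.dt
    fig, ax = plt.subplots(figsize=(8.0, 3.0))
    ax.plot(t, raw, color="red", linewidth=0.8, label="raw")
    ax.plot(t, filtered.f, color="blue", linewidth=1.2, label="filtered")
    if peaks:
        imax = [p.i_max for p in peaks]
        ts_ = [p.t_s for p in peaks]
        te_ = [p.t_e for p in peaks]
        ax.plot(t[imax], filtered.f[imax], linestyle="none", marker="^",
                color="green", label="peak maximum")
        ax.plot(t[ts_], filtered.f[ts_], linestyle="none", marker="o",
                markerfacecolor="none", color="blue", label="peak start")
        ax.plot(t[te_], filtered.f[te_], linestyle="none", marker="x",
                color="green", label="peak end")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ratio")
    if sample_id:
        ax.set_title(sample_id)
    ax.legend(loc="upper right", fontsize="small")
    fig.tight_layout()
    return fig


def render_trace_plot(raw, filtered, peaks, path, sample_id: str | None = None) -> None:
    """Render the per-cell result plot to a PNG file."""
    import matplotlib.pyplot as plt

    fig = build_trace_figure(raw, filtered, peaks, sample_id=sample_id)
    try:
        # suppress embedded software/timestamp metadata for reproducible files
        fig.savefig(path, format="png", dpi=100, metadata={"Software": None})
    finally:
        plt.close(fig)


# ---------------------------------------------------------------------------
# run report

@dataclass
class SampleResult:
    """Per-sample analysis outcome (or exclusion marker)."""

    sample_id: str
    excluded: bool = False
    n_peaks: int | None = None
    waiting_times: list[float] = field(default_factory=list)
    mean_waiting_time: float | None = None
    acf1: float | None = None
    active: bool | None = None


@dataclass
class RunReport:
    """Everything one analysis run reports: per-sample rows, cohort
    aggregates and a parameter echo.  Every input sample appears exactly
    once, either analyzed or excluded."""

    samples: list[SampleResult]
    params: dict
    excluded_ids: list[str]
    n_active: int
    fraction_active: float
    mean_peaks_active: float | None
    mean_waiting_time: float | None
    acf_classes: tuple[int, int, int]  # (negative, neutral, positive)

    @property
    def n_analyzed(self) -> int:
        return sum(not s.excluded for s in self.samples)


_LEGEND = """\
# Ca2+ spiking analysis report
# Legend:
#   n_peaks            number of validated Ca2+ peaks in the recording
#   mean_waiting_s     mean interval between consecutive peak maxima (s)
#   acf1               lag-1 autocorrelation of the waiting times
#                      (NA when fewer than 3 intervals or zero variance)
#   active             'yes' when the cell shows at least the configured
#                      minimum number of peaks (actively responding cell)
#   waiting_times_s    ';'-separated peak-to-peak intervals (s)
#   fraction_active    fraction of analyzed cells that are active
#   mean_peaks_active  mean peak count over active cells only
#   acf_negative/neutral/positive  counts of cells whose acf1 falls below
#                      -cutoff, inside [-cutoff, +cutoff], or above +cutoff\
"""


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "yes" if v else "no"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_report(report: RunReport, path) -> None:
    """Serialize a RunReport as a deterministic, human-readable text file."""
    lines = [_LEGEND, "[parameters]"]
    for key, val in report.params.items():
        lines.append(f"{key}\t{_fmt(val)}")
    lines.append("excluded_ids\t" + (",".join(report.excluded_ids) or "NA"))
    lines.append("[samples]")
    lines.append("sample_id\tstatus\tn_peaks\tmean_waiting_s\tacf1\tactive\twaiting_times_s")
    for s in report.samples:
        if s.excluded:
            lines.append(f"{s.sample_id}\texcluded\tNA\tNA\tNA\tNA\tNA")
        else:
            wt = ";".join(repr(float(x)) for x in s.waiting_times) or "NA"
            lines.append(
                f"{s.sample_id}\tanalyzed\t{s.n_peaks}\t"
                f"{_fmt(s.mean_waiting_time)}\t{_fmt(s.acf1)}\t"
                f"{_fmt(bool(s.active))}\t{wt}"
            )
    lines.append("[summary]")
    lines.append(f"n_samples\t{len(report.samples)}")
    lines.append(f"n_analyzed\t{report.n_analyzed}")
    lines.append(f"n_active\t{report.n_active}")
    lines.append(f"fraction_active\t{_fmt(float(report.fraction_active))}")
    lines.append(f"mean_peaks_active\t{_fmt(report.mean_peaks_active)}")
    lines.append(f"mean_waiting_time_s\t{_fmt(report.mean_waiting_time)}")
    for name, count in zip(("negative", "neutral", "positive"), report.acf_classes):
        lines.append(f"acf_{name}\t{count}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_scalar(text: str):
    if text == "NA":
        return None
    if text in ("yes", "no"):
        return text == "yes"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def read_report(path) -> RunReport:
    """Parse a report file written by :func:`write_report`."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if not ln.startswith("#")]
    section = None
    params: dict = {}
    excluded_ids: list[str] = []
    samples: list[SampleResult] = []
    summary: dict = {}
    for ln in lines:
        if not ln.strip():
            continue
        if ln in ("[parameters]", "[samples]", "[summary]"):
            section = ln
            continue
        cells = ln.split("\t")
        if section == "[parameters]":
            if cells[0] == "excluded_ids":
                excluded_ids = [] if cells[1] == "NA" else cells[1].split(",")
            else:
                params[cells[0]] = _parse_scalar(cells[1])
        elif section == "[samples]":
            if cells[0] == "sample_id":
                continue
            sid, status, npk, mwt, acf1, active, wts = cells
            if status == "excluded":
                samples.append(SampleResult(sid, excluded=True))
            else:
                samples.append(SampleResult(
                    sid,
                    n_peaks=int(npk),
                    waiting_times=[] if wts == "NA" else [float(x) for x in wts.split(";")],
                    mean_waiting_time=_parse_scalar(mwt),
                    acf1=_parse_scalar(acf1),
                    active=_parse_scalar(active),
                ))
        elif section == "[summary]":
            summary[cells[0]] = _parse_scalar(cells[1])
    return RunReport(
        samples=samples,
        params=params,
        excluded_ids=excluded_ids,
        n_active=summary["n_active"],
        fraction_active=float(summary["fraction_active"]),
        mean_peaks_active=summary["mean_peaks_active"],
        mean_waiting_time=summary["mean_waiting_time_s"],
        acf_classes=(summary["acf_negative"], summary["acf_neutral"], summary["acf_positive"]),
    )
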