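"""Savitzky-Golay smoothing with simultaneous derivative estimation.

A sliding window of ``w = 2n + 1`` samples is fit with a degree-``k``
polynomial by least squares; the filtered value and the first and second
derivative estimates at the window centre are linear in the window values,
so each output series is a dot product with a fixed weight vector.  The
first and last ``n`` points are produced by evaluating the fit of the
nearest full window at the corresponding off-centre offset, which keeps
output length equal to input length without padding artifacts.

Derivatives are returned in physical time units (signal units per second
and per second squared), obtained by dividing the index-unit estimates by
``dt`` and ``dt**2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import perm

import numpy as np

__all__ = ["FilterParams", "FilteredTrace", "sg_weights", "filter_trace"]


@dataclass(frozen=True)
class FilterParams:
    """Window width ``w`` (odd, >= 5) and polynomial degree ``k`` (>= 2).

    The fit is well-posed when ``w > k + 1`` (more points than free
    polynomial coefficients).
    """

    w: int = 9
    k: int = 5

    def __post_init__(self) -> None:
        if self.w < 5 or self.w % 2 == 0:
            raise ValueError(f"window width w must be odd and >= 5, got {self.w}")
        if self.k < 2:
            raise ValueError(f"polynomial degree k must be >= 2, got {self.k}")
        if self.w <= self.k + 1:
            raise ValueError(
                f"w must exceed k + 1 for a well-posed least-squares fit "
                f"(got w={self.w}, k={self.k})"
            )

    @property
    def n(self) -> int:
        """Half-width: number of points on each side of the centre."""
        return self.w // 2


@dataclass(frozen=True)
class FilteredTrace:
    """Smoothed series with first/second derivative estimates.

    ``f`` is in signal units, ``d1`` in signal units per second, ``d2`` in
    signal units per second squared; all three have the length of the input.
    ``n`` is the filter half-width (the first/last ``n`` points are
    off-centre extrapolations and are excluded from peak candidacy).
    """

    f: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    dt: float
    n: int

    def __len__(self) -> int:
        return len(self.f)


def sg_weights(params: FilterParams, deriv_order: int = 0, offset: int = 0) -> np.ndarray:
    """Linear filter weights for one evaluation point of the window fit.

    The returned length-``w`` vector ``c`` satisfies: for window values
    ``y[-n..n]``, ``c @ y`` equals the least-squares degree-``k`` polynomial
    fit (or its ``deriv_order``-th derivative, in index units) evaluated at
    position ``offset`` within the window.  ``offset != 0`` is used only for
    edge handling.
    """
    return _sg_weights_cached(params.w, params.k, deriv_order, offset).copy()


@lru_cache(maxsize=512)
def _sg_weights_cached(w: int, k: int, deriv_order: int, offset: int) -> np.ndarray:
    params = FilterParams(w, k)
    if deriv_order not in (0, 1, 2):
        raise ValueError(f"deriv_order must be 0, 1 or 2, got {deriv_order}")
    n = params.n
    if not -n <= offset <= n:
        raise ValueError(f"offset must lie in [-{n}, {n}], got {offset}")
    x = np.arange(-n, n + 1, dtype=float)
    design = np.vander(x, params.k + 1, increasing=True)
    # row mapping polynomial coefficients to the deriv at `offset`:
    # d^r/dx^r x^j = j!/(j-r)! x^(j-r)
    row = np.zeros(params.k + 1)
    for j in range(deriv_order, params.k + 1):
        row[j] = perm(j, deriv_order) * float(offset) ** (j - deriv_order)
    return row @ np.linalg.pinv(design)


def filter_trace(series: np.ndarray, params: FilterParams, dt: float) -> FilteredTrace:
    """Filter a trace, returning smoothed values and d1/d2 per second.

    Interior points use the centred window; the first and last ``n`` points
    evaluate the fit of the nearest full window at the matching off-centre
    offset.  Requires ``len(series) >= w`` and finite values.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    n, w = params.n, params.w
    if len(y) < w:
        raise ValueError(f"series length {len(y)} is shorter than the window w={w}")

    out = {}
    for order in (0, 1, 2):
        c = sg_weights(params, order, 0)
        # np.correlate slides the kernel without reversal: interior dot products
        interior = np.correlate(y, c, mode="valid")
        full = np.empty_like(y)
        full[n:len(y) - n] = interior
        for i in range(n):  # leading edge: first full window, offset i - n < 0
            full[i] = sg_weights(params, order, i - n) @ y[:w]
        for i in range(len(y) - n, len(y)):  # trailing edge
            full[i] = sg_weights(params, order, i - (len(y) - 1 - n)) @ y[-w:]
        out[order] = full

    return FilteredTrace(
        f=out[0], d1=out[1] / dt, d2=out[2] / dt**2, dt=float(dt), n=n
    )
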