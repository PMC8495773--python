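"""Density-based peak calling on gene-expression distributions.

First step of the bimodality screen: estimate the expression density with a
Gaussian kernel and Silverman's rule-of-thumb ("nrd0") bandwidth, take the
first derivative of the density curve (optionally smoothed with a
GCV-penalized cubic spline), and call peaks/valleys where the derivative
changes sign.  Two height rules prune the candidates:

* *threshold down* — a peak whose density is below this fraction of the
  maximum density is discarded (kills ripples in the upper tail);
* *threshold up* — an adjacent peak/valley pair whose height difference is
  below this fraction of the maximum density is merged (the taller peak
  survives).

The number of surviving peaks, ``k``, parameterizes the downstream Gaussian
mixture fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

GRID_SIZE = 512
GRID_CUT_BANDWIDTHS = 3.0


@dataclass(frozen=True)
class DensityCurve:
    """Kernel density estimate evaluated on an equally spaced grid."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if len(self.grid_x) != len(self.grid_y):
            raise ValueError("grid_x and grid_y must have equal length")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if np.any(self.grid_y < 0):
            raise ValueError("density values must be non-negative")

    @property
    def step(self) -> float:
        return float(self.grid_x[1] - self.grid_x[0])


@dataclass(frozen=True)
class DerivativeCurve:
    """First derivative of a density curve on the same grid."""

    grid_x: np.ndarray
    dydx: np.ndarray
    smoothed: bool

    def __post_init__(self) -> None:
        if len(self.grid_x) != len(self.dydx):
            raise ValueError("grid_x and dydx must have equal length")


@dataclass(frozen=True)
class PeakSet:
    """Alternating peaks and valleys surviving the height thresholds.

    ``peaks`` and ``valleys`` are lists of ``(location, height)`` pairs sorted
    by location; every valley lies between two peaks.
    """

    peaks: list[tuple[float, float]] = field(default_factory=list)
    valleys: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def peak_locations(self) -> list[float]:
        return [loc for loc, _ in self.peaks]


def rule_of_thumb_bandwidth(values) -> float:
    """Silverman's rule-of-thumb bandwidth, 0.9·min(sd, IQR/1.34)·n^(−1/5).

    Follows the reference nrd0 rule, including its fallback chain when the
    spread estimate degenerates to zero: substitute max(sd, IQR/1.34), then
    ``|x1|``, then 1.  Always returns a strictly positive bandwidth.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("bandwidth requires at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("bandwidth requires finite values")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])  # linear interpolation = R type 7
    iqr_scaled = float(q75 - q25) / 1.34
    lo = min(sd, iqr_scaled)
    if lo == 0.0:
        lo = max(sd, iqr_scaled)
    if lo == 0.0:
        lo = abs(float(x[0]))
    if lo == 0.0:
        lo = 1.0
    return 0.9 * lo * x.size ** (-0.2)


def kernel_density(values, bandwidth: float) -> DensityCurve:
    """Gaussian KDE on a 512-point grid spanning [min−3·bw, max+3·bw].

    Direct kernel summation; the trapezoidal integral of the result is ~1
    because the grid covers essentially all of the kernel mass.
    """
    x = np.asarray(values, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if x.size < 2:
        raise ValueError("kernel density requires at least 2 values")
    lo = x.min() - GRID_CUT_BANDWIDTHS * bandwidth
    hi = x.max() + GRID_CUT_BANDWIDTHS * bandwidth
    grid = np.linspace(lo, hi, GRID_SIZE)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bandwidth * np.sqrt(2 * np.pi))
    return DensityCurve(grid_x=grid, grid_y=dens, bandwidth=float(bandwidth))


def smoothed_derivative(curve: DensityCurve, smoothing_enabled: bool = True,
                        smoothing_penalty: float | None = None) -> DerivativeCurve:
    """Finite-difference slope of the density, optionally spline-smoothed.

    The slope is the central finite difference on the grid.  With smoothing
    enabled, a cubic smoothing spline is fit to the slope values — penalty
    chosen by generalized cross-validation unless ``smoothing_penalty``
    overrides it — and evaluated back on the same grid.  Smoothing
    deliberately desensitizes peak detection to small density wiggles.
    """
    dydx = np.gradient(curve.grid_y, curve.grid_x)
    if smoothing_enabled:
        # The KDE derivative is heavily oversampled at 512 points; fitting the
        # GCV spline on a 4x-thinned subgrid (last point always kept) gives an
        # indistinguishable smooth at a quarter of the penalty-search cost.
        idx = np.unique(np.r_[np.arange(0, GRID_SIZE, 4), GRID_SIZE - 1])
        spline = make_smoothing_spline(curve.grid_x[idx], dydx[idx],
                                       lam=smoothing_penalty)
        dydx = spline(curve.grid_x)
    return DerivativeCurve(grid_x=curve.grid_x, dydx=np.asarray(dydx),
                           smoothed=bool(smoothing_enabled))


def _sign_change_extrema(curve: DensityCurve, deriv: DerivativeCurve):
    """Candidate extrema as (index, kind) where kind is 'peak' or 'valley'.

    A +→− flip of the derivative marks a peak, −→+ a valley.  Runs of exact
    zeros are collapsed to their midpoint; within the bracketing index range
    the extremum index is refined to the arg-extreme of the density, which is
    robust when the crossing falls between grid points.  Grid endpoints are
    never candidates.
    """
    y = curve.grid_y
    s = np.sign(deriv.dydx)
    nz = np.flatnonzero(s != 0)
    out = []
    for a, b in zip(nz[:-1], nz[1:]):
        if s[a] == s[b]:
            continue
        lo, hi = a, b
        seg = slice(lo, hi + 1)
        if s[a] > 0:  # + -> -: peak
            idx = lo + int(np.argmax(y[seg]))
            kind = "peak"
        else:
            idx = lo + int(np.argmin(y[seg]))
            kind = "valley"
        if idx == 0 or idx == len(y) - 1:
            continue
        out.append((idx, kind))
    return out


def detect_peaks(curve: DensityCurve, deriv: DerivativeCurve,
                 threshold_up: float = 0.10,
                 threshold_down: float = 0.20) -> PeakSet:
    """Call peaks and valleys from derivative sign changes, then prune.

    Pruning order: first the *down* rule removes peaks with density below
    ``threshold_down × max(density)``; then the *up* rule iteratively merges
    the adjacent peak–valley pair with the smallest height gap while that gap
    is below ``threshold_up × max(density)``, keeping the taller peak
    (leftmost on ties).  Output alternates peak/valley sorted by location.
    """
    if not np.array_equal(curve.grid_x, deriv.grid_x):
        raise ValueError("density and derivative curves must share a grid")
    if not (0 <= threshold_up <= 1 and 0 <= threshold_down <= 1):
        raise ValueError("thresholds must lie in [0, 1]")

    y = curve.grid_y
    ymax = float(y.max())
    extrema = _sign_change_extrema(curve, deriv)

    # threshold-down pruning of peaks
    kept = [(i, k) for i, k in extrema
            if not (k == "peak" and y[i] < threshold_down * ymax)]

    # collapse to strict alternation: drop leading/trailing valleys, and
    # between consecutive peaks keep only the deepest valley
    peaks = [i for i, k in kept if k == "peak"]
    peak_list: list[int] = sorted(peaks)
    valley_list: list[int] = []
    all_valleys = sorted(i for i, k in kept if k == "valley")
    for left, right in zip(peak_list[:-1], peak_list[1:]):
        between = [v for v in all_valleys if left < v < right]
        if between:
            valley_list.append(min(between, key=lambda v: y[v]))
        else:
            # no surviving sign-change valley between two peaks (pruning
            # artifact): use the density minimum between them
            seg = slice(left + 1, right)
            valley_list.append(left + 1 + int(np.argmin(y[seg])))

    # threshold-up merging
    def smallest_gap():
        best = None
        for j, v in enumerate(valley_list):
            for p in (peak_list[j], peak_list[j + 1]):
                gap = y[p] - y[v]
                if best is None or gap < best[0]:
                    best = (gap, j)
        return best

    while valley_list:
        best = smallest_gap()
        if best is None or best[0] >= threshold_up * ymax:
            break
        _, j = best
        left, right = peak_list[j], peak_list[j + 1]
        # keep the taller peak; leftmost wins ties
        keep = left if y[left] >= y[right] else right
        drop = right if keep == left else left
        peak_list.remove(drop)
        del valley_list[j]

    gx = curve.grid_x
    return PeakSet(
        peaks=[(float(gx[i]), float(y[i])) for i in peak_list],
        valleys=[(float(gx[i]), float(y[i])) for i in valley_list],
    )


def estimate_peaks(values, threshold_up: float = 0.10,
                   threshold_down: float = 0.20,
                   smoothing: bool = True,
                   smoothing_penalty: float | None = None) -> PeakSet:
    """Convenience pipeline: bandwidth → KDE → derivative → peak calling."""
    bw = rule_of_thumb_bandwidth(values)
    curve = kernel_density(values, bw)
    deriv = smoothed_derivative(curve, smoothing, smoothing_penalty)
    return detect_peaks(curve, deriv, threshold_up, threshold_down)
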