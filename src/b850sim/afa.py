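"""Adaptive fractal analysis (AFA) of exciton population time series.

A globally smooth trend nu(i) is built by fitting an order-M polynomial
(M = 1 here by default) in overlapping windows of odd length w = 2n + 1;
neighboring windows share n + 1 points and are stitched with linearly
varying weights, so the trend has no segment-boundary discontinuities.  The
root-mean-square residual

    F(w) = sqrt( (1/Nf) sum_i [u(i) - nu(i)]^2 )  ~  w^H

scales with the window size; the Hurst exponent H is the slope of
log2 F vs log2 w.  0 < H < 1/2 indicates anti-persistent, H = 1/2
short-range and 1/2 < H < 1 persistent long-range correlation; smooth
superdiffusive signals can show H > 1, outside the fBm/fGn range.

A spectral (circulant-embedding) fractional Brownian motion generator is
included as the calibration fixture for the estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AFAResult",
    "adaptive_trend",
    "fluctuation_scaling",
    "fbm_generator",
    "default_window_sizes",
]


@dataclass(frozen=True)
class AFAResult:
    """Fluctuation function F(w) and segmented Hurst fits."""

    window_sizes: np.ndarray  # odd ints, increasing
    F: np.ndarray  # same length, >= 0
    segments: tuple = ()  # ((log2w_lo, log2w_hi, H, intercept), ...)

    def __post_init__(self):
        w = np.asarray(self.window_sizes)
        if np.any(np.diff(w) <= 0) or np.any(w % 2 == 0) or np.any(w < 3):
            raise ValueError("window sizes must be increasing odd integers >= 3")
        if np.any(np.asarray(self.F) < 0):
            raise ValueError("fluctuation values must be nonnegative")

    @property
    def hurst(self) -> float:
        """H of the first (short-window) segment."""
        if not self.segments:
            raise ValueError("no fitted segments")
        return self.segments[0][2]


def _window_starts(n_points: int, half: int) -> list[int]:
    """Start indices of overlapping windows of length 2*half + 1 stepping by
    ``half``; the final window is shifted to end exactly at the last point."""
    w = 2 * half + 1
    starts = list(range(0, n_points - w + 1, half))
    if starts[-1] != n_points - w:
        starts.append(n_points - w)
    return starts


def adaptive_trend(u: np.ndarray, w: int, M: int = 1) -> np.ndarray:
    """Globally continuous adaptive trend of ``u`` at window size ``w``.

    Each window of length w = 2n + 1 is fitted with a polynomial of order
    ``M``; in the overlap of two neighboring windows (n + 1 points) the
    trend is the weighted combination y = w1 y1 + w2 y2 with weights
    falling/rising linearly across the overlap.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if w < 3 or w % 2 == 0:
        raise ValueError("window length must be an odd integer >= 3")
    if w >= len(u):
        raise ValueError(f"window {w} must be shorter than the series ({len(u)})")
    if M < 0:
        raise ValueError("polynomial order must be >= 0")
    half = (w - 1) // 2
    starts = _window_starts(len(u), half)
    x = np.arange(len(u), dtype=float)

    fits = []
    for s in starts:
        seg = slice(s, s + w)
        coef = np.polynomial.polynomial.polyfit(x[seg], u[seg], M)
        fits.append(coef)

    trend = np.empty_like(u)
    # first window owns everything before the first overlap
    trend[: starts[0] + half] = np.polynomial.polynomial.polyval(
        x[: starts[0] + half], fits[0]
    )
    for kk in range(len(starts) - 1):
        s_next = starts[kk + 1]
        end_cur = starts[kk] + w - 1  # inclusive
        lo, hi = s_next, end_cur  # inclusive overlap bounds
        n_ov = hi - lo  # overlap length - 1
        xs = x[lo : hi + 1]
        y1 = np.polynomial.polynomial.polyval(xs, fits[kk])
        y2 = np.polynomial.polynomial.polyval(xs, fits[kk + 1])
        if n_ov == 0:
            trend[lo] = 0.5 * (y1 + y2)
        else:
            w2 = np.arange(n_ov + 1) / n_ov
            trend[lo : hi + 1] = (1.0 - w2) * y1 + w2 * y2
        # points owned solely by window kk+1 until its own overlap begins
        own_end = starts[kk + 1] + half if kk + 1 < len(starts) - 1 else len(u) - 1
        if hi + 1 <= own_end:
            trend[hi + 1 : own_end + 1] = np.polynomial.polynomial.polyval(
                x[hi + 1 : own_end + 1], fits[kk + 1]
            )
    # last window owns the tail
    last_start = starts[-1]
    tail_from = max(last_start + half, starts[-2] + w if len(starts) > 1 else 0)
    trend[tail_from:] = np.polynomial.polynomial.polyval(x[tail_from:], fits[-1])
    return trend


def default_window_sizes(n_points: int, w_min: int = 5) -> np.ndarray:
    """Dyadic window ladder w = 2^m + 1 up to ~an eighth of the series."""
    sizes = []
    m = 2
    while 2**m + 1 <= max(n_points // 8, w_min):
        if 2**m + 1 >= w_min:
            sizes.append(2**m + 1)
        m += 1
    if len(sizes) < 3:
        raise ValueError("series too short for a window ladder")
    return np.array(sizes, dtype=int)


def fluctuation_scaling(
    u: np.ndarray,
    window_sizes: np.ndarray | None = None,
    M: int = 1,
    breakpoint_w: float | None = None,
    detect_breakpoint: bool = False,
) -> AFAResult:
    """F(w) over a ladder of window sizes plus segmented Hurst fits.

    With ``breakpoint_w`` the log2 F vs log2 w cloud is fitted in two
    segments split at that window size (e.g. 257 for a 1 fs sampled series
    with a 256 fs scaling boundary); with ``detect_breakpoint`` the split
    minimizing the total squared residual of a continuous two-line fit is
    chosen automatically.  Without either, a single line is fitted.
    """
    u = np.asarray(u, dtype=float)
    if window_sizes is None:
        window_sizes = default_window_sizes(len(u))
    window_sizes = np.asarray(window_sizes, dtype=int)

    F = np.empty(len(window_sizes), dtype=float)
    for i, w in enumerate(window_sizes):
        resid = u - adaptive_trend(u, int(w), M)
        F[i] = np.sqrt(np.mean(resid**2))

    # a perfectly detrended signal leaves only rounding residue; treat
    # anything at the machine-precision scale of the data as F = 0
    f_floor = 1e-12 * max(1.0, float(np.max(np.abs(u))))
    keep = F > f_floor
    if not np.all(keep):
        warnings.warn(
            "dropping perfectly detrended window sizes "
            f"{window_sizes[~keep].tolist()} (F = 0)",
            stacklevel=2,
        )
    ws, Fs = window_sizes[keep], F[keep]
    if len(ws) < 2:
        raise ValueError("fewer than 2 usable window sizes")
    lw, lF = np.log2(ws.astype(float)), np.log2(Fs)

    def line(xs, ys):
        slope, intercept = np.polyfit(xs, ys, 1)
        return (float(xs[0]), float(xs[-1]), float(slope), float(intercept))

    segments: list[tuple] = []
    if detect_breakpoint and len(lw) >= 6:
        best = None
        for i in range(2, len(lw) - 2):
            xb = lw[i]
            X = np.column_stack(
                [np.ones_like(lw), lw, np.maximum(lw - xb, 0.0)]
            )
            coef, *_ = np.linalg.lstsq(X, lF, rcond=None)
            sse = float(np.sum((X @ coef - lF) ** 2))
            if best is None or sse < best[0]:
                best = (sse, i)
        i = best[1]
        segments.append(line(lw[: i + 1], lF[: i + 1]))
        segments.append(line(lw[i:], lF[i:]))
    elif breakpoint_w is not None:
        cut = lw <= np.log2(breakpoint_w)
        if cut.sum() >= 2:
            segments.append(line(lw[cut], lF[cut]))
        if (~cut).sum() >= 2:
            segments.append(line(lw[~cut], lF[~cut]))
    else:
        segments.append(line(lw, lF))
    return AFAResult(window_sizes=ws, F=Fs, segments=tuple(segments))


def fbm_generator(H: float, n: int, seed: int) -> np.ndarray:
    """Fractional Brownian motion of length ``n`` by circulant embedding.

    Generates exact fractional Gaussian noise increments via the
    Davies-Harte spectral method and cumulates them; deterministic for a
    fixed seed.  Requires 0 < H < 1 and ``n`` a power of two.
    """
    if not 0.0 < H < 1.0:
        raise ValueError("H must lie strictly between 0 and 1")
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError("n must be a power of two")
    rng = np.random.default_rng(seed)
    # fGn autocovariance
    kk = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(kk + 1) ** (2 * H) - 2 * np.abs(kk) ** (2 * H) + np.abs(kk - 1) ** (2 * H)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, len 2n
    eig = np.fft.rfft(row).real
    eig = np.maximum(eig, 0.0)  # clip tiny negatives from rounding
    m = len(row)
    z = rng.standard_normal(m // 2 + 1) + 1j * rng.standard_normal(m // 2 + 1)
    z[0] = z[0].real * np.sqrt(2.0)
    z[-1] = z[-1].real * np.sqrt(2.0)
    spectrum = np.sqrt(eig / (2.0 * m)) * z
    fgn = np.fft.irfft(spectrum, n=m)[:n] * m
    return np.cumsum(fgn)
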