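"""Baseline subtraction, Gaussian peak extraction and lamellar analysis.

Bragg and pseudo-Bragg peaks ride on a smooth particle form-factor
background.  The workflow is: estimate a lower-envelope baseline by
iterative clipped smoothing in (log q, log I) space, subtract it, locate
local maxima and refine each with a Gaussian plus local linear term, then
group the peak positions into lamellar order series (q_n = n * 2*pi/d) and
convert positions to repeat distances d = 2*pi/q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .curves import SASCurve, ValidationError

__all__ = [
    "Peak",
    "PeakSet",
    "LamellarSeries",
    "estimate_baseline",
    "subtract_baseline",
    "extract_peaks",
    "d_spacing",
    "find_lamellar_series",
    "low_q_slope",
    "difference_intensity",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class Peak:
    """One extracted peak: center q_max [1/A], amplitude, FWHM [1/A]."""

    q_max: float
    amplitude: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.q_max <= 0:
            raise ValidationError("q_max must be > 0")
        if self.fwhm <= 0:
            raise ValidationError("fwhm must be > 0")

    @property
    def d_spacing(self) -> float:
        """Real-space repeat distance 2*pi/q_max [A]."""
        return TWO_PI / self.q_max

    @property
    def sigma_q(self) -> float:
        """Gaussian sigma equivalent of the FWHM [1/A]."""
        return self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PeakSet:
    """Peaks of one curve, sorted by q_max, with overlaps merged."""

    peaks: tuple[Peak, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        qs = [p.q_max for p in self.peaks]
        if any(b <= a for a, b in zip(qs, qs[1:])):
            raise ValidationError("peaks must be strictly increasing in q_max")
        for a, b in zip(self.peaks, self.peaks[1:]):
            if b.q_max - a.q_max < 0.5 * 0.5 * (a.fwhm + b.fwhm):
                raise ValidationError(
                    "peaks closer than half their mean fwhm must be merged"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.q_max for p in self.peaks])


@dataclass(frozen=True)
class LamellarSeries:
    """A diffraction-order family q_n ~ n * 2*pi/d.

    ``orders`` maps order number n (starting at 1) to the observed q.
    """

    d: float
    orders: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "orders", tuple(self.orders))
        if self.d <= 0:
            raise ValidationError("d must be > 0")
        if not self.orders or self.orders[0][0] != 1:
            raise ValidationError("orders must start at 1")

    @property
    def max_order(self) -> int:
        return max(n for n, _ in self.orders)


def d_spacing(q: float) -> float:
    """Repeat distance d = 2*pi/q [A] for a peak at q [1/A].

    The same formula maps d back to q, so the function is its own inverse
    up to the 2*pi factor.
    """
    if q <= 0:
        raise ValidationError("q must be > 0")
    return TWO_PI / q


def estimate_baseline(
    curve: SASCurve, half_width: int = 12, n_iter: int = 1
) -> SASCurve:
    """Lower-envelope baseline by iterative clipped smoothing in log-log.

    On log I over a uniform log-q grid, each pass applies a grey-scale
    opening (min-filter then max-filter over a ``2*half_width + 1``
    window) followed by a moving-average smoothing, clipped from above by
    the data.  Peaks narrower than the window are removed; straight
    power-law stretches (linear in log-log) are reproduced exactly, and
    smoothly curved peak-free regions are followed to second order
    instead of being dug into (the opening's error is a single chord
    sagitta, not a compounded one).
    """
    from scipy.ndimage import grey_opening, uniform_filter1d

    n = len(curve)
    if n <= 2 * half_width:
        raise ValidationError("curve too short for this half_width")
    if np.any(curve.intensity <= 0):
        floor = np.max(curve.intensity) * 1e-12
        y_in = np.log(np.maximum(curve.intensity, floor))
    else:
        y_in = np.log(curve.intensity)
    lq = np.log(curve.q)
    u = np.linspace(lq[0], lq[-1], n)
    y0 = np.interp(u, lq, y_in)
    w = 2 * half_width + 1
    # pad by extending the boundary slopes so the opening sees a straight
    # continuation instead of a replicated edge (a replicated edge on a
    # steep curve digs a large spurious residual at the boundary)
    k = np.arange(1, w + 1, dtype=float)
    fit_l = np.polyfit(np.arange(half_width + 1), y0[: half_width + 1], 1)
    fit_r = np.polyfit(np.arange(half_width + 1), y0[-(half_width + 1) :], 1)
    pad_l = y0[0] - fit_l[0] * k[::-1]
    pad_r = y0[-1] + fit_r[0] * k
    y = np.concatenate([pad_l, y0, pad_r])
    for _ in range(max(1, n_iter)):
        y = grey_opening(y, size=w, mode="nearest")
        y = uniform_filter1d(y, size=w, mode="nearest")
        y[w:-w] = np.minimum(y[w:-w], y0)
    y = np.minimum(y[w:-w], y0)
    base = np.interp(lq, u, y)
    return SASCurve(curve.q, np.exp(base), None, label=f"{curve.label}:baseline")


def subtract_baseline(
    curve: SASCurve, baseline: SASCurve, clip_negative: bool = False
) -> SASCurve:
    """Pointwise curve - baseline on a shared q grid.

    With ``clip_negative`` the residual is floored at 0.  Sigma of the
    original curve is carried through unchanged (the baseline is treated
    as noise-free).
    """
    if len(curve) != len(baseline) or not np.allclose(
        curve.q, baseline.q, rtol=0, atol=1e-12
    ):
        raise ValidationError("curve and baseline must share the q grid")
    resid = curve.intensity - baseline.intensity
    if clip_negative:
        resid = np.maximum(resid, 0.0)
    return SASCurve(curve.q, resid, curve.sigma, label=f"{curve.label}:residual")


def _gauss_linear(q, center, sigma, amp, slope, offset):
    return amp * np.exp(-((q - center) ** 2) / (2.0 * sigma**2)) + slope * q + offset


def _multi_gauss_linear(q: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    """n Gaussians (center, sigma, amp each) plus a shared linear term."""
    out = x[3 * n] * q + x[3 * n + 1]
    for k in range(n):
        c, s, a = x[3 * k], x[3 * k + 1], x[3 * k + 2]
        out = out + a * np.exp(-((q - c) ** 2) / (2.0 * s**2))
    return out


def _multi_gauss_linear_jac(q: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    jac = np.empty((len(q), 3 * n + 2))
    for k in range(n):
        c, s, a = x[3 * k], x[3 * k + 1], x[3 * k + 2]
        g = np.exp(-((q - c) ** 2) / (2.0 * s**2))
        jac[:, 3 * k] = a * g * (q - c) / s**2
        jac[:, 3 * k + 1] = a * g * (q - c) ** 2 / s**3
        jac[:, 3 * k + 2] = g
    jac[:, 3 * n] = q
    jac[:, 3 * n + 1] = 1.0
    return jac


def extract_peaks(
    residual: SASCurve,
    min_prominence: float = 0.05,
    q_window: tuple[float, float] | None = None,
    min_snr: float = 5.0,
    min_width_frac: float = 0.5,
) -> PeakSet:
    """Locate and refine peaks in a baseline-subtracted curve.

    Local maxima with prominence above ``min_prominence`` times the
    residual maximum seed the refinement; maxima close enough to overlap
    are grouped into a cluster and fitted jointly as a sum of Gaussians
    plus a shared local-linear term (each center constrained to one grid
    step around its raw maximum, so neighbouring reflections stay
    distinct).  When the curve carries uncertainties, peaks below
    ``min_snr`` local sigma are rejected; peaks narrower than
    ``min_width_frac`` of the local grid spacing are rejected as
    single-point spikes.  Refined centers that still collide (closer than
    half their mean FWHM) are merged keeping the larger amplitude.  An
    empty result is not an error.
    """
    from scipy.optimize import least_squares as _lsq

    c = residual if q_window is None else residual.window(*q_window)
    y = c.intensity
    top = float(np.max(y)) if len(y) else 0.0
    if top <= 0:
        return PeakSet((), source_label=residual.label)
    idx, props = find_peaks(y, prominence=min_prominence * top)
    if len(idx) == 0:
        return PeakSet((), source_label=residual.label)

    # cluster maxima whose windows touch (gap below ~8 samples)
    clusters: list[list[int]] = [[0]]
    for pos in range(1, len(idx)):
        if idx[pos] - idx[clusters[-1][-1]] <= 8:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])

    found: list[Peak] = []
    for members in clusters:
        i_first, i_last = int(idx[members[0]]), int(idx[members[-1]])
        lo = max(int(props["left_bases"][members[0]]), i_first - 12)
        hi = min(int(props["right_bases"][members[-1]]), i_last + 12)
        lo, hi = max(0, min(lo, i_first - 3)), min(len(y) - 1, max(hi, i_last + 3))
        qw = c.q[lo : hi + 1]
        yw = y[lo : hi + 1]
        span = qw[-1] - qw[0]
        ymax = float(np.max(yw))
        n = len(members)
        centers = [float(c.q[int(idx[pos])]) for pos in members]
        x0, lob, upb = [], [], []
        for k, pos in enumerate(members):
            i = int(idx[pos])
            # a resolvable raw maximum localizes its center to one grid step
            c_lo, c_hi = c.q[max(i - 1, 0)], c.q[min(i + 1, len(y) - 1)]
            # sigma is capped by the nearest other maximum so no component
            # can widen across its neighbours and swallow them
            if n > 1:
                d_near = min(
                    abs(centers[k] - centers[j]) for j in range(n) if j != k
                )
                sig_hi = max(0.75 * d_near, 0.75 * (c_hi - c_lo))
            else:
                sig_hi = min(
                    span,
                    2.0 * min(c.q[i] - qw[0], qw[-1] - c.q[i]) + (c_hi - c_lo),
                )
            x0 += [c.q[i], max(min(sig_hi, span) / 4.0, 1e-7), max(y[i], top * 1e-6)]
            lob += [c_lo, 1e-8, 0.0]
            # amplitude capped near the observed maximum: a sampled Gaussian
            # at the narrowest accepted width can top its largest sample by
            # ~1.7x, no more
            upb += [c_hi, max(sig_hi, 2e-8), 1.8 * ymax]
        x0 += [0.0, float(np.min(yw))]
        lob += [-4.0 * ymax / span, -2.0 * ymax]
        upb += [4.0 * ymax / span, 2.0 * ymax]
        x0 = np.clip(x0, lob, upb)
        try:
            sol = _lsq(
                lambda x: _multi_gauss_linear(qw, x, n) - yw,
                x0,
                jac=lambda x: _multi_gauss_linear_jac(qw, x, n),
                bounds=(lob, upb),
                method="trf",
                max_nfev=1000,
            )
            x = sol.x
        except Exception:
            x = np.asarray(x0)
        for k, pos in enumerate(members):
            i = int(idx[pos])
            center, sigma, amp = float(x[3 * k]), float(x[3 * k + 1]), float(x[3 * k + 2])
            if amp <= 0:
                continue
            spacing = c.q[min(i + 1, len(y) - 1)] - c.q[max(i - 1, 0)]
            if sigma < min_width_frac * spacing / 2.0:
                continue  # narrower than the sampling: a spike, not a peak
            if c.sigma is not None:
                local_noise = float(np.median(c.sigma[lo : hi + 1]))
                if amp < min_snr * local_noise:
                    continue
            found.append(
                Peak(center, amp, fwhm=2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma)
            )
    found.sort(key=lambda p: p.q_max)
    merged: list[Peak] = []
    for p in found:
        while merged and p.q_max - merged[-1].q_max < 0.25 * (p.fwhm + merged[-1].fwhm):
            prev = merged.pop()
            if prev.amplitude > p.amplitude:
                p = prev
        merged.append(p)
    return PeakSet(tuple(merged), source_label=residual.label)


def find_lamellar_series(
    peaks: PeakSet, rel_tol: float = 0.03, max_order: int = 4
) -> list[LamellarSeries]:
    """Group peaks into diffraction-order series q_n = n * q_1.

    Greedy: each unassigned peak, in ascending q, seeds a series as order
    1; higher peaks within ``rel_tol`` relative of n*q_1 are absorbed as
    order n, up to ``max_order``.  Every peak belongs to at most one
    series (lowest-q fundamental wins).  Singleton series are returned
    too, so isolated reflections stay visible.  The order cap keeps a
    long-period fundamental from swallowing unrelated peaks at large
    multiples of its position.
    """
    if not (0 < rel_tol <= 0.1):
        raise ValidationError("rel_tol must be in (0, 0.1]")
    if max_order < 1:
        raise ValidationError("max_order must be >= 1")
    qs = peaks.positions
    taken = np.zeros(len(qs), dtype=bool)
    series: list[LamellarSeries] = []
    for i, q1 in enumerate(qs):
        if taken[i]:
            continue
        taken[i] = True
        orders: list[tuple[int, float]] = [(1, float(q1))]
        for j in range(i + 1, len(qs)):
            if taken[j]:
                continue
            n = int(round(qs[j] / q1))
            if 2 <= n <= max_order and abs(qs[j] - n * q1) <= rel_tol * n * q1:
                taken[j] = True
                orders.append((n, float(qs[j])))
        series.append(LamellarSeries(d=TWO_PI / float(q1), orders=tuple(orders)))
    return series


def low_q_slope(
    curve: SASCurve, q_window: tuple[float, float]
) -> tuple[float, float]:
    """Log-log slope of I(q) over a q window, with its standard error.

    Ordinary least squares of log10 I against log10 q; a pure power law
    I = A q^s returns exactly s.  Requires >= 5 points with I > 0 in the
    window.
    """
    c = curve.window(*q_window)
    if len(c) < 5:
        raise ValidationError("need >= 5 points in the window")
    if np.any(c.intensity <= 0):
        raise ValidationError("all intensities in the window must be > 0")
    x = np.log10(c.q)
    y = np.log10(c.intensity)
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    resid = y - (ym + slope * (x - xm))
    if n > 2:
        stderr = float(np.sqrt(np.sum(resid**2) / (n - 2) / sxx))
    else:
        stderr = float("nan")
    return slope, stderr


def difference_intensity(
    curve_sys: SASCurve,
    curve_ref: SASCurve,
    coefficient: float = 1.0,
    rebin: bool = False,
) -> SASCurve:
    """I_sys - coefficient * I_ref, with uncertainties added in quadrature.

    By default both curves must share the q grid to 1e-9; with ``rebin``
    the reference is linearly interpolated onto the overlapping part of
    the system grid.
    """
    if rebin:
        lo = max(curve_sys.q[0], curve_ref.q[0])
        hi = min(curve_sys.q[-1], curve_ref.q[-1])
        sys_c = curve_sys.window(lo, hi)
        ref_i = np.interp(sys_c.q, curve_ref.q, curve_ref.intensity)
        ref_s = (
            np.interp(sys_c.q, curve_ref.q, curve_ref.sigma)
            if curve_ref.sigma is not None
            else None
        )
    else:
        if len(curve_sys) != len(curve_ref) or not np.allclose(
            curve_sys.q, curve_ref.q, rtol=0, atol=1e-9
        ):
            raise ValidationError(
                "q grids differ; pass rebin=True to interpolate the reference"
            )
        sys_c, ref_i, ref_s = curve_sys, curve_ref.intensity, curve_ref.sigma
    intensity = sys_c.intensity - coefficient * ref_i
    sigma = None
    if sys_c.sigma is not None and ref_s is not None:
        sigma = np.sqrt(sys_c.sigma**2 + coefficient**2 * ref_s**2)
    elif sys_c.sigma is not None:
        sigma = sys_c.sigma
    return SASCurve(
        sys_c.q, intensity, sigma, label=f"{curve_sys.label}:difference"
    )
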