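"""Spatial and temporal correlation analyses.

Spatial: masked Pearson coefficient and the cross-correlation-vs-shift
curve used to read out two-channel colocalization. Temporal: min-max
normalization of coefficient series and peak-lag estimation between
pulsatile traces (the lag-cascade readout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import SignalTrace

__all__ = [
    "ImagePair",
    "CCFCurve",
    "masked_pearson",
    "vsc_ccf",
    "temporal_coloc_normalize",
    "lag_estimate",
]


@dataclass
class ImagePair:
    """Two equal-shape 2-D intensity channels with a physical pixel size."""

    channel1: np.ndarray
    channel2: np.ndarray
    pixel_size_nm: float = 100.0

    def __post_init__(self):
        c1 = np.asarray(self.channel1, float)
        c2 = np.asarray(self.channel2, float)
        if c1.ndim != 2 or c1.shape != c2.shape:
            raise ValueError("channels must be 2-D arrays of identical shape")
        if not (np.all(np.isfinite(c1)) and np.all(np.isfinite(c2))):
            raise ValueError("intensities must be finite")
        if np.any(c1 < 0) or np.any(c2 < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        self.channel1, self.channel2 = c1, c2


@dataclass
class CCFCurve:
    """Pearson coefficient as a function of shift (nm) or lag (min)."""

    shifts: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.shifts, float)
        c = np.asarray(self.coefficients, float)
        if s.size != c.size or s.size == 0:
            raise ValueError("shifts and coefficients must match and be non-empty")
        if np.any(np.diff(s) <= 0):
            raise ValueError("shifts must be strictly increasing")
        if np.any(np.abs(c) > 1 + 1e-9):
            raise ValueError("coefficients must lie in [-1, 1]")
        self.shifts, self.coefficients = s, c

    @property
    def peak_shift(self) -> float:
        return float(self.shifts[int(np.argmax(self.coefficients))])

    @property
    def peak_value(self) -> float:
        return float(np.max(self.coefficients))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt(np.sum(da * da) * np.sum(db * db))
    if denom == 0:
        raise ValueError("zero variance in a channel")
    return float(np.sum(da * db) / denom)


def masked_pearson(pair: ImagePair, low_fraction: float = 0.10) -> float:
    """Pearson coefficient over pixels above the low-intensity quantile.

    The mask keeps pixels whose intensity exceeds the ``low_fraction``
    quantile in *both* channels (default: reject the 10% dimmest of each).
    """
    if not 0 <= low_fraction < 1:
        raise ValueError("low_fraction must be in [0, 1)")
    c1, c2 = pair.channel1, pair.channel2
    if low_fraction > 0:
        mask = (c1 > np.quantile(c1, low_fraction)) & (
            c2 > np.quantile(c2, low_fraction)
        )
    else:
        mask = np.ones_like(c1, bool)
    if mask.sum() < 2:
        raise ValueError("mask keeps fewer than 2 pixels")
    return _pearson(c1[mask], c2[mask])


def vsc_ccf(
    pair: ImagePair, max_shift_nm: float = 940.0, low_fraction: float = 0.10
) -> CCFCurve:
    """Pearson coefficient versus lateral x-shift of channel 2.

    Channel 2 is translated by every integer pixel shift whose physical
    extent lies within ±``max_shift_nm``; the coefficient is computed over
    the overlap region only (plus the low-intensity mask). Positive shift
    means channel 2 displaced toward +x before comparison, so a channel 2
    that is a +k px shifted copy of channel 1 peaks at -k px.
    """
    h, w = pair.channel1.shape
    max_px = int(max_shift_nm / pair.pixel_size_nm)
    if max_px > w // 2:
        raise ValueError("max shift exceeds half the image width")
    shifts_px = np.arange(-max_px, max_px + 1)
    coeffs = []
    for dx in shifts_px:
        if dx >= 0:
            a = pair.channel1[:, dx:]
            b = pair.channel2[:, : w - dx]
        else:
            a = pair.channel1[:, :w + dx]
            b = pair.channel2[:, -dx:]
        coeffs.append(
            masked_pearson(ImagePair(a, b, pair.pixel_size_nm), low_fraction)
        )
    return CCFCurve(shifts_px * pair.pixel_size_nm, np.asarray(coeffs))


def temporal_coloc_normalize(coefficients) -> np.ndarray:
    """Min-max normalization P -> (P - Pmin)/(Pmax - Pmin)."""
    p = np.asarray(coefficients, float)
    if p.size < 2:
        raise ValueError("need >= 2 coefficients")
    span = p.max() - p.min()
    if span == 0:
        raise ValueError("constant series: zero range")
    return (p - p.min()) / span


def lag_estimate(a: SignalTrace, b: SignalTrace, max_lag: float) -> float:
    """Lag (min) maximizing the cross-correlation of mean-removed traces.

    Positive result means ``b`` follows ``a``. Both traces must share a
    sampling interval; the search covers integer-sample lags within
    ±``max_lag`` with overlap-normalized correlation.
    """
    if abs(a.dt_sample - b.dt_sample) > 1e-12:
        raise ValueError("traces must share the sampling interval")
    va = a.values - a.values.mean()
    vb = b.values - b.values.mean()
    if np.allclose(va, 0) or np.allclose(vb, 0):
        raise ValueError("zero-variance trace")
    max_k = int(round(max_lag / a.dt_sample))
    best_k, best_r = 0, -np.inf
    for k in range(-max_k, max_k + 1):
        if k >= 0:
            x, y = va[: va.size - k] if k else va, vb[k:]
        else:
            x, y = va[-k:], vb[: vb.size + k]
        m = min(x.size, y.size)
        if m < 2:
            continue
        x, y = x[:m], y[:m]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        if r > best_r:
            best_r, best_k = r, k
    return best_k * a.dt_sample
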