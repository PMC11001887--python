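"""Seeded generators of synthetic inputs with known ground truth.

Every generator is deterministic for a given seed and returns its ground
truth alongside the data, so downstream estimators (ruffle detection, lag
estimation, shift recovery, bleach correction, fiber polarity) can be
round-trip tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import ImagePair
from .geometry import BoundaryPolygon
from .metrics import SignalTrace

__all__ = [
    "CascadeSpec",
    "make_ruffled_polygon",
    "make_pulse_cascade",
    "make_shifted_image_pair",
    "make_bleached_trace",
    "make_fiber_image",
]


@dataclass
class CascadeSpec:
    """Specification of a multichannel pulsatile lag cascade.

    Channels share one period; channel k is delayed behind channel k-1 by
    ``lags[k-1]`` minutes (defaults mirror the measured signal ordering:
    protrusive activity leads the local area increase by ~3 min, contractile
    activity follows by ~1 min, the actomyosin pulse ~2 min later, adhesion
    densification last).
    """

    period: float = 8.0
    labels: tuple[str, ...] = ("rac", "area", "rho", "actomyosin", "adhesion")
    lags: tuple[float, ...] = (3.0, 1.0, 2.0, 1.0)
    noise_sd: float = 0.0  # fraction of pulse amplitude
    duration: float = 60.0
    dt_sample: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if len(self.lags) != len(self.labels) - 1:
            raise ValueError("need one lag per consecutive channel pair")
        if any(abs(l) >= self.period / 2 for l in self.lags):
            raise ValueError("|lags| must be < period/2")
        if self.lags and self.dt_sample > min(abs(l) for l in self.lags if l != 0):
            raise ValueError("dt_sample must resolve the smallest lag")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_ruffled_polygon(
    base_radius: float = 5.0,
    n_lobes: int = 0,
    amplitude: float = 0.0,
    n_points: int = 180,
    seed: int = 0,
    frame_time: float = 0.0,
    cell_id: str = "synthetic",
) -> BoundaryPolygon:
    """Rose-modulated circle r(theta) = R*(1 + amplitude*cos(n_lobes*theta)).

    ``n_lobes = 0`` gives a plain circle. The seed rotates the lobe pattern
    by a random phase so repeated draws differ.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    if n_lobes < 0:
        raise ValueError("n_lobes must be >= 0")
    if not 0 <= amplitude < base_radius:
        raise ValueError("amplitude must be in [0, base_radius)")
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0, 2 * np.pi)) if n_lobes > 0 else 0.0
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    if n_lobes > 0:
        r = base_radius + amplitude * np.cos(n_lobes * theta + phase)
    else:
        r = np.full(n_points, base_radius)
    v = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    return BoundaryPolygon(v, frame_time=frame_time, cell_id=cell_id)


def make_pulse_cascade(spec: CascadeSpec) -> tuple[dict[str, SignalTrace], dict]:
    """Raised-cosine pulse trains with cumulative inter-channel lags.

    Returns (traces by label, ground truth with the pairwise lags).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, spec.dt_sample)
    cum_lags = np.concatenate([[0.0], np.cumsum(spec.lags)])
    traces: dict[str, SignalTrace] = {}
    for label, lag in zip(spec.labels, cum_lags):
        base = 0.5 * (1.0 + np.cos(2 * np.pi * (t - lag) / spec.period))
        if spec.noise_sd > 0:
            base = base + spec.noise_sd * rng.standard_normal(t.size)
        traces[label] = SignalTrace(base, spec.dt_sample, label=label)
    truth = {
        "period": spec.period,
        "pairwise_lags": {
            f"{a}->{b}": float(l)
            for (a, b), l in zip(zip(spec.labels, spec.labels[1:]), spec.lags)
        },
        "seed": spec.seed,
    }
    return traces, truth


def make_shifted_image_pair(
    size: int = 128,
    blob_density: float = 0.002,
    shift: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size_nm: float = 100.0,
    blob_sigma: float = 2.0,
    independent: bool = False,
) -> tuple[ImagePair, dict]:
    """Random Gaussian-blob texture plus an x-shifted (or independent) copy.

    channel2 is channel1 translated by ``shift`` pixels along +x (circular)
    with optional additive noise; ``independent=True`` draws a fresh blob
    field instead (null fixture). Returns (pair, ground truth).
    """
    if abs(shift) >= size // 4:
        raise ValueError("|shift| must be < size/4")
    rng = np.random.default_rng(seed)

    def blobs(local_rng: np.random.Generator) -> np.ndarray:
        n_blobs = max(1, int(blob_density * size * size))
        img = np.zeros((size, size))
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(n_blobs):
            cy, cx = local_rng.uniform(0, size, 2)
            amp = local_rng.uniform(0.5, 1.0)
            img += amp * np.exp(
                -(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * blob_sigma**2))
            )
        return img

    c1 = blobs(rng)
    c2 = blobs(rng) if independent else np.roll(c1, shift, axis=1)
    if noise_sd > 0:
        c2 = c2 + noise_sd * rng.standard_normal(c2.shape)
        c2 = np.clip(c2, 0.0, None)
    pair = ImagePair(c1, c2, pixel_size_nm)
    truth = {
        "shift_px": 0 if independent else int(shift),
        "expected_peak_shift_nm": None
        if independent
        else -float(shift) * pixel_size_nm,
        "independent": bool(independent),
        "seed": seed,
    }
    return pair, truth


def make_bleached_trace(
    base_trace: SignalTrace,
    decay_rate: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    background_level: float = 100.0,
) -> tuple[SignalTrace, SignalTrace, dict]:
    """Exponential photobleaching applied to a signal plus a background.

    observed = base * exp(-decay_rate * t) (+ noise);
    background = background_level * exp(-decay_rate * t).
    """
    if decay_rate < 0:
        raise ValueError("decay_rate must be >= 0")
    rng = np.random.default_rng(seed)
    t = base_trace.times
    decay = np.exp(-decay_rate * t)
    observed = base_trace.values * decay
    if noise_sd > 0:
        observed = observed + noise_sd * rng.standard_normal(t.size)
    background = background_level * decay
    truth = {"decay_rate": decay_rate, "seed": seed}
    return (
        SignalTrace(observed, base_trace.dt_sample, base_trace.label or "observed"),
        SignalTrace(background, base_trace.dt_sample, "background"),
        truth,
    )


def make_fiber_image(
    size: int = 128,
    orientation_mix: dict[float, float] | None = None,
    line_density: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Anti-aliased straight segments at specified orientations.

    ``orientation_mix`` maps line direction (degrees from +x) to its weight;
    weights must sum to 1. Returns (image, ground truth).
    """
    from skimage.draw import line_aa

    orientation_mix = orientation_mix if orientation_mix is not None else {90.0: 1.0}
    weights = np.asarray(list(orientation_mix.values()), float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("orientation weights must sum to 1")
    rng = np.random.default_rng(seed)
    img = np.zeros((size, size))
    n_lines = max(1, int(line_density * size))
    angles = list(orientation_mix.keys())
    counts = np.round(weights * n_lines).astype(int)
    counts[0] += n_lines - counts.sum()
    length = size * 0.6
    for ang, cnt in zip(angles, counts):
        # image row = -y, so a +ang line direction maps to (-sin, cos) in (r, c)
        dr = -np.sin(np.deg2rad(ang)) * length / 2
        dc = np.cos(np.deg2rad(ang)) * length / 2
        for _ in range(int(cnt)):
            r0, c0 = rng.uniform(size * 0.2, size * 0.8, 2)
            rr, cc, val = line_aa(
                int(round(r0 - dr)), int(round(c0 - dc)),
                int(round(r0 + dr)), int(round(c0 + dc)),
            )
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            img[rr[keep], cc[keep]] = np.maximum(img[rr[keep], cc[keep]], val[keep])
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(img.shape)
        img = np.clip(img, 0.0, None)
    truth = {"orientation_mix": dict(orientation_mix), "seed": seed}
    return img, truth
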