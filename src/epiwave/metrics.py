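"""Cell-shape, kinematics and signal metrics.

Applied identically to simulated trajectories and synthetic boundaries or
traces: circularity, 3-D volume / flattening, curvature-based ruffle
detection with rose-diagram binning, migration kinematics, autocorrelation
period, photobleaching correction, oriented-filter fiber polarity, and
phase segmentation of circularity traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .geometry import (
    AxisFrame,
    BoundaryPolygon,
    GeometryError,
    discrete_curvature,
    outward_normal,
    polygon_measures,
)

__all__ = [
    "CellGeometry3D",
    "SignalTrace",
    "RuffleEvent",
    "circularity",
    "cell_volume",
    "flatten_ratio",
    "detect_ruffles",
    "count_ruffle_arcs",
    "ruffle_rose",
    "migration_kinematics",
    "autocorr_period",
    "bleach_correct",
    "fiber_polarity",
    "phase_segment",
]


@dataclass(frozen=True)
class CellGeometry3D:
    """Apical area, basal area (um^2) and height (um) of one cell."""

    s_apical: float
    s_basal: float
    height: float

    def __post_init__(self):
        if self.s_apical <= 0 or self.s_basal <= 0 or self.height <= 0:
            raise ValueError("areas and height must be > 0")


@dataclass
class SignalTrace:
    """Uniformly sampled scalar time series."""

    values: np.ndarray
    dt_sample: float
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("trace needs >= 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be > 0")
        self.values = v

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt_sample


@dataclass(frozen=True)
class RuffleEvent:
    """A de-novo outward protrusion: frame time, vertex arc, orientation."""

    frame_time: float
    arc: tuple[int, ...]
    orientation_deg: float


def circularity(poly: BoundaryPolygon) -> float:
    """Circularity index 4*pi*area / perimeter^2 (1 = circle, lower = ruffled)."""
    m = polygon_measures(poly)
    if m["perimeter"] <= 0:
        raise GeometryError("zero perimeter")
    return 4.0 * np.pi * m["area"] / m["perimeter"] ** 2


def cell_volume(g: CellGeometry3D) -> float:
    """Truncated-cone volume H*(S_a + sqrt(S_a*S_b) + S_b)/3."""
    return g.height * (g.s_apical + np.sqrt(g.s_apical * g.s_basal) + g.s_basal) / 3.0


def flatten_ratio(g: CellGeometry3D) -> float:
    """Flattening measure sqrt(S_a + S_b) / H."""
    if g.height <= 0:
        raise ValueError("height must be > 0")
    return np.sqrt(g.s_apical + g.s_basal) / g.height


# ---------------------------------------------------------------------------
# Ruffles


def _ruffle_arcs(
    poly: BoundaryPolygon,
    curvature_threshold: float | None,
    min_arc_len: int,
    smooth_window: int,
) -> list[np.ndarray]:
    """Maximal circular runs of vertices with curvature above threshold."""
    if curvature_threshold is None:
        # default: twice the curvature of the equivalent circle
        curvature_threshold = 2.0 / polygon_measures(poly)["equivdiameter"]
    kappa = discrete_curvature(poly, smooth_window)
    above = kappa > curvature_threshold
    if not above.any():
        return []
    if above.all():
        return [np.arange(above.size)]
    n = above.size
    # rotate so position 0 is below threshold, then split into runs
    start = int(np.argmin(above))
    rolled = np.roll(above, -start)
    idx = np.arange(n)
    runs, current = [], []
    for k in range(n):
        if rolled[k]:
            current.append((k + start) % n)
        elif current:
            runs.append(np.asarray(current))
            current = []
    if current:
        runs.append(np.asarray(current))
    return [r for r in runs if r.size >= min_arc_len]


def count_ruffle_arcs(
    poly: BoundaryPolygon,
    curvature_threshold: float | None = None,
    min_arc_len: int = 3,
    smooth_window: int = 3,
) -> int:
    """Number of above-threshold convex arcs in a single frame."""
    return len(_ruffle_arcs(poly, curvature_threshold, min_arc_len, smooth_window))


def _arc_orientation(poly: BoundaryPolygon, arc: np.ndarray, axis: AxisFrame) -> float:
    mid = arc[arc.size // 2]
    n = outward_normal(poly, int(mid))
    ang = np.degrees(np.arctan2(float(n @ axis.dv), float(n @ axis.ap)))
    return float(ang % 360.0)


def detect_ruffles(
    trajectory: list[BoundaryPolygon],
    curvature_threshold: float | None = None,
    min_arc_len: int = 3,
    smooth_window: int = 3,
    axis: AxisFrame | None = None,
) -> list[RuffleEvent]:
    """De-novo outward protrusions along a single cell's frame sequence.

    A ruffle is a maximal contiguous arc with curvature above threshold
    (default 2/equivdiameter) and at least ``min_arc_len`` vertices that has
    no overlapping above-threshold arc in the previous frame. Frames must
    share a vertex count so arcs are comparable by index.
    """
    if len(trajectory) < 2:
        raise ValueError("need >= 2 frames to detect de-novo ruffles")
    axis = axis or AxisFrame()
    events: list[RuffleEvent] = []
    prev_covered: np.ndarray | None = None
    for frame_no, poly in enumerate(trajectory):
        arcs = _ruffle_arcs(poly, curvature_threshold, min_arc_len, smooth_window)
        covered = np.zeros(poly.n_vertices, bool)
        for arc in arcs:
            covered[arc] = True
        if frame_no > 0 and prev_covered is not None:
            for arc in arcs:
                if prev_covered.size == covered.size and prev_covered[arc].any():
                    continue  # persisted from the previous frame
                events.append(
                    RuffleEvent(
                        frame_time=float(poly.frame_time),
                        arc=tuple(int(i) for i in arc),
                        orientation_deg=_arc_orientation(poly, arc, axis),
                    )
                )
        prev_covered = covered
    return events


def ruffle_rose(events: list[RuffleEvent], axis: AxisFrame | None = None) -> np.ndarray:
    """12-bin orientation histogram; half-open 30-degree bins [k*30, (k+1)*30)."""
    counts = np.zeros(12, dtype=int)
    for ev in events:
        ang = ev.orientation_deg % 360.0
        counts[int(ang // 30.0) % 12] += 1
    return counts


# ---------------------------------------------------------------------------
# Kinematics and traces


def migration_kinematics(
    centroids: np.ndarray, times: np.ndarray, axis: AxisFrame | None = None
) -> dict:
    """Total displacement distance and per-axis mean velocities.

    distance = |final - initial centroid|; v_ap / v_dv are the A-P and D-V
    displacement components divided by elapsed time.
    """
    axis = axis or AxisFrame()
    c = np.asarray(centroids, float)
    t = np.asarray(times, float)
    if c.shape[0] < 2 or t.size != c.shape[0]:
        raise ValueError("need >= 2 centroid frames with matching times")
    elapsed = float(t[-1] - t[0])
    if elapsed <= 0:
        raise ValueError("zero elapsed time")
    disp = c[-1] - c[0]
    return {
        "distance": float(np.hypot(*disp)),
        "v_ap": float(disp @ axis.ap) / elapsed,
        "v_dv": float(disp @ axis.dv) / elapsed,
    }


def autocorr_period(trace: SignalTrace) -> float | None:
    """Dominant period from the first autocorrelation maximum after lag 0.

    The trace is mean-removed; the search is restricted to lags in
    [2*dt_sample, duration/2]. Returns None when no secondary peak exists
    (aperiodic or constant input).
    """
    v = trace.values - trace.values.mean()
    n = v.size
    if np.allclose(v, 0.0):
        return None
    ac = np.correlate(v, v, mode="full")[n - 1 :]
    ac = ac / ac[0]
    lo = max(2, 2)
    hi = n // 2
    if hi <= lo + 1:
        return None
    peaks, _ = sp_signal.find_peaks(ac[: hi + 1])
    peaks = peaks[peaks >= lo]
    if peaks.size == 0:
        return None
    return float(peaks[0] * trace.dt_sample)


def bleach_correct(
    trace: SignalTrace, background: SignalTrace, drop_threshold: float = 0.05
) -> SignalTrace:
    """Photobleaching correction driven by the background channel.

    If the largest intensity drop between adjacent background frames is
    below ``drop_threshold`` (default 5%) the trace is returned unchanged.
    Otherwise a single exponential decay is fitted to the background and the
    trace is divided by the fitted decay normalised to its first frame.
    """
    if trace.values.size != background.values.size:
        raise ValueError("trace and background must have equal length")
    b = background.values
    if np.any(b <= 0):
        raise ValueError("background must be strictly positive")
    drops = (b[:-1] - b[1:]) / b[:-1]
    if drops.size == 0 or np.max(drops) < drop_threshold:
        return SignalTrace(trace.values.copy(), trace.dt_sample, trace.label)
    t = background.times
    slope, intercept = np.polyfit(t, np.log(b), 1)
    fitted = np.exp(intercept + slope * t)
    decay = fitted / fitted[0]
    return SignalTrace(trace.values / decay, trace.dt_sample, trace.label)


# ---------------------------------------------------------------------------
# Fiber polarity


def fiber_polarity(
    image: np.ndarray,
    axis: AxisFrame | None = None,
    n_orientations: int = 12,
    frequency: float = 0.2,
) -> dict:
    """Orientation histogram of fibrous texture and the D-V-isolated image.

    A bank of ``n_orientations`` oriented (Gabor) filters evenly spaced over
    [0, 180) degrees is applied; each foreground pixel votes for the
    orientation with the strongest response magnitude. Angles are line
    directions measured from the A-P (+x) axis. Returns the histogram, the
    bin angles, and the response magnitude at the orientation nearest the
    D-V axis.
    """
    from skimage.filters import gabor, threshold_otsu

    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    axis = axis or AxisFrame()
    angles = np.linspace(0.0, 180.0, n_orientations, endpoint=False)
    responses = []
    for ang in angles:
        # skimage's theta=0 responds to structures along y; a line at
        # direction `ang` from +x is matched by theta = 90 - ang.
        theta = np.deg2rad(90.0 - ang)
        real, imag = gabor(img, frequency=frequency, theta=theta)
        responses.append(np.hypot(real, imag))
    stack = np.stack(responses)
    if img.max() <= img.min():
        raise ValueError("empty foreground: image is constant")
    mask = img > threshold_otsu(img)
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    dominant = np.argmax(stack, axis=0)[mask]
    hist = np.bincount(dominant, minlength=n_orientations)
    dv_angle = float(np.degrees(np.arctan2(axis.dv[1], axis.dv[0]))) % 180.0
    dv_bin = int(np.argmin(np.abs((angles - dv_angle + 90) % 180 - 90)))
    return {
        "angles_deg": angles,
        "histogram": hist,
        "dv_isolated": stack[dv_bin],
        "dv_bin": dv_bin,
    }


# ---------------------------------------------------------------------------
# Phase segmentation


def phase_segment(
    trace: SignalTrace, smooth_window: int = 5, slope_tol: float | None = None
) -> dict:
    """Locate ruffling and increasing onsets in a circularity trace.

    The trace is smoothed by a moving average; ``ruffling_onset`` is the
    start of the run of declining slope with the largest total fall, and
    ``increasing_onset`` the start of the subsequent positive-slope run
    with the largest total rise. Both are in minutes; missing transitions
    are returned as None. Slope-sign based, hence invariant to uniform
    scaling of the values.
    """
    v = trace.values
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.concatenate([np.full(pad, v[0]), v, np.full(pad, v[-1])])
        v = np.convolve(padded, kernel, mode="valid")
    slope = np.diff(v)
    if slope_tol is None:
        scale = float(np.max(np.abs(slope))) if slope.size else 0.0
        slope_tol = 0.10 * scale

    def runs(mask: np.ndarray) -> list[tuple[int, int]]:
        out, start = [], None
        for i, m in enumerate(mask):
            if m and start is None:
                start = i
            elif not m and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, mask.size))
        return out

    neg_runs = runs(slope < -slope_tol)
    ruffling_onset = None
    decline_end = 0
    if neg_runs:
        falls = [v[a] - v[b] for a, b in neg_runs]
        best = int(np.argmax(falls))
        if falls[best] > 0:
            a, b = neg_runs[best]
            ruffling_onset = a * trace.dt_sample
            decline_end = a

    pos_runs = [(a, b) for a, b in runs(slope > slope_tol) if a >= decline_end]
    increasing_onset = None
    if ruffling_onset is not None and pos_runs:
        rises = [v[b] - v[a] for a, b in pos_runs]
        best = int(np.argmax(rises))
        if rises[best] > 0:
            increasing_onset = pos_runs[best][0] * trace.dt_sample
    if ruffling_onset is None and increasing_onset is None:
        return {"ruffling_onset": None, "increasing_onset": None}
    return {"ruffling_onset": ruffling_onset, "increasing_onset": increasing_onset}
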