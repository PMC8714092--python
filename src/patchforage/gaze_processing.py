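"""Signal-level processing of eye-position traces for the visual-search task.

Implements saccade detection (velocity threshold on smoothed 1-ms-resampled
traces), the task's screen geometry (12 environmental fractals in three
rings, 4 possible target locations, a central start position, and per-object
gaze windows on a 100x100 bin grid), per-trial decomposition of search time
into gaze components, object-inspection counting, and gaze heatmaps.

Coordinate convention: screen-centered degrees of visual angle, +x right,
+y up; ring rotations are applied counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "Saccade",
    "TaskGeometry",
    "ComponentDurations",
    "InitialSaccade",
    "regularize_trace",
    "detect_saccades",
    "classify_initial_saccade",
    "assign_gaze_components",
    "count_inspected_fractals",
    "gaze_heatmap",
    "gaze_fraction_at_location",
]

#: Saccade velocity threshold, degrees per millisecond.
VELOCITY_THRESHOLD = 0.025
#: Width of the moving-mean velocity smoother, milliseconds.
SMOOTH_MS = 15
#: Minimum saccade amplitude, degrees; smaller movements are ignored.
MIN_AMPLITUDE = 1.0
#: Radius defining "direct" saccades and novel-fractal proximity, degrees.
DIRECT_RADIUS = 1.5
#: Minimum cumulative dwell for an environmental fractal to count as
#: inspected, milliseconds.
INSPECT_DWELL_MS = 50
#: Bins per gaze window (approximately a 3-degree-radius circle).
WINDOW_BINS = 77


@dataclass(frozen=True)
class Saccade:
    """One detected saccade (times in ms, positions in degrees)."""

    t_start: float
    t_end: float
    x_start: float
    y_start: float
    x_end: float
    y_end: float
    amplitude: float
    peak_velocity: float


@dataclass(frozen=True)
class ComponentDurations:
    """Partition of one trial's search duration into gaze components (s)."""

    environmental: float
    target: float
    start: float
    other: float

    @property
    def total(self) -> float:
        return self.environmental + self.target + self.start + self.other


@dataclass(frozen=True)
class InitialSaccade:
    """Classification of the first search saccade relative to the target.

    ``direct`` is None when no saccade occurred in the search window
    (a "no-response" trial).
    """

    direct: bool | None
    angle_to_target: float | None
    saccade: Saccade | None


def _polar(ecc: float, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([ecc * np.cos(a), ecc * np.sin(a)])


class TaskGeometry:
    """Screen layout of the probabilistic visual-search task.

    Twelve environmental fractals in three radially symmetric rings: inner
    at 6 deg eccentricity rotated -22.5 deg from the cardinal axes, middle at
    15 deg rotated +22.5 deg, outer at 17.5 deg rotated -22.5 deg. Four
    possible target locations at 12 deg eccentricity, canted at 40, 130, 220
    and 310 deg. The start (trial-start cue) position is the screen center.

    Gaze windows are the 77 grid bins nearest each object's center on a
    100x100 grid spanning a 61x61 deg square (bin edge 0.61 deg; the window
    is approximately a 3-deg-radius circle). Environmental and start windows
    are verified disjoint at construction; target windows can graze the
    nearest middle-ring windows and are resolved by assignment priority
    (target > start > environmental > other).
    """

    grid_extent = 61.0
    n_bins = 100

    def __init__(self):
        edges = np.linspace(-self.grid_extent / 2, self.grid_extent / 2,
                            self.n_bins + 1)
        self.bin_edges = edges
        centers = (edges[:-1] + edges[1:]) / 2
        bx, by = np.meshgrid(centers, centers, indexing="ij")
        self._bin_centers = np.column_stack([bx.ravel(), by.ravel()])

        self.environmental_positions = np.array(
            [_polar(6.0, a - 22.5) for a in (0, 90, 180, 270)]
            + [_polar(15.0, a + 22.5) for a in (0, 90, 180, 270)]
            + [_polar(17.5, a - 22.5) for a in (0, 90, 180, 270)])
        self.target_positions = np.array(
            [_polar(12.0, a) for a in (40, 130, 220, 310)])
        self.start_position = np.zeros(2)

        self.environmental_windows = [
            self._window(p) for p in self.environmental_positions]
        self.target_windows = [self._window(p) for p in self.target_positions]
        self.start_window = self._window(self.start_position)

        exclusive = self.environmental_windows + [self.start_window]
        for i in range(len(exclusive)):
            for j in range(i + 1, len(exclusive)):
                if exclusive[i] & exclusive[j]:
                    raise ValueError(
                        "environmental/start gaze windows overlap; "
                        "geometry is inconsistent")

    def _window(self, center: np.ndarray) -> frozenset:
        d = np.hypot(self._bin_centers[:, 0] - center[0],
                     self._bin_centers[:, 1] - center[1])
        order = np.argsort(d, kind="stable")
        return frozenset(order[:WINDOW_BINS].tolist())

    def bin_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Flat grid-bin index per sample; -1 for samples off the grid."""
        half = self.grid_extent / 2
        width = self.grid_extent / self.n_bins
        ix = np.floor((np.asarray(x) + half) / width).astype(int)
        iy = np.floor((np.asarray(y) + half) / width).astype(int)
        inside = (ix >= 0) & (ix < self.n_bins) & (iy >= 0) & (iy < self.n_bins)
        out = np.where(inside, ix * self.n_bins + iy, -1)
        return out

    def window_mask(self, window: frozenset) -> np.ndarray:
        mask = np.zeros(self.n_bins * self.n_bins, dtype=bool)
        mask[list(window)] = True
        return mask


def regularize_trace(trace: pd.DataFrame) -> pd.DataFrame:
    """Resample a gaze trace to 1-ms spacing by linear interpolation.

    Invalid samples (blinks, track loss) are interpolated across for the
    position signal but the returned ``valid`` flag marks every 1-ms sample
    falling inside an invalid span.
    """
    if len(trace) == 0:
        raise ValueError("empty gaze trace")
    t = trace["t_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    grid = np.arange(np.ceil(t[0]), np.floor(t[-1]) + 1)
    valid = trace["valid"].to_numpy(dtype=bool) if "valid" in trace else \
        np.ones(len(trace), dtype=bool)
    if not valid.any():
        return pd.DataFrame({"t_ms": grid,
                             "x_deg": np.full(len(grid), np.nan),
                             "y_deg": np.full(len(grid), np.nan),
                             "valid": np.zeros(len(grid), dtype=bool)})
    tv = t[valid]
    x = np.interp(grid, tv, trace["x_deg"].to_numpy(dtype=float)[valid])
    y = np.interp(grid, tv, trace["y_deg"].to_numpy(dtype=float)[valid])
    valid_grid = np.interp(grid, t, valid.astype(float)) >= 1.0
    return pd.DataFrame({"t_ms": grid, "x_deg": x, "y_deg": y,
                         "valid": valid_grid})


def detect_saccades(trace: pd.DataFrame) -> list[Saccade]:
    """Velocity-threshold saccade detection.

    Pipeline: linear interpolation to 1-ms spacing, velocity by
    differentiation, 15-ms moving-mean smoothing, threshold at
    0.025 deg/ms; contiguous super-threshold periods are saccades, with
    start/end positions taken at the period boundaries. Saccades covering
    less than 1 deg of distance are discarded.
    """
    reg = regularize_trace(trace)
    if not reg["valid"].any():
        return []
    if len(reg) <= SMOOTH_MS:
        raise ValueError(
            f"trace too short for the {SMOOTH_MS}-ms smoothing window")
    x = reg["x_deg"].to_numpy()
    y = reg["y_deg"].to_numpy()
    t = reg["t_ms"].to_numpy()
    speed = np.hypot(np.diff(x), np.diff(y))  # deg per ms
    speed = uniform_filter1d(speed, size=SMOOTH_MS, mode="nearest")
    above = speed > VELOCITY_THRESHOLD
    # run boundaries of super-threshold periods
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1) if edges.size else []
    ends = list(edges[above[edges]] + 1) if edges.size else []
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    out = []
    for s, e in zip(starts, ends):
        # velocity sample v[i] spans positions i -> i+1
        amp = float(np.hypot(x[e] - x[s], y[e] - y[s]))
        if amp < MIN_AMPLITUDE:
            continue
        out.append(Saccade(
            t_start=float(t[s]), t_end=float(t[e]),
            x_start=float(x[s]), y_start=float(y[s]),
            x_end=float(x[e]), y_end=float(y[e]),
            amplitude=amp,
            peak_velocity=float(speed[s:e].max())))
    return out


def classify_initial_saccade(
    trial, saccades: list[Saccade], geometry: TaskGeometry
) -> InitialSaccade:
    """Classify the first search saccade as direct or not.

    A saccade is *direct* when its endpoint lands within 1.5 deg of the
    target fractal's center. The angle to target is the signed angular
    difference (degrees, in (-180, 180]) between the saccade endpoint's
    direction from screen center and the target's direction.
    """
    if not saccades:
        return InitialSaccade(None, None, None)
    first = saccades[0]
    target = geometry.target_positions[int(trial["target_location"])]
    dist = float(np.hypot(first.x_end - target[0], first.y_end - target[1]))
    sacc_angle = np.rad2deg(np.arctan2(first.y_end, first.x_end))
    tgt_angle = np.rad2deg(np.arctan2(target[1], target[0]))
    angle = (sacc_angle - tgt_angle + 180.0) % 360.0 - 180.0
    return InitialSaccade(dist <= DIRECT_RADIUS, float(angle), first)


def _search_window(trace: pd.DataFrame, trial) -> pd.DataFrame:
    reg = regularize_trace(trace)
    lo, hi = float(trial["search_start_ms"]), float(trial["search_end_ms"])
    return reg[(reg.t_ms >= lo) & (reg.t_ms < hi)]


def assign_gaze_components(
    trace: pd.DataFrame, trial, geometry: TaskGeometry
) -> ComponentDurations:
    """Partition the search duration into the four gaze components.

    Every 1-ms sample of the search period is assigned to exactly one of:
    gaze at the target fractal's window, gaze at the start (trial-start cue)
    window, gaze at any environmental fractal's window, or all other search
    time. Priority when windows could both claim a sample:
    target > start > environmental > other. Invalid (blink) samples count as
    "other". The four components sum to the search duration exactly.
    """
    seg = _search_window(trace, trial)
    bins = geometry.bin_index(seg["x_deg"].to_numpy(),
                              seg["y_deg"].to_numpy())
    valid = seg["valid"].to_numpy()
    bins = np.where(valid & (bins >= 0), bins, -1)

    tgt_mask = geometry.window_mask(
        geometry.target_windows[int(trial["target_location"])])
    start_mask = geometry.window_mask(geometry.start_window)
    env_mask = np.zeros_like(start_mask)
    for w in geometry.environmental_windows:
        env_mask |= geometry.window_mask(w)

    ok = bins >= 0
    in_tgt = np.zeros(len(bins), dtype=bool)
    in_start = np.zeros(len(bins), dtype=bool)
    in_env = np.zeros(len(bins), dtype=bool)
    in_tgt[ok] = tgt_mask[bins[ok]]
    in_start[ok] = start_mask[bins[ok]] & ~in_tgt[ok]
    in_env[ok] = env_mask[bins[ok]] & ~in_tgt[ok] & ~in_start[ok]
    n_other = len(bins) - in_tgt.sum() - in_start.sum() - in_env.sum()
    return ComponentDurations(
        environmental=float(in_env.sum()) / 1000.0,
        target=float(in_tgt.sum()) / 1000.0,
        start=float(in_start.sum()) / 1000.0,
        other=float(n_other) / 1000.0,
    )


def count_inspected_fractals(
    trace: pd.DataFrame, geometry: TaskGeometry,
    trial=None,
) -> int:
    """Number of environmental fractals with >= 50 ms cumulative gaze.

    Operates on the search-period trace (pass ``trial`` to clip to the
    search window, or pre-clip the trace).
    """
    seg = _search_window(trace, trial) if trial is not None else \
        regularize_trace(trace)
    bins = geometry.bin_index(seg["x_deg"].to_numpy(),
                              seg["y_deg"].to_numpy())
    valid = seg["valid"].to_numpy() & (bins >= 0)
    count = 0
    for w in geometry.environmental_windows:
        mask = geometry.window_mask(w)
        dwell = int(mask[bins[valid]].sum())
        if dwell >= INSPECT_DWELL_MS:
            count += 1
    return count


def gaze_heatmap(
    traces: list[pd.DataFrame], geometry: TaskGeometry
) -> np.ndarray:
    """Mean milliseconds of gaze per grid bin per trial (100x100 array).

    Each trace should already be clipped to its trial's search period.
    The grid total equals the mean in-grid search milliseconds per trial.
    """
    if not traces:
        raise ValueError("need at least one trial")
    acc = np.zeros(geometry.n_bins * geometry.n_bins)
    for trace in traces:
        reg = regularize_trace(trace)
        bins = geometry.bin_index(reg["x_deg"].to_numpy(),
                                  reg["y_deg"].to_numpy())
        ok = reg["valid"].to_numpy() & (bins >= 0)
        np.add.at(acc, bins[ok], 1.0)
    return (acc / len(traces)).reshape(geometry.n_bins, geometry.n_bins)


def gaze_fraction_at_location(
    trace: pd.DataFrame, center, radius: float = DIRECT_RADIUS,
    trial=None,
) -> float:
    """Fraction of the search period spent within ``radius`` of a location."""
    seg = _search_window(trace, trial) if trial is not None else \
        regularize_trace(trace)
    if len(seg) == 0:
        raise ValueError("zero-length search period: fraction undefined")
    d = np.hypot(seg["x_deg"].to_numpy() - center[0],
                 seg["y_deg"].to_numpy() - center[1])
    return float((seg["valid"].to_numpy() & (d <= radius)).mean())
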