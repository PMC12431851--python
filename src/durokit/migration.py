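"""Cell-trajectory statistics for time-lapse migration assays.

Per-track metrics (path length, net displacement, mean speed, directionality
a.k.a. straightness, forward migration index, end-to-end angle), population
rose histograms, coverage filtering, ensemble drift correction and a
boundary-crossing invasion fraction.

Conventions
-----------
* the forward migration index (FMI) divides the net displacement component
  along the reference axis by the *accumulated path length* (the standard
  chemotaxis-tool convention), so |FMI| <= directionality <= 1;
* the per-track angle is the end-to-end angle relative to the reference
  axis, in degrees in (-180, 180], with angular bins half-open (a, b];
* speeds use actual timestamps — no constant frame interval is assumed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DurokitError

AXES = {"+x": (1.0, 0.0), "-x": (-1.0, 0.0), "+y": (0.0, 1.0), "-y": (0.0, -1.0)}


def parse_axis(axis):
    """Accept '+x'-style labels or explicit (dx, dy) vectors; returns a unit vector."""
    if isinstance(axis, str):
        try:
            v = np.array(AXES[axis])
        except KeyError:
            raise ValueError(f"unknown axis label {axis!r}; use one of {sorted(AXES)}")
    else:
        v = np.asarray(axis, dtype=float)
        norm = np.hypot(*v)
        if norm == 0:
            raise ValueError("axis vector must be nonzero")
        v = v / norm
    return v


@dataclass
class Track:
    """One cell trajectory: strictly increasing times (s), positions (µm)."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise ValueError(f"track {self.track_id}: t, x, y must be equal-length 1-D")
        if len(self.t) < 2:
            raise ValueError(f"track {self.track_id}: needs at least 2 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")

    def __len__(self):
        return len(self.t)

    @property
    def span(self) -> float:
        """Observed duration in seconds."""
        return float(self.t[-1] - self.t[0])


@dataclass
class TrackMetrics:
    track_id: str
    path_length: float  # µm
    net_displacement: float  # µm
    mean_speed: float  # µm/min
    directionality: float  # net/path, in [0, 1]
    fmi_parallel: float  # in [-1, 1]
    fmi_perpendicular: float
    end_angle: float  # degrees in (-180, 180], relative to the reference axis


@dataclass
class RoseHistogram:
    bin_edges: np.ndarray  # degrees, partitioning (-180, 180]
    counts: np.ndarray  # per-bin track counts
    reference_axis: tuple
    n_excluded: int = 0  # tracks with zero net displacement

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have one more entry than counts")


def track_metrics(track: Track, gradient_axis="+x") -> TrackMetrics:
    """Standard per-track migration statistics relative to a gradient axis."""
    axis = parse_axis(gradient_axis)
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    path = float(np.sum(np.hypot(dx, dy)))
    net_vec = np.array([track.x[-1] - track.x[0], track.y[-1] - track.y[0]])
    net = float(np.hypot(*net_vec))
    elapsed = track.span
    if elapsed <= 0:
        raise DurokitError(f"track {track.track_id}: zero elapsed time")
    speed = path / (elapsed / 60.0)
    perp = np.array([-axis[1], axis[0]])
    if path > 0:
        directionality = net / path
        fmi_par = float(net_vec @ axis) / path
        fmi_perp = float(net_vec @ perp) / path
    else:
        directionality = fmi_par = fmi_perp = 0.0
    ang = math.degrees(math.atan2(float(net_vec @ perp), float(net_vec @ axis)))
    if ang <= -180.0:
        ang += 360.0
    return TrackMetrics(track.track_id, path, net, speed, directionality,
                        fmi_par, fmi_perp, ang)


def filter_tracks(tracks, recording_duration, min_coverage=0.10):
    """Keep tracks observed for strictly more than ``min_coverage`` of the recording.

    This is the conventional inclusion rule for intravital tracking: tracks
    covering more than 10% of the total recording time enter the analysis.
    """
    if not recording_duration > 0:
        raise ValueError("recording_duration must be positive")
    return [tr for tr in tracks if tr.span > min_coverage * recording_duration]


def rose_histogram(tracks, gradient_axis="+x", n_bins=18) -> RoseHistogram:
    """Circular histogram of per-track end-to-end angles.

    One angle per track; tracks with zero net displacement carry no direction
    and are excluded (their count is reported in ``n_excluded``).  Bins are
    half-open (a, b] over (-180, 180], with 0 degrees on the reference axis.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be at least 4")
    axis = parse_axis(gradient_axis)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    angles = []
    excluded = 0
    for tr in tracks:
        m = track_metrics(tr, axis)
        if m.net_displacement == 0:
            excluded += 1
        else:
            angles.append(m.end_angle)
    counts = np.zeros(n_bins, dtype=int)
    for a in angles:
        # half-open (a, b]: index of the right edge >= a (strictly > left edge)
        i = int(np.searchsorted(edges, a, side="left")) - 1
        counts[min(max(i, 0), n_bins - 1)] += 1
    return RoseHistogram(edges, counts, tuple(axis), excluded)


def resultant_length(histogram_or_angles):
    """Mean resultant length of track angles (0 = uniform, 1 = aligned)."""
    if isinstance(histogram_or_angles, RoseHistogram):
        centers = np.deg2rad(0.5 * (histogram_or_angles.bin_edges[:-1]
                                    + histogram_or_angles.bin_edges[1:]))
        w = histogram_or_angles.counts
        if w.sum() == 0:
            return 0.0
        z = np.sum(w * np.exp(1j * centers)) / w.sum()
    else:
        ang = np.deg2rad(np.asarray(histogram_or_angles, dtype=float))
        if ang.size == 0:
            return 0.0
        z = np.mean(np.exp(1j * ang))
    return float(abs(z))


def drift_correct(tracks):
    """Remove the ensemble median per-frame displacement from every track.

    For each pair of consecutive observed timestamps, the median step of all
    tracks spanning that interval is taken as stage/specimen drift; its
    cumulative sum is subtracted from every position.  A rigid common
    translation is removed exactly.  A single track is returned unchanged
    with a warning.
    """
    if len(tracks) < 2:
        warnings.warn("drift correction needs multiple simultaneous tracks; "
                      "returning input unchanged")
        return list(tracks)
    times = np.unique(np.concatenate([tr.t for tr in tracks]))
    t_index = {t: i for i, t in enumerate(times)}
    # median displacement per consecutive-timestamp interval
    drift_steps = np.zeros((len(times) - 1, 2))
    for k in range(len(times) - 1):
        steps = []
        for tr in tracks:
            ia = np.searchsorted(tr.t, times[k])
            ib = np.searchsorted(tr.t, times[k + 1])
            if (ia < len(tr.t) and ib < len(tr.t)
                    and tr.t[ia] == times[k] and tr.t[ib] == times[k + 1]):
                steps.append([tr.x[ib] - tr.x[ia], tr.y[ib] - tr.y[ia]])
        if steps:
            drift_steps[k] = np.median(np.asarray(steps), axis=0)
    cum = np.vstack([[0.0, 0.0], np.cumsum(drift_steps, axis=0)])
    out = []
    for tr in tracks:
        idx = np.array([t_index[t] for t in tr.t])
        out.append(Track(tr.track_id, tr.t.copy(),
                         tr.x - cum[idx, 0], tr.y - cum[idx, 1]))
    return out


def _side_of_polyline(boundary: np.ndarray, pts: np.ndarray):
    """Sign of each point relative to a polyline: +1 left of travel, -1 right."""
    a = boundary[:-1]
    b = boundary[1:]
    ab = b - a
    seg_len2 = np.sum(ab**2, axis=1)
    signs = np.empty(len(pts))
    for i, p in enumerate(pts):
        ap = p - a
        t = np.clip(np.sum(ap * ab, axis=1) / seg_len2, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.sum((p - proj) ** 2, axis=1)
        k = int(np.argmin(d2))
        cross = ab[k, 0] * (p[1] - a[k, 1]) - ab[k, 1] * (p[0] - a[k, 0])
        signs[i] = np.sign(cross) if cross != 0 else 0.0
    return signs


def invasion_index(tracks, boundary, invaded_side="left"):
    """Fraction of tracks that start outside the invaded side and end on it.

    ``boundary`` is an ordered polyline ((x, y) µm) that must span the field
    of view occupied by the tracks (its ends must lie outside the tracks'
    bounding box, so it genuinely partitions the field); ``invaded_side`` is
    ``"left"`` or ``"right"`` of the polyline's direction of travel.
    This boundary-crossing fraction is a declared operationalization of
    "invasion into stroma" — tissue studies rarely state a formula.
    """
    if invaded_side not in ("left", "right"):
        raise ValueError("invaded_side must be 'left' or 'right'")
    boundary = np.asarray(boundary, dtype=float)
    if boundary.ndim != 2 or boundary.shape[0] < 2 or boundary.shape[1] != 2:
        raise ValueError("boundary must be an (N>=2, 2) polyline")
    if not tracks:
        return 0.0
    starts = np.array([[tr.x[0], tr.y[0]] for tr in tracks])
    ends = np.array([[tr.x[-1], tr.y[-1]] for tr in tracks])
    allpts = np.vstack([starts, ends])
    # the boundary must span the whole track cloud along its chord direction,
    # otherwise points can pass around its ends and sides are meaningless
    chord = boundary[-1] - boundary[0]
    norm = np.hypot(*chord)
    if norm == 0:
        raise DurokitError("boundary chord has zero length")
    d = chord / norm
    proj_pts = allpts @ d
    proj_b = boundary @ d
    if proj_pts.min() < proj_b.min() - 1e-9 or proj_pts.max() > proj_b.max() + 1e-9:
        raise DurokitError("boundary does not partition the field of view: "
                           "tracks extend past its ends")
    sign = 1.0 if invaded_side == "left" else -1.0
    s_start = _side_of_polyline(boundary, starts) * sign
    s_end = _side_of_polyline(boundary, ends) * sign
    crossed = np.count_nonzero((s_start < 0) & (s_end > 0))
    return crossed / len(tracks)


def metrics_table(tracks, gradient_axis="+x"):
    """All per-track metrics as a pandas DataFrame (one row per track)."""
    import pandas as pd

    rows = [vars(track_metrics(tr, gradient_axis)) for tr in tracks]
    return pd.DataFrame(rows)
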