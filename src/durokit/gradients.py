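"""Stiffness-gradient statistics on elastographs.

Implements stiffness-vs-distance profiles along transects, decomposition of
a profile into monotone runs with one regression slope per run, the
``n``-slope average-slope summary statistic (the per-sample "average slope
based on 50 slopes" readout), and focal peak/valley detection.

The average-slope statistic samples seeded random transects *along the local
steepest-ascent direction* of the map.  Sampling transect directions
uniformly instead would average |cos| of the angle to the true gradient and
systematically report ~2/pi of it; aligning with the gradient reproduces the
nominal gradient of rasterized calibration substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .afm import StiffnessMap
from .exceptions import OutOfExtentError


@dataclass
class GradientProfile:
    """Moduli sampled along one straight transect."""

    distances: np.ndarray  # µm, strictly increasing
    moduli: np.ndarray  # Pa, NaN where the map has gaps
    source_transect: tuple = ((0.0, 0.0), (0.0, 0.0))  # (start, end) µm

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.moduli = np.asarray(self.moduli, dtype=float)
        if self.distances.shape != self.moduli.shape:
            raise ValueError("distances and moduli must have equal length")
        if len(self.distances) > 1 and np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")


@dataclass
class SlopeSummary:
    """Mean magnitude of transect slopes on one elastograph."""

    slopes: list  # Pa/µm magnitudes
    average_slope: float  # Pa/µm, mean of |slopes| (0 when none found)
    n_slopes: int
    seed: int
    scheme: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_slopes != len(self.slopes):
            raise ValueError("n_slopes must equal len(slopes)")


def _interpolator(smap: StiffnessMap):
    from scipy.interpolate import RegularGridInterpolator
    xc, yc = smap.pixel_centers()
    return RegularGridInterpolator((yc, xc), smap.grid, bounds_error=False,
                                   fill_value=None)


def profile_along_transect(smap: StiffnessMap, start, end, step=None) -> GradientProfile:
    """Bilinear stiffness profile along the segment start→end.

    ``step`` defaults to half the map pitch.  Missing map cells propagate as
    NaN gaps in the profile.  Endpoints must lie inside the map's pixel area.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    w, h = smap.extent
    ox, oy = smap.origin
    for p in (start, end):
        if not (ox <= p[0] <= ox + w and oy <= p[1] <= oy + h):
            raise OutOfExtentError((p[0], p[1]), (ox + w, oy + h))
    if step is None:
        step = smap.pitch / 2.0
    length = float(np.hypot(*(end - start)))
    if length == 0:
        d = np.array([0.0])
    else:
        n = max(2, int(np.floor(length / step)) + 1)
        d = np.linspace(0.0, length, n)
    direction = (end - start) / length if length else np.zeros(2)
    pts = start + d[:, None] * direction
    e = _interpolator(smap)(np.column_stack([pts[:, 1], pts[:, 0]]))
    return GradientProfile(d, e, (tuple(start), tuple(end)))


def extract_slopes(profile: GradientProfile, trim_run_ends=True, smooth_window=1):
    """One |slope| (Pa/µm) per monotone run of the profile.

    Runs are maximal strictly monotone segments between consecutive local
    extrema (ties/plateaus break runs, so a plateau point adjoins at most one
    run on each side).  Each slope is the least-squares regression of modulus
    on distance over the run.  When ``trim_run_ends`` and a run has at least
    5 points, its first and last sample (the extremum samples, which are
    biased on discretized ramps) are dropped before regression.
    ``smooth_window`` > 1 applies a centred moving average before run
    decomposition — useful on noisy measured maps, where pixel noise
    otherwise fragments plateaus into spurious micro-runs; the default (1)
    leaves exact calibration profiles untouched.  NaN gaps split the
    profile; runs shorter than 3 points are discarded.
    """
    d = profile.distances
    e = profile.moduli
    if smooth_window > 1:
        w = int(smooth_window)
        kernel = np.ones(w) / w
        filled = np.where(np.isfinite(e), e, np.nan)
        sm = np.convolve(np.nan_to_num(filled, nan=0.0), kernel, mode="same")
        norm = np.convolve(np.isfinite(filled).astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore"):
            e = np.where(norm > 0, sm / norm, np.nan)
        e[~np.isfinite(profile.moduli)] = np.nan
    slopes = []
    # split at NaN gaps
    ok = np.isfinite(e)
    if not ok.any():
        return []
    idx = np.arange(len(e))
    for seg in np.split(idx, np.where(~ok)[0]):
        seg = seg[np.isfinite(e[seg])]
        if len(seg) < 3:
            continue
        slopes.extend(_segment_slopes(d[seg], e[seg], trim_run_ends))
    return slopes


def _segment_slopes(d, e, trim):
    # differences below float jitter count as ties, so plateaus stay plateaus
    # under rescaling or interpolation round-off
    de = np.diff(e)
    tol = 1e-9 * np.max(np.abs(e)) if len(e) else 0.0
    de[np.abs(de) <= tol] = 0.0
    diffs = np.sign(de)
    slopes = []
    i = 0
    n = len(diffs)
    while i < n:
        s = diffs[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j < n and diffs[j] == s:
            j += 1
        run = slice(i, j + 1)  # points i..j inclusive
        rd, re = d[run], e[run]
        if trim and len(rd) >= 5:
            rd, re = rd[1:-1], re[1:-1]
        if len(rd) >= 3:
            slope = np.polyfit(rd, re, 1)[0]
            slopes.append(abs(float(slope)))
        i = j
    return slopes


def _gradient_field(smap: StiffnessMap, smooth_sigma_px=0.0):
    g = smap.grid
    if smooth_sigma_px > 0:
        g = ndimage.gaussian_filter(np.nan_to_num(g, nan=np.nanmedian(g)),
                                    smooth_sigma_px)
    gy, gx = np.gradient(g, smap.pitch)
    return gx, gy


def _dominant_direction(gx, gy):
    """Axial (mod-pi) mean gradient orientation, weighted by magnitude."""
    mag = np.hypot(gx, gy)
    ok = np.isfinite(mag) & (mag > 0)
    if not ok.any():
        return None
    ang = np.arctan2(gy[ok], gx[ok])
    z = np.sum(mag[ok] * np.exp(2j * ang))
    if abs(z) == 0:
        return None
    theta = np.angle(z) / 2.0
    return np.array([np.cos(theta), np.sin(theta)])


def average_slope(smap: StiffnessMap, n_slopes=50, seed=0, step=None,
                  max_transects=None, min_gradient=1e-9,
                  smooth_window=1) -> SlopeSummary:
    """Seeded average-slope statistic of an elastograph.

    Random start points are drawn inside the map; through each, a transect is
    cast along the local steepest-ascent direction (falling back to the map's
    dominant gradient axis on plateaus) across the full map, and the monotone
    runs of its profile each contribute one slope magnitude.  Sampling stops
    once ``n_slopes`` slopes are collected or the transect budget
    (``max_transects``, default ``20 * n_slopes``) is spent.  A uniform map
    yields no slopes and an average of 0.  Fully reproducible given ``seed``.
    """
    finite = np.isfinite(smap.grid)
    if finite.sum() < 2:
        raise ValueError("map needs at least 2 finite cells")
    rng = np.random.default_rng(seed)
    if max_transects is None:
        max_transects = 20 * n_slopes
    gx, gy = _gradient_field(smap)
    dom = _dominant_direction(gx, gy)
    w, h = smap.extent
    ox, oy = smap.origin
    xc, yc = smap.pixel_centers()
    slopes = []
    n_used = 0
    for _ in range(max_transects):
        if len(slopes) >= n_slopes:
            break
        x0 = ox + rng.uniform(0, w)
        y0 = oy + rng.uniform(0, h)
        col = int(np.clip(np.searchsorted(xc, x0), 0, len(xc) - 1))
        row = int(np.clip(np.searchsorted(yc, y0), 0, len(yc) - 1))
        g = np.array([gx[row, col], gy[row, col]])
        if not np.all(np.isfinite(g)) or np.hypot(*g) < min_gradient:
            if dom is None:
                continue
            u = dom
        else:
            u = g / np.hypot(*g)
        # clip the infinite line through (x0, y0) along u to the extent
        ts = []
        for c0, uc, lo, hi in ((x0, u[0], ox, ox + w), (y0, u[1], oy, oy + h)):
            if abs(uc) > 1e-12:
                ts.append(sorted(((lo - c0) / uc, (hi - c0) / uc)))
            elif not lo <= c0 <= hi:
                ts = None
                break
        if ts is None:
            continue
        t0 = max(t[0] for t in ts)
        t1 = min(t[1] for t in ts)
        if t1 <= t0:
            continue
        lo = np.array([ox, oy])
        hi = np.array([ox + w, oy + h])
        start = np.clip(np.array([x0, y0]) + t0 * u, lo, hi)
        end = np.clip(np.array([x0, y0]) + t1 * u, lo, hi)
        prof = profile_along_transect(smap, start, end, step=step)
        got = extract_slopes(prof, smooth_window=smooth_window)
        if got:
            n_used += 1
            slopes.extend(got)
    slopes = slopes[:n_slopes]
    avg = float(np.mean(slopes)) if slopes else 0.0
    scheme = {"direction": "steepest_ascent", "transects_used": n_used,
              "max_transects": max_transects, "smooth_window": smooth_window,
              "step_um": step if step is not None else smap.pitch / 2.0}
    return SlopeSummary(slopes, avg, len(slopes), seed, scheme)


def detect_peaks_valleys(smap: StiffnessMap, min_prominence=1e3,
                         smooth_sigma_px=0.0, neighborhood_px=3):
    """Focal stiffness peaks and valleys of an elastograph.

    A peak (valley) is a local maximum (minimum) of the optionally smoothed
    field whose excursion |E - median| exceeds ``min_prominence`` Pa.
    Returns a list of ``((x_um, y_um), modulus_Pa, kind)`` tuples sorted by
    decreasing excursion; ``kind`` is ``"peak"`` or ``"valley"``.
    """
    g = smap.grid
    finite = np.isfinite(g)
    if finite.sum() < 9:
        raise ValueError("map needs at least 9 finite cells")
    med = float(np.nanmedian(g))
    filled = np.where(finite, g, med)
    if smooth_sigma_px > 0:
        filled = ndimage.gaussian_filter(filled, smooth_sigma_px)
    size = neighborhood_px
    mx = ndimage.maximum_filter(filled, size=size, mode="nearest")
    mn = ndimage.minimum_filter(filled, size=size, mode="nearest")
    xc, yc = smap.pixel_centers()
    out = []
    for kind, mask in (("peak", (filled == mx) & (filled - med >= min_prominence)),
                       ("valley", (filled == mn) & (med - filled >= min_prominence))):
        rows, cols = np.nonzero(mask & finite)
        for r, c in zip(rows, cols):
            out.append(((float(xc[c]), float(yc[r])), float(g[r, c]), kind))
    out.sort(key=lambda item: -abs(item[1] - med))
    return out
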