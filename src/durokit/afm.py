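"""Hertz-model AFM elastography.

Forward spherical-indenter contact model, contact-point estimation on raw
approach traces, Young's-modulus fitting from force-indentation curves, and
assembly of gridded stiffness maps (elastographs).

The contact model for a rigid sphere of radius ``R`` indenting an elastic
half-space of Young's modulus ``E`` and Poisson ratio ``nu`` to depth
``delta`` is

    F = (4/3) * E / (1 - nu**2) * sqrt(R) * delta**(3/2)

whose inverse, E = (3/4) * (1 - nu**2) * F / (sqrt(R) * delta**(3/2)), is the
form conventionally used to report tissue moduli from nanoindentation.

Units are SI throughout this module (m, N, Pa); micrometre/nanonewton
conversions belong at the I/O edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DurokitError

#: Default probe constants: 5 µm diameter borosilicate sphere, tissue Poisson
#: ratio 0.4, ~60 pN/nm cantilever, curves fitted up to ~16 nN.
DEFAULT_TIP_RADIUS_M = 2.5e-6
DEFAULT_POISSON = 0.4
DEFAULT_SPRING_CONSTANT_N_PER_M = 0.060
DEFAULT_MAX_FORCE_N = 16e-9

MIN_FIT_SAMPLES = 8


def hertz_force(delta, modulus, poisson=DEFAULT_POISSON, tip_radius=DEFAULT_TIP_RADIUS_M):
    """Forward Hertz force for a spherical indenter.

    Parameters
    ----------
    delta : float or array
        Indentation depth in metres, >= 0.
    modulus : float
        Young's modulus in pascals, > 0.
    poisson : float
        Poisson ratio, 0 <= nu < 0.5.
    tip_radius : float
        Sphere radius in metres, > 0.

    Returns
    -------
    float or ndarray
        Force in newtons.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be non-negative")
    if modulus <= 0:
        raise ValueError("Young's modulus must be positive")
    if tip_radius <= 0:
        raise ValueError("tip radius must be positive")
    if not 0 <= poisson < 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    out = (4.0 / 3.0) * modulus / (1.0 - poisson**2) * np.sqrt(tip_radius) * delta**1.5
    return out if out.ndim else float(out)


def hertz_modulus(delta, force, poisson=DEFAULT_POISSON, tip_radius=DEFAULT_TIP_RADIUS_M):
    """Inverse Hertz relation: modulus from a single (delta, force) pair."""
    delta = np.asarray(delta, dtype=float)
    force = np.asarray(force, dtype=float)
    out = 0.75 * (1.0 - poisson**2) * force / (np.sqrt(tip_radius) * delta**1.5)
    return out if out.ndim else float(out)


@dataclass
class ForceCurve:
    """A force-indentation curve plus the probe constants needed to fit it.

    ``indentation`` must be non-decreasing.  Curves with fewer than
    :data:`MIN_FIT_SAMPLES` points are constructible but will never yield a
    valid fit.
    """

    indentation: np.ndarray  # m
    force: np.ndarray  # N
    tip_radius: float = DEFAULT_TIP_RADIUS_M
    poisson: float = DEFAULT_POISSON
    spring_constant: float = DEFAULT_SPRING_CONSTANT_N_PER_M
    position: tuple | None = None  # (x_um, y_um) grid coordinate, optional

    def __post_init__(self):
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.indentation.ndim != 1 or self.indentation.shape != self.force.shape:
            raise ValueError("indentation and force must be 1-D arrays of equal length")
        if len(self.indentation) < 2:
            raise ValueError("a force curve needs at least 2 samples")
        if np.any(np.diff(self.indentation) < 0):
            raise ValueError("indentation must be non-decreasing")
        if self.tip_radius <= 0:
            raise ValueError("tip radius must be positive")
        if not 0 <= self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")

    def __len__(self):
        return len(self.indentation)


@dataclass
class ElasticityFit:
    """Result of fitting one force curve."""

    modulus: float  # Pa (E)
    contact_point: float  # m, offset applied to the z axis (0 if pre-aligned)
    residual_rms: float  # N
    n_points_used: int
    valid: bool
    position: tuple | None = None

    def __post_init__(self):
        if self.valid and not self.modulus > 0:
            raise ValueError("a valid fit must carry a positive modulus")
        if self.residual_rms < 0:
            raise ValueError("residual RMS cannot be negative")


@dataclass
class StiffnessMap:
    """Gridded Young's moduli (an elastograph).

    ``grid[row, col]`` holds the modulus in Pa at pixel centre
    ``(origin + (col + 0.5) * pitch, origin + (row + 0.5) * pitch)`` µm;
    NaN marks missing (unfittable) positions.
    """

    grid: np.ndarray  # Pa, NaN = missing
    pitch: float  # µm between neighbouring grid points
    origin: tuple = (0.0, 0.0)  # µm, lower-left corner of the pixel area
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("stiffness grid must be 2-D")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")
        finite = self.grid[np.isfinite(self.grid)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("all finite moduli must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self):
        return self.grid.shape

    @property
    def extent(self):
        """(width, height) of the pixel area in µm."""
        nr, nc = self.grid.shape
        return (nc * self.pitch, nr * self.pitch)

    def pixel_centers(self):
        """Return (x_centers, y_centers) in µm."""
        nr, nc = self.grid.shape
        x = self.origin[0] + (np.arange(nc) + 0.5) * self.pitch
        y = self.origin[1] + (np.arange(nr) + 0.5) * self.pitch
        return x, y


def estimate_contact_point(z, force, baseline_fraction=0.3, threshold_sigmas=3.0,
                           min_run=4, refine=True):
    """Locate the contact point on a raw approach trace.

    The first ``baseline_fraction`` of samples is treated as the off-surface
    baseline; the coarse contact point is the last z before the force rises
    above ``baseline mean + threshold_sigmas * baseline std`` and stays above
    it for ``min_run`` consecutive samples.  Because the Hertzian rise is
    shallow (F ~ delta**(3/2)), the threshold crossing is systematically late
    at finite noise, so by default the estimate is refined by a grid search
    over candidate contact points near the crossing, minimizing the
    whole-trace residual of the piecewise model (zero force before contact,
    through-origin Hertz-shaped rise after).

    Returns
    -------
    (contact_z, valid) : (float, bool)
        ``valid`` is False (and ``contact_z`` NaN) when no sustained rise is
        detected — degenerate traces are flagged, not raised.
    """
    z = np.asarray(z, dtype=float)
    force = np.asarray(force, dtype=float)
    n = len(z)
    if n < 8:
        return float("nan"), False
    nb = max(3, int(round(baseline_fraction * n)))
    base = force[:nb]
    thr = base.mean() + threshold_sigmas * base.std()
    above = force > thr
    # first index from which `above` holds for min_run consecutive samples
    run = 0
    start = None
    for i in range(n):
        run = run + 1 if above[i] else 0
        if run >= min_run:
            start = i - min_run + 1
            break
    if start is None or start == 0:
        return float("nan"), False
    if not refine:
        return float(z[start - 1]), True
    f0 = base.mean()
    lo = max(1, start - max(min_run, int(0.15 * n)))
    hi = min(n - MIN_FIT_SAMPLES, start + min_run)
    best, best_sse = start - 1, np.inf
    for k in range(lo, hi):
        delta = np.clip(z - z[k], 0.0, None) ** 1.5
        resid = force - f0
        denom = float(np.dot(delta, delta))
        if denom == 0:
            continue
        slope = float(np.dot(delta, resid)) / denom
        if slope <= 0:
            continue
        sse = float(np.sum((resid - slope * delta) ** 2))
        if sse < best_sse:
            best, best_sse = k, sse
    return float(z[best]), True


def indentation_from_trace(z, force, contact_z, spring_constant=None):
    """Convert a raw (z, force) approach trace to an indentation axis.

    delta = (z - contact_z) - force / k corrects for cantilever deflection
    when the spring constant ``k`` is given; samples before contact are
    dropped.
    """
    z = np.asarray(z, dtype=float)
    force = np.asarray(force, dtype=float)
    delta = z - contact_z
    if spring_constant is not None:
        delta = delta - force / spring_constant
    keep = delta >= 0
    return delta[keep], force[keep]


def fit_hertz(curve: ForceCurve, max_force=DEFAULT_MAX_FORCE_N, poisson=None):
    """Least-squares Young's modulus from a force-indentation curve.

    The model is linear in the reduced modulus when expressed against
    delta**(3/2), so the fit is the closed-form through-origin regression of
    F on delta**(3/2) over samples with F <= ``max_force``; no iterative
    optimiser is involved.  Fewer than 8 in-range samples yields
    ``valid=False`` rather than an exception.
    """
    nu = curve.poisson if poisson is None else poisson
    delta = curve.indentation
    force = curve.force
    sel = (delta >= 0) & (force <= max_force) & np.isfinite(force) & np.isfinite(delta)
    d = delta[sel]
    f = force[sel]
    # guard against all-zero indentation ranges
    usable = int(np.count_nonzero(d > 0))
    if usable < MIN_FIT_SAMPLES:
        return ElasticityFit(float("nan"), 0.0, float("nan"), usable, False,
                             position=curve.position)
    x = d**1.5
    denom = float(np.dot(x, x))
    slope = float(np.dot(x, f)) / denom
    if slope <= 0:
        return ElasticityFit(float("nan"), 0.0, float("nan"), usable, False,
                             position=curve.position)
    modulus = 0.75 * slope * (1.0 - nu**2) / np.sqrt(curve.tip_radius)
    resid = f - slope * x
    rms = float(np.sqrt(np.mean(resid**2)))
    return ElasticityFit(modulus, 0.0, rms, usable, True, position=curve.position)


def build_stiffness_map(fits: Sequence[ElasticityFit], pitch=None) -> StiffnessMap:
    """Arrange per-position fits on their regular lattice.

    Every fit must carry a ``position`` (x_um, y_um); the positions must lie
    on a regular lattice (pitch inferred from nearest-neighbour spacing when
    not given).  Invalid fits become NaN cells; duplicate positions raise.
    """
    if not fits:
        raise ValueError("no fits supplied")
    pos = []
    for f in fits:
        if f.position is None:
            raise ValueError("every fit needs a grid position to build a map")
        pos.append((float(f.position[0]), float(f.position[1])))
    seen = {}
    dups = []
    for p in pos:
        seen[p] = seen.get(p, 0) + 1
        if seen[p] == 2:
            dups.append(p)
    if dups:
        raise DurokitError(f"duplicate grid positions: {dups}")

    xs = np.unique([p[0] for p in pos])
    ys = np.unique([p[1] for p in pos])
    if pitch is None:
        steps = np.concatenate([np.diff(xs), np.diff(ys)])
        steps = steps[steps > 0]
        pitch = float(steps.min()) if steps.size else 1.0
    # verify lattice alignment
    for arr, name in ((xs, "x"), (ys, "y")):
        frac = (arr - arr.min()) / pitch
        if np.any(np.abs(frac - np.round(frac)) > 1e-6):
            raise DurokitError(f"{name} positions do not lie on a {pitch} µm lattice")

    nc = int(round((xs.max() - xs.min()) / pitch)) + 1
    nr = int(round((ys.max() - ys.min()) / pitch)) + 1
    grid = np.full((nr, nc), np.nan)
    for f, (x, y) in zip(fits, pos):
        col = int(round((x - xs.min()) / pitch))
        row = int(round((y - ys.min()) / pitch))
        if f.valid:
            grid[row, col] = f.modulus
    origin = (xs.min() - 0.5 * pitch, ys.min() - 0.5 * pitch)
    prov = {
        "n_fits": len(fits),
        "n_invalid": int(sum(not f.valid for f in fits)),
        "pitch_um": float(pitch),
        "lattice_extent_um": (float(xs.max() - xs.min()), float(ys.max() - ys.min())),
    }
    return StiffnessMap(grid, float(pitch), origin, prov)
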