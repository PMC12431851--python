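"""Parametric models of mechanically patterned hydrogel substrates.

A :class:`SubstratePattern` describes an engineered stiffness field E(x, y)
in continuous 2-D coordinates (µm, origin at the lower-left corner, stiffness
varying along +x).  Five kinds are supported:

``step_stripes``
    Alternating soft/stiff stripes joined by linear transition ramps — the
    photolithographic "zebra" gels (defaults: 4 kPa / 40 kPa, 100 µm stiff
    stripes, 200 µm soft stripes, 40 µm transitions, i.e. a 900 Pa/µm step
    gradient between stripes).
``linear_gradient``
    One continuous linear ramp from E_soft to E_stiff over
    ``transition_width`` (defaults: 4→40 kPa over 1,000 µm = 36 Pa/µm), the
    microfluidically cast shallow-gradient gels.
``island``
    A central circular soft island surrounded by the stripe field, emulating
    a soft tumour core within alternating-stiffness stroma.
``uniform``
    Constant stiffness control gel.
``field``
    Wraps a measured :class:`~durokit.afm.StiffnessMap`, interpolated
    bilinearly.

The transition profile is modelled as a linear ramp; only the end moduli and
the transition distance are physically constrained, so the ramp shape is a
declared modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .afm import StiffnessMap
from .exceptions import OutOfExtentError, UnsupportedKindError

KINDS = ("step_stripes", "linear_gradient", "island", "uniform", "field")

#: region labels returned by :func:`region_of`
SOFT, STIFF, TRANSITION = "soft", "stiff", "transition"


@dataclass
class SubstratePattern:
    kind: str
    E_soft: float  # Pa
    E_stiff: float  # Pa
    stripe_width_stiff: float = 100.0  # µm
    stripe_width_soft: float = 200.0  # µm
    transition_width: float = 40.0  # µm
    extent: tuple = (1000.0, 1000.0)  # (width, height) µm
    gradient_axis: str = "+x"  # fixed convention; recorded for metadata
    island_radius: float | None = None  # µm, island kind only
    field_grid: StiffnessMap | None = None  # field kind only

    def __post_init__(self):
        if self.kind not in KINDS:
            raise UnsupportedKindError(f"unknown pattern kind {self.kind!r}")
        if not self.E_soft > 0:
            raise ValueError("E_soft must be positive")
        if self.E_stiff < self.E_soft:
            raise ValueError("E_stiff must be >= E_soft")
        if not (self.transition_width > 0 and self.stripe_width_stiff > 0
                and self.stripe_width_soft > 0):
            raise ValueError("stripe and transition widths must be positive")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be positive")
        if self.gradient_axis != "+x":
            raise UnsupportedKindError(
                "patterns vary along +x by convention; rotate points, not the pattern")
        if self.kind == "island" and not (self.island_radius and self.island_radius > 0):
            raise ValueError("island kind requires a positive island_radius")
        if self.kind == "field" and self.field_grid is None:
            raise ValueError("field kind requires a field_grid StiffnessMap")
        self._interp = None  # cached interpolator for field kind

    @property
    def period(self) -> float:
        """Stripe repeat length in µm (striped kinds)."""
        return (self.stripe_width_soft + self.stripe_width_stiff
                + 2.0 * self.transition_width)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "E_soft_Pa": self.E_soft,
            "E_stiff_Pa": self.E_stiff,
            "stripe_width_stiff_um": self.stripe_width_stiff,
            "stripe_width_soft_um": self.stripe_width_soft,
            "transition_width_um": self.transition_width,
            "extent_um": list(self.extent),
            "gradient_axis": self.gradient_axis,
        }
        if self.island_radius is not None:
            d["island_radius_um"] = self.island_radius
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubstratePattern":
        return cls(
            kind=d["kind"],
            E_soft=d["E_soft_Pa"],
            E_stiff=d["E_stiff_Pa"],
            stripe_width_stiff=d.get("stripe_width_stiff_um", 100.0),
            stripe_width_soft=d.get("stripe_width_soft_um", 200.0),
            transition_width=d.get("transition_width_um", 40.0),
            extent=tuple(d.get("extent_um", (1000.0, 1000.0))),
            gradient_axis=d.get("gradient_axis", "+x"),
            island_radius=d.get("island_radius_um"),
        )


# ---------------------------------------------------------------- factories

def step_pattern(E_soft=4e3, E_stiff=40e3, stripe_width_stiff=100.0,
                 stripe_width_soft=200.0, transition_width=40.0,
                 extent=(1000.0, 1000.0)) -> SubstratePattern:
    """Alternating-stripe gel; defaults give the 900 Pa/µm step gradient."""
    return SubstratePattern("step_stripes", E_soft, E_stiff, stripe_width_stiff,
                            stripe_width_soft, transition_width, extent)


def gradient_pattern(E_soft=4e3, E_stiff=40e3, length=1000.0,
                     extent=None) -> SubstratePattern:
    """Single shallow linear gradient; defaults give 36 Pa/µm over 1 mm."""
    if extent is None:
        extent = (length, length / 2.0)
    return SubstratePattern("linear_gradient", E_soft, E_stiff,
                            transition_width=length, extent=extent)


def island_pattern(E_soft=1e3, E_stiff=25e3, island_radius=150.0,
                   stripe_width_stiff=100.0, stripe_width_soft=100.0,
                   transition_width=40.0, extent=(1000.0, 1000.0)) -> SubstratePattern:
    """Soft circular island surrounded by alternating soft/stiff stripes."""
    return SubstratePattern("island", E_soft, E_stiff, stripe_width_stiff,
                            stripe_width_soft, transition_width, extent,
                            island_radius=island_radius)


def uniform_pattern(E=25e3, extent=(1000.0, 1000.0)) -> SubstratePattern:
    return SubstratePattern("uniform", E, E, extent=extent)


def field_pattern(stiffness_map: StiffnessMap) -> SubstratePattern:
    grid = stiffness_map.grid
    finite = grid[np.isfinite(grid)]
    return SubstratePattern("field", float(finite.min()), float(finite.max()),
                            extent=stiffness_map.extent, field_grid=stiffness_map)


# ------------------------------------------------------------ field queries

def _check_in_extent(pattern, x, y):
    w, h = pattern.extent
    bad = (x < 0) | (x > w) | (y < 0) | (y > h)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise OutOfExtentError((np.atleast_1d(x)[i] if np.ndim(x) else x,
                                np.atleast_1d(y)[i] if np.ndim(y) else y),
                               pattern.extent)


def _stripe_phase(pattern, x):
    """Position within the repeat cell: soft plateau, ramp up, stiff, ramp down."""
    p = pattern.period
    return x - p * np.floor(x / p)


def _stripe_modulus(pattern, x):
    u = _stripe_phase(pattern, np.asarray(x, dtype=float))
    ws, wt, wf = pattern.stripe_width_soft, pattern.transition_width, pattern.stripe_width_stiff
    dE = pattern.E_stiff - pattern.E_soft
    up = (u - ws) / wt  # ramp-up progress
    down = (pattern.period - u) / wt  # ramp-down progress (1 at stiff edge)
    conds = [u < ws, u < ws + wt, u < ws + wt + wf]
    vals = [pattern.E_soft * np.ones_like(u),
            pattern.E_soft + dE * up,
            pattern.E_stiff * np.ones_like(u)]
    return np.select(conds, vals, default=pattern.E_soft + dE * down)


def _field_interp(pattern):
    if pattern._interp is None:
        from scipy.interpolate import RegularGridInterpolator
        m = pattern.field_grid
        xc, yc = m.pixel_centers()
        pattern._interp = RegularGridInterpolator(
            (yc - m.origin[1], xc - m.origin[0]), m.grid,
            bounds_error=False, fill_value=None)
    return pattern._interp


def stiffness_at(pattern: SubstratePattern, point):
    """Young's modulus E(x, y) in Pa at one point or an (N, 2) array of points."""
    pt = np.asarray(point, dtype=float)
    scalar = pt.ndim == 1
    pts = np.atleast_2d(pt)
    x, y = pts[:, 0], pts[:, 1]
    _check_in_extent(pattern, x, y)
    kind = pattern.kind
    if kind == "uniform":
        out = np.full_like(x, pattern.E_soft)
    elif kind == "linear_gradient":
        t = np.clip(x / pattern.transition_width, 0.0, 1.0)
        out = pattern.E_soft + (pattern.E_stiff - pattern.E_soft) * t
    elif kind == "step_stripes":
        out = _stripe_modulus(pattern, x)
    elif kind == "island":
        cx, cy = pattern.extent[0] / 2.0, pattern.extent[1] / 2.0
        r = np.hypot(x - cx, y - cy)
        stripe = _stripe_modulus(pattern, x)
        t = np.clip((r - pattern.island_radius) / pattern.transition_width, 0.0, 1.0)
        out = pattern.E_soft + t * (stripe - pattern.E_soft)
    else:  # field
        out = _field_interp(pattern)(np.column_stack([y, x]))
        out = np.clip(out, pattern.E_soft, pattern.E_stiff)
    return float(out[0]) if scalar else out


def nominal_gradient(pattern: SubstratePattern) -> float:
    """Design stiffness gradient (E_stiff - E_soft) / transition distance, Pa/µm."""
    if pattern.kind in ("uniform", "field"):
        raise UnsupportedKindError(
            f"nominal_gradient is undefined for {pattern.kind!r} patterns")
    return (pattern.E_stiff - pattern.E_soft) / pattern.transition_width


def local_gradient(pattern: SubstratePattern, point, fd_step=0.05):
    """Spatial gradient of E at a point, Pa/µm, as a (dE/dx, dE/dy) vector.

    Analytic for the piecewise-linear kinds; central finite differences
    (step ``fd_step`` µm, one-sided at the extent boundary) for island and
    measured-field kinds.
    """
    pt = np.asarray(point, dtype=float)
    scalar = pt.ndim == 1
    pts = np.atleast_2d(pt)
    x, y = pts[:, 0], pts[:, 1]
    _check_in_extent(pattern, x, y)
    kind = pattern.kind
    if kind == "uniform":
        g = np.zeros((len(x), 2))
    elif kind == "linear_gradient":
        inside = (x > 0) & (x < pattern.transition_width)
        g = np.zeros((len(x), 2))
        g[inside, 0] = nominal_gradient(pattern)
    elif kind == "step_stripes":
        u = _stripe_phase(pattern, x)
        ws, wt, wf = (pattern.stripe_width_soft, pattern.transition_width,
                      pattern.stripe_width_stiff)
        slope = nominal_gradient(pattern)
        g = np.zeros((len(x), 2))
        g[(u > ws) & (u < ws + wt), 0] = slope
        g[(u > ws + wt + wf) & (u < pattern.period), 0] = -slope
    else:  # island, field: finite differences
        w, h = pattern.extent
        g = np.empty((len(x), 2))
        for axis, (lo, hi) in enumerate([(0.0, w), (0.0, h)]):
            c = x if axis == 0 else y
            cp = np.minimum(c + fd_step, hi)
            cm = np.maximum(c - fd_step, lo)
            pp = np.column_stack([cp, y]) if axis == 0 else np.column_stack([x, cp])
            pm = np.column_stack([cm, y]) if axis == 0 else np.column_stack([x, cm])
            g[:, axis] = (stiffness_at(pattern, pp) - stiffness_at(pattern, pm)) / (cp - cm)
    return g[0] if scalar else g


def region_of(pattern: SubstratePattern, point, rule="exclude"):
    """Label points as ``soft``, ``stiff`` or ``transition``.

    ``rule`` controls how transition-band points are binned:

    - ``"exclude"`` (default): labelled ``transition`` (excluded from the
      durotactic index);
    - ``"midpoint"``: split at the ramp midpoint — stiff iff past it.

    Field-kind patterns have no geometric plateaus, so they are always split
    at the modulus midpoint.
    """
    if rule not in ("exclude", "midpoint"):
        raise ValueError(f"unknown transition rule {rule!r}")
    pt = np.asarray(point, dtype=float)
    scalar = pt.ndim == 1
    pts = np.atleast_2d(pt)
    e = np.atleast_1d(stiffness_at(pattern, pts))
    if pattern.kind == "uniform":
        lab = np.full(len(pts), SOFT, dtype=object)
    elif pattern.kind == "field" or rule == "midpoint":
        mid = 0.5 * (pattern.E_soft + pattern.E_stiff)
        lab = np.where(e > mid, STIFF, SOFT).astype(object)
    else:
        lab = np.full(len(pts), TRANSITION, dtype=object)
        lab[e == pattern.E_soft] = SOFT
        lab[e == pattern.E_stiff] = STIFF
    return str(lab[0]) if scalar else lab


def region_area_fractions(pattern: SubstratePattern, rule="exclude", n_grid=500):
    """Approximate area fraction of each region label within the extent.

    Analytic for step stripes; otherwise estimated on a deterministic
    ``n_grid`` × ``n_grid`` lattice of points.
    """
    if pattern.kind == "step_stripes":
        p = pattern.period
        ws, wt, wf = (pattern.stripe_width_soft, pattern.transition_width,
                      pattern.stripe_width_stiff)
        if rule == "midpoint":
            return {SOFT: (ws + wt) / p, STIFF: (wf + wt) / p, TRANSITION: 0.0}
        return {SOFT: ws / p, STIFF: wf / p, TRANSITION: 2 * wt / p}
    w, h = pattern.extent
    xs = (np.arange(n_grid) + 0.5) * (w / n_grid)
    ys = (np.arange(n_grid) + 0.5) * (h / n_grid)
    gx, gy = np.meshgrid(xs, ys)
    labs = region_of(pattern, np.column_stack([gx.ravel(), gy.ravel()]), rule=rule)
    n = labs.size
    return {k: float(np.count_nonzero(labs == k)) / n for k in (SOFT, STIFF, TRANSITION)}


def rasterize(pattern: SubstratePattern, pitch: float) -> StiffnessMap:
    """Sample E(x, y) at pixel centres on a ``pitch`` µm grid."""
    if not pitch > 0:
        raise ValueError("pitch must be positive")
    w, h = pattern.extent
    nc, nr = int(round(w / pitch)), int(round(h / pitch))
    xs = (np.arange(nc) + 0.5) * pitch
    ys = (np.arange(nr) + 0.5) * pitch
    gx, gy = np.meshgrid(xs, ys)
    e = stiffness_at(pattern, np.column_stack([gx.ravel(), gy.ravel()]))
    grid = e.reshape(nr, nc)
    prov = {"source": "rasterized pattern", "pattern": pattern.to_dict(),
            "pitch_um": pitch}
    return StiffnessMap(grid, pitch, (0.0, 0.0), prov)
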