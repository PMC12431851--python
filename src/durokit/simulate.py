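"""Seeded synthetic-data generators with known ground truth.

Every pipeline input has a generator here: Hertzian force curves and raw
approach traces, healthy (uniform) versus fibrotic (focal peaks/valleys)
stiffness fields, persistent biased random walks on patterned substrates,
per-animal photon-flux tables, and curly versus straight-aligned fibre
centerlines.  Each generator is a pure function of its arguments — a fixed
seed gives byte-identical output — and each derives an independent random
stream from the root seed, so adding a generator never perturbs another's
fixtures.

Default parameters mirror the assay conditions the analysis modules target:
5 µm diameter spherical probe (R = 2.5 µm), Poisson ratio 0.4, ~16 nN curves,
5 µm map pitch, 4/40 kPa stripes with 40 µm transitions, 1,000 µm shallow
gradients, 24 h recordings at 5-min frame intervals with 75 walkers.  Noise
levels (2% multiplicative force noise, 10% speed CV) are modelling choices —
real acquisition noise is instrument-specific.

The gradient-biased heading update of the walkers is an explicit stand-in
for cellular mechanosensing, not a molecular-clutch model: at each step the
heading relaxes toward the local stiffness-gradient direction with a
saturating weight ``b·|∇E| / (1 + b·|∇E|)`` where ``b`` is the bias
strength in (Pa/µm)^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import afm, substrates
from .migration import Track
from .tumor import FiberPolyline

_GENERATOR_IDS = {
    "force_curves": 11,
    "force_trace": 12,
    "stiffness_field": 13,
    "tracks": 14,
    "flux_table": 15,
    "fibers": 16,
}


def derive_rng(seed: int, generator: str) -> np.random.Generator:
    """Independent, reproducible stream for one generator from a root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed),
                                                         _GENERATOR_IDS[generator]]))


@dataclass
class SimulationConfig:
    """Shared knobs for the track simulator (see module docstring for units)."""

    seed: int = 0
    n: int = 75  # walkers per condition
    bias_strength: float = 0.0  # (Pa/µm)^-1, >= 0
    persistence_time: float = 1800.0  # s
    speed_mean: float = 0.5  # µm/min
    speed_cv: float = 0.10
    duration: float = 24 * 3600.0  # s
    frame_interval: float = 300.0  # s

    def __post_init__(self):
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        for name in ("persistence_time", "speed_mean", "duration", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self):
        return asdict(self)


# ------------------------------------------------------------- force curves

def gen_force_curves(seed, E_true, n_curves=1, n_samples=100, noise_frac=0.02,
                     tip_radius=afm.DEFAULT_TIP_RADIUS_M,
                     poisson=afm.DEFAULT_POISSON,
                     max_force=afm.DEFAULT_MAX_FORCE_N, positions=None):
    """Hertzian force-indentation curves with multiplicative Gaussian noise.

    Indentation runs from 0 to the depth at which the noiseless force reaches
    ``max_force``.  Returns ``(curves, truth)`` where truth records the
    generating modulus and constants.
    """
    rng = derive_rng(seed, "force_curves")
    E_true = float(E_true)
    delta_max = (3.0 * max_force * (1.0 - poisson**2)
                 / (4.0 * E_true * np.sqrt(tip_radius))) ** (2.0 / 3.0)
    delta = np.linspace(0.0, delta_max, n_samples)
    f_clean = afm.hertz_force(delta, E_true, poisson, tip_radius)
    curves = []
    for i in range(n_curves):
        noise = rng.normal(0.0, noise_frac, n_samples) if noise_frac > 0 else 0.0
        force = f_clean * (1.0 + noise)
        pos = tuple(positions[i]) if positions is not None else None
        curves.append(afm.ForceCurve(delta, force, tip_radius, poisson,
                                     position=pos))
    truth = {"E_true_Pa": E_true, "noise_frac": noise_frac,
             "tip_radius_m": tip_radius, "poisson": poisson,
             "delta_max_m": float(delta_max)}
    return curves, truth


def gen_force_trace(seed, E_true, contact_z=1e-6, n_samples=400, noise_frac=0.02,
                    baseline_noise_frac=0.005, tip_radius=afm.DEFAULT_TIP_RADIUS_M,
                    poisson=afm.DEFAULT_POISSON, max_force=afm.DEFAULT_MAX_FORCE_N):
    """Raw approach trace (z, force) with a pre-contact baseline.

    Force is zero until ``contact_z`` and Hertzian beyond; multiplicative
    noise scales with the signal while ``baseline_noise_frac * max_force`` of
    additive noise covers the whole trace (so the baseline is not trivially
    silent).  Returns ``(z, force, truth)``.
    """
    rng = derive_rng(seed, "force_trace")
    delta_max = (3.0 * max_force * (1.0 - poisson**2)
                 / (4.0 * float(E_true) * np.sqrt(tip_radius))) ** (2.0 / 3.0)
    z = np.linspace(0.0, contact_z + delta_max, n_samples)
    delta = np.clip(z - contact_z, 0.0, None)
    force = afm.hertz_force(delta, float(E_true), poisson, tip_radius)
    if noise_frac > 0:
        force = force * (1.0 + rng.normal(0.0, noise_frac, n_samples))
    if baseline_noise_frac > 0:
        force = force + rng.normal(0.0, baseline_noise_frac * max_force, n_samples)
    truth = {"E_true_Pa": float(E_true), "contact_z_m": float(contact_z),
             "sample_spacing_m": float(z[1] - z[0])}
    return z, force, truth


# ---------------------------------------------------------- stiffness field

def gen_stiffness_field(seed, kind="fibrotic", extent=(200.0, 200.0), pitch=5.0,
                        baseline=4e3, healthy_amplitude=1.4e3,
                        healthy_corr_um=15.0, n_peaks=5, n_valleys=3,
                        focus_sigma_um=10.0, ceiling=40e3, floor=0.5e3):
    """Synthetic elastograph: healthy (smooth, shallow) or fibrotic (focal).

    Healthy fields are a baseline plus low-amplitude spatially smooth
    variation; fibrotic fields add Gaussian stiff foci (amplitudes up to
    ``ceiling``) and soft valleys (down to ``floor``) at mutually separated
    random positions.  Returns ``(StiffnessMap, foci)`` where ``foci`` lists
    ground-truth focus centres, kinds and amplitudes (empty for healthy).
    """
    if kind not in ("healthy", "fibrotic"):
        raise ValueError("kind must be 'healthy' or 'fibrotic'")
    rng = derive_rng(seed, "stiffness_field")
    w, h = extent
    nc, nr = int(round(w / pitch)), int(round(h / pitch))
    xc = (np.arange(nc) + 0.5) * pitch
    yc = (np.arange(nr) + 0.5) * pitch
    gx, gy = np.meshgrid(xc, yc)

    from scipy import ndimage

    grid = np.full((nr, nc), float(baseline))
    foci = []
    if kind == "healthy":
        if healthy_amplitude > 0:
            noise = rng.standard_normal((nr, nc))
            smooth = ndimage.gaussian_filter(noise, healthy_corr_um / pitch,
                                             mode="nearest")
            sd = smooth.std()
            if sd > 0:
                grid = grid + healthy_amplitude * smooth / sd
    else:
        n_foci = n_peaks + n_valleys
        margin = 2.0 * focus_sigma_um
        min_sep = 3.5 * focus_sigma_um
        centers = []
        attempts = 0
        while len(centers) < n_foci and attempts < 10000:
            attempts += 1
            c = np.array([rng.uniform(margin, w - margin),
                          rng.uniform(margin, h - margin)])
            if all(np.hypot(*(c - np.asarray(o))) >= min_sep for o in centers):
                centers.append(tuple(c))
        kinds = ["peak"] * n_peaks + ["valley"] * n_valleys
        for (cx, cy), fk in zip(centers, kinds):
            r2 = (gx - cx) ** 2 + (gy - cy) ** 2
            bump = np.exp(-r2 / (2.0 * focus_sigma_um**2))
            if fk == "peak":
                amp = rng.uniform(0.6, 1.0) * (ceiling - baseline)
                grid = grid + amp * bump
            else:
                amp = rng.uniform(0.6, 1.0) * (baseline - floor)
                grid = grid - amp * bump
            foci.append({"x_um": float(cx), "y_um": float(cy), "kind": fk,
                         "amplitude_Pa": float(amp)})
    grid = np.clip(grid, floor, ceiling)
    prov = {"source": "gen_stiffness_field", "kind": kind, "seed": int(seed),
            "baseline_Pa": baseline, "pitch_um": pitch}
    return afm.StiffnessMap(grid, pitch, (0.0, 0.0), prov), foci


# ------------------------------------------------------------------ tracks

def _reflect(v, lo, hi):
    """Reflect values into [lo, hi] (handles multiple bounces)."""
    span = hi - lo
    v = np.mod(v - lo, 2.0 * span)
    v = np.where(v > span, 2.0 * span - v, v)
    return v + lo


def gen_tracks(pattern: substrates.SubstratePattern, config: SimulationConfig,
               start_positions=None):
    """Persistent biased random walks on a stiffness pattern.

    Headings are persistent (rotational diffusion with correlation time
    ``persistence_time``) and relax toward the local stiffness-gradient
    direction with the saturating weight described in the module docstring;
    boundaries reflect.  With ``bias_strength`` 0, or on a uniform pattern,
    the walk is an unbiased persistent random walk.

    Returns ``(tracks, truth)``; ``truth`` records the config and pattern.
    """
    rng = derive_rng(config.seed, "tracks")
    n = config.n
    w, h = pattern.extent
    dt = config.frame_interval
    n_steps = int(round(config.duration / dt))
    if start_positions is None:
        pos = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    else:
        pos = np.asarray(start_positions, dtype=float).copy()
        n = len(pos)
    theta = rng.uniform(-np.pi, np.pi, n)
    sigma = np.sqrt(2.0 * dt / config.persistence_time)
    speed_um_s = config.speed_mean / 60.0

    xs = np.empty((n_steps + 1, n))
    ys = np.empty((n_steps + 1, n))
    xs[0], ys[0] = pos[:, 0], pos[:, 1]
    for k in range(n_steps):
        if config.bias_strength > 0:
            g = substrates.local_gradient(pattern, pos)
            mag = np.hypot(g[:, 0], g[:, 1])
            weight = config.bias_strength * mag / (1.0 + config.bias_strength * mag)
            has_g = mag > 0
            theta_g = np.arctan2(g[:, 1], g[:, 0])
            dtheta = np.mod(theta_g - theta + np.pi, 2.0 * np.pi) - np.pi
            theta = theta + np.where(has_g, weight * dtheta, 0.0)
        theta = theta + sigma * rng.standard_normal(n)
        step_speed = np.clip(
            speed_um_s * (1.0 + config.speed_cv * rng.standard_normal(n)), 0.0, None)
        pos = pos + (step_speed * dt)[:, None] * np.column_stack(
            [np.cos(theta), np.sin(theta)])
        pos[:, 0] = _reflect(pos[:, 0], 0.0, w)
        pos[:, 1] = _reflect(pos[:, 1], 0.0, h)
        xs[k + 1], ys[k + 1] = pos[:, 0], pos[:, 1]

    t = np.arange(n_steps + 1) * dt
    tracks = [Track(f"sim{i:04d}", t, xs[:, i], ys[:, i]) for i in range(n)]
    truth = {"config": config.to_dict(), "pattern": pattern.to_dict(),
             "n_steps": n_steps}
    return tracks, truth


# -------------------------------------------------------------- flux tables

def gen_flux_table(seed, n_animals=8, metastatic_fraction_mean=0.3,
                   sites=("liver", "lung"), primary_flux_scale=1e7,
                   primary_flux_sigma=0.5, fraction_cv=0.5):
    """Per-animal photon-flux tables with known metastatic indices.

    Primary fluxes are log-normal; each animal's total metastatic flux is a
    configured fraction of its primary (log-normal around
    ``metastatic_fraction_mean``), split across ``sites`` by a uniform
    Dirichlet draw — so the true index equals the drawn fraction exactly.
    Returns ``(table, truth_indices)``.
    """
    if n_animals < 1:
        raise ValueError("need at least one animal")
    rng = derive_rng(seed, "flux_table")
    rows = []
    truth = {}
    for i in range(n_animals):
        animal = f"A{i:03d}"
        primary = primary_flux_scale * rng.lognormal(0.0, primary_flux_sigma)
        rows.append({"animal_id": animal, "site": "primary", "photon_flux": primary})
        if metastatic_fraction_mean > 0:
            sigma = np.sqrt(np.log1p(fraction_cv**2))
            frac = metastatic_fraction_mean * rng.lognormal(-sigma**2 / 2.0, sigma)
        else:
            frac = 0.0
        shares = rng.dirichlet(np.ones(len(sites)))
        for s, share in zip(sites, shares):
            rows.append({"animal_id": animal, "site": s,
                         "photon_flux": frac * primary * share})
        truth[animal] = float(frac)
    return pd.DataFrame(rows), truth


# ------------------------------------------------------------------ fibres

def gen_fibers(seed, style="curly", n=100, n_points=50, segment_um=1.0,
               axis_deg=30.0, axis_spread_deg=5.0, wiggle_um=0.5,
               wiggle_wavelength_um=25.0, heading_sigma_deg=25.0,
               width_mean_um=None, width_sd_um=None):
    """Synthetic fibre centerlines: curly/dispersed vs straight/aligned.

    ``straight_aligned`` fibres share the ``axis_deg`` axis (per-fibre jitter
    ``axis_spread_deg``) with smooth sinusoidal perpendicular waviness
    (amplitude ``wiggle_um``, wavelength ``wiggle_wavelength_um``) and
    thicker widths; ``curly`` fibres are heading-diffusing random walks
    (``heading_sigma_deg`` per step) with dispersed orientations and thinner
    widths.  Returns ``(fibers, truth)``.
    """
    if style not in ("curly", "straight_aligned"):
        raise ValueError("style must be 'curly' or 'straight_aligned'")
    rng = derive_rng(seed, "fibers")
    if width_mean_um is None:
        width_mean_um = 3.0 if style == "straight_aligned" else 1.5
    if width_sd_um is None:
        width_sd_um = width_mean_um / 6.0
    fibers = []
    for i in range(n):
        width = float(max(0.2, rng.normal(width_mean_um, width_sd_um)))
        if style == "straight_aligned":
            ang = np.deg2rad(axis_deg + rng.normal(0.0, axis_spread_deg))
            s = np.arange(n_points) * segment_um
            if wiggle_um > 0:
                phase = rng.uniform(0.0, 2.0 * np.pi)
                perp = wiggle_um * np.sin(2.0 * np.pi * s / wiggle_wavelength_um
                                          + phase)
            else:
                perp = np.zeros(n_points)
            u = np.array([np.cos(ang), np.sin(ang)])
            v = np.array([-np.sin(ang), np.cos(ang)])
            pts = s[:, None] * u + perp[:, None] * v
        else:
            heading = rng.uniform(-np.pi, np.pi) + np.cumsum(
                np.deg2rad(heading_sigma_deg) * rng.standard_normal(n_points - 1))
            steps = segment_um * np.column_stack([np.cos(heading), np.sin(heading)])
            pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        fibers.append(FiberPolyline(pts, width, fiber_id=f"F{i:04d}"))
    truth = {"style": style, "axis_deg": axis_deg if style == "straight_aligned" else None,
             "n": n, "segment_um": segment_um}
    return fibers, truth
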