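"""Tumour dissemination and stroma-geometry metrics.

The bioluminescence metastatic index normalizes metastatic burden by primary
tumour burden: summed photon flux of the metastatic sites (default liver +
lung; liver + GI for some readouts) divided by the primary-tumour flux of the
same animal.  The fibre-geometry functions summarize collagen centerlines as
produced by upstream fibre-extraction software: curvature ratio (chord /
contour length, the straightness convention), axial end-to-end orientation,
and population histograms with an alignment score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DurokitError, SchemaError

SITES = ("primary", "liver", "lung", "GI")
DEFAULT_METASTATIC_SITES = frozenset({"liver", "lung"})


def validate_flux_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a per-animal photon-flux table against its schema.

    Required columns: ``animal_id``, ``site`` (one of primary/liver/lung/GI),
    ``photon_flux`` (>= 0); each animal must have exactly one primary row.
    """
    missing = {"animal_id", "site", "photon_flux"} - set(table.columns)
    if missing:
        raise SchemaError(f"flux table missing columns: {sorted(missing)}")
    bad_site = ~table["site"].isin(SITES)
    if bad_site.any():
        row = int(np.flatnonzero(bad_site)[0])
        raise SchemaError(f"row {row}: unknown site {table['site'].iloc[row]!r}")
    neg = table["photon_flux"] < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0])
        raise SchemaError(f"row {row}: negative photon flux "
                          f"({table['photon_flux'].iloc[row]})")
    n_primary = table[table["site"] == "primary"].groupby("animal_id").size()
    for animal in table["animal_id"].unique():
        if n_primary.get(animal, 0) > 1:
            raise SchemaError(f"animal {animal!r}: more than one primary row")
    return table


def metastatic_index(table: pd.DataFrame, sites=DEFAULT_METASTATIC_SITES) -> pd.DataFrame:
    """Per-animal normalized metastatic burden.

    index = sum of selected metastatic-site flux / primary flux.  Animals
    with a missing or zero primary flux get an ``error`` message instead of a
    value; the other animals are still computed.  Doubling all of one
    animal's fluxes leaves its index unchanged (ratio scale invariance).
    """
    validate_flux_table(table)
    sites = set(sites)
    unknown = sites - (set(SITES) - {"primary"})
    if unknown:
        raise DurokitError(f"unknown metastatic sites: {sorted(unknown)}")
    rows = []
    for animal, sub in table.groupby("animal_id", sort=False):
        prim = sub.loc[sub["site"] == "primary", "photon_flux"]
        met = float(sub.loc[sub["site"].isin(sites), "photon_flux"].sum())
        if prim.empty:
            rows.append({"animal_id": animal, "metastatic_index": np.nan,
                         "error": "missing primary flux"})
        elif float(prim.iloc[0]) == 0:
            rows.append({"animal_id": animal, "metastatic_index": np.nan,
                         "error": "primary flux is zero"})
        else:
            rows.append({"animal_id": animal,
                         "metastatic_index": met / float(prim.iloc[0]),
                         "error": None})
    return pd.DataFrame(rows)


@dataclass
class FiberPolyline:
    """An ordered fibre centerline (µm) with optional width."""

    points: np.ndarray  # (N, 2) µm
    width: float | None = None  # µm
    fiber_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise ValueError("a fibre needs at least 2 (x, y) points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive fibre points must be distinct")

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    @property
    def chord_length(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))


def curvature_ratio(fiber: FiberPolyline) -> float:
    """Chord length over contour length: 1 for straight fibres, → 0 for loops."""
    return fiber.chord_length / fiber.arc_length


def fiber_orientation(fiber: FiberPolyline):
    """Axial end-to-end orientation in degrees in [0, 180).

    θ and θ + 180° are identified (a fibre has no direction of travel).
    Returns ``(angle, valid)``; a closed loop has no chord and is flagged
    invalid rather than raising.
    """
    chord = fiber.points[-1] - fiber.points[0]
    if chord[0] == 0 and chord[1] == 0:
        return float("nan"), False
    ang = np.degrees(np.arctan2(chord[1], chord[0])) % 180.0
    return float(ang), True


def alignment_score(angles_deg) -> float:
    """1 minus the circular variance of doubled axial angles, in [0, 1].

    1 = all fibres share one axis; ~0 = orientations uniformly dispersed.
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return 0.0
    return float(abs(np.mean(np.exp(2j * np.deg2rad(a)))))


def fiber_population_summary(fibers, n_orientation_bins=18, width_bin_um=0.5):
    """Population histograms and alignment for a set of fibre centerlines.

    Returns a dict with orientation histogram (10-degree bins over [0, 180)),
    width histogram (``width_bin_um`` bins from 0), the list of curvature
    ratios, the alignment score, and counts of excluded (closed-loop) fibres.
    """
    if not fibers:
        raise DurokitError("at least one fibre is required")
    angles, ratios, widths = [], [], []
    n_loops = 0
    for f in fibers:
        ang, ok = fiber_orientation(f)
        if ok:
            angles.append(ang)
        else:
            n_loops += 1
        ratios.append(curvature_ratio(f))
        if f.width is not None:
            widths.append(f.width)
    o_edges = np.linspace(0.0, 180.0, n_orientation_bins + 1)
    o_counts, _ = np.histogram(angles, bins=o_edges)
    if widths:
        top = max(widths)
        w_edges = np.arange(0.0, top + 2 * width_bin_um, width_bin_um)
        w_counts, _ = np.histogram(widths, bins=w_edges)
    else:
        w_edges = np.array([0.0, width_bin_um])
        w_counts = np.array([0])
    return {
        "orientation_bin_edges_deg": o_edges,
        "orientation_counts": o_counts,
        "width_bin_edges_um": w_edges,
        "width_counts": w_counts,
        "curvature_ratios": ratios,
        "alignment_score": alignment_score(angles),
        "n_fibers": len(fibers),
        "n_closed_loops": n_loops,
    }
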