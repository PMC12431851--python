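"""End-point durotaxis-assay quantification on patterned substrates.

Cells are counted per stiffness region; the durotactic index is the ratio of
cells on stiff versus soft stripes, optionally normalized so that the
plating-time (4 h) distribution — cells equally split over soft and stiff
stripes — scores 1.  Index thresholds classify the response: strong (> 6,
mesenchymal stem cells and fibroblasts), confluence-dependent (> 4,
epithelial sheets at high confluence), moderate (> 2, endothelial cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import substrates
from .exceptions import DurokitError


@dataclass
class AssayObservation:
    """Cell positions on one pattern at one timepoint."""

    timepoint: float  # h
    positions: np.ndarray  # (N, 2) µm
    pattern: substrates.SubstratePattern

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array of µm coordinates")
        # raises OutOfExtentError naming the offender if any position is outside
        substrates._check_in_extent(self.pattern, self.positions[:, 0],
                                    self.positions[:, 1])


@dataclass
class DurotaxisResult:
    n_stiff: int
    n_soft: int
    n_excluded: int  # transition-band cells (no standard binning convention)
    index_raw: float  # n_stiff / n_soft; NaN when saturated
    index_normalized: float  # index_raw / normalization_baseline
    normalization_baseline: float  # 1.0 when no baseline observation given
    saturated: bool = False  # zero soft count — reported as a flag, never inf


def durotactic_index(obs: AssayObservation, baseline: AssayObservation | None = None,
                     density_normalize=False, region_rule="exclude") -> DurotaxisResult:
    """Ratio of cells over stiff versus soft stripes.

    ``density_normalize`` divides the counts by the respective region area
    fractions first — an explicit option, because the raw count ratio (the
    faithful field convention) conflates occupancy with unequal stripe
    widths.  A baseline observation (typically 4 h after plating) rescales
    the index so the baseline distribution scores 1.
    """
    if len(obs.positions) == 0:
        raise DurokitError("observation holds no cell positions")
    n_stiff, n_soft, n_excl, raw, sat = _raw_index(obs, density_normalize, region_rule)
    base = 1.0
    if baseline is not None:
        if baseline.pattern is not obs.pattern and \
                baseline.pattern.to_dict() != obs.pattern.to_dict():
            raise DurokitError("baseline observation uses a different pattern")
        _, _, _, base_raw, base_sat = _raw_index(baseline, density_normalize, region_rule)
        if base_sat or not np.isfinite(base_raw) or base_raw == 0:
            raise DurokitError("baseline index is degenerate (saturated or zero)")
        base = base_raw
    norm = raw / base if not sat else float("nan")
    return DurotaxisResult(n_stiff, n_soft, n_excl, raw, norm, base, sat)


def _raw_index(obs, density_normalize, region_rule):
    labels = substrates.region_of(obs.pattern, obs.positions, rule=region_rule)
    n_stiff = int(np.count_nonzero(labels == substrates.STIFF))
    n_soft = int(np.count_nonzero(labels == substrates.SOFT))
    n_excl = int(np.count_nonzero(labels == substrates.TRANSITION))
    num, den = float(n_stiff), float(n_soft)
    if density_normalize:
        areas = substrates.region_area_fractions(obs.pattern, rule=region_rule)
        if areas[substrates.STIFF] == 0 or areas[substrates.SOFT] == 0:
            raise DurokitError("pattern has a zero-area region; cannot density-normalize")
        num /= areas[substrates.STIFF]
        den /= areas[substrates.SOFT]
    if den == 0:
        return n_stiff, n_soft, n_excl, float("nan"), True
    return n_stiff, n_soft, n_excl, num / den, False


def classify_durotaxis(index, confluent=False, strong=6.0, confluence_dependent=4.0,
                       moderate=2.0) -> str:
    """Categorical durotaxis label from an index value.

    strong if > 6; confluence_dependent if confluent and > 4; moderate if
    > 2; otherwise none.  Thresholds are configurable.
    """
    if index < 0:
        raise DurokitError("durotactic index cannot be negative")
    if index > strong:
        return "strong"
    if confluent and index > confluence_dependent:
        return "confluence_dependent"
    if index > moderate:
        return "moderate"
    return "none"


def assay_timecourse(observations, density_normalize=False, region_rule="exclude"):
    """Per-timepoint durotaxis results, each normalized to the earliest timepoint.

    All observations must share one pattern; the earliest (typically 4 h)
    observation anchors the normalization.  Returns a list of
    ``(timepoint_h, DurotaxisResult)`` sorted by time.
    """
    if not observations:
        raise DurokitError("no observations supplied")
    ref = observations[0].pattern.to_dict()
    for o in observations[1:]:
        if o.pattern.to_dict() != ref:
            raise DurokitError("observations mix different patterns")
    ordered = sorted(observations, key=lambda o: o.timepoint)
    base = ordered[0]
    out = []
    for o in ordered:
        res = durotactic_index(o, baseline=base, density_normalize=density_normalize,
                               region_rule=region_rule)
        out.append((o.timepoint, res))
    return out
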