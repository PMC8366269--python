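"""Cytocochleogram construction from traced organ-of-Corti segments.

The organ of Corti (OC) is traced as three whole-mount segments (apical,
middle, basal).  Typed cell markers (OHC/IHC present, OHx/IHx missing) are
projected to the nearest point on the traced spiral, the three segments are
concatenated, the arc length is normalized to 100% distance from apex, and
per-5%-bin loss percentages are computed.  A place-frequency map converts
positions to characteristic frequencies for the low/high band split at 8 kHz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKER_TYPES = ("OHC", "OHx", "IHC", "IHx")
SEGMENT_ORDER = ("apical", "middle", "basal")
BIN_WIDTH_PCT = 5.0
N_BINS = 20


@dataclass
class Marker:
    type: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.type not in MARKER_TYPES:
            raise ValueError(f"unknown marker type {self.type!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("marker coordinates must be finite")


@dataclass
class SegmentTrace:
    """One whole-mount segment: a traced polyline plus its cell markers.

    Coordinates are image pixels (0-based pixel centers, y down);
    ``scale_um_per_px`` converts to micrometers.  ``invalid_spans_um`` lists
    arc-length intervals (in µm along this segment) damaged during
    preparation: the length axis is kept but markers there are not counted.
    """

    label: str
    path: np.ndarray                       # (N, 2) vertices
    scale_um_per_px: float = 1.0
    markers: list[Marker] = field(default_factory=list)
    invalid_spans_um: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        if self.path.ndim != 2 or self.path.shape[1] != 2 or len(self.path) < 2:
            raise ValueError("path needs >=2 2D points")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale must be positive")
        if self.label not in SEGMENT_ORDER:
            raise ValueError(f"segment label must be one of {SEGMENT_ORDER}")


def _dedup(path: np.ndarray) -> np.ndarray:
    """Collapse consecutive duplicate vertices."""
    keep = np.ones(len(path), dtype=bool)
    keep[1:] = np.any(np.diff(path, axis=0) != 0, axis=1)
    return path[keep]


def path_length(trace: SegmentTrace) -> float:
    """Arc length of the traced junction line in µm."""
    p = _dedup(trace.path)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return float(seg.sum() * trace.scale_um_per_px)


def project_point(path: np.ndarray, x: float, y: float) -> tuple[float, float]:
    """Nearest point on a polyline: (arc length at projection, distance).

    Each polyline segment is treated as a true line segment (perpendicular
    projection clamped to the endpoints), not a set of vertices.  Ties are
    broken toward the smaller arc length.  All quantities in path units.
    """
    p = _dedup(np.asarray(path, dtype=float))
    a, b = p[:-1], p[1:]
    d = b - a
    seg_len = np.linalg.norm(d, axis=1)
    m = np.array([x, y], dtype=float)
    t = np.einsum("ij,ij->i", m - a, d) / (seg_len ** 2)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * d
    dist = np.linalg.norm(closest - m, axis=1)
    i = int(np.argmin(dist))          # first minimum -> smaller arc length
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    return float(cum[i] + t[i] * seg_len[i]), float(dist[i])


def assign_marker(trace: SegmentTrace, marker: Marker,
                  max_distance_um: float = 200.0) -> float | None:
    """Arc-length position (µm, within the segment) of a marker, or None if
    it lies farther than ``max_distance_um`` from the path (orphan)."""
    arc_px, dist_px = project_point(trace.path, marker.x, marker.y)
    if dist_px * trace.scale_um_per_px > max_distance_um:
        warnings.warn(
            f"marker {marker.type} at ({marker.x:.1f},{marker.y:.1f}) is "
            f"{dist_px * trace.scale_um_per_px:.0f} µm from the path; excluded",
            stacklevel=2)
        return None
    return arc_px * trace.scale_um_per_px


@dataclass
class SpiralMap:
    """Arc-length parameterization of the concatenated OC spiral.

    Marker positions are percent distance from the apical end in [0, 100].
    """

    total_length_um: float
    markers: pd.DataFrame                     # columns: type, position_pct, segment
    invalid_spans_pct: list[tuple[float, float]]
    n_orphans: int = 0

    def __post_init__(self) -> None:
        if not self.total_length_um > 0:
            raise ValueError("total length must be positive")
        pos = self.markers["position_pct"].to_numpy()
        if len(pos) and (pos.min() < 0 or pos.max() > 100):
            raise ValueError("marker positions outside [0, 100]%")


def build_spiral_map(apical: SegmentTrace, middle: SegmentTrace,
                     basal: SegmentTrace,
                     max_distance_um: float = 200.0) -> SpiralMap:
    """Concatenate the three segments apical->middle->basal and normalize.

    A marker is projected within its own segment; its global arc length adds
    the cumulative length of the preceding segments.  Invalid spans are carried
    through to normalized coordinates.
    """
    traces = {t.label: t for t in (apical, middle, basal)}
    if set(traces) != set(SEGMENT_ORDER):
        raise ValueError("need exactly apical, middle and basal segments")
    scales = {t.scale_um_per_px for t in traces.values()}
    if len(scales) != 1:
        raise ValueError("inconsistent µm/px scales across segments")
    lengths = {lab: path_length(traces[lab]) for lab in SEGMENT_ORDER}
    total = sum(lengths.values())
    offset, rows, spans, orphans = 0.0, [], [], 0
    for lab in SEGMENT_ORDER:
        t = traces[lab]
        for mk in t.markers:
            arc = assign_marker(t, mk, max_distance_um)
            if arc is None:
                orphans += 1
                continue
            rows.append((mk.type, 100.0 * (offset + arc) / total, lab))
        for a, b in t.invalid_spans_um:
            spans.append((100.0 * (offset + a) / total,
                          100.0 * (offset + b) / total))
        offset += lengths[lab]
    markers = pd.DataFrame(rows, columns=["type", "position_pct", "segment"])
    return SpiralMap(total, markers, spans, orphans)


@dataclass
class Cytocochleogram:
    """Per-5%-bin present/missing counts and loss percentages.

    ``table`` has one row per (bin, cell class) with columns bin_start,
    bin_end, cell_class, n_present, n_missing, loss_pct, excluded.  A bin is
    excluded for a class when it holds no valid marker of that class or is
    fully covered by an invalid span.
    """

    table: pd.DataFrame
    total_length_um: float

    def loss(self, cell_class: str) -> pd.DataFrame:
        return self.table[self.table["cell_class"] == cell_class].reset_index(drop=True)


def bin_cytocochleogram(spiral: SpiralMap) -> Cytocochleogram:
    """Count present/missing OHC and IHC in twenty 5% bins.

    Bins are half-open [a, a+5) with the final bin closed so position 100
    falls in the last bin.  loss_pct = 100 * missing / (present + missing).
    """
    edges = np.arange(0.0, 100.0 + BIN_WIDTH_PCT, BIN_WIDTH_PCT)
    pos = spiral.markers["position_pct"].to_numpy()
    idx = np.minimum((pos // BIN_WIDTH_PCT).astype(int), N_BINS - 1)
    rows = []
    for cls, present_tok, missing_tok in (("OHC", "OHC", "OHx"),
                                          ("IHC", "IHC", "IHx")):
        types = spiral.markers["type"].to_numpy()
        for b in range(N_BINS):
            in_bin = idx == b
            n_present = int(np.sum(in_bin & (types == present_tok)))
            n_missing = int(np.sum(in_bin & (types == missing_tok)))
            total = n_present + n_missing
            lo, hi = edges[b], edges[b + 1]
            covered = any(a <= lo and b_ >= hi for a, b_ in spiral.invalid_spans_pct)
            excluded = total == 0 or covered
            loss = math.nan if excluded else 100.0 * n_missing / total
            rows.append((lo, hi, cls, n_present, n_missing, loss, excluded))
    table = pd.DataFrame(rows, columns=["bin_start", "bin_end", "cell_class",
                                        "n_present", "n_missing", "loss_pct",
                                        "excluded"])
    return Cytocochleogram(table, spiral.total_length_um)


# ---------------------------------------------------------------------------
# Place-frequency map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaceFrequencyMap:
    """Logarithmic cochlear place-frequency map.

    position_pct = anchor_pct + slope * log10(f / anchor_khz), with position
    measured as percent distance from the apex (frequency increases toward the
    base).  ``slope_pct_per_decade`` is percent of cochlear length per decade
    of frequency.
    """

    name: str
    slope_pct_per_decade: float
    anchor_pct: float
    anchor_khz: float

    def to_frequency(self, position_pct) -> np.ndarray | float:
        p = np.asarray(position_pct, dtype=float)
        if np.any((p < 0) | (p > 100)):
            raise ValueError("position outside [0, 100]%")
        f = self.anchor_khz * 10 ** ((p - self.anchor_pct) / self.slope_pct_per_decade)
        return float(f) if np.isscalar(position_pct) else f

    def to_place(self, frequency_khz) -> np.ndarray | float:
        f = np.asarray(frequency_khz, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequency must be positive")
        p = self.anchor_pct + self.slope_pct_per_decade * np.log10(f / self.anchor_khz)
        return float(p) if np.isscalar(frequency_khz) else p


#: Mouse map after Müller et al.: distance from base d(%) = 156.5 - 82.5 log10(f),
#: re-expressed as percent from apex (p = 100 - d); apex maps to ~4.84 kHz.
MULLER_2005 = PlaceFrequencyMap("muller2005", 82.5, 0.0, 10 ** (56.5 / 82.5))

#: Same 82.5 %/decade slope re-anchored so 40% from apex corresponds to 9 kHz.
ANCHORED_9KHZ = PlaceFrequencyMap("anchored_9khz", 82.5, 40.0, 9.0)

_PRESETS = {"muller2005": MULLER_2005, "anchored_9khz": ANCHORED_9KHZ}


def place_frequency_map(preset: str = "anchored_9khz") -> PlaceFrequencyMap:
    try:
        return _PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown place-frequency preset {preset!r}") from None


@dataclass
class BandLoss:
    low_pct: float
    high_pct: float
    n_bins_low: int
    n_bins_high: int


def band_loss(cyto: Cytocochleogram, pfmap: PlaceFrequencyMap,
              cell_class: str = "OHC", weighted: bool = False,
              split_khz: float = 8.0) -> BandLoss:
    """Mean loss in the low (<= split) and high (> split) frequency bands.

    Each bin is assigned by the characteristic frequency of its center; the
    default band mean is unweighted over non-excluded bins, optionally
    weighted by cell count.
    """
    t = cyto.loss(cell_class)
    valid = ~t["excluded"]
    centers = (t["bin_start"] + t["bin_end"]).to_numpy() / 2.0
    freq = pfmap.to_frequency(centers)
    out = {}
    for band, mask in (("low", freq <= split_khz), ("high", freq > split_khz)):
        sel = valid & mask
        if not sel.any():
            warnings.warn(f"{band} band has no valid bins", stacklevel=2)
            out[band] = (math.nan, 0)
            continue
        loss = t.loc[sel, "loss_pct"].to_numpy()
        if weighted:
            w = (t.loc[sel, "n_present"] + t.loc[sel, "n_missing"]).to_numpy()
            out[band] = (float(np.average(loss, weights=w)), int(sel.sum()))
        else:
            out[band] = (float(loss.mean()), int(sel.sum()))
    return BandLoss(out["low"][0], out["high"][0], out["low"][1], out["high"][1])
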