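"""Synthetic cohorts, spiral marker sets and fluorescence images.

The generators emulate the statistical structure the analysis assumes, with
known ground truth:

* ABR cohorts with a bifurcated threshold distribution — a planted upper
  subgroup offset by 16 dB at all ages, band-specific progression (8 dB per
  50 days above 8 kHz, 1.5 dB below), and within-group SD growing from 12 dB
  (juvenile) to 18 dB (adult);
* organ-of-Corti spirals (~5.33 mm) traced as three equal segments carrying
  OHC/IHC markers with a position- and age-dependent missing probability;
* single-channel fluorescence images (puncta or stripe structure on a known
  background) whose noise-free twin defines the true quantification result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .abr import (STANDARD_FREQUENCIES_KHZ, ThresholdGrid, low_band_mask,
                  quantize_level)
from .cochleogram import Marker, SegmentTrace
from .fluorquant import (DEFAULT_BALL_RADIUS, DEFAULT_FLOOR, FluorImage,
                         RoiSpec, quantify)

AGE_GROUP_NAMES = ("juvenile", "young_adult", "adult")

#: Default juvenile audiogram (dB SPL per standard frequency): flat 30 dB up
#: to 8 kHz rising to 45 dB at 45.2 kHz.  A configuration default, not data;
#: it sits far enough above the 10 dB instrument floor that the recorded
#: within-group spread is not censored by the level grid.
DEFAULT_BASELINE_AUDIOGRAM = (30.0, 30.0, 30.0, 30.0, 30.0,
                              33.0, 36.0, 39.0, 42.0, 45.0)


# ---------------------------------------------------------------------------
# ABR cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Conditions for a simulated ABR reference cohort.

    Group sizes and mean ages follow the three-age-group design (juvenile /
    young adult / adult); slopes are dB per 50 days of age, applied per band
    (split at 8 kHz); the planted upper subgroup is offset by ``upper_offset``
    dB at every age.  Per-frequency noise SD interpolates linearly from
    ``within_sd_juvenile`` at the first group age to ``within_sd_adult`` at
    the last.
    """

    n_per_group: Sequence[int] = (84, 49, 22)
    ages_days: Sequence[float] = (34.0, 80.0, 188.0)
    age_sd_days: Sequence[float] = (6.0, 11.0, 14.0)
    baseline_audiogram: Sequence[float] = DEFAULT_BASELINE_AUDIOGRAM
    high_band_slope: float = 8.0          # dB per 50 days, > 8 kHz
    low_band_slope: float = 1.5           # dB per 50 days, <= 8 kHz
    upper_offset: float = 16.0            # dB
    upper_fraction: float = 0.25
    within_sd_juvenile: float = 12.0      # dB
    within_sd_adult: float = 18.0         # dB
    max_level: float = 100.0              # dB SPL ceiling
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != len(self.ages_days):
            raise ValueError("n_per_group and ages_days differ in length")
        if np.any(np.diff(self.ages_days) <= 0):
            raise ValueError("ages must be strictly increasing")
        if not (0 < self.upper_fraction < 1):
            raise ValueError("upper_fraction must be in (0, 1)")
        if self.within_sd_juvenile < 0 or self.within_sd_adult < 0:
            raise ValueError("SDs must be non-negative")
        base = np.asarray(self.baseline_audiogram, dtype=float)
        if base.shape != (len(STANDARD_FREQUENCIES_KHZ),) or not np.all(np.isfinite(base)):
            raise ValueError("baseline audiogram must give a finite value per "
                             "standard frequency")

    def within_sd(self, age_days: float) -> float:
        a0, a1 = self.ages_days[0], self.ages_days[-1]
        if a1 == a0:
            return float(self.within_sd_juvenile)
        t = np.clip((age_days - a0) / (a1 - a0), 0.0, 1.0)
        return float(self.within_sd_juvenile
                     + t * (self.within_sd_adult - self.within_sd_juvenile))


@dataclass
class CohortGroundTruth:
    """Planted subgroup labels and noise-free expectations per subject."""

    labels: pd.DataFrame   # subject_id, age_group, age_days, planted
    params: CohortSimParams

    def planted(self, label: str) -> list[str]:
        return self.labels.loc[self.labels["planted"] == label,
                               "subject_id"].tolist()


def expected_thresholds(params: CohortSimParams, age_days: float,
                        planted: str) -> np.ndarray:
    """Noise-free (pre-quantization) thresholds for a subject."""
    freqs = np.array(STANDARD_FREQUENCIES_KHZ)
    base = np.asarray(params.baseline_audiogram, dtype=float)
    low = low_band_mask(freqs)
    slope = np.where(low, params.low_band_slope, params.high_band_slope)
    thr = base + slope * (age_days - params.ages_days[0]) / 50.0
    if planted == "upper":
        thr = thr + params.upper_offset
    return thr


def gen_cohort(params: CohortSimParams) -> tuple[list[ThresholdGrid],
                                                 CohortGroundTruth]:
    """Simulate a bifurcated cohort of threshold grids.

    Each group plants ``round(n * upper_fraction)`` upper subjects (faster/
    elevated progressors); everyone else is planted lower.  Thresholds are the
    noise-free expectation plus independent per-frequency Gaussian noise,
    snapped to the 3 dB level grid and clipped to [10, max_level]; clipped
    ceiling hits are flagged as no-response.
    """
    rng = np.random.default_rng(params.seed)
    grids: list[ThresholdGrid] = []
    rows = []
    for gi, (n, age_mean, group) in enumerate(zip(params.n_per_group,
                                                  params.ages_days,
                                                  AGE_GROUP_NAMES)):
        n_upper = int(round(n * params.upper_fraction))
        planted = np.array(["lower"] * n, dtype=object)
        planted[rng.permutation(n)[:n_upper]] = "upper"
        age_sd = params.age_sd_days[gi] if gi < len(params.age_sd_days) else 0.0
        for si in range(n):
            sid = f"{group[0]}{gi}{si:03d}"
            age = float(np.clip(age_mean + rng.normal(0.0, age_sd),
                                21.0, None))
            exp = expected_thresholds(params, age, planted[si])
            raw = exp + rng.normal(0.0, params.within_sd(age), exp.shape)
            thr = np.minimum(quantize_level(raw), params.max_level)
            nr = raw > params.max_level
            thr[nr] = params.max_level
            grids.append(ThresholdGrid(sid, "left", age, group, thr, nr))
            rows.append((sid, group, age, planted[si]))
    labels = pd.DataFrame(rows, columns=["subject_id", "age_group",
                                         "age_days", "planted"])
    return grids, CohortGroundTruth(labels, params)


# ---------------------------------------------------------------------------
# Organ-of-Corti spiral
# ---------------------------------------------------------------------------

LossProfile = Callable[[float, float], tuple[float, float]]
"""(position % from apex, age in days) -> (P(missing OHC), P(missing IHC))."""


def zero_loss(position_pct: float, age_days: float) -> tuple[float, float]:
    return 0.0, 0.0


def step_loss(threshold_pct: float, p_basal: float,
              p_apical: float = 0.0, ihc_factor: float = 0.1) -> LossProfile:
    """Step profile: apical of ``threshold_pct`` the OHC missing probability is
    ``p_apical``, basal of it ``p_basal``; IHC loss is scaled down by
    ``ihc_factor`` (IHCs are largely preserved)."""

    def profile(position_pct: float, age_days: float) -> tuple[float, float]:
        p = p_basal if position_pct >= threshold_pct else p_apical
        return p, p * ihc_factor

    return profile


@dataclass
class SpiralSimParams:
    """Geometry and loss structure of a simulated organ-of-Corti spiral.

    The path is a planar Archimedean spiral of the target arc length, sampled
    at <= 5 µm vertex spacing and cut into three equal-arc segments (apical,
    middle, basal).  Cells sit along the path at a fixed pitch per row; a cell
    is marked missing with probability ``loss_profile(position, age)``.
    """

    total_length_um: float = 5330.0
    ohc_rows: int = 3
    cell_pitch_um: float = 6.5            # OHC longitudinal spacing per row
    ihc_pitch_um: float = 7.0
    loss_profile: LossProfile = zero_loss
    age_days: float = 34.0
    artifact_spans: Sequence[tuple[float, float]] = ()   # % from apex
    vertex_spacing_um: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.total_length_um > 0:
            raise ValueError("total length must be positive")
        if self.cell_pitch_um <= 0 or self.ihc_pitch_um <= 0:
            raise ValueError("cell pitch must be positive")
        if not 0 < self.vertex_spacing_um <= 5.0:
            raise ValueError("vertex spacing must be in (0, 5] µm")
        spans = sorted(self.artifact_spans)
        for a, b in spans:
            if not (0 <= a < b <= 100):
                raise ValueError("artifact spans must lie within [0, 100]%")
        for (_, b1), (a2, _) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("artifact spans must not overlap")


@dataclass
class SpiralGroundTruth:
    """Realized per-bin loss fractions and cell records of a generated spiral."""

    cells: pd.DataFrame        # cell_class, row, position_pct, missing
    bin_loss: pd.DataFrame     # bin_start, bin_end, cell_class, n, n_missing, loss_frac
    total_length_um: float


def _archimedean_path(total_length_um: float, spacing_um: float) -> np.ndarray:
    """Dense polyline along r = a + b*theta with ~1.75 turns, trimmed by
    linear interpolation to the exact target arc length."""
    turns = 1.75
    a = total_length_um / 35.0
    theta_max = 2 * math.pi * turns
    # choose b so the analytic arc length overshoots slightly, then trim
    # s ≈ integral sqrt(r^2 + b^2) dtheta ~ (a + b*theta_mid) * theta_max
    b = (1.06 * total_length_um / theta_max - a) / (theta_max / 2)
    theta = np.arange(0.0, theta_max, spacing_um / (a + b * theta_max))
    r = a + b * theta
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] < total_length_um:
        raise RuntimeError("spiral undershoots target length")
    i = int(np.searchsorted(cum, total_length_um))
    frac = (total_length_um - cum[i - 1]) / (cum[i] - cum[i - 1])
    end = pts[i - 1] + frac * (pts[i] - pts[i - 1])
    return np.vstack([pts[:i], end])


def _point_at(path: np.ndarray, cum: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit normal on a polyline at arc length s."""
    i = int(np.clip(np.searchsorted(cum, s), 1, len(cum) - 1))
    t = (s - cum[i - 1]) / (cum[i] - cum[i - 1])
    p = path[i - 1] + t * (path[i] - path[i - 1])
    d = path[i] - path[i - 1]
    d = d / np.linalg.norm(d)
    return p, np.array([-d[1], d[0]])


def gen_spiral(params: SpiralSimParams) -> tuple[list[SegmentTrace],
                                                 SpiralGroundTruth]:
    """Simulate three traced segments with typed hair-cell markers.

    OHC rows sit at 8, 16, 24 µm lateral offsets from the traced junction,
    IHCs at -10 µm; markers inside artifact spans are dropped (the span is
    recorded as invalid so the length axis is preserved).
    """
    rng = np.random.default_rng(params.seed)
    path = _archimedean_path(params.total_length_um, params.vertex_spacing_um)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    cut = [0.0, total / 3.0, 2.0 * total / 3.0, total]
    spans = [(a / 100.0 * total, b / 100.0 * total) for a, b in params.artifact_spans]

    def in_span(s: float) -> bool:
        return any(a <= s <= b for a, b in spans)

    # per-segment vertex lists (cut points interpolated as shared vertices)
    seg_paths = []
    for k in range(3):
        lo, hi = cut[k], cut[k + 1]
        i0 = int(np.searchsorted(cum, lo, side="right"))
        i1 = int(np.searchsorted(cum, hi, side="left"))
        p_lo = _point_at(path, cum, lo)[0]
        p_hi = _point_at(path, cum, min(hi, total))[0]
        seg_paths.append(np.vstack([p_lo, path[i0:i1], p_hi]))

    cells, marker_lists = [], [[], [], []]
    specs = ([("OHC", row, params.cell_pitch_um,
               8.0 * (row + 1)) for row in range(params.ohc_rows)]
             + [("IHC", 0, params.ihc_pitch_um, -10.0)])
    for cls, row, pitch, offset in specs:
        positions = np.arange(pitch / 2.0 + (row % 2) * pitch / 2.0, total, pitch)
        for s in positions:
            pct = 100.0 * s / total
            p_ohc, p_ihc = params.loss_profile(pct, params.age_days)
            p_miss = p_ohc if cls == "OHC" else p_ihc
            if not 0.0 <= p_miss <= 1.0:
                raise ValueError("loss probability outside [0, 1]")
            missing = bool(rng.random() < p_miss)
            if in_span(s):
                continue          # damaged region: no marker placed
            cells.append((cls, row, pct, missing))
            point, normal = _point_at(path, cum, s)
            xy = point + offset * normal
            tok = {("OHC", False): "OHC", ("OHC", True): "OHx",
                   ("IHC", False): "IHC", ("IHC", True): "IHx"}[(cls, missing)]
            k = min(int(s // (total / 3.0)), 2)
            marker_lists[k].append(Marker(tok, float(xy[0]), float(xy[1])))

    traces = []
    for k, lab in enumerate(("apical", "middle", "basal")):
        lo, hi = cut[k], cut[k + 1]
        inv = [(max(a, lo) - lo, min(b, hi) - lo)
               for a, b in spans if a < hi and b > lo]
        traces.append(SegmentTrace(lab, seg_paths[k], 1.0, marker_lists[k], inv))

    cells_df = pd.DataFrame(cells, columns=["cell_class", "row",
                                            "position_pct", "missing"])
    rows = []
    edges = np.arange(0.0, 105.0, 5.0)
    for cls in ("OHC", "IHC"):
        sub = cells_df[cells_df["cell_class"] == cls]
        idx = np.minimum((sub["position_pct"].to_numpy() // 5.0).astype(int), 19)
        for b in range(20):
            m = idx == b
            n = int(m.sum())
            nm = int(sub["missing"].to_numpy()[m].sum())
            rows.append((edges[b], edges[b + 1], cls, n, nm,
                         nm / n if n else math.nan))
    bin_loss = pd.DataFrame(rows, columns=["bin_start", "bin_end", "cell_class",
                                           "n", "n_missing", "loss_frac"])
    return traces, SpiralGroundTruth(cells_df, bin_loss, total)


# ---------------------------------------------------------------------------
# Fluorescence images
# ---------------------------------------------------------------------------

@dataclass
class PunctaSpec:
    """Gaussian puncta: n spots of given sigma (px) and peak amplitude.

    ``positions`` optionally fixes the (x, y) centers; otherwise centers are
    drawn uniformly inside the image margins.  ``sigma=0`` places single-pixel
    puncta.
    """

    n: int = 5
    sigma: float = 2.0
    amplitude: float = 150.0
    positions: Sequence[tuple[float, float]] | None = None


@dataclass
class StripeSpec:
    """A vertical stripe (SV marginal layer): length x width px at amplitude."""

    length: int = 150
    width: int = 12
    amplitude: float = 150.0


@dataclass
class FluorSimParams:
    """Known-structure fluorescence image: structure + background + noise.

    ``background`` is (constant, x-gradient, y-gradient) in counts (per px for
    the gradients); noise is additive Gaussian of SD ``noise_sd`` (a Poisson
    option via ``poisson=True`` replaces it with shot noise).
    """

    shape: tuple[int, int] = (256, 256)
    bit_depth: int = 8
    structure: PunctaSpec | StripeSpec = field(default_factory=PunctaSpec)
    background: tuple[float, float, float] = (10.0, 0.0, 0.0)
    noise_sd: float = 3.0
    poisson: bool = False
    rois: Sequence[RoiSpec] = ()
    normalizer_kind: str = "n_ohc"
    n_ohc: int = 5
    sv_length: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("image shape must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        amp = self.structure.amplitude
        if amp < 0:
            raise ValueError("amplitude must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")


@dataclass
class FluorGroundTruth:
    """Noise-free twin and its pipeline quantification."""

    clean: FluorImage
    auc_clean: float
    normalized_clean: float
    structure_positions: np.ndarray


def gen_fluor(params: FluorSimParams) -> tuple[FluorImage, FluorGroundTruth]:
    """Simulate a fluorescence image and its noise-free ground truth.

    The true AUC / normalized intensity is obtained by running the same
    quantification pipeline on the noise-free image, so recovery tests compare
    like with like.  Amplitudes exceeding the bit-depth ceiling are clipped
    with a warning.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    c0, gx, gy = params.background
    clean = c0 + gx * xx + gy * yy
    st = params.structure
    if isinstance(st, PunctaSpec):
        if st.positions is not None:
            positions = np.asarray(st.positions, dtype=float)[:st.n]
        else:
            margin = max(4.0 * st.sigma, 5.0)
            cx = rng.uniform(margin, w - margin, st.n)
            cy = rng.uniform(margin, h - margin, st.n)
            positions = np.column_stack([cx, cy])
        for x0, y0 in positions:
            if st.sigma == 0:      # single-pixel punctum
                clean[int(round(y0)), int(round(x0))] += st.amplitude
            else:
                clean += st.amplitude * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2)
                                               / (2 * st.sigma ** 2))
    elif isinstance(st, StripeSpec):
        x0 = (w - st.width) // 2
        y0 = (h - st.length) // 2
        clean[y0:y0 + st.length, x0:x0 + st.width] += st.amplitude
        positions = np.array([[x0, y0]])
    else:
        raise TypeError("structure must be PunctaSpec or StripeSpec")
    ceiling = (1 << params.bit_depth) - 1
    if clean.max() > ceiling:
        warnings.warn("structure amplitude exceeds bit-depth ceiling; clipping",
                      stacklevel=2)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    clean_q = np.clip(np.rint(clean), 0, ceiling).astype(dtype)
    if params.poisson:
        noisy = rng.poisson(clean)
    else:
        noisy = clean + rng.normal(0.0, params.noise_sd, clean.shape)
    noisy_q = np.clip(np.rint(noisy), 0, ceiling).astype(dtype)
    clean_img = FluorImage(clean_q, params.bit_depth)
    noisy_img = FluorImage(noisy_q, params.bit_depth)
    rois = list(params.rois) or [RoiSpec("rectangle", x0=0, y0=0,
                                         width=w, height=h)]
    sv_length = params.sv_length
    if params.normalizer_kind == "sv_length" and sv_length is None:
        sv_length = float(st.length) if isinstance(st, StripeSpec) else None
    qr = quantify(clean_img, rois, params.normalizer_kind,
                  n_ohc=params.n_ohc, sv_length=sv_length,
                  radius=DEFAULT_BALL_RADIUS, floor=DEFAULT_FLOOR)
    return noisy_img, FluorGroundTruth(clean_img, qr.auc, qr.normalized_intensity,
                                       positions)
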