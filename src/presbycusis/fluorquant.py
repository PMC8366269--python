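"""KCNQ4/KCNQ1 immunofluorescence quantification.

Pipeline mirroring the standard ImageJ workflow: rolling-ball background
subtraction (radius 6 px), ROI isolation onto a black background, 8-bit
conversion, an intensity floor of 75 counts to suppress background staining,
integration of the remaining pixel intensity (AUC), and normalization by the
number of outer hair cells (KCNQ4) or by the stria vascularis length (KCNQ1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_BALL_RADIUS = 6
DEFAULT_FLOOR = 75


@dataclass
class FluorImage:
    """Single-channel fluorescence image with its bit depth.

    ``data`` is a 2D array; integer values must lie within the bit-depth
    range.  ``scale_um_per_px`` is optional and only used to express SV
    lengths in µm.
    """

    data: np.ndarray
    bit_depth: int = 8
    channel: str = ""
    scale_um_per_px: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("image must be a non-empty 2D array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")
        if self.data.max(initial=0) > self.max_value or self.data.min(initial=0) < 0:
            raise ValueError("pixel values outside bit-depth range")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def with_data(self, data: np.ndarray) -> "FluorImage":
        return FluorImage(data, self.bit_depth, self.channel, self.scale_um_per_px)


@dataclass
class RoiSpec:
    """Quantification region: a circle (diameter in px) or an axis-aligned
    rectangle (fixed 100 px width along the structure's long axis).

    Circles delimit the OHC basal pole (KCNQ4); rectangles follow the SV
    marginal layer (KCNQ1).  Coordinates are 0-based pixel centers.
    """

    kind: str                              # circle | rectangle
    cx: float = 0.0
    cy: float = 0.0
    diameter: float = 100.0
    x0: float = 0.0
    y0: float = 0.0
    width: float = 100.0
    height: float = 100.0
    target: str = ""                       # e.g. ohc_basal_pole | sv_marginal_layer

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "rectangle"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "circle" and not self.diameter > 0:
            raise ValueError("circle diameter must be positive")
        if self.kind == "rectangle" and (self.width <= 0 or self.height <= 0):
            raise ValueError("rectangle sides must be positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        if self.kind == "circle":
            return ((xx - self.cx) ** 2 + (yy - self.cy) ** 2
                    <= (self.diameter / 2.0) ** 2)
        return ((xx >= self.x0) & (xx < self.x0 + self.width)
                & (yy >= self.y0) & (yy < self.y0 + self.height))

    def length_px(self) -> float:
        """Extent of a rectangle ROI along its long axis (SV length)."""
        if self.kind != "rectangle":
            raise ValueError("length is defined for rectangle ROIs only")
        return float(max(self.width, self.height))


# ---------------------------------------------------------------------------
# Rolling-ball background subtraction
# ---------------------------------------------------------------------------

def ball_element(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-cap structuring element: boolean footprint and cap heights.

    heights(dx, dy) = sqrt(r^2 - dx^2 - dy^2) on the disk dx^2 + dy^2 <= r^2,
    expressed in intensity counts (the ball's intensity radius equals its
    spatial radius).
    """
    r = int(radius)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    sq = dx ** 2 + dy ** 2
    footprint = sq <= r ** 2
    heights = np.where(footprint, np.sqrt(np.maximum(r ** 2 - sq, 0.0)), 0.0)
    return footprint, heights


def _shift_reduce(img: np.ndarray, footprint: np.ndarray, heights: np.ndarray,
                  op: str) -> np.ndarray:
    """Grayscale erosion/dilation by a non-flat element, restricted to the
    image domain (no padding values enter the extrema)."""
    r = footprint.shape[0] // 2
    fill = np.inf if op == "erode" else -np.inf
    pad = np.pad(img.astype(float), r, constant_values=fill)
    out = np.full(img.shape, fill)
    h, w = img.shape
    for (i, j) in np.argwhere(footprint):
        block = pad[i:i + h, j:j + w]
        hv = heights[i, j]
        if op == "erode":
            np.minimum(out, block - hv, out=out)
        else:
            np.maximum(out, block + hv, out=out)
    return out


def rolling_ball(image: FluorImage, radius: int = DEFAULT_BALL_RADIUS,
                 return_background: bool = False):
    """Subtract the rolling-ball background (grayscale opening by a ball).

    The background is the morphological opening of the image with the
    spherical-cap element of the given radius (erosion then dilation),
    clipped below at 0; the result is image minus background, rounded back to
    the integer grid for integer inputs and clipped to [0, max].  The output
    never exceeds the input.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > min(image.data.shape):
        raise ValueError("ball larger than the image")
    footprint, heights = ball_element(radius)
    eroded = _shift_reduce(image.data, footprint, heights, "erode")
    background = np.maximum(_shift_reduce(eroded, footprint, heights, "dilate"), 0.0)
    sub = image.data.astype(float) - background
    if np.issubdtype(image.data.dtype, np.integer):
        sub = np.rint(sub)
    out = image.with_data(np.clip(sub, 0, image.max_value).astype(image.data.dtype))
    if return_background:
        return out, background
    return out


def roi_isolate(image: FluorImage, roi: RoiSpec) -> FluorImage:
    """Keep pixels inside the ROI, set everything else to 0 (black background).

    Circle membership: center-to-pixel-center distance <= diameter/2.
    """
    mask = roi.mask(image.data.shape)
    if not mask.any():
        raise ValueError("ROI does not intersect the image")
    out = np.where(mask, image.data, 0).astype(image.data.dtype)
    return image.with_data(out)


def to_8bit(image: FluorImage, mode: str = "full_scale") -> FluorImage:
    """Convert to 8-bit grayscale.

    Default is the fixed full-scale linear map v -> round(v * 255 / 65535),
    preserving cross-image comparability of images acquired with identical
    settings; ``mode='display_range'`` instead stretches the per-image
    min-max range (the interactive-display behavior, not comparable across
    images).
    """
    if image.bit_depth == 8:
        return FluorImage(image.data.astype(np.uint8), 8, image.channel,
                          image.scale_um_per_px)
    data = image.data.astype(float)
    if mode == "full_scale":
        out = np.rint(data * 255.0 / 65535.0)
    elif mode == "display_range":
        lo, hi = data.min(), data.max()
        out = np.zeros_like(data) if hi == lo else np.rint((data - lo) * 255.0 / (hi - lo))
    else:
        raise ValueError(f"unknown 8-bit conversion mode {mode!r}")
    return FluorImage(out.astype(np.uint8), 8, image.channel, image.scale_um_per_px)


def apply_floor(image: FluorImage, threshold: int = DEFAULT_FLOOR) -> FluorImage:
    """Zero all pixels below the intensity floor; pixels >= threshold keep
    their value (a floor, not a binarization: the AUC integrates intensity)."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    if image.bit_depth != 8:
        raise ValueError("floor applies to 8-bit images")
    out = np.where(image.data >= threshold, image.data, 0).astype(image.data.dtype)
    return image.with_data(out)


def integrate_auc(image: FluorImage) -> float:
    """Integrated pixel intensity (AUC) of a processed 8-bit image."""
    return float(image.data.astype(np.int64).sum())


@dataclass
class QuantResult:
    """Normalized fluorescence of one image's ROIs."""

    auc: float
    normalizer: float
    normalized_intensity: float
    normalizer_kind: str                  # n_ohc | sv_length
    per_roi_auc: list[float]
    turn: str | None = None               # apical | middle | midbasal
    quartile: str | None = None

    def __post_init__(self) -> None:
        if self.auc < 0 or self.normalizer <= 0:
            raise ValueError("AUC must be >= 0 and normalizer > 0")


def quantify(image: FluorImage, rois: list[RoiSpec], normalizer_kind: str,
             n_ohc: int | None = None, sv_length: float | None = None,
             radius: int = DEFAULT_BALL_RADIUS, floor: int = DEFAULT_FLOOR,
             eight_bit_mode: str = "full_scale", turn: str | None = None,
             quartile: str | None = None) -> QuantResult:
    """Full quantification: rolling ball -> ROI isolation -> 8-bit -> floor ->
    AUC, divided by the normalizer.

    KCNQ4 mode (``n_ohc``): AUC per outer hair cell, requiring at least three
    OHCs with localized expression.  KCNQ1 mode (``sv_length``): AUC per SV
    width; if no length is given it is taken from the (single) rectangle ROI's
    long axis.
    """
    if not rois:
        raise ValueError("need at least one ROI")
    if normalizer_kind == "n_ohc":
        if n_ohc is None:
            raise ValueError("n_ohc normalizer requires the OHC count")
        if n_ohc < 3:
            raise ValueError("KCNQ4 quantification requires >= 3 OHCs")
        norm = float(n_ohc)
    elif normalizer_kind == "sv_length":
        if sv_length is None:
            rects = [r for r in rois if r.kind == "rectangle"]
            if len(rects) != 1:
                raise ValueError("sv_length not given and not a single rectangle ROI")
            sv_length = rects[0].length_px()
        if not sv_length > 0:
            raise ValueError("SV length must be positive")
        norm = float(sv_length)
    else:
        raise ValueError(f"unknown normalizer {normalizer_kind!r}")
    sub = rolling_ball(image, radius)
    per_roi = []
    for roi in rois:
        isolated = roi_isolate(sub, roi)
        floored = apply_floor(to_8bit(isolated, eight_bit_mode), floor)
        per_roi.append(integrate_auc(floored))
    auc = float(sum(per_roi))
    return QuantResult(auc, norm, auc / norm, normalizer_kind, per_roi,
                       turn=turn, quartile=quartile)


def mean_over_turns(results: list[QuantResult]) -> float:
    """Average normalized intensity over cochlear turns (apical, middle,
    midbasal), as used for per-animal summaries."""
    if not results:
        raise ValueError("no results")
    vals = [r.normalized_intensity for r in results]
    if any(not math.isfinite(v) for v in vals):
        warnings.warn("non-finite normalized intensity in turn average",
                      stacklevel=2)
    return float(np.mean(vals))
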