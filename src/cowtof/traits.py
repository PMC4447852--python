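"""Camera-trait extraction: 13 surface traits from height profiles.

Straight cuts through the segmented cow surface yield height profiles
(heights in cm above the floor), from which the traits are computed:

* ``hip2hip`` — area between the hip-to-hip profile and its upper
  horizontal tangent line;
* ``depthleft/right``, ``volumeleft/right`` — from a cut perpendicular to
  the backbone through the dish region: per side, the maximal vertical gap
  between the profile and the closing line joining the two local maxima
  flanking the dish minimum, and the area of that gap;
* ``distpin/areapin`` and ``distmid/areamid`` (left/right) — from diagonal
  cuts hip → ischeal tuberosity ("pin") and hip → dish ("mid"): a low-order
  polynomial approximation of the profile is compared with the straight
  connecting line of its endpoints; the maximal vertical distortion and the
  enclosed (unsigned) area are the traits.

Metric conversion uses a pinhole model: at working depth ``d`` one pixel
spans ``100*d/focal_px`` centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from cowtof.config import TraitConfig
from cowtof.roi import RoiResult
from cowtof.segment import SegmentedFrame

#: CSV column order of the trait abbreviations
TRAIT_ORDER = (
    "HH", "DL", "DR", "VL", "VR",
    "DPL", "APL", "DML", "AML",
    "DPR", "APR", "DMR", "AMR",
)


class TraitExtractionError(RuntimeError):
    """A trait could not be measured; the frame contributes nothing."""


@dataclass
class HeightProfile:
    """Heights (cm above floor) sampled along a straight pixel segment."""

    heights: np.ndarray  # cm
    spacing_cm: float  # cm between consecutive samples
    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        if self.heights.size < 2:
            raise ValueError("a profile needs at least two samples")

    @property
    def s(self) -> np.ndarray:
        """Arc-length positions (cm) of the samples."""
        return np.arange(self.heights.size) * self.spacing_cm

    @property
    def length_cm(self) -> float:
        return float((self.heights.size - 1) * self.spacing_cm)


@dataclass
class CameraTraits:
    """The 13 camera traits of one valid frame (cm / cm^2)."""

    hip2hip: float
    depthleft: float
    depthright: float
    volumeleft: float
    volumeright: float
    distpinleft: float
    areapinleft: float
    distmidleft: float
    areamidleft: float
    distpinright: float
    areapinright: float
    distmidright: float
    areamidright: float

    _BY_ABBREV = {
        "HH": "hip2hip", "DL": "depthleft", "DR": "depthright",
        "VL": "volumeleft", "VR": "volumeright",
        "DPL": "distpinleft", "APL": "areapinleft",
        "DML": "distmidleft", "AML": "areamidleft",
        "DPR": "distpinright", "APR": "areapinright",
        "DMR": "distmidright", "AMR": "areamidright",
    }

    def to_row(self) -> dict[str, float]:
        """Trait values keyed by abbreviation, in the day-list column order."""
        return {ab: getattr(self, name) for ab, name in self._BY_ABBREV.items()}

    def as_array(self) -> np.ndarray:
        return np.array([self.to_row()[ab] for ab in TRAIT_ORDER])


# ---------------------------------------------------------------------------
# profile sampling
# ---------------------------------------------------------------------------


def _filled_depth(seg: SegmentedFrame) -> np.ndarray:
    """Depth with background replaced by the nearest foreground value, so
    bilinear sampling near the mask boundary is not dragged toward zero."""
    if seg.mask.all() or not seg.mask.any():
        return seg.depth
    idx = ndimage.distance_transform_edt(
        ~seg.mask, return_distances=False, return_indices=True
    )
    return seg.depth[tuple(idx)]


def height_profile(
    seg: SegmentedFrame,
    p0: Sequence[float],
    p1: Sequence[float],
    n_samples: int = 100,
    focal_px: float = 222.0,
) -> HeightProfile:
    """Sample the surface height along the segment ``p0 -> p1``.

    Bilinear interpolation at ``n_samples`` equidistant points; the sample
    spacing in cm follows from the pixel pitch at the profile's mean depth.
    Endpoints must lie on the foreground.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    for p in (p0, p1):
        r, c = int(round(p[0])), int(round(p[1]))
        if not (
            0 <= r < seg.mask.shape[0]
            and 0 <= c < seg.mask.shape[1]
            and seg.mask[r, c]
        ):
            raise TraitExtractionError(f"profile endpoint {tuple(p)} outside foreground")
    if np.allclose(p0, p1):
        raise TraitExtractionError("degenerate profile: endpoints coincide")
    t = np.linspace(0.0, 1.0, n_samples)
    coords = p0[:, None] * (1 - t) + p1[:, None] * t
    depth = ndimage.map_coordinates(_filled_depth(seg), coords, order=1)
    heights = (seg.camera_height - depth) * 100.0
    cm_per_px = 100.0 * float(depth.mean()) / focal_px
    pixel_len = float(np.hypot(*(p1 - p0)))
    spacing = pixel_len / (n_samples - 1) * cm_per_px
    return HeightProfile(heights=heights, spacing_cm=spacing, p0=tuple(p0), p1=tuple(p1))


# ---------------------------------------------------------------------------
# trait primitives (operate on 1-D profiles; closed-form testable)
# ---------------------------------------------------------------------------


def trait_hip2hip(profile: HeightProfile, smooth_window: int = 5) -> float:
    """Area (cm^2) between the profile and its upper horizontal tangent.

    A light moving average suppresses per-sample sensor noise before the
    tangent level (the profile maximum) is taken; it preserves the integral
    of smooth profiles.
    """
    hs = _smooth1d(profile.heights, smooth_window)
    gap = hs.max() - hs
    return float(np.trapezoid(gap, dx=profile.spacing_cm))


def closing_line_depth_volume(
    heights: np.ndarray,
    spacing_cm: float,
    dish_idx: int,
    lo: int | None = None,
    hi: int | None = None,
    smooth_window: int = 5,
) -> tuple[float, float]:
    """Dish depth (cm) and volume (cm^2) under the closing line.

    The closing line joins the two maxima flanking the dish minimum at
    ``dish_idx`` (searched on the lightly smoothed profile within
    ``[lo, hi]``); the depth is the maximal vertical gap between the closing
    line and the profile, the volume the integral of the positive gap
    between the flanking maxima.
    """
    h = np.asarray(heights, dtype=float)
    hs = _smooth1d(h, smooth_window)
    lo = 0 if lo is None else max(lo, 0)
    hi = h.size if hi is None else min(hi, h.size)
    if not lo < dish_idx < hi - 1:
        raise TraitExtractionError("dish minimum outside the searchable span")
    left = lo + int(np.argmax(hs[lo:dish_idx]))
    right = dish_idx + 1 + int(np.argmax(hs[dish_idx + 1 : hi]))
    if hs[left] <= hs[dish_idx] or hs[right] <= hs[dish_idx]:
        raise TraitExtractionError("no flanking maxima around the dish minimum")
    i = np.arange(left, right + 1)
    chord = h[left] + (h[right] - h[left]) * (i - left) / max(right - left, 1)
    gap = chord - h[left : right + 1]
    depth = float(gap.max())
    volume = float(np.trapezoid(np.clip(gap, 0.0, None), dx=spacing_cm))
    return depth, volume


def chord_deviation(
    profile: HeightProfile, degree: int = 4
) -> tuple[float, float]:
    """Maximal distortion (cm) and unsigned area (cm^2) between a polynomial
    approximation of the profile and the straight line joining its
    endpoints."""
    s = profile.s
    h = profile.heights
    if profile.length_cm <= 0:
        raise TraitExtractionError("degenerate profile: zero length")
    coeff = np.polynomial.polynomial.polyfit(s, h, degree)
    poly = np.polynomial.polynomial.polyval(s, coeff)
    chord = h[0] + (h[-1] - h[0]) * s / s[-1]
    dev = poly - chord
    dist = float(np.abs(dev).max())
    area = float(np.trapezoid(np.abs(dev), dx=profile.spacing_cm))
    return dist, area


def _smooth1d(x: np.ndarray, window: int) -> np.ndarray:
    """Moving average that leaves the first/last half-window untouched, so
    profile endpoints (tangent levels, chord anchors) are not biased by the
    boundary."""
    if window <= 1 or x.size < window:
        return x.astype(float)
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    out = np.convolve(padded, np.ones(window) / window, mode="valid")
    out[:pad] = x[:pad]
    out[-pad:] = x[-pad:]
    return out


# ---------------------------------------------------------------------------
# cut construction on a frame
# ---------------------------------------------------------------------------


def dish_cut_traits(
    seg: SegmentedFrame,
    roi_result: RoiResult,
    config: TraitConfig | None = None,
) -> tuple[float, float, float, float]:
    """(depthleft, depthright, volumeleft, volumeright) from the dish cut.

    The cut runs perpendicular to the backbone through a point a configured
    few pixels forward of the midpoint of the two dish landmarks (where the
    rump surface, rather than the mask boundary, carries the dips), clipped
    to the mask.
    """
    cfg = config or TraitConfig()
    slope, intercept = roi_result.backbone
    d = np.array([1.0, slope]) / np.hypot(1.0, slope)  # along the backbone
    p = np.array([-slope, 1.0]) / np.hypot(1.0, slope)  # across the body
    dish_l = np.asarray(roi_result.dish_left, dtype=float)
    dish_r = np.asarray(roi_result.dish_right, dtype=float)
    centre = 0.5 * (dish_l + dish_r) + cfg.dish_cut_forward_px * d

    t_lo = _extent_in_mask(seg.mask, centre, -p)
    t_hi = _extent_in_mask(seg.mask, centre, p)
    if t_lo < 2 or t_hi < 2:
        raise TraitExtractionError("dish cut does not span the mask")
    p0 = centre - (t_lo - 1.0) * p
    p1 = centre + (t_hi - 1.0) * p
    prof = _profile_snapped(seg, p0, p1, cfg)

    n = prof.heights.size
    px_per_sample = np.hypot(*(np.asarray(p1) - np.asarray(p0))) / (n - 1)
    centre_idx = int(round(float(np.dot(centre - np.asarray(p0), p)) / px_per_sample))
    centre_idx = int(np.clip(centre_idx, 1, n - 2))
    out: dict[str, tuple[float, float]] = {}
    for name, dish in (("left", dish_l), ("right", dish_r)):
        t_dish = float(np.dot(dish - np.asarray(p0), p))
        idx = t_dish / px_per_sample
        win = max(int(round(cfg.dish_window_px / px_per_sample)), 2)
        lo = int(np.clip(idx - win, 1, n - 2))
        hi = int(np.clip(idx + win, 1, n - 2))
        if hi <= lo:
            raise TraitExtractionError("dish position outside the cut")
        local = int(np.argmin(_smooth1d(prof.heights, 5)[lo : hi + 1])) + lo
        # flanking maxima live on this dish's side of the cut: between the
        # outer cut end and the backbone crossing at the cut centre
        side_lo, side_hi = (0, centre_idx + 2) if name == "left" else (
            max(centre_idx - 1, 0), n
        )
        out[name] = closing_line_depth_volume(
            prof.heights, prof.spacing_cm, local, lo=side_lo, hi=side_hi
        )
    return (
        out["left"][0], out["right"][0], out["left"][1], out["right"][1],
    )


def _extent_in_mask(
    mask: np.ndarray, origin: np.ndarray, direction: np.ndarray, step: float = 0.5
) -> float:
    """Distance (px) from origin along direction until leaving the mask."""
    t = 0.0
    H, W = mask.shape
    while True:
        q = origin + (t + step) * direction
        r, c = int(round(q[0])), int(round(q[1]))
        if not (0 <= r < H and 0 <= c < W) or not mask[r, c]:
            return t
        t += step


def _profile_snapped(
    seg: SegmentedFrame, p0: np.ndarray, p1: np.ndarray, cfg: TraitConfig
) -> HeightProfile:
    """height_profile with endpoints snapped onto the mask if rounding
    pushed them just outside."""
    p0 = _snap(seg.mask, p0)
    p1 = _snap(seg.mask, p1)
    return height_profile(seg, p0, p1, cfg.n_samples, cfg.focal_px)


def _snap(mask: np.ndarray, p: np.ndarray) -> np.ndarray:
    r, c = int(round(p[0])), int(round(p[1]))
    if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]:
        return p
    rr, cc = np.nonzero(mask)
    k = np.argmin((rr - p[0]) ** 2 + (cc - p[1]) ** 2)
    return np.array([float(rr[k]), float(cc[k])])


def diagonal_traits(
    seg: SegmentedFrame,
    roi_result: RoiResult,
    config: TraitConfig | None = None,
) -> dict[str, float]:
    """The eight diagonal-cut traits (dist/area, pin/mid, left/right)."""
    cfg = config or TraitConfig()
    cuts = {
        ("pin", "left"): (roi_result.hip_left, roi_result.tuberosity_left),
        ("pin", "right"): (roi_result.hip_right, roi_result.tuberosity_right),
        ("mid", "left"): (roi_result.hip_left, roi_result.dish_left),
        ("mid", "right"): (roi_result.hip_right, roi_result.dish_right),
    }
    out: dict[str, float] = {}
    for (kind, side), (a, b) in cuts.items():
        prof = height_profile(seg, a, b, cfg.n_samples, cfg.focal_px)
        dist, area = chord_deviation(prof, cfg.poly_degree)
        out[f"dist{kind}{side}"] = dist
        out[f"area{kind}{side}"] = area
    return out


def extract_all(
    seg: SegmentedFrame,
    roi_result: RoiResult,
    config: TraitConfig | None = None,
) -> CameraTraits:
    """All 13 camera traits of a valid frame, or failure as a unit."""
    cfg = config or TraitConfig()
    if not roi_result.valid:
        raise TraitExtractionError("ROI result is not valid")
    hip_prof = height_profile(
        seg, roi_result.hip_left, roi_result.hip_right, cfg.n_samples, cfg.focal_px
    )
    hh = trait_hip2hip(hip_prof)
    dl, dr, vl, vr = dish_cut_traits(seg, roi_result, cfg)
    diag = diagonal_traits(seg, roi_result, cfg)
    return CameraTraits(
        hip2hip=hh,
        depthleft=dl, depthright=dr, volumeleft=vl, volumeright=vr,
        distpinleft=diag["distpinleft"], areapinleft=diag["areapinleft"],
        distmidleft=diag["distmidleft"], areamidleft=diag["areamidleft"],
        distpinright=diag["distpinright"], areapinright=diag["areapinright"],
        distmidright=diag["distmidright"], areamidright=diag["areamidright"],
    )
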