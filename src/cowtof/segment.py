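"""Frame sorting and segmentation ("sortout_and_segment").

Decides whether a frame shows a cow's lower back and separates it from the
background.  Moving objects are found from the per-pixel difference to the
background model, confirmed by a depth-value histogram (the object must form
a depth mode clearly separated from the background mode), restricted to the
largest connected component, and finally judged by the position test: the
lower back including the tail is visible only while the body intersects the
lower image boundary and keeps distance to the upper one.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from cowtof.calib import SceneryInfo
from cowtof.config import SegmentConfig
from cowtof.frames import DepthFrame


class RejectionReason(str, Enum):
    NONE = "none"
    NO_OBJECT = "no_object"
    POSITION_FAIL = "position_fail"


@dataclass
class SegmentedFrame:
    """A frame with the background set to zero, plus the sorting verdict."""

    depth: np.ndarray  # background pixels exactly 0.0
    mask: np.ndarray  # boolean foreground
    keep_decision: bool
    rejection_reason: RejectionReason
    camera_height: float

    @property
    def height_cm(self) -> np.ndarray:
        """Surface height above the floor (cm); 0 outside the mask."""
        h = (self.camera_height - self.depth) * 100.0
        h[~self.mask] = 0.0
        return h


def has_object_between_walls(
    frame: DepthFrame, scenery: SceneryInfo, config: SegmentConfig | None = None
) -> tuple[bool, tuple[int, int] | None]:
    """Is there an object strictly between the box walls, and where?

    Returns ``(present, (col_lo, col_hi))``; the extent is the column range
    of pixels deviating from the camera height by more than the difference
    threshold.
    """
    cfg = config or SegmentConfig()
    inner = slice(scenery.wall_left_col + 1, scenery.wall_right_col)
    depth = np.asarray(frame, dtype=float)[:, inner]
    thresh = cfg.k_sigma * np.maximum(scenery.std_map[:, inner], cfg.sigma_floor_m)
    dev = np.abs(depth - scenery.camera_height) > thresh
    if dev.sum() < cfg.min_object_pixels:
        return False, None
    cols = np.nonzero(dev.any(axis=0))[0] + scenery.wall_left_col + 1
    return True, (int(cols.min()), int(cols.max()))


def position_test(mask: np.ndarray, gap_min: int = 10) -> bool:
    """True iff the mask reaches the bottom row and clears the top margin."""
    if not mask.any():
        return False
    touches_bottom = bool(mask[-1].any())
    top_row = int(np.nonzero(mask.any(axis=1))[0][0])
    return touches_bottom and top_row >= gap_min


def segment_cow(
    frame: DepthFrame, scenery: SceneryInfo, config: SegmentConfig | None = None
) -> SegmentedFrame:
    """Separate the moving object from the background.

    The candidate mask is ``|IMG - meanIMG| > k * max(stdIMG, sigma_floor)``
    between the walls; a depth histogram must then confirm a foreground mode
    separated from the background mode, and the mask is restricted to its
    largest 8-connected component.
    """
    cfg = config or SegmentConfig()
    depth = np.asarray(frame, dtype=float)
    thresh = cfg.k_sigma * np.maximum(scenery.std_map, cfg.sigma_floor_m)
    candidate = np.abs(depth - scenery.mean_map) > thresh
    candidate &= depth > 0  # exact zero marks already-removed background
    cols = np.arange(depth.shape[1])
    candidate &= (cols > scenery.wall_left_col) & (cols < scenery.wall_right_col)

    if candidate.sum() < cfg.min_object_pixels or not _histogram_confirms(
        depth, candidate, scenery, cfg
    ):
        return _rejected(depth, RejectionReason.NO_OBJECT, scenery)

    # the object is one coherent depth mode: drop candidate pixels whose
    # depth lies far from the candidate median (floor pixels with extreme
    # noise that happen to touch the object's rim)
    fg_median = float(np.median(depth[candidate]))
    candidate &= np.abs(depth - fg_median) <= cfg.fg_depth_halfwidth_m
    # prune weakly attached speckle (noise pixels touching the object rim
    # only diagonally); pixels of a coherent surface keep >= 3 neighbours
    neighbours = ndimage.convolve(
        candidate.astype(np.uint8), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
        mode="constant",
    )
    candidate &= neighbours >= 3
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return _rejected(depth, RejectionReason.NO_OBJECT, scenery)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))

    segmented = np.where(mask, depth, 0.0)
    return SegmentedFrame(
        depth=segmented,
        mask=mask,
        keep_decision=True,  # provisional; position judged in sort_frame
        rejection_reason=RejectionReason.NONE,
        camera_height=scenery.camera_height,
    )


def _histogram_confirms(
    depth: np.ndarray,
    candidate: np.ndarray,
    scenery: SceneryInfo,
    cfg: SegmentConfig,
) -> bool:
    """Depth-histogram check: candidate pixels must form a mode separated
    from the background mode by at least ``mode_separation_m`` with a valley
    between the two modes."""
    inner = np.zeros_like(candidate)
    inner[:, scenery.wall_left_col + 1 : scenery.wall_right_col] = True
    values = depth[inner]
    fg_mode = float(np.median(depth[candidate]))
    bg_px = inner & ~candidate
    if not bg_px.any():
        return True  # object fills the box; nothing to separate from
    bg_mode = float(np.median(depth[bg_px]))
    if abs(bg_mode - fg_mode) < cfg.mode_separation_m:
        return False
    counts, edges = np.histogram(values, bins=cfg.hist_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo, hi = sorted((fg_mode, bg_mode))
    fg_count = counts[np.argmin(np.abs(centers - fg_mode))]
    bg_count = counts[np.argmin(np.abs(centers - bg_mode))]
    between = (centers > lo + 0.02) & (centers < hi - 0.02)
    if not between.any():
        return False
    valley = counts[between].min()
    return bool(valley <= cfg.valley_frac * min(fg_count, bg_count))


def _rejected(
    depth: np.ndarray, reason: RejectionReason, scenery: SceneryInfo
) -> SegmentedFrame:
    return SegmentedFrame(
        depth=np.zeros_like(depth),
        mask=np.zeros(depth.shape, dtype=bool),
        keep_decision=False,
        rejection_reason=reason,
        camera_height=scenery.camera_height,
    )


def sort_frame(
    frame: DepthFrame, scenery: SceneryInfo, config: SegmentConfig | None = None
) -> SegmentedFrame:
    """Full sorting decision: object present, segmented, position plausible.

    Kept frames carry the zero-background image; rejected frames record why.
    """
    cfg = config or SegmentConfig()
    present, _ = has_object_between_walls(frame, scenery, cfg)
    if not present:
        return _rejected(np.asarray(frame, dtype=float), RejectionReason.NO_OBJECT, scenery)
    seg = segment_cow(frame, scenery, cfg)
    if not seg.keep_decision:
        return seg
    if not position_test(seg.mask, cfg.gap_min):
        seg.keep_decision = False
        seg.rejection_reason = RejectionReason.POSITION_FAIL
    return seg
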