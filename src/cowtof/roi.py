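"""Region-of-interest detection: the multistage test battery.

A kept, segmented frame passes through (in order) the ImageBorder tests
(left/right), the HindBoundaryCurve test, and — only for code (1,1,1) —
landmark detection on the *signature*: the sequence of distances between the
centre of mass of the cow area and every point of its rear boundary curve.
The tail is the signature's local maximum aligned with the centre of mass;
the dishes of the rump appear as explicit local minima beside the tail bump
(classified "deep") or, when the signature segues into a flat course, at the
point of maximal curvature at the bump's base (classified "flat").  Ischeal
tuberosities follow breed-specific rules, the backbone is a linear fit to
the per-row highest surface points, and hips are the lateral height bumps in
the forward body half.  A final anatomical plausibility check compares the
left and right body halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal as sp_signal

from cowtof.config import RoiConfig
from cowtof.segment import SegmentedFrame


class FailureStage(str, Enum):
    NONE = "none"
    BORDER = "border"
    HIND_BOUNDARY = "hind_boundary"
    TAIL = "tail"
    DISH = "dish"
    TUBEROSITY = "tuberosity"
    BACKBONE = "backbone"
    HIP = "hip"
    ANATOMY = "anatomy"


@dataclass
class BoundaryCurves:
    """Outer and inner hind boundary curves, per foreground column.

    ``outer`` is the first nonzero row scanning downward from the upper
    image boundary; ``inner`` the topmost row of the vertical foreground run
    that contains the torso (the run holding the column's bottommost
    foreground pixel).  They differ only over artifacts such as an
    overhanging tail or leftover wall/floor fragments.
    """

    cols: np.ndarray
    outer: np.ndarray
    inner: np.ndarray


@dataclass
class Signature:
    distances: np.ndarray  # px, ordered left-to-right by column
    points: np.ndarray  # (n, 2) boundary points (row, col)
    com: tuple[float, float]
    smoothed: np.ndarray = field(repr=False, default=None)


@dataclass
class RoiResult:
    code_triple: tuple[int, int, int]  # (hind_boundary, border_left, border_right)
    valid: bool = False
    failure_stage: FailureStage = FailureStage.NONE
    tail: tuple[int, int] | None = None
    tuberosity_left: tuple[int, int] | None = None
    tuberosity_right: tuple[int, int] | None = None
    dish_left: tuple[int, int] | None = None
    dish_right: tuple[int, int] | None = None
    dish_class_left: str | None = None
    dish_class_right: str | None = None
    backbone: tuple[float, float] | None = None  # (slope dcol/drow, col at row 0)
    hip_left: tuple[int, int] | None = None
    hip_right: tuple[int, int] | None = None

    @property
    def code_str(self) -> str:
        return "-".join(str(c) for c in self.code_triple)

    @property
    def landmarks(self) -> dict[str, tuple[int, int]]:
        names = (
            "tail", "tuberosity_left", "tuberosity_right",
            "dish_left", "dish_right", "hip_left", "hip_right",
        )
        return {n: getattr(self, n) for n in names if getattr(self, n) is not None}

    def to_record(self) -> dict:
        rec = {
            "code_triple": self.code_str,
            "valid": self.valid,
            "failure_stage": self.failure_stage.value,
            "dish_class_left": self.dish_class_left,
            "dish_class_right": self.dish_class_right,
            "backbone": list(self.backbone) if self.backbone else None,
        }
        rec.update({k: list(v) for k, v in self.landmarks.items()})
        return rec


# ---------------------------------------------------------------------------
# stage 1: border and boundary-curve tests
# ---------------------------------------------------------------------------


def test_image_border(
    seg: SegmentedFrame, config: RoiConfig | None = None
) -> tuple[int, int]:
    """(left_pass, right_pass): a side fails iff foreground occupies its
    outermost ``border_margin`` columns."""
    cfg = config or RoiConfig()
    m = cfg.border_margin
    left = 0 if seg.mask[:, :m].any() else 1
    right = 0 if seg.mask[:, -m:].any() else 1
    return left, right


def compute_boundary_curves(seg: SegmentedFrame) -> BoundaryCurves:
    mask = seg.mask
    cols = np.nonzero(mask.any(axis=0))[0]
    outer = np.empty(cols.size, dtype=int)
    inner = np.empty(cols.size, dtype=int)
    for i, c in enumerate(cols):
        rows = np.nonzero(mask[:, c])[0]
        outer[i] = rows[0]
        # the torso run: the run of consecutive rows containing the
        # bottommost pixel (artifacts hang above the body)
        breaks = np.nonzero(np.diff(rows) > 1)[0]
        inner[i] = rows[breaks[-1] + 1] if breaks.size else rows[0]
    return BoundaryCurves(cols=cols, outer=outer, inner=inner)


def test_hind_boundary(curves: BoundaryCurves, tol_rows: int = 3) -> int:
    """Pass iff the inner and outer curves differ by at most ``tol_rows``."""
    if curves.cols.size == 0:
        return 0
    return int(np.max(curves.inner - curves.outer) <= tol_rows)


# ---------------------------------------------------------------------------
# stage 2: signature and knuckles
# ---------------------------------------------------------------------------


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or x.size < window:
        return x.astype(float)
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def compute_signature(
    seg: SegmentedFrame,
    curves: BoundaryCurves | None = None,
    config: RoiConfig | None = None,
) -> Signature:
    """Distances from the centre of mass to every outer-boundary point."""
    cfg = config or RoiConfig()
    if curves is None:
        curves = compute_boundary_curves(seg)
    rr, cc = np.nonzero(seg.mask)
    if rr.size == 0:
        raise ValueError("empty mask has no signature")
    com = (float(rr.mean()), float(cc.mean()))
    points = np.column_stack([curves.outer, curves.cols])
    dist = np.hypot(points[:, 0] - com[0], points[:, 1] - com[1])
    return Signature(
        distances=dist, points=points, com=com,
        smoothed=_smooth(dist, cfg.smooth_window),
    )


def detect_tail(sig: Signature, config: RoiConfig | None = None) -> int | None:
    """The signature's local maximum in alignment with the centre of mass.

    Among local maxima of the smoothed signature, return the one whose
    boundary point lies within ``axis_tol_deg`` of the body axis (the
    straight-up direction from the centre of mass); ties resolve to the
    smallest off-axis angle.
    """
    cfg = config or RoiConfig()
    peaks, _ = sp_signal.find_peaks(sig.smoothed)
    if peaks.size == 0:
        return None
    drow = sig.points[peaks, 0] - sig.com[0]
    dcol = sig.points[peaks, 1] - sig.com[1]
    angles = np.degrees(np.arctan2(np.abs(dcol), -drow))  # 0 = straight up
    ok = angles <= cfg.axis_tol_deg
    if not ok.any():
        return None
    return int(peaks[ok][np.argmin(angles[ok])])


def _curvature(x: np.ndarray) -> np.ndarray:
    d2 = np.zeros_like(x)
    d2[1:-1] = x[:-2] - 2 * x[1:-1] + x[2:]
    return d2


def classify_and_detect_dishes(
    sig: Signature, tail_idx: int, config: RoiConfig | None = None
) -> dict[str, tuple[int, str] | None]:
    """Per side: (signature index, "deep"|"flat") of the dish of the rump.

    Deep: an explicit local minimum sideways of the tail maximum.  Flat: the
    signature's gradient runs flat beyond the tail bump; the dish then sits
    at the base of the bump where the curvature is largest.  ``None`` marks
    a side where neither pattern is found.
    """
    cfg = config or RoiConfig()
    s = sig.smoothed
    out: dict[str, tuple[int, str] | None] = {}
    for name, direction in (("left", -1), ("right", +1)):
        out[name] = _detect_dish_side(s, tail_idx, direction, cfg)
    return out


def _detect_dish_side(
    s: np.ndarray, tail_idx: int, direction: int, cfg: RoiConfig
) -> tuple[int, str] | None:
    lo = tail_idx + direction * cfg.dish_search_from
    hi = tail_idx + direction * cfg.dish_search_to
    lo, hi = min(lo, hi), max(lo, hi)
    lo, hi = max(lo, 0), min(hi, s.size - 1)
    if hi - lo < 3:
        return None
    side = s[lo : hi + 1]
    if direction < 0:
        side = side[::-1]  # walk outward from the tail
    minima, props = sp_signal.find_peaks(-side, prominence=cfg.dish_min_prominence)
    if minima.size > 0:
        first = int(minima[0])
        idx = (tail_idx + cfg.dish_search_from + first) if direction > 0 else (
            tail_idx - cfg.dish_search_from - first
        )
        return idx, "deep"
    # flat course: maximal curvature at the base of the tail bump.  The raw
    # second difference oscillates with the integer-row staircase of the
    # boundary, so it is averaged over the staircase period first and the
    # peak refined parabolically.
    curv = _curvature(side)
    if curv.size < 5:
        return None
    curv = _smooth(curv, 5)
    base = int(np.argmax(curv[1:-1])) + 1
    if 1 <= base <= curv.size - 2:
        denom = curv[base - 1] - 2 * curv[base] + curv[base + 1]
        if denom < 0:
            base = int(round(base + 0.5 * (curv[base - 1] - curv[base + 1]) / denom))
            base = int(np.clip(base, 1, curv.size - 2))
    if base <= 2:
        # curvature peak at the search-window edge: the signature has no
        # resolvable bump base on this side
        return None
    beyond = side[base:]
    if beyond.size >= 4:
        grad = np.abs(np.diff(beyond))
        if grad.mean() > cfg.grad_flat:
            return None
    idx = (tail_idx + cfg.dish_search_from + base) if direction > 0 else (
        tail_idx - cfg.dish_search_from - base
    )
    return idx, "flat"


def detect_tuberosities(
    sig: Signature,
    dishes: dict[str, tuple[int, str] | None],
    breed_class: str,
    config: RoiConfig | None = None,
) -> dict[str, int] | None:
    """Per-side signature index of the ischeal tuberosities.

    Both dishes deep (required for HF; also accepted for FV): the local
    maxima adjacent to each dish on its outward side.  Both dishes flat
    (FV only): the point midway (rounded toward the dish) between the dish
    and the first index where the signature drops below ``drop_tol`` times
    the tail value.  Any other combination rejects the frame.
    """
    cfg = config or RoiConfig()
    if dishes["left"] is None or dishes["right"] is None:
        return None
    classes = {dishes["left"][1], dishes["right"][1]}
    if classes == {"deep"}:
        rule = "deep"
    elif classes == {"flat"} and breed_class.upper() == "FV":
        rule = "flat"
    else:
        return None

    s = sig.smoothed
    out: dict[str, int] = {}
    for name, direction in (("left", -1), ("right", +1)):
        dish_idx = dishes[name][0]
        if rule == "deep":
            idx = _next_local_max(s, dish_idx, direction)
        else:
            idx = _halfway_to_drop(s, dish_idx, direction, cfg)
        if idx is None:
            return None
        out[name] = idx
    return out


def _next_local_max(s: np.ndarray, start: int, direction: int) -> int | None:
    """First local maximum of s strictly beyond ``start`` in ``direction``."""
    i = start + direction
    while 1 <= i <= s.size - 2:
        if s[i] >= s[i - 1] and s[i] >= s[i + 1] and (s[i] > s[i - direction]):
            return int(i)
        i += direction
    return None


def _halfway_to_drop(
    s: np.ndarray, dish_idx: int, direction: int, cfg: RoiConfig
) -> int | None:
    tail_val = s.max()  # tail is the global maximum for valid frames
    level = cfg.drop_tol * tail_val
    i = dish_idx
    drop = None
    while 0 <= i <= s.size - 1:
        if s[i] < level:
            drop = i
            break
        i += direction
    if drop is None or abs(drop - dish_idx) < cfg.min_drop_gap:
        return None  # no drop, or degenerate (signature already below level)
    return dish_idx + direction * (abs(drop - dish_idx) // 2)


# ---------------------------------------------------------------------------
# stage 3: backbone and hips
# ---------------------------------------------------------------------------


def fit_backbone(
    seg: SegmentedFrame, config: RoiConfig | None = None
) -> tuple[float, float] | None:
    """Linear approximation of the highest points on the cow's back.

    Per usable mask row the column of minimal depth (the surface point
    closest to the camera); the rearmost ``backbone_tail_frac`` of mask rows
    is excluded so the tail does not dominate.  Returns ``(slope,
    intercept)`` of the least-squares line ``col = intercept + slope*row``.
    """
    cfg = config or RoiConfig()
    mask = seg.mask
    rows_with = np.nonzero(mask.any(axis=1))[0]
    if rows_with.size < cfg.min_backbone_rows:
        return None
    span = rows_with[-1] - rows_with[0]
    cut = rows_with[0] + cfg.backbone_tail_frac * span
    use_rows = rows_with[rows_with >= cut]
    if use_rows.size < cfg.min_backbone_rows:
        return None
    ridge_cols = np.empty(use_rows.size, dtype=float)
    depth = np.where(mask, seg.depth, np.inf)
    for i, r in enumerate(use_rows):
        ridge_cols[i] = np.argmin(depth[r])
    slope, intercept = np.polyfit(use_rows.astype(float), ridge_cols, 1)
    return float(slope), float(intercept)


def detect_hips(
    seg: SegmentedFrame,
    backbone: tuple[float, float],
    config: RoiConfig | None = None,
) -> dict[str, tuple[int, int]] | None:
    """Hip coordinates from the lateral height bumps in the forward half.

    Per body side the tallest local height maximum clear of the backbone
    band; among near-equal maxima the one at maximal lateral distance from
    the backbone.  Returned only if the two sides are sufficiently
    symmetric in backbone distance and height.
    """
    cfg = config or RoiConfig()
    from scipy import ndimage

    slope, intercept = backbone
    mask = seg.mask
    rows_with = np.nonzero(mask.any(axis=1))[0]
    if rows_with.size == 0:
        return None
    mid = rows_with[0] + 0.5 * (rows_with[-1] - rows_with[0])
    h = ndimage.gaussian_filter(seg.height_cm, 1.5)
    rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    lateral = cc - (intercept + slope * rr)
    forward = mask & (rr >= mid) & (np.abs(lateral) >= cfg.hip_min_lateral)
    out: dict[str, tuple[int, int]] = {}
    feats: dict[str, tuple[float, float]] = {}
    for name, side_sel in (("left", lateral < 0), ("right", lateral > 0)):
        region = forward & side_sel
        if not region.any():
            return None
        hv = np.where(region, h, -np.inf)
        peak = float(hv.max())
        local_max = (h >= ndimage.maximum_filter(h, size=5)) & region
        cand = local_max & (hv >= peak - 0.5)
        if not cand.any():
            return None
        pr, pc = np.nonzero(cand)
        dist = np.abs(pc - (intercept + slope * pr))
        k = int(np.argmax(dist))
        out[name] = (int(pr[k]), int(pc[k]))
        feats[name] = (float(dist[k]), float(h[pr[k], pc[k]]))
    dl, hl = feats["left"]
    dr, hr = feats["right"]
    if abs(dl - dr) > max(cfg.sym_tol * max(dl, dr), cfg.sym_floor_px):
        return None
    if abs(hl - hr) > cfg.depth_tol_m * 100.0:
        return None
    return out


# ---------------------------------------------------------------------------
# stage 4: anatomical validation and the full cascade
# ---------------------------------------------------------------------------


def _depth_at(seg: SegmentedFrame, pt: tuple[int, int]) -> float:
    """Median foreground depth in a small window around a landmark (robust
    against per-pixel sensor noise)."""
    r, c = pt
    r = int(np.clip(r, 0, seg.depth.shape[0] - 1))
    c = int(np.clip(c, 0, seg.depth.shape[1] - 1))
    win = seg.depth[max(r - 2, 0) : r + 3, max(c - 2, 0) : c + 3]
    vals = win[win > 0]
    return float(np.median(vals)) if vals.size else 0.0


def validate_anatomy(
    result: RoiResult, seg: SegmentedFrame, config: RoiConfig | None = None
) -> bool:
    """Left/right landmark symmetry check.

    Knuckle (tuberosity, dish) distances to the tail, hip distances to the
    backbone, and the landmarks' depth values must agree between the body
    halves (relative ``sym_tol``; absolute ``depth_tol_m``).
    """
    cfg = config or RoiConfig()
    tail = np.asarray(result.tail, dtype=float)
    slope, intercept = result.backbone

    def to_tail(pt) -> float:
        return float(np.hypot(*(np.asarray(pt, dtype=float) - tail)))

    def to_backbone(pt) -> float:
        r, c = pt
        return abs(c - (intercept + slope * r))

    pairs = [
        (to_tail(result.tuberosity_left), to_tail(result.tuberosity_right)),
        (to_tail(result.dish_left), to_tail(result.dish_right)),
        (to_backbone(result.hip_left), to_backbone(result.hip_right)),
    ]
    for dl, dr in pairs:
        tol = max(cfg.sym_tol * max(dl, dr), cfg.sym_floor_px)
        if max(dl, dr) > 0 and abs(dl - dr) > tol:
            return False
    depth_pairs = [
        (result.tuberosity_left, result.tuberosity_right),
        (result.dish_left, result.dish_right),
        (result.hip_left, result.hip_right),
    ]
    for pl, pr in depth_pairs:
        if abs(_depth_at(seg, pl) - _depth_at(seg, pr)) > cfg.depth_tol_m:
            return False
    return True


def run_roi(
    seg: SegmentedFrame, breed_class: str, config: RoiConfig | None = None
) -> RoiResult:
    """Full multistage cascade on one kept frame.

    The ImageBorder and HindBoundaryCurve tests are always evaluated and
    recorded in the code triple ``(hind, left, right)``; landmark stages run
    only for code (1,1,1) and short-circuit at the first failure.
    """
    cfg = config or RoiConfig()
    left, right = test_image_border(seg, cfg)
    curves = compute_boundary_curves(seg)
    hind = test_hind_boundary(curves, cfg.tol_rows)
    code = (hind, left, right)

    def failed(stage: FailureStage) -> RoiResult:
        # landmarks are reported only for fully valid frames
        return RoiResult(code_triple=code, failure_stage=stage)

    if not (left and right):
        return failed(FailureStage.BORDER)
    if not hind:
        return failed(FailureStage.HIND_BOUNDARY)

    sig = compute_signature(seg, curves, cfg)
    tail_idx = detect_tail(sig, cfg)
    if tail_idx is None:
        return failed(FailureStage.TAIL)

    dishes = classify_and_detect_dishes(sig, tail_idx, cfg)
    if dishes["left"] is None or dishes["right"] is None:
        return failed(FailureStage.DISH)

    tubs = detect_tuberosities(sig, dishes, breed_class, cfg)
    if tubs is None:
        return failed(FailureStage.TUBEROSITY)

    backbone = fit_backbone(seg, cfg)
    if backbone is None:
        return failed(FailureStage.BACKBONE)

    hips = detect_hips(seg, backbone, cfg)
    if hips is None:
        return failed(FailureStage.HIP)

    result = RoiResult(
        code_triple=code,
        tail=tuple(int(v) for v in sig.points[tail_idx]),
        dish_left=tuple(int(v) for v in sig.points[dishes["left"][0]]),
        dish_right=tuple(int(v) for v in sig.points[dishes["right"][0]]),
        dish_class_left=dishes["left"][1],
        dish_class_right=dishes["right"][1],
        tuberosity_left=tuple(int(v) for v in sig.points[tubs["left"]]),
        tuberosity_right=tuple(int(v) for v in sig.points[tubs["right"]]),
        backbone=backbone,
        hip_left=hips["left"],
        hip_right=hips["right"],
    )
    if not validate_anatomy(result, seg, cfg):
        return failed(FailureStage.ANATOMY)
    result.valid = True
    return result
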