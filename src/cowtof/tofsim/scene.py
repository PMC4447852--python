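"""Parametric rendering of empty-box and cow-back depth scenes.

Geometry conventions
--------------------
Images are ``(rows, cols)`` with row 0 at the *upper* image boundary.  The
cow enters head-first from the top of the image and walks toward the lower
boundary, so once it dwells at the feeder its rear (tail) lies toward the
upper boundary.  Depth is metres from the camera; surface heights are
centimetres above the floor, ``depth = camera_height - height/100``.

The cow-back surface is a sum of analytic components so that every landmark
has a known location:

* a domed torso (elliptical cross-section) on a constant clearance,
* a narrow backbone ridge whose amplitude ramps up away from the rump,
* Gaussian bumps for pin bones (ischeal tuberosities) and hips,
* negative Gaussians for the dishes of the rump,
* a tapered tail ridge protruding toward the upper boundary.

The rear contour (the mask boundary toward the upper image boundary, from
which the signature is computed) is modelled separately per pelvis class:
a parabolic rump with explicit pin-bone protrusions and dish recessions for
the HF-like class, and a gently tapering circular arc around the expected
centre of mass for the FV-like class, whose signature therefore "segues
into a flat course" with the tail clearly the farthest point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from cowtof.frames import DepthFrame

CAMERA_RANGE_M = (0.8, 5.0)

#: dishes at least this deep (cm) are classified "deep"
DEEP_DISH_THRESHOLD_CM = 2.0


def _gauss(x: np.ndarray | float, sigma: float) -> np.ndarray | float:
    return np.exp(-0.5 * (np.asarray(x, dtype=float) / sigma) ** 2)


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class SceneConfig:
    """Recording-box geometry and camera parameters.

    Defaults follow the published recording setup: a 176 x 144 px TOF
    sensor mounted 2.55 m above the box, depth accuracy about 1 cm.  The
    left wall sits at the image edge (a high stone wall effectively at the
    border of the field of view); the right, lower wooden wall lies inside
    the view.  Walls must not reach within the camera's near range.
    """

    frame_width: int = 176
    frame_height: int = 144
    camera_height: float = 2.55  # m
    wall_left_col: int = 0
    wall_right_col: int = 169
    wall_height: float = 1.70  # m, left wall
    wall_height_right: float | None = 1.45  # m; None -> same as left
    noise_sigma: float = 1.0  # cm, per-pixel Gaussian depth noise
    focal_px: float = 222.0  # pinhole focal length, for metric traits
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if not (0 <= self.wall_left_col < self.wall_right_col < self.frame_width):
            raise ValueError("require 0 <= wall_left_col < wall_right_col < width")
        lo, hi = CAMERA_RANGE_M
        if not (lo <= self.camera_height <= hi):
            raise ValueError(f"camera height outside operating range {CAMERA_RANGE_M}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.wall_height_right is None:
            self.wall_height_right = self.wall_height
        for wh in (self.wall_height, self.wall_height_right):
            if wh < 0:
                raise ValueError("wall height must be >= 0")
            if wh > 0 and self.camera_height - wh < lo:
                raise ValueError(
                    "wall top closer than the camera's near range: "
                    f"need wall_height <= camera_height - {lo}"
                )

    @property
    def centre_col(self) -> float:
        return 0.5 * (self.wall_left_col + self.wall_right_col)


@dataclass
class CowShapeParams:
    """Parameters of the synthetic cow-back surface.

    Use :func:`hf_shape` / :func:`fv_shape` for class defaults; individual
    fields can be overridden there.  ``body_advance`` is the row the muzzle
    end has reached; the rendered mask touches the lower image boundary iff
    ``body_advance >= frame_height - 1``.  Its default (``None``) is the
    dwell position ``rear_row + body_len`` (tail fully visible).
    """

    breed_class: Literal["HF", "FV"] = "HF"
    torso_half_width: float = 55.0  # px
    torso_height: float = 145.0  # cm, back crest above floor
    hip_offset_row: float = 75.0  # rows forward of the rump base row
    hip_offset_col: float = 30.0  # px lateral offset of the hip bumps
    hip_prominence: float = 6.0  # cm
    pin_prominence: float = 1.2  # cm, pin-bone surface bumps
    dish_depth_left: float = 3.0  # cm
    dish_depth_right: float = 3.0  # cm
    dish_mode_left: Literal["deep", "flat"] | None = None  # None -> from depth
    dish_mode_right: Literal["deep", "flat"] | None = None
    tail_overhang: int = 0  # rows of gap behind a sideways-hanging tail
    rear_row: float = 26.0  # px, tail tip row at dwell
    body_advance: float | None = None
    asymmetry: float = 0.0  # 0 = symmetric; scales down right-side features

    # --- contour model -----------------------------------------------------
    rump_base_row: float = 34.0  # parabolic rump apex row (HF contour)
    contour_a2: float = 0.008  # parabolic rump curvature (rows/px^2)
    flank_u: float = 45.0  # extra contour falloff beyond this |u|
    flank_steep: float = 0.25
    arc_center_row: float = 87.0  # FV contour: arc centre (expected COM row)
    arc_r0: float = 64.2  # FV contour: arc radius at the axis (px)
    arc_taper: float = 0.10  # FV contour: radius decrease per px of |u|
    tail_sigma: float = 2.5  # px, width of the tail contour bump
    contour_pin_ext: float = 5.0  # rows, contour pin-bone protrusion (HF)
    contour_pin_sigma: float = 3.0
    contour_dish_rec: float = 4.0  # rows, contour dish recession (deep dishes)
    contour_dish_sigma: float = 3.0
    dish_u: float | None = 14.0  # px, dish lateral offset (None: FV-derived)
    pin_u: float | None = 27.0  # px, pin lateral offset (None: FV-derived)
    roi_drop_tol: float = 0.85  # signature drop tolerance the FV contour targets

    # --- surface model -----------------------------------------------------
    relief: float = 25.0  # cm, dome height of the torso cross-section
    ridge_amp: float = 3.0  # cm, backbone ridge at mid-body
    ridge_sigma: float = 4.0  # px
    ridge_rear_frac: float = 0.15  # ridge fraction at the rump
    ridge_ramp_rows: tuple[float, float] = (10.0, 40.0)  # ramp, rel. rump row
    dish_sigma_col: float = 3.5
    dish_sigma_row: float = 6.0
    dish_row_offset: float = 6.0  # surface dish centre forward of the contour
    pin_sigma_col: float = 2.5
    pin_sigma_row: float = 4.0
    hip_sigma_col: float = 4.0
    hip_sigma_row: float = 8.0
    tail_drop: float = 28.0  # cm, tail surface below the back crest
    tail_halfwidth: float = 2.5  # px, width of the hanging tail surface
    body_len: float = 160.0  # rows from tail tip to (off-frame) muzzle end
    yaw_deg: float = 0.0  # rotation of the body axis
    lateral_drift: float = 0.0  # px, axis offset from the box centre

    def __post_init__(self) -> None:
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must be within [0, 1]")
        for side in ("left", "right"):
            depth = getattr(self, f"dish_depth_{side}")
            mode = getattr(self, f"dish_mode_{side}")
            derived = "deep" if depth >= DEEP_DISH_THRESHOLD_CM else "flat"
            if mode is None:
                setattr(self, f"dish_mode_{side}", derived)
            elif mode != derived:
                raise ValueError(
                    f"dish_mode_{side}={mode!r} inconsistent with "
                    f"dish_depth_{side}={depth} (deep iff depth >= "
                    f"{DEEP_DISH_THRESHOLD_CM} cm)"
                )

    @property
    def tail_len(self) -> float:
        return self.contour_base(0.0) - self.rear_row

    def contour_base(self, u: np.ndarray | float) -> np.ndarray | float:
        """Rear contour row without tail/pin/dish features (float rows)."""
        u = np.asarray(u, dtype=float)
        if self.breed_class == "FV":
            r = np.maximum(self.arc_r0 - self.arc_taper * np.abs(u), np.abs(u) + 1.0)
            base = self.arc_center_row - np.sqrt(r**2 - u**2)
        else:
            base = self.rump_base_row + self.contour_a2 * u**2
        over = np.maximum(np.abs(u) - self.flank_u, 0.0)
        return base + self.flank_steep * over**2

    def side_scale(self, sign: int) -> float:
        """Feature scaling: right-side (+1) features shrink with asymmetry."""
        return 1.0 - self.asymmetry if sign > 0 else 1.0


def hf_shape(**overrides) -> CowShapeParams:
    """Holstein-Friesian-like shape: deep dishes, angular pelvis; the tail
    and the ischeal tuberosities lie near-equidistant from the centre of
    mass, so the signature shows comparable tail and pin peaks."""
    return CowShapeParams(breed_class="HF", **overrides)


def fv_shape(**overrides) -> CowShapeParams:
    """Fleckvieh-like shape: rounder, flatter rump (flat dishes) whose
    signature declines gently from a dominant tail peak; the tail is clearly
    the farthest boundary point from the centre of mass."""
    defaults = dict(
        breed_class="FV",
        torso_half_width=48.0,
        torso_height=140.0,
        relief=10.0,
        ridge_amp=6.0,
        hip_prominence=3.0,
        rear_row=14.0,
        tail_sigma=3.5,
        dish_depth_left=1.2,
        dish_depth_right=1.2,
        dish_sigma_col=3.0,
        pin_prominence=1.0,
        pin_sigma_col=2.0,
        contour_pin_ext=0.0,
        contour_dish_rec=0.0,
        dish_u=None,
        pin_u=None,
    )
    defaults.update(overrides)
    return CowShapeParams(**defaults)


@dataclass
class GroundTruth:
    """Exact landmark locations and auxiliary truth for one rendered frame.

    Coordinates are 0-based ``(row, col)`` pixels.  The dish/tuberosity/tail
    coordinates are rear-contour (boundary) points, matching what the
    signature-based detector reports; hips are surface-bump centres.
    """

    tail: tuple[int, int]
    tuberosity_left: tuple[int, int]
    tuberosity_right: tuple[int, int]
    dish_left: tuple[int, int]
    dish_right: tuple[int, int]
    hip_left: tuple[int, int]
    hip_right: tuple[int, int]
    dish_class_left: str
    dish_class_right: str
    backbone_slope: float  # d(col)/d(row)
    backbone_intercept: float  # col at row 0
    mask: np.ndarray = field(repr=False)
    com: tuple[float, float] = (0.0, 0.0)
    dish_depth_left_cm: float = 0.0
    dish_depth_right_cm: float = 0.0
    hip2hip_area_cm2: float = 0.0
    touches_bottom: bool = False
    clears_top: bool = False

    @property
    def landmarks(self) -> dict[str, tuple[int, int]]:
        return {
            "tail": self.tail,
            "tuberosity_left": self.tuberosity_left,
            "tuberosity_right": self.tuberosity_right,
            "dish_left": self.dish_left,
            "dish_right": self.dish_right,
            "hip_left": self.hip_left,
            "hip_right": self.hip_right,
        }

    def to_record(self) -> dict:
        rec = {k: list(v) for k, v in self.landmarks.items()}
        rec.update(
            dish_class_left=self.dish_class_left,
            dish_class_right=self.dish_class_right,
            backbone_slope=self.backbone_slope,
            backbone_intercept=self.backbone_intercept,
            touches_bottom=self.touches_bottom,
            clears_top=self.clears_top,
        )
        return rec


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_empty_frame(
    config: SceneConfig, rng: np.random.Generator | None = None
) -> DepthFrame:
    """Render the empty box: floor at camera height, walls at the sides."""
    frame = np.full(
        (config.frame_height, config.frame_width), config.camera_height, dtype=float
    )
    if config.wall_height > 0:
        frame[:, : config.wall_left_col + 1] = config.camera_height - config.wall_height
    if config.wall_height_right and config.wall_height_right > 0:
        frame[:, config.wall_right_col :] = (
            config.camera_height - config.wall_height_right
        )
    _add_noise(frame, config, rng)
    return frame


def _add_noise(
    frame: np.ndarray, config: SceneConfig, rng: np.random.Generator | None
) -> None:
    if config.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        frame += rng.normal(0.0, config.noise_sigma / 100.0, frame.shape)
    np.clip(frame, *CAMERA_RANGE_M, out=frame)


def _axis_col(shape: CowShapeParams, config: SceneConfig, rows: np.ndarray) -> np.ndarray:
    """Body-axis column per row (yaw rotates the axis about mid-body)."""
    c0 = config.centre_col + shape.lateral_drift
    slope = np.tan(np.deg2rad(shape.yaw_deg))
    r_ref = shape.rump_base_row + 60.0
    return c0 + slope * (rows - r_ref)


def _contour(shape: CowShapeParams, u: np.ndarray, side_of: np.ndarray) -> np.ndarray:
    """Full rear contour row as a function of signed lateral offset u."""
    rear = np.asarray(shape.contour_base(u), dtype=float)
    if shape.tail_overhang == 0:
        # upright tail: a narrow rearward bump in the contour.  With an
        # overhanging tail the tail bends sideways instead (rendered as a
        # separate diagonal chain of pixels).
        rear = rear - shape.tail_len * _gauss(u, shape.tail_sigma)
    for sign, u_feat in ((-1, shape.pin_u), (1, shape.pin_u)):
        if u_feat is None or shape.contour_pin_ext == 0:
            continue
        amp = shape.contour_pin_ext * shape.side_scale(sign)
        rear = rear - amp * _gauss(u - sign * u_feat, shape.contour_pin_sigma)
    if shape.dish_u is not None and shape.contour_dish_rec > 0:
        for sign, mode in ((-1, shape.dish_mode_left), (1, shape.dish_mode_right)):
            if mode != "deep":
                continue
            amp = shape.contour_dish_rec * shape.side_scale(sign)
            rear = rear + amp * _gauss(u - sign * shape.dish_u, shape.contour_dish_sigma)
    del side_of
    return rear


def _surface_height_cm(
    shape: CowShapeParams,
    r: np.ndarray,
    u: np.ndarray,
    dish_u: tuple[float, float],
    pin_u: tuple[float, float],
    dish_row: tuple[float, float],
    pin_row: tuple[float, float],
) -> np.ndarray:
    """Analytic surface height (cm above floor) at body rows r, offsets u."""
    W = shape.torso_half_width
    clearance = shape.torso_height - shape.relief - shape.ridge_amp
    ell = np.sqrt(np.clip(1.0 - (u / W) ** 2, 0.0, None))
    h = clearance + shape.relief * ell

    lo, hi = shape.ridge_ramp_rows
    ramp = np.clip(
        (r - (shape.rump_base_row + lo)) / max(hi - lo, 1e-9), 0.0, 1.0
    )
    ridge_frac = shape.ridge_rear_frac + (1.0 - shape.ridge_rear_frac) * ramp
    h = h + shape.ridge_amp * ridge_frac * _gauss(u, shape.ridge_sigma)

    for i, sign in enumerate((-1, 1)):
        scale = shape.side_scale(sign)
        # pin bones
        h = h + shape.pin_prominence * scale * _gauss(
            u - sign * pin_u[i], shape.pin_sigma_col
        ) * _gauss(r - pin_row[i], shape.pin_sigma_row)
        # dishes of the rump
        depth = shape.dish_depth_left if sign < 0 else shape.dish_depth_right
        h = h - depth * scale * _gauss(u - sign * dish_u[i], shape.dish_sigma_col) * _gauss(
            r - dish_row[i], shape.dish_sigma_row
        )
        # hips
        hip_r = shape.rump_base_row + shape.hip_offset_row
        h = h + shape.hip_prominence * scale * _gauss(
            u - sign * shape.hip_offset_col, shape.hip_sigma_col
        ) * _gauss(r - hip_r, shape.hip_sigma_row)
    return h


def _smooth(x: np.ndarray, window: int = 5) -> np.ndarray:
    if window <= 1 or x.size < window:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _derive_fv_features(
    shape: CowShapeParams,
    config: SceneConfig,
    mask: np.ndarray,
    outer_rows: dict[int, float],
) -> tuple[float, float] | None:
    """Locate the FV dish and pin offsets on the rendered contour.

    For the flat-dished class, dish and pin positions are *defined* by the
    contour rules (dish at the curvature maximum at the base of the tail
    bump, pins halfway between the dish and the signature's drop point), so
    the generator applies the detection rules to its own noise-free contour
    and renders the surface bumps there.  Returns None when the contour
    admits no such features (the frame is then an invalid-by-design shape).
    """
    from cowtof.config import RoiConfig
    from cowtof.roi import (
        Signature,
        _halfway_to_drop,
        _smooth as roi_smooth,
        classify_and_detect_dishes,
        detect_tail,
    )

    rcfg = RoiConfig(drop_tol=shape.roi_drop_tol)
    rr, cc = np.nonzero(mask)
    com = (float(rr.mean()), float(cc.mean()))
    cols = np.array(sorted(outer_rows))
    rows = np.array([outer_rows[c] for c in cols])
    points = np.column_stack([rows, cols])
    dist = np.hypot(rows - com[0], cols - com[1])
    sig = Signature(
        distances=dist, points=points, com=com,
        smoothed=roi_smooth(dist, rcfg.smooth_window),
    )
    tail_i = detect_tail(sig, rcfg)
    if tail_i is None:
        return None
    dishes = classify_and_detect_dishes(sig, tail_i, rcfg)
    out: dict[str, tuple[int, int]] = {}
    for name, direction in (("left", -1), ("right", +1)):
        dish = dishes[name]
        if dish is None or dish[1] != "flat":
            return None
        pin_i = _halfway_to_drop(sig.smoothed, dish[0], direction, rcfg)
        if pin_i is None:
            return None
        out[f"dish_{name}"] = tuple(int(v) for v in points[dish[0]])
        out[f"pin_{name}"] = tuple(int(v) for v in points[pin_i])
    return out


def render_cow_frame(
    config: SceneConfig,
    shape: CowShapeParams,
    rng: np.random.Generator | None = None,
) -> tuple[DepthFrame, GroundTruth]:
    """Render one cow-back frame plus its exact ground truth."""
    H, W = config.frame_height, config.frame_width
    gap = config.wall_right_col - config.wall_left_col - 1
    if 2 * shape.torso_half_width >= gap:
        raise ValueError("cow torso wider than the gap between the box walls")

    advance = (
        shape.body_advance
        if shape.body_advance is not None
        else shape.rear_row + shape.body_len
    )
    shift = advance - (shape.rear_row + shape.body_len)

    rows = np.arange(H, dtype=float)[:, None]
    cols = np.arange(W, dtype=float)[None, :]
    u = cols - _axis_col(shape, config, rows)

    contour = _contour(shape, u, np.sign(u)) + shift
    bottom = contour - shift + shape.body_len + shift  # = contour + body_len
    mask = (rows >= np.ceil(contour)) & (rows <= bottom) & (
        np.abs(u) <= shape.torso_half_width
    )
    # keep strictly between the walls
    between = (cols > config.wall_left_col) & (cols < config.wall_right_col)
    mask &= between
    # sideways-bent, overhanging tail: a diagonal chain of pixels rising
    # from the rump contour toward the upper-right, connected to the body
    # but leaving a growing gap between the outer and inner boundary curves
    # (the gap magnitude tracks ``tail_overhang`` rows)
    overhang_px: list[tuple[int, int]] = []
    if shape.tail_overhang > 0:
        axis_mid = float(
            _axis_col(shape, config, np.array([shape.rump_base_row + shift]))[0]
        )
        c_axis = int(np.floor(axis_mid))
        r_base = int(np.ceil(shape.contour_base(0.0))) + int(round(shift))
        for k in range(shape.tail_overhang + 1):
            c = c_axis + k
            if not (config.wall_left_col < c < config.wall_right_col):
                continue
            for dr in (0, 1, 2):
                r = r_base - k - 1 + dr
                if 0 <= r < H:
                    overhang_px.append((r, c))

    if not mask.any():
        frame = render_empty_frame(config, rng)
        gt = _empty_ground_truth(mask)
        return frame, gt

    # --- ground-truth feature placement ------------------------------------
    rr, cc = np.nonzero(mask)
    com = (float(rr.mean()), float(cc.mean()))
    fv_points = None
    if shape.dish_u is None or shape.pin_u is None:
        outer = {int(c): int(rr[cc == c].min()) for c in np.unique(cc)}
        fv_points = _derive_fv_features(shape, config, mask, outer)

    def contour_at(u_off: float) -> float:
        return float(_contour(shape, np.array([u_off]), np.array([np.sign(u_off)]))[0])

    axis0 = float(
        _axis_col(shape, config, np.array([shape.rump_base_row + shift]))[0]
    )
    if fv_points is not None:
        # features per side exactly where the contour rules place them
        dish_u_v = (
            axis0 - fv_points["dish_left"][1], fv_points["dish_right"][1] - axis0,
        )
        pin_u_v = (
            axis0 - fv_points["pin_left"][1], fv_points["pin_right"][1] - axis0,
        )
        dish_contour = (
            fv_points["dish_left"][0] - shift, fv_points["dish_right"][0] - shift,
        )
        pin_contour = (
            fv_points["pin_left"][0] - shift, fv_points["pin_right"][0] - shift,
        )
    else:
        if shape.dish_u is None or shape.pin_u is None:
            # contour admits no flat-dish features; render plausible bump
            # positions anyway (such frames fail the detection cascade)
            shape = replace(
                shape,
                dish_u=0.17 * shape.torso_half_width,
                pin_u=0.5 * shape.torso_half_width,
            )
        dish_u_v = (float(shape.dish_u), float(shape.dish_u))
        pin_u_v = (float(shape.pin_u), float(shape.pin_u))
        dish_contour = (contour_at(-dish_u_v[0]), contour_at(dish_u_v[1]))
        pin_contour = (contour_at(-pin_u_v[0]), contour_at(pin_u_v[1]))
    dish_row = tuple(dc + shape.dish_row_offset for dc in dish_contour)
    pin_row = dish_row  # pins rendered in the dish-cut plane

    # --- surface ------------------------------------------------------------
    body_r = rows - shift  # body frame of reference
    h = _surface_height_cm(shape, body_r * np.ones_like(u), u, dish_u_v, pin_u_v,
                           dish_row, pin_row)
    # a narrow tail ridge overrides the body surface; the wider shoulders of
    # the contour bump keep body-like heights (rump around the tail base)
    tail_lift = shape.tail_len * _gauss(u, shape.tail_sigma)
    tail_region = mask & (tail_lift > 0.5) & (
        np.abs(u) <= shape.tail_halfwidth
    ) & (body_r < np.asarray(shape.contour_base(u)) - 1.0)
    h = np.where(tail_region, shape.torso_height - shape.tail_drop, h)

    max_h = shape.torso_height + shape.hip_prominence + shape.pin_prominence
    if config.camera_height - max_h / 100.0 < CAMERA_RANGE_M[0]:
        raise ValueError("cow surface closer than the camera's near range")

    frame = np.full((H, W), config.camera_height, dtype=float)
    if config.wall_height > 0:
        frame[:, : config.wall_left_col + 1] = config.camera_height - config.wall_height
    if config.wall_height_right and config.wall_height_right > 0:
        frame[:, config.wall_right_col :] = (
            config.camera_height - config.wall_height_right
        )
    frame[mask] = config.camera_height - h[mask] / 100.0
    for r, c in overhang_px:
        mask[r, c] = True
        frame[r, c] = config.camera_height - (shape.torso_height - shape.tail_drop) / 100.0
    _add_noise(frame, config, rng)

    # --- ground truth -------------------------------------------------------
    axis_of = lambda r: float(_axis_col(shape, config, np.array([float(r)]))[0])
    # the rendered tail tip: topmost mask row in the axis columns (the
    # continuous tip row lands on the pixel grid via the mask ceiling)
    axis_tail = axis_of(shape.rear_row + shift)
    tip_cand = [
        (int(rr[cc == c].min()), int(c))
        for c in (int(np.floor(axis_tail)), int(np.ceil(axis_tail)))
        if (cc == c).any()
    ]
    gt_tail = min(tip_cand) if tip_cand else (
        int(round(shape.rear_row + shift)), int(round(axis_tail))
    )

    def boundary_pt(u_off: float, contour_r: float) -> tuple[int, int]:
        # snap to the pixel column first (ties break away from the axis so
        # mirrored landmarks stay mirrored), then take that column's first
        # masked row (the outer boundary curve the detector sees)
        r_approx = contour_r + shift
        x = axis_of(r_approx) + u_off
        c = int(np.floor(x + 0.5)) if u_off > 0 else int(np.ceil(x - 0.5))
        u_real = c - axis_of(r_approx)
        r = int(np.ceil(float(
            _contour(shape, np.array([u_real]), np.array([np.sign(u_real)]))[0]
        ) + shift))
        return (r, c)

    if fv_points is not None:
        tub_l, tub_r = fv_points["pin_left"], fv_points["pin_right"]
        dish_l, dish_r = fv_points["dish_left"], fv_points["dish_right"]
    else:
        tub_l = boundary_pt(-pin_u_v[0], pin_contour[0])
        tub_r = boundary_pt(pin_u_v[1], pin_contour[1])
        dish_l = boundary_pt(-dish_u_v[0], dish_contour[0])
        dish_r = boundary_pt(dish_u_v[1], dish_contour[1])
    gt = GroundTruth(
        tail=gt_tail,
        tuberosity_left=tub_l,
        tuberosity_right=tub_r,
        dish_left=dish_l,
        dish_right=dish_r,
        hip_left=_hip_gt(shape, config, shift, -1, dish_u_v, pin_u_v, dish_row, pin_row),
        hip_right=_hip_gt(shape, config, shift, +1, dish_u_v, pin_u_v, dish_row, pin_row),
        dish_class_left=shape.dish_mode_left,
        dish_class_right=shape.dish_mode_right,
        backbone_slope=float(np.tan(np.deg2rad(shape.yaw_deg))),
        backbone_intercept=float(axis_of(0.0)),
        mask=mask,
        com=com,
        dish_depth_left_cm=shape.dish_depth_left,
        dish_depth_right_cm=shape.dish_depth_right * shape.side_scale(1),
        hip2hip_area_cm2=_analytic_hip2hip(shape, config, dish_u_v, pin_u_v,
                                           dish_row, pin_row),
        touches_bottom=bool(mask[H - 1].any()),
        clears_top=bool(int(rr.min()) >= 1),
    )
    return frame, gt


def _hip_gt(
    shape: CowShapeParams,
    config: SceneConfig,
    shift: float,
    sign: int,
    dish_u: tuple[float, float],
    pin_u: tuple[float, float],
    dish_row: tuple[float, float],
    pin_row: tuple[float, float],
) -> tuple[int, int]:
    """True local height maximum of the hip bump on the analytic surface.

    The dome slope shifts the combined maximum slightly toward the axis
    relative to the bump centre; the ground truth is the actual maximum,
    refined on a fine lateral grid at the hip row.
    """
    r = shape.rump_base_row + shape.hip_offset_row
    uu = sign * shape.hip_offset_col + np.linspace(-6.0, 6.0, 1201)
    h = _surface_height_cm(
        shape, np.full(uu.size, r), uu, dish_u, pin_u, dish_row, pin_row
    )
    u_star = float(uu[np.argmax(h)])
    r_img = r + shift
    c = float(_axis_col(shape, config, np.array([r_img]))[0]) + u_star
    return (int(round(r_img)), int(round(c)))


def _empty_ground_truth(mask: np.ndarray) -> GroundTruth:
    z = (0, 0)
    return GroundTruth(
        tail=z, tuberosity_left=z, tuberosity_right=z, dish_left=z, dish_right=z,
        hip_left=z, hip_right=z, dish_class_left="flat", dish_class_right="flat",
        backbone_slope=0.0, backbone_intercept=0.0, mask=mask,
    )


def _analytic_hip2hip(
    shape: CowShapeParams,
    config: SceneConfig,
    dish_u: tuple[float, float],
    pin_u: tuple[float, float],
    dish_row: tuple[float, float],
    pin_row: tuple[float, float],
) -> float:
    """Area (cm^2) between the hip-to-hip height profile and its upper
    horizontal tangent, from dense quadrature of the analytic surface."""
    hip_r = shape.rump_base_row + shape.hip_offset_row
    n = 2001
    uu = np.linspace(-shape.hip_offset_col, shape.hip_offset_col, n)
    h = _surface_height_cm(
        shape, np.full(n, hip_r), uu, dish_u, pin_u, dish_row, pin_row
    )
    depth_m = config.camera_height - float(h.mean()) / 100.0
    cm_per_px = 100.0 * depth_m / config.focal_px
    return float(np.trapezoid((h.max() - h), dx=(uu[1] - uu[0]) * cm_per_px))


def jittered_shape(
    breed_class: str, rng: np.random.Generator, scale: float = 1.0
) -> CowShapeParams:
    """A randomly varied individual of the given pelvis-shape class.

    Jitters size, relief, feature positions and prominences within ranges
    that keep the shape anatomically plausible for its class.
    """
    u = lambda lo, hi: float(rng.uniform(lo * scale, hi * scale))
    common = dict(
        torso_height=145.0 + u(-4, 4),
        hip_offset_col=30.0 + u(-2, 2),
        hip_offset_row=75.0 + u(-4, 4),
        lateral_drift=u(-6, 6),
    )
    if breed_class.upper() == "HF":
        return hf_shape(
            **common,
            relief=25.0 + u(-2, 2),
            rear_row=26.0 + u(-2, 2),
            dish_depth_left=3.0 + u(-0.5, 0.5),
            dish_depth_right=3.0 + u(-0.5, 0.5),
            dish_u=14.0 + u(-1.5, 1.5),
            pin_u=27.0 + u(-2, 2),
            hip_prominence=6.0 + u(-1, 1),
        )
    common["torso_height"] = 140.0 + u(-4, 4)
    # tail length and rump-arc radius vary together so the signature's flat
    # course stays in the detectable band above the drop tolerance
    rear_jit = u(-0.8, 0.8)
    return fv_shape(
        **common,
        relief=10.0 + u(-1.5, 1.5),
        rear_row=14.0 + rear_jit,
        arc_r0=64.2 - 0.85 * rear_jit + u(-0.5, 0.5),
        arc_taper=0.10 + u(-0.008, 0.008),
        dish_depth_left=1.2 + u(-0.3, 0.3),
        dish_depth_right=1.2 + u(-0.3, 0.3),
        hip_prominence=3.25 + u(-0.25, 0.25),
        hip_sigma_row=6.0,
    )


# ---------------------------------------------------------------------------
# streams
# ---------------------------------------------------------------------------


def make_trajectory(
    n_in: int, n_dwell: int, n_out: int, shape: CowShapeParams, config: SceneConfig
) -> list[float]:
    """Advance values for an in / dwell / out visit.

    Entry and exit frames never satisfy the position test (the body either
    misses the lower boundary or still touches the upper one); dwell frames
    always do.
    """
    dwell = shape.rear_row + shape.body_len
    enter = list(np.linspace(40.0, min(130.0, config.frame_height - 14), max(n_in, 0)))
    leave = enter[::-1]
    return enter + [dwell] * n_dwell + leave


def generate_stream(
    config: SceneConfig,
    shape: CowShapeParams,
    trajectory: Sequence[float],
    rng: np.random.Generator | None = None,
) -> tuple[list[DepthFrame], list[GroundTruth]]:
    """Render a frame sequence with ``body_advance`` following ``trajectory``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames: list[DepthFrame] = []
    truths: list[GroundTruth] = []
    for adv in trajectory:
        frame, gt = render_cow_frame(config, replace(shape, body_advance=adv), rng)
        frames.append(frame)
        truths.append(gt)
    return frames, truths
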