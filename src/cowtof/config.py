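"""Pipeline configuration: every tolerance of the test battery in one place.

Defaults follow the camera's printed characteristics where it states one
(e.g. depth accuracy 1 cm); the remaining thresholds are this package's own
choices and are deliberately exposed so they can be tuned per installation
from a TOML file (:meth:`PipelineConfig.from_toml`).
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path


@dataclass
class CalibConfig:
    # number of empty frames required for a scenery model (NUM)
    num_calibration_frames: int = 20
    # scenery model lifetime before recalibration (DUR)
    recalibration_hours: float = 24.0
    camera_height_m: float = 2.55
    # |depth - camera_height| above this marks a pixel as non-floor (m)
    empty_tol_m: float = 0.05
    # max fraction of deviating non-wall pixels for an "empty" verdict
    empty_max_frac: float = 0.01
    # minimal column-gradient magnitude accepted as a wall edge (m)
    wall_grad_min_m: float = 0.30


@dataclass
class SegmentConfig:
    # difference test: |IMG - meanIMG| > k * max(stdIMG, sigma_floor)
    k_sigma: float = 3.0
    sigma_floor_m: float = 0.005
    # histogram confirmation: foreground/background modes must be separated
    hist_bins: int = 64
    mode_separation_m: float = 0.10
    # fraction of the smaller mode the valley between the modes must drop to
    valley_frac: float = 0.5
    # minimum number of deviating pixels for "object present"
    min_object_pixels: int = 50
    # candidate pixels farther than this from the object's median depth are
    # background noise (the object forms one coherent depth mode)
    fg_depth_halfwidth_m: float = 0.35
    # position test: topmost foreground pixel must be >= gap_min rows from row 0
    gap_min: int = 10


@dataclass
class RoiConfig:
    # ImageBorder: side fails if foreground occupies its outermost columns
    border_margin: int = 2
    # HindBoundaryCurve: max allowed inner-outer difference (rows)
    tol_rows: int = 3
    # signature smoothing window (moving average, samples)
    smooth_window: int = 5
    # tail: local maximum within this cone around the body axis (degrees)
    axis_tol_deg: float = 15.0
    # deep dish: minimal prominence of the signature local minimum (px)
    dish_min_prominence: float = 1.0
    # columns next to the tail peak excluded from dish search
    dish_search_from: int = 3
    dish_search_to: int = 30
    # flat dish: |signature gradient| beyond the tail bump below this (px/px)
    grad_flat: float = 0.35
    # FV drop point: signature below drop_tol * signature(tail)
    drop_tol: float = 0.85
    # drop point closer than this to the dish marks a degenerate signature
    min_drop_gap: int = 4
    # backbone: fraction of rearmost mask rows excluded from the fit
    backbone_tail_frac: float = 0.20
    min_backbone_rows: int = 10
    # hips: exclusion band around the backbone (px) when searching bumps
    hip_min_lateral: int = 10
    # anatomical validation: relative left/right tolerance (with a pixel
    # floor: below the floor a difference is within quantisation) and the
    # depth tolerance between paired landmarks
    sym_tol: float = 0.15
    sym_floor_px: float = 3.0
    depth_tol_m: float = 0.02


@dataclass
class TraitConfig:
    # samples per height profile
    n_samples: int = 100
    # polynomial degree for the diagonal-cut approximation; an even-order
    # term is needed to capture a symmetric bump's amplitude faithfully
    poly_degree: int = 4
    # focal length of the pinhole model (px) for metric conversion
    focal_px: float = 222.0
    # dish cut: forward offset from the contour dish midpoint (px)
    dish_cut_forward_px: float = 6.0
    # half-window (px along the cut) for locating a dish minimum
    dish_window_px: float = 8.0


@dataclass
class PipelineConfig:
    calib: CalibConfig = field(default_factory=CalibConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    traits: TraitConfig = field(default_factory=TraitConfig)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from TOML; unknown keys raise, absent keys default."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls()
        for section_name, section in raw.items():
            if not hasattr(cfg, section_name):
                raise KeyError(f"unknown config section: {section_name}")
            target = getattr(cfg, section_name)
            known = {f.name for f in fields(target)}
            for key, value in section.items():
                if key not in known:
                    raise KeyError(f"unknown key {section_name}.{key}")
                setattr(target, key, value)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
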