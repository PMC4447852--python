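"""Empty-scenery calibration: background model and box-wall localisation.

From a specified number (``NUM``) of frames showing the completely empty
box, a scenery model is built: per-pixel mean and standard deviation of the
depth (``mean_map`` / ``std_map``) plus the wall columns found from depth
gradients in the mean map.  The model ages; after ``DUR`` hours it should be
renewed from a fresh streak of empty frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from cowtof.config import CalibConfig
from cowtof.frames import DepthFrame, read_pgm16, write_pgm16


class CalibrationError(RuntimeError):
    pass


@dataclass
class SceneryInfo:
    """Background model of the empty recording box."""

    mean_map: np.ndarray  # per-pixel mean depth (m)
    std_map: np.ndarray  # per-pixel depth SD (m)
    wall_left_col: int
    wall_right_col: int
    camera_height: float  # m
    num_frames_used: int
    valid_hours: float  # model lifetime (DUR)

    def __post_init__(self) -> None:
        if self.mean_map.shape != self.std_map.shape:
            raise ValueError("mean_map and std_map must have equal shape")
        if (self.std_map < 0).any():
            raise ValueError("std_map must be non-negative")
        if not self.wall_left_col < self.wall_right_col:
            raise ValueError("wall_left_col must be < wall_right_col")

    # -- serialisation: JSON header + two 16-bit PGM maps -------------------
    def save(self, basename: str | Path) -> Path:
        """Write ``<basename>.json`` plus ``<basename>_mean/std.pgm``.

        The mean map is stored in millimetres, the SD map in 0.01 mm units
        (clipped at ~0.65 m, far above any plausible scenery SD).
        """
        base = Path(basename)
        base.parent.mkdir(parents=True, exist_ok=True)
        write_pgm16(base.with_name(base.name + "_mean.pgm"), self.mean_map)
        write_pgm16(
            base.with_name(base.name + "_std.pgm"),
            np.clip(self.std_map * 100.0, 0.0, 65.535),
        )
        header = {
            "wall_left_col": int(self.wall_left_col),
            "wall_right_col": int(self.wall_right_col),
            "camera_height": self.camera_height,
            "num_frames_used": int(self.num_frames_used),
            "valid_hours": self.valid_hours,
        }
        path = base.with_suffix(".json")
        path.write_text(json.dumps(header, indent=1))
        return path

    @classmethod
    def load(cls, basename: str | Path) -> "SceneryInfo":
        base = Path(basename)
        if base.suffix == ".json":
            base = base.with_suffix("")
        header = json.loads(base.with_suffix(".json").read_text())
        mean_map = read_pgm16(base.with_name(base.name + "_mean.pgm"))
        std_map = read_pgm16(base.with_name(base.name + "_std.pgm")) / 100.0
        return cls(mean_map=mean_map, std_map=std_map, **header)


def is_empty_scene(
    frame: DepthFrame,
    camera_height: float,
    tol: float = 0.05,
    max_frac: float = 0.01,
) -> bool:
    """True iff the frame shows only floor (and static wall structure).

    Columns whose *median* depth deviates from the camera height are treated
    as wall columns (static structure spanning the column) and excluded;
    among the remaining pixels the fraction deviating by more than ``tol``
    must stay below ``max_frac``.  A cow always leaves partially covered
    columns at its flanks, so it cannot masquerade as wall structure.
    """
    frame = np.asarray(frame, dtype=float)
    col_dev = np.abs(np.median(frame, axis=0) - camera_height) > tol
    floor = frame[:, ~col_dev]
    if floor.size == 0:
        return False
    frac = np.mean(np.abs(floor - camera_height) > tol)
    return bool(frac < max_frac)


def detect_walls(
    mean_map: np.ndarray, grad_min: float = 0.30
) -> tuple[int, int]:
    """Locate the two wall columns from horizontal depth gradients.

    Uses the column-wise median of the depth difference between neighbouring
    columns; the left wall is the strongest positive jump (wall -> floor,
    depth increases to the right), the right wall the strongest negative
    one.  Works for walls of unequal height.
    """
    grad = np.median(np.diff(np.asarray(mean_map, dtype=float), axis=1), axis=0)
    left = int(np.argmax(grad))
    right = int(np.argmin(grad)) + 1
    if grad[left] < grad_min or grad[right - 1] > -grad_min:
        raise CalibrationError("no wall edges found in mean map")
    if not left < right:
        raise CalibrationError("wall edges out of order")
    return left, right


def compute_scenery_info(
    frames: Sequence[DepthFrame], config: CalibConfig | None = None
) -> SceneryInfo:
    """Build the scenery model from at least NUM empty frames."""
    cfg = config or CalibConfig()
    if len(frames) < cfg.num_calibration_frames:
        raise CalibrationError(
            f"need at least {cfg.num_calibration_frames} empty frames, "
            f"got {len(frames)}"
        )
    for i, frame in enumerate(frames):
        if not is_empty_scene(
            frame, cfg.camera_height_m, cfg.empty_tol_m, cfg.empty_max_frac
        ):
            raise CalibrationError(f"frame {i} is not an empty scene")
    stack = np.stack([np.asarray(f, dtype=float) for f in frames])
    mean_map = stack.mean(axis=0)
    std_map = stack.std(axis=0, ddof=0)
    # identical inputs must give a zero SD map, not accumulation residue
    std_map[std_map < 1e-12] = 0.0
    left, right = detect_walls(mean_map, cfg.wall_grad_min_m)
    return SceneryInfo(
        mean_map=mean_map,
        std_map=std_map,
        wall_left_col=left,
        wall_right_col=right,
        camera_height=cfg.camera_height_m,
        num_frames_used=len(frames),
        valid_hours=cfg.recalibration_hours,
    )
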