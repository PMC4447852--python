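"""Stream orchestration: calibration, sorting, ROI, traits, day lists.

Processes a stored frame stream end to end and produces one *day list*:
per valid frame the cow id, timestamp, code triple, landmark record and the
13 camera traits, plus per-day accounting of frames per code triple and per
rejection stage.  Kept frames can be mirrored into per-cow-ID folders, one
folder per animal, as the original recording software did.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cowtof.calib import CalibrationError, SceneryInfo, compute_scenery_info, is_empty_scene
from cowtof.config import PipelineConfig
from cowtof.frames import read_stream, write_pgm16
from cowtof.roi import run_roi
from cowtof.segment import RejectionReason, sort_frame
from cowtof.traits import TRAIT_ORDER, TraitExtractionError, extract_all

#: code triples in reporting order; the second block can only be populated
#: if a cow reaches the outermost right-hand columns, which the default
#: scenery (right wall inside the field of view) makes impossible
CODE_ORDER = (
    "1-1-1", "1-0-1", "0-1-1", "0-0-1",
    "1-1-0", "1-0-0", "0-1-0", "0-0-0",
)

DAY_LIST_COLUMNS = ("cow_id", "date", "frame", "code_triple", *TRAIT_ORDER)


@dataclass
class DayList:
    """Output of one processed recording day."""

    rows: pd.DataFrame  # one row per valid frame
    code_counts: dict[str, int] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    n_frames: int = 0
    n_kept: int = 0

    @property
    def kept_fraction(self) -> float:
        return self.n_kept / self.n_frames if self.n_frames else 0.0

    def summary(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "n_kept": self.n_kept,
            "kept_fraction": self.kept_fraction,
            "n_valid": len(self.rows),
            "code_counts": dict(self.code_counts),
            "stage_counts": dict(self.stage_counts),
        }

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        out = self.rows.reindex(columns=list(DAY_LIST_COLUMNS))
        out.to_csv(path, index=False)
        return path


def process_stream(
    stream_dir: str | Path,
    scenery: SceneryInfo | None = None,
    breed_class: str = "HF",
    config: PipelineConfig | None = None,
    id_folder_dir: str | Path | None = None,
) -> DayList:
    """Run the full pipeline over a stored stream directory.

    Without a scenery model, the leading empty frames of the stream are used
    to calibrate in-stream (at least NUM of them must occur before the first
    cow); every frame is then routed sort -> ROI -> trait extraction.
    """
    cfg = config or PipelineConfig()
    pairs = list(read_stream(stream_dir))
    if scenery is None:
        empties = [
            f for f, _ in pairs
            if is_empty_scene(
                f, cfg.calib.camera_height_m, cfg.calib.empty_tol_m,
                cfg.calib.empty_max_frac,
            )
        ]
        if len(empties) < cfg.calib.num_calibration_frames:
            raise CalibrationError(
                "no scenery model and not enough empty frames to calibrate"
            )
        scenery = compute_scenery_info(
            empties[: cfg.calib.num_calibration_frames], cfg.calib
        )

    rows: list[dict] = []
    code_counts: dict[str, int] = {c: 0 for c in CODE_ORDER}
    stage_counts: dict[str, int] = {}
    n_kept = 0
    for frame, meta in pairs:
        seg = sort_frame(frame, scenery, cfg.segment)
        if not seg.keep_decision:
            key = f"rejected_{seg.rejection_reason.value}"
            stage_counts[key] = stage_counts.get(key, 0) + 1
            continue
        n_kept += 1
        cow_id = str(meta.get("cow_id", "unknown"))
        if id_folder_dir is not None:
            folder = Path(id_folder_dir) / cow_id
            folder.mkdir(parents=True, exist_ok=True)
            write_pgm16(folder / f"{meta.get('frame_index', 0):05d}.pgm", seg.depth)
        result = run_roi(seg, breed_class, cfg.roi)
        code_counts[result.code_str] = code_counts.get(result.code_str, 0) + 1
        if not result.valid:
            stage = f"roi_{result.failure_stage.value}"
            stage_counts[stage] = stage_counts.get(stage, 0) + 1
            continue
        try:
            traits = extract_all(seg, result, cfg.traits)
        except TraitExtractionError:
            stage_counts["trait_fail"] = stage_counts.get("trait_fail", 0) + 1
            continue
        row = {
            "cow_id": cow_id,
            "date": meta.get("timestamp", ""),
            "frame": meta.get("frame_index", len(rows)),
            "code_triple": result.code_str,
            **traits.to_row(),
        }
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(DAY_LIST_COLUMNS))
    return DayList(
        rows=df,
        code_counts=code_counts,
        stage_counts=stage_counts,
        n_frames=len(pairs),
        n_kept=n_kept,
    )


def summarize_codes(day_lists: list[DayList]) -> pd.DataFrame:
    """Absolute counts and percentages per code triple, in reporting order.

    The four groups with a failed right-hand border test come last; with the
    default scenery they stay empty over any processed batch because the
    right wall bounds the foreground inside the image.
    """
    if not day_lists:
        raise ValueError("need at least one day list")
    totals: dict[str, int] = {c: 0 for c in CODE_ORDER}
    for dl in day_lists:
        for code, n in dl.code_counts.items():
            totals[code] = totals.get(code, 0) + n
    grand = sum(totals.values())
    rows = [
        {
            "code": code,
            "count": totals[code],
            "percent": 100.0 * totals[code] / grand if grand else 0.0,
        }
        for code in CODE_ORDER
    ]
    return pd.DataFrame(rows)
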