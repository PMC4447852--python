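"""Depth-frame I/O: 16-bit PGM frames plus a JSON-lines metadata sidecar.

A *depth frame* is a 2-D ``float64`` array of per-pixel distances from the
camera in metres.  On disk each frame is one binary PGM (P5) file with
``maxval`` 65535 holding the depth in millimetres, and a stream directory
carries a ``metadata.jsonl`` sidecar with one record per frame (frame index,
file name, timestamp, cow id, and — for synthetic streams — the ground-truth
landmark coordinates).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterator

import numpy as np

DepthFrame = np.ndarray  # (rows, cols), metres from camera

METADATA_NAME = "metadata.jsonl"

# depth quantisation on disk: 1 mm
_MM = 1000.0


def write_pgm16(path: str | Path, frame: DepthFrame) -> None:
    """Write a depth frame (metres) as a 16-bit binary PGM in millimetres."""
    mm = np.rint(np.asarray(frame, dtype=float) * _MM)
    if mm.min() < 0 or mm.max() > 65535:
        raise ValueError("depth out of range for 16-bit millimetre PGM")
    data = mm.astype(">u2")
    h, w = data.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n65535\n".encode("ascii"))
        fh.write(data.tobytes())


def read_pgm16(path: str | Path) -> DepthFrame:
    """Read a 16-bit binary PGM written by :func:`write_pgm16` (→ metres)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    # header: magic, width, height, maxval separated by whitespace/comments
    tokens: list[bytes] = []
    pos = 0
    while len(tokens) < 4:
        while pos < len(raw) and raw[pos : pos + 1].isspace():
            pos += 1
        if raw[pos : pos + 1] == b"#":
            pos = raw.index(b"\n", pos) + 1
            continue
        start = pos
        while pos < len(raw) and not raw[pos : pos + 1].isspace():
            pos += 1
        tokens.append(raw[start:pos])
    pos += 1  # single whitespace after maxval
    if tokens[0] != b"P5":
        raise ValueError(f"{path}: not a binary PGM")
    w, h, maxval = (int(t) for t in tokens[1:])
    if maxval != 65535:
        raise ValueError(f"{path}: expected 16-bit PGM, got maxval {maxval}")
    data = np.frombuffer(raw, dtype=">u2", count=w * h, offset=pos)
    return data.reshape(h, w).astype(float) / _MM


def write_stream(
    out_dir: str | Path,
    frames: list[DepthFrame],
    metadata: list[dict[str, Any]],
) -> Path:
    """Write a frame stack: ``frame_00000.pgm`` ... plus ``metadata.jsonl``.

    ``metadata[i]`` is augmented with ``frame_index`` and ``file`` keys.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(frames) != len(metadata):
        raise ValueError("frames and metadata must have equal length")
    with open(out / METADATA_NAME, "w") as fh:
        for i, (frame, meta) in enumerate(zip(frames, metadata)):
            name = f"frame_{i:05d}.pgm"
            write_pgm16(out / name, frame)
            record = {"frame_index": i, "file": name, **meta}
            fh.write(json.dumps(record, default=_jsonable) + "\n")
    return out


def read_stream(stream_dir: str | Path) -> Iterator[tuple[DepthFrame, dict[str, Any]]]:
    """Yield ``(frame, metadata)`` pairs from a stream directory in order."""
    stream = Path(stream_dir)
    meta_path = stream / METADATA_NAME
    if not meta_path.exists():
        raise FileNotFoundError(f"no {METADATA_NAME} in {stream}")
    with open(meta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            meta = json.loads(line)
            yield read_pgm16(stream / meta["file"]), meta


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
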