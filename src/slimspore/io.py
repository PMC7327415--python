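"""File formats: multi-page TIFF stacks with JSON calibration sidecars,
tidy CSV tables with unit-bearing headers, and schema-versioned JSON
summaries."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from slimspore.simulate import ImageStack
from slimspore.tracking import Track

SUMMARY_SCHEMA_VERSION = 1


def save_stack(stack: ImageStack, path: str | Path,
               write_sidecar: bool = True) -> None:
    """Write a stack as multi-page float32 TIFF plus a JSON sidecar holding
    the calibration (frame interval, pixel size, channel)."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    if write_sidecar:
        sidecar = {
            "frame_interval_ms": stack.frame_interval_ms,
            "pixel_size_nm": stack.pixel_size_nm,
            "channel": stack.channel,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1))


def load_stack(path: str | Path, frame_interval_ms: float | None = None,
               pixel_size_nm: float | None = None,
               channel: str | None = None) -> ImageStack:
    """Read a multi-page TIFF; calibration comes from the sidecar when
    present, else from the arguments, else defaults (with a warning)."""
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:   # noqa: BLE001 - reraise with the file named
        raise ValueError(f"malformed TIFF {path}: {exc}") from exc
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    dt = frame_interval_ms or meta.get("frame_interval_ms")
    px = pixel_size_nm or meta.get("pixel_size_nm")
    ch = channel or meta.get("channel") or "mYPet"
    if dt is None or px is None:
        warnings.warn(f"{path.name}: missing calibration, applying defaults "
                      "(5 ms/frame, 80 nm/px)", stacklevel=2)
        dt = dt or 5.0
        px = px or 80.0
    return ImageStack(np.asarray(frames, dtype=float), frame_interval_ms=dt,
                      pixel_size_nm=px, channel=ch)


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Tidy per-focus table: track_id, frame, x_px, y_px, intensity_counts,
    snr, included flag."""
    rows = []
    for tr in tracks:
        for f in tr.foci:
            rows.append({
                "track_id": tr.track_id,
                "frame": f.frame_index,
                "x_px": f.x_px,
                "y_px": f.y_px,
                "intensity_counts": f.intensity,
                "snr": f.snr,
                "included": tr.included,
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px",
                                       "intensity_counts", "snr", "included"])


def write_summary(path: str | Path, payload: dict) -> None:
    out = {"schema_version": SUMMARY_SCHEMA_VERSION}
    out.update(payload)
    Path(path).write_text(json.dumps(out, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
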