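"""Reading recordings into :class:`ColorTimeSeries` and tidy-CSV round trips.

Recordings arrive either as a directory of image frames (PNG/JPEG, one frame
per timepoint, fixed camera) or as tidy CSV tables with columns
``tube_id, concentration, time_s, channel, intensity``.  Frame order is the
lexicographic filename sort — deterministic and independent of file
timestamps.  Channel values are the arithmetic mean over the region of
interest, rescaled to [0, 1] by the image bit depth (8-bit / 255, 16-bit /
65535).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import DEFAULT_CHANNELS, ColorTimeSeries

_FRAME_SUFFIXES = {".png", ".jpg", ".jpeg"}
_CSV_COLUMNS = ["tube_id", "concentration", "time_s", "channel", "intensity"]


@dataclass(frozen=True)
class RoiSpec:
    """Half-open pixel rectangle [x0, x1) x [y0, y1), 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate ROI {self}")
        if min(self.x0, self.y0) < 0:
            raise ValueError(f"ROI {self} has negative coordinates")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)

    @classmethod
    def parse(cls, text: str) -> "RoiSpec":
        """Parse 'x0,y0,x1,y1'."""
        parts = text.split(",")
        if len(parts) != 4:
            raise ValueError(f"ROI must be 'x0,y0,x1,y1', got {text!r}")
        return cls(*(int(p) for p in parts))


def _rescale(frame: np.ndarray, path: Path) -> np.ndarray:
    if frame.dtype == np.uint8:
        return frame / 255.0
    if frame.dtype == np.uint16:
        return frame / 65535.0
    if np.issubdtype(frame.dtype, np.floating):
        return frame.astype(float)
    raise ValueError(f"unsupported pixel dtype {frame.dtype} in {path.name}")


def extract_series_from_frames(
    frame_dir: "str | Path",
    roi: RoiSpec,
    frame_rate_hz: float,
    tube_id: str | None = None,
    true_concentration: float | None = None,
) -> ColorTimeSeries:
    """Mean-ROI intensity trace from a directory of image frames.

    One timepoint per frame, frames taken in lexicographic filename order;
    the sampling interval is 1/frame_rate_hz.
    """
    frame_dir = Path(frame_dir)
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    paths = sorted(
        p for p in frame_dir.iterdir()
        if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not paths:
        raise ValueError(f"no readable frames (png/jpeg) in {frame_dir}")
    rows = []
    shape = None
    for path in paths:
        try:
            frame = iio.imread(path)
        except Exception as exc:
            raise ValueError(f"unreadable frame {path.name}: {exc}") from exc
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise ValueError(
                f"frame {path.name} has shape {frame.shape}, "
                f"expected {shape} from {paths[0].name}"
            )
        h, w = frame.shape[:2]
        if not (roi.x1 <= w and roi.y1 <= h):
            raise ValueError(f"ROI {roi} outside {w}x{h} frame {path.name}")
        patch = _rescale(frame, path)[roi.y0:roi.y1, roi.x0:roi.x1]
        if patch.ndim == 2:  # grayscale
            rows.append([float(patch.mean())])
        else:
            rows.append(list(patch.reshape(-1, patch.shape[-1]).mean(axis=0)))
    values = np.array(rows, dtype=float).T
    n_ch = values.shape[0]
    if n_ch == 3:
        names: tuple[str, ...] = DEFAULT_CHANNELS
    elif n_ch == 1:
        names = ("I",)
    else:
        names = tuple(f"ch{i}" for i in range(n_ch))
    return ColorTimeSeries(
        tube_id=tube_id or frame_dir.name,
        channel_names=names,
        values=values,
        sampling_interval_s=1.0 / frame_rate_hz,
        true_concentration=true_concentration,
    )


def write_frames(
    frames: np.ndarray,
    out_dir: "str | Path",
    frame_rate_hz: float,
    roi: RoiSpec,
) -> Path:
    """Write rendered frames as zero-padded PNGs plus a sidecar JSON.

    The sidecar records the frame rate and ROI so a directory is
    self-describing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(frames) - 1)))
    for i, frame in enumerate(frames):
        iio.imwrite(out_dir / f"frame_{i:0{width}d}.png", frame)
    (out_dir / "recording.json").write_text(
        json.dumps(
            {"frame_rate_hz": frame_rate_hz, "roi": list(roi.as_tuple()),
             "n_frames": int(len(frames))},
            indent=2,
        )
    )
    return out_dir


# ---------------------------------------------------------------------------
# Tidy CSV round trip
# ---------------------------------------------------------------------------

def write_series_csv(
    series: "list[ColorTimeSeries] | ColorTimeSeries", path: "str | Path"
) -> Path:
    """Write series as tidy CSV (tube_id, concentration, time_s, channel,
    intensity); floats are written with the shortest representation that
    parses back to the same double, so the round trip is lossless."""
    if isinstance(series, ColorTimeSeries):
        series = [series]
    frames = []
    for s in series:
        t = s.times_s
        for ch_i, ch in enumerate(s.channel_names):
            frames.append(
                pd.DataFrame(
                    {
                        "tube_id": s.tube_id,
                        "concentration": (
                            math.nan
                            if s.true_concentration is None
                            else s.true_concentration
                        ),
                        "time_s": t,
                        "channel": ch,
                        "intensity": s.values[ch_i],
                    }
                )
            )
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_series_csv(path: "str | Path") -> list[ColorTimeSeries]:
    """Read a tidy series CSV back into :class:`ColorTimeSeries` objects.

    Tubes keep file order; within a tube, channels keep first-appearance
    order and timepoints are sorted by time.  Ragged channels (a channel
    missing a timepoint) raise a validation error naming the tube.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in ("time_s", "intensity"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric values in column {col!r}")
    out: list[ColorTimeSeries] = []
    for tube_id, group in df.groupby("tube_id", sort=False):
        channels = list(dict.fromkeys(group["channel"]))
        times = np.sort(group["time_s"].unique())
        mat = np.empty((len(channels), len(times)))
        for ch_i, ch in enumerate(channels):
            sub = group[group["channel"] == ch].sort_values("time_s")
            if len(sub) != len(times) or not np.array_equal(
                sub["time_s"].to_numpy(), times
            ):
                raise ValueError(
                    f"{path}: tube {tube_id!r} channel {ch!r} has a ragged "
                    f"time grid ({len(sub)} rows vs {len(times)} timepoints)"
                )
            mat[ch_i] = sub["intensity"].to_numpy()
        conc = group["concentration"].iloc[0]
        interval = float(np.diff(times)[0]) if len(times) > 1 else 1.0
        if len(times) > 1 and not np.allclose(np.diff(times), interval):
            raise ValueError(f"{path}: tube {tube_id!r} has non-uniform sampling")
        out.append(
            ColorTimeSeries(
                tube_id=str(tube_id),
                channel_names=tuple(str(c) for c in channels),
                values=mat,
                sampling_interval_s=interval,
                true_concentration=None if pd.isna(conc) else float(conc),
            )
        )
    return out
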