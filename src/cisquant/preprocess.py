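"""Temporal downsampling by strided window averaging.

The pipeline reduces each 150-sample, 1 Hz recording to 30 samples with a
moving average of 5 s window and 5 s stride — with window equal to stride
this is non-overlapping block averaging.  The implementation handles the
general strided case: output sample j per channel is the mean of input
samples ``[j*s, j*s + w)``, giving ``floor((T - w)/s) + 1`` outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ColorTimeSeries


@dataclass(frozen=True)
class PreprocessConfig:
    """Window/stride of the temporal moving average, in seconds.

    ``partial_window_policy`` controls trailing samples that do not fill a
    whole window: ``"drop"`` (default) discards them, ``"keep"`` emits one
    final shorter-window mean.
    """

    window_s: float = 5.0
    stride_s: float = 5.0
    partial_window_policy: str = "drop"

    def __post_init__(self) -> None:
        if not self.window_s > 0 or not self.stride_s > 0:
            raise ValueError("window_s and stride_s must be > 0")
        if self.partial_window_policy not in ("drop", "keep"):
            raise ValueError(
                f"unknown partial_window_policy {self.partial_window_policy!r}"
            )


def _as_samples(value_s: float, interval_s: float, name: str) -> int:
    ratio = value_s / interval_s
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"{name} ({value_s} s) must be a positive integer multiple of "
            f"the sampling interval ({interval_s} s)"
        )
    return int(round(ratio))


def block_average(
    series: ColorTimeSeries, config: PreprocessConfig | None = None
) -> ColorTimeSeries:
    """Strided window average applied identically to every channel.

    The output's sampling interval is the stride.  Raises if the window is
    longer than the series or not a multiple of the sampling interval.
    """
    config = config or PreprocessConfig()
    w = _as_samples(config.window_s, series.sampling_interval_s, "window_s")
    s = _as_samples(config.stride_s, series.sampling_interval_s, "stride_s")
    n = series.n_timepoints
    if n < w:
        raise ValueError(
            f"tube {series.tube_id!r}: series of {n} samples shorter than "
            f"window of {w} samples"
        )
    starts = list(range(0, n - w + 1, s))
    out = np.empty((series.n_channels, len(starts)))
    for j, start in enumerate(starts):
        out[:, j] = series.values[:, start : start + w].mean(axis=1)
    if config.partial_window_policy == "keep":
        tail_start = starts[-1] + s
        if tail_start < n:
            tail = series.values[:, tail_start:].mean(axis=1, keepdims=True)
            out = np.hstack([out, tail])
    return series.with_values(out, sampling_interval_s=config.stride_s)
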