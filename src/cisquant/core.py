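"""Core containers shared across the pipeline.

The central object is :class:`ColorTimeSeries`, one test tube's recorded
multichannel intensity trace.  Intensities are dimensionless, nominally in
[0, 1] (camera counts rescaled by the bit depth), sampled on a uniform time
grid.  The true concentration, when known, is a plain float carried along as
a label; the package treats concentrations as unit-agnostic numeric levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CHANNELS: tuple[str, ...] = ("R", "G", "B")


@dataclass(frozen=True)
class ColorTimeSeries:
    """One tube's multichannel kinetic intensity trace.

    Parameters
    ----------
    tube_id
        Opaque identifier, unique within a dataset.
    channel_names
        Ordered channel labels, e.g. ``("R", "G", "B")``.
    values
        ``(n_channels, n_timepoints)`` array of intensities.  Stored as a
        read-only float64 array.
    sampling_interval_s
        Seconds between consecutive samples (> 0).
    true_concentration
        Known concentration level, or ``None`` for an unlabeled query.
    """

    tube_id: str
    channel_names: tuple[str, ...]
    values: np.ndarray
    sampling_interval_s: float
    true_concentration: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError(
                f"tube {self.tube_id!r}: values must be 2-D "
                f"(channels x timepoints), got shape {vals.shape}"
            )
        if vals.shape[0] != len(self.channel_names):
            raise ValueError(
                f"tube {self.tube_id!r}: {len(self.channel_names)} channel "
                f"names but {vals.shape[0]} value rows"
            )
        if vals.shape[1] < 1:
            raise ValueError(f"tube {self.tube_id!r}: needs >= 1 timepoint")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"tube {self.tube_id!r}: non-finite intensities")
        if not self.sampling_interval_s > 0:
            raise ValueError(
                f"tube {self.tube_id!r}: sampling_interval_s must be > 0"
            )
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_timepoints) * self.sampling_interval_s

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's trace by label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"tube {self.tube_id!r} has no channel {name!r}; "
                f"available: {self.channel_names}"
            ) from None
        return self.values[idx]

    def with_values(
        self, values: np.ndarray, sampling_interval_s: float | None = None
    ) -> "ColorTimeSeries":
        """Copy of this series with replaced values (and optionally interval)."""
        return ColorTimeSeries(
            tube_id=self.tube_id,
            channel_names=self.channel_names,
            values=np.array(values, dtype=float),
            sampling_interval_s=(
                self.sampling_interval_s
                if sampling_interval_s is None
                else sampling_interval_s
            ),
            true_concentration=self.true_concentration,
        )


def check_common_channels(series: "list[ColorTimeSeries]") -> tuple[str, ...]:
    """Verify all series share one channel layout; return it."""
    if not series:
        raise ValueError("empty series collection")
    ref = series[0].channel_names
    for s in series[1:]:
        if s.channel_names != ref:
            raise ValueError(
                f"channel mismatch: tube {series[0].tube_id!r} has {ref}, "
                f"tube {s.tube_id!r} has {s.channel_names}"
            )
    return ref
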