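"""Synthetic colorimetric kinetics: concentration-dependent RGB time series.

The assay being emulated: platinum nanoparticles formed in proportion to the
cisplatin content of a sample act as peroxidase mimics and oxidize TMB, whose
blue product absorbs red light (~652 nm).  A camera pointed at the tube under
fixed lighting therefore records a red-channel intensity that falls as color
develops, a green channel that falls more slowly, and a nearly unchanged blue
channel; a cisplatin-free tube stays transparent.

No public recordings of the assay exist, so this module generates the study
design from first principles:

* absorbance follows a saturating-growth law
  ``A(c, t) = Amax * c / (c + c_half) * (1 - exp(-k(c) * t))`` with a
  concentration-coupled rate ``k(c) = rate_base * (c / conc_ref) ** gamma``
  — amplitude saturates in catalyst amount (Michaelis–Menten-style) and the
  color develops faster the more catalyst there is;
* channel intensities follow Beer–Lambert attenuation of the baseline,
  ``I_ch = baseline_ch * 10 ** (-extinction_ch * A)``;
* tube-to-tube variability is a single lognormal amplitude multiplier per
  tube (mean 1, given CV), and the camera adds per-sample Gaussian noise.

Defaults replicate a 62-tube design: 22 tubes over the low grid
{1.5, 3, 6.5, 17, 33, 45, 65} and 4 replicates at each of
{100, 200, 350, 500, 600, 700, 900, 1000, 1100, 1200}, recorded for 150 s at
1 frame per second in 3 channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DEFAULT_CHANNELS, ColorTimeSeries

LOW_LEVELS: tuple[float, ...] = (1.5, 3.0, 6.5, 17.0, 33.0, 45.0, 65.0)
HIGH_LEVELS: tuple[float, ...] = (
    100.0, 200.0, 350.0, 500.0, 600.0, 700.0, 900.0, 1000.0, 1100.0, 1200.0,
)


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the synthetic color-development model.

    Attributes
    ----------
    max_amplitude
        Absorbance ceiling ``Amax`` at saturating concentration (> 0).
    half_saturation_conc
        Concentration at which the amplitude reaches half the ceiling (> 0).
    rate_base
        First-order rate constant (1/s) at the reference concentration (> 0).
    rate_conc_exponent
        Exponent ``gamma`` coupling the rate to concentration (>= 0); 0 means
        every level develops at the same speed.
    conc_ref
        Reference concentration for the rate law; defaults to the largest
        level of the standard design.
    baseline_rgb
        Channel intensities of the cisplatin-free (transparent) tube, each in
        [0, 1].
    channel_extinction
        Effective per-channel extinction coefficients (>= 0).  The oxidized
        TMB product is blue, i.e. absorbs red light, so the default profile
        is ordered red >= green >= blue.
    noise_sd
        Per-sample additive Gaussian camera noise, intensity units (>= 0).
    replicate_amplitude_cv
        Coefficient of variation of the lognormal per-tube amplitude
        multiplier (>= 0).
    drift_per_s
        Optional linear intensity drift (per second) applied to every
        channel; 0 by default — lighting and framing are fixed.
    """

    max_amplitude: float = 1.0
    half_saturation_conc: float = 150.0
    rate_base: float = 0.035
    rate_conc_exponent: float = 0.3
    conc_ref: float = max(HIGH_LEVELS)
    baseline_rgb: tuple[float, float, float] = (0.92, 0.90, 0.88)
    channel_extinction: tuple[float, float, float] = (1.2, 0.45, 0.08)
    noise_sd: float = 0.004
    replicate_amplitude_cv: float = 0.003
    drift_per_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("max_amplitude", "half_saturation_conc", "rate_base",
                     "conc_ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rate_conc_exponent", "noise_sd",
                     "replicate_amplitude_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.baseline_rgb) != len(self.channel_extinction):
            raise ValueError("baseline_rgb and channel_extinction lengths differ")
        if any(not (0.0 <= b <= 1.0) for b in self.baseline_rgb):
            raise ValueError("baseline_rgb components must lie in [0, 1]")
        if any(e < 0 for e in self.channel_extinction):
            raise ValueError("channel_extinction components must be >= 0")


@dataclass(frozen=True)
class DatasetDesign:
    """The experimental design to simulate: levels, replication, sampling.

    The default instance encodes the 62-tube study: 3 replicates at each of
    7 low levels plus one extra tube at 33 (22 tubes), and 4 replicates at
    each of 10 high levels (40 tubes); 150 s recordings at 1 frame/s in
    3 color channels.
    """

    levels: tuple[tuple[float, int], ...] = field(
        default_factory=lambda: tuple(
            [(c, 4 if c == 33.0 else 3) for c in LOW_LEVELS]
            + [(c, 4) for c in HIGH_LEVELS]
        )
    )
    duration_s: float = 150.0
    frame_rate_hz: float = 1.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.levels]
        if not concs:
            raise ValueError("design needs at least one level")
        if any(c < 0 for c in concs):
            raise ValueError("concentrations must be non-negative")
        if not all(b > a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if any(n < 1 for _, n in self.levels):
            raise ValueError("replicate counts must be >= 1")
        n = self.duration_s * self.frame_rate_hz
        if not (n > 0 and abs(n - round(n)) < 1e-9):
            raise ValueError(
                "duration_s * frame_rate_hz must be a positive integer "
                f"(got {n})"
            )

    @property
    def n_timepoints(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def n_tubes(self) -> int:
        return sum(n for _, n in self.levels)

    @property
    def concentration_grid(self) -> tuple[float, ...]:
        """Sorted distinct concentration levels."""
        return tuple(c for c, _ in self.levels)


# ---------------------------------------------------------------------------
# Kinetic model
# ---------------------------------------------------------------------------

def kinetic_curve(
    concentration: float,
    time_grid: np.ndarray,
    params: KineticParams,
) -> np.ndarray:
    """Noise-free absorbance trace A(c, t) on the given time grid.

    ``A(c, t) = Amax * c/(c + c_half) * (1 - exp(-k(c) * t))`` with
    ``k(c) = rate_base * (c / conc_ref) ** gamma``.  Zero concentration gives
    zero absorbance (no catalyst, no color); the curve is non-decreasing in
    both time and concentration.
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    t = np.asarray(time_grid, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
        raise ValueError("time_grid must be non-negative and non-decreasing")
    if concentration == 0:
        return np.zeros_like(t)
    amplitude = (
        params.max_amplitude
        * concentration
        / (concentration + params.half_saturation_conc)
    )
    rate = params.rate_base * (concentration / params.conc_ref) ** params.rate_conc_exponent
    return amplitude * (1.0 - np.exp(-rate * t))


def absorbance_to_channels(
    absorbance: "float | np.ndarray",
    params: KineticParams,
) -> np.ndarray:
    """Map absorbance to per-channel intensities by Beer–Lambert attenuation.

    ``I_ch = baseline_ch * 10 ** (-extinction_ch * A)``.  Returns an array of
    shape ``(n_channels,) + shape(absorbance)``.
    """
    a = np.asarray(absorbance, dtype=float)
    if np.any(a < 0):
        raise ValueError("absorbance must be >= 0")
    baseline = np.asarray(params.baseline_rgb, dtype=float)
    ext = np.asarray(params.channel_extinction, dtype=float)
    shape = (len(baseline),) + (1,) * a.ndim
    return baseline.reshape(shape) * 10.0 ** (-ext.reshape(shape) * a)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Draw a mean-1 lognormal multiplier with the given CV (0 -> exactly 1)."""
    if cv == 0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2)))


def generate_dataset(
    design: DatasetDesign | None = None,
    params: KineticParams | None = None,
    seed: int = 0,
) -> list[ColorTimeSeries]:
    """Simulate one full dataset of tubes under the given design.

    Each tube draws one amplitude multiplier (lognormal, mean 1, CV
    ``replicate_amplitude_cv``) scaling its absorbance curve, then per-sample
    Gaussian noise of sd ``noise_sd`` is added to every channel intensity and
    the result is clipped to [0, 1].  Identical ``(design, params, seed)``
    reproduce the dataset bit for bit.
    """
    design = design or DatasetDesign()
    params = params or KineticParams()
    if len(design.channel_names) != len(params.baseline_rgb):
        raise ValueError(
            f"design has {len(design.channel_names)} channels but params "
            f"describe {len(params.baseline_rgb)}"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(design.n_timepoints) / design.frame_rate_hz
    out: list[ColorTimeSeries] = []
    tube_index = 0
    for conc, n_rep in design.levels:
        base_absorbance = kinetic_curve(conc, t, params)
        for _ in range(n_rep):
            mult = _lognormal_multiplier(rng, params.replicate_amplitude_cv)
            values = absorbance_to_channels(mult * base_absorbance, params)
            if params.drift_per_s:
                values = values + params.drift_per_s * t[None, :]
            if params.noise_sd > 0:
                values = values + rng.normal(0.0, params.noise_sd, values.shape)
            values = np.clip(values, 0.0, 1.0)
            out.append(
                ColorTimeSeries(
                    tube_id=f"tube{tube_index:03d}_c{conc:g}",
                    channel_names=design.channel_names,
                    values=values,
                    sampling_interval_s=1.0 / design.frame_rate_hz,
                    true_concentration=conc,
                )
            )
            tube_index += 1
    return out


# ---------------------------------------------------------------------------
# Frame rendering (lets the image-ingest path be tested end to end)
# ---------------------------------------------------------------------------

def render_frames(
    series: ColorTimeSeries,
    image_size: tuple[int, int] = (48, 64),
    tube_roi: tuple[int, int, int, int] = (20, 12, 44, 36),
    pixel_noise_sd: float = 0.0,
    background: float = 0.15,
    seed: int = 0,
) -> np.ndarray:
    """Render a series as synthetic 8-bit RGB camera frames.

    One frame per timepoint, shape ``(T, height, width, 3)``, dtype uint8.
    Pixels inside the half-open ROI rectangle ``(x0, y0, x1, y1)`` carry the
    series' channel intensities at that timepoint (plus optional Gaussian
    pixel noise); the background is a constant gray.  Intensities are
    quantized to 8 bits, so a zero-noise round trip through ROI extraction
    recovers the series to within 1/510 per sample.
    """
    if series.n_channels != 3:
        raise ValueError("frame rendering expects 3-channel (RGB) series")
    height, width = image_size
    x0, y0, x1, y1 = tube_roi
    if not (0 <= x0 < x1 <= width and 0 <= y0 < y1 <= height):
        raise ValueError(
            f"ROI {tube_roi} outside image bounds {width}x{height}"
        )
    rng = np.random.default_rng(seed)
    n_t = series.n_timepoints
    frames = np.full((n_t, height, width, 3), background, dtype=float)
    roi_block = np.broadcast_to(
        series.values.T[:, None, None, :], (n_t, y1 - y0, x1 - x0, 3)
    ).copy()
    if pixel_noise_sd > 0:
        roi_block += rng.normal(0.0, pixel_noise_sd, roi_block.shape)
    frames[:, y0:y1, x0:x1, :] = roi_block
    return (np.clip(frames, 0.0, 1.0) * 255.0).round().astype(np.uint8)
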