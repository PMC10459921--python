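"""FPM image formation: angled plane-wave illumination, pupil filtering,
and low-resolution intensity capture.

Conventions
-----------
* Wave vectors are spatial frequencies in cycles/µm (no 2π); the 2π enters
  only inside the modulation exponent.  The pupil radius is then na/λ.
* Spectra are handled fftshift-centered; the spectrum shift for LED n is an
  integer-bin circular roll (nearest bin of kn·FOV).
* The sensor is modeled as spectral cropping to the central low-res band
  followed by an inverse transform on the small grid, scaled by 1/ratio² so a
  unit plane wave through an all-pass pupil yields unit intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CHANNELS",
    "LEDArray",
    "WaveVector",
    "ComplexField",
    "CoherentTransferFunction",
    "Frame",
    "AcquisitionStack",
    "NoiseSpec",
    "compute_wave_vector",
    "modulate_sample",
    "apply_ctf",
    "capture_intensity",
    "simulate_stack",
]

CHANNELS = ("red", "green", "blue")

DEFAULT_WAVELENGTHS = {"red": 0.632, "green": 0.532, "blue": 0.470}


@dataclass(frozen=True)
class LEDArray:
    """Planar LED grid illuminating the sample from below.

    ``pitch`` and ``distance_to_sample`` are in mm; wavelengths in µm.
    """

    rows: int = 13
    cols: int = 13
    pitch: float = 4.0
    distance_to_sample: float = 90.0
    center_offset: Tuple[float, float] = (0.0, 0.0)
    wavelengths: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WAVELENGTHS)
    )

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("LED grid must have at least one row and column")
        if self.distance_to_sample <= 0:
            raise ValueError("distance_to_sample must be positive")
        if any(w <= 0 for w in self.wavelengths.values()):
            raise ValueError("wavelengths must be positive")

    @property
    def n_led(self) -> int:
        return self.rows * self.cols

    def led_positions_mm(self) -> np.ndarray:
        """(rows, cols, 2) lateral offsets (x, y) of each LED in mm."""
        r = np.arange(self.rows) - (self.rows - 1) / 2
        c = np.arange(self.cols) - (self.cols - 1) / 2
        yy, xx = np.meshgrid(r * self.pitch, c * self.pitch, indexing="ij")
        return np.stack(
            [xx + self.center_offset[0], yy + self.center_offset[1]], axis=-1
        )

    def led_order(self) -> List[Tuple[int, int]]:
        """Row-major (row, col) scan order, top-left first."""
        return [(r, c) for r in range(self.rows) for c in range(self.cols)]

    def led_index(self, led_row: int, led_col: int) -> int:
        """1-based LED index; n = 1 is the on-axis LED, others ranked by
        ascending illumination angle (ties row-major)."""
        pos = self.led_positions_mm()
        mag = np.hypot(pos[..., 0], pos[..., 1]).ravel()
        order = np.lexsort((np.arange(mag.size), mag))
        flat = led_row * self.cols + led_col
        return int(np.nonzero(order == flat)[0][0]) + 1


@dataclass(frozen=True)
class WaveVector:
    """Illumination spatial frequency (cycles/µm) for one LED and channel."""

    kx: float
    ky: float
    led_index: int
    channel: str

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.kx, self.ky))


@dataclass
class ComplexField:
    """2-D complex amplitude on a square grid with physical pixel pitch (µm)."""

    values: np.ndarray
    pixel_pitch: float
    channel: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("field must be a square 2-D array")
        if self.values.shape[0] % 2 != 0:
            raise ValueError("field side must be even")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @property
    def fov(self) -> float:
        """Field of view in µm."""
        return self.side * self.pixel_pitch

    def coords(self) -> Tuple[np.ndarray, np.ndarray]:
        """Centered spatial coordinate grids (x, y) in µm."""
        ax = (np.arange(self.side) - self.side // 2) * self.pixel_pitch
        return np.meshgrid(ax, ax, indexing="xy")


@dataclass(frozen=True)
class CoherentTransferFunction:
    """Binary circular pupil of radius na/λ on the high-res frequency grid."""

    na: float
    wavelength: float
    grid_side: int
    pixel_pitch_highres: float

    def __post_init__(self) -> None:
        if not 0 < self.na < 1:
            raise ValueError("numerical aperture must be in (0, 1)")
        if self.wavelength <= 0 or self.pixel_pitch_highres <= 0:
            raise ValueError("wavelength and pitch must be positive")

    @property
    def cutoff(self) -> float:
        """Pupil radius in cycles/µm."""
        return self.na / self.wavelength

    @property
    def freq_step(self) -> float:
        """Frequency-grid bin size, cycles/µm."""
        return 1.0 / (self.grid_side * self.pixel_pitch_highres)

    def mask(self, side: Optional[int] = None) -> np.ndarray:
        """Centered boolean pupil mask on a ``side``² grid (default full grid)."""
        side = self.grid_side if side is None else side
        ax = (np.arange(side) - side // 2) * self.freq_step
        kx, ky = np.meshgrid(ax, ax, indexing="xy")
        return kx**2 + ky**2 <= self.cutoff**2


@dataclass(frozen=True)
class Frame:
    intensity: np.ndarray
    led_row: int
    led_col: int
    led_index: int
    channel: str
    wavelength: float
    kx: float
    ky: float


@dataclass
class AcquisitionStack:
    """Ordered low-resolution intensity frames with acquisition metadata."""

    frames: List[Frame]
    lowres_side: int
    downsample_ratio: int
    pixel_pitch_highres: float
    na: float

    def __post_init__(self) -> None:
        for f in self.frames:
            if f.intensity.shape != (self.lowres_side, self.lowres_side):
                raise ValueError("all frames must share lowres_side")
            if np.any(f.intensity < 0):
                raise ValueError("intensities must be nonnegative")

    @property
    def highres_side(self) -> int:
        return self.lowres_side * self.downsample_ratio

    def channels(self) -> List[str]:
        seen: List[str] = []
        for f in self.frames:
            if f.channel not in seen:
                seen.append(f.channel)
        return seen

    def channel_frames(self, channel: str) -> List[Frame]:
        return [f for f in self.frames if f.channel == channel]


@dataclass(frozen=True)
class NoiseSpec:
    """Optional sensor noise: Gaussian read noise + Poisson shot noise."""

    gaussian_sigma: float = 0.0
    poisson_photons: float = 0.0  # photons per unit intensity; 0 disables

    @property
    def enabled(self) -> bool:
        return self.gaussian_sigma > 0 or self.poisson_photons > 0


def compute_wave_vector(
    array: LEDArray, led_row: int, led_col: int, channel: str
) -> WaveVector:
    """Illumination wave vector kn = (sin ax, sin ay)/λ for one LED.

    The sine of the incidence angle is offset/√(offset² + distance²), exact
    trigonometry from the LED's lateral position.
    """
    if not (0 <= led_row < array.rows and 0 <= led_col < array.cols):
        raise IndexError(f"LED index ({led_row}, {led_col}) out of range")
    if channel not in array.wavelengths:
        raise KeyError(f"no wavelength configured for channel {channel!r}")
    lam = array.wavelengths[channel]
    x_mm, y_mm = array.led_positions_mm()[led_row, led_col]
    hyp = np.sqrt(x_mm**2 + y_mm**2 + array.distance_to_sample**2)
    # Sign convention: k carries the sign of the LED offset; forward model and
    # reconstruction only need mutual consistency.
    sin_x = x_mm / hyp
    sin_y = y_mm / hyp
    return WaveVector(
        kx=float(sin_x / lam),
        ky=float(sin_y / lam),
        led_index=array.led_index(led_row, led_col),
        channel=channel,
    )


def modulate_sample(sample: ComplexField, k: WaveVector) -> ComplexField:
    """Tilted-illumination modulation e(r) = o(r)·exp(j·2π·(kx·x + ky·y))."""
    x, y = sample.coords()
    phase = np.exp(2j * np.pi * (k.kx * x + k.ky * y))
    return ComplexField(sample.values * phase, sample.pixel_pitch, sample.channel)


def apply_ctf(
    shifted_spectrum: np.ndarray, ctf: CoherentTransferFunction
) -> np.ndarray:
    """Binary pupil filter on a centered spectrum: Gn(k) = O(k−kn)·H(k)."""
    spec = np.asarray(shifted_spectrum, dtype=complex)
    if spec.shape != (ctf.grid_side, ctf.grid_side):
        raise ValueError(
            f"spectrum shape {spec.shape} does not match CTF grid {ctf.grid_side}"
        )
    return spec * ctf.mask()


def capture_intensity(filtered_spectrum: np.ndarray, ratio: int) -> np.ndarray:
    """Sensor capture: crop the central low-res band, inverse transform on the
    small grid, return |gn|²."""
    spec = np.asarray(filtered_spectrum, dtype=complex)
    side = spec.shape[0]
    if side % ratio != 0:
        raise ValueError(f"ratio {ratio} does not divide grid side {side}")
    small = side // ratio
    lo = side // 2 - small // 2
    cropped = spec[lo : lo + small, lo : lo + small] / ratio**2
    g = np.fft.ifft2(np.fft.ifftshift(cropped))
    return np.abs(g) ** 2


def _centered_spectrum(field: ComplexField) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(field.values))


def shift_bins(k: WaveVector, freq_step: float) -> Tuple[int, int]:
    """Nearest-bin spectrum shift for a wave vector (x-bins, y-bins)."""
    return int(np.rint(k.kx / freq_step)), int(np.rint(k.ky / freq_step))


def simulate_frame(
    spectrum: np.ndarray,
    k: WaveVector,
    ctf: CoherentTransferFunction,
    ratio: int,
) -> np.ndarray:
    """One forward capture from a precomputed centered high-res spectrum."""
    bx, by = shift_bins(k, ctf.freq_step)
    # O(k − kn): tilted illumination moves spectrum content toward +kn, so the
    # centered pupil admits the sample band around −kn.
    shifted = np.roll(spectrum, shift=(by, bx), axis=(0, 1))
    return capture_intensity(apply_ctf(shifted, ctf), ratio)


def simulate_stack(
    sample_per_channel: Dict[str, ComplexField],
    array: LEDArray,
    ctf_per_channel: Dict[str, CoherentTransferFunction],
    ratio: int,
    noise: Optional[NoiseSpec] = None,
    seed: Optional[int] = None,
    channels: Optional[Sequence[str]] = None,
) -> AcquisitionStack:
    """Simulate a full acquisition: frames ordered channel-major, then
    row-major over the LED grid.  Deterministic for a fixed seed."""
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    channels = list(channels) if channels is not None else list(sample_per_channel)
    frames: List[Frame] = []
    lowres_side = None
    pitch = None
    na = None
    for ch in channels:
        if ch not in sample_per_channel:
            raise KeyError(f"missing sample field for channel {ch!r}")
        if ch not in ctf_per_channel:
            raise KeyError(f"missing CTF for channel {ch!r}")
        sample = sample_per_channel[ch]
        ctf = ctf_per_channel[ch]
        if ctf.grid_side != sample.side:
            raise ValueError("CTF grid does not match sample grid")
        pitch = sample.pixel_pitch
        na = ctf.na
        spectrum = _centered_spectrum(sample)
        for r, c in array.led_order():
            k = compute_wave_vector(array, r, c, ch)
            intensity = simulate_frame(spectrum, k, ctf, ratio)
            if noise.enabled:
                if noise.poisson_photons > 0:
                    intensity = (
                        rng.poisson(intensity * noise.poisson_photons)
                        / noise.poisson_photons
                    )
                if noise.gaussian_sigma > 0:
                    intensity = intensity + rng.normal(
                        0, noise.gaussian_sigma, intensity.shape
                    )
                intensity = np.clip(intensity, 0, None)
            lowres_side = intensity.shape[0]
            frames.append(
                Frame(
                    intensity=intensity,
                    led_row=r,
                    led_col=c,
                    led_index=k.led_index,
                    channel=ch,
                    wavelength=array.wavelengths[ch],
                    kx=k.kx,
                    ky=k.ky,
                )
            )
    if lowres_side is None:
        raise ValueError("no channels requested")
    return AcquisitionStack(
        frames=frames,
        lowres_side=lowres_side,
        downsample_ratio=ratio,
        pixel_pitch_highres=pitch,
        na=na,
    )
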