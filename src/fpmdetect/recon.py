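"""High-resolution recovery by iterative frequency-domain sub-aperture
replacement (alternating-projection amplitude replacement), plus RGB synthesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional

import numpy as np

from .optics import (
    AcquisitionStack,
    CoherentTransferFunction,
    ComplexField,
    Frame,
    WaveVector,
    shift_bins,
    simulate_frame,
)

__all__ = [
    "SpectrumEstimate",
    "ReconResult",
    "initialize_spectrum",
    "update_subaperture",
    "reconstruct_channel",
    "reconstruct_rgb",
    "data_consistency_error",
]


@dataclass
class SpectrumEstimate:
    """Running high-resolution spectrum estimate (fftshift-centered)."""

    spectrum: np.ndarray
    channel: str
    iteration: int
    pixel_pitch_highres: float
    downsample_ratio: int

    @property
    def side(self) -> int:
        return self.spectrum.shape[0]

    @property
    def freq_step(self) -> float:
        return 1.0 / (self.side * self.pixel_pitch_highres)


@dataclass
class ReconResult:
    field: ComplexField
    convergence_trace: List[float] = dc_field(default_factory=list)


def _ctf_for(stack: AcquisitionStack, wavelength: float) -> CoherentTransferFunction:
    return CoherentTransferFunction(
        na=stack.na,
        wavelength=wavelength,
        grid_side=stack.highres_side,
        pixel_pitch_highres=stack.pixel_pitch_highres,
    )


def _onaxis_frame(stack: AcquisitionStack, channel: str) -> Frame:
    frames = stack.channel_frames(channel)
    if not frames:
        raise ValueError(f"stack holds no frames for channel {channel!r}")
    on_axis = [f for f in frames if f.led_index == 1]
    if not on_axis:
        raise ValueError(f"stack holds no on-axis frame for channel {channel!r}")
    return on_axis[0]


def initialize_spectrum(stack: AcquisitionStack, channel: str) -> SpectrumEstimate:
    """Seed the estimate with the band-limited upsampled on-axis amplitude."""
    frame = _onaxis_frame(stack, channel)
    amp = np.sqrt(frame.intensity)
    small = np.fft.fftshift(np.fft.fft2(amp))
    n = stack.highres_side
    m = stack.lowres_side
    lo = n // 2 - m // 2
    spectrum = np.zeros((n, n), dtype=complex)
    # Inverse of the capture scaling so field amplitude is preserved.
    spectrum[lo : lo + m, lo : lo + m] = small * stack.downsample_ratio**2
    return SpectrumEstimate(
        spectrum=spectrum,
        channel=channel,
        iteration=0,
        pixel_pitch_highres=stack.pixel_pitch_highres,
        downsample_ratio=stack.downsample_ratio,
    )


def update_subaperture(
    estimate: SpectrumEstimate,
    frame: Frame,
    k: WaveVector,
    ctf: CoherentTransferFunction,
) -> SpectrumEstimate:
    """One amplitude-replacement projection for a single frame.

    Extracts the pupil-supported sub-spectrum at offset kn, replaces the
    low-res field magnitude with √In (keeping phase), and writes the result
    back into the pupil region only; everything else is untouched.
    """
    n = estimate.side
    r = estimate.downsample_ratio
    m = n // r
    bx, by = shift_bins(k, estimate.freq_step)
    if abs(bx) > n // 2 or abs(by) > n // 2:
        raise ValueError("wave vector shift exceeds the frequency grid")
    mask = ctf.mask(side=m)
    lo = n // 2 - m // 2
    shifted = np.roll(estimate.spectrum, shift=(by, bx), axis=(0, 1))
    sub = shifted[lo : lo + m, lo : lo + m]
    g = np.fft.ifft2(np.fft.ifftshift(sub * mask / r**2))
    mag = np.abs(g)
    phase = np.where(mag > 0, g / np.where(mag > 0, mag, 1.0), 1.0)
    g_new = np.sqrt(frame.intensity) * phase
    sub_new = np.fft.fftshift(np.fft.fft2(g_new)) * r**2
    sub[mask] = sub_new[mask]
    spectrum = np.roll(shifted, shift=(-by, -bx), axis=(0, 1))
    return SpectrumEstimate(
        spectrum=spectrum,
        channel=estimate.channel,
        iteration=estimate.iteration,
        pixel_pitch_highres=estimate.pixel_pitch_highres,
        downsample_ratio=estimate.downsample_ratio,
    )


def data_consistency_error(
    estimate: SpectrumEstimate, frames: List[Frame], stack: AcquisitionStack
) -> float:
    """Σ‖√In_sim − √In_meas‖² / Σ‖√In_meas‖² over the given frames."""
    num = 0.0
    den = 0.0
    for f in frames:
        ctf = _ctf_for(stack, f.wavelength)
        k = WaveVector(kx=f.kx, ky=f.ky, led_index=f.led_index, channel=f.channel)
        sim = simulate_frame(estimate.spectrum, k, ctf, estimate.downsample_ratio)
        num += float(np.sum((np.sqrt(sim) - np.sqrt(f.intensity)) ** 2))
        den += float(np.sum(f.intensity))
    return num / den if den > 0 else 0.0


def _pairwise_overlap(stack: AcquisitionStack, channel: str) -> float:
    """Spectral overlap fraction of adjacent LED sub-apertures (area of the
    lens disk shared by neighbors, relative to the disk area)."""
    frames = stack.channel_frames(channel)
    ks = np.array([[f.kx, f.ky] for f in frames])
    if len(ks) < 2:
        return 1.0
    radius = stack.na / frames[0].wavelength
    d = np.sqrt(np.sort(np.sum((ks[None] - ks[:, None]) ** 2, axis=-1), axis=1)[:, 1])
    d = float(np.median(d))
    if d >= 2 * radius:
        return 0.0
    area = 2 * radius**2 * np.arccos(d / (2 * radius)) - (d / 2) * np.sqrt(
        4 * radius**2 - d**2
    )
    return float(area / (np.pi * radius**2))


def reconstruct_channel(
    stack: AcquisitionStack,
    channel: str,
    n_iters: int = 15,
    early_stop_rel: float = 1e-4,
) -> ReconResult:
    """Sweep all frames of one channel per iteration, low-to-high |kn|."""
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    frames = stack.channel_frames(channel)
    if not frames:
        raise ValueError(f"stack holds no frames for channel {channel!r}")
    overlap = _pairwise_overlap(stack, channel)
    if overlap < 0.35:
        warnings.warn(
            f"adjacent sub-aperture overlap {overlap:.0%} < 35%; "
            "reconstruction may not converge",
            stacklevel=2,
        )
    order = sorted(range(len(frames)), key=lambda i: (np.hypot(frames[i].kx, frames[i].ky), i))
    estimate = initialize_spectrum(stack, channel)
    wavelength = frames[0].wavelength
    ctf = _ctf_for(stack, wavelength)
    trace: List[float] = []
    for it in range(n_iters):
        for i in order:
            f = frames[i]
            k = WaveVector(kx=f.kx, ky=f.ky, led_index=f.led_index, channel=channel)
            estimate = update_subaperture(estimate, f, k, ctf)
        estimate.iteration = it + 1
        err = data_consistency_error(estimate, frames, stack)
        trace.append(err)
        if len(trace) >= 2 and trace[-2] > 0:
            if (trace[-2] - trace[-1]) / trace[-2] < early_stop_rel:
                break
    values = np.fft.ifft2(np.fft.ifftshift(estimate.spectrum))
    field = ComplexField(values, stack.pixel_pitch_highres, channel)
    return ReconResult(field=field, convergence_trace=trace)


def reconstruct_rgb(
    stack: AcquisitionStack,
    n_iters: int = 15,
    channels: tuple = ("red", "green", "blue"),
) -> np.ndarray:
    """Per-channel magnitude reconstructions stacked as an RGB image in [0, 1]."""
    present = stack.channels()
    missing = [c for c in channels if c not in present]
    if missing:
        raise ValueError(f"stack is missing channels {missing}")
    planes = []
    for ch in channels:
        result = reconstruct_channel(stack, ch, n_iters=n_iters)
        mag = np.abs(result.field.values)
        peak = mag.max()
        planes.append(mag / peak if peak > 0 else mag)
    return np.clip(np.stack(planes, axis=-1), 0.0, 1.0)
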