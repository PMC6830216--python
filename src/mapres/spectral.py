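"""Fourier-domain volume operations.

Frequency convention: ``f`` is radial spatial frequency in cycles/voxel
(normalised units), so Nyquist sits at 0.5 and a resolution cutoff of
``d`` Angstrom on a grid sampled at ``v`` A/voxel maps to ``f_c = v / d``.
Physical frequency ``s = f / v`` is in 1/A.

All operations act on the full 3D discrete Fourier transform and return
real volumes with unchanged sampling metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy.signal import resample as _fourier_resample

from .map_io import DensityMap, Mask, ValidationError

__all__ = [
    "FilterSpec",
    "FilterBankSpec",
    "lowpass_raised_cosine",
    "bfactor_apply",
    "phase_randomize",
    "resample",
    "resample_mask",
]

DEFAULT_TRANSITION_WIDTH = 0.02  # full width of the raised cosine, cycles/voxel


@dataclass
class FilterSpec:
    """Low-pass passband edge ``cutoff`` (A) with raised-cosine transition.

    ``transition_width`` is the *full* width of the cosine roll-off in
    normalised frequency units (cycles/voxel); the response is 1 up to
    ``f_c - w/2`` and 0 beyond ``f_c + w/2``.
    """

    cutoff: float
    transition_width: float = DEFAULT_TRANSITION_WIDTH

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError(f"cutoff must be > 0 A, got {self.cutoff}")
        if self.transition_width <= 0:
            raise ValidationError("transition_width must be > 0")

    def check_nyquist(self, voxel_size: float) -> None:
        if self.cutoff < 2.0 * voxel_size:
            raise ValidationError(
                f"cutoff {self.cutoff} A is below Nyquist ({2 * voxel_size} A) "
                f"for sampling {voxel_size} A/voxel"
            )


@dataclass
class FilterBankSpec:
    """Arithmetic bank of low-pass cutoffs ``{d_min, d_min+step, ..., d_max}``."""

    d_min: float
    d_max: float
    step: float

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise ValidationError(f"d_min must be < d_max, got [{self.d_min}, {self.d_max}]")
        if self.step <= 0:
            raise ValidationError(f"bank step must be > 0, got {self.step}")

    def cutoffs(self) -> np.ndarray:
        n = int(np.floor((self.d_max - self.d_min) / self.step + 1e-9)) + 1
        return self.d_min + self.step * np.arange(n)


def _radial_freq(shape: tuple[int, ...], rfft_last: bool = True) -> np.ndarray:
    """Radial normalised frequency grid (cycles/voxel) for (r)fftn layout."""
    nz, ny, nx = shape
    fz = np.fft.fftfreq(nz)
    fy = np.fft.fftfreq(ny)
    fx = np.fft.rfftfreq(nx) if rfft_last else np.fft.fftfreq(nx)
    return np.sqrt(
        fz[:, None, None] ** 2 + fy[None, :, None] ** 2 + fx[None, None, :] ** 2
    )


def raised_cosine_response(f: np.ndarray, f_c: float, width: float) -> np.ndarray:
    """Evaluate the raised-cosine low-pass response H(f) elementwise."""
    lo = f_c - width / 2.0
    hi = f_c + width / 2.0
    h = np.ones_like(f)
    h[f >= hi] = 0.0
    band = (f > lo) & (f < hi)
    h[band] = 0.5 * (1.0 + np.cos(np.pi * (f[band] - lo) / width))
    return h


def lowpass_raised_cosine(dmap: DensityMap, spec: FilterSpec) -> DensityMap:
    """Low-pass filter with a raised-cosine transition band.

    ``H = 1`` for ``f <= f_c - w/2``, half-cosine roll-off of full width
    ``w`` centred on ``f_c``, ``H = 0`` above.  The DC component is always
    preserved exactly.
    """
    spec.check_nyquist(dmap.voxel_size)
    f = _radial_freq(dmap.shape)
    f_c = dmap.voxel_size / spec.cutoff
    h = raised_cosine_response(f, f_c, spec.transition_width)
    spectrum = sfft.rfftn(dmap.data.astype(np.float64))
    out = sfft.irfftn(spectrum * h, s=dmap.shape)
    return dmap.with_data(out.astype(dmap.data.dtype))


def bfactor_apply(dmap: DensityMap, b_factor: float) -> DensityMap:
    """Multiply each Fourier coefficient by ``exp(-B s^2 / 4)``, s in 1/A.

    Negative B amplifies high frequencies (sharpening).
    """
    if b_factor == 0.0:
        return dmap.with_data(dmap.data.copy())
    s = _radial_freq(dmap.shape) / dmap.voxel_size
    gain = np.exp(-b_factor * s**2 / 4.0)
    spectrum = sfft.rfftn(dmap.data.astype(np.float64))
    out = sfft.irfftn(spectrum * gain, s=dmap.shape)
    return dmap.with_data(out.astype(dmap.data.dtype))


def phase_randomize(dmap: DensityMap, beyond: float, seed: int = 0) -> DensityMap:
    """Replace Fourier phases at ``s > 1/beyond`` with random phases.

    Amplitudes are preserved exactly; Hermitian symmetry (hence a real
    output) is guaranteed by drawing the replacement phases from the
    spectrum of a real white-noise field.  Deterministic under ``seed``.
    """
    if beyond < 2.0 * dmap.voxel_size:
        raise ValidationError(
            f"randomisation cutoff {beyond} A is below Nyquist "
            f"({2 * dmap.voxel_size} A) at {dmap.voxel_size} A/voxel"
        )
    f_c = dmap.voxel_size / beyond
    if f_c >= 0.5:  # nothing inside Nyquist to randomise
        return dmap.with_data(dmap.data.copy())
    f = _radial_freq(dmap.shape, rfft_last=False)
    outside = f > f_c

    spectrum = sfft.fftn(dmap.data.astype(np.float64))
    rng = np.random.default_rng(seed)
    noise_spec = sfft.fftn(rng.standard_normal(dmap.shape))
    mag = np.abs(noise_spec)
    mag[mag == 0] = 1.0
    random_phase = noise_spec / mag

    randomized = np.where(outside, np.abs(spectrum) * random_phase, spectrum)
    out = sfft.ifftn(randomized)
    # Hermitian by construction: the imaginary residue is numerical only.
    return dmap.with_data(out.real.astype(dmap.data.dtype))


def resample(dmap: DensityMap, new_voxel_size: float, min_edge: int = 13) -> DensityMap:
    """Fourier-space resampling to ``new_voxel_size`` A/voxel.

    Frequency-domain cropping (downsampling) or zero-padding (upsampling)
    per axis; preserves the physical extent to within one voxel and
    introduces no interpolation blur.  The output voxel size is exactly
    ``new_voxel_size``.
    """
    if new_voxel_size <= 0:
        raise ValidationError(f"new_voxel_size must be > 0, got {new_voxel_size}")
    if abs(new_voxel_size - dmap.voxel_size) / dmap.voxel_size < 1e-9:
        return dmap.with_data(dmap.data.copy())

    ratio = dmap.voxel_size / new_voxel_size
    new_shape = tuple(max(int(round(n * ratio)), 1) for n in dmap.shape)
    if min(new_shape) < min_edge and min(dmap.shape) >= min_edge:
        raise ValidationError(
            f"resampling to {new_voxel_size} A/voxel shrinks the grid to "
            f"{new_shape}, below the minimum boxable edge of {min_edge}"
        )
    out = dmap.data.astype(np.float64)
    for axis, n_new in enumerate(new_shape):
        if n_new != out.shape[axis]:
            out = _fourier_resample(out, n_new, axis=axis)
    return DensityMap(
        data=out.astype(dmap.data.dtype), voxel_size=float(new_voxel_size), origin=dmap.origin.copy()
    )


def resample_mask(mask: Mask, voxel_size: float, new_voxel_size: float) -> Mask:
    """Resample a binary mask by Fourier resampling + 0.5 rebinarisation."""
    as_map = DensityMap(mask.data.astype(np.float32), voxel_size=voxel_size)
    resampled = resample(as_map, new_voxel_size, min_edge=1)
    binary = (resampled.data > 0.5).astype(np.uint8)
    if not binary.any():
        raise ValidationError("mask is empty after resampling")
    return Mask(data=binary)
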