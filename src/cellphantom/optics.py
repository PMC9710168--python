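"""Parametric point-spread-function models and the optical forward pass.

Fluorescence is modelled by the Airy intensity pattern of a circular
aperture, phase contrast by the obscured-Airy pattern of the annular phase
ring.  Kernels are rendered at the scene's super-sampled pitch, optionally
Gaussian-apodised and defocused, convolved with the OPL scene, and the
result is block-averaged back to camera resolution.

For the phase-contrast image itself the weak-object approximation is used:
the observed intensity is the background minus the *signed* amplitude
spread function convolved with the excess optical path.  The annular
aperture has (near) zero DC response, which is what produces the shade-off
inside large objects and the bright halo around cell edges; a small
constant kernel offset restores part of the DC response and thereby
modulates both artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Literal

import numpy as np
from scipy import ndimage, signal
from scipy.special import j1

from .render import OPLImage

#: first root of the Bessel function J1, fixing the Airy first zero
#: at radius 0.61 λ/NA (v = 2π·NA·ρ/λ = 3.8317…)
J1_FIRST_ROOT = 3.8317059702075125


class KernelTruncationError(ValueError):
    """Requested kernel radius too small to capture the PSF support."""


PSFMode = Literal["fluorescence", "phase_contrast", "3d_fluorescence"]


@dataclass(frozen=True)
class PSFConfig:
    """Microscope parameters from which kernels are generated.

    ``wavelength`` in nm; ``camera_pixel_size`` is the physical camera pixel
    in μm, divided by ``magnification`` and ``supersample_factor`` to give
    the object-plane rendering pitch.  The phase ring is described by the
    outer/inner annulus radius fractions; only their ratio ε = in/out enters
    the obscured-Airy formula, but both are kept configurable.
    """

    mode: PSFMode = "phase_contrast"
    numerical_aperture: float = 1.45
    wavelength: float = 600.0
    refractive_index: float = 1.518
    camera_pixel_size: float = 6.5
    magnification: float = 100.0
    supersample_factor: int = 3
    annulus_outer: float = 1.0
    annulus_inner: float = 0.55
    apodisation_sigma: float = math.inf  # pixels; inf = off
    defocus: float = 0.0                 # μm
    defocus_rate: float = 0.3            # μm lateral blur per μm defocus
    halo_offset: float = 0.0             # a.u., Supplementary-style constant
    kernel_radius: int | None = None     # super-sampled pixels; None = auto

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture <= self.refractive_index:
            raise ValueError("need 0 < NA <= medium refractive index")
        if not 0 < self.annulus_inner < self.annulus_outer <= 1.0:
            raise ValueError("need 0 < annulus_inner < annulus_outer <= 1")

    @property
    def pitch(self) -> float:
        """Object-plane pixel pitch of the super-sampled rendering (μm)."""
        return self.camera_pixel_size / self.magnification / self.supersample_factor

    @property
    def obscuration(self) -> float:
        """ε = inner/outer annulus radius ratio."""
        return self.annulus_inner / self.annulus_outer

    @property
    def first_zero_radius(self) -> float:
        """Airy first dark ring radius 0.61 λ/NA in μm."""
        return 0.61 * (self.wavelength * 1e-3) / self.numerical_aperture

    def resolved_radius(self) -> int:
        """Kernel half-width in pixels; ≥ 3× the first-zero radius."""
        min_r = int(math.ceil(3.0 * self.first_zero_radius / self.pitch))
        if self.kernel_radius is None:
            return max(min_r, int(math.ceil(4.0 * self.first_zero_radius / self.pitch)))
        if self.kernel_radius < min_r:
            raise KernelTruncationError(
                f"kernel radius {self.kernel_radius} px < 3× first zero ({min_r} px)"
            )
        return self.kernel_radius


@dataclass
class PSFKernel:
    """A convolution kernel plus the configuration that generated it."""

    array: np.ndarray
    config: PSFConfig
    normalised: bool = True

    @property
    def pitch(self) -> float:
        return self.config.pitch


def _radial_v(config: PSFConfig) -> np.ndarray:
    """Dimensionless optical coordinate v = 2π·NA·ρ/λ on the kernel grid."""
    radius = config.resolved_radius()
    idx = np.arange(-radius, radius + 1)
    rho = np.hypot(idx[:, None], idx[None, :]) * config.pitch
    return 2.0 * np.pi * config.numerical_aperture * rho / (config.wavelength * 1e-3)


def _jinc(v: np.ndarray) -> np.ndarray:
    """2·J1(v)/v with the v→0 limit 1."""
    out = np.ones_like(v)
    nz = v != 0
    out[nz] = 2.0 * j1(v[nz]) / v[nz]
    return out


def airy_psf(config: PSFConfig) -> PSFKernel:
    """Diffraction-limited fluorescence PSF: h(v) = [2J1(v)/v]², unit sum."""
    v = _radial_v(config)
    h = _jinc(v) ** 2
    total = h.sum()
    if total <= 0:
        raise KernelTruncationError("empty kernel")
    return PSFKernel(h / total, config)


def obscured_airy_amplitude(config: PSFConfig) -> np.ndarray:
    """Signed amplitude spread function of the annular aperture.

    A(v) = [2/(1−ε²)]·[J1(v)/v − ε²·J1(εv)/(εv)], normalised so A(0) = 1.
    Its 2-D integral is (near) zero — the annulus passes no DC — which is
    the mathematical origin of shade-off and halo in phase contrast.
    """
    eps = config.obscuration
    if eps >= 1.0:
        raise ValueError("obscuration ratio must be < 1")
    v = _radial_v(config)
    if eps == 0.0:
        return _jinc(v)
    return (_jinc(v) - eps**2 * _jinc(eps * v)) / (1.0 - eps**2)


def obscured_airy_psf(config: PSFConfig) -> PSFKernel:
    """Phase-contrast intensity PSF |A(v)|², with optional constant offset.

    ``halo_offset`` is added uniformly before renormalising; at ε → 0 (no
    obscuration, δ = 0) the kernel reduces elementwise to the fluorescence
    Airy kernel.
    """
    h = obscured_airy_amplitude(config) ** 2
    h += config.halo_offset
    total = h.sum()
    if total <= 0:
        raise KernelTruncationError("kernel sum non-positive after offset")
    return PSFKernel(h / total, config)


def apodise(kernel: PSFKernel, sigma: float) -> PSFKernel:
    """Multiply by a centred Gaussian of width ``sigma`` px and renormalise."""
    if sigma <= 0:
        raise ValueError("apodisation sigma must be positive (inf disables)")
    if not math.isfinite(sigma):
        return kernel
    n = kernel.array.shape[0]
    idx = np.arange(n) - (n - 1) / 2.0
    g = np.exp(-(idx[:, None] ** 2 + idx[None, :] ** 2) / (2.0 * sigma**2))
    arr = kernel.array * g
    return PSFKernel(arr / arr.sum(), kernel.config, normalised=True)


def defocus_psf(config: PSFConfig, z: float | None = None) -> PSFKernel:
    """In-focus kernel blurred by a Gaussian of width ``defocus_rate·|z|``.

    A deliberately simple axial model: defocus broadens the lateral kernel
    monotonically in |z| while conserving its sum.  z = 0 returns the
    in-focus kernel unchanged.
    """
    z = config.defocus if z is None else z
    base = make_kernel(dc_replace(config, defocus=0.0))
    if z == 0:
        return base
    sigma_px = config.defocus_rate * abs(z) / config.pitch
    arr = ndimage.gaussian_filter(base.array, sigma_px, mode="constant")
    return PSFKernel(arr / arr.sum(), dc_replace(config, defocus=z))


def make_kernel(config: PSFConfig) -> PSFKernel:
    """Kernel dispatch: mode, then apodisation, then defocus."""
    if config.mode == "fluorescence":
        kernel = airy_psf(config)
    elif config.mode == "phase_contrast":
        kernel = obscured_airy_psf(config)
    elif config.mode == "3d_fluorescence":
        return psf_stack(config)
    else:
        raise ValueError(f"unknown PSF mode {config.mode!r}")
    if math.isfinite(config.apodisation_sigma):
        kernel = apodise(kernel, config.apodisation_sigma)
    if config.defocus != 0:
        kernel = defocus_psf(config, config.defocus)
    return kernel


def psf_stack(
    config: PSFConfig, z_planes: np.ndarray | None = None
) -> PSFKernel:
    """Simplified 3-D fluorescence PSF: a stack of defocused 2-D kernels."""
    if z_planes is None:
        z_planes = np.linspace(-2.0, 2.0, 9)
    flat = dc_replace(config, mode="fluorescence")
    planes = [defocus_psf(flat, z).array for z in z_planes]
    arr = np.stack(planes)
    return PSFKernel(arr / arr.sum(), config)


def convolve2d_oracle(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct double-loop spatial convolution with reflective boundaries.

    Independent slow path used to validate the FFT implementation; O(N²K²).
    """
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="reflect")
    out = np.zeros_like(image, dtype=float)
    fk = kernel[::-1, ::-1]
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = np.sum(padded[i : i + kh, j : j + kw] * fk)
    return out


def _convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """FFT convolution with reflective boundary handling."""
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="reflect")
    full = signal.fftconvolve(padded, kernel, mode="same")
    return full[ph : ph + image.shape[0], pw : pw + image.shape[1]]


def block_downsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-average an image by an integer factor (trailing rows trimmed)."""
    if factor == 1:
        return image
    h = image.shape[0] - image.shape[0] % factor
    w = image.shape[1] - image.shape[1] % factor
    view = image[:h, :w].reshape(h // factor, factor, w // factor, factor)
    return view.mean(axis=(1, 3))


def convolve_and_downsample(opl: OPLImage, kernel: PSFKernel) -> np.ndarray:
    """PSF-convolve the super-sampled scene, then return it at camera pitch."""
    if not np.isclose(opl.pixel_size, kernel.pitch, rtol=1e-6):
        raise ValueError(
            f"kernel pitch {kernel.pitch:.6f} μm does not match scene pitch "
            f"{opl.pixel_size:.6f} μm"
        )
    arr = kernel.array
    if arr.ndim == 3:  # simplified 3-D stack: project to its in-focus sum
        arr = arr.sum(axis=0)
        arr = arr / arr.sum()
    blurred = _convolve_reflect(opl.opl, arr)
    return block_downsample(blurred, opl.supersample_factor)


def render_phase_contrast(
    opl: OPLImage,
    config: PSFConfig,
    background: float = 1.0,
    contrast: float = 0.35,
) -> np.ndarray:
    """Weak-object phase-contrast image at camera resolution.

    out = background · (1 − contrast · (A ⊛ φ) / max φ), where A is the
    signed obscured-Airy amplitude kernel (apodised, offset by the
    configured halo constant) and φ the excess optical path over the media.
    Cell bodies come out dark, their rims bright (halo), and the interiors
    of large objects sag towards background (shade-off).
    """
    amp = obscured_airy_amplitude(config)
    amp = amp + config.halo_offset
    amp = amp / amp.max()
    if math.isfinite(config.apodisation_sigma):
        n = amp.shape[0]
        idx = np.arange(n) - (n - 1) / 2.0
        amp = amp * np.exp(
            -(idx[:, None] ** 2 + idx[None, :] ** 2) / (2 * config.apodisation_sigma**2)
        )
    phi = opl.opl - np.median(opl.opl)
    scale = max(np.abs(phi).max(), 1e-12)
    response = _convolve_reflect(phi / scale, amp / np.abs(amp).sum())
    image = background * (1.0 - contrast * response / max(np.abs(response).max(), 1e-12))
    return block_downsample(np.clip(image, 0.0, None), opl.supersample_factor)


def write_kernel(kernel: PSFKernel, path: str) -> None:
    """Kernel as 32-bit float TIFF plus a JSON sidecar of its parameters."""
    import dataclasses
    import json
    from pathlib import Path

    import tifffile

    out = Path(path)
    tifffile.imwrite(out, kernel.array.astype(np.float32))
    meta = dataclasses.asdict(kernel.config)
    meta = {k: (None if isinstance(v, float) and not math.isfinite(v) else v)
            for k, v in meta.items()}
    out.with_suffix(".json").write_text(json.dumps(meta, indent=2))
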