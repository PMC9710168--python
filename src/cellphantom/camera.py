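"""Camera capture model and synthetic-vs-real image similarity tools.

The capture chain is the standard photon-counting model: expected
photoelectrons are Poisson-distributed (shot noise), Gaussian read noise is
added in electrons, the signal is amplified to digital numbers, offset, and
quantised to the sensor bit depth.  Matching utilities align a synthetic
image's intensity histogram and rotationally averaged Fourier amplitude
spectrum to those of a real reference micrograph, and report per-region
(cells / device / media) intensity and variance errors for manual tuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class DegenerateReferenceError(ValueError):
    """Reference image carries no usable intensity distribution."""


@dataclass(frozen=True)
class CameraConfig:
    """Sensor parameters of the capture model."""

    photon_scale: float = 100.0  # expected photoelectrons per unit input
    read_noise: float = 2.0      # electrons RMS
    baseline: float = 100.0      # DN offset
    gain: float = 2.0            # DN per electron
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon scale must be positive")
        if self.read_noise < 0 or self.baseline < 0:
            raise ValueError("read noise and baseline must be non-negative")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit depth must be 8, 12 or 16")

    @property
    def max_dn(self) -> int:
        return 2**self.bit_depth - 1


def apply_camera(
    image: np.ndarray, config: CameraConfig, rng: np.random.Generator
) -> np.ndarray:
    """Simulate image capture; returns an integer image in DN.

    out = clip(round(gain·(Poisson(scale·I) + N(0, σ_r)) + baseline),
               0, 2^bits − 1)
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("input image must be non-negative")
    electrons = rng.poisson(config.photon_scale * image).astype(float)
    if config.read_noise > 0:
        electrons += rng.normal(0.0, config.read_noise, size=image.shape)
    dn = np.rint(config.gain * electrons + config.baseline)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    return np.clip(dn, 0, config.max_dn).astype(dtype)


def match_histogram(synthetic: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Remap pixel intensities so the output's empirical CDF is the reference's.

    Exact rank mapping: the k-th brightest synthetic pixel receives the
    k-th brightest reference value (quantile-interpolated when the pixel
    counts differ).  Strictly monotone in the input up to ties, hence
    idempotent and rank-preserving.
    """
    syn = np.asarray(synthetic, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0 or np.ptp(ref) == 0:
        raise DegenerateReferenceError("reference image is constant")
    order = np.argsort(syn.ravel(), kind="stable")
    ref_sorted = np.sort(ref.ravel())
    if ref.size != syn.size:
        q = np.linspace(0.0, 1.0, syn.size)
        ref_sorted = np.interp(q, np.linspace(0.0, 1.0, ref.size), ref_sorted)
    out = np.empty(syn.size, dtype=float)
    out[order] = ref_sorted
    # equal inputs must map to equal outputs: average within tie groups
    flat = syn.ravel()
    uniq, inverse, counts = np.unique(flat, return_inverse=True, return_counts=True)
    if uniq.size != flat.size:
        sums = np.bincount(inverse, weights=out)
        out = (sums / counts)[inverse]
    return out.reshape(syn.shape)


def _radial_bins(shape: tuple[int, int]) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    r = np.hypot(fy * shape[0], fx * shape[1])
    return np.rint(r).astype(int)


def radial_spectrum(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotationally averaged Fourier amplitude per integer radial bin."""
    amp = np.abs(np.fft.fft2(image))
    bins = _radial_bins(image.shape)
    n = bins.max() + 1
    totals = np.bincount(bins.ravel(), weights=amp.ravel(), minlength=n)
    counts = np.bincount(bins.ravel(), minlength=n)
    return np.arange(n), totals / np.maximum(counts, 1)


def match_fourier_spectrum(synthetic: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Impose the reference's rotational amplitude spectrum, keep synthetic phases.

    Each Fourier coefficient is rescaled by the ratio of the reference to
    synthetic mean amplitude of its radial bin; the inverse transform is
    real by conjugate symmetry of the (real) inputs.
    """
    syn = np.asarray(synthetic, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if syn.shape != ref.shape:
        raise ValueError("synthetic and reference must share a shape")
    f_syn = np.fft.fft2(syn)
    bins = _radial_bins(syn.shape)
    n = bins.max() + 1
    amp_syn = np.bincount(bins.ravel(), weights=np.abs(f_syn).ravel(), minlength=n)
    amp_ref = np.bincount(
        bins.ravel(), weights=np.abs(np.fft.fft2(ref)).ravel(), minlength=n
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(amp_syn > 0, amp_ref / np.maximum(amp_syn, 1e-300), 0.0)
    out = np.fft.ifft2(f_syn * ratio[bins]).real
    return out


def region_error_report(
    synthetic: np.ndarray,
    real: np.ndarray,
    region_masks: dict[str, np.ndarray],
) -> dict[str, dict[str, float]]:
    """Relative mean/variance errors per scene region (cells, device, media).

    Regions must be pairwise disjoint.  Empty regions are reported as NaN
    with a warning rather than failing, since coarse hand-drawn masks may
    miss a region entirely.
    """
    names = list(region_masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.any(region_masks[a] & region_masks[b]):
                raise ValueError(f"region masks {a!r} and {b!r} overlap")
    report: dict[str, dict[str, float]] = {}
    for name, mask in region_masks.items():
        if not np.any(mask):
            warnings.warn(f"region {name!r} is empty", stacklevel=2)
            report[name] = {"mean_error": float("nan"), "variance_error": float("nan")}
            continue
        s = np.asarray(synthetic, dtype=float)[mask]
        r = np.asarray(real, dtype=float)[mask]
        mean_r, var_r = r.mean(), r.var()
        report[name] = {
            "mean_error": float((s.mean() - mean_r) / mean_r) if mean_r else float("inf"),
            "variance_error": float((s.var() - var_r) / var_r) if var_r else float("inf"),
        }
    return report
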