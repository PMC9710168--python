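"""Training-dataset generation: jittered image/ground-truth pairs.

Two mask dialects are produced, matching the two families of segmentation
trainers: ``binary_weightmap`` (binary non-touching masks plus a U-net
style border weightmap) and ``instances_tiled`` (labelled touching
instances, optionally tiled as multi-trench montages).  Optical and camera
parameters are jittered around their tuned values — mechanistic variation
of the image-formation process rather than post-hoc augmentation — while
the ground truth, derived from the physics alone, is pixel-identical across
jitters of the same frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .camera import CameraConfig, apply_camera
from .growth import SceneFrame
from .optics import PSFConfig, convolve_and_downsample, make_kernel, render_phase_contrast
from .render import OPLImage, RenderIntensities, render_opl

logger = logging.getLogger(__name__)

Dialect = Literal["binary_weightmap", "instances_tiled"]


@dataclass(frozen=True)
class JitterSpec:
    """Random perturbation of image-formation parameters.

    Each scalar in ``base`` is drawn within ±``half_width`` (relative) of
    its value, uniformly by default, or with that relative SD if gaussian.
    """

    base: dict[str, float]
    half_width: float = 0.05
    distribution: Literal["uniform", "gaussian"] = "uniform"

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half-width must be non-negative")
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass
class TrainingSample:
    """One exported image with its ground truth and provenance."""

    image: np.ndarray
    mask: np.ndarray
    weightmap: np.ndarray | None
    provenance: dict

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask must share a shape")


def jitter_parameters(spec: JitterSpec, rng: np.random.Generator) -> dict[str, float]:
    """Draw one jittered parameter set from the spec."""
    draw: dict[str, float] = {}
    for name, value in spec.base.items():
        if spec.half_width == 0:
            draw[name] = value
        elif spec.distribution == "uniform":
            draw[name] = value * rng.uniform(1.0 - spec.half_width, 1.0 + spec.half_width)
        else:
            draw[name] = value * (1.0 + rng.normal(0.0, spec.half_width))
    return draw


_STRUCT8 = np.ones((3, 3), dtype=bool)


def _touching_pairs(labels: np.ndarray) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    ids = np.unique(labels)
    ids = ids[ids != 0]
    for k in ids:
        ring = ndimage.binary_dilation(labels == k, _STRUCT8) & (labels != k) & (labels != 0)
        for other in np.unique(labels[ring]):
            pairs.add((min(k, other), max(k, other)))
    return pairs


def make_nontouching_masks(labels: np.ndarray) -> np.ndarray:
    """Binary mask with every instance separated by ≥1 background pixel.

    Labels that are 8-adjacent to another label are eroded one pixel at a
    time until no two foreground components touch; an instance eroded away
    entirely is dropped with a warning (pathological for realistic cells).
    """
    work = np.asarray(labels).copy()
    for _ in range(32):
        pairs = _touching_pairs(work)
        if not pairs:
            break
        involved = {k for pair in pairs for k in pair}
        for k in involved:
            mask_k = work == k
            eroded = ndimage.binary_erosion(mask_k, _STRUCT8)
            if not eroded.any():
                warnings.warn(f"label {k} vanished under erosion; dropped", stacklevel=2)
                work[mask_k] = 0
            else:
                work[mask_k & ~eroded] = 0
    return (work > 0).astype(np.uint8)


def make_weightmap(
    binary_mask: np.ndarray,
    w0: float = 10.0,
    sigma: float = 5.0,
    class_balance: bool = False,
) -> np.ndarray:
    """U-net border weightmap: emphasise narrow gaps between instances.

    w(x) = w_class(x) + w0·exp(−(d₁+d₂)²/(2σ²)) on background pixels, with
    d₁, d₂ the distances to the two nearest foreground components.  With
    fewer than two components the border term is identically zero.
    """
    fg = np.asarray(binary_mask) > 0
    labelled, n = ndimage.label(fg, structure=_STRUCT8)
    if class_balance and fg.any() and (~fg).any():
        w_fg = fg.size / (2.0 * fg.sum())
        w_bg = fg.size / (2.0 * (~fg).sum())
        w_class = np.where(fg, w_fg, w_bg)
    else:
        w_class = np.ones(fg.shape)
    if n < 2:
        return w_class.astype(float)
    dists = np.stack(
        [ndimage.distance_transform_edt(labelled != k) for k in range(1, n + 1)]
    )
    dists.sort(axis=0)
    d1, d2 = dists[0], dists[1]
    border = w0 * np.exp(-((d1 + d2) ** 2) / (2.0 * sigma**2))
    border[fg] = 0.0
    return (w_class + border).astype(float)


def tile_trenches(samples: list[TrainingSample], n_trenches: int) -> TrainingSample:
    """Horizontally concatenate trench crops into one multi-trench montage.

    Labels are re-indexed so every instance id is unique across the tile.
    """
    if n_trenches < 1 or n_trenches > len(samples):
        raise ValueError("n_trenches must be in [1, len(samples)]")
    chosen = samples[:n_trenches]
    heights = {s.image.shape[0] for s in chosen}
    if len(heights) != 1:
        raise ValueError(f"mixed sample heights {sorted(heights)}")
    images, masks = [], []
    offset = 0
    for s in chosen:
        m = s.mask.astype(np.int32).copy()
        ids = np.unique(m)
        ids = ids[ids != 0]
        remap = {old: offset + i + 1 for i, old in enumerate(ids)}
        out = np.zeros_like(m)
        for old, new in remap.items():
            out[m == old] = new
        offset += len(ids)
        images.append(s.image)
        masks.append(out)
    return TrainingSample(
        image=np.hstack(images),
        mask=np.hstack(masks),
        weightmap=None,
        provenance={"tiled_from": [s.provenance for s in chosen]},
    )


def _downsample_labels(labels: np.ndarray, factor: int) -> np.ndarray:
    """Per camera pixel, the label covering the largest share of the block."""
    if factor == 1:
        return labels.astype(np.int32)
    h = labels.shape[0] - labels.shape[0] % factor
    w = labels.shape[1] - labels.shape[1] % factor
    blocks = labels[:h, :w].reshape(h // factor, factor, w // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(h // factor, w // factor, -1)
    out = np.zeros(blocks.shape[:2], dtype=np.int32)
    ids = np.unique(labels)
    ids = ids[ids != 0]
    best = np.zeros(blocks.shape[:2], dtype=np.int64)
    for k in ids:
        cover = (blocks == k).sum(axis=-1)
        take = cover > best
        out[take] = k
        best[take] = cover[take]
    out[best * 2 < factor * factor] = 0  # background majority
    return out


@dataclass
class FrameImager:
    """Renders one simulation frame into a camera image under a parameter draw."""

    intensities: RenderIntensities = RenderIntensities()
    psf: PSFConfig = PSFConfig()
    cam: CameraConfig = CameraConfig()
    pixel_size: float = 0.065
    supersample_factor: int = 3

    def jitterable(self) -> dict[str, float]:
        return {
            "intensity_cell": self.intensities.cell,
            "intensity_trench": self.intensities.trench,
            "intensity_media": self.intensities.media,
            "apodisation_sigma": (
                self.psf.apodisation_sigma
                if np.isfinite(self.psf.apodisation_sigma)
                else 0.0
            ),
            "defocus": self.psf.defocus if self.psf.defocus else 0.0,
            "halo_offset": self.psf.halo_offset,
            "photon_scale": self.cam.photon_scale,
            "read_noise": self.cam.read_noise,
        }

    def with_draw(self, draw: dict[str, float]) -> "FrameImager":
        psf = self.psf
        if np.isfinite(psf.apodisation_sigma):
            psf = dc_replace(psf, apodisation_sigma=draw["apodisation_sigma"])
        psf = dc_replace(
            psf, defocus=draw.get("defocus", psf.defocus),
            halo_offset=draw.get("halo_offset", psf.halo_offset),
        )
        return FrameImager(
            intensities=RenderIntensities(
                cell=draw["intensity_cell"],
                trench=draw["intensity_trench"],
                media=draw["intensity_media"],
            ),
            psf=psf,
            cam=dc_replace(
                self.cam,
                photon_scale=draw["photon_scale"],
                read_noise=draw["read_noise"],
            ),
            pixel_size=self.pixel_size,
            supersample_factor=self.supersample_factor,
        )

    def render(self, frame: SceneFrame, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
        """Camera image (DN) and camera-resolution instance labels."""
        scene = render_opl(
            frame, self.intensities, self.pixel_size, self.supersample_factor
        )
        if self.psf.mode == "phase_contrast":
            optical = render_phase_contrast(scene, self.psf)
        else:
            optical = convolve_and_downsample(scene, make_kernel(self.psf))
        image = apply_camera(optical, self.cam, rng)
        labels = _downsample_labels(scene.labels, self.supersample_factor)
        return image, labels


def _save_array(arr: np.ndarray, path: Path) -> None:
    if path.suffix == ".png":
        Image.fromarray(arr).save(path)
    else:
        import tifffile

        tifffile.imwrite(path, arr)


def generate_dataset(
    n_samples: int,
    frames: list[SceneFrame],
    out_dir: str | Path,
    imager: FrameImager | None = None,
    jitter: JitterSpec | None = None,
    dialect: Dialect = "binary_weightmap",
    rng: np.random.Generator | None = None,
    cell_count_proportional: bool = False,
    weightmap_w0: float = 10.0,
    weightmap_sigma: float = 5.0,
) -> pd.DataFrame:
    """Write an image/ground-truth training set plus a manifest CSV.

    Frames are sampled with replacement; with ``cell_count_proportional``
    the sampling weight is inversely proportional to a frame's cell count,
    keeping the expected number of exported cells per image roughly
    constant across cell-size regimes (small-cell frames carry more cells
    each, so fewer of them are needed).
    """
    if not frames:
        raise ValueError("no frames supplied")
    imager = imager or FrameImager()
    rng = rng or np.random.default_rng(0)
    if jitter is None:
        jitter = JitterSpec(base=imager.jitterable())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = np.array([max(len(f.cells), 1) for f in frames], dtype=float)
    if cell_count_proportional:
        weights = 1.0 / counts
    else:
        weights = np.ones_like(counts)
    weights /= weights.sum()
    records = []
    for i in range(n_samples):
        frame_idx = int(rng.choice(len(frames), p=weights))
        draw = jitter_parameters(jitter, rng)
        image, labels = imager.with_draw(draw).render(frames[frame_idx], rng)
        img_path = out / f"{i:05d}_image.tif"
        _save_array(image.astype(np.uint16), img_path)
        record = {"sample": i, "frame": frame_idx, "image": img_path.name, **draw}
        if dialect == "binary_weightmap":
            binary = make_nontouching_masks(labels)
            wm = make_weightmap(binary, w0=weightmap_w0, sigma=weightmap_sigma)
            _save_array((binary * 255).astype(np.uint8), out / f"{i:05d}_mask.png")
            _save_array(wm.astype(np.float32), out / f"{i:05d}_weightmap.tif")
            record["mask"] = f"{i:05d}_mask.png"
            record["weightmap"] = f"{i:05d}_weightmap.tif"
        elif dialect == "instances_tiled":
            _save_array(labels.astype(np.uint16), out / f"{i:05d}_mask.png")
            record["mask"] = f"{i:05d}_mask.png"
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        records.append(record)
        logger.debug("exported sample %d from frame %d", i, frame_idx)
    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
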