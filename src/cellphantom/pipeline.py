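"""End-to-end orchestration: config file, pipeline runner, test fixtures.

One ``PipelineConfig`` describes biology, trench geometry, optics, camera
and export; ``run_pipeline`` executes simulate → render → optics → camera →
export with a single global seed propagated deterministically to every
stage (numpy ``SeedSequence`` spawning, so no stage consumes entropy
outside the seeded stream), and writes a JSON run log with per-stage
timings and every jittered parameter draw.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .camera import CameraConfig
from .evaluate import GrowthTrace
from .export import Dialect, FrameImager, JitterSpec, generate_dataset
from .growth import SimConfig, TrenchGeometry, run_simulation
from .optics import PSFConfig
from .render import RenderIntensities

logger = logging.getLogger("cellphantom")


def configure_logging(level: str = "INFO", json_lines: bool = False) -> None:
    """Structured (optionally JSON-lines) logging for pipeline runs."""
    handler = logging.StreamHandler()
    if json_lines:
        class _JsonFormatter(logging.Formatter):
            def format(self, record: logging.LogRecord) -> str:
                return json.dumps(
                    {
                        "time": self.formatTime(record),
                        "level": record.levelname,
                        "name": record.name,
                        "message": record.getMessage(),
                    }
                )

        handler.setFormatter(_JsonFormatter())
    else:
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("cellphantom")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


@dataclass
class PipelineConfig:
    """Every stage's parameters plus the global seed and output location."""

    sim: SimConfig = field(default_factory=SimConfig)
    geometry: TrenchGeometry = field(default_factory=TrenchGeometry)
    intensities: RenderIntensities = field(default_factory=RenderIntensities)
    psf: PSFConfig = field(default_factory=PSFConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    jitter_half_width: float = 0.05
    jitter_distribution: str = "uniform"
    dialect: Dialect = "binary_weightmap"
    n_samples: int = 100
    pixel_size: float = 0.065
    supersample_factor: int = 3
    out_dir: str = "dataset"
    seed: int = 0

    # -- (de)serialisation ---------------------------------------------------

    _SECTIONS = {
        "sim": SimConfig,
        "geometry": TrenchGeometry,
        "intensities": RenderIntensities,
        "psf": PSFConfig,
        "camera": CameraConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key, value in data.items():
            if key in cls._SECTIONS:
                kwargs[key] = cls._SECTIONS[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for section in self._SECTIONS:
            out[section] = {
                k: (None if isinstance(v, float) and not math.isfinite(v) else v)
                for k, v in out[section].items()
            }
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the run log (also written out).

    The returned dict records per-stage wall-clock timings, the simulation
    summary, the manifest path and every jittered parameter draw.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    run_log: dict = {"seed": config.seed, "stages": {}}

    t0 = time.perf_counter()
    sim_cfg = dataclasses.replace(config.sim, seed=int(seeds[0].generate_state(1)[0] % 2**31))
    try:
        result = run_simulation(sim_cfg, config.geometry)
    except Exception as exc:  # pragma: no cover - surfaced with stage name
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    result.events.to_csv(out / "events.csv", index=False)
    run_log["stages"]["simulate"] = {
        "seconds": time.perf_counter() - t0,
        "n_frames": len(result.frames),
        "n_events": len(result.events),
        "mass_balance_error": result.mass_balance_error(),
    }

    t0 = time.perf_counter()
    imager = FrameImager(
        intensities=config.intensities,
        psf=config.psf,
        cam=config.camera,
        pixel_size=config.pixel_size,
        supersample_factor=config.supersample_factor,
    )
    jitter = JitterSpec(
        base=imager.jitterable(),
        half_width=config.jitter_half_width,
        distribution=config.jitter_distribution,  # type: ignore[arg-type]
    )
    rng = np.random.default_rng(seeds[1])
    # skip the sparse burn-in frames: sample from the filled trench
    usable = [f for f in result.frames if f.cells] or result.frames
    try:
        manifest = generate_dataset(
            config.n_samples,
            usable,
            out,
            imager=imager,
            jitter=jitter,
            dialect=config.dialect,
            rng=rng,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'export' failed: {exc}") from exc
    run_log["stages"]["export"] = {
        "seconds": time.perf_counter() - t0,
        "n_samples": len(manifest),
        "manifest": str(out / "manifest.csv"),
    }
    run_log["parameter_draws"] = manifest.drop(
        columns=[c for c in ("image", "mask", "weightmap") if c in manifest], errors="ignore"
    ).to_dict(orient="records")
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=float))
    logger.info("pipeline complete: %d samples in %s", len(manifest), out)
    return run_log


# ---------------------------------------------------------------------------
# deterministic fixtures for the evaluation and camera test suites
# ---------------------------------------------------------------------------

def make_clean_trace(
    seed: int = 0, n_timepoints: int = 500, **sim_kwargs
) -> GrowthTrace:
    """A mother-cell sawtooth straight from the simulator's event loop."""
    cfg = SimConfig(seed=seed, n_timepoints=n_timepoints, **sim_kwargs)
    result = run_simulation(cfg)
    t, l = result.mother_trace()
    keep = np.isfinite(l)
    return GrowthTrace(0, t[keep], l[keep])


def make_error_trace(
    epsilon: float, seed: int = 0, n_timepoints: int = 500, dip: float = 0.8
) -> GrowthTrace:
    """Clean sawtooth with ``round(ε·n)`` injected one-frame length dips.

    Dips multiply the length by ``dip`` (default 0.8 — well outside the
    division-halving band) at non-adjacent timepoints away from divisions,
    so the expected identification-error rate is exactly ε.
    """
    trace = make_clean_trace(seed=seed, n_timepoints=n_timepoints)
    n = trace.length.size
    k = int(round(epsilon * n))
    l = trace.length.copy()
    # candidate timepoints: interior, not adjacent to a division drop
    ratio_prev = l[1:] / l[:-1]
    division_at = set(np.nonzero(ratio_prev < 0.8)[0] + 1)
    rng = np.random.default_rng(seed + 1)
    chosen: list[int] = []
    candidates = list(range(2, n - 2))
    rng.shuffle(candidates)
    for t in candidates:
        if len(chosen) == k:
            break
        if any(abs(t - c) <= 2 for c in chosen):
            continue
        if any(abs(t - d) <= 2 for d in division_at):
            continue
        chosen.append(t)
    if len(chosen) < k:
        raise RuntimeError("could not place all injected errors non-adjacently")
    for t in chosen:
        l[t] *= dip
    return GrowthTrace(trace.trench_id, trace.t, l)


def make_blob_probmap(
    seed: int = 0, shape: tuple[int, int] = (64, 64), separation: float = 18.0
) -> np.ndarray:
    """Two Gaussian blobs merged at moderate thresholds, separate at high ones."""
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    c1 = (h / 2 - separation / 2, w / 2)
    c2 = (h / 2 + separation / 2, w / 2)
    sigma = separation / 2.9  # valley ≈ 0.7·peak: merged at 0.5, split at 0.95
    blob = np.exp(-((yy - c1[0]) ** 2 + (xx - c1[1]) ** 2) / (2 * sigma**2))
    blob += np.exp(-((yy - c2[0]) ** 2 + (xx - c2[1]) ** 2) / (2 * sigma**2))
    blob += rng.normal(0, 1e-4, size=shape)
    blob -= blob.min()
    return np.clip(blob / blob.max(), 0.0, 1.0)


def make_flatfield_stack(
    seed: int = 0,
    levels: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0),
    shape: tuple[int, int] = (320, 320),
    camera: CameraConfig | None = None,
) -> list[np.ndarray]:
    """Uniform illumination frames at several levels, through the camera model."""
    from .camera import apply_camera

    camera = camera or CameraConfig()
    rng = np.random.default_rng(seed)
    return [
        apply_camera(np.full(shape, level), camera, rng) for level in levels
    ]


def make_fixtures(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write deterministic small test inputs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    if kind == "clean_trace":
        trace = make_clean_trace(seed=seed)
        p = out / "clean_trace.csv"
        np.savetxt(p, np.column_stack([trace.t, trace.length]), delimiter=",",
                   header="t,length", comments="")
        paths.append(p)
    elif kind == "error_trace":
        trace = make_error_trace(0.01, seed=seed)
        p = out / "error_trace.csv"
        np.savetxt(p, np.column_stack([trace.t, trace.length]), delimiter=",",
                   header="t,length", comments="")
        paths.append(p)
    elif kind == "blob_probmap":
        import tifffile

        p = out / "blob_probmap.tif"
        tifffile.imwrite(p, make_blob_probmap(seed=seed).astype(np.float32))
        paths.append(p)
    elif kind == "flatfield_stack":
        import tifffile

        for i, frame in enumerate(make_flatfield_stack(seed=seed)):
            p = out / f"flatfield_{i}.tif"
            tifffile.imwrite(p, frame)
            paths.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return paths
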