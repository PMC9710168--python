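"""Label-free evaluation statistics and mask post-processing.

A mother cell's length over time traces a sawtooth: exponential rise, then
an ≈2× drop at each division.  Over- and under-segmentation show up as
spurious peaks in the first derivative of that trace — one-frame dips or
spikes that are not compatible with a division — so the fraction of
affected timepoints is a ground-truth-free error statistic usable on real
data.  The module also provides Jaccard-optimal probability thresholding,
seeded watershed splitting of merged masks, segmentation precision from
stationary-phase residuals, and principal-axis mask geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .growth import TrenchGeometry


@dataclass
class GrowthTrace:
    """Mother-cell (closed-end) length time series of one trench."""

    trench_id: int
    t: np.ndarray
    length: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t)
        self.length = np.asarray(self.length, dtype=float)
        if self.t.shape != self.length.shape:
            raise ValueError("time and length arrays must match")
        if np.any(self.length[np.isfinite(self.length)] <= 0):
            raise ValueError("lengths must be positive")


@dataclass
class EvalReport:
    """Summary statistics of one evaluation run."""

    identification_error_rate: float | None = None
    optimal_threshold: float | None = None
    precision_length: float | None = None
    precision_width: float | None = None

    def as_dict(self) -> dict:
        return {
            "identification_error_rate": self.identification_error_rate,
            "optimal_threshold": self.optimal_threshold,
            "precision_length": self.precision_length,
            "precision_width": self.precision_width,
        }


# ---------------------------------------------------------------------------
# trace extraction and the sawtooth statistic
# ---------------------------------------------------------------------------

def mask_geometry(labels: np.ndarray) -> dict[int, tuple[float, float]]:
    """Per-label (length, width) in pixels via principal-axis extents.

    Length is the extent of the pixel cloud along its major principal axis;
    width is the mean lateral extent over the cylindrical mid-section
    (middle half of the major axis), which excludes the tapering poles.
    Single-pixel labels are flagged with a warning and reported as (1, 1).
    """
    out: dict[int, tuple[float, float]] = {}
    for k in np.unique(labels):
        if k == 0:
            continue
        ys, xs = np.nonzero(labels == k)
        if ys.size == 1:
            warnings.warn(f"label {k} is a single pixel", stacklevel=2)
            out[int(k)] = (1.0, 1.0)
            continue
        coords = np.column_stack([ys, xs]).astype(float)
        centred = coords - coords.mean(axis=0)
        cov = centred.T @ centred / len(centred)
        evals, evecs = np.linalg.eigh(cov)
        major, minor = evecs[:, 1], evecs[:, 0]
        s = centred @ major
        p = centred @ minor
        length = s.max() - s.min() + 1.0
        half = (s.max() - s.min()) / 2.0
        mid = np.abs(s) <= half / 2.0  # middle half of the axial extent
        if not mid.any():
            mid = np.ones_like(s, dtype=bool)
        # mean lateral extent over axial bins of the mid-section
        bins = np.rint(s[mid]).astype(int)
        widths = [
            p[mid][bins == b].max() - p[mid][bins == b].min() + 1.0
            for b in np.unique(bins)
        ]
        out[int(k)] = (float(length), float(np.mean(widths)))
    return out


def extract_mother_trace(
    label_stack: list[np.ndarray] | np.ndarray,
    geometry: TrenchGeometry | None = None,
    trench_id: int = 0,
) -> GrowthTrace:
    """Length of the cell nearest the closed end (row 0) at each timepoint.

    Empty frames are marked NaN (a gap); no interpolation is performed.
    """
    times, lengths = [], []
    for t, labels in enumerate(label_stack):
        times.append(t)
        ids = np.unique(labels)
        ids = ids[ids != 0]
        if ids.size == 0:
            lengths.append(np.nan)
            continue
        # nearest the closed end: smallest centroid row
        centroids = ndimage.center_of_mass(labels > 0, labels, ids)
        mother = ids[int(np.argmin([c[0] for c in centroids]))]
        geom = mask_geometry(np.where(labels == mother, labels, 0))
        lengths.append(geom[int(mother)][0])
    return GrowthTrace(trench_id, np.array(times), np.array(lengths))


def identification_error(
    trace: GrowthTrace,
    division_ratio: tuple[float, float] = (0.4, 0.6),
    min_change: float = 0.05,
) -> float:
    """Fraction of timepoints carrying a spurious (non-division) length peak.

    The first derivative of the sawtooth is scanned for one-frame
    decrease-then-increase or increase-then-decrease events whose relative
    size exceeds ``min_change``.  A decrease is division-compatible — and
    hence not an error — when the post/pre length ratio falls inside
    ``division_ratio`` (≈ halving).
    """
    l = np.asarray(trace.length, dtype=float)
    n = l.size
    if n < 3:
        raise ValueError("trace too short (need >= 3 timepoints)")
    lo, hi = division_ratio
    flagged = np.zeros(n, dtype=bool)
    for t in range(1, n - 1):
        if not (np.isfinite(l[t - 1]) and np.isfinite(l[t]) and np.isfinite(l[t + 1])):
            continue
        d1 = l[t] - l[t - 1]
        d2 = l[t + 1] - l[t]
        if d1 == 0 or d2 == 0 or np.sign(d1) == np.sign(d2):
            continue
        if abs(d1) / l[t - 1] < min_change or abs(d2) / l[t] < min_change:
            continue
        # sharp reversal; excuse it if either leg is a division-like halving
        drop_in = lo <= l[t] / l[t - 1] <= hi and d1 < 0
        drop_out = lo <= l[t + 1] / l[t] <= hi and d2 < 0
        if drop_in or drop_out:
            continue
        flagged[t] = True
    return float(flagged.sum()) / n


# ---------------------------------------------------------------------------
# threshold optimisation and watershed post-processing
# ---------------------------------------------------------------------------

def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum()) / float(union)


def _distribution_intersection(
    pred_labels: np.ndarray, true_labels: np.ndarray, bins: int = 50
) -> float:
    """Cumulative intersection of length and width histograms, in [0, 2]."""
    geom_p = list(mask_geometry(pred_labels).values())
    geom_t = list(mask_geometry(true_labels).values())
    if not geom_p or not geom_t:
        return 0.0
    total = 0.0
    for axis in (0, 1):
        vals_p = np.array([g[axis] for g in geom_p])
        vals_t = np.array([g[axis] for g in geom_t])
        lo = min(vals_p.min(), vals_t.min())
        hi = max(vals_p.max(), vals_t.max())
        edges = np.linspace(lo, hi + 1e-9, bins + 1)
        h_p, _ = np.histogram(vals_p, bins=edges, density=False)
        h_t, _ = np.histogram(vals_t, bins=edges, density=False)
        h_p = h_p / max(h_p.sum(), 1)
        h_t = h_t / max(h_t.sum(), 1)
        total += float(np.minimum(h_p, h_t).sum())
    return total


@dataclass
class ThresholdResult:
    """Outcome of the probability-threshold grid search."""

    threshold: float
    grid: np.ndarray
    jaccard: np.ndarray
    distribution_intersection: np.ndarray | None = None

    @property
    def curve(self) -> np.ndarray:
        return np.column_stack([self.grid, self.jaccard])


def optimal_threshold(
    probability_maps: list[np.ndarray] | np.ndarray,
    truth_labels: list[np.ndarray] | np.ndarray,
    grid: np.ndarray | None = None,
    with_distribution_statistic: bool = False,
) -> ThresholdResult:
    """Grid-search the probability threshold maximising the mean Jaccard index.

    Ties are broken towards the lowest threshold.  Optionally also computes
    the alternative statistic: the cumulative intersection of cell length
    and width histograms between the thresholded and true masks.
    """
    if isinstance(probability_maps, np.ndarray) and probability_maps.ndim == 2:
        probability_maps = [probability_maps]
    if isinstance(truth_labels, np.ndarray) and truth_labels.ndim == 2:
        truth_labels = [truth_labels]
    maps = [np.asarray(m, dtype=float) for m in probability_maps]
    truths = [np.asarray(t) for t in truth_labels]
    for m in maps:
        if m.min() < 0 or m.max() > 1:
            raise ValueError("probability maps must lie in [0, 1]")
    if all(m.max() == 0 for m in maps):
        raise ValueError("all-zero probability map: no foreground at any threshold")
    if grid is None:
        grid = np.arange(0.50, 0.9951, 0.005)
    jac = np.zeros(grid.size)
    dist = np.zeros(grid.size) if with_distribution_statistic else None
    for i, thr in enumerate(grid):
        scores, dscores = [], []
        for m, truth in zip(maps, truths):
            pred = m > thr
            scores.append(_jaccard(pred, truth > 0))
            if with_distribution_statistic:
                pred_lab, _ = ndimage.label(pred)
                dscores.append(_distribution_intersection(pred_lab, truth))
        jac[i] = np.mean(scores)
        if dist is not None:
            dist[i] = np.mean(dscores)
    best = int(np.argmax(jac))  # argmax returns the first (lowest) maximiser
    return ThresholdResult(float(grid[best]), grid, jac, dist)


def seeded_watershed(
    probability_map: np.ndarray, t_opt: float, t_seed: float = 0.999
) -> np.ndarray:
    """Split merged masks: watershed seeded at very-high-probability cores.

    Seeds are the connected components of ``map > t_seed``; the watershed
    floods the inverted probability map restricted to ``map > t_opt``, so
    the output labels partition the optimal-threshold foreground and every
    component contains at least one seed.
    """
    pmap = np.asarray(probability_map, dtype=float)
    if not 0.0 < t_opt < t_seed < 1.0:
        raise ValueError("need 0 < t_opt < t_seed < 1")
    seeds, n = ndimage.label(pmap > t_seed)
    if n == 0:
        warnings.warn("no seeds above t_seed; returning empty labelling", stacklevel=2)
        return np.zeros_like(pmap, dtype=np.int32)
    return watershed(-pmap, markers=seeds, mask=pmap > t_opt).astype(np.int32)


# ---------------------------------------------------------------------------
# precision from stationary-phase traces
# ---------------------------------------------------------------------------

def precision_from_stationary(segments: list[np.ndarray]) -> float:
    """Segmentation precision: SD of residuals around per-segment quadratics.

    In deep stationary phase a cell's true length is essentially constant
    (slow drift at most), so a quadratic absorbs the trend and the residual
    scatter is measurement noise.  Segments shorter than 4 points cannot
    constrain a quadratic and are skipped with a warning.
    """
    residuals = []
    for seg in segments:
        y = np.asarray(seg, dtype=float)
        if y.size < 4:
            warnings.warn(f"segment of length {y.size} skipped", stacklevel=2)
            continue
        x = np.arange(y.size, dtype=float)
        coef = np.polynomial.polynomial.polyfit(x, y, 2)
        residuals.append(y - np.polynomial.polynomial.polyval(x, coef))
    if not residuals:
        raise ValueError("no segment long enough for a quadratic fit")
    pooled = np.concatenate(residuals)
    return float(pooled.std(ddof=3))
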