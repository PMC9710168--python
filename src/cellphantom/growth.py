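"""Agent-based growth simulation of a mother-machine linear colony.

Rod-shaped cells (spherocylinders) grow exponentially inside a dead-end
microfluidic trench, divide under one of three size-regulation strategies
(adder / sizer / timer), may lyse stochastically, and are pushed along the
trench axis by rigid-body contact until they wash out of the open end.

Conventions
-----------
* Lengths in micrometres, time in minutes.
* Trench coordinates: origin at the closed end, ``x`` along the trench axis
  (increasing towards the open end), ``y`` lateral with 0 on the centreline.
* A cell of length ``l`` centred at ``x`` occupies the axial interval
  ``[x - l/2, x + l/2]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

#: default maximum tolerated pairwise axial overlap after collision
#: resolution, in micrometres
OVERLAP_TOLERANCE = 0.01

RegulationMode = Literal["adder", "sizer", "timer"]


class GeometryError(ValueError):
    """Configuration incompatible with the trench geometry."""


class SimulationError(RuntimeError):
    """The physics state could not be brought back to a valid configuration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CellAgent:
    """One bacterium's geometric and physiological state.

    ``division_threshold`` is interpreted according to the regulation mode:
    added length (adder, μm), absolute division length (sizer, μm) or age at
    division (timer, minutes).  It is drawn once at birth.
    """

    id: int
    parent_id: int | None
    length: float
    width: float
    x: float
    y: float = 0.0
    angle: float = 0.0
    age: float = 0.0
    birth_length: float = 0.0
    division_threshold: float = 0.0
    bend_amplitude: float = 0.0
    alive: bool = True
    fluorescence: float = 1.0  # hook for expression models; no dynamics here

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def x_lo(self) -> float:
        return self.x - self.length / 2.0

    @property
    def x_hi(self) -> float:
        return self.x + self.length / 2.0

    def __post_init__(self) -> None:
        if self.length < self.width - 1e-9:
            raise ValueError(
                f"spherocylinder length {self.length} < cap diameter {self.width}"
            )
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class TrenchGeometry:
    """A dead-end mother-machine trench: closed at x=0, open at x=length."""

    length: float = 40.0
    width: float = 1.4
    wall_thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0 or self.wall_thickness <= 0:
            raise GeometryError("trench dimensions must be positive")

    @property
    def closed_end(self) -> float:
        return 0.0

    @property
    def open_end(self) -> float:
        return self.length


@dataclass(frozen=True)
class SimConfig:
    """Biological parameters of one simulation run.

    Division-length statistics set the sizer threshold directly; in adder
    mode the per-cell added length defaults to half the division length
    (steady state then divides at the configured mean), and in timer mode
    the interdivision time defaults to the doubling time ln2/λ.
    """

    regulation_mode: RegulationMode = "adder"
    div_length_mean: float = 4.0
    div_length_sd: float = 0.3
    width_mean: float = 1.0
    width_sd: float = 0.05
    growth_rate: float = math.log(2) / 23.0  # 1/min; 23 min doubling time
    dt: float = 1.0
    p_lyse: float = 0.0
    seed: int = 0
    n_timepoints: int = 100
    septum_gap: float = 0.1
    division_asymmetry: float = 0.5
    bend_sigma: float = 0.0  # half-normal scale of per-cell bend amplitude
    adder_delta_mean: float | None = None
    adder_delta_sd: float | None = None
    timer_tau_mean: float | None = None
    timer_tau_sd: float | None = None

    def __post_init__(self) -> None:
        if self.regulation_mode not in ("adder", "sizer", "timer"):
            raise ValueError(f"unknown regulation mode {self.regulation_mode!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.p_lyse <= 1.0:
            raise ValueError("p_lyse must lie in [0, 1]")
        if self.div_length_sd < 0 or self.width_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 < self.division_asymmetry < 1.0:
            raise ValueError("division asymmetry must lie in (0, 1)")

    @property
    def delta_mean(self) -> float:
        return (
            self.adder_delta_mean
            if self.adder_delta_mean is not None
            else self.div_length_mean / 2.0
        )

    @property
    def delta_sd(self) -> float:
        return (
            self.adder_delta_sd
            if self.adder_delta_sd is not None
            else self.div_length_sd
        )

    @property
    def tau_mean(self) -> float:
        """Steady-state-preserving timer period.

        A daughter of birth length ℓ needs exp(λτ)·ℓ = 2ℓ + septum_gap for
        its own daughters to be born at ℓ again; the plain doubling time
        ln2/λ would lose the septum gap every generation and sizes would
        drift to the minimum-size floor (timer mode has no size feedback to
        absorb it).
        """
        if self.timer_tau_mean is not None:
            return self.timer_tau_mean
        typical_birth = self.div_length_mean / 2.0
        return math.log(2.0 + self.septum_gap / typical_birth) / self.growth_rate

    @property
    def tau_sd(self) -> float:
        return self.timer_tau_sd if self.timer_tau_sd is not None else 1.0


@dataclass
class SceneFrame:
    """Static trench geometry plus every cell's state at one timepoint."""

    timepoint: int
    cells: list[CellAgent]
    geometry: TrenchGeometry

    def mother(self) -> CellAgent | None:
        """The cell nearest the closed end, or None if the trench is empty."""
        if not self.cells:
            return None
        return min(self.cells, key=lambda c: c.x)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    """Normal draw rejected until it exceeds ``lower`` (clipped as last resort)."""
    if sd == 0:
        return max(mean, lower)
    for _ in range(1000):
        draw = rng.normal(mean, sd)
        if draw > lower:
            return draw
    return lower + abs(rng.normal(0.0, sd))


def _draw_threshold(config: SimConfig, rng: np.random.Generator, width: float) -> float:
    mode = config.regulation_mode
    if mode == "adder":
        return _truncated_normal(rng, config.delta_mean, config.delta_sd, 1e-3)
    if mode == "sizer":
        # division length must exceed the cap diameter 2r
        return _truncated_normal(rng, config.div_length_mean, config.div_length_sd, width)
    return _truncated_normal(rng, config.tau_mean, config.tau_sd, 0.0)


def _draw_width(config: SimConfig, geometry: TrenchGeometry, rng: np.random.Generator) -> float:
    lower = 0.2
    w = _truncated_normal(rng, config.width_mean, config.width_sd, lower)
    return min(w, geometry.width)


def _draw_bend(config: SimConfig, rng: np.random.Generator) -> float:
    if config.bend_sigma <= 0:
        return 0.0
    return abs(rng.normal(0.0, config.bend_sigma))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def init_scene(
    config: SimConfig, geometry: TrenchGeometry, rng: np.random.Generator | None = None
) -> SceneFrame:
    """Frame 0: a single founder cell resting against the closed end.

    The founder's length is drawn uniformly between its cap diameter and its
    division threshold so that lineages started from different seeds sit at
    random phases of the division cycle.
    """
    if config.width_mean > geometry.width:
        raise GeometryError(
            f"mean cell width {config.width_mean} exceeds trench width {geometry.width}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    width = _draw_width(config, geometry, rng)
    threshold = _draw_threshold(config, rng, width)
    if config.regulation_mode == "sizer":
        hi = threshold
    else:
        hi = max(config.div_length_mean, width * 1.05)
    length = rng.uniform(width, max(hi, width * 1.05))
    founder = CellAgent(
        id=1,
        parent_id=None,
        length=length,
        width=width,
        x=length / 2.0,
        birth_length=length,
        division_threshold=threshold,
        bend_amplitude=_draw_bend(config, rng),
    )
    return SceneFrame(timepoint=0, cells=[founder], geometry=geometry)


def grow_cell(cell: CellAgent, rate: float, dt: float) -> CellAgent:
    """Exponential single-cell elongation: l' = l·exp(λ·dt); width fixed."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if not cell.alive:
        raise ValueError("cannot grow a dead cell")
    return replace(cell, length=cell.length * math.exp(rate * dt), age=cell.age + dt)


def _division_due(cell: CellAgent, mode: RegulationMode) -> bool:
    if mode == "adder":
        return cell.length - cell.birth_length >= cell.division_threshold
    if mode == "sizer":
        return cell.length >= cell.division_threshold
    if mode == "timer":
        return cell.age >= cell.division_threshold
    raise ValueError(f"unknown regulation mode {mode!r}")


def maybe_divide(
    cell: CellAgent,
    config: SimConfig,
    rng: np.random.Generator,
    next_id: int,
    geometry: TrenchGeometry | None = None,
) -> list[CellAgent]:
    """Return ``[cell]`` or two daughters if the regulation rule fires.

    Daughters split the mother's length minus a septum gap according to the
    configured asymmetry ratio (proximal daughter keeps the closed-end side),
    receive fresh ids, widths, thresholds and bend amplitudes, and start at
    age 0 with ``birth_length`` equal to their initial length.
    """
    if not cell.alive:
        raise ValueError("cannot divide a dead cell")
    if not _division_due(cell, config.regulation_mode):
        return [cell]
    geometry = geometry or TrenchGeometry()
    usable = cell.length - config.septum_gap
    if usable < 0.4:  # too short to form two viable daughters; retry later
        return [cell]
    # timer mode: carry the discrete-step overshoot (age past threshold at
    # the frame where division fires) into the daughters, otherwise every
    # cycle is inflated by up to dt and sizes drift systematically downward
    if config.regulation_mode == "timer":
        birth_age = max(cell.age - cell.division_threshold, 0.0)
    else:
        birth_age = 0.0
    a = config.division_asymmetry
    l1 = usable * a
    l2 = usable * (1.0 - a)
    daughters = []
    for k, (l_d, x_d) in enumerate(
        [(l1, cell.x_lo + l1 / 2.0), (l2, cell.x_hi - l2 / 2.0)]
    ):
        w = min(_draw_width(config, geometry, rng), l_d)  # keep l >= 2r
        daughters.append(
            CellAgent(
                id=next_id + k,
                parent_id=cell.id,
                length=l_d,
                width=w,
                x=x_d,
                y=cell.y,
                age=birth_age,
                birth_length=l_d,
                division_threshold=_draw_threshold(config, rng, w),
                bend_amplitude=_draw_bend(config, rng),
            )
        )
    return daughters


def resolve_collisions(
    frame: SceneFrame, tolerance: float = OVERLAP_TOLERANCE
) -> tuple[SceneFrame, list[CellAgent]]:
    """Push overlapping cells towards the open end; wash out those that exit.

    Cells are quasi-1-D in a mother-machine trench, so contacts are resolved
    by a single sweep along the axis from the closed end: each cell is
    displaced outward just enough to clear the closed-end wall and the cell
    before it.  The sweep preserves axial ordering, is exact (residual
    overlap 0 ≤ tolerance) and cannot fail to converge.  Cells whose
    centroid crosses the open end are removed and returned separately.
    """
    ordered = sorted(frame.cells, key=lambda c: c.x)
    resolved: list[CellAgent] = []
    washed: list[CellAgent] = []
    frontier = frame.geometry.closed_end
    for cell in ordered:
        if cell.x_lo < frontier:
            cell = replace(cell, x=frontier + cell.length / 2.0)
        frontier = cell.x_hi
        if cell.x > frame.geometry.open_end:
            washed.append(cell)
        else:
            resolved.append(cell)
    return SceneFrame(frame.timepoint, resolved, frame.geometry), washed


@dataclass
class SimulationResult:
    """Frames, the event log and the mass-audit accumulators of one run."""

    frames: list[SceneFrame]
    events: pd.DataFrame
    config: SimConfig
    geometry: TrenchGeometry
    total_grown: float = 0.0
    total_septum_loss: float = 0.0
    lysed_length: float = 0.0
    washed_length: float = 0.0
    founder_length: float = 0.0

    def mother_trace(self) -> tuple[np.ndarray, np.ndarray]:
        """Time indices and mother-cell (closed-end) lengths; NaN when empty."""
        t = np.array([f.timepoint for f in self.frames])
        l = np.array(
            [f.mother().length if f.mother() else np.nan for f in self.frames]
        )
        return t, l

    def mass_balance_error(self) -> float:
        """|growth input − accounted output|; ≈0 when the audit closes."""
        final = sum(c.length for c in self.frames[-1].cells)
        lhs = self.founder_length + self.total_grown - self.total_septum_loss
        rhs = final + self.lysed_length + self.washed_length
        return abs(lhs - rhs)


class _EventLog:
    COLUMNS = ["t", "id", "parent_id", "event", "l", "x"]

    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def add(self, t: int, cell: CellAgent, event: str) -> None:
        self.rows.append(
            (t, cell.id, cell.parent_id, event, round(cell.length, 9), round(cell.x, 9))
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.COLUMNS)


def step(
    frame: SceneFrame,
    config: SimConfig,
    rng: np.random.Generator,
    id_counter: list[int] | None = None,
    log: _EventLog | None = None,
    result: SimulationResult | None = None,
) -> SceneFrame:
    """One event-loop iteration: grow, divide, lyse, resolve contacts.

    ``id_counter`` is a single-element mutable list holding the next free
    cell id; ``log`` and ``result`` accumulate events and audit totals.
    """
    if id_counter is None:
        id_counter = [max((c.id for c in frame.cells), default=0) + 1]
    t_next = frame.timepoint + 1
    cells: list[CellAgent] = []
    for cell in frame.cells:
        grown = grow_cell(cell, config.growth_rate, config.dt)
        if result is not None:
            result.total_grown += grown.length - cell.length
        offspring = maybe_divide(grown, config, rng, id_counter[0], frame.geometry)
        if len(offspring) == 2:
            id_counter[0] += 2
            if log is not None:
                log.add(t_next, grown, "division")
                for d in offspring:
                    log.add(t_next, d, "birth")
            if result is not None:
                result.total_septum_loss += grown.length - sum(
                    d.length for d in offspring
                )
        for d in offspring:
            if config.p_lyse > 0 and rng.random() < config.p_lyse:
                if log is not None:
                    log.add(t_next, d, "lysis")
                if result is not None:
                    result.lysed_length += d.length
                continue
            cells.append(d)
    interim = SceneFrame(t_next, cells, frame.geometry)
    resolved, washed = resolve_collisions(interim)
    for cell in washed:
        if log is not None:
            log.add(t_next, cell, "washout")
        if result is not None:
            result.washed_length += cell.length
    return resolved


def run_simulation(
    config: SimConfig, geometry: TrenchGeometry | None = None
) -> SimulationResult:
    """Run the full event loop; reproducible bit-for-bit under a fixed seed."""
    geometry = geometry or TrenchGeometry()
    rng = np.random.default_rng(config.seed)
    frame = init_scene(config, geometry, rng)
    log = _EventLog()
    log.add(0, frame.cells[0], "birth")
    result = SimulationResult(
        frames=[frame],
        events=pd.DataFrame(),
        config=config,
        geometry=geometry,
        founder_length=frame.cells[0].length,
    )
    id_counter = [2]
    for _ in range(config.n_timepoints):
        frame = step(frame, config, rng, id_counter, log, result)
        result.frames.append(frame)
    result.events = log.frame()
    return result


def cell_volume(length: float, radius: float) -> float:
    """Spherocylinder volume V = πr²(l − 2r/3).

    Equivalent to cylinder + two hemispherical caps:
    πr²(l − 2r) + 4πr³/3.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if length < 2 * radius - 1e-12:
        raise ValueError(f"length {length} shorter than cap diameter {2 * radius}")
    return math.pi * radius**2 * (length - 2.0 * radius / 3.0)


# ---------------------------------------------------------------------------
# validation helpers (used by tests and the pipeline's invariant sweep)
# ---------------------------------------------------------------------------

def frame_violations(
    frame: SceneFrame, tolerance: float = OVERLAP_TOLERANCE
) -> list[str]:
    """List invariant violations of a frame (empty list when valid)."""
    out: list[str] = []
    ordered = sorted(frame.cells, key=lambda c: c.x)
    for a, b in zip(ordered, ordered[1:]):
        overlap = a.x_hi - b.x_lo
        if overlap > tolerance:
            out.append(f"t={frame.timepoint}: cells {a.id},{b.id} overlap {overlap:.4f} μm")
    for c in ordered:
        if c.x_lo < frame.geometry.closed_end - tolerance:
            out.append(f"t={frame.timepoint}: cell {c.id} through closed end")
        if abs(c.y) + c.radius > frame.geometry.width / 2.0 + tolerance:
            out.append(f"t={frame.timepoint}: cell {c.id} through side wall")
        if c.length < c.width - 1e-9:
            out.append(f"t={frame.timepoint}: cell {c.id} shorter than its diameter")
    return out


def lineage_table(events: pd.DataFrame) -> pd.DataFrame:
    """Per completed division: birth length, division length, interdivision time.

    Joins each cell's birth event with its division event; cells that never
    divided (washed out, lysed, or alive at the end) are excluded.
    """
    births = events[events.event == "birth"].set_index("id")
    divisions = events[events.event == "division"].set_index("id")
    joined = births.join(divisions, how="inner", lsuffix="_birth", rsuffix="_div")
    return pd.DataFrame(
        {
            "birth_length": joined["l_birth"],
            "division_length": joined["l_div"],
            "added_length": joined["l_div"] - joined["l_birth"],
            "interdivision_time": joined["t_div"] - joined["t_birth"],
        }
    )
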