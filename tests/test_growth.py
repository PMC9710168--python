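"""Growth-simulation physics: determinism, division rules, confinement."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from cellphantom import (
    CellAgent,
    SceneFrame,
    SimConfig,
    TrenchGeometry,
    cell_volume,
    grow_cell,
    init_scene,
    lineage_table,
    maybe_divide,
    resolve_collisions,
    run_simulation,
    step,
)
from cellphantom.growth import GeometryError, frame_violations


def spherocylinder_volume_numeric(length, radius):
    """Independent oracle: integrate the cross-section area along the axis."""
    a = length / 2.0 - radius

    def area(u):
        if abs(u) <= a:
            return math.pi * radius**2
        return math.pi * max(radius**2 - (abs(u) - a) ** 2, 0.0)

    val, _ = quad(area, -length / 2.0, length / 2.0, limit=200)
    return val


class TestInitScene:
    def test_fixed_seed_reproduces_founder(self):
        a = init_scene(SimConfig(seed=1), TrenchGeometry())
        b = init_scene(SimConfig(seed=1), TrenchGeometry())
        assert a.cells[0] == b.cells[0]

    def test_founder_rests_at_closed_end(self):
        frame = init_scene(SimConfig(seed=4), TrenchGeometry(length=20.0))
        founder = frame.cells[0]
        assert founder.x_lo >= 0.0
        assert founder.radius <= founder.x <= founder.division_threshold + founder.length

    def test_cell_wider_than_trench_is_rejected(self):
        with pytest.raises(GeometryError):
            init_scene(SimConfig(width_mean=2.0), TrenchGeometry(width=1.0))


class TestGrowCell:
    @pytest.fixture()
    def cell(self):
        return CellAgent(id=1, parent_id=None, length=2.0, width=1.0, x=1.0,
                         birth_length=2.0, division_threshold=4.0)

    def test_one_doubling(self, cell):
        grown = grow_cell(cell, math.log(2), 1.0)
        assert grown.length == pytest.approx(4.0)
        assert grown.width == cell.width

    def test_zero_dt_is_identity(self, cell):
        assert grow_cell(cell, 0.5, 0.0) == cell

    def test_zero_rate_only_ages(self, cell):
        grown = grow_cell(cell, 0.0, 3.0)
        assert grown.length == cell.length
        assert grown.age == cell.age + 3.0

    def test_negative_dt_rejected(self, cell):
        with pytest.raises(ValueError):
            grow_cell(cell, 0.5, -1.0)


class TestMaybeDivide:
    def test_sizer_past_threshold_splits_symmetrically(self, rng):
        cell = CellAgent(id=1, parent_id=None, length=4.01, width=1.0, x=3.0,
                         birth_length=2.0, division_threshold=4.0)
        cfg = SimConfig(regulation_mode="sizer", div_length_sd=0.0, width_sd=0.0)
        daughters = maybe_divide(cell, cfg, rng, next_id=2)
        assert len(daughters) == 2
        for d in daughters:
            assert 1.9 <= d.length <= 2.1
            assert d.parent_id == 1
            assert d.age == 0.0
            assert d.birth_length == d.length

    def test_adder_below_added_length_keeps_cell(self, rng):
        cell = CellAgent(id=1, parent_id=None, length=3.5, width=1.0, x=2.0,
                         birth_length=2.0, division_threshold=2.0)
        cfg = SimConfig(regulation_mode="adder")
        assert maybe_divide(cell, cfg, rng, next_id=2) == [cell]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(regulation_mode="divider")

    def test_daughters_partition_mother_span(self, rng):
        cell = CellAgent(id=1, parent_id=None, length=5.0, width=1.0, x=4.0,
                         birth_length=2.0, division_threshold=4.0)
        cfg = SimConfig(regulation_mode="sizer")
        d1, d2 = maybe_divide(cell, cfg, rng, next_id=7)
        assert d1.x_lo == pytest.approx(cell.x_lo)
        assert d2.x_hi == pytest.approx(cell.x_hi)
        assert d1.length + d2.length == pytest.approx(cell.length - cfg.septum_gap)


class TestResolveCollisions:
    GEO = TrenchGeometry(length=20.0)

    def _cell(self, cid, length, x):
        return CellAgent(id=cid, parent_id=None, length=length, width=1.0, x=x,
                         birth_length=length, division_threshold=9.0)

    def test_overlap_removed_order_preserved(self):
        frame = SceneFrame(0, [self._cell(1, 3.0, 2.0), self._cell(2, 3.0, 4.5)],
                           self.GEO)
        resolved, washed = resolve_collisions(frame)
        assert not washed
        a, b = sorted(resolved.cells, key=lambda c: c.x)
        assert (a.id, b.id) == (1, 2)
        assert a.x_hi - b.x_lo <= 0.01

    def test_closed_end_protrusion_pushed_inside(self):
        frame = SceneFrame(0, [self._cell(1, 4.0, 1.0)], self.GEO)
        resolved, _ = resolve_collisions(frame)
        assert resolved.cells[0].x_lo >= 0.0

    def test_washout_when_centroid_crosses_open_end(self):
        frame = SceneFrame(0, [self._cell(1, 3.0, 21.0)], self.GEO)
        resolved, washed = resolve_collisions(frame)
        assert not resolved.cells
        assert [c.id for c in washed] == [1]


class TestStep:
    def test_certain_lysis_empties_trench(self, rng):
        cfg = SimConfig(p_lyse=1.0, seed=3)
        frame = init_scene(cfg, TrenchGeometry(), rng)
        assert step(frame, cfg, rng).cells == []

    def test_no_lysis_no_division_preserves_count(self, rng):
        cfg = SimConfig(p_lyse=0.0, seed=3, div_length_mean=50.0)
        frame = init_scene(cfg, TrenchGeometry(length=200.0), rng)
        nxt = step(frame, cfg, rng)
        assert len(nxt.cells) == len(frame.cells)


class TestRunSimulation:
    def test_fixed_seed_gives_identical_event_logs(self):
        cfg = SimConfig(seed=11, n_timepoints=80)
        a = run_simulation(cfg).events.to_csv(index=False)
        b = run_simulation(cfg).events.to_csv(index=False)
        assert a == b

    def test_zero_timepoints_returns_only_frame0(self):
        result = run_simulation(SimConfig(seed=1, n_timepoints=0))
        assert len(result.frames) == 1
        assert result.frames[0].timepoint == 0

    def test_mother_trace_is_a_sawtooth(self, short_sim):
        _, l = short_sim.mother_trace()
        l = l[np.isfinite(l)]
        ratios = l[1:] / l[:-1]
        drops = ratios[ratios < 0.9]
        assert drops.size > 0, "mother cell never divided"
        assert np.all((drops > 0.35) & (drops < 0.65)), "drops should halve length"
        rises = ratios[ratios >= 0.9]
        assert np.all(rises > 1.0), "length must rise between divisions"

    def test_every_frame_satisfies_scene_invariants(self, short_sim):
        violations = [v for f in short_sim.frames for v in frame_violations(f)]
        assert violations == []

    def test_widths_constant_and_lengths_monotone_within_life(self, short_sim):
        by_id: dict[int, list] = {}
        for frame in short_sim.frames:
            for cell in frame.cells:
                by_id.setdefault(cell.id, []).append(cell)
        for cells in by_id.values():
            widths = {c.width for c in cells}
            assert len(widths) == 1
            lengths = [c.length for c in cells]
            assert all(b >= a for a, b in zip(lengths, lengths[1:]))

    def test_mass_audit_closes(self, short_sim):
        assert short_sim.mass_balance_error() < 1e-9


class TestCellVolume:
    def test_sphere_limit(self):
        assert cell_volume(2.0, 1.0) == pytest.approx(4.0 * math.pi / 3.0, abs=1e-9)

    @pytest.mark.parametrize("length,radius", [(3.0, 0.5), (4.0, 1.0), (2.5, 0.4)])
    def test_matches_numerical_integration(self, length, radius):
        assert cell_volume(length, radius) == pytest.approx(
            spherocylinder_volume_numeric(length, radius), rel=1e-8
        )

    def test_specific_value(self):
        assert cell_volume(3.0, 0.5) == pytest.approx(2.0944, abs=1e-4)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cell_volume(1.0 - 1e-6, 0.5001)


class TestRegulationModes:
    def test_adder_added_length_uncorrelated_with_birth_length(self):
        cfg = SimConfig(regulation_mode="adder", seed=2, n_timepoints=6000)
        table = lineage_table(run_simulation(cfg).events)
        assert len(table) >= 1000
        slope = np.polyfit(table.birth_length, table.added_length, 1)[0]
        assert abs(slope) < 0.1

    def test_sizer_division_length_sd_recovered(self):
        cfg = SimConfig(regulation_mode="sizer", seed=2, n_timepoints=1500)
        table = lineage_table(run_simulation(cfg).events)
        assert table.division_length.std() == pytest.approx(
            cfg.div_length_sd, rel=0.2
        )

    def test_timer_interdivision_sd_recovered(self):
        cfg = SimConfig(regulation_mode="timer", seed=2, n_timepoints=2600, dt=0.5)
        table = lineage_table(run_simulation(cfg).events)
        sd = (table.interdivision_time * cfg.dt).std()
        assert sd == pytest.approx(cfg.tau_sd, rel=0.2)
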