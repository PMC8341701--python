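"""Oxygen dynamics: masks, stepping, stabilization, schedules, balance."""

import numpy as np
import pytest

import oxyvoxel as ov
from oxyvoxel.oxygen import OxygenField, _advance

from oracles import newton_steady_state


def _layout(params, vessels=(), tumor=(), stromal=()):
    return ov.TissueLayout(
        vessels=np.asarray(vessels, dtype=float).reshape(-1, 2),
        tumor_cells=np.asarray(tumor, dtype=float).reshape(-1, 2),
        stromal_cells=np.asarray(stromal, dtype=float).reshape(-1, 2),
        composition=ov.TissueComposition(0, 0, 0), relaxed=True)


class TestIndicatorMasks:
    def test_vessel_on_node_covers_45_nodes(self, params):
        # R_V = 20, dx = 5: lattice points with i^2 + j^2 < 16
        lay = _layout(params, vessels=[(0.0, 0.0)])
        m = ov.build_indicator_masks(lay, params)
        assert m.vessel.sum() == 45
        assert m.tumor.sum() == 0 and m.stromal.sum() == 0

    def test_every_stromal_cell_covers_a_node(self, params, rng):
        # R_S = 3.75 exceeds the worst-case node distance dx*sqrt(2)/2
        pts = rng.uniform(-400, 400, size=(200, 2))
        m = ov.build_indicator_masks(_layout(params, stromal=pts), params)
        assert m.stromal.sum() >= 200  # every cell covers >= 1 node

    def test_empty_layout_all_zero(self, params):
        m = ov.build_indicator_masks(_layout(params), params)
        assert m.vessel.sum() == m.tumor.sum() == m.stromal.sum() == 0

    def test_counts_sum_over_coinciding_elements(self, params):
        lay = _layout(params, tumor=[(0.0, 0.0), (1.0, 0.0)])
        m = ov.build_indicator_masks(lay, params)
        assert m.tumor.max() == 2

    def test_strict_inequality_at_radius(self, params):
        # node exactly at distance R is NOT covered: center on a node,
        # R_V=20 is 4 grid steps; the node 4 steps away must be excluded
        lay = _layout(params, vessels=[(0.0, 0.0)])
        m = ov.build_indicator_masks(lay, params)
        nx, ny = params.grid_shape
        ic, jc = nx // 2, ny // 2
        assert m.vessel[ic + 4, jc] == 0 and m.vessel[ic + 3, jc] == 1


class TestStepOxygen:
    def test_zero_field_zero_influx_stays_zero(self, params):
        lay = _layout(params, tumor=[(0.0, 0.0)])
        m = ov.build_indicator_masks(lay, params)
        f = OxygenField(np.zeros(params.grid_shape), params)
        out = ov.step_oxygen(f, m, delta_V=0.0, delta_T=1.0, params=params)
        assert not out.values.any()

    def test_uniform_field_no_elements_unchanged(self, params):
        m = ov.build_indicator_masks(_layout(params), params)
        f = OxygenField(np.full(params.grid_shape, 17.0), params)
        out = ov.step_oxygen(f, m, 1.0, 1.0, params)
        np.testing.assert_allclose(out.values, 17.0)

    def test_single_source_node_one_step(self):
        # one vessel node, no cells, one step from zero: value dv*gmax*dt
        p = ov.default_params(domain=(-25.0, 25.0, -25.0, 25.0),
                              vessel_ceiling=False)
        m = ov.build_indicator_masks(_layout(p), p)
        m.vessel[5, 5] = 1
        f = OxygenField(np.zeros(p.grid_shape), p)
        out = ov.step_oxygen(f, m, delta_V=0.5, delta_T=1.0, params=p)
        assert out.values[5, 5] == pytest.approx(0.5 * p.gamma_max * p.dt)
        assert out.values.sum() == pytest.approx(out.values[5, 5])

    def test_rate_bounds_enforced(self, params):
        m = ov.build_indicator_masks(_layout(params), params)
        f = OxygenField(np.zeros(params.grid_shape), params)
        with pytest.raises(ValueError):
            ov.step_oxygen(f, m, 1.5, 1.0, params)
        with pytest.raises(ValueError):
            ov.step_oxygen(f, m, 1.0, 60.0, params)

    def test_kernel_matches_reference_step(self, desk_params, desk_tissue):
        """Compiled stepping must agree with the numpy reference exactly."""
        layout, masks, field, _ = desk_tissue
        g = field.values * 0.35 + 1.0  # out-of-equilibrium state
        ref = OxygenField(g.copy(), desk_params)
        for _ in range(25):
            ref = ov.step_oxygen(ref, masks, 0.7, 2.0, desk_params)
        ker = OxygenField(g.copy(), desk_params)
        _advance(ker, masks, 0.7, 2.0, desk_params, 25, -1.0)
        # identical update rule; only FP reassociation may differ
        np.testing.assert_allclose(ker.values, ref.values, rtol=0, atol=1e-10)

    def test_cfl_violations_refused(self):
        with pytest.raises(ValueError, match="stability"):
            ov.default_params(dt=0.1)  # D dt / dx^2 = 0.4 > 1/4


class TestStabilize:
    def test_no_vessels_converges_to_zero(self, desk_params):
        lay = _layout(desk_params, tumor=[(0.0, 0.0), (30.0, 30.0)])
        field, rep = ov.stabilize(lay, desk_params)
        assert rep.converged and rep.iterations == 1
        assert field.average == 0.0

    def test_initial_condition_independence(self, desk_params, desk_tissue):
        layout, masks, field, report = desk_tissue
        finals = [report.average_po2]
        for init in (30.0, 60.0):
            _, rep = ov.stabilize(layout, desk_params, init_value=init,
                                  masks=masks)
            assert rep.converged
            finals.append(rep.average_po2)
        assert max(finals) - min(finals) <= 0.1

    def test_steady_state_mass_balance(self, desk_params, desk_tissue):
        layout, masks, _, _ = desk_tissue
        # converge one decade deeper so the stationarity residual does not
        # mask the conservation property being audited
        field, rep = ov.stabilize(layout, desk_params, masks=masks,
                                  eps_threshold=1e-11)
        assert rep.converged
        influx, uptake, rel = ov.mass_balance(field, masks, 1.0, 1.0,
                                              desk_params)
        assert influx > 0
        assert rel <= 1e-6

    def test_monotone_in_influx_and_uptake(self, desk_params, desk_tissue):
        layout, masks, _, _ = desk_tissue
        avgs_v = [ov.stabilize(layout, desk_params, delta_V=dv,
                               masks=masks)[1].average_po2
                  for dv in (0.25, 0.5, 1.0)]
        assert avgs_v[0] < avgs_v[1] < avgs_v[2]
        avgs_t = [ov.stabilize(layout, desk_params, delta_T=dt_,
                               masks=masks)[1].average_po2
                  for dt_ in (0.5, 1.0, 4.0)]
        assert avgs_t[0] > avgs_t[1] > avgs_t[2]

    def test_uncapped_influx_overload_rejected(self):
        p = ov.default_params(domain=(-100.0, 100.0, -100.0, 100.0),
                              vessel_ceiling=False)
        lay = _layout(p, vessels=[(0.0, 0.0)], stromal=[(60.0, 60.0)])
        with pytest.raises(ov.NoSteadyStateError):
            ov.stabilize(lay, p)

    def test_field_bounded_by_vascular_level(self, desk_tissue, desk_params):
        _, _, field, _ = desk_tissue
        assert field.values.max() <= desk_params.gamma_max + 1e-9
        assert field.values.min() >= 0.0


class TestNewtonOracle:
    def test_steady_state_matches_newton_solve_uncapped(self):
        """Time-stepped steady state vs a direct nonlinear solve, on an
        11x11 grid with one vessel and one tumor cell (literal source)."""
        p = ov.default_params(domain=(-25.0, 25.0, -25.0, 25.0),
                              vessel_ceiling=False, uptake_scale=2000.0)
        lay = _layout(p, vessels=[(-10.0, -10.0)], tumor=[(12.0, 12.0)])
        m = ov.build_indicator_masks(lay, p)
        field, rep = ov.stabilize(lay, p, eps_threshold=1e-14)
        assert rep.converged
        oracle = newton_steady_state(m, 1.0, 1.0, p, x0=field.values)
        np.testing.assert_allclose(field.values, oracle, rtol=0, atol=1e-6)

    def test_steady_state_matches_newton_solve_capped(self):
        """Default (vessel-ceiling) model vs a Dirichlet-vessel solve."""
        p = ov.default_params(domain=(-25.0, 25.0, -25.0, 25.0),
                              uptake_scale=5.0)
        lay = _layout(p, vessels=[(0.0, 0.0)], tumor=[(15.0, 15.0)],
                      stromal=[(-15.0, 10.0)])
        m = ov.build_indicator_masks(lay, p)
        field, rep = ov.stabilize(lay, p, eps_threshold=1e-14)
        assert rep.converged
        # ceiling active: vessel nodes pinned at gamma_max
        assert field.values[m.vessel > 0].max() == pytest.approx(p.gamma_max)
        oracle = newton_steady_state(m, 1.0, 1.0, p, x0=field.values,
                                     dirichlet_vessels=True)
        np.testing.assert_allclose(field.values, oracle, rtol=0, atol=1e-6)


class TestAveragePo2:
    def test_uniform_and_checkerboard(self, params):
        nx, ny = 10, 10
        assert ov.average_po2(np.full((nx, ny), 60.0)) == 60.0
        assert ov.average_po2(np.zeros((nx, ny))) == 0.0
        cb = np.indices((nx, ny)).sum(axis=0) % 2 * 60.0
        assert ov.average_po2(cb) == pytest.approx(30.0)


class TestSimulateSchedule:
    def test_steady_state_preserved_under_unit_rates(self, desk_params,
                                                     desk_tissue):
        _, masks, field, rep = desk_tissue
        out = ov.simulate_schedule(field, masks, params=desk_params)
        np.testing.assert_allclose(out, rep.average_po2, atol=5e-4)

    def test_influx_shutdown_decays_toward_zero(self, desk_params, desk_tissue):
        _, masks, field, rep = desk_tissue
        out = ov.simulate_schedule(field, masks, influx_rates=np.zeros(9),
                                   params=desk_params)
        assert np.all(np.diff(out) < 0) or out[-1] < 1e-3
        assert out[0] < rep.average_po2
        assert out[-1] < 0.05 * rep.average_po2

    def test_uptake_doubling_lowers_endpoint(self, desk_params, desk_tissue):
        _, masks, field, _ = desk_tissue
        base = ov.simulate_schedule(field, masks, params=desk_params)
        up = np.ones(9)
        up[3] = 2.0
        out = ov.simulate_schedule(field, masks, uptake_rates=up,
                                   params=desk_params)
        assert out[3] < base[3]

    def test_rate_bounds_rejected(self, desk_params, desk_tissue):
        _, masks, field, _ = desk_tissue
        with pytest.raises(ValueError):
            ov.simulate_schedule(field, masks, influx_rates=np.full(9, 1.2),
                                 params=desk_params)
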