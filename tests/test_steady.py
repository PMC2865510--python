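"""Steady-state location, stability, branch tracing, switchability."""

import itertools
import math
import warnings

import numpy as np
import pytest

import triadswitch as ts
from conftest import triad_from_truth
from triadswitch.steady import (
    _integrate_to,
    _log_dist,
    find_steady_states,
    signal_of,
)


def attractors_by_integration(params, signal=ts.ZERO_SIGNAL, grid=(1e-3, 0.1, 2.0)):
    """Brute-force oracle: integrate from a grid of starts and cluster the
    endpoints (independent of the Newton-refinement machinery)."""
    ends = [
        _integrate_to(params, signal, combo, horizon=400.0)
        for combo in itertools.product(grid, repeat=3)
    ]
    clusters = []
    for e in ends:
        if not any(_log_dist(e, c) < 1e-2 for c in clusters):
            clusters.append(e)
    return clusters


class TestFindSteadyStates:
    def test_wild_type_is_irreversibly_bistable_at_zero_signal(self, wt_zero_states):
        stable = wt_zero_states.stable_points
        assert len(stable) == 2
        on = wt_zero_states.highest_stable()
        off = wt_zero_states.lowest_stable()
        assert on.state == pytest.approx((1.0, 1.0, 1.0), abs=1e-6)
        assert all(x < 0.05 for x in off.state)
        assert all(p.residual < 1e-10 for p in wt_zero_states)

    def test_saddle_lies_between_the_stable_states(self, wt_zero_states):
        saddles = wt_zero_states.unstable_points
        assert len(saddles) >= 1
        off = wt_zero_states.lowest_stable().state[1]
        on = wt_zero_states.highest_stable().state[1]
        assert any(off < s.state[1] < on for s in saddles)

    def test_saddle_confirmed_by_sign_change_grid_oracle(
        self, wt_params, wt_zero_states
    ):
        """A coarse 3-D grid scan finds a box with sign changes in every rhs
        component around the reported saddle."""
        saddle = next(
            s for s in wt_zero_states.unstable_points
            if wt_zero_states.lowest_stable().state[1]
            < s.state[1]
            < wt_zero_states.highest_stable().state[1]
        )
        # box spanning +/- 30% around the saddle must show all sign patterns
        corners = list(itertools.product((0.7, 1.3), repeat=3))
        signs = np.array(
            [
                ts.rhs(tuple(c * x for c, x in zip(combo, saddle.state)),
                       ts.ZERO_SIGNAL, wt_params)
                for combo in corners
            ]
        )
        for comp in range(3):
            assert signs[:, comp].min() < 0 < signs[:, comp].max()

    def test_scl_knockout_has_single_low_state(self, wt_params):
        ko = ts.make_design(wt_params, ts.parse_design("ko:Scl"))
        sset = find_steady_states(ko)
        assert len(sset.stable_points) == 1
        st = sset.stable_points[0].state
        assert st[0] == 0.0 and st[1] < 0.05 and st[2] < 0.05

    def test_stability_flags_match_perturbed_integration(
        self, wt_params, wt_zero_states
    ):
        for p in wt_zero_states:
            pert = tuple(x * 1.01 + 1e-5 for x in p.state)
            end = _integrate_to(wt_params, ts.ZERO_SIGNAL, pert, horizon=150.0)
            returned = _log_dist(end, p.state) < 1e-3
            assert returned == p.stable

    def test_agrees_with_integration_endpoint_oracle(self, wt_params):
        clusters = attractors_by_integration(wt_params)
        sset = find_steady_states(wt_params)
        for c in clusters:
            assert min(_log_dist(c, p.state) for p in sset.stable_points) < 1e-2


class TestTraceResponse:
    def test_wild_type_notch_axis_is_irreversible(self, wt_params):
        curve = ts.trace_response(wt_params, "notch", refine_thresholds=False)
        assert curve.classification == "irreversible_bistable"
        # ON branch exists at zero signal after switching
        assert len(curve.sets[0].stable_points) == 2

    def test_fli1_ebox_design_is_reversible(self, wt_params):
        p = ts.make_design(wt_params, ts.parse_design("fli1p12:dEbox"))
        curve = ts.trace_response(p, "notch", refine_thresholds=False)
        assert curve.classification == "reversible_bistable"

    def test_fli1_primary_gata_design_monostable_with_flat_fli1(self, wt_params):
        p = ts.make_design(wt_params, ts.parse_design("fli1p12:dGATAp"))
        curve = ts.trace_response(p, "notch", refine_thresholds=False)
        assert curve.classification == "monostable"
        xf = [s.stable_points[0].state[2] for s in curve.sets]
        assert max(xf) / min(xf) < 1.05  # Notch has no effect on Fli1

    def test_branches_match_independent_solves(self, wt_params):
        grid = ts.default_axis_grid("notch", n=13)
        curve = ts.trace_response(wt_params, "notch", grid=grid,
                                  refine_thresholds=False)
        for i in range(0, len(grid), 5):
            indep = find_steady_states(wt_params, signal_of("notch", grid[i]))
            a = sorted(p.state for p in curve.sets[i].stable_points)
            b = sorted(p.state for p in indep.stable_points)
            assert len(a) == len(b)
            assert all(_log_dist(x, y) < 1e-3 for x, y in zip(a, b))

    def test_saddle_node_threshold_is_bracketed(self, wt_params):
        curve = ts.trace_response(wt_params, "notch")
        assert len(curve.thresholds) == 1
        thr = curve.thresholds[0]
        below = find_steady_states(wt_params, signal_of("notch", thr * 0.98))
        above = find_steady_states(wt_params, signal_of("notch", thr * 1.02))
        assert len(below.stable_points) == 2
        assert len(above.stable_points) == 1

    def test_hysteresis_forward_backward_sweeps_differ(self, wt_params):
        grid = [0.0, 2.0, 5.0, 12.0, 5.0, 2.0, 0.0]
        x = find_steady_states(wt_params).lowest_stable().state
        for v in grid:
            x = _integrate_to(wt_params, signal_of("notch", v), x, horizon=60.0)
        # after visiting n=12 (above threshold) and returning, the system
        # rests on the ON branch although it started OFF
        assert _log_dist(x, (1.0, 1.0, 1.0)) < 1e-2


class TestSwitchability:
    def test_scan_reproduces_band_structure(self, reference_tables):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            df = ts.switchability_scan(
                reference_tables,
                K_s=861.5,
                Kg_values=[490.0, 525.0, 5000.0],
                Kf_values=[63.0, 3000.0],
            )
        out = {(r.K_g, r.K_f): r.outcome for r in df.itertuples()}
        assert out[(490.0, 63.0)] == "infeasible"  # below the 500-fold bound
        assert out[(525.0, 63.0)] == "both_switch"  # narrow band above bounds
        assert out[(5000.0, 63.0)] == "bmp4_only"
        assert out[(5000.0, 3000.0)] == "neither"

    def test_fixed_energies_robust_to_severalfold_K_changes(self, wt_params):
        """With the free energies held at their calibrated values (no refit),
        scaling the chromatin constants severalfold preserves irreversible
        bistability with finite Notch and Bmp4 switching thresholds (the
        thresholds shift, but switchability is not lost structurally, unlike
        the exact-refit case where it survives only in a narrow K band)."""
        from dataclasses import replace

        for mult in (1.0 / 3.0, 3.0):
            models = {
                g: replace(m, K=m.K * mult) for g, m in wt_params.models.items()
            }
            p = ts.TriadParameters(
                models=models, gamma=wt_params.gamma,
                hours_per_tau=wt_params.hours_per_tau,
            )
            zs = find_steady_states(p)
            assert len(zs.stable_points) >= 2
            for axis in ("notch", "bmp4"):
                thr = ts.static_threshold(p, axis)  # finite saddle-node
                assert ts.can_switch(p, axis, 2.0 * thr, zero_sets=zs)


class TestRandomParameterSets:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trace_and_fresh_solves_agree(self, seed):
        p = triad_from_truth(seed)
        grid = np.concatenate([[0.0], np.geomspace(0.1, 100.0, 5)])
        curve = ts.trace_response(p, "notch", grid=grid, refine_thresholds=False)
        for v, sset in zip(curve.grid, curve.sets):
            indep = find_steady_states(p, signal_of("notch", v))
            assert len(sset.stable_points) == len(indep.stable_points)
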