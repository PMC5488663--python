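"""Growth laws, fixed points, integration and basins of the core circuits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeostat.core_dynamics import (
    DeltaUndefinedError,
    FixedPoint,
    FixedPointSet,
    GrowthLaw,
    HillTerm,
    SignalDomainError,
    basin_outcome,
    delta_metric,
    eval_growth,
    find_fixed_points,
    find_growth_roots,
    nullclines,
    simulate,
)


class TestHillTerm:
    def test_orientation_formulas(self):
        inc = HillTerm(amplitude=4.8, threshold=7.0, exponent=5.0, orientation="increasing")
        assert inc.value(7.0) == pytest.approx(2.4)  # half-max at threshold
        dec = HillTerm(amplitude=6.0, threshold=8.0, exponent=5.0, orientation="decreasing")
        assert dec.value(8.0) == pytest.approx(3.0)
        # increasing rises, decreasing falls
        assert inc.value(10.0) > inc.value(5.0)
        assert dec.value(10.0) < dec.value(5.0)

    @given(
        a=st.floats(0.0, 100.0),
        K=st.floats(0.01, 100.0),
        n=st.floats(0.1, 10.0),
        y=st.floats(1e-6, 1e6),
        orientation=st.sampled_from(["increasing", "decreasing"]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_value_bounded_by_amplitude(self, a, K, n, y, orientation):
        term = HillTerm(a, K, n, orientation)
        v = term.value(y)
        assert 0.0 <= v <= a

    @pytest.mark.parametrize("bad", [dict(amplitude=-1, threshold=1, exponent=1),
                                     dict(amplitude=1, threshold=0, exponent=1),
                                     dict(amplitude=1, threshold=1, exponent=0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            HillTerm(**bad)


class TestEvalGrowth:
    def test_monophasic_balances_at_set_point(self, mono):
        assert eval_growth(mono.growth_law, 5.0) == pytest.approx(0.0)

    def test_biphasic_negative_at_both_extremes(self, biphasic):
        law = biphasic.growth_law
        assert eval_growth(law, 1e6) == pytest.approx(4.8 - 6.0 - 0.1, abs=1e-3)
        assert eval_growth(law, 1e-6) == pytest.approx(-0.1, abs=1e-6)

    def test_biphasic_near_zero_at_printed_steady_signal(self, biphasic):
        assert abs(eval_growth(biphasic.growth_law, 4.06)) < 5e-4

    def test_nonpositive_signal_rejected(self, mono):
        with pytest.raises(SignalDomainError):
            eval_growth(mono.growth_law, 0.0)
        with pytest.raises(SignalDomainError):
            eval_growth(mono.growth_law, -1.0)

    def test_classification(self, mono, biphasic, biphasic_narrow):
        assert mono.growth_law.classify() == "monophasic"
        assert biphasic.growth_law.classify() == "biphasic"
        assert biphasic_narrow.growth_law.classify() == "biphasic"


class TestFixedPoints:
    def test_monophasic_single_stable_point(self, mono):
        fps = find_fixed_points(mono)
        assert len(fps) == 1
        (p,) = fps.stable
        assert p.y == pytest.approx(5.0, abs=1e-8)
        assert p.Z == pytest.approx(5.0, abs=1e-8)

    def test_biphasic_pair(self, biphasic):
        fps = find_fixed_points(biphasic)
        assert len(fps.stable) == 1 and len(fps.unstable) == 1
        assert fps.y_stable == pytest.approx(4.0578, abs=1e-3)
        assert fps.stable[0].Z == pytest.approx(6.1609, abs=1e-3)
        assert fps.y_unstable == pytest.approx(8.2624, abs=1e-3)
        assert fps.y_unstable > fps.y_stable

    def test_conservation_at_fixed_points(self, biphasic):
        fps = find_fixed_points(biphasic)
        for p in fps:
            assert abs(eval_growth(biphasic.growth_law, p.y)) < 1e-9
            assert abs(p.Z * p.y - biphasic.coupling.scale) < 1e-8

    def test_bisection_agrees_with_dense_grid_scan(self, mono, biphasic, biphasic_narrow):
        """Independent oracle: arithmetic sign-change scan at resolution 1e-3."""
        for model in (mono, biphasic, biphasic_narrow):
            law = model.growth_law
            grid = np.arange(1e-3, 50.0, 1e-3)
            vals = law.net(grid)
            exact = grid[vals == 0.0]
            nz = vals != 0.0
            g, s = grid[nz], np.sign(vals[nz])
            crossings = np.sort(np.concatenate([exact, g[:-1][s[:-1] * s[1:] < 0]]))
            # an exact zero at a grid point and the adjacent sign change
            # are the same root; merge anything within one grid step
            crossings = crossings[np.concatenate([[True], np.diff(crossings) > 1.5e-3])]
            roots = find_growth_roots(law)
            assert len(roots) == len(crossings)
            for r, c in zip(roots, crossings):
                assert abs(r - c) < 2e-3

    def test_narrow_circuit_has_smaller_gap(self, biphasic, biphasic_narrow):
        d_wide = delta_metric(find_fixed_points(biphasic))
        d_narrow = delta_metric(find_fixed_points(biphasic_narrow))
        assert 0 < d_narrow < d_wide


class TestDeltaMetric:
    def test_unit_gap(self):
        fps = FixedPointSet([
            FixedPoint(5.0, 5.0, "stable"), FixedPoint(10.0, 2.5, "unstable"),
        ])
        assert delta_metric(fps) == pytest.approx(1.0)

    def test_degenerate_gap_is_zero(self):
        fps = FixedPointSet([
            FixedPoint(5.0, 5.0, "stable"), FixedPoint(5.0, 5.0, "unstable"),
        ])
        assert delta_metric(fps) == 0.0

    def test_toy_biphasic_value(self, biphasic):
        assert delta_metric(find_fixed_points(biphasic)) == pytest.approx(1.036, abs=2e-3)

    def test_monophasic_undefined(self, mono):
        with pytest.raises(DeltaUndefinedError):
            delta_metric(find_fixed_points(mono))


class TestSimulate:
    def test_monophasic_reaches_set_point(self, mono):
        traj = simulate(mono, 5.0, 4.0)
        assert traj.outcome == "steady"
        assert traj.populations["Z"][-1] == pytest.approx(5.0, rel=1e-6)
        assert traj.signal[-1] == pytest.approx(5.0, rel=1e-6)

    def test_biphasic_stays_at_steady_state(self, biphasic):
        traj = simulate(biphasic, 6.16, 4.06)
        assert traj.outcome == "steady"
        assert traj.populations["Z"][-1] == pytest.approx(6.16, abs=0.01)
        assert traj.signal[-1] == pytest.approx(4.06, abs=0.01)

    def test_biphasic_small_tissue_collapses(self, biphasic):
        traj = simulate(biphasic, 0.05, 4.06)
        assert traj.outcome == "collapsed"
        assert traj.populations["Z"][-1] < 0.05 * 1e-3

    def test_monophasic_global_stability(self, mono):
        """Any interior initial condition converges to the (5, 5) set point."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            Z0 = 10 ** rng.uniform(-2, 2)
            y0 = 10 ** rng.uniform(-1, 1.5)
            traj = simulate(mono, Z0, y0, horizon=2000.0)
            assert traj.outcome == "steady"
            assert traj.populations["Z"][-1] == pytest.approx(5.0, rel=0.01)
            assert traj.signal[-1] == pytest.approx(5.0, rel=0.01)

    def test_trajectory_invariants(self, biphasic):
        traj = simulate(biphasic, 5.0, 5.0)
        assert np.all(np.diff(traj.t) >= 0)
        assert np.all(traj.populations["Z"] >= 0)
        assert np.all(traj.signal > 0)

    def test_zero_mass_is_absorbing(self, mono):
        traj = simulate(mono, 0.0, 4.0, horizon=10.0)
        assert np.all(traj.populations["Z"] == 0.0)

    def test_tsv_roundtrip(self, mono, tmp_path):
        import pandas as pd

        traj = simulate(mono, 1.0, 4.0)
        path = tmp_path / "traj.tsv"
        traj.write_tsv(path, metadata={"seed": 0})
        df = pd.read_csv(path, sep="\t", comment="#")
        assert list(df.columns) == ["time", "Z", "signal"]
        assert len(df) == len(traj.t)
        sidecar = path.with_suffix(".tsv.json")
        assert sidecar.exists()


class TestNullclines:
    def test_monophasic(self, mono):
        nc = nullclines(mono)
        assert nc["growth_nullcline_y"] == pytest.approx([5.0], abs=1e-8)
        y, Z = nc["signal_nullcline"]
        assert np.allclose(Z, 25.0 / y)

    def test_intersections_are_fixed_points(self, biphasic):
        nc = nullclines(biphasic)
        fps = find_fixed_points(biphasic)
        for root, p in zip(sorted(nc["growth_nullcline_y"]), sorted(fps, key=lambda q: q.y)):
            assert root == pytest.approx(p.y, abs=1e-9)
            assert biphasic.coupling.steady_mass(root) == pytest.approx(p.Z, abs=1e-9)


class TestBasins:
    def test_monophasic_always_homeostatic(self, mono):
        out = basin_outcome(mono, [0.1, 1.0, 10.0], [1.0, 5.0, 20.0], horizon=2000.0)
        assert (out.values == "homeostasis").all()

    def test_biphasic_outcome_monotone(self, biphasic):
        Z_vals = [0.05, 0.5, 3.0, 6.16]
        y_vals = [4.06, 9.0, 20.0]
        out = basin_outcome(biphasic, Z_vals, y_vals)
        assert not (out.values == "undecided").any()
        # lowering initial Z never converts collapse into homeostasis
        for y in y_vals:
            col = [out.loc[Z, y] for Z in Z_vals]  # increasing Z
            first_home = next((i for i, o in enumerate(col) if o == "homeostasis"), len(col))
            assert all(o == "homeostasis" for o in col[first_home:])
        # raising initial y past the unstable point never rescues a collapse
        for Z in Z_vals:
            row = [out.loc[Z, y] for y in y_vals]  # increasing y
            first_collapse = next((i for i, o in enumerate(row) if o == "collapse"), len(row))
            assert all(o == "collapse" for o in row[first_collapse:])

    def test_high_signal_collapse(self, biphasic):
        traj = simulate(biphasic, 6.16, 20.0)
        assert traj.outcome == "collapsed"


class TestVariants:
    def test_fixed_points_unchanged_by_logistic_cap_and_delay(self, biphasic):
        fps0 = [p.y for p in find_fixed_points(biphasic)]
        capped = biphasic.with_variant(carrying_capacity=100 * 6.16)
        delayed = biphasic.with_variant(sensing_delay=0.1)
        assert [p.y for p in find_fixed_points(capped)] == pytest.approx(fps0)
        assert [p.y for p in find_fixed_points(delayed)] == pytest.approx(fps0)

    def test_logistic_variant_reaches_same_steady_signal(self, biphasic):
        capped = biphasic.with_variant(carrying_capacity=100 * 6.16)
        traj = simulate(capped, 5.0, 5.0)
        assert traj.outcome == "steady"
        assert traj.signal[-1] == pytest.approx(4.058, abs=1e-2)

    def test_delay_variant_reaches_same_steady_signal(self, biphasic):
        delayed = biphasic.with_variant(sensing_delay=0.1)
        traj = simulate(delayed, 5.0, 5.0, horizon=100.0)
        assert traj.outcome == "steady"
        assert traj.signal[-1] == pytest.approx(4.058, abs=1e-2)
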