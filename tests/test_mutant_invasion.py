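"""Invasion, selection coefficients and frequency-dependent elimination."""

import math

import numpy as np
import pytest

from homeostat.core_dynamics import find_fixed_points, simulate
from homeostat.mutant_invasion import (
    InvasionSchedule,
    MutantClone,
    advantageous_window,
    clone_fates,
    frequency_dependence,
    selection_coefficient,
    simulate_with_mutants,
)


class TestSchedules:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            InvasionSchedule([MutantClone(4, 1, 1, "a"), MutantClone(2, 5, 1, "a")])

    def test_events_sorted_by_time(self):
        sched = InvasionSchedule([MutantClone(4, 47, 1, "b"), MutantClone(4, 10, 1, "a")])
        assert [c.time for c in sched] == [10, 47]

    def test_inactivating_constructor(self):
        clone = MutantClone.inactivating(16, label="dead_sensor")
        assert clone.fold == pytest.approx(1 / 16)


class TestInvasionRuns:
    def test_monophasic_takeover_lowers_signal(self, mono):
        """An activating mis-senser sweeps the monophasic circuit and drags
        the signal below the set point."""
        sched = InvasionSchedule([MutantClone(4.0, 10.0, 1.0, "mut")])
        traj = simulate_with_mutants(mono, sched, Z0=5.0, y0=4.0, horizon=200.0)
        wt, mut = traj.populations["wt"][-1], traj.populations["mut"][-1]
        assert mut > wt
        assert wt < 1e-3
        assert traj.signal[-1] < 5.0
        # the pure-mutant steady state senses 4y = 5, so y = 1.25
        assert traj.signal[-1] == pytest.approx(1.25, rel=1e-3)

    def test_biphasic_eliminates_both_clones(self, biphasic):
        sched = InvasionSchedule(
            [MutantClone(4.0, 10.0, 1.0, "m10"), MutantClone(4.0, 47.0, 1.0, "m47")]
        )
        traj = simulate_with_mutants(biphasic, sched, Z0=6.16, y0=4.06, horizon=200.0)
        fates = clone_fates(traj, sched)
        assert fates == {"m10": "eliminated", "m47": "eliminated"}
        assert traj.populations["wt"][-1] == pytest.approx(6.16, abs=0.01)

    def test_empty_schedule_reduces_to_plain_simulation(self, biphasic):
        traj_a = simulate_with_mutants(biphasic, InvasionSchedule([]), Z0=5.0, y0=5.0)
        traj_b = simulate(biphasic, 5.0, 5.0)
        assert traj_a.outcome == traj_b.outcome == "steady"
        assert traj_a.populations["wt"][-1] == pytest.approx(traj_b.populations["Z"][-1], rel=1e-9)
        assert traj_a.signal[-1] == pytest.approx(traj_b.signal[-1], rel=1e-9)


class TestSelectionCoefficient:
    def test_monophasic_fourfold(self, mono):
        # lambda(4*5) = 20/10 - 0.5
        assert selection_coefficient(mono, 4.0) == pytest.approx(1.5)

    def test_biphasic_fourfold_disadvantage(self, biphasic):
        assert selection_coefficient(biphasic, 4.0) == pytest.approx(-1.201, abs=2e-3)

    def test_resident_is_neutral(self, mono, biphasic):
        assert selection_coefficient(mono, 1.0) == pytest.approx(0.0, abs=1e-9)
        assert selection_coefficient(biphasic, 1.0) == pytest.approx(0.0, abs=1e-7)


class TestAdvantageousWindow:
    def test_biphasic_window_is_fixed_point_ratio(self, biphasic):
        lo, hi = advantageous_window(biphasic)
        fps = find_fixed_points(biphasic)
        assert lo == 1.0
        assert hi == pytest.approx(fps.y_unstable / fps.y_stable, rel=1e-6)
        assert hi == pytest.approx(2.036, abs=2e-3)

    def test_monophasic_window_unbounded(self, mono):
        assert advantageous_window(mono) == (1.0, math.inf)

    def test_window_endpoint_selection_vanishes(self, biphasic):
        lo, hi = advantageous_window(biphasic)
        assert abs(selection_coefficient(biphasic, hi)) < 1e-6

    def test_inside_window_invades_outside_eliminated(self, biphasic):
        assert selection_coefficient(biphasic, 1.5) > 0
        assert selection_coefficient(biphasic, 4.0) < 0
        assert selection_coefficient(biphasic, 0.25) < 0


class TestRareCloneFateMatchesSelectionSign:
    def test_fifty_random_folds(self, biphasic):
        """The early fate (grow vs decay over 5 time units) of a rare clone
        agrees with the sign of its selection coefficient."""
        fps = find_fixed_points(biphasic)
        y_st, Z_st = fps.y_stable, fps.stable[0].Z
        rng = np.random.default_rng(0)
        for k in np.exp(rng.uniform(np.log(0.1), np.log(10.0), 50)):
            s = selection_coefficient(biphasic, float(k))
            sched = InvasionSchedule([MutantClone(float(k), 0.0, 1e-3 * Z_st, "m")])
            traj = simulate_with_mutants(biphasic, sched, Z0=Z_st, y0=y_st, horizon=5.0)
            grew = traj.populations["m"][-1] > 1e-3 * Z_st
            assert grew == (s > 0), f"k={k}: sel={s}, grew={grew}"


class TestFrequencyDependence:
    def test_strong_activating_mutant_toy(self, biphasic):
        res = frequency_dependence(biphasic, 4.0, [1e-3, 0.1, 0.5, 0.9, 1.0])
        out = res["outcomes"]
        assert out[1e-3] == "eliminated"
        assert out[1.0] == "persists"
        labels = [out[f] for f in sorted(out)]
        # monotone: once persisting, stays persisting at higher fractions
        first = labels.index("persists")
        assert all(o == "persists" for o in labels[first:])
        assert res["threshold"] is not None and 0 < res["threshold"] < 1

    def test_strong_inactivating_mutant_toy(self, biphasic):
        res = frequency_dependence(biphasic, 0.25, [1e-3, 0.5, 1.0])
        out = res["outcomes"]
        assert out[1e-3] == "eliminated"
        assert out[1.0] == "persists"
        labels = [out[f] for f in sorted(out)]
        first = labels.index("persists")
        assert all(o == "persists" for o in labels[first:])

    def test_pure_mutant_settles_at_mis_sensed_set_point(self, biphasic):
        """A homogeneous 4-fold tissue holds the signal where it senses the
        wild-type set point: y = y_ST / 4."""
        fps = find_fixed_points(biphasic)
        y_st = fps.y_stable
        Z_mut = biphasic.coupling.steady_mass(y_st / 4.0)
        sched = InvasionSchedule([MutantClone(4.0, 0.0, Z_mut, "m")])
        traj = simulate_with_mutants(
            biphasic, sched, Z0=0.0, y0=y_st / 4.0, horizon=200.0,
            mutant_masses0={"m": Z_mut},
        )
        assert traj.populations["m"][-1] == pytest.approx(Z_mut, rel=1e-3)
        assert traj.signal[-1] == pytest.approx(y_st / 4.0, rel=1e-3)

    def test_variants_do_not_change_invasion_fates(self, mono, biphasic):
        """Logistic capacity and sensing delay leave the fate of a 4-fold
        clone unchanged (eliminated in biphasic, sweeps in monophasic)."""
        sched = InvasionSchedule([MutantClone(4.0, 5.0, 1.0, "m")])
        for variant in (
            biphasic.with_variant(carrying_capacity=100 * 6.16),
            biphasic.with_variant(sensing_delay=0.1),
        ):
            traj = simulate_with_mutants(variant, sched, Z0=6.16, y0=4.06, horizon=40.0)
            assert clone_fates(traj, sched)["m"] == "eliminated"
        for variant in (
            mono.with_variant(carrying_capacity=500.0),
            mono.with_variant(sensing_delay=0.1),
        ):
            traj = simulate_with_mutants(variant, sched, Z0=5.0, y0=5.0, horizon=40.0)
            assert traj.populations["m"][-1] > traj.populations["wt"][-1]
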