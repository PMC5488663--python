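"""Mis-sensing mutant clones and their invasion dynamics.

A clone with fold factor ``k`` reads the shared signal ``y`` as ``k*y``
(k > 1: activating mis-sensing, the clone believes the signal is higher
than it is; k < 1: inactivating). Every clone contributes to the same
signal balance, so dy/dt = mu*(M - (Z_wt + sum Z_mut)*y) for the
inhibitory coupling; each clone grows at the per-capita rate
lambda(k*y).

In a monophasic circuit any activating mutant has positive growth at the
resident set point and sweeps, dragging the signal below the set point.
In a biphasic circuit a rare mutant with sensed signal past the unstable
threshold (k > y_UST/y_ST) lands on the toxic branch and is eliminated —
but the same genotype persists if introduced at high frequency, because
then *it* sets the signal: selection is frequency dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from homeostat.core_dynamics import (
    CircuitModel,
    FixedPointSet,
    Trajectory,
    delta_metric,
    eval_growth,
    find_fixed_points,
    integrate_populations,
)

__all__ = [
    "MutantClone",
    "InvasionSchedule",
    "simulate_with_mutants",
    "clone_fates",
    "selection_coefficient",
    "advantageous_window",
    "frequency_dependence",
]

WILD_TYPE = "wt"

#: fate-classification defaults for the toy circuits
FATE_HORIZON = 200.0
ELIMINATION_FRACTION = 1e-3


@dataclass(frozen=True)
class MutantClone:
    """A clone that senses ``fold * y`` instead of y.

    Use :meth:`inactivating` for loss-of-sensing mutants described by their
    attenuation factor (a "16-fold inactivating" mutant senses y/16).
    """

    fold: float
    time: float = 0.0
    mass: float = 1.0
    label: str = "mut"

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold factor must be positive")
        if self.mass <= 0:
            raise ValueError("introduction mass must be positive")

    @classmethod
    def inactivating(cls, fold: float, **kwargs) -> "MutantClone":
        return cls(fold=1.0 / fold, **kwargs)


@dataclass
class InvasionSchedule:
    """Ordered clone-introduction events with unique labels."""

    clones: list[MutantClone] = field(default_factory=list)

    def __post_init__(self):
        labels = [c.label for c in self.clones]
        if len(set(labels)) != len(labels):
            raise ValueError(f"clone labels must be unique, got {labels}")
        self.clones = sorted(self.clones, key=lambda c: c.time)

    def __iter__(self):
        return iter(self.clones)

    def __len__(self):
        return len(self.clones)


def simulate_with_mutants(
    model: CircuitModel,
    schedule: InvasionSchedule,
    Z0: float,
    y0: float,
    horizon: float = FATE_HORIZON,
    mutant_masses0: dict[str, float] | None = None,
    **integrate_kwargs,
) -> Trajectory:
    """Integrate wild type plus scheduled mutant clones sharing one signal.

    At each clone's introduction time its mass is reset to the introduction
    mass (an instantaneous event, as in a conditional induction), after
    which it obeys dZ_mut/dt = Z_mut * lambda(k*y). ``mutant_masses0``
    optionally seeds clones with nonzero mass from t = 0 (germline-style
    initial frequency). An empty schedule reduces to the wild-type-only
    simulation.
    """
    for clone in schedule:
        if not (0 <= clone.time <= horizon):
            raise ValueError(f"clone {clone.label!r} introduced outside horizon")
    labels = [WILD_TYPE] + [c.label for c in schedule]
    folds = [1.0] + [c.fold for c in schedule]
    init = dict.fromkeys(labels, 0.0)
    init[WILD_TYPE] = Z0
    if mutant_masses0:
        for lab, m in mutant_masses0.items():
            if lab not in init:
                raise KeyError(f"unknown clone label {lab!r}")
            init[lab] = m
    resets = [(c.time, c.label, c.mass) for c in schedule if c.time > 0 or init[c.label] == 0.0]
    return integrate_populations(
        model,
        labels=labels,
        folds=folds,
        masses0=[init[lab] for lab in labels],
        y0=y0,
        horizon=horizon,
        resets=resets,
        **integrate_kwargs,
    )


def clone_fates(
    traj: Trajectory,
    schedule: InvasionSchedule,
    elimination_fraction: float = ELIMINATION_FRACTION,
) -> dict[str, str]:
    """'eliminated' if the clone's final mass fell below
    ``elimination_fraction`` of its introduction mass, else 'persists'."""
    fates = {}
    for clone in schedule:
        final = traj.populations[clone.label][-1]
        fates[clone.label] = (
            "eliminated" if final < elimination_fraction * clone.mass else "persists"
        )
    return fates


def _resident_set_point(model: CircuitModel) -> float:
    fps = find_fixed_points(model)
    stable = fps.stable
    if not stable:
        raise ValueError("model has no stable fixed point")
    return stable[0].y


def selection_coefficient(model: CircuitModel, k: float, fixed_points: FixedPointSet | None = None) -> float:
    """Initial per-capita growth rate lambda(k * y_ST) of a rare clone at
    the resident steady state; positive means the clone invades."""
    if fixed_points is not None:
        stable = fixed_points.stable
        if not stable:
            raise ValueError("model has no stable fixed point")
        y_st = stable[0].y
    else:
        y_st = _resident_set_point(model)
    return float(eval_growth(model.growth_law, k * y_st))


def advantageous_window(model: CircuitModel) -> tuple[float, float]:
    """Fold-factor interval (k_lo, k_hi) over which a rare mutant has
    positive selection.

    For an inhibitory biphasic circuit the window is (1, y_UST/y_ST): the
    mutant's sensed signal must land between the two fixed points. For a
    monophasic circuit whose growth rate keeps rising with the signal, the
    upper edge is infinite — any activating mis-senser may invade.
    """
    fps = find_fixed_points(model)
    try:
        delta = delta_metric(fps)
    except Exception:
        # monophasic: single stable point; check whether growth stays
        # positive above the set point
        y_st = _resident_set_point(model)
        upper = eval_growth(model.growth_law, 100.0 * y_st)
        return (1.0, math.inf) if upper > 0 else (1.0, 1.0)
    return (1.0, 1.0 + delta)


def frequency_dependence(
    model: CircuitModel,
    k: float,
    fractions: Sequence[float],
    horizon: float = FATE_HORIZON,
    elimination_fraction: float = ELIMINATION_FRACTION,
    threshold_tol: float = 1e-3,
) -> dict:
    """Fate of a k-fold mutant as a function of its initial frequency.

    The initial tissue interpolates between the two homogeneous steady
    states: total mass T(f) = (1-f)*Z_ST + f*Z_ST_mut, split (1-f) wild
    type / f mutant, with the signal at its quasi-steady value for T(f).
    Here Z_ST_mut is the steady mass of a pure mutant tissue (for the
    inhibitory coupling k*Z_ST: the mutant holds the signal at y_ST/k).
    The f = 0 end is the adult wild-type tissue in which a somatic clone
    appears; the f = 1 end is the tissue a germline mutant develops, at
    its own mis-sensed set point. Returns per-fraction outcomes
    ('eliminated' or 'persists') and, when both outcomes occur, the
    threshold frequency located by bisection.
    """
    fps = find_fixed_points(model)
    stable = fps.stable
    if not stable:
        raise ValueError("model has no stable fixed point")
    y_st, Z_st = stable[0].y, stable[0].Z
    # a homogeneous mutant tissue is stationary where it senses y_ST
    Z_st_mut = model.coupling.steady_mass(y_st / k)

    def fate(f: float) -> str:
        if f == 0:
            return "eliminated"
        total = (1 - f) * Z_st + f * Z_st_mut
        clone = MutantClone(fold=k, time=0.0, mass=f * total, label="mut")
        schedule = InvasionSchedule([clone])
        traj = simulate_with_mutants(
            model,
            schedule,
            Z0=(1 - f) * total,
            y0=model.coupling.steady_signal(total),
            horizon=horizon,
            mutant_masses0={"mut": f * total},
        )
        return clone_fates(traj, schedule, elimination_fraction)["mut"]

    outcomes = {f: fate(f) for f in fractions}

    threshold = None
    elim = [f for f, o in outcomes.items() if o == "eliminated"]
    fixed = [f for f, o in outcomes.items() if o == "persists"]
    if elim and fixed:
        lo, hi = max(elim), min(fixed)
        while hi - lo > threshold_tol:
            mid = 0.5 * (lo + hi)
            if fate(mid) == "eliminated":
                lo = mid
            else:
                hi = mid
        threshold = 0.5 * (lo + hi)
    return {"outcomes": outcomes, "threshold": threshold}
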