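"""Stem-cell renewal/differentiation feedback and mutant stem cells.

Stem cells divide at rate lambda_plus; each division either self-renews
(probability p_r(y)) or differentiates (1 - p_r). Differentiated cells
are removed at rate lambda_minus and secrete the feedback signal, so the
sensed signal is proportional to the differentiated pool: y = c * Z_d.

    dZ_s/dt     = (2*p_r(y) - 1) * lambda_plus * Z_s
    dZ_s_mut/dt = (2*p_r(k*y) - 1) * lambda_plus * Z_s_mut
    dZ_d/dt     = 2*(1-p_r(y))*lambda_plus*Z_s
                  + 2*(1-p_r(k*y))*lambda_plus*Z_s_mut - lambda_minus*Z_d

Steady state requires p_r = 1/2 (each stem division yields one stem cell
on average). The monophasic renewal law p_r(y) = 1/(1+y) crosses 1/2
once (at y = 1); any mutant whose sensed signal is lower — e.g. one with
strongly inactivated sensing, reading y/16 — sees p_r > 1/2 forever and
expands without bound, dragging the differentiated pool up with it. The
biphasic law p_r(y) = 1/(1+y) * 1/(1+(1/(5y))**4) also *falls* at low
signal, so the same sensing-dead mutant has p_r < 1/2 and is eliminated;
the price is a second, unstable crossing below which the whole stem pool
is lost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from homeostat.core_dynamics import FixedPoint, FixedPointSet, Trajectory

__all__ = [
    "pr_monophasic",
    "pr_biphasic",
    "StemCellModel",
    "StemState",
    "simulate_stem",
    "stem_fixed_points",
]


def pr_monophasic(y):
    """Renewal probability 1/(1+y): monotone from 1 at no signal to 0."""
    y = np.asarray(y, dtype=float)
    out = 1.0 / (1.0 + y)
    return float(out) if out.ndim == 0 else out


def pr_biphasic(y, low_threshold: float = 0.2, low_exponent: float = 4.0):
    """Renewal probability 1/(1+y) * 1/(1+(low_threshold/y)**low_exponent).

    The second factor suppresses renewal when the signal falls below
    ``low_threshold`` (default 0.2, i.e. the factor is (1+(1/(5y))^4)^-1),
    making the law biphasic: p_r -> 0 at both extremes and crosses 1/2
    exactly twice (stable crossing near y = 0.99, unstable near 0.25).
    """
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore"):
        low = np.where(y > 0, (low_threshold / np.where(y > 0, y, 1.0)) ** low_exponent, np.inf)
    out = 1.0 / (1.0 + y) / (1.0 + low)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StemCellModel:
    """Parameters of the renewal circuit.

    ``renewal``: the p_r law; ``fold``: the mutant's sensing factor on y
    (use 1/16 for the strongly sensing-inactivated mutant). Defaults are
    the toy values lambda_plus = 1, lambda_minus = 0.5, c = 1.
    """

    renewal: Callable = pr_monophasic
    division_rate: float = 1.0  # lambda_plus
    removal_rate: float = 0.5  # lambda_minus
    signal_per_cell: float = 1.0  # c in y = c * Z_d
    fold: float = 1.0 / 16.0

    def pr(self, y):
        return self.renewal(y)


@dataclass(frozen=True)
class StemState:
    Z_s: float = 0.5
    Z_s_mut: float = 0.0
    Z_d: float = 1.0

    def __post_init__(self):
        if min(self.Z_s, self.Z_s_mut, self.Z_d) < 0:
            raise ValueError("all pools must be nonnegative")


def simulate_stem(
    model: StemCellModel,
    state0: StemState = StemState(),
    mutant_time: float | None = None,
    mutant_mass: float = 0.01,
    horizon: float = 100.0,
    steady_tol: float = 1e-8,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    n_out: int = 400,
) -> Trajectory:
    """Integrate the three-pool system; optionally seed the mutant stem
    pool with ``mutant_mass`` at ``mutant_time`` (an instantaneous event).

    Outcome 'steady' once relative derivatives fall below tolerance,
    'collapsed' if the total stem pool drops below 1e-6 of its initial
    value, else 'max_time'.
    """
    lp, lm, c, k = (
        model.division_rate,
        model.removal_rate,
        model.signal_per_cell,
        model.fold,
    )
    pr = model.pr

    def rhs(t, s):
        Zs, Zm, Zd = s
        y = max(c * Zd, 1e-300)
        pw = pr(y)
        pm = pr(k * y)
        return np.array(
            [
                (2 * pw - 1) * lp * Zs,
                (2 * pm - 1) * lp * Zm,
                2 * (1 - pw) * lp * Zs + 2 * (1 - pm) * lp * Zm - lm * Zd,
            ]
        )

    init_stem = state0.Z_s + state0.Z_s_mut

    def steady_event(t, s):
        d = rhs(t, s)
        floor = 1e-9 * max(init_stem + state0.Z_d, 1e-3)
        rel = max(
            abs(di) / max(si, floor) for di, si in zip(d, s) if si >= floor
        ) if np.any(np.asarray(s) >= floor) else 0.0
        return rel - steady_tol

    steady_event.terminal = True

    def collapse_event(t, s):
        return s[0] + s[1] - 1e-6 * max(init_stem, 1e-30)

    collapse_event.terminal = init_stem > 0

    segments = [(0.0, horizon)] if mutant_time is None else [
        (0.0, mutant_time),
        (mutant_time, horizon),
    ]
    state = np.array([state0.Z_s, state0.Z_s_mut, state0.Z_d], dtype=float)
    ts, states = [], []
    outcome = "max_time"
    for i, (t0, t1) in enumerate(segments):
        if i == 1:
            state = state.copy()
            state[1] = mutant_mass
            outcome = "max_time"
        if t1 <= t0:
            continue
        sol = solve_ivp(
            rhs, (t0, t1), state, method="LSODA", rtol=rtol, atol=atol,
            events=[steady_event, collapse_event],
            t_eval=np.linspace(t0, t1, max(int(n_out * (t1 - t0) / horizon), 10)),
        )
        if not sol.success and sol.status != 1:
            raise RuntimeError(f"stem-cell integration failed: {sol.message}")
        t_arr, s_arr = sol.t, sol.y
        if sol.status == 1:
            if sol.t_events[1].size:
                outcome, t_ev, s_ev = "collapsed", sol.t_events[1][0], sol.y_events[1][0]
            else:
                outcome, t_ev, s_ev = "steady", sol.t_events[0][0], sol.y_events[0][0]
            if t_arr.size == 0 or t_arr[-1] < t_ev:
                t_arr = np.append(t_arr, t_ev)
                s_arr = np.column_stack([s_arr, s_ev]) if s_arr.size else s_ev[:, None]
        ts.append(t_arr)
        states.append(s_arr)
        state = s_arr[:, -1]
    t = np.concatenate(ts)
    s = np.column_stack(states)
    populations = {
        "stem": np.clip(s[0], 0.0, None),
        "stem_mut": np.clip(s[1], 0.0, None),
        "diff": np.clip(s[2], 0.0, None),
    }
    return Trajectory(
        t=t, populations=populations, signal=model.signal_per_cell * s[2], outcome=outcome
    )


def stem_fixed_points(model: StemCellModel, interval=(1e-3, 1e2), n_scan: int = 2000) -> FixedPointSet:
    """Signal levels where p_r(y) = 1/2, with stability from the sign of
    p_r - 1/2 around each crossing.

    Below a stable crossing p_r > 1/2: the stem pool expands, the
    differentiated pool and hence y rise back — so p_r falling through
    1/2 is stable. The steady differentiated pool is Z_d = y/c and the
    stem pool follows from the division/removal balance
    lambda_minus * Z_d = 2*(1 - p_r)*lambda_plus*Z_s = lambda_plus*Z_s.
    """
    grid = np.geomspace(interval[0], interval[1], n_scan)
    vals = np.asarray(model.pr(grid)) - 0.5
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(lambda y: model.pr(y) - 0.5, grid[i], grid[i + 1], xtol=1e-12))
    points = []
    for r in roots:
        h = 1e-6 * r
        falling = model.pr(r + h) < model.pr(r - h)
        Z_d = r / model.signal_per_cell
        Z_s = model.removal_rate * Z_d / model.division_rate
        points.append(
            FixedPoint(y=r, Z=Z_s + Z_d, stability="stable" if falling else "unstable")
        )
    return FixedPointSet(points)
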