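"""Circuit models of tissue-size feedback and their deterministic dynamics.

A circuit couples a cell mass ``Z`` to a signal ``y`` through two laws:

* a growth law: per-capita proliferation and removal rates as functions of
  the sensed signal, ``dZ/dt = Z * (lambda_plus(y) - lambda_minus(y))``;
* a signal coupling: how the tissue sets the signal, either inhibitory
  (``dy/dt = mu * (M - Z*y)``, so that at steady state ``Z*y = M``) or
  activating (``dy/dt = mu * (a*Z - y)``, so ``y = a*Z``).

Growth laws are sums of Hill terms plus optional constant and linear
offsets. A *monophasic* law crosses zero once on the scanned signal range;
a *biphasic* law crosses twice, producing one stable set point ``y_ST``
and one unstable threshold ``y_UST`` whose relative gap
``delta = (y_UST - y_ST)/y_ST`` measures the circuit's dynamic stability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "SignalDomainError",
    "DeltaUndefinedError",
    "IntegrationError",
    "HillTerm",
    "GrowthLaw",
    "SignalCoupling",
    "CircuitModel",
    "FixedPoint",
    "FixedPointSet",
    "Trajectory",
    "eval_growth",
    "find_fixed_points",
    "delta_metric",
    "simulate",
    "nullclines",
    "basin_outcome",
]

INHIBITS = "tissue_inhibits_signal"
ACTIVATES = "tissue_activates_signal"


class SignalDomainError(ValueError):
    """The signal value lies outside the admissible domain (y must be > 0)."""


class DeltaUndefinedError(ValueError):
    """delta requires exactly one stable and one unstable fixed point."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries the last valid state."""

    def __init__(self, message: str, last_state: tuple | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class HillTerm:
    """One saturating term of a growth law.

    ``increasing`` orientation evaluates ``a / (1 + (K/y)**n)`` (rises from 0
    to the amplitude ``a`` as y grows past the threshold ``K``); ``decreasing``
    evaluates ``a / (1 + (y/K)**n)``.
    """

    amplitude: float
    threshold: float
    exponent: float
    orientation: str = "increasing"

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.exponent <= 0:
            raise ValueError(f"exponent must be > 0, got {self.exponent}")
        if self.orientation not in ("increasing", "decreasing"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def value(self, y):
        y = np.asarray(y, dtype=float)
        if self.orientation == "increasing":
            ratio = self.threshold / y
        else:
            ratio = y / self.threshold
        out = self.amplitude / (1.0 + ratio**self.exponent)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "threshold": self.threshold,
            "exponent": self.exponent,
            "orientation": self.orientation,
        }


@dataclass(frozen=True)
class GrowthLaw:
    """Proliferation and removal rates as sums of Hill terms plus offsets.

    The linear coefficients allow laws such as ``lambda_plus(y) = y/10``
    that are not saturating.
    """

    proliferation: tuple[HillTerm, ...] = ()
    removal: tuple[HillTerm, ...] = ()
    proliferation_offset: float = 0.0
    removal_offset: float = 0.0
    proliferation_linear: float = 0.0
    removal_linear: float = 0.0

    def rate_up(self, y):
        y = np.asarray(y, dtype=float)
        out = np.full_like(y, self.proliferation_offset, dtype=float)
        out = out + self.proliferation_linear * y
        for term in self.proliferation:
            out = out + term.value(y)
        return float(out) if out.ndim == 0 else out

    def rate_down(self, y):
        y = np.asarray(y, dtype=float)
        out = np.full_like(y, self.removal_offset, dtype=float)
        out = out + self.removal_linear * y
        for term in self.removal:
            out = out + term.value(y)
        return float(out) if out.ndim == 0 else out

    def net(self, y):
        return self.rate_up(y) - self.rate_down(y)

    __call__ = net

    def classify(self, interval: tuple[float, float] = (1e-2, 1e2), num: int = 4000) -> str:
        """'monophasic' (one sign change of the net rate on the interval),
        'biphasic' (two), otherwise 'other'."""
        y = np.geomspace(interval[0], interval[1], num)
        signs = np.sign(self.net(y))
        crossings = int(np.count_nonzero(np.diff(signs[signs != 0])))
        return {1: "monophasic", 2: "biphasic"}.get(crossings, "other")

    def to_dict(self) -> dict:
        return {
            "proliferation": [t.to_dict() for t in self.proliferation],
            "removal": [t.to_dict() for t in self.removal],
            "proliferation_offset": self.proliferation_offset,
            "removal_offset": self.removal_offset,
            "proliferation_linear": self.proliferation_linear,
            "removal_linear": self.removal_linear,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthLaw":
        return cls(
            proliferation=tuple(HillTerm(**t) for t in d.get("proliferation", [])),
            removal=tuple(HillTerm(**t) for t in d.get("removal", [])),
            proliferation_offset=float(d.get("proliferation_offset", 0.0)),
            removal_offset=float(d.get("removal_offset", 0.0)),
            proliferation_linear=float(d.get("proliferation_linear", 0.0)),
            removal_linear=float(d.get("removal_linear", 0.0)),
        )


@dataclass(frozen=True)
class SignalCoupling:
    """How the tissue sets its signal.

    sign ``tissue_inhibits_signal``: dy/dt = mu*(scale - Z*y), steady Z*y = scale.
    sign ``tissue_activates_signal``: dy/dt = mu*(scale*Z - y), steady y = scale*Z.
    """

    sign: str = INHIBITS
    turnover: float = 0.25
    scale: float = 25.0

    def __post_init__(self):
        if self.sign not in (INHIBITS, ACTIVATES):
            raise ValueError(f"unknown coupling sign {self.sign!r}")
        if self.turnover <= 0:
            raise ValueError("turnover must be > 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def signal_rate(self, y, Z_total):
        if self.sign == INHIBITS:
            return self.turnover * (self.scale - Z_total * y)
        return self.turnover * (self.scale * Z_total - y)

    def steady_mass(self, y: float) -> float:
        """Mass at which the signal equation is stationary for a given y."""
        if self.sign == INHIBITS:
            return self.scale / y
        return y / self.scale

    def steady_signal(self, Z_total: float) -> float:
        if self.sign == INHIBITS:
            return self.scale / Z_total
        return self.scale * Z_total

    def to_dict(self) -> dict:
        return {"sign": self.sign, "turnover": self.turnover, "scale": self.scale}


@dataclass(frozen=True)
class CircuitModel:
    """A growth law plus a signal coupling, with optional variants.

    ``carrying_capacity`` multiplies the growth rate by (1 - Z_total/K_cap)
    (logistic variant); ``sensing_delay`` makes the growth law read the
    signal a fixed lag in the past. Both leave the zeroes of the net growth
    rate — and hence the fixed-point signal levels — unchanged.
    """

    growth_law: GrowthLaw
    coupling: SignalCoupling = SignalCoupling()
    carrying_capacity: float = math.inf
    sensing_delay: float = 0.0
    name: str = "circuit"

    def with_variant(self, carrying_capacity=None, sensing_delay=None) -> "CircuitModel":
        updates = {}
        if carrying_capacity is not None:
            updates["carrying_capacity"] = carrying_capacity
        if sensing_delay is not None:
            updates["sensing_delay"] = sensing_delay
        return replace(self, **updates)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "growth_law": self.growth_law.to_dict(),
            "coupling": self.coupling.to_dict(),
            "carrying_capacity": self.carrying_capacity,
            "sensing_delay": self.sensing_delay,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitModel":
        cap = d.get("carrying_capacity", math.inf)
        if isinstance(cap, str):  # "inf" in JSON/TOML configs
            cap = float(cap)
        return cls(
            growth_law=GrowthLaw.from_dict(d["growth_law"]),
            coupling=SignalCoupling(**d.get("coupling", {})),
            carrying_capacity=cap,
            sensing_delay=float(d.get("sensing_delay", 0.0)),
            name=d.get("name", "circuit"),
        )


@dataclass(frozen=True)
class FixedPoint:
    y: float
    Z: float
    stability: str  # "stable" | "unstable"
    at_boundary: bool = False


@dataclass
class FixedPointSet:
    points: list[FixedPoint] = field(default_factory=list)

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)

    @property
    def stable(self) -> list[FixedPoint]:
        return [p for p in self.points if p.stability == "stable"]

    @property
    def unstable(self) -> list[FixedPoint]:
        return [p for p in self.points if p.stability == "unstable"]

    @property
    def y_stable(self) -> float:
        (p,) = self.stable
        return p.y

    @property
    def y_unstable(self) -> float:
        (p,) = self.unstable
        return p.y

    def to_records(self) -> list[dict]:
        return [
            {"y": p.y, "Z": p.Z, "stability": p.stability, "at_boundary": p.at_boundary}
            for p in self.points
        ]


@dataclass
class Trajectory:
    """Simulation output: a time grid with per-population masses and the signal.

    ``outcome`` is 'steady' (relative derivatives fell below tolerance),
    'collapsed' (total mass fell below the collapse threshold), or
    'max_time'.
    """

    t: np.ndarray
    populations: dict[str, np.ndarray]
    signal: np.ndarray
    outcome: str
    fixed_points: FixedPointSet | None = None

    @property
    def total_mass(self) -> np.ndarray:
        return np.sum(list(self.populations.values()), axis=0)

    def final(self) -> dict:
        out = {label: float(series[-1]) for label, series in self.populations.items()}
        out["signal"] = float(self.signal[-1])
        out["t"] = float(self.t[-1])
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.t}
        data.update(self.populations)
        data["signal"] = self.signal
        return pd.DataFrame(data)

    def write_tsv(self, path: str | Path, metadata: dict | None = None) -> None:
        """TSV with '#'-prefixed metadata lines plus a JSON sidecar."""
        path = Path(path)
        meta = {"outcome": self.outcome}
        if metadata:
            meta.update(metadata)
        with open(path, "w") as fh:
            for key, val in meta.items():
                fh.write(f"# {key}: {val}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.9g")
        sidecar = {"outcome": self.outcome, "final": self.final()}
        if self.fixed_points is not None:
            sidecar["fixed_points"] = self.fixed_points.to_records()
        if metadata:
            sidecar.update(metadata)
        Path(path.with_suffix(path.suffix + ".json")).write_text(
            json.dumps(sidecar, indent=2, default=float)
        )


def eval_growth(law: GrowthLaw, y) -> float:
    """Net per-capita growth rate lambda(y) = lambda_plus(y) - lambda_minus(y)."""
    if np.any(np.asarray(y) <= 0):
        raise SignalDomainError(f"signal must be positive, got {y}")
    return law.net(y)


def _merge_close(roots: list[float], tol: float = 1e-6) -> list[float]:
    merged: list[float] = []
    for r in sorted(roots):
        if merged and abs(r - merged[-1]) < tol:
            continue
        merged.append(r)
    return merged


def find_growth_roots(
    law: GrowthLaw,
    interval: tuple[float, float] = (1e-2, 1e2),
    n_scan: int = 1000,
    xtol: float = 1e-12,
) -> list[float]:
    """All zeroes of the net growth rate on the interval.

    Log-spaced sign-change scan followed by bisection refinement; roots
    closer than 1e-6 are merged.
    """
    lo, hi = interval
    if lo <= 0:
        raise SignalDomainError("scan interval must lie in (0, inf)")
    grid = np.geomspace(lo, hi, n_scan)
    vals = law.net(grid)
    roots = [float(g) for g, v in zip(grid, vals) if v == 0.0]
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] < 0:
            roots.append(brentq(law.net, grid[i], grid[i + 1], xtol=xtol))
    return _merge_close(roots)


def find_fixed_points(
    model: CircuitModel,
    interval: tuple[float, float] = (1e-2, 1e2),
    n_scan: int = 1000,
) -> FixedPointSet:
    """Fixed points of the circuit: zeroes of the growth law combined with
    the coupling steady-state relation.

    Stability classification uses the sign pattern of lambda around the
    root together with the coupling sign: with inhibitory coupling a rise
    in Z lowers y, so lambda *increasing* through the root is stable; with
    activating coupling the roles reverse.
    """
    roots = find_growth_roots(model.growth_law, interval, n_scan)
    lo, hi = interval
    points = []
    for r in roots:
        h = max(1e-7, 1e-7 * r)
        below = model.growth_law.net(max(r - h, lo * 0.5))
        above = model.growth_law.net(r + h)
        increasing = above > below
        if model.coupling.sign == INHIBITS:
            stability = "stable" if increasing else "unstable"
        else:
            stability = "unstable" if increasing else "stable"
        boundary = (r - lo) < 1e-6 * lo or (hi - r) < 1e-6 * hi
        points.append(
            FixedPoint(y=r, Z=model.coupling.steady_mass(r), stability=stability, at_boundary=boundary)
        )
    return FixedPointSet(points)


def delta_metric(fp: FixedPointSet) -> float:
    """Dynamic-stability gap delta = (y_UST - y_ST)/y_ST.

    Requires exactly one stable and one unstable fixed point (a bistable,
    biphasic circuit); raises DeltaUndefinedError otherwise.
    """
    if len(fp.stable) != 1 or len(fp.unstable) != 1:
        raise DeltaUndefinedError(
            f"delta needs one stable and one unstable point, got "
            f"{len(fp.stable)} stable / {len(fp.unstable)} unstable"
        )
    y_st, y_ust = fp.y_stable, fp.y_unstable
    return (y_ust - y_st) / y_st


# ---------------------------------------------------------------------------
# Integration


def _rhs_factory(model: CircuitModel, folds: Sequence[float]):
    """Right-hand side for the multi-population system.

    State vector: [Z_0, ..., Z_{m-1}, y]. Clone i senses fold_i * y.
    """
    law = model.growth_law
    coupling = model.coupling
    cap = model.carrying_capacity
    folds = np.asarray(folds, dtype=float)

    def rhs(t, state, y_lookup=None):
        Z = state[:-1]
        y = state[-1]
        y_sensed = y if y_lookup is None else y_lookup(t)
        y_sensed = max(y_sensed, 1e-300)
        rates = law.net(folds * y_sensed)
        dZ = Z * rates
        if np.isfinite(cap):
            dZ = dZ * (1.0 - np.sum(Z) / cap)
        dy = coupling.signal_rate(y, np.sum(Z))
        return np.append(dZ, dy)

    return rhs


def _relative_rate(d: np.ndarray, s: np.ndarray, y_scale: float, mass_floor: float) -> float:
    """Largest relative state derivative, ignoring populations that have
    dropped below the extinction floor (their exponential tail would keep
    the per-capita rate finite forever)."""
    Z, dZ = s[:-1], d[:-1]
    live = Z >= mass_floor
    rel_mass = float(np.max(np.abs(dZ[live]) / np.maximum(Z[live], mass_floor))) if live.any() else 0.0
    return max(rel_mass, abs(d[-1]) / y_scale)


def _integrate_segment(
    model: CircuitModel,
    folds: Sequence[float],
    state0: np.ndarray,
    t0: float,
    t1: float,
    steady_tol: float,
    collapse_threshold: float,
    rtol: float,
    atol: float,
    n_out: int,
    mass_floor: float = 1e-12,
):
    """One event-free segment. Returns (t, states, outcome or None)."""
    rhs = _rhs_factory(model, folds)
    if model.sensing_delay > 0:
        return _integrate_delay_segment(
            model, folds, state0, t0, t1, steady_tol, collapse_threshold, n_out, mass_floor
        )

    y_scale = max(abs(state0[-1]), 1.0)

    def steady_event(t, s):
        return _relative_rate(rhs(t, s), s, y_scale, mass_floor) - steady_tol

    steady_event.terminal = True

    def collapse_event(t, s):
        return float(np.sum(s[:-1])) - collapse_threshold

    collapse_event.terminal = True

    events = [steady_event]
    if collapse_threshold > 0:
        events.append(collapse_event)

    sol = solve_ivp(
        rhs,
        (t0, t1),
        state0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=False,
        events=events,
        t_eval=np.linspace(t0, t1, n_out),
    )
    if not sol.success and sol.status != 1:
        last = (sol.t[-1], sol.y[:, -1]) if sol.t.size else (t0, state0)
        raise IntegrationError(f"integrator failed: {sol.message}", last_state=last)

    t = sol.t
    states = sol.y
    outcome = None
    if sol.status == 1:  # a terminal event fired
        if len(sol.t_events) > 1 and sol.t_events[1].size:
            outcome, t_ev, s_ev = "collapsed", sol.t_events[1][0], sol.y_events[1][0]
        else:
            outcome, t_ev, s_ev = "steady", sol.t_events[0][0], sol.y_events[0][0]
        if t.size == 0 or t[-1] < t_ev:
            t = np.append(t, t_ev)
            states = np.column_stack([states, s_ev]) if states.size else s_ev[:, None]
    return t, states, outcome


def _integrate_delay_segment(
    model, folds, state0, t0, t1, steady_tol, collapse_threshold, n_out, mass_floor=1e-12
):
    """Fixed-step RK4 with a linear-interpolation history for the delayed signal.

    The history before t0 is held at the initial signal value. Accuracy is
    sufficient for the robustness variants; the delay-free path uses the
    adaptive stiff integrator.
    """
    tau = model.sensing_delay
    h = min(tau / 20.0, (t1 - t0) / 200.0, 0.01)
    n_steps = max(int(math.ceil((t1 - t0) / h)), 1)
    h = (t1 - t0) / n_steps
    rhs = _rhs_factory(model, folds)

    ts = [t0]
    ys_hist = [state0[-1]]

    def y_delayed(t):
        td = t - tau
        if td <= ts[0]:
            return ys_hist[0]
        idx = np.searchsorted(ts, td)
        idx = min(max(idx, 1), len(ts) - 1)
        t_a, t_b = ts[idx - 1], ts[idx]
        y_a, y_b = ys_hist[idx - 1], ys_hist[idx]
        w = 0.0 if t_b == t_a else (td - t_a) / (t_b - t_a)
        return y_a + w * (y_b - y_a)

    states = [state0.copy()]
    t = t0
    s = state0.copy()
    outcome = None
    y_scale = max(abs(state0[-1]), 1.0)
    for _ in range(n_steps):
        f = lambda tt, ss: rhs(tt, ss, y_lookup=y_delayed)
        k1 = f(t, s)
        k2 = f(t + h / 2, s + h / 2 * k1)
        k3 = f(t + h / 2, s + h / 2 * k2)
        k4 = f(t + h, s + h * k3)
        s = s + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t + h
        ts.append(t)
        ys_hist.append(s[-1])
        states.append(s.copy())
        d = f(t, s)
        if _relative_rate(d, s, y_scale, mass_floor) < steady_tol:
            outcome = "steady"
            break
        if collapse_threshold > 0 and float(np.sum(s[:-1])) < collapse_threshold:
            outcome = "collapsed"
            break
    return np.asarray(ts), np.asarray(states).T, outcome


def integrate_populations(
    model: CircuitModel,
    labels: Sequence[str],
    folds: Sequence[float],
    masses0: Sequence[float],
    y0: float,
    horizon: float,
    resets: Iterable[tuple[float, str, float]] = (),
    steady_tol: float = 1e-8,
    collapse_fraction: float = 1e-6,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    n_out: int = 400,
) -> Trajectory:
    """Integrate the multi-population circuit with optional mass resets.

    ``resets`` is a sequence of (time, label, mass) events: at each event
    time the named population's mass is set to the given value (a clone
    introduction). Integration stops early at steadiness or collapse.
    """
    if y0 <= 0:
        raise SignalDomainError("initial signal must be positive")
    masses0 = np.asarray(masses0, dtype=float)
    if np.any(masses0 < 0):
        raise ValueError("initial masses must be nonnegative")

    label_index = {lab: i for i, lab in enumerate(labels)}
    events = sorted(resets, key=lambda e: e[0])
    for t_ev, lab, _ in events:
        if lab not in label_index:
            raise KeyError(f"reset references unknown population {lab!r}")
        if not (0 <= t_ev <= horizon):
            raise ValueError(f"reset time {t_ev} outside [0, {horizon}]")

    init_total = float(np.sum(masses0))
    collapse_threshold = collapse_fraction * init_total if init_total > 0 else 0.0
    mass_floor = max(1e-9 * init_total, 1e-12)

    breakpoints = [0.0] + [e[0] for e in events] + [horizon]
    state = np.append(masses0, y0)
    all_t: list[np.ndarray] = []
    all_s: list[np.ndarray] = []
    outcome = "max_time"
    ev_idx = 0
    done = False
    for seg in range(len(breakpoints) - 1):
        t0, t1 = breakpoints[seg], breakpoints[seg + 1]
        if t1 > t0 and not done:
            seg_frac = max((t1 - t0) / horizon, 1e-3)
            t_arr, s_arr, seg_outcome = _integrate_segment(
                model,
                folds,
                state,
                t0,
                t1,
                steady_tol,
                collapse_threshold,
                rtol,
                atol,
                max(int(n_out * seg_frac), 10),
                mass_floor,
            )
            all_t.append(t_arr)
            all_s.append(s_arr)
            state = s_arr[:, -1].copy()
            if seg_outcome is not None:
                outcome = seg_outcome
                # a reset (new clone) can still revive the run; stop only if
                # no further events remain
                if ev_idx >= len(events):
                    done = True
        if ev_idx < len(events) and seg + 1 < len(breakpoints) - 1:
            _, lab, mass = events[ev_idx]
            state[label_index[lab]] = mass
            outcome = "max_time"
            done = False
            ev_idx += 1

    t = np.concatenate(all_t)
    s = np.column_stack(all_s)
    populations = {lab: np.clip(s[i], 0.0, None) for i, lab in enumerate(labels)}
    return Trajectory(t=t, populations=populations, signal=s[-1], outcome=outcome)


def simulate(
    model: CircuitModel,
    Z0: float,
    y0: float,
    horizon: float = 200.0,
    steady_tol: float = 1e-8,
    collapse_fraction: float = 1e-6,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    n_out: int = 400,
) -> Trajectory:
    """Integrate a single wild-type population from (Z0, y0).

    Terminal outcome: 'steady' when the relative state derivatives fall
    below ``steady_tol`` per unit time, 'collapsed' when total mass drops
    below ``collapse_fraction`` of its initial value, else 'max_time'.
    """
    return integrate_populations(
        model,
        labels=["Z"],
        folds=[1.0],
        masses0=[Z0],
        y0=y0,
        horizon=horizon,
        steady_tol=steady_tol,
        collapse_fraction=collapse_fraction,
        rtol=rtol,
        atol=atol,
        n_out=n_out,
    )


def nullclines(model: CircuitModel, y_grid: np.ndarray | None = None) -> dict:
    """Nullclines in the (y, Z) plane.

    The mass nullcline is the set of vertical lines {y : lambda(y) = 0};
    the signal nullcline is Z = M/y (inhibitory) or y = a*Z (activating),
    returned sampled on ``y_grid``.
    """
    if y_grid is None:
        y_grid = np.geomspace(1e-2, 1e2, 400)
    y_grid = np.asarray(y_grid, dtype=float)
    if np.any(y_grid <= 0):
        raise SignalDomainError("grid must be positive")
    growth_roots = find_growth_roots(model.growth_law)
    signal_Z = np.array([model.coupling.steady_mass(y) for y in y_grid])
    return {
        "growth_nullcline_y": np.asarray(growth_roots),
        "signal_nullcline": (y_grid, signal_Z),
    }


def basin_outcome(
    model: CircuitModel,
    Z_values: Sequence[float],
    y_values: Sequence[float],
    horizon: float = 200.0,
) -> pd.DataFrame:
    """Outcome map over a grid of initial conditions.

    Returns a DataFrame indexed by initial Z with one column per initial y;
    entries are 'homeostasis' (steady state reached), 'collapse', or
    'undecided' (horizon hit). Z = 0 is absorbing and reported 'collapse'.
    """
    records = {}
    for Z0 in Z_values:
        row = {}
        for y0 in y_values:
            if Z0 == 0:
                row[y0] = "collapse"
                continue
            traj = simulate(model, Z0, y0, horizon=horizon)
            row[y0] = {
                "steady": "homeostasis",
                "collapsed": "collapse",
                "max_time": "undecided",
            }[traj.outcome]
        records[Z0] = row
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "Z0"
    df.columns.name = "y0"
    return df
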