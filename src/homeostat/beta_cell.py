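"""Glucose / beta-cell homeostasis with glucokinase (GCK) sensing.

Beta cells sense blood glucose through GCK, the rate-limiting hexokinase
of the secretion pathway, with half-maximal activity at K = 8.4 mM and a
Hill coefficient of n = 1.8 — so at the 5 mM homeostatic set point GCK
runs at roughly 30% of maximum. Chronically high sensed glucose kills
beta cells (glucotoxicity), making net beta-cell growth *biphasic* in
glucose: negative below 5 mM, positive between 5 and 10 mM, negative
above 10 mM. The model here is

    net growth (per day):  lambda(y_hat) = s * (y_hat - y_st) * (y_ust - y_hat)

with set points y_st = 5 mM (stable) and y_ust = 10 mM (unstable), so the
dynamic-stability gap is delta = 1, and the one free scale s (default
1e-3 per mM^2 per day) sets how slow beta-cell turnover is.

Glucose itself equilibrates much faster than cell mass, so it is solved
at quasi-steady state from an input/clearance balance in which insulin
action is proportional to total GCK flux:

    u0 = c * y * sum_i Z_i * gck_activity(k_i * y)

calibrated so that an all-wild-type tissue at reference mass sits at
exactly 5 mM. A clone with a k-fold GCK sensing mutation senses k*y in
both its secretion and its growth arm.

The conditional knock-in experiment converts a fraction of the mass to a
six-fold activating GCK mutant at day 0: glucose dips (the mutants
over-secrete), the mutants' own sensed glucose lands deep in the toxic
range, and they are purged over ~3 weeks while glucose returns to 5 mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from homeostat.core_dynamics import FixedPoint, FixedPointSet, Trajectory

__all__ = [
    "GCKParams",
    "BetaCellModel",
    "gck_activity",
    "betacell_growth",
    "glucose_balance",
    "knockin_experiment",
    "germline_vs_somatic",
    "growth_fixed_points",
    "mutant_percent",
    "remaining_of_induced",
]


@dataclass(frozen=True)
class GCKParams:
    """GCK Hill kinetics: half-activation K (mM) and exponent n."""

    K: float = 8.4
    n: float = 1.8

    def __post_init__(self):
        if self.K <= 0 or self.n <= 0:
            raise ValueError("K and n must be positive")


def gck_activity(y: float, params: GCKParams = GCKParams()):
    """Fraction of maximal GCK activation at glucose y (mM):
    y**n / (y**n + K**n). Monotone increasing; 0.5 at y = K."""
    y = np.asarray(y, dtype=float)
    with np.errstate(invalid="ignore"):
        yn = np.where(y > 0, y, 0.0) ** params.n
    out = yn / (yn + params.K**params.n)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BetaCellModel:
    """Calibrated beta-cell/glucose model.

    ``populations`` lists (label, fold, mass) clones; the glucose input
    ``u0`` is derived so that a single wild-type population at
    ``reference_mass`` sits at exactly ``y_st`` mM.
    """

    gck: GCKParams = GCKParams()
    s: float = 1e-3  # glucotoxicity scale, per mM^2 per day
    y_st: float = 5.0  # stable set point, mM
    y_ust: float = 10.0  # unstable (glucotoxic) threshold, mM
    reference_mass: float = 1.0
    clearance: float = 1.0  # c in u0 = c*y*sum Z_i*gck(k_i*y)
    input_scale: float = 1.0  # multiplies the calibrated u0 (dietary forcing)
    populations: tuple[tuple[str, float, float], ...] = (("wt", 1.0, 1.0),)

    def __post_init__(self):
        if not (0 < self.y_st < self.y_ust):
            raise ValueError("need 0 < y_st < y_ust")
        if self.s <= 0:
            raise ValueError("s must be positive")

    @property
    def delta(self) -> float:
        return (self.y_ust - self.y_st) / self.y_st

    @property
    def u0(self) -> float:
        """Glucose input rate from the wild-type calibration identity."""
        base = self.clearance * self.y_st * self.reference_mass * gck_activity(self.y_st, self.gck)
        return self.input_scale * base



def betacell_growth(y_sensed, model: BetaCellModel = BetaCellModel()):
    """Net per-capita beta-cell growth rate (per day) at sensed glucose
    y_hat: s*(y_hat - y_st)*(y_ust - y_hat). Positive only between the
    set points; the clone's y_hat is k*y."""
    y_sensed = np.asarray(y_sensed, dtype=float)
    out = model.s * (y_sensed - model.y_st) * (model.y_ust - y_sensed)
    return float(out) if out.ndim == 0 else out


def growth_fixed_points(model: BetaCellModel = BetaCellModel()) -> FixedPointSet:
    """Roots of the net growth law with stability from its sign pattern.

    With the inhibitory glucose coupling (more beta-cell mass means lower
    glucose), growth increasing through a root is stable: the lower root
    y_st is stable, the glucotoxic root y_ust unstable. Located by
    bracketed root search rather than read off the parametrisation, so a
    miscalibrated law would be caught."""
    f = lambda y: betacell_growth(y, model)
    lo = brentq(f, 1e-3, 0.5 * (model.y_st + model.y_ust))
    hi = brentq(f, 0.5 * (model.y_st + model.y_ust), 100.0)
    Z = model.reference_mass
    return FixedPointSet(
        [
            FixedPoint(y=lo, Z=Z, stability="stable"),
            FixedPoint(y=hi, Z=Z, stability="unstable"),
        ]
    )


def glucose_balance(model: BetaCellModel, masses: dict[str, float] | None = None) -> float:
    """Quasi-steady-state blood glucose (mM) for the current populations.

    Solves u0 = c * y * sum_i Z_i * gck(k_i * y) for y by bracketed root
    search. The left side is the (constant) glucose input; the right side
    is insulin-mediated clearance, increasing in y, so the root is
    unique. With a single wild-type population at reference mass the
    answer is the calibration identity y = y_st exactly.
    """
    pops = model.populations
    if masses is not None:
        pops = tuple((lab, k, masses[lab]) for lab, k, _ in pops)
    total = sum(m for _, _, m in pops)
    if total <= 0:
        raise ValueError("total beta-cell mass must be positive")

    def excess(y):
        clearance = model.clearance * y * sum(
            m * gck_activity(k * y, model.gck) for _, k, m in pops
        )
        return model.u0 - clearance

    lo, hi = 1e-6, 1e4
    while excess(hi) > 0 and hi < 1e12:
        hi *= 10.0  # vanishing beta-cell mass pushes glucose arbitrarily high
    if excess(hi) > 0:
        raise RuntimeError("no positive glucose root: clearance cannot match input")
    return brentq(excess, lo, hi, xtol=1e-12)


def _integrate_masses(
    model: BetaCellModel,
    days: float,
    n_out: int = 400,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    labels = [lab for lab, _, _ in model.populations]
    folds = np.array([k for _, k, _ in model.populations])
    Z0 = np.array([m for _, _, m in model.populations], dtype=float)

    def rhs(t, Z):
        masses = dict(zip(labels, Z))
        y = glucose_balance(model, masses)
        return Z * betacell_growth(folds * y, model)

    init_total = float(np.sum(Z0))

    def collapse_event(t, Z):
        return float(np.sum(Z)) - 1e-6 * init_total

    collapse_event.terminal = True

    sol = solve_ivp(
        rhs, (0.0, days), Z0, method="LSODA", rtol=rtol, atol=atol,
        events=[collapse_event], t_eval=np.linspace(0.0, days, n_out),
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"beta-cell integration failed: {sol.message}")
    outcome = "collapsed" if sol.status == 1 else "max_time"
    signal = np.array(
        [glucose_balance(model, dict(zip(labels, col))) for col in sol.y.T]
    )
    populations = {lab: np.clip(sol.y[i], 0.0, None) for i, lab in enumerate(labels)}
    return Trajectory(t=sol.t, populations=populations, signal=signal, outcome=outcome)


def knockin_experiment(
    fraction: float = 0.25,
    fold: float = 6.0,
    days: float = 60.0,
    model: BetaCellModel = BetaCellModel(),
    n_out: int = 400,
) -> Trajectory:
    """Conditional knock-in of a k-fold activating GCK mutant.

    At day 0 a ``fraction`` of the reference beta-cell mass is converted
    to the mutant genotype. Returns the trajectory of both masses and
    glucose; ``fraction = 0`` gives the flat wild-type control. The mutant
    percentage (of total mass) declines after the initial secretion
    transient, and glucose returns to the 5 mM set point.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    M = model.reference_mass
    pops = (("wt", 1.0, (1 - fraction) * M),)
    if fraction > 0:
        pops = pops + (("mut", fold, fraction * M),)
    return _integrate_masses(replace(model, populations=pops), days, n_out=n_out)


def mutant_percent(traj: Trajectory) -> np.ndarray:
    """Mutant share of total beta-cell mass, in percent, along a trajectory."""
    if "mut" not in traj.populations:
        return np.zeros_like(traj.t)
    mut = traj.populations["mut"]
    return 100.0 * mut / traj.total_mass


def remaining_of_induced(traj: Trajectory, at_day: float) -> float:
    """Mutant mass at ``at_day`` as a percentage of the induced (day-0)
    mutant mass — the readout of the lineage-tracing experiment."""
    if "mut" not in traj.populations:
        return 0.0
    induced = traj.populations["mut"][0]
    idx = int(np.searchsorted(traj.t, at_day))
    idx = min(idx, len(traj.t) - 1)
    return 100.0 * traj.populations["mut"][idx] / induced


def germline_vs_somatic(
    fold: float = 6.0,
    fractions: tuple[float, ...] = (1e-3, 0.01, 0.1, 0.5, 0.9, 1.0),
    days: float = 200.0,
    model: BetaCellModel = BetaCellModel(),
    elimination_fraction: float = 1e-3,
) -> dict:
    """Fate of a strong mis-sensing mutant by initial frequency.

    A somatic (rare) mutant is eliminated and glucose stays at 5 mM; a
    germline mutant (fraction 1) owns the tissue and settles where *it*
    senses the set point — glucose y_st/fold (severe hypoglycaemia for an
    activating GCK mutant), with the hyperfunctional tissue grown to
    fold * reference mass. The initial tissue interpolates between the
    homogeneous wild-type and homogeneous mutant steady sizes:
    T(f) = (1-f)*M + f*fold*M, split (1-f)/f — the germline end is the
    tissue the mutant itself develops. The outcome is monotone in the
    fraction; the switch point is located by bisection.
    """
    M = model.reference_mass
    mutant_steady = fold * M  # balance identity: senses y_st at mass fold*M

    def run(f: float) -> tuple[str, float]:
        if f == 0:
            return "eliminated", model.y_st
        total = (1 - f) * M + f * mutant_steady
        pops = (("wt", 1.0, (1 - f) * total), ("mut", fold, f * total))
        if f == 1.0:
            pops = (("mut", fold, total),)
        traj = _integrate_masses(replace(model, populations=pops), days, n_out=200)
        glucose = float(traj.signal[-1])
        if "mut" not in traj.populations:
            return "eliminated", glucose
        fate = (
            "eliminated"
            if traj.populations["mut"][-1] < elimination_fraction * f * M
            else "persists"
        )
        return fate, glucose

    outcomes = {}
    for f in fractions:
        fate, glucose = run(f)
        outcomes[f] = {"fate": fate, "glucose_mM": glucose}

    elim = [f for f, o in outcomes.items() if o["fate"] == "eliminated"]
    fixed = [f for f, o in outcomes.items() if o["fate"] == "persists"]
    threshold = None
    if elim and fixed:
        lo, hi = max(elim), min(fixed)
        while hi - lo > 1e-3:
            mid = 0.5 * (lo + hi)
            if run(mid)[0] == "eliminated":
                lo = mid
            else:
                hi = mid
        threshold = 0.5 * (lo + hi)
    return {"outcomes": outcomes, "threshold": threshold}
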