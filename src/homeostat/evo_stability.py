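"""Evolutionary stability of a compartmentalised tissue.

A tissue split into compartments of N cells (e.g. pancreatic islets)
accumulates mis-sensing mutants by somatic mutation during cell division.
Within a compartment a rare advantageous mutant fixes with the Moran
probability rho = (1 - 1/r)/(1 - 1/r^N), which tends to 1 - 1/r for large
N. Advantageous mutations arrive at rate N * tau_inv * delta * mu0 per
compartment (divisions per unit time, times the per-division probability
of producing a mutant whose sensed signal lands inside the advantageous
window of relative width delta). The probability that a compartment is
still mutant-free at time t is therefore

    zeta(t) = exp(-N * tau_inv * delta * mu0 * (1 - 1/nu) * t)

with nu = lambda_plus/lambda_minus the mutant's proliferation/removal
ratio (its Moran fitness in the large-N limit). All rates are per day.

The stochastic Moran simulator in this module is the brute-force check of
that formula, and of the fixation probability, at small N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from homeostat.core_dynamics import CircuitModel, delta_metric, find_fixed_points
from homeostat.mutant_invasion import advantageous_window

__all__ = [
    "EvoStabParams",
    "MoranConfig",
    "MoranResult",
    "zeta",
    "invaded_fraction",
    "fixation_probability",
    "moran_simulate",
    "response_rate",
    "tradeoff_table",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class EvoStabParams:
    """Parameters of the compartment-invasion formula.

    N: cells per compartment; tau_inv: per-cell division (turnover) rate
    in 1/day; mu0: probability per division of an advantageous mis-sensing
    mutation; delta: relative stable-unstable gap of the circuit; nu:
    mutant proliferation/removal ratio; t: elapsed time in days.
    """

    N: int = 3500
    tau_inv: float = 1e-3
    mu0: float = 1e-7
    delta: float = 1.0
    nu: float = 3.0
    t: float = 70 * DAYS_PER_YEAR

    def __post_init__(self):
        if self.N < 2 or self.N != int(self.N):
            raise ValueError("N must be an integer >= 2")
        for name in ("tau_inv", "mu0", "delta", "t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nu <= 0:
            raise ValueError("nu must be > 0")


def zeta(params: EvoStabParams) -> float:
    """Probability that no advantageous mutant has invaded a compartment
    by time t. Decreasing in every parameter; zeta(0) = 1."""
    exponent = params.N * params.tau_inv * params.delta * params.mu0 * (1 - 1 / params.nu) * params.t
    return math.exp(-exponent)


def invaded_fraction(params: EvoStabParams) -> float:
    """Expected fraction of compartments carrying an invading mutant: 1 - zeta."""
    return 1.0 - zeta(params)


def fixation_probability(r: float, N: int) -> float:
    """Moran fixation probability of a single mutant with relative fitness
    r in a population of N: (1 - 1/r)/(1 - 1/r**N); 1/N in the neutral
    limit. Tends to 1 - 1/r as N grows."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if r <= 0:
        raise ValueError("fitness must be positive")
    if abs(r - 1.0) < 1e-12:
        return 1.0 / N
    # for r < 1 and large N, r**(-N) overflows; p ~ (1/r - 1) * r**N then
    log_r_inv_N = -N * math.log(r)
    if log_r_inv_N > 700:
        return math.exp(math.log(1.0 / r - 1.0) - log_r_inv_N)
    return (1.0 - 1.0 / r) / (1.0 - r ** (-N))


def response_rate(tau_inv: float, nu: float) -> float:
    """Net per-capita recovery rate lambda_plus - lambda_minus =
    tau_inv * (nu - 1)/nu; the speed at which the tissue corrects a
    perturbation, and the other side of the evolutionary-stability
    tradeoff."""
    if nu <= 0:
        raise ValueError("nu must be > 0")
    return tau_inv * (nu - 1.0) / nu


@dataclass(frozen=True)
class MoranConfig:
    """Configuration of the stochastic Moran simulator.

    One generation = N birth-death update steps = 1/tau_inv time units.
    ``mutation_rate`` is the per-division probability that a wild-type
    offspring becomes the advantageous type.
    """

    N: int = 100
    fitness: float = 3.0
    mutation_rate: float = 0.0
    initial_mutants: int = 1
    max_generations: int = 10_000
    replicates: int = 1000
    seed: int = 0
    tau_inv: float = 1.0  # generations per unit time

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.fitness <= 0:
            raise ValueError("fitness must be positive")
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation rate must lie in [0, 1]")


@dataclass
class MoranResult:
    fixed: np.ndarray  # bool per replicate
    fixation_time: np.ndarray  # time units (nan if not fixed); with mutation,
    # the arrival time of the lineage that eventually fixed
    config: MoranConfig

    @property
    def fixation_fraction(self) -> float:
        return float(np.mean(self.fixed))

    def invaded_by(self, t: float) -> float:
        """Fraction of replicates whose successful mutant had arisen by t."""
        with np.errstate(invalid="ignore"):
            return float(np.mean(self.fixed & (self.fixation_time <= t)))


def moran_simulate(config: MoranConfig) -> MoranResult:
    """Seeded, vectorised Moran process over independent replicates.

    Each step picks a parent with probability proportional to fitness and
    replaces a uniformly chosen cell (population size constant at N). With
    mutation_rate > 0 a wild-type offspring converts to the advantageous
    type; in that regime a replicate counts as invaded once a mutant
    lineage reaches fixation, and the reported time is the *arrival* time
    of that lineage (the quantity the closed-form zeta describes).
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    N, r, u = config.N, config.fitness, config.mutation_rate
    reps = config.replicates
    i = np.full(reps, config.initial_mutants if u == 0 else 0, dtype=np.int64)
    fixed = np.zeros(reps, dtype=bool)
    # per-replicate step clocks (steps of size 1/(tau_inv*N) time units)
    steps = np.zeros(reps, dtype=np.float64)
    arrival = np.zeros(reps) if u == 0 else np.full(reps, np.nan)
    fix_time = np.full(reps, np.nan)
    active = np.ones(reps, dtype=bool)

    dt_step = 1.0 / (config.tau_inv * N)  # N steps per generation
    max_steps = float(config.max_generations) * N
    while active.any():
        idx = np.nonzero(active)[0]
        if u > 0:
            # replicates with no mutants: jump geometrically to the next
            # mutation event (a wild-type birth mutating, prob u per step);
            # secondary mutations during an ongoing sweep are neglected
            # (they would found a second, indistinguishable lineage)
            empty = idx[i[idx] == 0]
            if empty.size:
                wait = rng.geometric(u, size=empty.size)
                steps[empty] += wait
                timed_out = steps[empty] > max_steps
                active[empty[timed_out]] = False
                seeded = empty[~timed_out]
                i[seeded] = 1
                arrival[seeded] = steps[seeded] * dt_step
                idx = np.nonzero(active & (i > 0))[0]
        if idx.size == 0:
            continue
        m = i[idx].astype(float)
        w = N - m
        p_birth_mut = r * m / (r * m + w)
        birth_mut = rng.random(idx.size) < p_birth_mut
        death_mut = rng.random(idx.size) < m / N
        i[idx] += birth_mut.astype(np.int64) - death_mut.astype(np.int64)
        steps[idx] += 1
        at_fix = i[idx] >= N
        at_loss = i[idx] <= 0
        timed_out = steps[idx] > max_steps
        if at_fix.any():
            gidx = idx[at_fix]
            fixed[gidx] = True
            fix_time[gidx] = arrival[gidx] if u > 0 else steps[gidx] * dt_step
            active[gidx] = False
        if u == 0:
            active[idx[at_loss]] = False
        else:
            arrival[idx[at_loss]] = np.nan  # lineage lost; wait for the next
        active[idx[timed_out & ~at_fix]] = False
    return MoranResult(fixed=fixed, fixation_time=fix_time, config=config)


def tradeoff_table(
    circuits: list[CircuitModel],
    params: EvoStabParams = EvoStabParams(),
) -> pd.DataFrame:
    """Dynamic- vs evolutionary-stability tradeoff across a circuit family.

    For each biphasic circuit: its gap delta, zeta(t) evaluated with that
    delta (other compartment parameters fixed), and the advantageous
    fold-change window width k_max - 1 (= delta for inhibitory coupling).
    zeta falls as delta widens while the invadable window grows.
    """
    from dataclasses import replace

    rows = []
    for model in circuits:
        fps = find_fixed_points(model)
        d = delta_metric(fps)
        k_lo, k_hi = advantageous_window(model)
        rows.append(
            {
                "circuit": model.name,
                "delta": d,
                "zeta": zeta(replace(params, delta=d)),
                "window_width": k_hi - k_lo,
            }
        )
    return pd.DataFrame(rows).sort_values("delta", ignore_index=True)
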