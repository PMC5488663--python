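"""Config-driven scenario runs, stochastic mutation schedules, ensembles.

A scenario is one fully specified run — circuit, initial state, invasion
schedule (explicit clone events or a seeded stochastic generator),
integration settings, seed — stored in a single TOML or JSON file so that
every simulation in the package (and every figure-style experiment) is a
reviewable, diffable fixture. Outputs are a TSV trajectory with
'#'-prefixed metadata lines plus a JSON summary sidecar.

The stochastic schedule generator emulates the mutational input a tissue
compartment actually sees: mutant clones arrive as a Poisson process at
rate N * tau_inv * mu0, and their sensing fold-effects are drawn from a
mixture dominated by strong effects — loss-of-function (k << 1) and
locked-on (k >> 1) point masses — plus a log-normal mild-effect tail,
reflecting the larger mutational target of breaking a sensor than of
tuning it.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from homeostat import presets
from homeostat.core_dynamics import CircuitModel, Trajectory, find_fixed_points, simulate
from homeostat.evo_stability import EvoStabParams, MoranConfig, moran_simulate, zeta
from homeostat.mutant_invasion import (
    InvasionSchedule,
    MutantClone,
    clone_fates,
    simulate_with_mutants,
)

__all__ = [
    "ScenarioConfig",
    "MutationScheduleSpec",
    "ConfigError",
    "generate_schedule",
    "load_config",
    "run_scenario",
    "ensemble",
    "list_fixtures",
    "fixture_path",
]

KINDS = ("simulate", "invade", "betacell", "stemcell", "moran")


class ConfigError(ValueError):
    """A scenario file violates the schema; the message names the key."""


@dataclass(frozen=True)
class MutationScheduleSpec:
    """Seeded stochastic mutation schedule.

    ``rate`` is the clone arrival rate per unit time (per compartment,
    N * tau_inv * mu0). The fold-effect mixture has point masses at
    ``k_loss`` (< 1, strong sensing loss) and ``k_locked`` (> 1, sensor
    locked on) with a log-normal mild-effect component centred on k = 1.
    """

    rate: float = 0.05
    horizon: float = 1000.0
    seed: int = 0
    weight_loss: float = 0.4
    weight_locked: float = 0.4
    weight_mild: float = 0.2
    k_loss: float = 1.0 / 16.0
    k_locked: float = 8.0
    mild_sigma: float = 0.35
    introduction_mass: float = 1.0

    def __post_init__(self):
        w = self.weight_loss + self.weight_locked + self.weight_mild
        if abs(w - 1.0) > 1e-9:
            raise ConfigError(f"mixture weights must sum to 1, got {w}")
        if not (self.k_loss < 1.0 < self.k_locked):
            raise ConfigError("need k_loss < 1 < k_locked")
        if self.rate < 0:
            raise ConfigError("rate must be >= 0")


def generate_schedule(spec: MutationScheduleSpec) -> InvasionSchedule:
    """Draw a Poisson arrival schedule with i.i.d. mixture fold-effects.

    Reproducible for a fixed seed; a zero rate yields an empty schedule.
    """
    if spec.rate == 0:
        return InvasionSchedule([])
    rng = np.random.default_rng(spec.seed)
    n = rng.poisson(spec.rate * spec.horizon)
    times = np.sort(rng.uniform(0.0, spec.horizon, size=n))
    comp = rng.choice(
        3, size=n, p=[spec.weight_loss, spec.weight_locked, spec.weight_mild]
    )
    folds = np.where(
        comp == 0,
        spec.k_loss,
        np.where(comp == 1, spec.k_locked, rng.lognormal(0.0, spec.mild_sigma, size=n)),
    )
    clones = [
        MutantClone(fold=float(k), time=float(t), mass=spec.introduction_mass, label=f"mut{i:03d}")
        for i, (t, k) in enumerate(zip(times, folds))
    ]
    return InvasionSchedule(clones)


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully specified run; round-trips losslessly through to_dict."""

    kind: str = "simulate"
    seed: int = 0
    circuit: dict = field(default_factory=lambda: {"preset": "monophasic"})
    initial: dict = field(default_factory=dict)
    run: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)  # betacell / stemcell / moran params

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"kind: unknown scenario kind {self.kind!r}; expected one of {KINDS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def build_circuit(self) -> CircuitModel:
        spec = dict(self.circuit)
        preset = spec.pop("preset", None)
        if preset is not None:
            try:
                model = getattr(presets, preset)()
            except AttributeError:
                raise ConfigError(f"circuit.preset: unknown preset {preset!r}")
            cap = spec.pop("carrying_capacity", None)
            delay = spec.pop("sensing_delay", None)
            if spec:
                raise ConfigError(f"circuit: unexpected key(s) {sorted(spec)}")
            if cap is not None or delay is not None:
                model = model.with_variant(
                    carrying_capacity=float(cap) if cap is not None else None,
                    sensing_delay=delay,
                )
            return model
        try:
            return CircuitModel.from_dict(spec)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"circuit: {exc}") from exc

    def build_schedule(self) -> InvasionSchedule:
        sched = dict(self.schedule)
        clones = sched.pop("clones", None)
        stochastic = sched.pop("stochastic", None)
        if sched:
            raise ConfigError(f"schedule: unexpected key(s) {sorted(sched)}")
        if clones is not None and stochastic is not None:
            raise ConfigError("schedule: give either clones or stochastic, not both")
        if stochastic is not None:
            try:
                spec = MutationScheduleSpec(**stochastic)
            except TypeError as exc:
                raise ConfigError(f"schedule.stochastic: {exc}") from exc
            return generate_schedule(spec)
        if clones is None:
            return InvasionSchedule([])
        try:
            return InvasionSchedule([MutantClone(**c) for c in clones])
        except TypeError as exc:
            raise ConfigError(f"schedule.clones: {exc}") from exc


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a scenario from TOML or JSON (by extension)."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    elif path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        raise ConfigError(f"unsupported config extension {path.suffix!r} (use .toml or .json)")
    return ScenarioConfig.from_dict(data)


def _run_circuit(config: ScenarioConfig):
    model = config.build_circuit()
    init = config.initial
    Z0 = float(init.get("Z", 1.0))
    y0 = float(init.get("y", 1.0))
    horizon = float(config.run.get("horizon", 200.0))
    schedule = config.build_schedule() if config.kind == "invade" else InvasionSchedule([])
    if len(schedule):
        traj = simulate_with_mutants(model, schedule, Z0=Z0, y0=y0, horizon=horizon)
        fates = clone_fates(traj, schedule)
    else:
        traj = simulate(model, Z0, y0, horizon=horizon)
        fates = {}
    fps = find_fixed_points(model)
    traj.fixed_points = fps
    summary = {
        "kind": config.kind,
        "seed": config.seed,
        "outcome": traj.outcome,
        "final": traj.final(),
        "fixed_points": fps.to_records(),
        "clone_fates": fates,
    }
    return traj, summary


def _run_betacell(config: ScenarioConfig):
    from homeostat import beta_cell

    params = dict(config.model)
    fraction = float(params.pop("fraction", 0.25))
    fold = float(params.pop("fold", 6.0))
    days = float(params.pop("days", 60.0))
    model = beta_cell.BetaCellModel(**params) if params else beta_cell.BetaCellModel()
    traj = beta_cell.knockin_experiment(fraction=fraction, fold=fold, days=days, model=model)
    pct = beta_cell.mutant_percent(traj)
    summary = {
        "kind": "betacell",
        "seed": config.seed,
        "final": traj.final(),
        "mutant_percent_final": float(pct[-1]),
        "remaining_of_induced_day22": beta_cell.remaining_of_induced(traj, 22.0),
        "glucose_final_mM": float(traj.signal[-1]),
    }
    traj.populations["mutant_percent"] = pct
    return traj, summary


def _run_stemcell(config: ScenarioConfig):
    from homeostat import stem_cell

    params = dict(config.model)
    law = params.pop("law", "monophasic")
    renewal = {"monophasic": stem_cell.pr_monophasic, "biphasic": stem_cell.pr_biphasic}.get(law)
    if renewal is None:
        raise ConfigError(f"model.law: unknown renewal law {law!r}")
    mutant_time = params.pop("mutant_time", None)
    mutant_mass = float(params.pop("mutant_mass", 0.01))
    horizon = float(params.pop("horizon", 100.0))
    fold = float(params.pop("fold", 1.0 / 16.0))
    init = config.initial
    state0 = stem_cell.StemState(
        Z_s=float(init.get("Z_s", 0.5)),
        Z_s_mut=float(init.get("Z_s_mut", 0.0)),
        Z_d=float(init.get("Z_d", 1.0)),
    )
    model = stem_cell.StemCellModel(renewal=renewal, fold=fold, **params)
    traj = stem_cell.simulate_stem(
        model, state0, mutant_time=mutant_time, mutant_mass=mutant_mass, horizon=horizon
    )
    summary = {
        "kind": "stemcell",
        "seed": config.seed,
        "outcome": traj.outcome,
        "final": traj.final(),
        "fixed_points": stem_cell.stem_fixed_points(model).to_records(),
    }
    return traj, summary


def _run_moran(config: ScenarioConfig):
    params = dict(config.model)
    params.setdefault("seed", config.seed)
    try:
        mc = MoranConfig(**params)
    except TypeError as exc:
        raise ConfigError(f"model: {exc}") from exc
    result = moran_simulate(mc)
    summary = {
        "kind": "moran",
        "seed": mc.seed,
        "fixation_fraction": result.fixation_fraction,
        "replicates": mc.replicates,
    }
    return result, summary


def run_scenario(config: ScenarioConfig, outdir: str | Path | None = None):
    """Dispatch a scenario to its module and optionally write results.

    Returns (result, summary). ``result`` is a Trajectory for ODE
    scenarios or a MoranResult for stochastic ones. With ``outdir`` set,
    writes trajectory.tsv (+ .json sidecar) and summary.json there.
    """
    from homeostat import __version__

    runner = {
        "simulate": _run_circuit,
        "invade": _run_circuit,
        "betacell": _run_betacell,
        "stemcell": _run_stemcell,
        "moran": _run_moran,
    }[config.kind]
    result, summary = runner(config)
    summary["version"] = __version__
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if isinstance(result, Trajectory):
            result.write_tsv(outdir / "trajectory.tsv", metadata={"seed": config.seed})
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return result, summary


def _wilson_ci(successes: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = successes / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(centre - half, 0.0), min(centre + half, 1.0))


def ensemble(
    config: ScenarioConfig,
    replicates: int,
    seed: int,
    checkpoints: list[float] | None = None,
) -> dict:
    """Independent seeded replicates of a stochastic scenario.

    For Moran scenarios the replicates are folded into one vectorised run
    (each compartment is a replicate); the invaded fraction at each time
    checkpoint comes with a 95% Wilson confidence interval. Deterministic
    scenarios return the single summary (replication would be identical)
    with a degenerate [0, 1] interval convention when only one replicate
    is informative.
    """
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    if config.kind == "moran":
        params = dict(config.model)
        params["replicates"] = replicates
        params["seed"] = seed
        mc = MoranConfig(**params)
        result = moran_simulate(mc)
        if checkpoints is None:
            checkpoints = [float(mc.max_generations) / mc.tau_inv]
        rows = []
        for t in checkpoints:
            frac = result.invaded_by(t)
            k = int(round(frac * replicates))
            lo, hi = _wilson_ci(k, replicates)
            rows.append({"t": t, "invaded_fraction": frac, "ci_low": lo, "ci_high": hi})
        return {"kind": "moran", "replicates": replicates, "seed": seed, "trajectory": rows}
    _, summary = run_scenario(config)
    summary["replicates"] = replicates
    summary["ci"] = [0.0, 1.0] if replicates == 1 else None
    return {"kind": config.kind, "replicates": replicates, "seed": seed, "summary": summary}


def list_fixtures() -> list[str]:
    """Names of the bundled scenario files (figure-style experiments)."""
    pkg = resources.files("homeostat") / "fixtures"
    return sorted(p.name for p in pkg.iterdir() if p.suffix == ".toml")


def fixture_path(name: str) -> Path:
    pkg = resources.files("homeostat") / "fixtures"
    path = pkg / name
    if not path.is_file():
        raise FileNotFoundError(f"no bundled fixture {name!r}; see list_fixtures()")
    return Path(str(path))
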