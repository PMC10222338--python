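"""Non-equilibrium switching engine.

A switch drives the system from the low to the high level of theory (or the
reverse) over ``n_switch_steps`` Langevin-dynamics steps while the coupling
parameter λ follows a schedule.  After every dynamics step the accumulated
work is incremented by

    W(t+δt) = W(t) + U(x_{t+δt}, λ_{t+δt}) − U(x_{t+δt}, λ_t)

i.e. both energies are evaluated at the post-step coordinates.  Since
U(λ) = (1−λ)·U_low + λ·U_high, the increment equals
(λ_{t+δt} − λ_t)·(U_high − U_low) at the new coordinates.

Schedules are piecewise-linear paths in *time fraction*; besides the plain
linear ramp (L1) three two/three-stage presets are shipped in which λ rises
quickly at first and more slowly afterwards:

========  =====================================================
label     stages (duration fs → λ at stage end), total 2000 fs
========  =====================================================
L2-1      200 → 0.35, 1800 → 1.0
L3-1      200 → 0.35, 900 → 0.8, 900 → 1.0
L3-2      200 → 0.35, 400 → 0.8, 1400 → 1.0
========  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import BAOAB, RestartPool, system_friction
from .model_systems import Configuration, DualLevelSystem
from .seeds import child_rng, child_seed

__all__ = [
    "Schedule",
    "SwitchSettings",
    "WorkRecord",
    "SwitchFailure",
    "linear_schedule",
    "stepwise_schedule",
    "preset_schedule",
    "lambda_at",
    "hybrid_energy",
    "run_switch",
    "run_switch_ensemble",
    "PRESET_STAGES",
]

#: stage tables (duration_fs, lambda_end) for the shipped presets, 2000 fs total
PRESET_STAGES: dict[str, list[tuple[float, float]]] = {
    "L2-1": [(200.0, 0.35), (1800.0, 1.0)],
    "L3-1": [(200.0, 0.35), (900.0, 0.8), (900.0, 1.0)],
    "L3-2": [(200.0, 0.35), (400.0, 0.8), (1400.0, 1.0)],
}


class ScheduleError(ValueError):
    pass


class SwitchFailure(RuntimeError):
    """Integration divergence during a switch; carries the partial work trace."""

    def __init__(self, message: str, partial_trace: np.ndarray):
        super().__init__(message)
        self.partial_trace = partial_trace


@dataclass(frozen=True)
class Schedule:
    """Piecewise-linear map from time fraction (0–1) to λ (0–1)."""

    breakpoints: tuple[tuple[float, float], ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if len(bp) < 2 or bp[0] != (0.0, 0.0) or bp[-1] != (1.0, 1.0):
            raise ScheduleError("schedule must start at (0,0) and end at (1,1)")
        t = np.array([p[0] for p in bp])
        lam = np.array([p[1] for p in bp])
        if np.any(np.diff(t) < 0) or np.any(np.diff(lam) < 0):
            raise ScheduleError("breakpoints must be non-decreasing in both axes")

    def value(self, time_fraction: float) -> float:
        t = np.array([p[0] for p in self.breakpoints])
        lam = np.array([p[1] for p in self.breakpoints])
        return float(np.interp(time_fraction, t, lam))


def linear_schedule(n_switch_steps: int = 2000) -> Schedule:
    """The standard linear ramp λ(i) = i/Nswitch (label L1)."""
    if n_switch_steps < 1:
        raise ValueError("n_switch_steps must be >= 1")
    return Schedule(breakpoints=((0.0, 0.0), (1.0, 1.0)), label="L1")


def stepwise_schedule(
    stages: list[tuple[float, float]], total_fs: float, label: str = "custom"
) -> Schedule:
    """A multi-stage piecewise-linear schedule from (duration_fs, λ_end) stages."""
    durations = np.array([s[0] for s in stages], float)
    lam_ends = [s[1] for s in stages]
    if abs(durations.sum() - total_fs) > 1e-9 * max(1.0, total_fs):
        raise ScheduleError(
            f"stage durations sum to {durations.sum():g} fs, expected {total_fs:g}"
        )
    if any(b < a for a, b in zip(lam_ends, lam_ends[1:])) or lam_ends[-1] != 1.0:
        raise ScheduleError("stage end-λ values must be non-decreasing and end at 1.0")
    bp = [(0.0, 0.0)]
    t = 0.0
    for dur, lam in stages:
        t += dur
        bp.append((t / total_fs, float(lam)))
    bp[-1] = (1.0, 1.0)
    return Schedule(breakpoints=tuple(bp), label=label)


def preset_schedule(label: str) -> Schedule:
    """L1, L2-1, L3-1 or L3-2 (2000 fs stage tables)."""
    if label == "L1":
        return linear_schedule()
    if label not in PRESET_STAGES:
        raise ScheduleError(f"unknown schedule label {label!r}")
    stages = PRESET_STAGES[label]
    return stepwise_schedule(stages, sum(d for d, _ in stages), label=label)


def lambda_at(schedule: Schedule, step: int, n_switch_steps: int) -> float:
    """λ at integer step ``step`` of an ``n_switch_steps``-step switch."""
    if not 0 <= step <= n_switch_steps:
        raise IndexError(f"step {step} outside [0, {n_switch_steps}]")
    return schedule.value(step / n_switch_steps)


@dataclass
class SwitchSettings:
    n_switch_steps: int = 2000
    timestep: float = 1.0  # fs
    schedule: Schedule = field(default_factory=linear_schedule)
    direction: str = "forward"
    seed: int = 0
    friction: float | None = None  # 1/ps; None = system default
    record_trace: bool = False

    def __post_init__(self) -> None:
        if self.n_switch_steps < 1:
            raise ValueError("n_switch_steps must be >= 1")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")


@dataclass
class WorkRecord:
    final_work: float  # kcal/mol
    direction: str
    schedule_label: str
    n_steps: int
    start_provenance: dict = field(default_factory=dict)
    seed: int = 0
    work_trace: np.ndarray | None = None
    final_configuration: Configuration | None = None


def hybrid_energy(
    system: DualLevelSystem, config: Configuration, lambda_value: float
) -> float:
    """U(λ) = (1−λ)·U_low + λ·U_high at a configuration."""
    if not 0.0 <= lambda_value <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    q, _ = system.engine.pack(config)
    e0, e1, _, _ = system.engine.both(q)
    u = (1.0 - lambda_value) * e0 + lambda_value * e1
    if not np.isfinite(u):
        raise FloatingPointError("non-finite hybrid energy")
    return float(u)


def run_switch(
    system: DualLevelSystem, start: Configuration, settings: SwitchSettings
) -> WorkRecord:
    """One non-equilibrium switch from a saved restart configuration.

    The starting velocities come from the restart record.  λ₀ = 0 at the
    starting configuration and is incremented after each dynamics step; the
    thermostat stays active throughout.  A backward switch runs the same
    schedule on the level-swapped system (λ measured toward the low level).
    """
    work_system = system.swapped() if settings.direction == "backward" else system
    engine = work_system.engine
    integ = BAOAB(
        engine,
        settings.timestep,
        system_friction(work_system, settings.friction),
        work_system.thermo.kT,
    )
    rng = child_rng(settings.seed, "switch-noise")
    n = settings.n_switch_steps
    lambdas = np.array([lambda_at(settings.schedule, i, n) for i in range(n + 1)])
    q, v = engine.pack(start)
    e0, e1, f0, f1 = engine.both(q)
    w = 0.0
    trace = np.zeros(n + 1) if settings.record_trace else None
    for i in range(1, n + 1):
        state = (e0, e1, f0, f1, lambdas[i - 1])
        try:
            q, v, state = integ.step(q, v, state, rng)
        except FloatingPointError as exc:  # pragma: no cover - defensive
            raise SwitchFailure(str(exc), trace[:i] if trace is not None else np.zeros(0))
        e0, e1, f0, f1, _ = state
        if not (np.isfinite(e0) and np.isfinite(e1)):
            raise SwitchFailure(
                f"non-finite energy at switch step {i}",
                trace[:i] if trace is not None else np.zeros(0),
            )
        w += (lambdas[i] - lambdas[i - 1]) * (e1 - e0)
        if trace is not None:
            trace[i] = w
    return WorkRecord(
        final_work=w,
        direction=settings.direction,
        schedule_label=settings.schedule.label,
        n_steps=n,
        start_provenance=dict(start.provenance),
        seed=settings.seed,
        work_trace=trace,
        final_configuration=engine.unpack(
            q, v, time_fs=n * settings.timestep, provenance=dict(start.provenance)
        ),
    )


def run_switch_ensemble(
    system: DualLevelSystem, starts: RestartPool, settings: SwitchSettings
) -> list[WorkRecord]:
    """Independent switches from every start in the pool, in pool order.

    Each switch gets a child seed derived from ``(settings.seed, index)``,
    so results do not depend on execution order and the ensemble is
    reproducible from the master seed.
    """
    if len(starts) == 0:
        raise ValueError("starts pool is empty")
    records: list[WorkRecord] = []
    failures: list[tuple[int, SwitchFailure]] = []
    for i, conf in enumerate(starts.configurations):
        s = SwitchSettings(
            n_switch_steps=settings.n_switch_steps,
            timestep=settings.timestep,
            schedule=settings.schedule,
            direction=settings.direction,
            seed=child_seed(settings.seed, "ensemble", i),
            friction=settings.friction,
            record_trace=settings.record_trace,
        )
        try:
            records.append(run_switch(system, conf, s))
        except SwitchFailure as exc:
            failures.append((i, exc))
    if failures and not records:
        raise failures[0][1]
    return records
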