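"""Langevin-dynamics sampling of equilibrium configurations.

A BAOAB-splitting Langevin integrator propagates the system on the hybrid
potential U(λ) at any fixed λ (including the λ=0 and λ=1 endpoints).
Replicate simulations with independent Maxwell–Boltzmann initial velocities
build a pool of restart configurations from which non-equilibrium switches
are started; velocities are part of each restart record and are *not*
resampled when a switch begins.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from .constants import KCAL_MOL_TO_INTERNAL
from .model_systems import Configuration, DualLevelSystem
from .seeds import child_rng

__all__ = [
    "SamplerSettings",
    "RestartPool",
    "IntegrationError",
    "sample_equilibrium",
    "select_switch_starts",
    "relax_gap_ensemble",
]


class IntegrationError(RuntimeError):
    """Raised when the dynamics produce a non-finite energy."""


@dataclass
class SamplerSettings:
    """Settings for equilibrium Langevin sampling.

    ``friction`` is the thermostat collision frequency in 1/ps; ``None``
    defers to the system: dipole-bath systems use their solvent's rotational
    friction, all others fall back to 5/ps.
    """

    timestep: float = 1.0  # fs
    friction: float | None = None  # 1/ps
    n_equil_steps: int = 1000
    n_prod_steps: int = 10000
    save_every: int = 10
    n_replicates: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.save_every < 1:
            raise ValueError("save_every must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class RestartPool:
    """An ordered pool of saved configurations with per-item provenance."""

    configurations: list[Configuration]
    source_level: float | str
    settings: SamplerSettings | None = None

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def replicate_ids(self) -> list[int]:
        return [c.provenance.get("replicate", 0) for c in self.configurations]


def system_friction(system: DualLevelSystem, settings_friction: float | None) -> float:
    if settings_friction is not None:
        return settings_friction
    if system.solvent is not None and getattr(system.engine, "uses_rotors", False):
        return system.solvent.rotational_friction
    return 5.0


class BAOAB:
    """BAOAB Langevin splitting (accurate configurational sampling at ~1 fs)."""

    def __init__(self, engine, dt_fs: float, friction_per_ps: float, kT_kcal: float):
        self.engine = engine
        self.dt = dt_fs
        self.h2 = 0.5 * dt_fs
        self.masses = np.asarray(engine.masses, float)
        self.kT_int = kT_kcal * KCAL_MOL_TO_INTERNAL
        gamma = friction_per_ps * 1e-3  # 1/fs
        self.c1 = np.exp(-gamma * dt_fs)
        self.c2 = np.sqrt((1.0 - self.c1**2) * self.kT_int / self.masses)
        self.f_scale = KCAL_MOL_TO_INTERNAL / self.masses

    def maxwell_velocities(self, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(self.kT_int / self.masses))

    def step(self, q, v, mix_old, rng):
        """One BAOAB step; ``mix_old`` is the cached (e0,e1,f0,f1,λ) force state."""
        e0, e1, f0, f1, lam = mix_old
        f = (1.0 - lam) * f0 + lam * f1
        v = v + self.h2 * self.f_scale * f
        q = q + self.h2 * v
        v = self.c1 * v + self.c2 * rng.standard_normal(q.size)
        q = q + self.h2 * v
        e0, e1, f0, f1 = self.engine.both(q)
        f = (1.0 - lam) * f0 + lam * f1
        v = v + self.h2 * self.f_scale * f
        return q, v, (e0, e1, f0, f1, lam)


def _initial_state(system: DualLevelSystem, rng: np.random.Generator, integ: BAOAB):
    engine = system.engine
    q = engine.initial_coords()
    if getattr(engine, "uses_rotors", False) and q.size:
        q = rng.uniform(0.0, 2.0 * np.pi, size=q.size)
    v = integ.maxwell_velocities(rng)
    return q, v


def _check_finite(e0, e1, lam, replicate, step):
    u = (1.0 - lam) * e0 + lam * e1
    if not np.isfinite(u):
        raise IntegrationError(
            f"non-finite energy in replicate {replicate} at step {step}"
        )


def sample_equilibrium(
    system: DualLevelSystem,
    lambda_value: float,
    settings: SamplerSettings,
    initial: Configuration | None = None,
) -> RestartPool:
    """Replicate Langevin sampling on U(λ); returns the saved restart pool.

    Each replicate is seeded deterministically from ``(settings.seed,
    replicate_id)``, draws fresh Maxwell–Boltzmann velocities, discards
    ``n_equil_steps``, then saves a configuration every ``save_every`` steps
    of the production phase.  When ``initial`` is given, every replicate
    starts from its coordinates (with fresh velocities) instead of a random
    configuration — used to chain λ windows in staged calculations.
    """
    if not 0.0 <= lambda_value <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    engine = system.engine
    integ = BAOAB(
        engine,
        settings.timestep,
        system_friction(system, settings.friction),
        system.thermo.kT,
    )
    configs: list[Configuration] = []
    for rep in range(settings.n_replicates):
        rng = child_rng(settings.seed, "equilibrate", rep)
        if initial is not None:
            q, _ = engine.pack(initial)
            v = integ.maxwell_velocities(rng)
        else:
            q, v = _initial_state(system, rng, integ)
        e0, e1, f0, f1 = engine.both(q)
        state = (e0, e1, f0, f1, lambda_value)
        for step in range(1, settings.n_equil_steps + settings.n_prod_steps + 1):
            q, v, state = integ.step(q, v, state, rng)
            _check_finite(state[0], state[1], lambda_value, rep, step)
            prod_step = step - settings.n_equil_steps
            if prod_step > 0 and prod_step % settings.save_every == 0:
                configs.append(
                    engine.unpack(
                        q,
                        v,
                        time_fs=prod_step * settings.timestep,
                        provenance={"replicate": rep, "step": prod_step},
                    )
                )
    label: float | str = lambda_value
    return RestartPool(configurations=configs, source_level=label, settings=settings)


def select_switch_starts(pool: RestartPool, stride: int) -> RestartPool:
    """Every ``stride``-th configuration, order and provenance preserved.

    Slicing starts at the first configuration, so a pool of 10 with stride 40
    yields a single start.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return RestartPool(
        configurations=pool.configurations[::stride],
        source_level=pool.source_level,
        settings=pool.settings,
    )


def relax_gap_ensemble(
    system: DualLevelSystem,
    starts: RestartPool,
    n_steps: int,
    timestep: float = 1.0,
    friction: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Energy-gap relaxation trajectories after an instantaneous level jump.

    Each start (equilibrated at some reference level) is propagated at the
    *high* level while the gap ΔU(t) = U_high − U_low is recorded every step,
    including t = 0.  Returns an array of shape ``(n_trajectories,
    n_steps + 1)``; rows are independent, per-trajectory seeded trajectories.
    """
    engine = system.engine
    integ = BAOAB(
        engine, timestep, system_friction(system, friction), system.thermo.kT
    )
    out = np.empty((len(starts), n_steps + 1))
    for i, conf in enumerate(starts.configurations):
        rng = child_rng(seed, "relax", i)
        q, v = engine.pack(conf)
        e0, e1, f0, f1 = engine.both(q)
        state = (e0, e1, f0, f1, 1.0)
        out[i, 0] = e1 - e0
        for step in range(1, n_steps + 1):
            q, v, state = integ.step(q, v, state, rng)
            _check_finite(state[0], state[1], 1.0, i, step)
            out[i, step] = state[1] - state[0]
    return out
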