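"""Hybrid charge intermediate states.

The low→high transformation is hardest when the two levels of theory assign
very different charge distributions to the solute.  A *hybrid charge
intermediate* (a "MULL" state) is a low-level Hamiltonian whose fixed partial
charges are the ensemble average of the fluctuating high-level charges.
Inserting it splits the transformation into a cheap classical leg
(low ↔ MULL, staged BAR) and a residual switching leg (MULL → high) whose
work distribution is much narrower.

Three averaging ensembles are distinguished by their source label:

- ``MULL(gas)``   — configurations from a solvent-free low-level ensemble,
- ``MULL(solv)``  — configurations from the solvated low-level ensemble,
- ``MULL(solv*)`` — configurations from the solvated high-level ensemble.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .dynamics import RestartPool
    from .model_systems import DualLevelSystem

__all__ = [
    "ChargeSet",
    "derive_average_charges",
    "interpolate_charges",
    "make_intermediate_system",
    "charge_ladder_delta_a",
    "write_charge_set",
    "read_charge_set",
]

#: default charge-perturbation ladder: three equidistant intermediates
DEFAULT_LADDER = (0.0, 0.25, 0.5, 0.75, 1.0)

_NEUTRALITY_TOL = 1e-10


@dataclass
class ChargeSet:
    """Per-atom partial charges (e), optionally with averaging statistics."""

    charges: np.ndarray
    atom_labels: Sequence[str] | None = None
    source: str = "MM"
    n_configs_averaged: int = 0
    per_atom_std: np.ndarray | None = None
    net_charge: float = 0.0

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        if self.atom_labels is None:
            self.atom_labels = [f"A{i+1}" for i in range(self.n_atoms)]
        if len(self.atom_labels) != self.n_atoms:
            raise ValueError("atom_labels length does not match charges")
        if self.per_atom_std is not None:
            self.per_atom_std = np.asarray(self.per_atom_std, dtype=float)
        if abs(float(self.charges.sum()) - self.net_charge) > _NEUTRALITY_TOL:
            raise ValueError(
                f"charges sum to {self.charges.sum():.3e}, expected net "
                f"{self.net_charge:g} (re-neutralize first)"
            )

    @property
    def n_atoms(self) -> int:
        return self.charges.size


def reneutralize(charges: np.ndarray, net_charge: float = 0.0) -> np.ndarray:
    """Remove excess charge by uniform per-atom subtraction."""
    q = np.asarray(charges, dtype=float)
    return q - (q.sum() - net_charge) / q.size


def derive_average_charges(
    system: "DualLevelSystem", pool: "RestartPool", n_samples: int = 200
) -> ChargeSet:
    """Average the configuration-dependent high-level charges over a pool.

    ``n_samples`` configurations are taken at even spacing across the pool
    (deterministic selection across replicates), the instantaneous high-level
    charges are evaluated on each, averaged per atom, and the mean set is
    re-neutralized to the solute's declared net charge.  The source label is
    inferred from the pool's provenance: a solvent-free low-level pool gives
    ``MULL(gas)``, a solvated low-level pool ``MULL(solv)``, and a solvated
    high-level pool ``MULL(solv*)``.

    Per-atom standard deviations use the n-1 denominator.
    """
    from .model_systems import high_level_charges

    if len(pool) == 0:
        raise ValueError("cannot derive charges from an empty pool")
    if n_samples > len(pool):
        raise ValueError(f"n_samples={n_samples} exceeds pool size {len(pool)}")
    idx = np.linspace(0, len(pool) - 1, n_samples).round().astype(int)
    samples = np.array(
        [high_level_charges(system, pool.configurations[i], raw=True) for i in idx]
    )
    mean = reneutralize(samples.mean(axis=0), system.solute.net_charge)
    std = samples.std(axis=0, ddof=1) if n_samples > 1 else np.zeros(mean.size)

    solvated = system.solvent is not None and system.solvent.n_sites > 0
    lam = pool.source_level
    at_high = isinstance(lam, (int, float)) and float(lam) == 1.0 or lam == "high"
    if not solvated:
        source = "MULL(gas)"
    elif at_high:
        source = "MULL(solv*)"
    else:
        source = "MULL(solv)"
    return ChargeSet(
        charges=mean,
        atom_labels=system.solute.atom_labels,
        source=source,
        n_configs_averaged=n_samples,
        per_atom_std=std,
        net_charge=system.solute.net_charge,
    )


def interpolate_charges(
    q_low: ChargeSet, q_target: ChargeSet, lambda_value: float
) -> ChargeSet:
    """Per-atom convex combination q(λ) = (1−λ)·q_low + λ·q_target."""
    if q_low.n_atoms != q_target.n_atoms:
        raise ValueError("charge sets have different atom counts")
    if not 0.0 <= lambda_value <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if lambda_value == 0.0:
        q = q_low.charges.copy()
    elif lambda_value == 1.0:
        q = q_target.charges.copy()
    else:
        q = (1.0 - lambda_value) * q_low.charges + lambda_value * q_target.charges
    net = (1.0 - lambda_value) * q_low.net_charge + lambda_value * q_target.net_charge
    return ChargeSet(
        charges=q,
        atom_labels=q_low.atom_labels,
        source="interpolated" if 0.0 < lambda_value < 1.0 else
        (q_low.source if lambda_value == 0.0 else q_target.source),
        net_charge=net,
    )


def make_intermediate_system(
    system: "DualLevelSystem", charge_set: ChargeSet
) -> "DualLevelSystem":
    """A system whose *low* level uses the supplied fixed charges.

    All other low-level terms are unchanged, and the high level is the
    original (charge-responsive) high level, so the result supports
    intermediate→high switching that closes the thermodynamic cycle.
    """
    from .model_systems import make_dipole_bath_system

    if system.solute is None:
        raise ValueError("intermediate states require a multi-site solute system")
    if charge_set.n_atoms != system.solute.n_atoms:
        raise ValueError("charge set does not match the solute atom count")
    out = make_dipole_bath_system(
        system.solute, system.solvent, system.thermo,
        low_charges=charge_set.charges,
    )
    out.label_low = charge_set.source
    out.label_high = system.label_high
    return out


def charge_ladder_delta_a(
    system: "DualLevelSystem",
    charge_set: ChargeSet,
    lambdas=DEFAULT_LADDER,
    steps_per_window: int = 4000,
    save_every: int = 20,
    n_equil_steps: int = 1000,
    seed: int = 0,
    n_repetitions: int = 8,
):
    """ΔA(low ↔ intermediate) by staged BAR over the charge ladder
    q(λ) = (1−λ)·q_low + λ·q_intermediate.

    Both endpoints are fixed-charge (classical) states, so the whole ladder
    is cheap equilibrium sampling.  The ladder defaults to three equidistant
    intermediate states between the endpoints; the calculation is repeated
    ``n_repetitions`` times from independent velocities and the stderr is the
    repetition standard deviation over √n.
    """
    from .model_systems import pair_low_levels, staged_ladder_delta_a

    bridge = pair_low_levels(system, make_intermediate_system(system, charge_set))
    return staged_ladder_delta_a(
        bridge,
        lambdas,
        steps_per_window=steps_per_window,
        save_every=save_every,
        n_equil_steps=n_equil_steps,
        seed=seed,
        n_repetitions=n_repetitions,
    )


# ---------------------------------------------------------------------------
# plain-text charge file (round-trips bit-exactly)
# ---------------------------------------------------------------------------

def write_charge_set(cs: ChargeSet, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write(f"# source: {cs.source}\n")
    buf.write(f"# n_configs: {cs.n_configs_averaged}\n")
    buf.write(f"# net_charge_e: {float(cs.net_charge)!r}\n")
    buf.write("atom_label\tcharge_e\tstd_e\n")
    std = cs.per_atom_std if cs.per_atom_std is not None else np.zeros(cs.n_atoms)
    for lab, q, s in zip(cs.atom_labels, cs.charges, std):
        buf.write(f"{lab}\t{float(q)!r}\t{float(s)!r}\n")
    Path(path).write_text(buf.getvalue())


def read_charge_set(path: str | Path) -> ChargeSet:
    source, n_configs, net = "MM", 0, 0.0
    labels: list[str] = []
    charges: list[float] = []
    stds: list[float] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# source:"):
            source = line.split(":", 1)[1].strip()
        elif line.startswith("# n_configs:"):
            n_configs = int(line.split(":", 1)[1])
        elif line.startswith("# net_charge_e:"):
            net = float(line.split(":", 1)[1])
        elif line.startswith("#") or line.startswith("atom_label") or not line.strip():
            continue
        else:
            lab, q, s = line.split("\t")
            labels.append(lab)
            charges.append(float(q))
            stds.append(float(s))
    return ChargeSet(
        charges=np.array(charges),
        atom_labels=labels,
        source=source,
        n_configs_averaged=n_configs,
        per_atom_std=np.array(stds),
        net_charge=net,
    )
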