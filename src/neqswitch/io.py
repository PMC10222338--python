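"""Plain-text file formats.

Everything the pipeline persists is diff-able text: system definitions as
YAML, restart pools as JSON-lines with a JSON sidecar, work tables as TSV,
estimates and exponential fits as JSON.  Floats are serialized through
``repr`` (shortest round-trip representation), so write → read → write is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import ExpFit
from .charges import read_charge_set, write_charge_set  # re-export  # noqa: F401
from .dynamics import RestartPool, SamplerSettings
from .estimators import FreeEnergyEstimate, OverlapDiagnostics
from .model_systems import (
    Configuration,
    DualLevelSystem,
    SoluteSpec,
    SolventSpec,
    ThermoState,
    make_dipole_bath_system,
    make_harmonic_pair,
)
from .switching import WorkRecord

__all__ = [
    "write_system",
    "read_system",
    "write_pool",
    "read_pool",
    "write_work_table",
    "read_work_table",
    "work_table_frame",
    "write_estimate",
    "read_estimate",
    "write_gap_series",
    "read_gap_series",
    "write_fit",
    "read_charge_set",
    "write_charge_set",
]


# ---------------------------------------------------------------------------
# systems (YAML)
# ---------------------------------------------------------------------------


def write_system(system: DualLevelSystem, path: str | Path) -> None:
    doc: dict = {"thermo": {"temperature_K": float(system.thermo.temperature)}}
    engine = system.engine
    if system.solute is not None:
        doc["kind"] = "dipole_bath"
        doc["solute"] = {
            "coordinates_A": system.solute.coordinates.tolist(),
            "base_charges_e": system.solute.base_charges.tolist(),
            "atom_labels": list(system.solute.atom_labels),
            "net_charge_e": float(system.solute.net_charge),
        }
        doc["solvent"] = {
            "site_positions_A": system.solvent.site_positions.tolist(),
            "dipole_magnitude_eA": float(system.solvent.dipole_magnitude),
            "rotational_friction_per_ps": float(system.solvent.rotational_friction),
            "inertia_amu_A2": float(system.solvent.inertia),
        }
        doc["high_level"] = {
            "response_coefficients": system.solute.response_coefficients.tolist(),
            "label": system.label_high,
        }
    else:
        doc["kind"] = "harmonic_pair"
        doc["harmonic"] = {
            "k_low": float(engine.k_low),
            "k_high": float(engine.k_high),
            "offset_A": float(engine.offset),
            "mass_amu": float(engine.masses[0]),
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_system(path: str | Path) -> DualLevelSystem:
    doc = yaml.safe_load(Path(path).read_text())
    thermo = ThermoState(temperature=float(doc["thermo"]["temperature_K"]))
    if doc["kind"] == "harmonic_pair":
        h = doc["harmonic"]
        return make_harmonic_pair(
            h["k_low"], h["k_high"], h.get("offset_A", 0.0), thermo,
            mass=h.get("mass_amu", 12.0),
        )
    if doc["kind"] != "dipole_bath":
        raise ValueError(f"unknown system kind {doc['kind']!r}")
    sol = doc["solute"]
    solute = SoluteSpec(
        coordinates=np.array(sol["coordinates_A"]),
        base_charges=np.array(sol["base_charges_e"]),
        response_coefficients=np.array(doc["high_level"]["response_coefficients"]),
        atom_labels=sol.get("atom_labels"),
        net_charge=sol.get("net_charge_e", 0.0),
    )
    sv = doc["solvent"]
    solvent = SolventSpec(
        site_positions=np.array(sv["site_positions_A"]).reshape(-1, 3),
        dipole_magnitude=sv["dipole_magnitude_eA"],
        rotational_friction=sv["rotational_friction_per_ps"],
        inertia=sv["inertia_amu_A2"],
    )
    system = make_dipole_bath_system(solute, solvent, thermo)
    system.label_high = doc["high_level"].get("label", "high")
    return system


# ---------------------------------------------------------------------------
# restart pools (JSON-lines + sidecar)
# ---------------------------------------------------------------------------


def _config_record(c: Configuration) -> dict:
    rec: dict = {"time_fs": c.time_fs, "provenance": c.provenance}
    for name in (
        "solute_displacements",
        "rotor_angles",
        "solute_velocities",
        "rotor_velocities",
    ):
        v = getattr(c, name)
        rec[name] = None if v is None else np.asarray(v).tolist()
    return rec


def write_pool(pool: RestartPool, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "pool.jsonl", "w") as fh:
        for c in pool.configurations:
            fh.write(json.dumps(_config_record(c), sort_keys=True) + "\n")
    meta = {
        "source_level": pool.source_level,
        "settings": None if pool.settings is None else asdict(pool.settings),
        "n_configurations": len(pool),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_pool(directory: str | Path, solvent_positions=None) -> RestartPool:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    configs = []
    for line in (d / "pool.jsonl").read_text().splitlines():
        rec = json.loads(line)
        kwargs = {}
        for name in (
            "solute_displacements",
            "rotor_angles",
            "solute_velocities",
            "rotor_velocities",
        ):
            kwargs[name] = None if rec[name] is None else np.array(rec[name])
        configs.append(
            Configuration(
                time_fs=rec["time_fs"],
                provenance=rec["provenance"],
                solvent_positions=solvent_positions,
                **kwargs,
            )
        )
    settings = (
        SamplerSettings(**meta["settings"]) if meta.get("settings") else None
    )
    return RestartPool(
        configurations=configs, source_level=meta["source_level"], settings=settings
    )


# ---------------------------------------------------------------------------
# work tables (TSV)
# ---------------------------------------------------------------------------

_WORK_COLUMNS = [
    "switch_id",
    "direction",
    "schedule",
    "n_steps",
    "final_work_kcal_mol",
    "start_replicate",
    "start_step",
    "seed",
]


def work_table_frame(records: list[WorkRecord]) -> pd.DataFrame:
    rows = [
        {
            "switch_id": i,
            "direction": r.direction,
            "schedule": r.schedule_label,
            "n_steps": r.n_steps,
            "final_work_kcal_mol": r.final_work,
            "start_replicate": r.start_provenance.get("replicate", -1),
            "start_step": r.start_provenance.get("step", -1),
            "seed": r.seed,
        }
        for i, r in enumerate(records)
    ]
    return pd.DataFrame(rows, columns=_WORK_COLUMNS)


def write_work_table(records: list[WorkRecord], path: str | Path) -> None:
    df = work_table_frame(records)
    with open(path, "w") as fh:
        fh.write("# work values in kcal/mol; timestep unit fs\n")
        df.to_csv(fh, sep="\t", index=False, float_format=None)


def read_work_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# estimates / fits (JSON)
# ---------------------------------------------------------------------------


def write_estimate(est: FreeEnergyEstimate, path: str | Path) -> None:
    doc = asdict(est)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_estimate(path: str | Path) -> FreeEnergyEstimate:
    doc = json.loads(Path(path).read_text())
    diag = doc.pop("diagnostics", None)
    if diag is not None:
        doc["diagnostics"] = OverlapDiagnostics(**diag)
    return FreeEnergyEstimate(**doc)


def write_fit(fit: ExpFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(fit), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# energy-gap series (TSV: time column + one column per trajectory)
# ---------------------------------------------------------------------------


def write_gap_series(times: np.ndarray, series: np.ndarray, path: str | Path) -> None:
    series = np.atleast_2d(series)
    data = np.column_stack([times, series.T])
    header = "time_fs\t" + "\t".join(f"traj{i}" for i in range(series.shape[0]))
    np.savetxt(path, data, delimiter="\t", header=header, comments="")


def read_gap_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    data = np.atleast_2d(data)
    return data[:, 0], data[:, 1:].T
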