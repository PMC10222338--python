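"""End-to-end pipeline: equilibrate → select starts → switch → estimate → report.

A single YAML config declares the stages; :func:`run_pipeline` executes them
in dependency order, persists every intermediate artifact as text, and writes
a run manifest recording the config hash, the master seed and every derived
child seed, so a rerun with the same config reproduces bit-identical work
tables.  Stages whose outputs already exist on disk are reused, making the
pipeline resumable stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import yaml

from . import __version__
from .dynamics import SamplerSettings, sample_equilibrium, select_switch_starts
from .estimators import WorkSample, jarzynski, two_sided
from .io import (
    read_pool,
    read_system,
    write_estimate,
    write_pool,
    write_system,
    write_work_table,
)
from .seeds import child_seed
from .switching import (  # noqa: F401
    PRESET_STAGES,
    ScheduleError,
    SwitchSettings,
    preset_schedule,
    run_switch_ensemble,
)

__all__ = ["run_pipeline", "harmonic_quickstart_config", "validate_config"]


class PipelineError(RuntimeError):
    pass


def harmonic_quickstart_config() -> dict:
    """A self-contained demo: harmonic pair, forward+backward switches, CRO
    estimate reported against the closed-form ΔA."""
    return {
        "name": "harmonic_quickstart",
        "seed": 1,
        "system": {
            "inline": {
                "kind": "harmonic_pair",
                "thermo": {"temperature_K": 300.0},
                "harmonic": {"k_low": 1.0, "k_high": 4.0, "offset_A": 0.3,
                             "mass_amu": 12.0},
            }
        },
        "equilibrate": {
            "n_replicates": 4,
            "n_equil_steps": 500,
            "n_prod_steps": 2000,
            "save_every": 20,
        },
        "select": {"stride": 4},
        "switch": {"schedule": "L1", "n_steps": 500,
                   "directions": ["forward", "backward"]},
        "estimate": {"method": "cro"},
        "report": {"reference": "analytic"},
    }


def validate_config(config: dict) -> None:
    """Fail fast on malformed configs before any compute happens."""
    if "system" not in config:
        raise PipelineError("config is missing the 'system' section")
    sw = config.get("switch", {})
    label = sw.get("schedule", "L1")
    if label not in ("L1", *PRESET_STAGES):
        raise PipelineError(f"unknown schedule label {label!r}")
    method = config.get("estimate", {}).get("method", "jar")
    if method not in ("jar", "cro"):
        raise PipelineError(f"unknown estimate method {method!r}")
    directions = sw.get("directions", ["forward"])
    if method == "cro" and set(directions) != {"forward", "backward"}:
        raise PipelineError("cro estimates need forward and backward switches")


def _load_system(config: dict, workdir: Path):
    spec = config["system"]
    if "path" in spec:
        return read_system(spec["path"])
    inline = workdir / "system.yaml"
    inline.write_text(yaml.safe_dump(spec["inline"], sort_keys=True))
    return read_system(inline)


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute all declared stages; returns the manifest dictionary."""
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text())
    validate_config(config)
    out = Path(out_dir) if out_dir else config_path.parent / f"{config['name']}_run"
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    t0 = time.time()
    manifest: dict = {
        "command": "pipeline",
        "config": str(config_path),
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "master_seed": seed,
        "child_seeds": {},
        "outputs": {},
        "version": __version__,
    }

    system = _load_system(config, out)
    write_system(system, out / "system.yaml")
    manifest["outputs"]["system"] = str(out / "system.yaml")

    eq = config.get("equilibrate", {})
    sw = config.get("switch", {})
    directions = sw.get("directions", ["forward"])
    method = config.get("estimate", {}).get("method", "jar")
    stride = config.get("select", {}).get("stride", 1)
    beta = system.thermo.beta

    samples: dict[str, WorkSample] = {}
    for direction in directions:
        lam = 0.0 if direction == "forward" else 1.0
        pool_dir = out / f"pool_{direction}"
        pool_seed = child_seed(seed, "equilibrate", direction)
        manifest["child_seeds"][f"equilibrate_{direction}"] = pool_seed
        if (pool_dir / "meta.json").exists():
            pool = read_pool(pool_dir)
        else:
            settings = SamplerSettings(
                n_equil_steps=eq.get("n_equil_steps", 1000),
                n_prod_steps=eq.get("n_prod_steps", 10000),
                save_every=eq.get("save_every", 10),
                n_replicates=eq.get("n_replicates", 8),
                seed=pool_seed,
            )
            pool = sample_equilibrium(system, lam, settings)
            write_pool(pool, pool_dir)
        manifest["outputs"][f"pool_{direction}"] = str(pool_dir)

        starts = select_switch_starts(pool, stride)
        if len(starts) == 0:
            raise PipelineError(
                f"stage switch_{direction}: upstream pool produced no starts"
            )
        works_path = out / f"works_{direction}.tsv"
        switch_seed = child_seed(seed, "switch", direction)
        manifest["child_seeds"][f"switch_{direction}"] = switch_seed
        settings = SwitchSettings(
            n_switch_steps=sw.get("n_steps", 2000),
            schedule=preset_schedule(sw.get("schedule", "L1")),
            direction=direction,
            seed=switch_seed,
        )
        records = run_switch_ensemble(system, starts, settings)
        write_work_table(records, works_path)
        manifest["outputs"][f"works_{direction}"] = str(works_path)
        samples[direction] = WorkSample.from_records(
            records, beta=beta, label=direction
        )

    est_seed = child_seed(seed, "estimate")
    manifest["child_seeds"]["estimate"] = est_seed
    if method == "jar":
        est = jarzynski(samples["forward"], seed=est_seed)
    else:
        est = two_sided(samples["forward"], samples["backward"])
    write_estimate(est, out / "estimate.json")
    manifest["outputs"]["estimate"] = str(out / "estimate.json")

    report = {"delta_a": est.delta_a, "stderr": est.stderr, "method": est.method}
    ref = config.get("report", {}).get("reference")
    if ref == "analytic" and system.analytic_delta_a is not None:
        report["reference"] = system.analytic_delta_a
        report["delta_delta_a"] = est.delta_a - system.analytic_delta_a
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["report"] = str(out / "report.json")

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
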