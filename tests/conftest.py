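import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")

from neqswitch import (
    Configuration,
    SamplerSettings,
    SoluteSpec,
    SolventSpec,
    ThermoState,
    make_dipole_bath_system,
    make_harmonic_pair,
    sample_equilibrium,
)

KT = 0.6  # kcal/mol


@pytest.fixture(scope="session")
def thermo06():
    return ThermoState.from_kT(KT)


@pytest.fixture(scope="session")
def harmonic_pair(thermo06):
    """The reference validation system: k 1 → 4 kcal/mol/Å² at kB·T = 0.6."""
    return make_harmonic_pair(1.0, 4.0, offset=0.0, thermo=thermo06)


@pytest.fixture(scope="session")
def tiny_bath(thermo06):
    """A 2-atom solute with a single rotor — small enough for hand checks."""
    solute = SoluteSpec(
        coordinates=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        base_charges=np.array([-0.2, 0.2]),
        response_coefficients=np.array([0.01, 0.01]),
        atom_labels=["X1", "X2"],
    )
    solvent = SolventSpec(
        site_positions=np.array([[0.0, 3.0, 0.0]]),
        dipole_magnitude=0.5,
        rotational_friction=20.0,
        inertia=10.0,
    )
    return make_dipole_bath_system(solute, solvent, thermo06)


@pytest.fixture(scope="session")
def harmonic_pool(harmonic_pair):
    """A moderately decorrelated equilibrium pool at the low level."""
    settings = SamplerSettings(
        n_equil_steps=2000,
        n_prod_steps=10000,
        save_every=200,
        n_replicates=4,
        seed=11,
    )
    return sample_equilibrium(harmonic_pair, 0.0, settings)


def make_configs(n, rotor_angles=None, x=0.0):
    """Manufacture dummy configurations with provenance for pool-logic tests."""
    out = []
    for i in range(n):
        out.append(
            Configuration(
                solute_displacements=np.array([x]),
                rotor_angles=None if rotor_angles is None else np.asarray(rotor_angles),
                time_fs=float(i),
                provenance={"replicate": i % 8, "step": i},
            )
        )
    return out


@pytest.fixture(scope="session")
def cycle_benchmark_results():
    """Full indirect-path workflow on the dipole-bath fixture (shared)."""
    from neqswitch.validation import bath_cycle_benchmark

    return bath_cycle_benchmark(seed=1)


@pytest.fixture(scope="session")
def stokes_benchmark_results():
    """Solvent-reorientation transients on the dipole-bath fixture (shared)."""
    from neqswitch.validation import bath_stokes_benchmark

    return bath_stokes_benchmark(seed=1)
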