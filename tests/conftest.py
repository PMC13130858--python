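"""Shared fixtures: a standard two-bath toy system, a sampled dataset and
its quadrature oracle.  Session-scoped because sampling is the expensive
part; all randomness is seeded so the suite is deterministic."""

import numpy as np
import pytest

from evbtherm import CouplingModel
from evbtherm.fep_us import LambdaSchedule, windows_from_replicate
from evbtherm.io_cli import run_single_temperature_analysis
from evbtherm.toy_system import (
    Harmonic,
    ToySystemSpec,
    exact_profiles_oracle,
    replicate_seed_sequence,
    simulate_replicate,
)

STANDARD_TEMPERATURE = 300.0


@pytest.fixture(scope="session")
def toy_spec():
    """Two harmonic diabats + 2 bath oscillators at the condensed-phase
    energy scale (uss_offset = −4e4 kcal/mol), constant coupling."""
    return ToySystemSpec(
        diabat1=Harmonic(k=100.0, r0=0.0),
        diabat2=Harmonic(k=100.0, r0=1.0),
        delta_alpha=3.0,
        coupling=CouplingModel(form="constant", A=8.0),
        n_bath=2,
        bath_k=(60.0, 80.0),
        bath_chain_kappa=5.0,
        g1=3.0,
        g2=-3.0,
        uss_offset=-4.0e4,
    )


@pytest.fixture(scope="session")
def toy_windows(toy_spec):
    """Six replicates of a 21-window FEP simulation at 300 K."""
    lams = LambdaSchedule.linear(21).values
    model = toy_spec.evb_model()
    out = {}
    for rep in range(6):
        data = simulate_replicate(
            toy_spec,
            lams,
            STANDARD_TEMPERATURE,
            n_steps=20000,
            n_equil=2000,
            seed=replicate_seed_sequence(123, 0, rep),
            replicate_id=rep,
        )
        out[rep] = windows_from_replicate(data, model, equil_fraction=0.1)
    return out


@pytest.fixture(scope="session")
def toy_result(toy_windows):
    return run_single_temperature_analysis(
        toy_windows, STANDARD_TEMPERATURE, n_bins=50, convergence_fractions=None
    )


@pytest.fixture(scope="session")
def toy_oracle(toy_spec, toy_result):
    return exact_profiles_oracle(toy_spec, STANDARD_TEMPERATURE, toy_result.profile.bin_edges)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
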