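"""Shared fixtures: session-scoped simulation runs and synthetic archives."""

import numpy as np
import pytest

from ionpull import (
    HarmonicPotential,
    LangevinParams,
    PullingSchedule,
    make_species_fixture,
    run_stepwise_pulling,
)
from ionpull.protocol import PullingRunArchive, StepRecord

TEMPERATURE = 310.0

#: Coupled-harmonic toy: system a z^2/2 with a = k = 0.6 has the closed-form
#: profile dF(lambda) = (a k / (a + k)) lambda^2 / 2 = 0.15 lambda^2.
HARMONIC_A = 0.6
HARMONIC_K = 0.6


def harmonic_exact_delta_f(lam: float) -> float:
    a, k = HARMONIC_A, HARMONIC_K
    return (a * k / (a + k)) * lam**2 / 2.0


@pytest.fixture(scope="session")
def harmonic_archive() -> PullingRunArchive:
    """3-step pull (lambda = 0, 1, 2) on the harmonic toy, tau2 = 5 ns."""
    pot = HarmonicPotential(HARMONIC_A)
    sched = PullingSchedule(
        lambda_start=0.0,
        delta_lambda=1.0,
        n_steps=3,
        tau1=0.5,
        tau2=5.0,
        k=HARMONIC_K,
    )
    params = LangevinParams(
        temperature=TEMPERATURE,
        diffusion_coefficient=40.0,
        timestep=5e-4,
        seed=7,
        sample_interval=5e-4,
    )
    return run_stepwise_pulling(pot, sched, params)


@pytest.fixture(scope="session")
def fixture_schedule() -> PullingSchedule:
    return PullingSchedule(
        n_steps=25, delta_lambda=1.0, tau1=0.2, tau2=1.0, k=0.6
    )


@pytest.fixture(scope="session")
def fixture_params() -> LangevinParams:
    return LangevinParams(
        temperature=TEMPERATURE,
        diffusion_coefficient=5.0,
        timestep=1e-4,
        seed=2024,
        sample_interval=1e-4,
    )


@pytest.fixture(scope="session")
def species_archives(fixture_schedule, fixture_params) -> dict:
    """Full 25-step pulls for both species fixtures (tau2 scaled to 1 ns)."""
    return {
        sp: run_stepwise_pulling(
            make_species_fixture(sp), fixture_schedule, fixture_params
        )
        for sp in ("K_like", "Na_like")
    }


def build_synthetic_archive(
    step_samples,
    k: float = 0.6,
    delta_lambda: float = 1.0,
    lambda_start: float = 0.0,
    tau1: float = 0.1,
    tau2: float = 10.0,
    times=None,
) -> PullingRunArchive:
    """Archive with prescribed per-step position samples (no engine run).

    ``step_samples`` is a list of 1D arrays; sample times are spread over
    (0, tau2] unless given explicitly per step.
    """
    n = len(step_samples)
    sched = PullingSchedule(
        lambda_start=lambda_start,
        delta_lambda=delta_lambda,
        n_steps=n,
        tau1=tau1,
        tau2=tau2,
        k=k,
    )
    params = LangevinParams()
    lams = sched.lambdas
    steps = []
    prev_end = float(lams[0])
    for i, z in enumerate(step_samples):
        z = np.asarray(z, dtype=float)
        if times is not None:
            t = np.asarray(times[i], dtype=float)
        else:
            t = tau2 * np.arange(1, z.size + 1) / z.size
        steps.append(
            StepRecord(
                index=i,
                lambda_i=float(lams[i]),
                times=t,
                z=z,
                z_init=prev_end,
                z_post_tau1=float(z[0]),
            )
        )
        prev_end = float(z[0])
    return PullingRunArchive(
        schedule=sched, params=params, steps=steps, potential_meta={"form": "synthetic"}
    )
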