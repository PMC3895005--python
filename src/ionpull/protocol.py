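"""Step-wise pulling protocol.

Drives the bias center lambda up (or down) a ladder in increments of
``delta_lambda``.  Each step relaxes the particle for ``tau1`` (burn-in,
sequentially seeded from the previous step's end state) and then for
``tau2`` (production sampling).  Per-step positions, normalised position
distributions g_i(z), mean positions and work increments

    w_i(z) = U(z, lambda_i + dl) - U(z, lambda_i)
           = (k/2) * [dl^2 - 2 dl (z - lambda_i)]

are recorded in a :class:`PullingRunArchive` that all estimators consume.

By default only tau2 samples are retained (tau1 is burn-in); pass
``include_burnin=True`` to keep tau1 samples as well (their times are
negative, counting back from the start of tau2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ArchiveValidationError, ConfigurationError, EmptyDataError
from .toysim import (
    BiasPotential,
    LangevinParams,
    Potential1D,
    simulate_relaxation,
)

__all__ = [
    "PullingSchedule",
    "Histogram",
    "StepRecord",
    "PullingRunArchive",
    "step_work_increment",
    "backward_schedule",
    "run_stepwise_pulling",
    "derive_step_seed",
]

#: Position-histogram bin width in A (configurable per call).
DEFAULT_BIN_WIDTH = 0.01


@dataclass(frozen=True)
class PullingSchedule:
    """The lambda ladder, bias stiffness and relaxation times.

    Defaults mirror the reference protocol: 25 lambda values from 0 to
    24 A in 1 A increments, tau1 = 0.5 ns, tau2 = 10 ns, k = 0.6
    kcal/mol/A^2.  ``direction="backward"`` makes the ladder descend from
    ``lambda_start``.
    """

    lambda_start: float = 0.0
    delta_lambda: float = 1.0
    n_steps: int = 25
    tau1: float = 0.5
    tau2: float = 10.0
    k: float = 0.6
    direction: str = "forward"

    def __post_init__(self):
        if self.n_steps < 2:
            raise ConfigurationError("n_steps must be >= 2")
        if self.delta_lambda < 0:
            raise ConfigurationError("delta_lambda must be >= 0")
        if self.tau1 <= 0 or self.tau2 < 0:
            raise ConfigurationError("tau1 > 0 and tau2 >= 0 required")
        if self.k < 0:
            raise ConfigurationError("bias stiffness k must be >= 0")
        if self.direction not in ("forward", "backward"):
            raise ConfigurationError("direction must be 'forward' or 'backward'")

    @property
    def signed_delta(self) -> float:
        """Increment applied at each step (+dl forward, -dl backward)."""
        return self.delta_lambda if self.direction == "forward" else -self.delta_lambda

    @property
    def lambdas(self) -> np.ndarray:
        """The ladder of bias centers, length ``n_steps``."""
        return self.lambda_start + self.signed_delta * np.arange(self.n_steps)

    def to_dict(self) -> dict:
        return {
            "lambda_start": self.lambda_start,
            "delta_lambda": self.delta_lambda,
            "n_steps": self.n_steps,
            "tau1": self.tau1,
            "tau2": self.tau2,
            "k": self.k,
            "direction": self.direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PullingSchedule":
        return cls(**d)


def backward_schedule(schedule: PullingSchedule) -> PullingSchedule:
    """Mirror a schedule: same ladder traversed in the opposite direction.

    An involution: ``backward_schedule(backward_schedule(s)) == s``.
    """
    flipped = "backward" if schedule.direction == "forward" else "forward"
    return replace(
        schedule,
        lambda_start=float(schedule.lambdas[-1]),
        direction=flipped,
    )


def step_work_increment(z, lambda_i: float, delta_lambda: float, k: float):
    """Work of the instantaneous switch lambda_i -> lambda_i + delta_lambda
    at frozen particle position z.

    Equals (k/2) * [(z - lambda_i - dl)^2 - (z - lambda_i)^2]
         = (k/2) * [dl^2 - 2 dl (z - lambda_i)].
    """
    z = np.asarray(z, dtype=float)
    return 0.5 * k * (delta_lambda**2 - 2.0 * delta_lambda * (z - lambda_i))


@dataclass(frozen=True)
class Histogram:
    """A normalised 1D histogram: density integrates to 1."""

    edges: np.ndarray
    density: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class StepRecord:
    """One pulling step's retained samples and derived quantities.

    ``times`` are in ns measured from the start of the tau2 production
    phase (burn-in samples, when retained, carry negative times).
    ``z_init`` is the particle position at the start of tau1 and
    ``z_post_tau1`` at its end; the archive audit checks that
    ``z_init[i] == z_post_tau1[i-1]``.
    """

    index: int
    lambda_i: float
    times: np.ndarray
    z: np.ndarray
    z_init: float
    z_post_tau1: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.size == 0:
            raise EmptyDataError(f"step {self.index}: empty sample set")
        if self.times.shape != self.z.shape:
            raise ConfigurationError("times and z must have equal length")

    @property
    def n_samples(self) -> int:
        return self.z.size

    @property
    def mean_z(self) -> float:
        """<z>_i over retained samples."""
        return float(np.mean(self.z))

    def g(self, bin_width: float = DEFAULT_BIN_WIDTH) -> Histogram:
        """Normalised position distribution g_i(z)."""
        lo = np.floor(self.z.min() / bin_width) * bin_width
        hi = np.ceil(self.z.max() / bin_width) * bin_width
        n_bins = max(1, int(round((hi - lo) / bin_width)))
        density, edges = np.histogram(
            self.z, bins=n_bins, range=(lo, lo + n_bins * bin_width), density=True
        )
        return Histogram(edges=edges, density=density)

    def work_increments(self, delta_lambda: float, k: float) -> np.ndarray:
        """w_i(z) for every retained sample."""
        return step_work_increment(self.z, self.lambda_i, delta_lambda, k)


@dataclass
class PullingRunArchive:
    """A full step-wise pulling run: schedule, engine params and step data."""

    schedule: PullingSchedule
    params: LangevinParams
    steps: list[StepRecord]
    potential_meta: dict = field(default_factory=dict)
    master_seed: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def lambdas(self) -> np.ndarray:
        return self.schedule.lambdas

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def validate(self, atol: float = 1e-9) -> None:
        """Audit structural integrity and the sequential-seeding chain."""
        if not self.steps:
            raise ArchiveValidationError("archive has no steps")
        if len(self.steps) != self.schedule.n_steps:
            raise ArchiveValidationError(
                f"expected {self.schedule.n_steps} steps, found {len(self.steps)}"
            )
        lam = self.schedule.lambdas
        for i, step in enumerate(self.steps):
            if step.index != i:
                raise ArchiveValidationError(f"step {i} has index {step.index}")
            if abs(step.lambda_i - lam[i]) > atol:
                raise ArchiveValidationError(
                    f"step {i}: lambda {step.lambda_i} != schedule {lam[i]}"
                )
        for i in range(1, len(self.steps)):
            a, b = self.steps[i - 1], self.steps[i]
            if abs(b.z_init - a.z_post_tau1) > atol:
                raise ArchiveValidationError(
                    f"sequential-seeding chain broken between steps {i - 1} and "
                    f"{i}: z_init={b.z_init!r} != z_post_tau1={a.z_post_tau1!r}"
                )

    def step_work_samples(self, i: int) -> np.ndarray:
        """Work increments w_i(z) over step i's retained samples."""
        return self.steps[i].work_increments(
            self.schedule.signed_delta, self.schedule.k
        )

    def mean_step_work(self, i: int) -> float:
        return float(np.mean(self.step_work_samples(i)))


def derive_step_seed(master_seed: int, step_index: int, phase: int) -> np.random.Generator:
    """Deterministic per-step generator: parallel and serial execution of the
    tau2 phases agree because each step's stream depends only on
    (master_seed, step_index, phase)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(step_index, phase))
    return np.random.default_rng(ss)


def run_stepwise_pulling(
    potential: Potential1D,
    schedule: PullingSchedule,
    params: LangevinParams,
    z0: float | None = None,
    include_burnin: bool = False,
) -> PullingRunArchive:
    """Execute the step-wise pulling protocol.

    For each step i the bias is centered at lambda_i; the particle relaxes
    for tau1 starting from the previous step's end-of-tau1 state (step 0
    starts at ``z0``, default lambda_start), then a tau2 production phase
    (independently seeded per step) collects the retained samples.
    Deterministic given ``params.seed``.
    """
    lam = schedule.lambdas
    z = float(lam[0] if z0 is None else z0)
    steps: list[StepRecord] = []
    for i in range(schedule.n_steps):
        bias = BiasPotential(k=schedule.k, lambda_center=float(lam[i]))
        rng1 = derive_step_seed(params.seed, i, 0)
        z_init = z
        try:
            burn = simulate_relaxation(
                potential, bias, z_init, params, schedule.tau1, rng=rng1
            )
        except ConfigurationError as exc:
            raise ConfigurationError(f"step {i}: {exc}") from exc
        z_post_tau1 = burn.final_z
        if schedule.tau2 >= params.sample_interval:
            rng2 = derive_step_seed(params.seed, i, 1)
            prod = simulate_relaxation(
                potential, bias, z_post_tau1, params, schedule.tau2, rng=rng2
            )
            times, zs = prod.times, prod.z
        else:
            times = np.empty(0)
            zs = np.empty(0)
        if include_burnin:
            times = np.concatenate([burn.times - schedule.tau1, times])
            zs = np.concatenate([burn.z, zs])
        if times.size == 0:
            raise EmptyDataError(
                f"step {i}: no retained samples (tau2 too short and burn-in "
                "excluded)"
            )
        steps.append(
            StepRecord(
                index=i,
                lambda_i=float(lam[i]),
                times=times,
                z=zs,
                z_init=z_init,
                z_post_tau1=z_post_tau1,
            )
        )
        # sequential seeding: next tau1 continues from this step's tau1 end
        z = z_post_tau1
    archive = PullingRunArchive(
        schedule=schedule,
        params=params,
        steps=steps,
        potential_meta=potential.to_dict(),
        master_seed=params.seed,
        metadata={"include_burnin": include_burnin},
    )
    archive.validate()
    return archive
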