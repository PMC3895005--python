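"""Free-energy profiles from step-wise work distributions.

Two estimators are provided:

* :func:`jarzynski_delta_f` — the exponential work average
  ``exp(-beta dF) = <exp(-beta W)>`` over assembled cumulative works,
  evaluated with an overflow-safe log-sum-exp;
* :func:`quasi_equilibrium_delta_f` — the stepwise free-energy-perturbation
  form ``dF(lambda_m) = sum_{i<m} -kBT ln <exp(-beta w_i)>_{g_i}``, plus a
  mean-force (thermodynamic-integration) cross-check
  ``sum_i k (lambda_i - <z>_i) dl`` exposed as
  :func:`mean_force_delta_f`.

Cumulative work distributions are assembled by drawing one retained
position per step independently (the construction implied by building
rho(W) from the per-step g_i); both a seeded Monte-Carlo mode and an
exhaustive product-space enumeration (small systems only) are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import (
    ConfigurationError,
    ConsistencyError,
    EmptyDataError,
    GridMismatchError,
)
from .protocol import PullingRunArchive, StepRecord
from .units import beta as inv_kbt
from .units import kbt

__all__ = [
    "WorkTrajectorySet",
    "FreeEnergyProfile",
    "DeltaDeltaF",
    "ConvergenceTrace",
    "assemble_work_distribution",
    "jarzynski_delta_f",
    "quasi_equilibrium_delta_f",
    "mean_force_delta_f",
    "delta_delta_f",
    "selectivity_ratio",
    "convergence_trace",
]

#: Cap on the exhaustive product-space size.
EXHAUSTIVE_CAP = 10_000_000

#: Default convergence tolerance (kcal/mol) for the last two trace points.
CONVERGENCE_TOL = 0.1


@dataclass
class WorkTrajectorySet:
    """Assembled cumulative works.

    ``works[t, m]`` is trajectory t's cumulative work up to the ladder
    position ``lambdas[m]`` (the sum of per-step increments for steps
    ``< m``; column 0 is identically zero).  ``weights`` are normalised
    trajectory weights (uniform in Monte-Carlo mode).
    """

    lambdas: np.ndarray
    works: np.ndarray
    weights: np.ndarray
    mode: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.works = np.atleast_2d(np.asarray(self.works, dtype=float))
        if self.works.shape[0] == 0:
            raise EmptyDataError("empty work trajectory set")
        if self.works.shape[1] != self.lambdas.size:
            raise ConfigurationError("works/lambdas shape mismatch")
        self.weights = np.asarray(self.weights, dtype=float)
        total = self.weights.sum()
        if total <= 0:
            raise ConfigurationError("weights must have positive mass")
        self.weights = self.weights / total

    @property
    def n_trajectories(self) -> int:
        return self.works.shape[0]

    def mean_works(self) -> np.ndarray:
        """<W> at each ladder position."""
        return self.weights @ self.works


@dataclass
class FreeEnergyProfile:
    """dF(lambda_i) relative to the ladder start, with bootstrap SE."""

    lambdas: np.ndarray
    delta_f: np.ndarray
    se: np.ndarray
    estimator: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.delta_f[0] != 0.0:
            # tolerate log-sum-exp rounding at the reference point only
            if abs(self.delta_f[0]) > 1e-9:
                raise ConsistencyError("delta_F at the ladder start must be 0")
            self.delta_f = self.delta_f.copy()
            self.delta_f[0] = 0.0

    def value_at(self, lam: float, atol: float = 1e-9) -> float:
        idx = np.flatnonzero(np.isclose(self.lambdas, lam, atol=atol))
        if idx.size == 0:
            raise GridMismatchError(f"lambda {lam} not on the profile grid")
        return float(self.delta_f[idx[0]])


def _collect_steps(
    archive: PullingRunArchive, upto_step: int | None
) -> list[StepRecord]:
    archive.validate()
    n = archive.n_steps if upto_step is None else upto_step + 1
    if n < 1 or n > archive.n_steps:
        raise ConfigurationError(f"upto_step out of range: {upto_step}")
    return archive.steps[:n]


def assemble_work_distribution(
    archive: PullingRunArchive,
    upto_step: int | None = None,
    mode: str = "monte_carlo",
    n_draws: int = 100_000,
    seed: int = 0,
) -> WorkTrajectorySet:
    """Assemble cumulative work trajectories from per-step samples.

    Each trajectory draws one retained position per step independently and
    sums the step work increments.  ``mode="exhaustive"`` enumerates the
    full product space (refused above ``EXHAUSTIVE_CAP`` combinations);
    ``mode="monte_carlo"`` draws ``n_draws`` trajectories with a seeded
    generator.
    """
    steps = _collect_steps(archive, upto_step)
    lambdas = archive.lambdas[: len(steps)]
    incs = [archive.step_work_samples(i) for i in range(len(steps))]
    # increments for steps < m contribute to column m; the last ladder
    # position needs increments from steps 0..m-1 only.
    n_lam = len(steps)
    if mode == "exhaustive":
        size = 1
        for w in incs[: n_lam - 1]:
            size *= w.size
            if size > EXHAUSTIVE_CAP:
                raise ConfigurationError(
                    f"exhaustive product space exceeds {EXHAUSTIVE_CAP:g} "
                    "combinations; use mode='monte_carlo'"
                )
        works = np.zeros((1, 1))
        for m in range(1, n_lam):
            w = incs[m - 1]
            prev = works[:, -1]
            new_col = (prev[:, None] + w[None, :]).reshape(-1)
            works = np.hstack(
                [
                    np.repeat(works, w.size, axis=0),
                    new_col[:, None],
                ]
            )
        weights = np.full(works.shape[0], 1.0 / works.shape[0])
        prov = {"mode": "exhaustive", "size": works.shape[0]}
    elif mode == "monte_carlo":
        if n_draws < 1:
            raise ConfigurationError("n_draws must be >= 1")
        rng = np.random.default_rng(seed)
        works = np.zeros((n_draws, n_lam))
        acc = np.zeros(n_draws)
        for m in range(1, n_lam):
            w = incs[m - 1]
            acc = acc + w[rng.integers(0, w.size, size=n_draws)]
            works[:, m] = acc
        weights = np.full(n_draws, 1.0 / n_draws)
        prov = {"mode": "monte_carlo", "n_draws": n_draws, "seed": seed}
    else:
        raise ConfigurationError(f"unknown assembly mode {mode!r}")
    prov["master_seed"] = archive.master_seed
    return WorkTrajectorySet(
        lambdas=lambdas, works=works, weights=weights, mode=mode, provenance=prov
    )


def _jarzynski_point(works_col, log_weights, kT):
    return -kT * logsumexp(-works_col / kT + log_weights)


def jarzynski_delta_f(
    works: WorkTrajectorySet,
    temperature: float,
    n_boot: int = 200,
    seed: int = 0,
) -> FreeEnergyProfile:
    """Jarzynski estimate dF(lambda) = -kBT ln <exp(-W/kBT)>.

    Computed with log-sum-exp; bootstrap SE over trajectories (``n_boot``
    resamples, seeded; 0 disables).  Raises :class:`ConsistencyError` if
    the Jensen bound dF <= <W> is violated beyond 1e-9.
    """
    kT = kbt(temperature)
    log_w = np.log(works.weights)
    delta_f = np.array(
        [_jarzynski_point(works.works[:, m], log_w, kT) for m in range(works.lambdas.size)]
    )
    mean_w = works.mean_works()
    if np.any(delta_f > mean_w + 1e-9):
        raise ConsistencyError("Jensen inequality violated: dF > <W>")
    se = np.zeros_like(delta_f)
    if n_boot > 0 and works.n_trajectories > 1:
        rng = np.random.default_rng(seed)
        n = works.n_trajectories
        boots = np.empty((n_boot, delta_f.size))
        for b in range(n_boot):
            idx = rng.choice(n, size=n, p=works.weights)
            cols = works.works[idx]
            boots[b] = -kT * logsumexp(-cols / kT, axis=0) + kT * np.log(n)
        se = boots.std(axis=0, ddof=1)
    return FreeEnergyProfile(
        lambdas=works.lambdas,
        delta_f=delta_f,
        se=se,
        estimator="jarzynski",
        metadata={"temperature": temperature, "n_boot": n_boot, **works.provenance},
    )


def quasi_equilibrium_delta_f(
    archive: PullingRunArchive,
    temperature: float,
    upto_step: int | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> FreeEnergyProfile:
    """Stepwise free-energy-perturbation estimate.

    dF(lambda_m) = sum_{i<m} -kBT ln <exp(-beta w_i(z))>_{z ~ g_i}.

    In the long-relaxation limit each g_i is the equilibrium marginal and
    every per-step average is exact, so this agrees with the Jarzynski
    estimate built from the same samples.
    """
    steps = _collect_steps(archive, upto_step)
    kT = kbt(temperature)
    n_lam = len(steps)
    inc_f = np.zeros(n_lam)
    inc_var = np.zeros(n_lam)
    rng = np.random.default_rng(seed)
    for m in range(1, n_lam):
        w = archive.step_work_samples(m - 1)
        inc_f[m] = -kT * (logsumexp(-w / kT) - np.log(w.size))
        if n_boot > 0 and w.size > 1:
            boots = np.empty(n_boot)
            for b in range(n_boot):
                res = w[rng.integers(0, w.size, size=w.size)]
                boots[b] = -kT * (logsumexp(-res / kT) - np.log(w.size))
            inc_var[m] = boots.var(ddof=1)
    delta_f = np.cumsum(inc_f)
    se = np.sqrt(np.cumsum(inc_var))
    return FreeEnergyProfile(
        lambdas=archive.lambdas[:n_lam],
        delta_f=delta_f,
        se=se,
        estimator="quasi_equilibrium",
        metadata={"temperature": temperature, "n_boot": n_boot},
    )


def mean_force_delta_f(
    archive: PullingRunArchive, upto_step: int | None = None
) -> FreeEnergyProfile:
    """Mean-force (thermodynamic-integration) cross-check.

    dF(lambda_m) = sum_{i<m} k (lambda_i - <z>_i) * dl  — a Riemann sum of
    the mean bias force along the ladder, exact up to O(dl) discretisation.
    """
    steps = _collect_steps(archive, upto_step)
    k = archive.schedule.k
    dl = archive.schedule.signed_delta
    incs = np.zeros(len(steps))
    for m in range(1, len(steps)):
        s = steps[m - 1]
        incs[m] = k * (s.lambda_i - s.mean_z) * dl
    return FreeEnergyProfile(
        lambdas=archive.lambdas[: len(steps)],
        delta_f=np.cumsum(incs),
        se=np.zeros(len(steps)),
        estimator="mean_force",
    )


@dataclass
class DeltaDeltaF:
    """Per-lambda |dF_A - dF_B| with its peak."""

    lambdas: np.ndarray
    values: np.ndarray
    signed: np.ndarray
    peak_lambda: float
    peak_value: float


def delta_delta_f(
    profile_a: FreeEnergyProfile, profile_b: FreeEnergyProfile
) -> DeltaDeltaF:
    """Pointwise |dF_A - dF_B| on a shared lambda grid."""
    if profile_a.lambdas.size != profile_b.lambdas.size or not np.allclose(
        profile_a.lambdas, profile_b.lambdas
    ):
        raise GridMismatchError("profiles are not on the same lambda grid")
    signed = profile_a.delta_f - profile_b.delta_f
    values = np.abs(signed)
    peak = int(np.argmax(values))
    return DeltaDeltaF(
        lambdas=profile_a.lambdas,
        values=values,
        signed=signed,
        peak_lambda=float(profile_a.lambdas[peak]),
        peak_value=float(values[peak]),
    )


def selectivity_ratio(delta_delta_f_value: float, temperature: float) -> float:
    """Boltzmann factor exp(ddF / kBT) — the species-selectivity ratio."""
    return float(np.exp(delta_delta_f_value * inv_kbt(temperature)))


@dataclass
class ConvergenceTrace:
    """dF (or ddF) at a focus lambda versus relaxation time."""

    taus: np.ndarray
    values: np.ndarray
    lambda_focus: float
    converged: bool | None
    tolerance: float


def _truncated_archive(archive: PullingRunArchive, tau: float) -> PullingRunArchive:
    steps = []
    for s in archive.steps:
        keep = s.times <= tau + 1e-12
        if not np.any(keep):
            raise EmptyDataError(
                f"step {s.index}: no samples within tau = {tau} ns"
            )
        steps.append(
            StepRecord(
                index=s.index,
                lambda_i=s.lambda_i,
                times=s.times[keep],
                z=s.z[keep],
                z_init=s.z_init,
                z_post_tau1=s.z_post_tau1,
            )
        )
    return PullingRunArchive(
        schedule=archive.schedule,
        params=archive.params,
        steps=steps,
        potential_meta=archive.potential_meta,
        master_seed=archive.master_seed,
        metadata={**archive.metadata, "truncated_to_tau": tau},
    )


def convergence_trace(
    archive: PullingRunArchive,
    lambda_focus: float,
    tau_grid,
    temperature: float,
    archive_b: PullingRunArchive | None = None,
    n_draws: int = 20_000,
    seed: int = 0,
    tolerance: float = CONVERGENCE_TOL,
) -> ConvergenceTrace:
    """Recompute the estimate at ``lambda_focus`` using only samples with
    production time <= tau, for each tau in ``tau_grid``.

    With ``archive_b`` given the trace is |dF_A - dF_B| at the focus;
    otherwise it is dF_A.  The ``converged`` flag compares the last two
    points against ``tolerance`` (None for a single-point grid).
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    max_t = max(float(s.times.max()) for s in archive.steps)
    if np.any(tau_grid > max_t + 1e-9):
        raise ConfigurationError(
            f"tau values must be <= recorded tau2 ({max_t} ns)"
        )
    lam = archive.lambdas
    idx = np.flatnonzero(np.isclose(lam, lambda_focus))
    if idx.size == 0:
        raise GridMismatchError(f"lambda_focus {lambda_focus} not on the ladder")
    focus = int(idx[0])

    def estimate(arc, tau):
        trunc = _truncated_archive(arc, tau)
        works = assemble_work_distribution(
            trunc, upto_step=focus, mode="monte_carlo", n_draws=n_draws, seed=seed
        )
        prof = jarzynski_delta_f(works, temperature, n_boot=0)
        return prof.delta_f[focus]

    values = []
    for tau in tau_grid:
        v = estimate(archive, tau)
        if archive_b is not None:
            v = abs(v - estimate(archive_b, tau))
        values.append(v)
    values = np.array(values)
    converged = None
    if values.size >= 2:
        converged = bool(abs(values[-1] - values[-2]) < tolerance)
    return ConvergenceTrace(
        taus=tau_grid,
        values=values,
        lambda_focus=lambda_focus,
        converged=converged,
        tolerance=tolerance,
    )
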