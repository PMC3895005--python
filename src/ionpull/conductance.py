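"""Conductance estimation from work and displacement statistics.

For a pair of pulling steps i < j, sample (t_i, z(t_i)) and (t_j, z(t_j))
independently from the two steps' retained streams, keep pairs with
positive effective time ``dt_eff = t_j - t_i + (j - i) * tau`` (the
steady-flow collection rule), and estimate

    G = (q / L)^2 * < dz^2 / dt_eff > / <W>,

with ``L = lambda_j - lambda_i`` the electrode separation, ``dz`` the
displacement and ``<W>`` the mean work between the steps (the sum of mean
per-step increments, per-particle in joule).  The form is fixed by exact
consistency with the steady-flow worked example (150 pS <-> ~0.6 kcal/mol
with L = 1 A, dz = 0.5 A, t = 10 ns) and the steady-flow current
``I = q v / L``.

``< dz^2 / dt_eff >`` is the dispersion (heat) term; under the
free-diffusion reading its half is an effective diffusion coefficient.
Per-pair G may be negative (negative mean work); the total over a ladder
is the series-resistor composition and is required positive whenever the
total work is positive — a violation raises, it is never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    ConsistencyError,
    EmptyDataError,
    UndefinedConductanceError,
)
from .protocol import PullingRunArchive
from .units import UNITS

__all__ = [
    "FlowPairSamples",
    "PairConductance",
    "TotalConductance",
    "make_flow_pairs",
    "pair_conductance",
    "steady_flow_work",
    "dispersion_term",
    "total_conductance",
    "independent_ion_scaling",
    "conductance_profile",
]

#: |<W>| below this (kcal/mol) makes the conductance undefined.
W_TOLERANCE = 1e-9


@dataclass
class FlowPairSamples:
    """Retained (dz, dt_eff) pairs for one step pair."""

    i: int
    j: int
    delta_z: np.ndarray  # A
    dt_eff: np.ndarray  # ns, all > 0
    electrode_separation: float  # A
    n_drawn: int = 0

    def __post_init__(self):
        self.delta_z = np.asarray(self.delta_z, dtype=float)
        self.dt_eff = np.asarray(self.dt_eff, dtype=float)
        if self.delta_z.shape != self.dt_eff.shape:
            raise ConfigurationError("delta_z/dt_eff shape mismatch")
        if self.delta_z.size and np.any(self.dt_eff <= 0):
            raise ConfigurationError("all retained pairs need dt_eff > 0")

    @property
    def n(self) -> int:
        return self.delta_z.size


def make_flow_pairs(
    times_i,
    z_i,
    times_j,
    z_j,
    step_gap: int,
    tau: float,
    n_pairs: int,
    rng: np.random.Generator,
    electrode_separation: float = 0.0,
    i: int = 0,
    j: int = 0,
) -> FlowPairSamples:
    """Draw flow pairs between two sample streams.

    The two endpoints are drawn independently (pass the same stream twice
    for same-step diagnostics: two positions on one trajectory).  Pairs
    with ``dt_eff = t_j - t_i + step_gap * tau <= 0`` are rejected.
    """
    times_i = np.asarray(times_i, float)
    z_i = np.asarray(z_i, float)
    times_j = np.asarray(times_j, float)
    z_j = np.asarray(z_j, float)
    idx_i = rng.integers(0, times_i.size, size=n_pairs)
    idx_j = rng.integers(0, times_j.size, size=n_pairs)
    dt = times_j[idx_j] - times_i[idx_i] + step_gap * tau
    dz = z_j[idx_j] - z_i[idx_i]
    keep = dt > 0
    if not np.any(keep):
        raise EmptyDataError("all sampled pairs were rejected (dt_eff <= 0)")
    return FlowPairSamples(
        i=i,
        j=j,
        delta_z=dz[keep],
        dt_eff=dt[keep],
        electrode_separation=electrode_separation,
        n_drawn=n_pairs,
    )


def dispersion_term(pairs: FlowPairSamples) -> tuple[float, float]:
    """Return ``(<dz^2/dt_eff>, implied_D)`` in A^2/ns.

    ``implied_D = <dz^2/dt_eff> / 2`` under the free-diffusion reading
    (for Brownian motion <dz^2> = 2 D dt).  Non-negative by construction.
    """
    if pairs.n == 0:
        raise EmptyDataError("no retained flow pairs")
    val = float(np.mean(pairs.delta_z**2 / pairs.dt_eff))
    return val, val / 2.0


@dataclass
class PairConductance:
    """Conductance for one step pair (may be negative: negative work)."""

    i: int
    j: int
    g_ps: float
    mean_work: float  # kcal/mol
    dispersion: float  # A^2/ns
    n_pairs: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        # sign consistency: the dispersion term is non-negative, so
        # G < 0 iff <W> < 0 (G may be 0 when the dispersion vanishes).
        if self.g_ps * self.mean_work < 0:
            raise ConsistencyError("sign(G) must equal sign(<W>)")


def _conductance_from_parts(
    dispersion_a2_ns: float,
    mean_work_kcalmol: float,
    electrode_separation: float,
    q: float,
) -> float:
    """(q/L)^2 <dz^2/dt_eff> / <W> in pS.  Lengths cancel; time to s and
    work to J/particle via the units module."""
    w_j = UNITS.kcalmol_to_joule(mean_work_kcalmol)
    disp_per_s = dispersion_a2_ns / UNITS.ns_to_s  # A^2/s
    g_siemens = (q / electrode_separation) ** 2 * disp_per_s / w_j
    return g_siemens * 1e12


def pair_conductance(
    archive: PullingRunArchive,
    i: int,
    j: int,
    q: float = UNITS.e_charge,
    tau: float | None = None,
    n_pairs: int = 10_000,
    seed: int = 0,
) -> PairConductance:
    """Estimate the conductance between pulling steps i < j.

    ``tau`` defaults to the schedule's tau2 (the duration of the retained
    production phase).  ``n_pairs`` endpoint pairs are drawn with a seeded
    generator; the mean work is the sum of mean per-step increments for
    steps i..j-1.
    """
    archive.validate()
    if not (0 <= i < j < archive.n_steps):
        raise ConfigurationError(f"need 0 <= i < j < n_steps, got ({i}, {j})")
    if n_pairs < 100:
        raise ConfigurationError("n_pairs must be >= 100")
    if tau is None:
        tau = archive.schedule.tau2
    lam = archive.lambdas
    L = float(abs(lam[j] - lam[i]))
    if L == 0:
        raise ConfigurationError("electrode separation L is zero")
    si, sj = archive.steps[i], archive.steps[j]
    rng = np.random.default_rng(seed)
    pairs = make_flow_pairs(
        si.times,
        si.z,
        sj.times,
        sj.z,
        step_gap=j - i,
        tau=tau,
        n_pairs=n_pairs,
        rng=rng,
        electrode_separation=L,
        i=i,
        j=j,
    )
    mean_w = float(sum(archive.mean_step_work(m) for m in range(i, j)))
    if abs(mean_w) < W_TOLERANCE:
        raise UndefinedConductanceError(
            f"mean work between steps {i} and {j} is zero within tolerance"
        )
    disp, _ = dispersion_term(pairs)
    g = _conductance_from_parts(disp, mean_w, L, q)
    return PairConductance(
        i=i,
        j=j,
        g_ps=g,
        mean_work=mean_w,
        dispersion=disp,
        n_pairs=pairs.n,
        metadata={"seed": seed, "tau": tau, "n_drawn": n_pairs, "L": L},
    )


def steady_flow_work(
    g_ps: float, L: float, delta_z: float, t_eff: float, q: float = UNITS.e_charge
) -> float:
    """Invert the steady-flow relation: W = (q dz / L)^2 / (G t), in
    kcal/mol.  ``g_ps`` in pS, lengths in A, ``t_eff`` in ns."""
    if g_ps <= 0 or t_eff <= 0 or L <= 0 or delta_z <= 0 or q <= 0:
        raise ConfigurationError("all steady-flow arguments must be > 0")
    g_siemens = g_ps * 1e-12
    t_s = t_eff * UNITS.ns_to_s
    w_joule = (q * delta_z / L) ** 2 / (g_siemens * t_s)
    return UNITS.joule_to_kcalmol(w_joule)


@dataclass
class TotalConductance:
    """Series composition of per-pair conductances."""

    pairs: list[PairConductance]
    g_total_ps: float
    total_work: float  # kcal/mol


def total_conductance(pairs: list[PairConductance]) -> TotalConductance:
    """G_total = [sum 1/G_i]^-1 over successive-step pairs.

    Any zero per-pair G is an error.  If the series value is non-positive
    while the total work is positive, a :class:`ConsistencyError` is
    raised (never silently clipped).
    """
    if not pairs:
        raise EmptyDataError("need at least one pair conductance")
    for p in pairs:
        if p.g_ps == 0:
            raise ConfigurationError(
                f"pair ({p.i}, {p.j}) has zero conductance; series sum undefined"
            )
    inv = sum(1.0 / p.g_ps for p in pairs)
    if inv == 0:
        raise ConsistencyError("series sum of inverse conductances is zero")
    g_total = 1.0 / inv
    w_total = float(sum(p.mean_work for p in pairs))
    if w_total > 0 and g_total <= 0:
        raise ConsistencyError(
            f"total conductance {g_total:.4g} pS is non-positive while total "
            f"work {w_total:.4g} kcal/mol is positive"
        )
    return TotalConductance(pairs=list(pairs), g_total_ps=g_total, total_work=w_total)


def independent_ion_scaling(g_single_ps: float, n_ions: int) -> float:
    """n independent carriers: G = n * G_single."""
    if n_ions < 1:
        raise ConfigurationError("n_ions must be >= 1")
    return n_ions * g_single_ps


def conductance_profile(
    archive: PullingRunArchive,
    q: float = UNITS.e_charge,
    tau: float | None = None,
    n_pairs: int = 10_000,
    seed: int = 0,
) -> list[PairConductance]:
    """Per-pair conductances over all successive step pairs of a ladder."""
    out = []
    for i in range(archive.n_steps - 1):
        out.append(
            pair_conductance(
                archive, i, i + 1, q=q, tau=tau, n_pairs=n_pairs, seed=seed + i
            )
        )
    return out
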