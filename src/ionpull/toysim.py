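"""One-dimensional overdamped Langevin engine over configurable potentials.

This is the synthetic stand-in for a thermostatted MD engine: estimators in
this package consume only (time, z) samples collected while a particle
relaxes in a fixed potential plus a harmonic bias, which this engine
produces with known analytic ground truth.

Integrator: Euler--Maruyama for the overdamped Langevin equation

    z <- z + (D / kBT) * F_total(z) * dt + sqrt(2 D dt) * xi,

with ``xi`` standard normal.  A stability guard requires
``dt * (k_total / kBT) * D < 0.1`` where ``k_total`` is an upper bound on
the curvature of the total potential.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ConfigurationError, StabilityError
from .units import kbt

__all__ = [
    "Potential1D",
    "HarmonicPotential",
    "DoubleWellPotential",
    "GaussianMultiwellPotential",
    "TabulatedPotential",
    "BiasPotential",
    "LangevinParams",
    "SampleStream",
    "simulate_relaxation",
    "make_species_fixture",
    "potential_from_dict",
    "SPECIES_FIXTURES",
]

#: Stability threshold for dt * (k_total/kBT) * D.
STABILITY_LIMIT = 0.1


class Potential1D:
    """Abstract 1D potential.

    Subclasses implement ``energy(z)`` (kcal/mol) and ``force(z)``
    (= -dU/dz, kcal/mol/A), both accepting scalars or arrays, plus
    ``curvature_scale()``, an upper bound on |U''| used by the stability
    guard, and ``to_dict()`` for serialisation.
    """

    form = "abstract"

    def energy(self, z):
        raise NotImplementedError

    def force(self, z):
        raise NotImplementedError

    def curvature_scale(self) -> float:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @property
    def potential_id(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class HarmonicPotential(Potential1D):
    """U(z) = a (z - center)^2 / 2."""

    a: float
    center: float = 0.0
    form = "harmonic"

    def __post_init__(self):
        if self.a < 0:
            raise ConfigurationError("harmonic stiffness must be >= 0")

    def energy(self, z):
        return 0.5 * self.a * (np.asarray(z) - self.center) ** 2

    def force(self, z):
        return -self.a * (np.asarray(z) - self.center)

    def curvature_scale(self) -> float:
        return self.a

    def to_dict(self) -> dict:
        return {"form": "harmonic", "a": self.a, "center": self.center}


@dataclass(frozen=True)
class DoubleWellPotential(Potential1D):
    """Quartic double well U(z) = barrier * ((z/half_spacing)^2 - 1)^2.

    Minima at +-half_spacing with energy 0; barrier at z = 0.
    """

    barrier: float
    half_spacing: float = 1.0
    form = "double_well"

    def __post_init__(self):
        if self.barrier < 0 or self.half_spacing <= 0:
            raise ConfigurationError("barrier >= 0 and half_spacing > 0 required")

    def energy(self, z):
        u = (np.asarray(z) / self.half_spacing) ** 2 - 1.0
        return self.barrier * u**2

    def force(self, z):
        z = np.asarray(z)
        u = (z / self.half_spacing) ** 2 - 1.0
        return -4.0 * self.barrier * u * z / self.half_spacing**2

    def curvature_scale(self) -> float:
        # |U''| attains 8 b / s^2 at the minima.
        return 8.0 * self.barrier / self.half_spacing**2

    def to_dict(self) -> dict:
        return {
            "form": "double_well",
            "barrier": self.barrier,
            "half_spacing": self.half_spacing,
        }


class GaussianMultiwellPotential(Potential1D):
    """Sum of inverted Gaussian wells.

    U(z) = -sum_a depth_a * exp(-(z - center_a)^2 / (2 width_a^2))

    ``wells`` is a sequence of (center A, depth kcal/mol, width A) tuples.
    """

    form = "piecewise_multiwell"

    def __init__(self, wells: Sequence[tuple[float, float, float]]):
        wells = [(float(c), float(d), float(w)) for c, d, w in wells]
        if not wells:
            raise ConfigurationError("at least one well required")
        for c, d, w in wells:
            if d < 0 or w <= 0:
                raise ConfigurationError("well depths >= 0 and widths > 0 required")
        self.wells = wells
        self._c = np.array([c for c, _, _ in wells])
        self._d = np.array([d for _, d, _ in wells])
        self._w2 = np.array([w * w for _, _, w in wells])

    def energy(self, z):
        z = np.asarray(z, dtype=float)
        dz = z[..., None] - self._c
        return -np.sum(self._d * np.exp(-0.5 * dz**2 / self._w2), axis=-1)

    def force(self, z):
        z = np.asarray(z, dtype=float)
        dz = z[..., None] - self._c
        g = self._d * np.exp(-0.5 * dz**2 / self._w2) / self._w2
        return -np.sum(g * dz, axis=-1)

    def curvature_scale(self) -> float:
        return float(np.sum(self._d / self._w2))

    def to_dict(self) -> dict:
        return {"form": "piecewise_multiwell", "wells": [list(w) for w in self.wells]}


class TabulatedPotential(Potential1D):
    """Cubic-spline interpolation of tabulated (z, U) pairs."""

    form = "tabulated"

    def __init__(self, z_grid, u_grid):
        z_grid = np.asarray(z_grid, dtype=float)
        u_grid = np.asarray(u_grid, dtype=float)
        if z_grid.ndim != 1 or z_grid.size < 4 or z_grid.size != u_grid.size:
            raise ConfigurationError("need >= 4 matching (z, U) grid points")
        if not np.all(np.diff(z_grid) > 0):
            raise ConfigurationError("z grid must be strictly increasing")
        if not np.all(np.isfinite(u_grid)):
            raise ConfigurationError("tabulated energies must be finite")
        self._z = z_grid
        self._u = u_grid
        self._spline = CubicSpline(z_grid, u_grid, extrapolate=True)
        self._dspline = self._spline.derivative()
        dense = np.linspace(z_grid[0], z_grid[-1], 4 * z_grid.size)
        self._curv = float(np.max(np.abs(self._spline(dense, 2))))

    def energy(self, z):
        return self._spline(np.asarray(z, dtype=float))

    def force(self, z):
        return -self._dspline(np.asarray(z, dtype=float))

    def curvature_scale(self) -> float:
        return self._curv

    def to_dict(self) -> dict:
        return {
            "form": "tabulated",
            "z_grid": self._z.tolist(),
            "u_grid": self._u.tolist(),
        }


@dataclass(frozen=True)
class BiasPotential:
    """Harmonic bias U(z, lambda) = k (z - lambda)^2 / 2."""

    k: float
    lambda_center: float

    def __post_init__(self):
        if self.k < 0:
            raise ConfigurationError("bias stiffness must be >= 0")

    def energy(self, z):
        return 0.5 * self.k * (np.asarray(z) - self.lambda_center) ** 2

    def force(self, z):
        return -self.k * (np.asarray(z) - self.lambda_center)


@dataclass(frozen=True)
class LangevinParams:
    """Engine parameters.

    ``noise_scale`` multiplies the thermal noise amplitude; setting it to 0
    yields deterministic steepest-descent dynamics (zero-temperature
    emulation) while keeping the mobility D/kBT finite.
    """

    temperature: float = 310.0
    diffusion_coefficient: float = 0.5  # A^2/ns
    timestep: float = 1e-4  # ns
    seed: int = 0
    sample_interval: float = 1e-4  # ns
    noise_scale: float = 1.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        if self.diffusion_coefficient <= 0:
            raise ConfigurationError("diffusion coefficient must be > 0")
        if self.timestep <= 0 or self.sample_interval <= 0:
            raise ConfigurationError("timestep and sample_interval must be > 0")
        ratio = self.sample_interval / self.timestep
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                "sample_interval must be an integer multiple of timestep"
            )

    @property
    def record_every(self) -> int:
        return int(round(self.sample_interval / self.timestep))

    def stability_number(self, k_total: float) -> float:
        """dt * (k_total/kBT) * D — must stay below STABILITY_LIMIT."""
        return (
            self.timestep
            * (k_total / kbt(self.temperature))
            * self.diffusion_coefficient
        )

    def check_stability(self, k_total: float) -> None:
        s = self.stability_number(k_total)
        if s >= STABILITY_LIMIT:
            raise StabilityError(
                f"unstable configuration: dt*(k_total/kBT)*D = {s:.3g} "
                f">= {STABILITY_LIMIT} (k_total = {k_total:.3g} kcal/mol/A^2)"
            )

    def params_hash(self) -> str:
        payload = json.dumps(
            {
                "temperature": self.temperature,
                "D": self.diffusion_coefficient,
                "dt": self.timestep,
                "seed": self.seed,
                "sample_interval": self.sample_interval,
                "noise_scale": self.noise_scale,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SampleStream:
    """Ordered (time, z) samples from one relaxation run.

    ``final_z`` is the exact final integrator state, retrievable for
    sequential seeding of the next pulling step.
    """

    times: np.ndarray  # ns, strictly increasing, spaced by sample_interval
    z: np.ndarray  # A
    final_z: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.shape != self.z.shape:
            raise ConfigurationError("times and z must have equal length")

    def __len__(self) -> int:
        return self.times.size


def simulate_relaxation(
    potential: Potential1D,
    bias: BiasPotential,
    z0: float,
    params: LangevinParams,
    duration: float,
    rng: np.random.Generator | None = None,
) -> SampleStream:
    """Relax a particle in ``potential`` + ``bias`` for ``duration`` ns.

    Euler--Maruyama overdamped update; samples recorded every
    ``params.sample_interval``.  With ``rng`` omitted a fresh generator is
    built from ``params.seed`` (same seed + same params => bit-identical
    stream); passing a generator supports seeding chains across steps.
    """
    if duration < params.sample_interval:
        raise ConfigurationError("duration must be >= sample_interval")
    k_total = potential.curvature_scale() + bias.k
    params.check_stability(k_total)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    dt = params.timestep
    n_iter = int(round(duration / dt))
    every = params.record_every
    kT = kbt(params.temperature)
    drift = params.diffusion_coefficient / kT * dt
    sigma = params.noise_scale * math.sqrt(
        2.0 * params.diffusion_coefficient * dt
    )

    pot_force = potential.force
    bias_k = bias.k
    lam = bias.lambda_center

    noise = rng.standard_normal(n_iter) * sigma if sigma > 0 else np.zeros(n_iter)
    n_rec = n_iter // every
    out = np.empty(n_rec)
    z = float(z0)
    idx = 0
    for m in range(n_iter):
        z = z + drift * (float(pot_force(z)) - bias_k * (z - lam)) + noise[m]
        if (m + 1) % every == 0:
            out[idx] = z
            idx += 1
    times = params.sample_interval * np.arange(1, n_rec + 1)
    meta = {
        "potential_id": potential.potential_id,
        "bias_k": bias.k,
        "bias_lambda": bias.lambda_center,
        "params_hash": params.params_hash(),
    }
    return SampleStream(times=times, z=out, final_z=z, metadata=meta)


# ---------------------------------------------------------------------------
# Species fixtures
# ---------------------------------------------------------------------------

#: Documented defaults for the two species-like multiwell fixtures on
#: z in [0, 25] A.  Depths are free toolkit parameters chosen so the
#: "Na_like" entry barrier (deepest-well depth, 6.5 kcal/mol) exceeds the
#: "K_like" one (3.0 kcal/mol) by 3.5 kcal/mol; widths keep wells well
#: separated so minima sit within 0.05 A of the nominal centers.
SPECIES_FIXTURES: dict[str, list[tuple[float, float, float]]] = {
    "K_like": [
        (7.1, 3.0, 0.6),
        (10.4, 2.6, 0.6),
        (13.6, 2.6, 0.6),
        (17.0, 2.4, 0.6),
        (23.1, 2.0, 0.6),
    ],
    "Na_like": [
        (5.5, 6.5, 0.6),
        (9.1, 2.5, 0.6),
    ],
}


def make_species_fixture(
    species: str,
    depth_scale: float = 1.0,
) -> GaussianMultiwellPotential:
    """Return the multiwell fixture potential for ``species``.

    ``species`` is one of ``"K_like"`` (five wells near 7.1, 10.4, 13.6,
    17.0 and 23.1 A) or ``"Na_like"`` (a deep well near 5.5 A, a well near
    9.1 A and no wells in (12, 21) A).  ``depth_scale`` uniformly rescales
    the documented default depths.
    """
    try:
        wells = SPECIES_FIXTURES[species]
    except KeyError:
        raise ConfigurationError(
            f"unknown species {species!r}; choose from {sorted(SPECIES_FIXTURES)}"
        ) from None
    return GaussianMultiwellPotential(
        [(c, d * depth_scale, w) for c, d, w in wells]
    )


def potential_from_dict(spec: dict) -> Potential1D:
    """Rebuild a potential from its ``to_dict`` serialisation (or a config
    entry ``{"form": "species", "species": "K_like"}``)."""
    form = spec.get("form")
    if form == "harmonic":
        return HarmonicPotential(a=spec["a"], center=spec.get("center", 0.0))
    if form == "double_well":
        return DoubleWellPotential(
            barrier=spec["barrier"], half_spacing=spec.get("half_spacing", 1.0)
        )
    if form == "piecewise_multiwell":
        return GaussianMultiwellPotential([tuple(w) for w in spec["wells"]])
    if form == "tabulated":
        return TabulatedPotential(spec["z_grid"], spec["u_grid"])
    if form == "species":
        return make_species_fixture(
            spec["species"], depth_scale=spec.get("depth_scale", 1.0)
        )
    raise ConfigurationError(f"unknown potential form {form!r}")
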