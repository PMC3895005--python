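"""Configuration and archive I/O.

Archive layout (one directory per run, text only):

    run.json                  schedule, engine params, potential spec,
                              seeds, per-step chain positions, config hash
    steps/step_000.tsv ...    per-step samples, columns time_ns, z_angstrom

Histograms are recomputable from the samples (samples are canonical).
Profiles and tables are written as tab-separated text with a JSON sidecar
carrying the producing config hash; analyses refuse archives whose stored
hash does not match their own declared config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ArchiveValidationError, ConfigurationError
from .free_energy import FreeEnergyProfile
from .protocol import PullingRunArchive, PullingSchedule, StepRecord
from .toysim import LangevinParams, Potential1D, potential_from_dict

__all__ = [
    "RunConfig",
    "config_hash",
    "write_archive",
    "read_archive",
    "write_profile",
    "read_profile",
]


def config_hash(payload: dict) -> str:
    """Stable hash of a JSON-serialisable configuration."""
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


@dataclass
class RunConfig:
    """Fully serialisable run description; re-running from a saved config
    reproduces all outputs (stochastic operations use seeds derived from
    ``seed``)."""

    potential: dict
    schedule: dict = field(default_factory=dict)
    engine: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "potential": self.potential,
            "schedule": self.schedule,
            "engine": self.engine,
            "analysis": self.analysis,
            "seed": self.seed,
        }

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "potential" not in raw:
            raise ConfigurationError(
                f"config {path} must be a mapping with a 'potential' entry"
            )
        known = {"potential", "schedule", "engine", "analysis", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            potential=raw["potential"],
            schedule=raw.get("schedule", {}),
            engine=raw.get("engine", {}),
            analysis=raw.get("analysis", {}),
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def build_potential(self) -> Potential1D:
        return potential_from_dict(self.potential)

    def build_schedule(self) -> PullingSchedule:
        return PullingSchedule(**self.schedule)

    def build_params(self) -> LangevinParams:
        engine = dict(self.engine)
        engine.setdefault("seed", self.seed)
        return LangevinParams(**engine)


def write_archive(archive: PullingRunArchive, outdir, cfg_hash: str | None = None) -> Path:
    """Write a validated archive to ``outdir``."""
    archive.validate()
    outdir = Path(outdir)
    (outdir / "steps").mkdir(parents=True, exist_ok=True)
    meta = {
        "schedule": archive.schedule.to_dict(),
        "params": {
            "temperature": archive.params.temperature,
            "diffusion_coefficient": archive.params.diffusion_coefficient,
            "timestep": archive.params.timestep,
            "seed": archive.params.seed,
            "sample_interval": archive.params.sample_interval,
            "noise_scale": archive.params.noise_scale,
        },
        "potential": archive.potential_meta,
        "master_seed": archive.master_seed,
        "metadata": archive.metadata,
        "chain": {
            "z_init": [s.z_init for s in archive.steps],
            "z_post_tau1": [s.z_post_tau1 for s in archive.steps],
        },
        "n_steps": archive.n_steps,
    }
    meta["config_hash"] = cfg_hash if cfg_hash is not None else config_hash(
        {k: meta[k] for k in ("schedule", "params", "potential", "master_seed")}
    )
    with open(outdir / "run.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    for s in archive.steps:
        data = np.column_stack([s.times, s.z])
        np.savetxt(
            outdir / "steps" / f"step_{s.index:03d}.tsv",
            data,
            delimiter="\t",
            header="time_ns\tz_angstrom",
            comments="",
            fmt="%.10g",
        )
    return outdir


def read_archive(path, expected_hash: str | None = None) -> PullingRunArchive:
    """Read an archive directory back; optionally enforce a config hash."""
    path = Path(path)
    run_json = path / "run.json"
    if not run_json.exists():
        raise ArchiveValidationError(f"{path} is not an archive (no run.json)")
    with open(run_json) as fh:
        meta = json.load(fh)
    if expected_hash is not None and meta.get("config_hash") != expected_hash:
        raise ArchiveValidationError(
            f"archive {path} config hash {meta.get('config_hash')!r} does not "
            f"match declared input {expected_hash!r}"
        )
    schedule = PullingSchedule.from_dict(meta["schedule"])
    params = LangevinParams(**meta["params"])
    chain = meta["chain"]
    steps = []
    for i in range(meta["n_steps"]):
        f = path / "steps" / f"step_{i:03d}.tsv"
        if not f.exists():
            raise ArchiveValidationError(f"missing step file {f}")
        data = np.loadtxt(f, delimiter="\t", skiprows=1, ndmin=2)
        steps.append(
            StepRecord(
                index=i,
                lambda_i=float(schedule.lambdas[i]),
                times=data[:, 0],
                z=data[:, 1],
                z_init=chain["z_init"][i],
                z_post_tau1=chain["z_post_tau1"][i],
            )
        )
    archive = PullingRunArchive(
        schedule=schedule,
        params=params,
        steps=steps,
        potential_meta=meta.get("potential", {}),
        master_seed=meta.get("master_seed", params.seed),
        metadata=meta.get("metadata", {}),
    )
    archive.validate(atol=1e-6)  # text round-trip precision
    archive.metadata["config_hash"] = meta.get("config_hash")
    return archive


def write_profile(profile: FreeEnergyProfile, path, extra_meta: dict | None = None) -> None:
    """Profile as TSV (lambda_angstrom, delta_F_kcalmol, se) + JSON sidecar."""
    path = Path(path)
    data = np.column_stack([profile.lambdas, profile.delta_f, profile.se])
    np.savetxt(
        path,
        data,
        delimiter="\t",
        header="lambda_angstrom\tdelta_F_kcalmol\tse",
        comments="",
        fmt="%.10g",
    )
    meta = {"estimator": profile.estimator, **profile.metadata}
    if extra_meta:
        meta.update(extra_meta)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def read_profile(path) -> FreeEnergyProfile:
    """Lossless inverse of :func:`write_profile`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return FreeEnergyProfile(
        lambdas=data[:, 0],
        delta_f=data[:, 1],
        se=data[:, 2],
        estimator=meta.pop("estimator", "unknown"),
        metadata=meta,
    )
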