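"""Generic 3D geometry observables on synthetic coordinate frames.

Two analyses operating on tabulated (frame, label, x, y, z) coordinates:

* :func:`coordination_count` — per-frame count of labelled particles within
  a Euclidean cutoff of the ion, aggregated as mean +- SD binned by the
  ion's axial position;
* :func:`axial_dispersion_histogram` — per-label-group histograms of
  (z - reference) with a bimodality flag (1-vs-2 component BIC).

Distances are plain Euclidean with no periodic minimum-image convention by
default; a rectangular-box-aware option exists but defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyDataError
from .states import fit_gaussian_mixture_1d

__all__ = [
    "CoordinateFrame",
    "CoordinationProfile",
    "AxialDispersion",
    "coordination_count",
    "axial_dispersion_histogram",
    "read_frames_tsv",
    "write_frames_tsv",
]

#: Row label marking the ion in tabulated coordinate files.
ION_LABEL = "ion"


@dataclass
class CoordinateFrame:
    """One snapshot: the ion plus labelled particles."""

    time: float
    ion: tuple[float, float, float]
    particles: dict[str, tuple[float, float, float]]

    def __post_init__(self):
        coords = [self.ion, *self.particles.values()]
        if not np.all(np.isfinite(np.asarray(coords, dtype=float))):
            raise ConfigurationError("all coordinates must be finite")


def _distances(frame: CoordinateFrame, labels, box=None) -> np.ndarray:
    ion = np.asarray(frame.ion, dtype=float)
    pts = np.asarray([frame.particles[lb] for lb in labels], dtype=float)
    d = pts - ion
    if box is not None:
        box = np.asarray(box, dtype=float)
        d -= box * np.round(d / box)
    return np.sqrt((d**2).sum(axis=1))


@dataclass
class CoordinationProfile:
    """Per-frame counts plus mean +- SD binned by ion z."""

    counts: np.ndarray
    ion_z: np.ndarray
    bin_centers: np.ndarray
    bin_mean: np.ndarray
    bin_sd: np.ndarray


def coordination_count(
    frames: list[CoordinateFrame],
    target_labels,
    cutoff: float,
    z_bin_width: float = 1.0,
    box=None,
) -> CoordinationProfile:
    """Count particles (whose label is in ``target_labels``) within
    ``cutoff`` A of the ion, per frame; aggregate mean and SD per ion-z
    bin of width ``z_bin_width``."""
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be > 0")
    if not frames:
        raise EmptyDataError("no coordinate frames")
    target = set(target_labels)
    counts = np.empty(len(frames))
    ion_z = np.empty(len(frames))
    for n, fr in enumerate(frames):
        labels = [lb for lb in fr.particles if lb in target]
        counts[n] = (
            np.count_nonzero(_distances(fr, labels, box=box) <= cutoff)
            if labels
            else 0
        )
        ion_z[n] = fr.ion[2]
    lo = np.floor(ion_z.min() / z_bin_width) * z_bin_width
    n_bins = max(1, int(np.ceil((ion_z.max() - lo) / z_bin_width + 1e-9)))
    edges = lo + z_bin_width * np.arange(n_bins + 1)
    which = np.clip(np.digitize(ion_z, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if np.any(sel):
            mean[b] = counts[sel].mean()
            sd[b] = counts[sel].std()
    return CoordinationProfile(
        counts=counts,
        ion_z=ion_z,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        bin_mean=mean,
        bin_sd=sd,
    )


@dataclass
class AxialDispersion:
    """Per-group normalised histogram of axial deviation from a reference
    plane, with a bimodality summary."""

    group: str
    edges: np.ndarray
    density: np.ndarray
    deviations: np.ndarray
    bimodal: bool
    component_means: list[float]
    metadata: dict = field(default_factory=dict)


def axial_dispersion_histogram(
    frames: list[CoordinateFrame],
    label_groups: dict[str, list[str]],
    reference_plane_z: dict[str, float],
    bin_width: float = 0.05,
    seed: int = 0,
) -> dict[str, AxialDispersion]:
    """Histogram of (z - reference) per label group.

    The bimodality flag compares 1- vs 2-component Gaussian mixtures by
    BIC (seeded); the winning model's component means are reported.
    """
    if not frames:
        raise EmptyDataError("no coordinate frames")
    known = set().union(*(fr.particles.keys() for fr in frames))
    out: dict[str, AxialDispersion] = {}
    for group, labels in label_groups.items():
        if group not in reference_plane_z:
            raise ConfigurationError(f"no reference plane for group {group!r}")
        unknown = [lb for lb in labels if lb not in known]
        if unknown:
            raise ConfigurationError(f"unknown labels {unknown} in group {group!r}")
        ref = reference_plane_z[group]
        dev = np.array(
            [
                fr.particles[lb][2] - ref
                for fr in frames
                for lb in labels
                if lb in fr.particles
            ]
        )
        lo = np.floor(dev.min() / bin_width) * bin_width
        n_bins = max(1, int(np.ceil((dev.max() - lo) / bin_width + 1e-9)))
        density, edges = np.histogram(
            dev, bins=n_bins, range=(lo, lo + n_bins * bin_width), density=True
        )
        bimodal = False
        means = [float(dev.mean())]
        if np.ptp(dev) > 0 and dev.size >= 20:
            c1, ll1, _ = fit_gaussian_mixture_1d(dev, 1, seed=seed)
            c2, ll2, _ = fit_gaussian_mixture_1d(dev, 2, seed=seed)
            bic1 = 2 * np.log(dev.size) - 2 * ll1
            bic2 = 5 * np.log(dev.size) - 2 * ll2
            if bic2 < bic1:
                bimodal = True
                means = [c.mean for c in c2]
            else:
                means = [c.mean for c in c1]
        out[group] = AxialDispersion(
            group=group,
            edges=edges,
            density=density,
            deviations=dev,
            bimodal=bimodal,
            component_means=means,
            metadata={"reference_plane_z": ref, "n": int(dev.size)},
        )
    return out


def read_frames_tsv(path) -> list[CoordinateFrame]:
    """Read frames from a tab-separated table (frame, label, x, y, z).

    The row labelled ``"ion"`` in each frame is the ion; every other label
    must be unique within its frame.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"frame", "label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"frame table needs columns {sorted(required)}")
    frames = []
    for fid, grp in df.groupby("frame", sort=True):
        ions = grp[grp["label"] == ION_LABEL]
        if len(ions) != 1:
            raise ConfigurationError(f"frame {fid}: need exactly one ion row")
        others = grp[grp["label"] != ION_LABEL]
        if others["label"].duplicated().any():
            raise ConfigurationError(f"frame {fid}: duplicate particle labels")
        ion = tuple(ions.iloc[0][["x", "y", "z"]].astype(float))
        particles = {
            str(r["label"]): (float(r["x"]), float(r["y"]), float(r["z"]))
            for _, r in others.iterrows()
        }
        t = float(grp["time"].iloc[0]) if "time" in grp.columns else float(fid)
        frames.append(CoordinateFrame(time=t, ion=ion, particles=particles))
    if not frames:
        raise EmptyDataError("no frames in table")
    return frames


def write_frames_tsv(frames: list[CoordinateFrame], path) -> None:
    """Inverse of :func:`read_frames_tsv`."""
    rows = []
    for fid, fr in enumerate(frames):
        rows.append(
            {"frame": fid, "time": fr.time, "label": ION_LABEL,
             "x": fr.ion[0], "y": fr.ion[1], "z": fr.ion[2]}
        )
        for lb, (x, y, z) in fr.particles.items():
            rows.append(
                {"frame": fid, "time": fr.time, "label": lb, "x": x, "y": y, "z": z}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
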