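"""Stable-state identification and transition-probability analysis.

Pools per-step position samples into a single histogram, decomposes the
pooled distribution into univariate normal mixture components (EM with BIC
model selection), partitions the bias-force samples ``f(z) = k (lambda - z)``
by each component's 95% CI in z, and computes the three-case transition
probabilities between successive stable positions:

* both segments small-SD: probability 1 if mean f_i >= mean f_j, else 0
  (and the reverse probability is 0 when the forward one is 1);
* one small, one large SD: the empirical fraction, within the large-SD
  segment, of force observations satisfying the inequality against the
  small-SD segment's mean;
* both large SD: the product P(f_i >= f_j) * P(f_j <= f_i), each factor the
  empirical fraction over the product of the two samples (the two events
  are treated as independent).

Ties (f_i == f_j) count as satisfying "equal to or larger".

Detailed-balance diagnostics use the overlap coefficient
``sum min(g_i, g_j) * bin_width`` between successive step distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ConsistencyError, EmptyDataError
from .protocol import DEFAULT_BIN_WIDTH, Histogram, PullingRunArchive

__all__ = [
    "PooledPositionHistogram",
    "MixtureComponent",
    "ForceSegment",
    "OverlapReport",
    "pool_positions",
    "fit_gaussian_mixture_1d",
    "fit_position_mixture",
    "partition_forces",
    "transition_probability",
    "reverse_transition_probability",
    "negative_force_fraction",
    "probability_ratio",
    "detailed_balance_overlap",
]

#: SD floor for degenerate (zero-variance) mixture fits, in the sample units.
SD_FLOOR = 1e-6

#: z-quantile of the two-sided 95% confidence interval.
CI_Z = 1.959963984540054


# ---------------------------------------------------------------------------
# Pooled histograms
# ---------------------------------------------------------------------------


@dataclass
class PooledPositionHistogram:
    """Counts of all retained positions pooled over every pulling step."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def density(self) -> Histogram:
        dens = self.counts / (self.total * self.bin_width)
        return Histogram(edges=self.edges, density=dens)

    def modes(self, min_prominence_fraction: float = 0.02) -> np.ndarray:
        """Positions of local maxima of the (lightly smoothed) histogram."""
        from scipy.signal import find_peaks

        kernel = np.ones(11) / 11.0
        smooth = np.convolve(self.counts.astype(float), kernel, mode="same")
        peaks, _ = find_peaks(
            smooth, prominence=min_prominence_fraction * smooth.max()
        )
        return self.centers[peaks]


def pool_positions(
    archive: PullingRunArchive, bin_width: float = DEFAULT_BIN_WIDTH
) -> PooledPositionHistogram:
    """Histogram of all steps' retained samples (0.01 A bins by default)."""
    archive.validate()
    allz = np.concatenate([s.z for s in archive.steps])
    if allz.size == 0:
        raise EmptyDataError("archive contains no retained samples")
    lo = np.floor(allz.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((allz.max() - lo) / bin_width + 1e-9)))
    counts, edges = np.histogram(
        allz, bins=n_bins, range=(lo, lo + n_bins * bin_width)
    )
    return PooledPositionHistogram(edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# Univariate Gaussian mixtures (EM + BIC)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian component of a 1D mixture, sorted by mean."""

    mean: float
    sd: float
    weight: float
    component_id: int

    def ci95(self) -> tuple[float, float]:
        return (self.mean - CI_Z * self.sd, self.mean + CI_Z * self.sd)


def _kmeanspp_init(x: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(x.size)]]
    for _ in range(1, n):
        d2 = np.min((x[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(x.size)])
            continue
        centers.append(x[rng.choice(x.size, p=d2 / total)])
    return np.sort(np.array(centers))


def fit_gaussian_mixture_1d(
    x,
    n_components: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
):
    """EM fit of a 1D Gaussian mixture with k-means++-style seeding.

    Returns ``(components, loglik, trace)`` where ``trace`` is the
    per-iteration log-likelihood (asserted non-decreasing).  Zero-variance
    input yields a single floored-SD component regardless of
    ``n_components``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise EmptyDataError("need at least 2 samples for a mixture fit")
    if np.ptp(x) == 0.0:
        comp = [MixtureComponent(float(x[0]), SD_FLOOR, 1.0, 0)]
        return comp, float("inf"), np.array([float("inf")])
    rng = np.random.default_rng(seed)
    mu = _kmeanspp_init(x, n_components, rng)
    sd = np.full(n_components, max(np.std(x), SD_FLOOR))
    w = np.full(n_components, 1.0 / n_components)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # E step (log domain)
        log_pdf = (
            -0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
            - np.log(sd[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(w[None, :])
        )
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        ll = float(lse.sum())
        if ll < prev - 1e-7 * max(1.0, abs(prev)):
            raise ConsistencyError("EM log-likelihood decreased")
        trace.append(ll)
        resp = np.exp(log_pdf - lse[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, SD_FLOOR**2))
        w = nk / x.size
        if abs(ll - prev) < tol * max(1.0, abs(ll)):
            prev = ll
            break
        prev = ll
    order = np.argsort(mu)
    comps = [
        MixtureComponent(float(mu[j]), float(sd[j]), float(w[j]), cid)
        for cid, j in enumerate(order)
    ]
    return comps, prev, np.array(trace)


def fit_position_mixture(
    samples, max_components: int, seed: int = 0
) -> list[MixtureComponent]:
    """Fit 1..max_components Gaussians and keep the BIC-optimal model.

    Components are returned sorted by mean with ids 0..c-1.  Requires
    ``len(samples) >= 10 * max_components``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if max_components < 1:
        raise ConfigurationError("max_components must be >= 1")
    if x.size < 10 * max_components:
        raise ConfigurationError(
            f"need >= {10 * max_components} samples for max_components="
            f"{max_components}, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        comps, _, _ = fit_gaussian_mixture_1d(x, 1, seed=seed)
        return comps
    best, best_bic = None, np.inf
    for c in range(1, max_components + 1):
        comps, ll, _ = fit_gaussian_mixture_1d(x, c, seed=seed)
        n_params = 3 * c - 1
        bic = n_params * np.log(x.size) - 2.0 * ll
        if bic < best_bic - 1e-9:
            best, best_bic = comps, bic
    return best


# ---------------------------------------------------------------------------
# Force segments and transition probabilities
# ---------------------------------------------------------------------------


@dataclass
class ForceSegment:
    """Bias-force samples attributed to one stable position.

    Forces are ``f = k (lambda - z)`` for every retained (lambda, z) pair
    whose z falls inside the component's 95% CI, pooled over all lambda.
    ``dispersion`` is "large" when SD(f) exceeds half the bias-force
    quantum ``0.5 * k * delta_lambda`` (configurable in
    :func:`partition_forces`).
    """

    component_id: int
    mean_z: float
    forces: np.ndarray
    dispersion: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.forces = np.asarray(self.forces, dtype=float)
        if self.dispersion not in ("small", "large"):
            raise ConfigurationError("dispersion must be 'small' or 'large'")

    @property
    def n(self) -> int:
        return self.forces.size

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.forces))

    @property
    def sd_f(self) -> float:
        return float(np.std(self.forces))


def partition_forces(
    archive: PullingRunArchive,
    components: list[MixtureComponent],
    sd_threshold: float | None = None,
) -> list[ForceSegment]:
    """Partition pooled force samples by the components' 95% CIs in z.

    ``sd_threshold`` classifies a segment's force dispersion; the default
    is ``0.5 * k * delta_lambda`` (an SD comparable to one pulling
    increment's force change makes the inequality outcome genuinely
    uncertain).  Components whose CI captures no samples are dropped with a
    warning recorded in the returned segments' metadata peers.
    """
    archive.validate()
    k = archive.schedule.k
    if sd_threshold is None:
        sd_threshold = 0.5 * k * archive.schedule.delta_lambda
    zs = np.concatenate([s.z for s in archive.steps])
    lams = np.concatenate(
        [np.full(s.n_samples, s.lambda_i) for s in archive.steps]
    )
    forces = k * (lams - zs)
    segments: list[ForceSegment] = []
    for comp in sorted(components, key=lambda c: c.mean):
        lo, hi = comp.ci95()
        mask = (zs >= lo) & (zs <= hi)
        if not np.any(mask):
            import warnings

            warnings.warn(
                f"component {comp.component_id} (mean z = {comp.mean:.2f} A) "
                "has no force samples in its 95% CI; excluded",
                stacklevel=2,
            )
            continue
        f = forces[mask]
        disp = "large" if np.std(f) > sd_threshold else "small"
        segments.append(
            ForceSegment(
                component_id=comp.component_id,
                mean_z=comp.mean,
                forces=f,
                dispersion=disp,
                metadata={
                    "ci": (lo, hi),
                    "sd_threshold": sd_threshold,
                    "weight": comp.weight,
                },
            )
        )
    return segments


def _pairwise_fraction_ge(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of pairs (x in a, y in b) with x >= y, via sorting.

    Ties count as satisfying the inequality.
    """
    b_sorted = np.sort(b)
    counts = np.searchsorted(b_sorted, a, side="right")
    return float(counts.sum()) / (a.size * b.size)


def _pairwise_fraction_le(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of pairs (x in a, y in b) with x <= y; ties count."""
    b_sorted = np.sort(b)
    counts = b.size - np.searchsorted(b_sorted, a, side="left")
    return float(counts.sum()) / (a.size * b.size)


def transition_probability(
    segment_i: ForceSegment,
    segment_j: ForceSegment,
    check_order: bool = True,
) -> float:
    """P(z_i -> z_j): probability that f(z_i) >= f(z_j), by the three-case
    rule documented in the module docstring."""
    if segment_i.n == 0 or segment_j.n == 0:
        raise EmptyDataError("transition probability needs nonempty segments")
    if check_order and not segment_i.mean_z < segment_j.mean_z:
        raise ConfigurationError(
            "segments must be ordered along z (mean_z_i < mean_z_j)"
        )
    di, dj = segment_i.dispersion, segment_j.dispersion
    if di == "small" and dj == "small":
        return 1.0 if segment_i.mean_f >= segment_j.mean_f else 0.0
    if di == "large" and dj == "small":
        return float(np.mean(segment_i.forces >= segment_j.mean_f))
    if di == "small" and dj == "large":
        return float(np.mean(segment_j.forces <= segment_i.mean_f))
    # both large: product P(f_i >= f_j) * P(f_j <= f_i), each factor an
    # empirical fraction over the sample product, the two events treated
    # as independent (the operational recipe; the two factors describe the
    # same pairwise event and so coincide up to tie handling).
    p1 = _pairwise_fraction_ge(segment_i.forces, segment_j.forces)
    p2 = _pairwise_fraction_le(segment_j.forces, segment_i.forces)
    return p1 * p2


def reverse_transition_probability(
    segment_i: ForceSegment, segment_j: ForceSegment
) -> float:
    """P(z_j -> z_i): the return transition, with the inequality roles of
    the two segments exchanged (0 whenever the forward case-(a) rule
    gives 1)."""
    if segment_i.n == 0 or segment_j.n == 0:
        raise EmptyDataError("transition probability needs nonempty segments")
    if not segment_i.mean_z < segment_j.mean_z:
        raise ConfigurationError(
            "segments must be ordered along z (mean_z_i < mean_z_j)"
        )
    di, dj = segment_i.dispersion, segment_j.dispersion
    if di == "small" and dj == "small":
        return 0.0 if segment_i.mean_f >= segment_j.mean_f else 1.0
    if dj == "large" and di == "small":
        return float(np.mean(segment_j.forces >= segment_i.mean_f))
    if dj == "small" and di == "large":
        return float(np.mean(segment_i.forces <= segment_j.mean_f))
    p1 = _pairwise_fraction_ge(segment_j.forces, segment_i.forces)
    p2 = _pairwise_fraction_le(segment_i.forces, segment_j.forces)
    return p1 * p2


def negative_force_fraction(segment: ForceSegment) -> float:
    """count(f < 0) / n — the spontaneous-jump probability into the next
    site (a negative bias force means the particle sits ahead of the bias
    center)."""
    if segment.n == 0:
        raise EmptyDataError("empty force segment")
    return float(np.mean(segment.forces < 0.0))


def probability_ratio(p_a: float, p_b: float) -> float:
    """p_a / p_b (e.g. relative entry frequencies of two species)."""
    if p_b <= 0:
        raise ConfigurationError("denominator probability must be > 0")
    return p_a / p_b


# ---------------------------------------------------------------------------
# Detailed-balance overlap diagnostics
# ---------------------------------------------------------------------------


@dataclass
class OverlapReport:
    """Overlap between two step distributions on a common grid."""

    overlap: float
    forward_weight: float
    backward_weight: float
    below_floor: bool
    floor: float


def _rebin(hist: Histogram, new_edges: np.ndarray) -> np.ndarray:
    """Re-aggregate a piecewise-constant density onto ``new_edges``."""
    cdf_x = hist.edges
    cdf_y = np.concatenate(
        [[0.0], np.cumsum(hist.density) * hist.bin_width]
    )
    vals = np.interp(new_edges, cdf_x, cdf_y, left=0.0, right=cdf_y[-1])
    widths = np.diff(new_edges)
    return np.diff(vals) / widths


def detailed_balance_overlap(
    g_i: Histogram,
    g_j: Histogram,
    floor: float = 0.05,
) -> OverlapReport:
    """Overlap coefficient ``sum min(g_i, g_j) * bin_width`` between two
    step distributions, rebinned onto a shared grid when needed.

    The forward/backward weights are the overlap mass normalised by each
    distribution's mass over the overlap support; pairs whose overlap falls
    below ``floor`` are flagged (path-dominance diagnostic).
    """
    bw = min(g_i.bin_width, g_j.bin_width)
    lo = min(g_i.edges[0], g_j.edges[0])
    hi = max(g_i.edges[-1], g_j.edges[-1])
    n_bins = max(1, int(np.ceil((hi - lo) / bw - 1e-9)))
    edges = lo + bw * np.arange(n_bins + 1)
    di = _rebin(g_i, edges)
    dj = _rebin(g_j, edges)
    overlap = float(np.minimum(di, dj).sum() * bw)
    overlap = min(max(overlap, 0.0), 1.0)
    support = (di > 0) & (dj > 0)
    mass_i = float(di[support].sum() * bw)
    mass_j = float(dj[support].sum() * bw)
    fwd = overlap / mass_i if mass_i > 0 else 0.0
    bwd = overlap / mass_j if mass_j > 0 else 0.0
    return OverlapReport(
        overlap=overlap,
        forward_weight=min(fwd, 1.0),
        backward_weight=min(bwd, 1.0),
        below_floor=overlap < floor,
        floor=floor,
    )
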