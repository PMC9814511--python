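"""Synthetic multi-subject, multi-condition parcel time series.

The generator's ground truth is a latent 3-axis gradient geometry:
every parcel carries a latent coordinate vector ``u_p`` on an ellipsoid
with distinct semi-extents per axis, and a scan's signal is

    x(t) = g0 f0(t) + U f(t) + amplitude * c_{s(t)} + eps(t)

where the columns of ``U`` hold the latent coordinates, ``f0`` and the
three ``f`` are independent unit-variance latent series band-limited to
the 0.01-0.1 Hz passband (so the generator's spectrum matches the
preprocessing passband and filtering cannot leak condition effects),
``g0`` is a common-mode (global-signal) loading shared by all parcels,
``s(t)`` is a Markov chain over co-activation pattern (CAP) centroids,
and ``eps`` is i.i.d. Gaussian noise.  The population correlation
between two parcels is then an increasing function of the inner product
of their latent coordinates, anchored by the common mode so that parcel
*positions* - not just directions - shape the correlation structure the
downstream gradient embedding recovers.

Three geometric choices make the planted coordinates recoverable by the
sparsified normalized-angle + diffusion-map pipeline and are deliberate:
(1) parcels tile the latent ellipsoid surface quasi-uniformly and
networks are contiguous regions of it (functional networks tile real
gradient space the same way; strongly clustered point clouds distort
neighborhood-graph spectral embeddings); (2) on a closed quasi-uniform
surface the three coordinate functions are the leading smooth modes of
any local similarity graph, so the embedding is essentially linear in
the planted coordinates; (3) distinct semi-extents give the recovered
gradients a stable order.

Condition effects are forward models of gradient degradation: per-axis
compression saturates the tails of a latent axis so its range scales
exactly by the stated factor (degradation is a loss of differentiation
at the gradient extremes), and a VAN-DMN convergence parameter moves
those two network centroids toward their midpoint.  CAP occupancy can
be coupled to the geometry via :func:`occupancy_from_geometry`, which
raises the VAN+ rate and lowers the DMN+/DAN+ rates as the VAN-DMN
latent distance contracts.

All outputs are bit-reproducible under a fixed seed.  The default
network anchor directions are package defaults chosen so the axis
orderings are realistic for resting cortex - axis 1 runs from unimodal
(VIS/SMN) to transmodal (FPN/DMN), axis 2 separates VIS from SMN, axis
3 separates VIS/DMN from the attention/control networks; the exact
numbers are NOT taken from any empirical atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io import NETWORKS, MotionTrace, ParcellationScheme, ParcelTimeSeries

#: Latent network centroids (rows follow :data:`gradientspace.io.NETWORKS`).
DEFAULT_NETWORK_CENTROIDS = np.array(
    [
        # G1     G2     G3
        [-1.00, 1.00, 0.80],  # VIS
        [-0.90, -1.00, 0.00],  # SMN
        [-0.20, -0.30, -0.80],  # DAN
        [0.10, -0.20, -1.00],  # VAN
        [0.40, 0.10, 0.20],  # LIM
        [0.80, 0.20, -0.70],  # FPN
        [1.00, 0.30, 0.90],  # DMN
    ]
)

#: Default CAP label order used throughout the package.
DEFAULT_CAP_LABELS = ("DMN+", "DAN+", "FPN+", "SMN+", "VIS+", "VAN+", "GN+", "GN-")

#: Semi-extents of the latent ellipsoid along gradients 1..3.  Distinct
#: values give the three recovered gradients distinct eigenvalues (so the
#: group-level gradient order is stable), mirroring the declining variance
#: shares of the first three empirical connectivity gradients; the gaps
#: keep all three linear modes above the first quadratic harmonic.
DEFAULT_SEMI_EXTENTS = (1.0, 0.95, 0.9)

#: Loading of the common-mode (global) signal shared by all parcels.  The
#: common mode anchors the correlation scale: without it, correlations -
#: and hence the embedding - would see only the directions of the latent
#: coordinates, not their positions.
DEFAULT_COMMON_MODE = 2.0



@dataclass
class GradientTemplate:
    """Latent gradient geometry for one (possibly condition-modified) brain.

    ``latent_coords`` is P x 3; ``network_centroids`` is a
    ``{network: (3,) array}`` mapping consistent with the coordinates.
    """

    scheme: ParcellationScheme
    latent_coords: np.ndarray
    network_centroids: dict[str, np.ndarray]
    within_network_sd: float
    common_mode: float = DEFAULT_COMMON_MODE

    def __post_init__(self) -> None:
        self.latent_coords = np.asarray(self.latent_coords, dtype=float)
        if self.latent_coords.shape != (self.scheme.n_parcels, 3):
            raise ValidationError("latent_coords must be P x 3")

    def centroid_distance(self, a: str, b: str) -> float:
        """Euclidean distance between two network centroids in latent space."""
        return float(np.linalg.norm(self.network_centroids[a] - self.network_centroids[b]))


@dataclass(frozen=True)
class ConditionEffect:
    """Forward model of a consciousness-state effect on the geometry.

    ``axis_compression``: per-axis factors in (0, 1]; 1 = no change.
    ``van_dmn_convergence``: fraction in [0, 1] by which the VAN and DMN
    centroids move toward their midpoint (1 = coincide).
    ``cap_coupling_beta``: non-negative gain linking VAN-DMN contraction
    to CAP occupancy shifts.
    """

    axis_compression: tuple[float, float, float] = (1.0, 1.0, 1.0)
    van_dmn_convergence: float = 0.0
    cap_coupling_beta: float = 0.0

    def __post_init__(self) -> None:
        if len(self.axis_compression) != 3 or any(
            not 0 < c <= 1 for c in self.axis_compression
        ):
            raise ValidationError("axis_compression factors must lie in (0, 1]")
        if not 0 <= self.van_dmn_convergence <= 1:
            raise ValidationError("van_dmn_convergence must lie in [0, 1]")
        if self.cap_coupling_beta < 0:
            raise ValidationError("cap_coupling_beta must be non-negative")


@dataclass
class CapDynamicsSpec:
    """Markov CAP dynamics: centroid topographies, a row-stochastic
    transition matrix, and the additive amplitude of the active pattern."""

    centroids: np.ndarray
    transition_matrix: np.ndarray
    amplitude: float = 1.0
    labels: tuple[str, ...] = DEFAULT_CAP_LABELS

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        k = self.centroids.shape[0]
        if k < 2:
            raise ValidationError("need at least 2 CAP centroids")
        if self.transition_matrix.shape != (k, k):
            raise ValidationError("transition matrix must be K x K")
        if np.any(self.transition_matrix < 0) or np.any(
            np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-12
        ):
            raise ValidationError("transition matrix rows must be non-negative and sum to 1")
        if len(self.labels) != k:
            raise ValidationError("one label per centroid required")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be non-negative")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Left Perron eigenvector of the transition matrix, normalized."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform deterministic lattice of ``n`` unit vectors."""
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azimuth = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [
            np.cos(azimuth) * np.sin(polar),
            np.sin(azimuth) * np.sin(polar),
            np.cos(polar),
        ]
    )


def _project_to_ellipsoid(coords: np.ndarray) -> np.ndarray:
    """Radially rescale points onto the ellipsoid with the default
    semi-extents."""
    ext = np.asarray(DEFAULT_SEMI_EXTENTS)
    norms = np.linalg.norm(coords / ext, axis=1, keepdims=True)
    return coords / np.where(norms > 0, norms, 1.0)


def _balanced_region_labels(points: np.ndarray, scheme: ParcellationScheme) -> np.ndarray:
    """Assign each point a network so regions are contiguous and the
    per-network counts match the scheme exactly (greedy nearest-centroid
    assignment with capacities)."""
    anchors = _project_to_ellipsoid(DEFAULT_NETWORK_CENTROIDS)
    capacity = {net: scheme.indices_of(net).size for net in NETWORKS}
    n = points.shape[0]
    d2 = ((points[:, None, :] - anchors[None, :, :]) ** 2).sum(-1)
    order = np.dstack(np.unravel_index(np.argsort(d2, axis=None), d2.shape))[0]
    assigned = np.full(n, -1, dtype=int)
    for p, k in order:
        if assigned[p] >= 0:
            continue
        net = NETWORKS[k]
        if capacity[net] > 0:
            assigned[p] = k
            capacity[net] -= 1
    return assigned


def _net_index(scheme: ParcellationScheme) -> np.ndarray:
    idx = np.empty(scheme.n_parcels, dtype=int)
    for k, net in enumerate(NETWORKS):
        idx[scheme.indices_of(net)] = k
    return idx


def _realized_centroids(coords: np.ndarray, labels: np.ndarray) -> dict[str, np.ndarray]:
    return {net: coords[labels == k].mean(axis=0) for k, net in enumerate(NETWORKS)}


def make_template(
    scheme: ParcellationScheme,
    within_network_sd: float = 0.04,
    seed: int = 0,
    layout: str = "surface",
    common_mode: float = DEFAULT_COMMON_MODE,
) -> GradientTemplate:
    """Build a latent gradient template for a parcellation scheme.

    The default ``"surface"`` layout places parcels quasi-uniformly on
    the ellipsoid with semi-extents :data:`DEFAULT_SEMI_EXTENTS` (a
    jittered spherical Fibonacci lattice, rescaled) and carves it into
    seven contiguous network regions around the canonical centroid
    directions, with region sizes matching the scheme.  Networks thus
    tile the latent gradient space continuously, the way functional
    networks tile real connectivity-gradient space; the quasi-uniform
    coverage of a closed surface is what makes the planted coordinates
    recoverable by a neighborhood-graph spectral embedding (the three
    coordinate functions are its leading smooth modes), and the
    distinct semi-extents keep the gradient order stable.
    ``within_network_sd`` is the SD of the Gaussian jitter applied to
    the lattice points before re-projection onto the surface.

    The alternative ``"cluster"`` layout draws each parcel as its
    network centroid plus isotropic Gaussian jitter; it produces
    well-separated point clusters but a correspondingly more distorted
    embedding.

    Deterministic given ``seed``.
    """
    missing = set(NETWORKS) - set(scheme.present_networks)
    if missing:
        raise ConfigurationError(f"scheme lacks networks: {sorted(missing)}")
    if within_network_sd < 0:
        raise ValidationError("within_network_sd must be non-negative")
    rng = np.random.default_rng(seed)
    P = scheme.n_parcels
    if layout == "surface":
        pts = _fibonacci_sphere(P)
        if within_network_sd > 0:
            pts = pts + rng.normal(0.0, within_network_sd, size=pts.shape)
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = pts * np.asarray(DEFAULT_SEMI_EXTENTS)
        labels = _balanced_region_labels(pts, scheme)
        # reorder so that parcels carry their scheme-assigned network
        coords = np.empty_like(pts)
        for k, net in enumerate(NETWORKS):
            coords[scheme.indices_of(net)] = pts[labels == k]
        centroids = _realized_centroids(coords, _net_index(scheme))
    elif layout == "cluster":
        counts = np.array([scheme.indices_of(net).size for net in NETWORKS], dtype=float)
        weighted_mean = (counts[:, None] * DEFAULT_NETWORK_CENTROIDS).sum(0) / counts.sum()
        cent = DEFAULT_NETWORK_CENTROIDS - weighted_mean
        centroids = {net: cent[i].copy() for i, net in enumerate(NETWORKS)}
        coords = np.empty((P, 3))
        for net in NETWORKS:
            idx = scheme.indices_of(net)
            coords[idx] = centroids[net] + rng.normal(
                0.0, within_network_sd, size=(idx.size, 3)
            )
    else:
        raise ValidationError(f"layout must be 'surface' or 'cluster', got {layout!r}")
    return GradientTemplate(
        scheme=scheme,
        latent_coords=coords,
        network_centroids=centroids,
        within_network_sd=within_network_sd,
        common_mode=common_mode,
    )


def _saturate_axis(x: np.ndarray, c: float) -> np.ndarray:
    """Monotone saturating warp of one latent axis with an exact range ratio.

    Gradient degradation is a loss of functional differentiation at the
    gradient *extremes*, so compression is modeled as a saturation that
    squashes the tails of the axis while leaving its bulk nearly intact:
    ``f(x) = x (1 - (1 - c)|x/a|^p)`` with ``p = c/(1-c)`` (the largest
    exponent keeping ``f`` monotone), rescaled so the realized range is
    exactly ``c`` times the input range.  Concentrating the deformation
    in the sparsely populated tails also leaves the local point density
    of the rest of the manifold - and with it the spectral scale of the
    other gradients - essentially untouched.
    """
    a = float(np.max(np.abs(x)))
    if a == 0 or c >= 1.0:
        return x.copy()
    p = c / (1.0 - c)
    f = x * (1.0 - (1.0 - c) * (np.abs(x) / a) ** p)
    scale = c * (x.max() - x.min()) / (f.max() - f.min())
    return scale * f


def apply_condition(template: GradientTemplate, effect: ConditionEffect) -> GradientTemplate:
    """Apply axis compression and VAN-DMN convergence to a template.

    Compression applies a monotone saturating warp to each latent axis
    so that the planted per-axis range scales exactly by ``c_k`` (see
    :func:`_saturate_axis`); convergence then moves every VAN and DMN
    parcel toward the other network's centroid by half the convergence
    fraction of the centroid gap.  The identity effect returns an
    identical geometry.
    """
    coords = template.latent_coords.copy()
    mean = coords.mean(axis=0)
    for axis, c in enumerate(effect.axis_compression):
        if c < 1.0:
            coords[:, axis] = mean[axis] + _saturate_axis(coords[:, axis] - mean[axis], float(c))
    gamma = effect.van_dmn_convergence
    scheme = template.scheme
    labels = _net_index(scheme)
    if gamma > 0:
        cen = _realized_centroids(coords, labels)
        van, dmn = cen["VAN"], cen["DMN"]
        coords[scheme.indices_of("VAN")] += (gamma / 2.0) * (dmn - van)
        coords[scheme.indices_of("DMN")] += (gamma / 2.0) * (van - dmn)
    return replace(
        template,
        latent_coords=coords,
        network_centroids=_realized_centroids(coords, labels),
    )


def perturb_template(
    template: GradientTemplate, subject_sd_fraction: float, rng: np.random.Generator
) -> GradientTemplate:
    """Subject-level variability: every network's parcels share a Gaussian
    centroid offset with SD equal to ``subject_sd_fraction`` of the
    between-network centroid spread."""
    cent = np.stack([template.network_centroids[n] for n in NETWORKS])
    spread = float(cent.std())
    sd = subject_sd_fraction * spread
    coords = template.latent_coords.copy()
    scheme = template.scheme
    for net in NETWORKS:
        coords[scheme.indices_of(net)] += rng.normal(0.0, sd, size=3)
    return replace(
        template,
        latent_coords=coords,
        network_centroids=_realized_centroids(coords, _net_index(scheme)),
    )


def default_cap_spec(
    scheme: ParcellationScheme,
    base_rates: np.ndarray | None = None,
    stickiness: float = 0.5,
    amplitude: float = 5.0,
) -> CapDynamicsSpec:
    """Eight signed network-indicator CAP centroids with a sticky chain.

    Each network pattern is +1 on its own parcels and ``-1 / (P - n_net)``
    elsewhere, unit-normalized; GN+ and GN- are uniform global
    activation/deactivation.  The transition matrix is
    ``stickiness * I + (1 - stickiness) * 1 pi^T`` so its stationary
    distribution equals ``base_rates`` (uniform by default).
    """
    P = scheme.n_parcels
    rows = []
    for lab in DEFAULT_CAP_LABELS:
        if lab == "GN+":
            v = np.ones(P)
        elif lab == "GN-":
            v = -np.ones(P)
        else:
            net = lab[:-1]
            idx = scheme.indices_of(net)
            v = np.full(P, -1.0 / (P - idx.size))
            v[idx] = 1.0
        rows.append(v / np.linalg.norm(v))
    centroids = np.stack(rows)
    k = len(DEFAULT_CAP_LABELS)
    if base_rates is None:
        base_rates = np.full(k, 1.0 / k)
    base_rates = np.asarray(base_rates, dtype=float)
    if base_rates.shape != (k,) or abs(base_rates.sum() - 1.0) > 1e-9 or np.any(base_rates < 0):
        raise ValidationError("base_rates must be a length-K simplex")
    if not 0 <= stickiness < 1:
        raise ValidationError("stickiness must lie in [0, 1)")
    trans = stickiness * np.eye(k) + (1 - stickiness) * np.tile(base_rates, (k, 1))
    trans = trans / trans.sum(axis=1, keepdims=True)
    return CapDynamicsSpec(
        centroids=centroids,
        transition_matrix=trans,
        amplitude=amplitude,
        labels=DEFAULT_CAP_LABELS,
    )


def occupancy_from_geometry(
    template: GradientTemplate,
    effect: ConditionEffect,
    base_rates: np.ndarray,
    labels: tuple[str, ...] = DEFAULT_CAP_LABELS,
) -> np.ndarray:
    """CAP occupancy implied by a condition's VAN-DMN contraction.

    With ``delta_d`` = (baseline VAN-DMN latent distance) minus the
    post-effect distance and ``beta`` = ``effect.cap_coupling_beta``, the
    VAN+ rate is multiplied by ``exp(+beta * delta_d)`` and the DMN+ and
    DAN+ rates by ``exp(-beta * delta_d)``; the result is renormalized to
    a simplex.  ``beta = 0`` returns ``base_rates`` unchanged.
    """
    base_rates = np.asarray(base_rates, dtype=float)
    if abs(base_rates.sum() - 1.0) > 1e-9 or np.any(base_rates < 0):
        raise ValidationError("base_rates must sum to 1 and be non-negative")
    if len(labels) != base_rates.size:
        raise ValidationError("one label per base rate required")
    beta = effect.cap_coupling_beta
    d0 = template.centroid_distance("VAN", "DMN")
    d1 = apply_condition(template, effect).centroid_distance("VAN", "DMN")
    delta = d0 - d1
    rates = base_rates.copy()
    lab = list(labels)
    rates[lab.index("VAN+")] *= np.exp(beta * delta)
    for name in ("DMN+", "DAN+"):
        rates[lab.index(name)] *= np.exp(-beta * delta)
    return rates / rates.sum()


def _band_limited_series(
    rng: np.random.Generator, T: int, tr: float, band: tuple[float, float], n_series: int
) -> np.ndarray:
    """Unit-variance Gaussian series filtered to the passband (T x n)."""
    lo, hi = band
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= lo) & (freqs <= hi)
    if not np.any(keep):
        raise ValidationError(
            f"no DFT frequency falls inside the {band} Hz band for T={T}, tr={tr}"
        )
    white = rng.standard_normal((T, n_series))
    spec = np.fft.rfft(white, axis=0)
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=0)
    out -= out.mean(axis=0)
    sd = out.std(axis=0)
    sd = np.where(sd < 1e-13, 1.0, sd)
    return out / sd


def _markov_chain(
    rng: np.random.Generator, trans: np.ndarray, T: int, init: np.ndarray
) -> np.ndarray:
    k = trans.shape[0]
    cum = np.cumsum(trans, axis=1)
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(k, p=init)
    u = rng.random(T)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def simulate_subject(
    template: GradientTemplate,
    caps: CapDynamicsSpec | None,
    T: int,
    tr: float = 2.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    passband: tuple[float, float] = (0.01, 0.1),
    spike_rate_per_minute: float = 0.5,
    spike_mm: float = 0.6,
    motion_walk_sd: float = 0.02,
    subject_id: str = "",
    condition_id: str = "",
) -> tuple[ParcelTimeSeries, MotionTrace, np.ndarray | None]:
    """Simulate one scan: signal, motion trace, and true CAP labels.

    Motion is a gentle random walk plus single-frame translation jumps of
    ``spike_mm`` (default 0.6 mm, above the usual 0.4 mm FD threshold so
    scrubbing is exercised) at Poisson-distributed frames.  Returns
    ``(time_series, motion, cap_labels)``; ``cap_labels`` is None when no
    CAP dynamics are supplied.
    """
    if T < 10:
        raise ValidationError("T must be at least 10")
    rng = np.random.default_rng(seed)
    U = template.latent_coords
    P = U.shape[0]
    f = _band_limited_series(rng, T, tr, passband, 4)
    x = f[:, :3] @ U.T + template.common_mode * f[:, [3]]
    labels: np.ndarray | None = None
    if caps is not None and caps.amplitude > 0:
        if caps.centroids.shape[1] != P:
            raise ValidationError("CAP centroids and template disagree on parcel count")
        pi = caps.stationary_distribution()
        labels = _markov_chain(rng, caps.transition_matrix, T, pi)
        x = x + caps.amplitude * caps.centroids[labels]
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=(T, P))

    motion = np.cumsum(rng.normal(0.0, motion_walk_sd, size=(T, 6)), axis=0)
    expected_spikes = spike_rate_per_minute * T * tr / 60.0
    n_spikes = rng.poisson(expected_spikes)
    if n_spikes > 0:
        frames = rng.choice(np.arange(2, T - 1), size=min(n_spikes, T - 3), replace=False)
        motion[frames, 0] += spike_mm

    ts = ParcelTimeSeries(
        data=x, tr_seconds=tr, subject_id=subject_id, condition_id=condition_id
    )
    return ts, MotionTrace(motion), labels


@dataclass
class CohortScan:
    """One simulated scan plus its ground truth."""

    timeseries: ParcelTimeSeries
    motion: MotionTrace
    template: GradientTemplate
    cap_labels: np.ndarray | None
    subject_id: str
    condition_id: str


@dataclass
class Cohort:
    scans: list[CohortScan]
    base_template: GradientTemplate
    effects: dict[str, ConditionEffect]
    paired: bool

    def by_condition(self, condition_id: str) -> list[CohortScan]:
        return [s for s in self.scans if s.condition_id == condition_id]


def simulate_cohort(
    scheme: ParcellationScheme,
    effects_by_condition: dict[str, ConditionEffect],
    n_subjects: int,
    paired: bool = True,
    T: int = 120,
    tr: float = 2.0,
    noise_sd: float = 2.0,
    within_network_sd: float = 0.15,
    subject_sd_fraction: float = 0.1,
    caps: CapDynamicsSpec | None = None,
    couple_caps_to_geometry: bool = False,
    seed: int = 0,
    spike_rate_per_minute: float = 0.5,
) -> Cohort:
    """Simulate a multi-subject, multi-condition cohort.

    With ``paired=True`` each subject's centroid jitter is shared across
    that subject's conditions (within-subject design); with
    ``paired=False`` every scan draws an independent jitter.  With
    ``couple_caps_to_geometry=True`` each scan's CAP transition matrix is
    rebuilt so its stationary occupancy follows
    :func:`occupancy_from_geometry` for that scan's effect.
    """
    if n_subjects < 2:
        raise ValidationError("n_subjects must be at least 2")
    if not effects_by_condition:
        raise ValidationError("need at least one condition")
    ss = np.random.SeedSequence(seed)
    template_seed, scan_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    base = make_template(scheme, within_network_sd=within_network_sd, seed=template_seed)
    rng = np.random.default_rng(scan_seed)
    scans: list[CohortScan] = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        shared = (
            perturb_template(base, subject_sd_fraction, rng) if paired else None
        )
        for cond, effect in effects_by_condition.items():
            subj_template = (
                shared if shared is not None else perturb_template(base, subject_sd_fraction, rng)
            )
            cond_template = apply_condition(subj_template, effect)
            scan_caps = caps
            if caps is not None and couple_caps_to_geometry:
                pi0 = caps.stationary_distribution()
                pi = occupancy_from_geometry(subj_template, effect, pi0, caps.labels)
                k = caps.k
                stick = 0.5  # sticky chain with the coupled stationary law
                trans = stick * np.eye(k) + (1 - stick) * np.tile(pi, (k, 1))
                trans /= trans.sum(axis=1, keepdims=True)
                scan_caps = replace(caps, transition_matrix=trans)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            ts, motion, labels = simulate_subject(
                cond_template,
                scan_caps,
                T=T,
                tr=tr,
                noise_sd=noise_sd,
                seed=sub_seed,
                spike_rate_per_minute=spike_rate_per_minute,
                subject_id=sid,
                condition_id=cond,
            )
            scans.append(
                CohortScan(
                    timeseries=ts,
                    motion=motion,
                    template=cond_template,
                    cap_labels=labels,
                    subject_id=sid,
                    condition_id=cond,
                )
            )
    return Cohort(scans=scans, base_template=base, effects=dict(effects_by_condition), paired=paired)


def population_correlation(
    template: GradientTemplate,
    noise_sd: float = 0.0,
    caps: CapDynamicsSpec | None = None,
) -> np.ndarray:
    """Exact population correlation matrix implied by the generative model.

    With unit-variance independent latents the signal covariance is
    ``g0^2 + U U^T`` (``g0`` the common-mode loading); CAP dynamics add
    ``amplitude^2 * sum_k pi_k c_k c_k^T`` minus the mean-pattern outer
    product, and measurement noise adds ``noise_sd^2`` to the diagonal.
    Useful for noise-free recoverability analyses (no sampling
    variability at all).
    """
    U = template.latent_coords
    cov = template.common_mode**2 + U @ U.T
    if caps is not None and caps.amplitude > 0:
        pi = caps.stationary_distribution()
        C = caps.centroids
        mean_pat = pi @ C
        second = (C.T * pi) @ C
        cov = cov + caps.amplitude**2 * (second - np.outer(mean_pat, mean_pat))
    cov = cov + noise_sd**2 * np.eye(U.shape[0])
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)
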