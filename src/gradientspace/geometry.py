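"""Distance statistics in the low-dimensional gradient space.

Four per-scan statistics summarize a (typically 3-dimensional) aligned
gradient embedding: the numerical range of each gradient, the global
dispersion (sum of squared distances of all parcels to the global
centroid), per-network eccentricity (distance of a network's centroid to
the global centroid), and pairwise between-network centroid distances.

Eccentricity and network distance default to *squared* Euclidean
distances, with ``squared=False`` available because both conventions
appear in the field; which one a given analysis used should always be
stated alongside its numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .embedding import EmbeddingResult
from .io import ParcellationScheme


@dataclass
class GeometryMetrics:
    """Per-scan gradient-space statistics."""

    gradient_range: np.ndarray
    global_dispersion: float
    eccentricity: dict[str, float] = field(default_factory=dict)
    network_distance: dict[tuple[str, str], float] = field(default_factory=dict)
    n_gradients_used: int = 3
    squared: bool = True

    def distance(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.network_distance[tuple(sorted((a, b)))]

    def to_records(self, subject_id: str = "", condition_id: str = "") -> list[dict]:
        base = {"subject": subject_id, "condition": condition_id}
        recs = []
        for g, r in enumerate(self.gradient_range, start=1):
            recs.append({**base, "metric": f"range_G{g}", "networks": "", "value": float(r)})
        recs.append({**base, "metric": "dispersion", "networks": "", "value": self.global_dispersion})
        for net, e in self.eccentricity.items():
            recs.append({**base, "metric": "eccentricity", "networks": net, "value": e})
        for (na, nb), dist in self.network_distance.items():
            recs.append({**base, "metric": "distance", "networks": f"{na}-{nb}", "value": dist})
        return recs


def gradient_range(e: EmbeddingResult, g: int) -> float:
    """Max minus min loading of gradient ``g`` (1-based gradient index)."""
    if not 1 <= g <= e.n_components:
        raise ValidationError(f"gradient index {g} outside 1..{e.n_components}")
    col = e.gradients[:, g - 1]
    return float(col.max() - col.min())


def global_dispersion(e: EmbeddingResult, n_gradients: int = 3) -> float:
    """Sum of squared Euclidean distances of all parcels to the global
    centroid in the first ``n_gradients`` coordinates."""
    if not 1 <= n_gradients <= e.n_components:
        raise ValidationError(f"n_gradients {n_gradients} outside 1..{e.n_components}")
    X = e.gradients[:, :n_gradients]
    centered = X - X.mean(axis=0)
    return float(np.sum(centered**2))


def network_geometry(
    e: EmbeddingResult,
    scheme: ParcellationScheme,
    squared: bool = True,
    n_gradients: int = 3,
) -> GeometryMetrics:
    """Eccentricity and pairwise centroid distances for the 7 networks.

    Network centroids are the mean coordinates of the network's parcels
    in the first ``n_gradients`` axes; the global centroid averages all
    parcels.  With ``squared=True`` both statistics are squared Euclidean
    distances.
    """
    if e.n_parcels != scheme.n_parcels:
        raise ValidationError("embedding and scheme disagree on parcel count")
    if not 1 <= n_gradients <= e.n_components:
        raise ValidationError(f"n_gradients {n_gradients} outside 1..{e.n_components}")
    X = e.gradients[:, :n_gradients]
    global_centroid = X.mean(axis=0)
    centroids: dict[str, np.ndarray] = {}
    for net in scheme.present_networks:
        idx = scheme.indices_of(net)
        if idx.size == 0:  # pragma: no cover - present_networks excludes these
            raise DegenerateInputError(f"network {net} has no parcels")
        centroids[net] = X[idx].mean(axis=0)

    def _dist(u: np.ndarray, v: np.ndarray) -> float:
        d2 = float(np.sum((u - v) ** 2))
        return d2 if squared else float(np.sqrt(d2))

    ecc = {net: _dist(c, global_centroid) for net, c in centroids.items()}
    nets = list(centroids)
    dist = {
        tuple(sorted((a, b))): _dist(centroids[a], centroids[b])
        for i, a in enumerate(nets)
        for b in nets[i + 1 :]
    }
    ranges = np.array([gradient_range(e, g) for g in range(1, n_gradients + 1)])
    return GeometryMetrics(
        gradient_range=ranges,
        global_dispersion=global_dispersion(e, n_gradients),
        eccentricity=ecc,
        network_distance=dist,
        n_gradients_used=n_gradients,
        squared=squared,
    )


def network_loading_summary(
    e: EmbeddingResult, scheme: ParcellationScheme
) -> dict[str, dict[str, np.ndarray]]:
    """Mean and sample SD of gradient loadings per network per gradient.

    Returns ``{network: {"mean": (k,), "sd": (k,)}}``.  A single-parcel
    network reports SD 0 with a warning.
    """
    if e.n_parcels != scheme.n_parcels:
        raise ValidationError("embedding and scheme disagree on parcel count")
    out: dict[str, dict[str, np.ndarray]] = {}
    for net in scheme.present_networks:
        idx = scheme.indices_of(net)
        block = e.gradients[idx]
        if idx.size == 1:
            warnings.warn(f"network {net} has a single parcel; SD reported as 0")
            sd = np.zeros(e.n_components)
        else:
            sd = block.std(axis=0, ddof=1)
        out[net] = {"mean": block.mean(axis=0), "sd": sd}
    return out
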