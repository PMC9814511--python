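"""Co-activation pattern (CAP) derivation, assignment, and occurrence rates.

A CAP is a recurring whole-cortex activation topography.  Patterns are
derived by k-means over z-scored single volumes pooled across scans, or
supplied as pre-defined centroids (one per canonical network plus global
activation/deactivation patterns GN+/GN-).  Each retained volume is then
assigned to the centroid it is most spatially similar to (Pearson
correlation across parcels), and per-scan occurrence rates are the
fraction of retained volumes carrying each label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ValidationError
from .io import ParcelTimeSeries


@dataclass
class CapSet:
    """K centroid topographies over P parcels, with one label per pattern."""

    centroids: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 2:
            raise ValidationError("need a K x P centroid matrix with K >= 2")
        if len(self.labels) != self.centroids.shape[0]:
            raise ValidationError("one label per centroid required")
        norms = np.linalg.norm(self.centroids, axis=1)
        if np.any(norms < 1e-300):
            raise ValidationError("centroid rows must be non-zero")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclass
class CapAssignment:
    """Per-retained-volume labels and per-scan occurrence rates."""

    per_volume_label: np.ndarray
    occurrence_rate: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.per_volume_label = np.asarray(self.per_volume_label, dtype=int)
        self.occurrence_rate = np.asarray(self.occurrence_rate, dtype=float)
        if abs(self.occurrence_rate.sum() - 1.0) > 1e-12:
            raise ValidationError("occurrence rates must sum to 1")

    def rate(self, label: str) -> float:
        return float(self.occurrence_rate[self.labels.index(label)])


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd < 1e-13, 1.0, sd)
    return (X - mu) / sd


def derive_caps(
    volumes: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    labels: tuple[str, ...] | None = None,
) -> CapSet:
    """k-means CAP derivation over stacked retained volumes.

    Volumes are z-scored across parcels before clustering (Euclidean
    distance); the best of ``n_restarts`` initializations by
    within-cluster sum of squares is kept, and the returned centroids are
    themselves z-scored.  Deterministic given ``seed``.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 2:
        raise ValidationError("volumes must be a (n_volumes, P) matrix")
    if k > volumes.shape[0]:
        raise ValidationError(f"k={k} exceeds the number of volumes {volumes.shape[0]}")
    Z = _zscore_rows(volumes)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(Z)
    centroids = _zscore_rows(km.cluster_centers_)
    if labels is None:
        labels = tuple(f"CAP{i + 1}" for i in range(k))
    return CapSet(centroids=centroids, labels=tuple(labels))


def assign_caps(
    ts: ParcelTimeSeries, caps: CapSet, zscore_volumes: bool = True
) -> CapAssignment:
    """Assign each retained volume to its most similar CAP centroid.

    Similarity is the Pearson spatial correlation across parcels between
    the volume and each centroid; ties go to the lowest centroid index.
    A zero-variance volume (flat topography) is assigned by unnormalized
    dot product instead, with a warning.  Censored volumes contribute to
    neither the numerator nor the denominator of occurrence rates.
    """
    X = ts.retained
    if X.shape[0] < 1:
        raise ValidationError("no retained volumes to assign")
    if X.shape[1] != caps.centroids.shape[1]:
        raise ValidationError("volume and centroid parcel counts differ")
    C = caps.centroids - caps.centroids.mean(axis=1, keepdims=True)
    c_sd = C.std(axis=1)
    flat_centroid = c_sd < 1e-13

    if zscore_volumes:
        X = _zscore_rows(X)
    V = X - X.mean(axis=1, keepdims=True)
    v_sd = V.std(axis=1)
    flat_volume = v_sd < 1e-13

    # Pearson correlation = cosine of the row-centered vectors
    sim = np.zeros((X.shape[0], caps.k))
    ok_c = ~flat_centroid
    denom = np.outer(np.where(flat_volume, 1.0, v_sd), c_sd[ok_c]) * X.shape[1]
    sim[:, ok_c] = (V @ C[ok_c].T) / denom
    if np.any(flat_centroid):
        # correlation undefined against a flat centroid; fall back to dot product
        sim[:, flat_centroid] = (X @ caps.centroids[flat_centroid].T) / X.shape[1]
    if np.any(flat_volume):
        warnings.warn(
            f"{int(flat_volume.sum())} zero-variance volumes assigned by dot product"
        )
        sim[flat_volume] = (X[flat_volume] @ caps.centroids.T) / X.shape[1]

    lab = np.argmax(sim, axis=1)  # argmax takes the lowest index on ties
    counts = np.bincount(lab, minlength=caps.k).astype(float)
    rates = counts / counts.sum()
    return CapAssignment(per_volume_label=lab, occurrence_rate=rates, labels=caps.labels)


def geometry_dynamics_correlation(
    distances: pd.DataFrame,
    rates: pd.DataFrame,
    distance_pairs: tuple[str, ...] = ("DMN-VAN", "DMN-DAN", "DAN-VAN"),
    rate_labels: tuple[str, ...] = ("VAN+", "DAN+", "DMN+"),
) -> pd.DataFrame:
    """Kendall tau-b between network distances and CAP occurrence rates.

    Both inputs are indexed by scan: ``distances`` has one column per
    network pair, ``rates`` one column per CAP label.  Each of the
    ``len(distance_pairs) * len(rate_labels)`` correlations is computed
    across scans, and the classical p values are FDR-corrected across
    that family.  If a variable is constant across scans, tau is reported
    as 0 with ``all_ties=True``.
    """
    from .stats import bh_fdr, kendall_tau_b

    if len(distances) != len(rates) or not distances.index.equals(rates.index):
        raise ValidationError("distance and rate tables must cover the same scans")
    if len(distances) < 10:
        raise ValidationError("need at least 10 scans for the correlation analysis")
    rows = []
    for dpair in distance_pairs:
        for rlab in rate_labels:
            x = distances[dpair].to_numpy(dtype=float)
            y = rates[rlab].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rows.append(
                    {"distance": dpair, "rate": rlab, "tau_b": 0.0, "p": np.nan, "all_ties": True}
                )
                continue
            tau, p = kendall_tau_b(x, y)
            rows.append({"distance": dpair, "rate": rlab, "tau_b": tau, "p": p, "all_ties": False})
    df = pd.DataFrame(rows)
    valid = ~df["p"].isna()
    if valid.any():
        adj = np.full(len(df), np.nan)
        adj[valid.to_numpy()] = bh_fdr(df.loc[valid, "p"].to_numpy())
        df["p_fdr"] = adj
    else:
        df["p_fdr"] = np.nan
    return df
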