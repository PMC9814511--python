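"""Functional connectivity and the normalized-angle affinity kernel.

The connectivity pipeline is: Pearson correlation over retained frames,
Fisher z-transform (diagonal set to 0), per-row retention of the top
fraction of weighted connections, and conversion of the sparsified row
profiles to a normalized cosine-angle affinity
``a_ij = 1 - arccos(cos(row_i, row_j)) / pi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .io import ParcelTimeSeries

# Perfect correlations are clipped before atanh; finite-arithmetic guard.
_R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """P x P connectivity; ``kind`` is one of pearson / fisher_z / sparsified."""

    values: np.ndarray
    kind: str = "fisher_z"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("connectivity matrix must be square")
        if self.kind not in {"pearson", "fisher_z", "sparsified"}:
            raise ValidationError(f"unknown connectivity kind {self.kind!r}")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class AffinityMatrix:
    """Symmetric parcel-by-parcel similarity in [0, 1] with unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("affinity matrix must be square")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


def compute_fc(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Fisher-z connectivity from Pearson correlation over retained frames.

    The diagonal is set to 0 rather than +inf: a self-connection carries
    no profile information and an infinite value would always survive row
    thresholding.
    """
    data = ts.retained
    if data.shape[0] < 3:
        raise ValidationError("need at least 3 retained frames for correlation")
    sd = data.std(axis=0)
    zero = np.flatnonzero(sd < 1e-13)
    if zero.size:
        raise DegenerateInputError(
            f"zero-variance parcels on retained frames: indices {zero[:5].tolist()}"
        )
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2
    return ConnectivityMatrix(values=z, kind="fisher_z")


def correlation_to_fisher_z(r: np.ndarray) -> ConnectivityMatrix:
    """Fisher-z matrix from an externally supplied correlation matrix
    (e.g. a population correlation with no sampling noise)."""
    r = np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2
    return ConnectivityMatrix(values=z, kind="fisher_z")


def sparsify_rows(
    m: ConnectivityMatrix, sparsity: float, threshold_by: str = "value"
) -> ConnectivityMatrix:
    """Keep the top ``ceil((1 - sparsity) * P)`` off-diagonal entries per row.

    Ranking is by signed value by default (``threshold_by="value"``); pass
    ``"abs"`` to rank by magnitude.  Ties at the cutoff are broken
    deterministically by (value desc, column index asc).  The result is
    generally asymmetric; the input is not modified.
    """
    if not 0 <= sparsity < 1:
        raise ValidationError(f"sparsity must be in [0, 1), got {sparsity}")
    if threshold_by not in {"value", "abs"}:
        raise ValidationError(f"threshold_by must be 'value' or 'abs', got {threshold_by!r}")
    P = m.n_parcels
    # guard against float fuzz in (1 - s) * P landing just above an integer
    n_keep = int(np.ceil(np.round((1.0 - sparsity) * P, 9)))
    n_keep = min(max(n_keep, 1), P - 1)
    vals = m.values.copy()
    key = np.abs(vals) if threshold_by == "abs" else vals
    key = key.astype(float).copy()
    np.fill_diagonal(key, -np.inf)  # diagonal never competes
    out = np.zeros_like(vals)
    # stable argsort on -key: primary value desc, ties broken by column asc
    order = np.argsort(-key, axis=1, kind="stable")
    keep = order[:, :n_keep]
    rows = np.repeat(np.arange(P), n_keep)
    out[rows, keep.ravel()] = vals[rows, keep.ravel()]
    return ConnectivityMatrix(values=out, kind="sparsified")


def cosine_affinity(m: ConnectivityMatrix) -> AffinityMatrix:
    """Normalized cosine-angle affinity between sparsified row profiles.

    ``a_ij = 1 - arccos(cos(row_i, row_j)) / pi`` maps parallel profiles
    to 1, orthogonal ones to 0.5, and anti-parallel ones to 0.  Because
    both arguments are row profiles, the output is symmetric even though
    sparsification itself is row-wise.
    """
    rows = m.values
    norms = np.linalg.norm(rows, axis=1)
    zero = np.flatnonzero(norms < 1e-300)
    if zero.size:
        raise DegenerateInputError(f"all-zero rows at indices {zero[:5].tolist()}")
    unit = rows / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    a = 1.0 - np.arccos(cos) / np.pi
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(values=a)
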