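"""Diffusion-map embedding of affinity matrices and Procrustes alignment.

The embedding follows the anisotropic diffusion-operator construction:
with affinity ``A`` and degrees ``d_i = sum_j A_ij``, the kernel is first
density-normalized, ``W_ij = A_ij / (d_i^alpha d_j^alpha)``, then row-
normalized into a Markov transition operator ``Pi = D_w^-1 W``.  The
eigenvectors of ``Pi`` are obtained stably from its symmetric conjugate
``S = D_w^-1/2 W D_w^-1/2``: if ``S v = lambda v`` then
``phi = D_w^-1/2 v`` is a right eigenvector of ``Pi``.  The trivial
constant eigenvector (``lambda = 1``) is dropped, and the remaining
components are scaled by ``lambda^t`` for diffusion time ``t > 0`` or by
the damped regularization ``lambda / (1 - lambda)`` when ``t = 0``
(automatic diffusion-time convention).  ``alpha = 0`` gives maximal
influence of the sampling density on the manifold, ``alpha = 1`` none;
``alpha = 0.5`` (the default elsewhere in the package) approximates the
Fokker-Planck normalization.

Variance explained is reported as each retained non-trivial eigenvalue's
share of the retained non-trivial spectrum (the denominator runs over
the ``n_components`` computed eigenvalues).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .errors import DegenerateInputError, ValidationError
from .connectivity import AffinityMatrix

_SYM_TOL = 1e-10


@dataclass
class EmbeddingResult:
    """Per-parcel gradient loadings plus the spectrum they came from.

    ``gradients`` is P x k with columns ordered Gradient-1..k by
    decreasing eigenvalue; loadings are unitless.
    """

    gradients: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    aligned: bool = False
    alpha: float = 0.5
    diffusion_time: float = 0.0

    def __post_init__(self) -> None:
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)

    @property
    def n_parcels(self) -> int:
        return self.gradients.shape[0]

    @property
    def n_components(self) -> int:
        return self.gradients.shape[1]


def diffusion_map(
    a: AffinityMatrix,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> EmbeddingResult:
    """Diffusion-map embedding of a symmetric non-negative affinity matrix.

    Raises
    ------
    ValidationError
        If the matrix is not symmetric or parameters are out of range.
    DegenerateInputError
        If the affinity graph is disconnected (the error reports the
        number of connected components).
    """
    A = a.values
    P = A.shape[0]
    if n_components < 1:
        raise ValidationError("n_components must be positive")
    if not 0 <= alpha <= 1:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    if diffusion_time < 0:
        raise ValidationError("diffusion_time must be non-negative")
    if np.max(np.abs(A - A.T)) > _SYM_TOL * max(1.0, np.max(np.abs(A))):
        raise ValidationError("affinity matrix must be symmetric")
    if np.any(A < 0):
        raise ValidationError("affinity matrix must be non-negative")
    n_comp_graph, _ = connected_components(A > 0, directed=False)
    if n_comp_graph > 1:
        raise DegenerateInputError(
            f"affinity graph is disconnected ({n_comp_graph} components)"
        )
    if n_components > P - 1:
        raise ValidationError("n_components must be at most P - 1")

    d = A.sum(axis=1)
    if alpha > 0:
        W = A / np.outer(d**alpha, d**alpha)
    else:
        W = A.copy()
    dw = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dw)
    S = W * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    # Right eigenvectors of the Markov operator; normalize against the
    # trivial stationary component so the constant mode is exactly 1.
    phi = evecs * inv_sqrt[:, None]
    phi = phi / phi[:, [0]]

    lambdas = evals[1 : n_components + 1]
    grads = phi[:, 1 : n_components + 1]
    if np.any(lambdas >= 1 - 1e-12):
        raise DegenerateInputError("non-trivial eigenvalue at 1: graph effectively disconnected")
    if diffusion_time > 0:
        scale = np.sign(lambdas) * np.abs(lambdas) ** diffusion_time
    else:
        scale = lambdas / (1.0 - lambdas)
    grads = grads * scale[None, :]

    pos = np.clip(lambdas, 0, None)
    total = pos.sum()
    var_exp = pos / total if total > 0 else np.zeros_like(pos)
    return EmbeddingResult(
        gradients=grads,
        eigenvalues=lambdas,
        variance_explained=var_exp,
        aligned=False,
        alpha=alpha,
        diffusion_time=diffusion_time,
    )


def procrustes_align(source: EmbeddingResult, reference: EmbeddingResult) -> EmbeddingResult:
    """Orthogonal (rotation/reflection, no scaling, no translation)
    Procrustes alignment of ``source`` onto ``reference``.

    Scaling is deliberately excluded: gradient range is a downstream
    outcome and must not be absorbed by the alignment step.  Eigenvalues
    pass through unchanged.
    """
    if source.gradients.shape != reference.gradients.shape:
        raise ValidationError(
            f"shape mismatch: source {source.gradients.shape} vs "
            f"reference {reference.gradients.shape}"
        )
    R, _ = orthogonal_procrustes(source.gradients, reference.gradients)
    return replace(source, gradients=source.gradients @ R, aligned=True)


def align_cohort(
    individuals: Sequence[EmbeddingResult], reference: EmbeddingResult
) -> list[EmbeddingResult]:
    """Align each embedding independently to the same reference.

    The reference is typically the embedding of the pooled baseline
    group-average connectivity matrix.
    """
    individuals = list(individuals)
    if not individuals:
        raise ValidationError("cannot align an empty cohort")
    return [procrustes_align(e, reference) for e in individuals]
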