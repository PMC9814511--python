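"""Parcel-level fMRI cleaning: motion scrubbing, nuisance projection,
band-pass filtering by spectral regression, and standardization.

The cleaning model follows common resting-state practice: frames whose
frame-wise displacement (FD) exceeds a threshold are censored together
with the preceding frame; on the retained frames a single ordinary
least-squares projection removes polynomial drift, the six motion
parameters and their first differences, optional white-matter/CSF
averages, optionally the global mean signal, and sine/cosine pairs at
every DFT frequency outside the passband.  Doing the band-pass by
regression (rather than an IIR filter) keeps the operation well defined
on time series with censored gaps and makes censor-then-filter
equivalent to row deletion followed by regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DegreesOfFreedomError, SchemaError, ValidationError
from .io import MotionTrace, ParcelTimeSeries


@dataclass
class FdSeries:
    """Frame-wise displacement in mm; ``fd[0] = 0`` by convention."""

    fd: np.ndarray
    threshold: float = 0.4

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if self.fd.ndim != 1:
            raise ValidationError("fd must be one-dimensional")
        if np.any(self.fd < 0):
            raise ValidationError("fd values must be non-negative")
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")


def compute_fd(motion: MotionTrace, threshold: float = 0.4) -> FdSeries:
    """Frame-wise Euclidean norm of the six motion-parameter derivatives.

    ``fd[t] = sqrt(sum_j (m[t, j] - m[t-1, j])^2)`` for ``t >= 1`` and
    ``fd[0] = 0`` (no prior frame).
    """
    params = motion.params
    if params.shape[1] != 6:
        raise SchemaError("motion trace must have 6 columns")
    if params.shape[0] < 2:
        raise ValidationError("need at least two frames to compute FD")
    deriv = np.diff(params, axis=0)
    fd = np.concatenate([[0.0], np.linalg.norm(deriv, axis=1)])
    return FdSeries(fd=fd, threshold=threshold)


def build_censor_mask(fd: FdSeries) -> np.ndarray:
    """True = retained.  A frame whose FD exceeds the threshold is
    censored together with its previous frame."""
    over = fd.fd > fd.threshold
    mask = ~over
    prev = np.flatnonzero(over)
    prev = prev[prev > 0] - 1
    mask[prev] = False
    return mask


def _drift_regressors(t_index: np.ndarray, order: int) -> np.ndarray:
    # Legendre-like scaled powers of the (full-scan) time index.
    x = (t_index - t_index.mean()) / max(t_index.max() - t_index.min(), 1)
    return np.column_stack([x**k for k in range(1, order + 1)])


def _band_stop_regressors(T: int, tr: float, passband: tuple[float, float]) -> np.ndarray:
    """Sine/cosine pairs at all DFT frequencies outside the passband,
    evaluated on the full time grid."""
    lo, hi = passband
    t = np.arange(T)
    cols = []
    for k in range(1, T // 2 + 1):
        f = k / (T * tr)
        if lo <= f <= hi:
            continue
        phase = 2 * np.pi * k * t / T
        cols.append(np.cos(phase))
        if k != T - k:  # sine at Nyquist is identically zero
            cols.append(np.sin(phase))
    if not cols:
        return np.empty((T, 0))
    return np.column_stack(cols)


def project_nuisance(
    ts: ParcelTimeSeries,
    motion: MotionTrace | None = None,
    mask: np.ndarray | None = None,
    wm_csf: np.ndarray | None = None,
    gsr: bool = True,
    passband: tuple[float, float] = (0.01, 0.1),
    drift_order: int = 2,
) -> ParcelTimeSeries:
    """Nuisance projection, band-pass and standardization on retained frames.

    Returns a new :class:`ParcelTimeSeries` whose retained frames are the
    OLS residuals of each parcel on the nuisance design, standardized to
    zero mean and unit variance; censored frames are NaN and the censor
    mask reflects ``mask``.

    Raises
    ------
    DegreesOfFreedomError
        If the retained frame count is below twice the regressor count.
    """
    T = ts.n_volumes
    if mask is None:
        mask = ts.censor_mask.copy()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (T,):
        raise ValidationError("mask length must equal the number of volumes")
    t_index = np.arange(T, dtype=float)

    design_cols = [np.ones(T)]
    if drift_order > 0:
        design_cols.append(_drift_regressors(t_index, drift_order))
    if motion is not None:
        if motion.params.shape[0] != T:
            raise ValidationError("motion trace length must match the time series")
        m = motion.params
        dm = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
        design_cols.extend([m, dm])
    if wm_csf is not None:
        wm_csf = np.asarray(wm_csf, dtype=float)
        if wm_csf.ndim == 1:
            wm_csf = wm_csf[:, None]
        if wm_csf.shape[0] != T:
            raise ValidationError("wm/csf regressors must match the time series length")
        design_cols.append(wm_csf)
    if gsr:
        design_cols.append(ts.data.mean(axis=1, keepdims=True))
    n_other = sum(1 if c.ndim == 1 else c.shape[1] for c in design_cols)
    design_cols.append(_band_stop_regressors(T, ts.tr_seconds, passband))
    design = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in design_cols])

    # Degrees-of-freedom guard.  The band-stop sinusoids remove a fixed
    # fraction of the spectrum by construction, so the safety margin is
    # assessed on the residual dof left after the whole design, relative
    # to the count of non-spectral (nuisance) regressors.
    n_retained = int(mask.sum())
    resid_dof = n_retained - design.shape[1]
    floor = max(n_other // 2, 5)
    if resid_dof < floor:
        raise DegreesOfFreedomError(
            f"{n_retained} retained frames for {design.shape[1]} regressors "
            f"({n_other} nuisance + {design.shape[1] - n_other} band-stop) leave "
            f"{resid_dof} residual dof; need at least {floor}"
        )

    X = design[mask]
    Y = ts.data[mask]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta

    sd = resid.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd < 1e-13)
    if zero.size:
        raise DegenerateInputError(
            f"parcels {zero[:5].tolist()} have zero residual variance on retained frames"
        )
    resid = (resid - resid.mean(axis=0)) / sd

    out = np.full_like(ts.data, np.nan)
    out[mask] = resid
    return ParcelTimeSeries(
        data=out,
        tr_seconds=ts.tr_seconds,
        censor_mask=mask,
        subject_id=ts.subject_id,
        condition_id=ts.condition_id,
    )


def preprocess_scan(
    ts: ParcelTimeSeries,
    motion: MotionTrace | None,
    fd_threshold_mm: float = 0.4,
    gsr: bool = True,
    passband: tuple[float, float] = (0.01, 0.1),
    wm_csf: np.ndarray | None = None,
    drift_order: int = 2,
) -> tuple[ParcelTimeSeries, FdSeries | None]:
    """Convenience wrapper: FD -> censor mask -> projection."""
    if motion is not None:
        fd = compute_fd(motion, threshold=fd_threshold_mm)
        mask = build_censor_mask(fd) & ts.censor_mask
    else:
        fd = None
        mask = ts.censor_mask.copy()
    cleaned = project_nuisance(
        ts, motion=motion, mask=mask, wm_csf=wm_csf, gsr=gsr,
        passband=passband, drift_order=drift_order,
    )
    return cleaned, fd
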