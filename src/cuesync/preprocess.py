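"""Time-series cleaning from the end of image preprocessing onward.

Operates on already-extracted voxel x TR matrices: initial-TR removal
(to discard large stimulus-onset transients), joint projection onto a
confound + cosine-drift + linear-trend basis (confound regression,
high-pass filtering with a 140 s cutoff period, and detrending in one
least-squares step), per-voxel z-scoring, and the decomposition of each
subject's data into a global component (the all-voxel average) and
selective components (per-voxel residuals after regressing out the
global component).

The expected order is drop -> clean -> global -> selective; the
pipeline enforces it, and ``VoxelSeries.tr_offset`` carries the number
of dropped initial TRs so the TR -> movie-time mapping stays correct
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._rng import zscore_rows


@dataclass(frozen=True)
class VoxelSeries:
    """A voxel x TR matrix for one subject and ROI.

    ``tr_offset`` counts initial TRs removed from the front, in TR
    units (seconds at a 1 s TR).
    """

    values: np.ndarray
    tr_seconds: float = 1.0
    subject_id: str | None = None
    roi_id: int | None = None
    tr_offset: int = 0

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(values).all():
            raise ValueError("voxel series contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_trs(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GlobalComponent:
    """Z-scored all-voxel average time series for one subject."""

    values: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())


def drop_initial_trs(x: VoxelSeries, n: int = 10) -> VoxelSeries:
    """Remove the first ``n`` TRs, recording the offset."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return x
    if x.n_trs <= n:
        raise ValueError(f"series has {x.n_trs} TRs, cannot drop {n}")
    return replace(x, values=x.values[:, n:], tr_offset=x.tr_offset + n)


def cosine_drift_basis(n_trs: int, tr_seconds: float, highpass_period: float) -> np.ndarray:
    """Discrete-cosine drift regressors for frequencies below the cutoff.

    Columns are cos(pi * k * (2t+1) / (2T)) for k = 1..K with
    K = floor(2 * T * tr / period), the DCT-II basis functions whose
    frequencies lie below 1/period Hz.
    """
    if highpass_period <= 0:
        raise ValueError("highpass_period must be positive")
    t = np.arange(n_trs)
    k_max = int(np.floor(2.0 * n_trs * tr_seconds / highpass_period))
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_trs)) for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n_trs, 0))
    return np.column_stack(cols)


def _project_out(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residual against ``design``, z-scored per row.

    Rows whose residual is numerically zero relative to the input
    (e.g. a voxel equal to a design column) are returned as exact
    zeros rather than z-scored round-off noise.
    """
    # QR-based projection: one factorization serves all voxels
    q, _ = np.linalg.qr(design)
    residual = (values.T - q @ (q.T @ values.T)).T
    input_scale = values.std(axis=1)
    resid_scale = residual.std(axis=1)
    negligible = resid_scale <= 1e-10 * np.maximum(input_scale, 1e-30)
    if np.any(negligible):
        residual[negligible] = 0.0
    return zscore_rows(residual, warn_constant=False)


def clean_series(
    x: VoxelSeries,
    confounds: np.ndarray | None = None,
    highpass_period: float = 140.0,
) -> VoxelSeries:
    """Confound regression, high-pass, detrend, and z-score in one step.

    The design matrix stacks an intercept, a linear trend, the cosine
    drift basis up to the cutoff period, and the supplied confound
    columns; each voxel is replaced by its least-squares residual
    against this basis, then z-scored.  The residual is exactly
    orthogonal to every basis column.
    """
    parts = [np.ones((x.n_trs, 1)), np.linspace(-1.0, 1.0, x.n_trs)[:, None]]
    drift = cosine_drift_basis(x.n_trs, x.tr_seconds, highpass_period)
    if drift.shape[1]:
        parts.append(drift)
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != x.n_trs:
            if confounds.shape[1] == x.n_trs:
                confounds = confounds.T
            else:
                raise ValueError("confound rows must match series length")
        if not np.isfinite(confounds).all():
            raise ValueError("confounds contain non-finite values")
        parts.append(confounds)
    design = np.column_stack(parts)
    return replace(x, values=_project_out(x.values, design))


def extract_global_component(
    all_series: Sequence[VoxelSeries] | VoxelSeries, subject_id: str | None = None
) -> GlobalComponent:
    """Average over all retained voxels of one subject, then z-score."""
    if isinstance(all_series, VoxelSeries):
        all_series = [all_series]
    if not all_series:
        raise ValueError("at least one voxel series is required")
    lengths = {s.n_trs for s in all_series}
    if len(lengths) != 1:
        raise ValueError("all series must share the same TR count")
    stacked = np.vstack([s.values for s in all_series])
    if stacked.shape[0] < 1:
        raise ValueError("at least one voxel is required")
    mean = stacked.mean(axis=0)
    if subject_id is None:
        subject_id = all_series[0].subject_id
    return GlobalComponent(values=zscore_rows(mean), subject_id=subject_id)


def selective_component(x: VoxelSeries, g: GlobalComponent) -> VoxelSeries:
    """Residual of each voxel after regressing on the global component.

    The residual of the least-squares fit of each voxel onto
    [1, global] is z-scored per voxel; it is numerically uncorrelated
    with the global component.
    """
    if g.values.size != x.n_trs:
        raise ValueError("global component length must match series length")
    design = np.column_stack([np.ones(x.n_trs), g.values])
    return replace(x, values=_project_out(x.values, design))
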