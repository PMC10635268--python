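"""Single-component shared response model (SRM) per ROI.

Reduces each ROI's multi-voxel data to one time series per subject by
fitting, per group (and session), the rank-one factorization

    minimize  sum_i || X_i - w_i s ||_F^2   subject to  ||w_i|| = 1,

where X_i is subject i's voxel x TR matrix, w_i the subject's voxel
weight vector, and s the shared time course.  Alternating minimization:
given s, the optimal unit weights are w_i = X_i s / ||X_i s||; given the
weights, s = (1/N) sum_i w_i' X_i.  Initialization is deterministic
(leading principal direction of the subject-stacked data), so the fit
needs no seed.  Voxel counts may differ between subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import zscore_rows


@dataclass
class SrmFit:
    """Fitted k=1 shared response model."""

    shared_series: np.ndarray
    subject_weights: list[np.ndarray]
    objective_trace: np.ndarray
    converged: bool


@dataclass
class SubjectSeriesSet:
    """Per-subject projected (z-scored) series for one ROI/group/session."""

    values: np.ndarray  # (n_subjects, n_trs)
    subject_ids: list[str] | None = None
    roi_id: int | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("subject series contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_trs(self) -> int:
        return self.values.shape[1]


def _as_matrices(group_voxel_data: Sequence[np.ndarray]) -> list[np.ndarray]:
    mats = [np.atleast_2d(np.asarray(x, dtype=float)) for x in group_voxel_data]
    if len(mats) < 2:
        raise ValueError("SRM requires at least 2 subjects")
    n_trs = {m.shape[1] for m in mats}
    if len(n_trs) != 1:
        raise ValueError("all subjects must have the same TR count")
    for i, m in enumerate(mats):
        if m.shape[0] < 1:
            raise ValueError("each subject needs at least one voxel")
        if not np.any(m):
            raise ValueError(f"subject {i} has an all-zero data matrix")
    return mats


def _leading_right_singular(stacked: np.ndarray, n_iter: int = 30, tol: float = 1e-10) -> np.ndarray:
    """Leading principal direction over TRs by deterministic power iteration.

    Starts from the mean voxel signal (falling back to a constant
    vector if it is null), iterating v <- X'Xv.  Only an approximate
    direction is needed — it seeds the alternating minimization.
    """
    v = stacked.mean(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        v = np.ones(stacked.shape[1])
        norm = np.linalg.norm(v)
    v = v / norm
    for _ in range(n_iter):
        w = stacked.T @ (stacked @ v)
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w = w / norm
        if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
            v = w
            break
        v = w
    scale = np.linalg.norm(stacked @ v)
    return v * scale


def fit_srm_k1(
    group_voxel_data: Sequence[np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SrmFit:
    """Fit the k=1 SRM by alternating minimization.

    Converges when the relative objective change drops below ``tol``
    (or after ``max_iter`` iterations).  The shared series' sign is
    fixed so that its correlation with the across-subject mean voxel
    signal is non-negative.
    """
    mats = _as_matrices(group_voxel_data)
    n = len(mats)

    stacked = np.vstack(mats)
    s = _leading_right_singular(stacked)

    trace: list[float] = []
    weights = [np.zeros(m.shape[0]) for m in mats]
    converged = False
    for _ in range(max_iter):
        for i, m in enumerate(mats):
            v = m @ s
            norm = np.linalg.norm(v)
            weights[i] = v / norm if norm > 0 else np.full(m.shape[0], 1.0 / np.sqrt(m.shape[0]))
        s = np.mean([w @ m for w, m in zip(weights, mats)], axis=0)
        obj = float(sum(np.sum((m - np.outer(w, s)) ** 2) for w, m in zip(weights, mats)))
        trace.append(obj)
        if len(trace) >= 2:
            prev = trace[-2]
            if prev == 0 or abs(prev - obj) <= tol * max(prev, 1e-300):
                converged = True
                break

    mean_signal = np.mean([m.mean(axis=0) for m in mats], axis=0)
    centered = mean_signal - mean_signal.mean()
    if float(np.dot(s - s.mean(), centered)) < 0:
        s = -s
        weights = [-w for w in weights]
    return SrmFit(
        shared_series=s,
        subject_weights=weights,
        objective_trace=np.asarray(trace),
        converged=converged,
    )


def project_subjects(
    fit: SrmFit,
    group_voxel_data: Sequence[np.ndarray],
    subject_ids: list[str] | None = None,
    roi_id: int | None = None,
) -> SubjectSeriesSet:
    """Project each subject onto their weight vector: series_i = w_i' X_i.

    The projected series are z-scored, so downstream statistics see
    each subject on a common scale.
    """
    mats = [np.atleast_2d(np.asarray(x, dtype=float)) for x in group_voxel_data]
    if len(mats) != len(fit.subject_weights):
        raise ValueError("subject count does not match fitted weights")
    rows = []
    for w, m in zip(fit.subject_weights, mats):
        if w.size != m.shape[0]:
            raise ValueError("weight length does not match voxel count")
        rows.append(w @ m)
    return SubjectSeriesSet(
        values=zscore_rows(np.vstack(rows)), subject_ids=subject_ids, roi_id=roi_id
    )
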