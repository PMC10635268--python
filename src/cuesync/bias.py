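"""Reverse-correlation content bias and its permutation tests.

Each synchronized TR (index on the post-drop grid) is mapped back to
the 5-second movie clip that preceded it by the hemodynamic lag: for a
TR at post-drop index t, movie time is m = t + tr_offset (restoring the
dropped initial TRs) and the contributing bins are
[m - lag_hi, m - lag_lo), i.e. {m-10, ..., m-6} at the default 5-10 s
window.  The *bias* of a TR set is the fraction of the resulting
*unique* bins that carry the content label (drug bias for drug labels).

Group differences (and group-by-session delta differences) in bias are
tested by comparing the observed statistic against a null built by
redistributing each T* uniformly at random (without replacement) over
the valid TR range, preserving its size.  P-values are two-sided with
the +1 permutation correction, and BH-FDR is applied across ROIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .labels import LabelTrack


@dataclass
class BiasResult:
    """Per-ROI bias statistic with its permutation evidence."""

    statistic: float
    p_value: float
    bias: dict = field(default_factory=dict)
    n_sync: dict = field(default_factory=dict)
    roi_id: int | None = None
    q_value: float | None = None
    n_perm: int = 0
    seed: int = 0

    @property
    def defined(self) -> bool:
        return math.isfinite(self.statistic)


def map_trs_to_bins(
    t_star: Sequence[int] | np.ndarray,
    n_bins: int,
    tr_offset_seconds: int = 10,
    lag_lo: int = 5,
    lag_hi: int = 10,
) -> np.ndarray:
    """Map synchronized TRs to the unique lagged movie bins they imply.

    Bins falling outside [0, n_bins) are discarded.  An empty TR set
    maps to an empty bin set.
    """
    if not lag_hi > lag_lo >= 0:
        raise ValueError("need lag_hi > lag_lo >= 0")
    t = np.asarray(list(t_star), dtype=int)
    if t.size == 0:
        return np.empty(0, dtype=int)
    m = t + int(tr_offset_seconds)
    offsets = np.arange(-lag_hi, -lag_lo)
    bins = (m[:, None] + offsets[None, :]).ravel()
    bins = bins[(bins >= 0) & (bins < n_bins)]
    return np.unique(bins)


def compute_bias(bins: Sequence[int] | np.ndarray, track: LabelTrack) -> float:
    """Fraction of unique bins carrying the label; NaN if no bins."""
    bins = np.unique(np.asarray(list(bins), dtype=int))
    if bins.size == 0:
        return float("nan")
    if bins.min() < 0 or bins.max() >= track.n_bins:
        raise ValueError("bin index outside the label track range")
    return float(track.labels[bins].mean())


def _coverage_bias(
    tr_sets: np.ndarray,
    track: LabelTrack,
    tr_offset_seconds: int,
    lag_lo: int,
    lag_hi: int,
) -> np.ndarray:
    """Vectorized bias for many TR sets: tr_sets is (n_draws, set_size)."""
    n_draws, k = tr_sets.shape
    offsets = np.arange(-lag_hi, -lag_lo)
    bins = (tr_sets[:, :, None] + int(tr_offset_seconds) + offsets[None, None, :]).reshape(
        n_draws, -1
    )
    valid = (bins >= 0) & (bins < track.n_bins)
    covered = np.zeros((n_draws, track.n_bins), dtype=bool)
    rows = np.broadcast_to(np.arange(n_draws)[:, None], bins.shape)
    covered[rows[valid], bins[valid]] = True
    counts = covered.sum(axis=1).astype(float)
    labeled = (covered & (track.labels.astype(bool))[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, labeled / counts, np.nan)


def _random_tr_sets(
    rng: np.random.Generator, n_draws: int, size: int, valid_trs: np.ndarray
) -> np.ndarray:
    """Draw ``n_draws`` TR sets of ``size`` without replacement from valid_trs."""
    n_valid = valid_trs.size
    if size > n_valid:
        raise ValueError("T* larger than the valid TR range")
    u = rng.random((n_draws, n_valid))
    idx = np.argpartition(u, size - 1, axis=1)[:, :size]
    return valid_trs[idx]


def _perm_p(observed: float, null: np.ndarray) -> float:
    null = null[np.isfinite(null)]
    n = null.size
    if n == 0:
        return float("nan")
    extreme = np.sum(np.abs(null) >= abs(observed) - 1e-12)
    return float((1 + extreme) / (n + 1))


def _observed_bias(
    t_star, track: LabelTrack, tr_offset_seconds: int, lag_lo: int, lag_hi: int
) -> float:
    bins = map_trs_to_bins(t_star, track.n_bins, tr_offset_seconds, lag_lo, lag_hi)
    if bins.size == 0:
        return float("nan")
    return compute_bias(bins, track)


def group_difference_test(
    t_star_a,
    t_star_b,
    track: LabelTrack,
    valid_trs: Sequence[int] | np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    tr_offset_seconds: int = 10,
    lag_lo: int = 5,
    lag_hi: int = 10,
    roi_id: int | None = None,
) -> BiasResult:
    """Permutation test of the between-group bias difference.

    statistic = bias(A) - bias(B); the null redistributes each group's
    T* uniformly (preserving its size) over ``valid_trs`` and
    recomputes the statistic ``n_perm`` times.  If either T* is empty,
    the result is undefined (NaN statistic and p) and should be
    excluded from FDR.
    """
    valid_trs = np.asarray(list(valid_trs), dtype=int)
    t_a = np.asarray(list(t_star_a), dtype=int)
    t_b = np.asarray(list(t_star_b), dtype=int)
    bias_a = _observed_bias(t_a, track, tr_offset_seconds, lag_lo, lag_hi)
    bias_b = _observed_bias(t_b, track, tr_offset_seconds, lag_lo, lag_hi)
    result = BiasResult(
        statistic=float("nan"),
        p_value=float("nan"),
        bias={"A": bias_a, "B": bias_b},
        n_sync={"A": int(t_a.size), "B": int(t_b.size)},
        roi_id=roi_id,
        n_perm=n_perm,
        seed=seed,
    )
    if t_a.size == 0 or t_b.size == 0:
        return result
    observed = bias_a - bias_b
    rng = substream(seed, "group-difference", roi_id)
    null_a = _coverage_bias(
        _random_tr_sets(rng, n_perm, t_a.size, valid_trs), track, tr_offset_seconds, lag_lo, lag_hi
    )
    null_b = _coverage_bias(
        _random_tr_sets(rng, n_perm, t_b.size, valid_trs), track, tr_offset_seconds, lag_lo, lag_hi
    )
    result.statistic = float(observed)
    result.p_value = _perm_p(observed, null_a - null_b)
    return result


def session_delta_test(
    t_star: Mapping[tuple[str, str], Sequence[int]],
    track: LabelTrack,
    valid_trs: Sequence[int] | np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    tr_offset_seconds: int = 10,
    lag_lo: int = 5,
    lag_hi: int = 10,
    roi_id: int | None = None,
    groups: tuple[str, str] = ("A", "B"),
    sessions: tuple[str, str] = ("baseline", "followup"),
) -> BiasResult:
    """Permutation test of the group difference in session bias deltas.

    statistic = (bias_base - bias_follow)_A - (bias_base - bias_follow)_B,
    with all four T* sets redistributed independently under the null.
    Undefined (NaN) if any of the four T* sets is empty.
    """
    valid_trs = np.asarray(list(valid_trs), dtype=int)
    ga, gb = groups
    s1, s2 = sessions
    sets = {key: np.asarray(list(t_star[key]), dtype=int) for key in t_star}
    expected = [(ga, s1), (ga, s2), (gb, s1), (gb, s2)]
    for key in expected:
        if key not in sets:
            raise KeyError(f"missing T* for {key}")
    biases = {
        key: _observed_bias(sets[key], track, tr_offset_seconds, lag_lo, lag_hi)
        for key in expected
    }
    result = BiasResult(
        statistic=float("nan"),
        p_value=float("nan"),
        bias={f"{g}_{s}": biases[(g, s)] for g, s in expected},
        n_sync={f"{g}_{s}": int(sets[(g, s)].size) for g, s in expected},
        roi_id=roi_id,
        n_perm=n_perm,
        seed=seed,
    )
    if any(sets[key].size == 0 for key in expected):
        return result
    observed = (biases[(ga, s1)] - biases[(ga, s2)]) - (biases[(gb, s1)] - biases[(gb, s2)])
    rng = substream(seed, "session-delta", roi_id)
    null = {}
    for key in expected:
        null[key] = _coverage_bias(
            _random_tr_sets(rng, n_perm, sets[key].size, valid_trs),
            track,
            tr_offset_seconds,
            lag_lo,
            lag_hi,
        )
    null_stat = (null[(ga, s1)] - null[(ga, s2)]) - (null[(gb, s1)] - null[(gb, s2)])
    result.statistic = float(observed)
    result.p_value = _perm_p(observed, null_stat)
    return result


def fdr_bh(p_values: Sequence[float] | np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q_values, discovery flags).

    NaN p-values (undefined-bias ROIs) are excluded from the correction
    and returned as NaN q with a False flag.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    finite = np.isfinite(p)
    if np.any((p[finite] <= 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q_values = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if finite.any():
        rej, qv, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")
        q_values[finite] = qv
        reject[finite] = rej
    return q_values, reject
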