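"""Small-sample median kernels for the resampling inner loops.

The bootstrap and the phase-randomization null both reduce to "median
over a dozen-odd subjects, for every (draw, TR) cell", which dominates
the cost of calibration experiments.  When numba is importable the
kernels below exploit the structure of each reduction:

* bootstrap medians are weighted medians of the (once-sorted) subject
  values, found by a short cumulative-weight walk per cell;
* the null needs only the maximum over TRs of each surrogate median,
  so each column is first screened against the running maximum (a
  median can exceed ``best`` only if more than half the values do).

Without numba the plain numpy implementations are used.  All kernels
operate in float32; callers convert.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _bootstrap_medians_np(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return np.median(values[idx], axis=1).astype(np.float32)


def _median_max_np(x: np.ndarray) -> np.ndarray:
    return np.median(x, axis=1).max(axis=-1).astype(np.float32)


if _HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=True)
    def _weighted_median_walk(sorted_vals, order, weights, n):
        # median of the resample {value_j with multiplicity weights_j}
        k_lo = (n + 1) // 2
        cum = 0
        i = -1
        while cum < k_lo:
            i += 1
            cum += weights[order[i]]
        v_lo = sorted_vals[i]
        if n % 2 == 1:
            return v_lo
        if cum >= k_lo + 1:
            return v_lo
        j = i
        while cum < k_lo + 1:
            j += 1
            cum += weights[order[j]]
        return np.float32(0.5) * (v_lo + sorted_vals[j])

    @numba.njit(cache=False, fastmath=True)
    def _bootstrap_medians_nb(sorted_vals, order, idx):
        # sorted_vals/order: (n_trs, n); idx: (n_boot, n) resampled subjects
        n_boot, n = idx.shape
        n_trs = sorted_vals.shape[0]
        out = np.empty((n_boot, n_trs), dtype=np.float32)
        weights = np.zeros(n, dtype=np.int64)
        for b in range(n_boot):
            for i in range(n):
                weights[idx[b, i]] += 1
            for t in range(n_trs):
                out[b, t] = _weighted_median_walk(sorted_vals[t], order[t], weights, n)
            for i in range(n):
                weights[idx[b, i]] -= 1
        return out

    @numba.njit(cache=False, fastmath=True)
    def _median_of_buffer(buf, n):
        half = n // 2
        for i in range(half + 1):
            mi = i
            for j in range(i + 1, n):
                if buf[j] < buf[mi]:
                    mi = j
            tmp = buf[i]
            buf[i] = buf[mi]
            buf[mi] = tmp
        if n % 2 == 1:
            return buf[half]
        return np.float32(0.5) * (buf[half] + buf[half - 1])

    @numba.njit(cache=False, fastmath=True)
    def _median_max_nb(x_t):
        # x_t: (n_draws, n_trs, n) contiguous
        n_draws, n_trs, n = x_t.shape
        out = np.empty(n_draws, dtype=np.float32)
        buf = np.empty(n, dtype=np.float32)
        # median > best requires at least this many values above best
        # (odd n: a strict majority; even n: the upper middle value)
        need = n // 2 + (n % 2)
        for d in range(n_draws):
            best = np.float32(-np.inf)
            for t in range(n_trs):
                above = 0
                for i in range(n):
                    if x_t[d, t, i] > best:
                        above += 1
                if above >= need:
                    for i in range(n):
                        buf[i] = x_t[d, t, i]
                    m = _median_of_buffer(buf, n)
                    if m > best:
                        best = m
            out[d] = best
        return out

    def bootstrap_medians(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
        values_t = np.ascontiguousarray(np.asarray(values, dtype=np.float32).T)
        order = np.argsort(values_t, axis=1, kind="stable")
        sorted_vals = np.take_along_axis(values_t, order, axis=1)
        return _bootstrap_medians_nb(
            np.ascontiguousarray(sorted_vals),
            np.ascontiguousarray(order),
            np.ascontiguousarray(idx),
        )

    def median_max(x: np.ndarray) -> np.ndarray:
        x_t = np.ascontiguousarray(np.asarray(x, dtype=np.float32).transpose(0, 2, 1))
        return _median_max_nb(x_t)

else:

    def bootstrap_medians(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return _bootstrap_medians_np(np.asarray(values, dtype=np.float32), idx)

    def median_max(x: np.ndarray) -> np.ndarray:
        return _median_max_np(np.asarray(x, dtype=np.float32))
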