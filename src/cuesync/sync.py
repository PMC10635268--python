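"""Detection of group-synchronized TRs.

A TR is called synchronized when the group's response there is reliably
positive beyond what chance alignment of similarly autocorrelated
signals produces.  Two ingredients:

* a subject-wise bootstrap confidence interval for the group *median*
  signal at every TR (percentile interval over resamples of subjects
  with replacement), and
* a family-wise null built by phase-randomizing every subject's series
  (preserving each amplitude spectrum, hence autocorrelation),
  recomputing the per-TR median, and keeping the *maximum* over TRs of
  each surrogate — so comparing against its 95th percentile controls
  the family-wise error rate over TRs.

A TR enters the significant set T* when the lower CI bound exceeds the
null threshold.  Detection is one-sided (positive deflections) by
default; a mirrored negative test can be enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fast import bootstrap_medians, median_max
from ._rng import substream

_MAX_CHUNK_ELEMENTS = 50_000_000


@dataclass
class SyncResult:
    """Significantly synchronized TRs with their supporting evidence."""

    significant_trs: np.ndarray
    median_trace: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    null_threshold: float
    null_maxima: np.ndarray
    n_boot: int
    n_phase: int
    seed: int
    negative_trs: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "significant_trs": [int(t) for t in self.significant_trs],
            "null_threshold": float(self.null_threshold),
            "n_boot": int(self.n_boot),
            "n_phase": int(self.n_phase),
            "seed": int(self.seed),
        }


def _check_subjects(values: np.ndarray) -> np.ndarray:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] < 2:
        raise ValueError("at least 2 subjects are required (got a single series)")
    if not np.isfinite(values).all():
        raise ValueError("subject series contain non-finite values")
    return values


def bootstrap_median_ci(
    series,
    n_boot: int = 5000,
    level: float = 95.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI for the group median at every TR.

    Resamples subjects with replacement ``n_boot`` times, takes the
    per-TR median of each resample, and returns the (100-level)/2 and
    100-(100-level)/2 percentiles.  Resample medians are computed in
    float32 (the resampling noise dwarfs the rounding).
    """
    values = _check_subjects(getattr(series, "values", series))
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if rng is None:
        rng = substream(seed, "bootstrap")
    n_subj, n_trs = values.shape
    alpha = (100.0 - level) / 2.0

    values32 = values.astype(np.float32)
    chunk = max(1, min(n_boot, _MAX_CHUNK_ELEMENTS // (n_subj * n_trs)))
    medians = np.empty((n_boot, n_trs), dtype=np.float32)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n_subj, size=(b, n_subj))
        medians[done : done + b] = bootstrap_medians(values32, idx)
        done += b
    ci_low, ci_high = np.percentile(medians.astype(float), [alpha, 100.0 - alpha], axis=0)
    return ci_low, ci_high


def phase_randomize(
    series: np.ndarray,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Phase-randomized surrogate of one or more series (last axis = time).

    Takes the FFT, replaces the phase of every strictly-positive,
    non-Nyquist frequency with an independent uniform phase, and
    inverse-transforms.  The amplitude spectrum (hence autocorrelation)
    and the mean are preserved exactly; DC and Nyquist bins are left
    real so the surrogate is real-valued.
    """
    x = np.asarray(series, dtype=float)
    if x.shape[-1] < 4:
        raise ValueError("series must have length >= 4")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    if rng is None:
        rng = substream(seed, "phase")
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    n_freq = spec.shape[-1]
    lo, hi = 1, n_freq - 1 if n % 2 == 0 else n_freq
    phases = np.zeros(spec.shape)
    phases[..., lo:hi] = rng.uniform(0.0, 2.0 * np.pi, size=spec[..., lo:hi].shape)
    return np.fft.irfft(spec * np.exp(1j * phases), n=n, axis=-1)


def null_max_median(
    series,
    n_phase: int = 5000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of the maximum surrogate group median.

    Each draw phase-randomizes every subject independently, computes
    the per-TR median across subjects, and records its maximum over
    TRs.  Returns the ``n_phase`` maxima.  Surrogates are synthesized
    in single precision.
    """
    values = _check_subjects(getattr(series, "values", series))
    if n_phase < 1:
        raise ValueError("n_phase must be >= 1")
    if rng is None:
        rng = substream(seed, "phase")
    n_subj, n_trs = values.shape
    spec = np.fft.rfft(values, axis=-1).astype(np.complex64)
    n_freq = spec.shape[-1]
    lo, hi = 1, n_freq - 1 if n_trs % 2 == 0 else n_freq
    n_rand = hi - lo

    maxima = np.empty(n_phase)
    chunk = max(1, min(n_phase, _MAX_CHUNK_ELEMENTS // (n_subj * max(n_trs, n_freq))))
    done = 0
    while done < n_phase:
        b = min(chunk, n_phase - done)
        shifted = np.broadcast_to(spec, (b, n_subj, n_freq)).copy()
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(b, n_subj, n_rand)).astype(np.float32)
        phasors = np.empty(phases.shape, dtype=np.complex64)
        phasors.real = np.cos(phases)
        phasors.imag = np.sin(phases)
        shifted[..., lo:hi] *= phasors
        surrogates = np.fft.irfft(shifted, n=n_trs, axis=-1)
        maxima[done : done + b] = median_max(surrogates)
        done += b
    return maxima


def find_sync_trs(
    series,
    n_boot: int = 5000,
    n_phase: int = 5000,
    ci_level: float = 95.0,
    null_percentile: float = 95.0,
    seed: int = 0,
    detect_negative: bool = False,
) -> SyncResult:
    """Identify the set T* of significantly synchronized TRs.

    T* = { t : ci_low[t] > null_threshold } with the bootstrap CI and
    the phase-randomized max-median null drawn from independent named
    substreams of ``seed``.  With ``detect_negative``, a mirrored test
    against the minimum-median null fills ``negative_trs``.
    """
    values = _check_subjects(getattr(series, "values", series))
    rng_boot = substream(seed, "bootstrap")
    rng_phase = substream(seed, "phase")
    median_trace = np.median(values, axis=0)
    ci_low, ci_high = bootstrap_median_ci(values, n_boot=n_boot, level=ci_level, rng=rng_boot)
    null_maxima = null_max_median(values, n_phase=n_phase, rng=rng_phase)
    null_threshold = float(np.percentile(null_maxima, null_percentile))
    significant = np.flatnonzero(ci_low > null_threshold)

    negative = None
    if detect_negative:
        neg = find_sync_trs(
            -values,
            n_boot=n_boot,
            n_phase=n_phase,
            ci_level=ci_level,
            null_percentile=null_percentile,
            seed=seed,
            detect_negative=False,
        )
        negative = neg.significant_trs
    return SyncResult(
        significant_trs=significant,
        median_trace=median_trace,
        ci_low=ci_low,
        ci_high=ci_high,
        null_threshold=null_threshold,
        null_maxima=null_maxima,
        n_boot=n_boot,
        n_phase=n_phase,
        seed=seed,
        negative_trs=negative,
    )
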