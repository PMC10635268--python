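"""Named, independent random substreams.

Every stochastic stage of the pipeline draws from its own substream so
that, e.g., changing the number of bootstrap resamples does not perturb
the phase-randomization null drawn under the same top-level seed.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _key_int(token: object) -> int:
    digest = hashlib.sha256(str(token).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    Deterministic in (seed, names); distinct name tuples give streams
    that are independent for all practical purposes (SeedSequence spawn
    keys derived by hashing the names).
    """
    key = tuple(_key_int(n) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def zscore_rows(a: np.ndarray, warn_constant: bool = True) -> np.ndarray:
    """Z-score along the last axis (population SD).

    Constant rows are mapped to all zeros instead of NaN so degenerate
    inputs do not poison downstream arrays; a warning is emitted.
    """
    import warnings

    a = np.asarray(a, dtype=float)
    mean = a.mean(axis=-1, keepdims=True)
    sd = a.std(axis=-1, keepdims=True)
    flat = sd <= 0
    if np.any(flat):
        if warn_constant:
            warnings.warn("constant series z-scored to zeros", RuntimeWarning, stacklevel=2)
        sd = np.where(flat, 1.0, sd)
        out = (a - mean) / sd
        out = np.where(np.broadcast_to(flat, out.shape), 0.0, out)
        return out
    return (a - mean) / sd
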